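"""Post-simulation reporting: NCA summaries, unit handling, plot payloads
and per-compound result stores.

Per-subject PK parameters are extracted model-free (noncompartmental
analysis): AUC by linear-up/log-down trapezoid, the terminal slope by
log-linear regression over the last monotonically declining grid points
after Tmax, Cmax/Tmax by grid maximum.  Population tables carry the
arithmetic mean and sample SD of every parameter.  Each simulated compound
is persisted to its own single-file SQLite store holding the full profiles,
the per-subject parameters, the subject demographics and the assumption
audit trail.
"""

from __future__ import annotations

import math
import re
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pbpk import CompoundSimulation, PredictedParameters
from .physiology import REPORTING_TISSUES

__all__ = [
    "PKSummary",
    "PlotData",
    "nca_terminal_phase",
    "auc_linear_up_log_down",
    "extract_pk_summary",
    "summarize_population",
    "convert_units",
    "make_plot_data",
    "write_result_store",
    "read_store_table",
]

#: minimum terminal points for a log-linear fit
MIN_TERMINAL_POINTS = 3
#: coefficient of determination below which the half-life is unreliable
TERMINAL_R2_FLAG = 0.9
#: dosing-interval convention for the single-dose accumulation index
ACCUMULATION_TAU_H = 24.0


# ---------------------------------------------------------------------------
# NCA primitives
# ---------------------------------------------------------------------------


def auc_linear_up_log_down(time_h: np.ndarray, conc: np.ndarray) -> float:
    """AUC by the linear-up/log-down trapezoid rule."""
    auc = 0.0
    for i in range(len(time_h) - 1):
        dt = time_h[i + 1] - time_h[i]
        c1, c2 = conc[i], conc[i + 1]
        if c1 > 0 and 0 < c2 < c1:
            auc += dt * (c1 - c2) / math.log(c1 / c2)
        else:
            auc += dt * (c1 + c2) / 2.0
    return float(auc)


def nca_terminal_phase(
    time_h: np.ndarray, conc: np.ndarray
) -> tuple[Optional[float], Optional[float], bool]:
    """Terminal elimination rate constant by log-linear regression.

    Candidate points are the strictly decreasing positive run at the end of
    the profile after the global Tmax; among windows of the last 3..n of
    those points the fit with the highest R² wins (more points break ties).
    Returns ``(kel, r_squared, reliable)`` where ``reliable`` is the
    R² >= 0.9 flag; ``(None, None, False)`` marks a non-identifiable phase
    (fewer than 3 qualifying points or a non-negative slope), e.g. a
    compound still absorbing at the end of the run.
    """
    i_max = int(np.argmax(conc))
    end = len(conc)
    start = end - 1
    while start - 1 > i_max and conc[start - 1] > conc[start] > 0:
        start -= 1
    t_run = time_h[start:end]
    c_run = conc[start:end]
    mask = c_run > 0
    t_run, c_run = t_run[mask], c_run[mask]
    if len(t_run) < MIN_TERMINAL_POINTS:
        return None, None, False
    log_c = np.log(c_run)
    best: Optional[tuple[float, float, int]] = None  # (r2, kel, n)
    for n in range(MIN_TERMINAL_POINTS, len(t_run) + 1):
        slope, _, r, _, _ = stats.linregress(t_run[-n:], log_c[-n:])
        if slope >= 0:
            continue
        r2 = float(r * r)
        if best is None or r2 > best[0] + 1e-12 or (
            abs(r2 - best[0]) <= 1e-12 and n > best[2]
        ):
            best = (r2, float(-slope), n)
    if best is None:
        return None, None, False
    r2, kel, _ = best
    return kel, r2, r2 >= TERMINAL_R2_FLAG


# ---------------------------------------------------------------------------
# per-subject summary
# ---------------------------------------------------------------------------


@dataclass
class PKSummary:
    """Per-subject rows plus the population mean/SD table for one compound."""

    code: str
    per_subject: pd.DataFrame
    population: pd.DataFrame


def extract_pk_summary(
    sim: CompoundSimulation,
    predicted: Optional[PredictedParameters] = None,
) -> pd.DataFrame:
    """One NCA + ledger row per simulated subject.

    Half-life and AUC-to-infinity are left missing (NaN) when the terminal
    phase is not identifiable — never fabricated.
    """
    rows = []
    ledger = sim.ledger.set_index("subject_id")
    for series in sim.series:
        t = series.time_h
        plasma = series.conc["plasma"]
        led = ledger.loc[series.subject_id]

        auc = auc_linear_up_log_down(t, plasma)
        kel, r2, reliable = nca_terminal_phase(t, plasma)
        if kel is not None:
            half_life = math.log(2.0) / kel
            auc_inf = auc + float(plasma[-1]) / kel
            accumulation = 1.0 / (1.0 - math.exp(-kel * ACCUMULATION_TAU_H))
        else:  # non-identifiable terminal phase: missing, never fabricated
            half_life = math.nan
            auc_inf = math.nan
            accumulation = math.nan

        row: dict[str, object] = {
            "subject_id": series.subject_id,
            "auc": auc,
            "auc_inf": auc_inf,
            "tmax_plasma": float(t[int(np.argmax(plasma))]),
            "half_life": half_life,
            "half_life_reliable": bool(reliable),
            "terminal_r2": r2 if r2 is not None else math.nan,
            "accumulation_index": accumulation,
        }
        for tissue in REPORTING_TISSUES:
            row[f"cmax_{tissue}"] = float(np.max(series.conc[tissue]))
        for col in (
            "ka", "fa", "fg", "fh", "vss_pred", "fu_used", "bp_used",
            "cl_h", "cl_r", "cl_tot", "gfr", "age", "bw", "bsa", "dose_mg",
        ):
            row[col] = led[col]
        if predicted is not None:
            row["fu_pred"] = predicted.fu_pred
            row["bp_pred"] = predicted.bp_pred
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_population(per_subject: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean and sample SD per parameter across the population.

    Missing values are excluded pairwise; the count of contributing subjects
    is reported per parameter.  With a single subject the SD is missing.
    """
    records = []
    for col in per_subject.columns:
        if col == "subject_id":
            continue
        values = pd.to_numeric(per_subject[col], errors="coerce").dropna()
        records.append(
            {
                "parameter": col,
                "mean": float(values.mean()) if len(values) else math.nan,
                "sd": float(values.std(ddof=1)) if len(values) >= 2 else math.nan,
                "n": int(len(values)),
            }
        )
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# units
# ---------------------------------------------------------------------------


def convert_units(
    values: np.ndarray | float,
    mw: Optional[float],
    source: str = "ng/mL",
    target: str = "µM",
):
    """Convert concentrations between ng/mL and µM via the molecular weight."""
    for unit in (source, target):
        if unit not in ("ng/mL", "µM", "uM"):
            raise ValueError(f"unknown concentration unit {unit!r}")
    source = "µM" if source == "uM" else source
    target = "µM" if target == "uM" else target
    if source == target:
        return values
    if mw is None or mw <= 0:
        raise ValueError("molecular weight required for unit conversion")
    if source == "ng/mL":  # ng/mL -> µM: (ng/mL) / (g/mol) = nmol/mL = µM
        return values / mw
    return values * mw


# ---------------------------------------------------------------------------
# plot payloads
# ---------------------------------------------------------------------------


@dataclass
class PlotData:
    """Serializable payload for any front end (variant + series + annotations)."""

    variant: str  # profile | relationship | distribution | comparison
    payload: dict
    annotations: dict = field(default_factory=dict)


PROFILE_SUBJECT_CAP = 30


def _check_parameter(name: str, frame: pd.DataFrame) -> None:
    valid = [c for c in frame.columns if c != "subject_id"]
    if name not in valid:
        raise ValueError(
            f"unknown parameter {name!r}; available parameters: "
            + ", ".join(sorted(valid))
        )


def make_plot_data(variant: str, **kwargs) -> PlotData:
    """Build one of the four plot payloads.

    profile       — sim=CompoundSimulation, tissue, scale ('natural'|'log'),
                    units ('ng/mL'|'µM'), mw (for µM), seed (subsampling)
    relationship  — summary=per-subject DataFrame, x, y
    distribution  — summary=per-subject DataFrame, parameter
    comparison    — population_means={code: per-subject DataFrame} or
                    {code: float}, parameter, order ('alphanumeric'|'ascending')
    """
    if variant == "profile":
        return _profile_payload(**kwargs)
    if variant == "relationship":
        return _relationship_payload(**kwargs)
    if variant == "distribution":
        return _distribution_payload(**kwargs)
    if variant == "comparison":
        return _comparison_payload(**kwargs)
    raise ValueError(
        f"unknown plot variant {variant!r}; expected profile, relationship, "
        "distribution or comparison"
    )


def _profile_payload(
    sim: CompoundSimulation,
    tissue: str = "plasma",
    scale: str = "natural",
    units: str = "ng/mL",
    mw: Optional[float] = None,
    seed: Optional[int] = None,
) -> PlotData:
    if tissue not in REPORTING_TISSUES:
        raise ValueError(
            f"unknown tissue {tissue!r}; available: {', '.join(REPORTING_TISSUES)}"
        )
    if scale not in ("natural", "log"):
        raise ValueError("scale must be 'natural' or 'log'")
    series_list = sim.series
    # at most 30 subjects, subsampled reproducibly with the run seed
    if len(series_list) > PROFILE_SUBJECT_CAP:
        rng = np.random.default_rng(seed)
        chosen = rng.choice(len(series_list), size=PROFILE_SUBJECT_CAP, replace=False)
        series_list = [series_list[i] for i in sorted(chosen)]
    traces = {}
    for series in series_list:
        conc = series.conc[tissue]
        if units in ("µM", "uM"):
            conc = convert_units(conc, mw, "ng/mL", "µM")
        traces[int(series.subject_id)] = {
            "time_h": series.time_h.tolist(),
            "conc": np.asarray(conc).tolist(),
        }
    return PlotData(
        variant="profile",
        payload={"code": sim.code, "tissue": tissue, "traces": traces},
        annotations={"scale": scale, "units": units},
    )


def _relationship_payload(summary: pd.DataFrame, x: str, y: str) -> PlotData:
    _check_parameter(x, summary)
    _check_parameter(y, summary)
    sub = summary[[x, y]].dropna()
    xv = sub[x].to_numpy(dtype=float)
    yv = sub[y].to_numpy(dtype=float)
    if len(xv) >= 2 and np.std(xv) > 0 and np.std(yv) > 0:
        r = float(stats.pearsonr(xv, yv)[0])
    else:
        r = math.nan
    slope, intercept = (
        np.polyfit(xv, yv, 1) if len(xv) >= 2 and np.std(xv) > 0 else (math.nan, math.nan)
    )
    return PlotData(
        variant="relationship",
        payload={"x": xv.tolist(), "y": yv.tolist(), "x_name": x, "y_name": y},
        annotations={"r": r, "slope": float(slope), "intercept": float(intercept)},
    )


def _distribution_payload(summary: pd.DataFrame, parameter: str) -> PlotData:
    _check_parameter(parameter, summary)
    values = pd.to_numeric(summary[parameter], errors="coerce").dropna().to_numpy()
    if len(values) < 2 or np.std(values) == 0:
        raise ValueError(
            f"cannot build a density for {parameter!r}: fewer than two distinct values"
        )
    kde = stats.gaussian_kde(values, bw_method="silverman")
    span = values.max() - values.min()
    grid = np.linspace(values.min() - 0.5 * span, values.max() + 0.5 * span, 512)
    return PlotData(
        variant="distribution",
        payload={"grid": grid.tolist(), "density": kde(grid).tolist()},
        annotations={"parameter": parameter, "n": int(len(values))},
    )


def _comparison_payload(
    population_means: dict[str, float], parameter: str, order: str = "alphanumeric"
) -> PlotData:
    if order not in ("alphanumeric", "ascending"):
        raise ValueError("order must be 'alphanumeric' or 'ascending'")
    items = list(population_means.items())
    if order == "alphanumeric":
        items.sort(key=lambda kv: kv[0])
    else:
        items.sort(key=lambda kv: kv[1])
    return PlotData(
        variant="comparison",
        payload={"codes": [k for k, _ in items], "values": [v for _, v in items]},
        annotations={"parameter": parameter, "order": order},
    )


# ---------------------------------------------------------------------------
# result stores
# ---------------------------------------------------------------------------


def sanitize_code(code: str) -> str:
    """Filesystem-safe variant of a compound code."""
    return re.sub(r"[^A-Za-z0-9._-]", "_", code)


def write_result_store(
    directory: str | Path,
    sim: CompoundSimulation,
    per_subject: pd.DataFrame,
    demographics: pd.DataFrame,
    assumptions: Sequence[str] = (),
) -> Path:
    """Persist one compound's complete results to its own SQLite file.

    Tables: ``profiles`` (all tissues, all subjects), ``parameters``
    (per-subject NCA + ledger), ``demographics``, ``assumptions`` and
    ``ledger`` (clearance/absorption audit).  Returns the file path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    safe = sanitize_code(sim.code)
    path = directory / f"{safe}.sqlite"
    if path.exists():
        path.unlink()

    frames = []
    for series in sim.series:
        for tissue in REPORTING_TISSUES:
            frames.append(
                pd.DataFrame(
                    {
                        "subject_id": series.subject_id,
                        "tissue": tissue,
                        "time_h": series.time_h,
                        "conc_ng_ml": series.conc[tissue],
                    }
                )
            )
    profiles = pd.concat(frames, ignore_index=True)

    with sqlite3.connect(path) as conn:
        profiles.to_sql("profiles", conn, index=False)
        per_subject.to_sql("parameters", conn, index=False)
        demographics.to_sql("demographics", conn, index=False)
        sim.ledger.to_sql("ledger", conn, index=False)
        pd.DataFrame({"assumption": list(assumptions)}).to_sql(
            "assumptions", conn, index=False
        )
    return path


def read_store_table(path: str | Path, table: str) -> pd.DataFrame:
    """Read one table back from a result store."""
    with sqlite3.connect(path) as conn:
        return pd.read_sql(f"SELECT * FROM {table}", conn)
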