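"""Offline snapshot fixtures and the end-to-end batch workflow.

The fixture generator builds a synthetic SQLite snapshot (five tables) plus
matching compound/experimental files, with controlled per-compound data
availability:

* **rich** — complete physicochemical record in the ChEMBL-like table and at
  least two of fu/BP/CLint across the experimental tables;
* **medium** — complete physicochemical record, CLint only (fu and BP
  missing, to be predicted);
* **poor** — present only in the SusDat-like table (MW and LogP), no
  experimental data at all, so the renal-only clearance fallback engages.

Every planted value is recorded in a *truth table* so curation can be
checked against an independent precedence oracle.  All sampling is
deterministic under the fixture seed.  Identifiers (InChIKeys, CAS, DTXSID)
are synthetic stand-ins shaped like the real thing.

``run_workflow`` drives the whole pipeline: parse -> collect -> assume ->
predict -> simulate -> persist, skipping compounds without physicochemical
data and recording (not raising) per-compound simulation failures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import data_collection as dc
from . import io_schemas as ios
from .assumptions import AssumptionSettings, SimReadyCompound, prepare_sim_ready
from .pbpk import (
    CompoundSimulation,
    SimulationConfig,
    SimulationError,
    predict_parameters,
    simulate_compound,
)
from .physiology import generate_population, population_frame
from .reporting import (
    extract_pk_summary,
    summarize_population,
    write_result_store,
)

__all__ = [
    "FixtureSpec",
    "FixturePaths",
    "build_snapshot_fixture",
    "WorkflowConfig",
    "WorkflowResult",
    "run_workflow",
]


# ---------------------------------------------------------------------------
# fixture generation
# ---------------------------------------------------------------------------


@dataclass
class FixtureSpec:
    """Composition of a synthetic batch (defaults mirror the nine-compound
    exemplar: four rich, four medium, one poor)."""

    n_compounds: int = 9
    rich_fraction: float = 4 / 9
    medium_fraction: float = 4 / 9
    poor_fraction: float = 1 / 9
    seed: int = 3

    def __post_init__(self) -> None:
        fractions = (self.rich_fraction, self.medium_fraction, self.poor_fraction)
        if any(f < 0 for f in fractions):
            raise ValueError("tier fractions must be non-negative")
        if abs(sum(fractions) - 1.0) > 1e-9:
            raise ValueError("tier fractions must sum to 1")
        if self.n_compounds < 1:
            raise ValueError("n_compounds must be >= 1")

    @property
    def tier_counts(self) -> tuple[int, int, int]:
        n = self.n_compounds
        n_rich = round(self.rich_fraction * n)
        n_medium = round(self.medium_fraction * n)
        n_poor = n - n_rich - n_medium
        if n_poor < 0:
            n_medium += n_poor
            n_poor = 0
        return n_rich, n_medium, n_poor


@dataclass
class FixturePaths:
    snapshot: Path
    compound_file: Path
    truth_table: Path


_INCHI_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def _fake_inchikey(rng: np.random.Generator) -> str:
    # synthetic stand-in shaped like a real InChIKey
    block1 = "".join(rng.choice(list(_INCHI_ALPHABET), size=14))
    block2 = "".join(rng.choice(list(_INCHI_ALPHABET), size=10))
    return f"{block1}-{block2}-N"


def build_snapshot_fixture(
    spec: FixtureSpec, directory: str | Path
) -> tuple[FixturePaths, pd.DataFrame]:
    """Write the snapshot SQLite, the compound CSV and the truth table.

    Returns the paths and the truth table: one row per planted value
    ``(code, tier, field, source, value)``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    n_rich, n_medium, n_poor = spec.tier_counts
    tiers = ["rich"] * n_rich + ["medium"] * n_medium + ["poor"] * n_poor

    snapshot_path = directory / "snapshot.sqlite"
    if snapshot_path.exists():
        snapshot_path.unlink()
    conn = dc.SnapshotDB.create(snapshot_path)

    records: list[ios.CompoundRecord] = []
    truth_rows: list[dict] = []

    def plant(code: str, tier: str, fieldname: str, source: str, value) -> None:
        truth_rows.append(
            {"code": code, "tier": tier, "field": fieldname, "source": source,
             "value": value}
        )

    for i, tier in enumerate(tiers, start=1):
        code = f"A{i}"
        inchikey = _fake_inchikey(rng)
        cas = f"{rng.integers(100, 99999)}-{rng.integers(10, 99)}-{rng.integers(0, 9)}"
        dtxsid = f"DTXSID{rng.integers(1000000, 9999999)}"
        records.append(
            ios.CompoundRecord(code=code, name=f"Compound-{i}", inchikey=inchikey)
        )

        if tier == "poor":
            # the data-poor tier emulates a small hydrophilic organic acid
            # (butoxyacetic-acid-like): low MW/LogP, renal-dominated kinetics
            mw = float(np.round(rng.uniform(100.0, 200.0), 2))
            logp = float(np.round(rng.uniform(-0.5, 1.5), 2))
        else:
            mw = float(np.round(rng.uniform(100.0, 450.0), 2))
            logp = float(np.round(rng.uniform(0.0, 4.5), 2))
        psa = float(np.round(rng.uniform(20.0, 150.0), 1))
        hbd = int(rng.integers(0, 5))
        n_pka = int(rng.integers(0, 3))
        pkas = sorted(float(np.round(rng.uniform(2.0, 11.0), 2)) for _ in range(n_pka))

        if tier == "poor":
            conn.execute(
                "INSERT INTO susdat VALUES (?,?,?,?,?,?)",
                (inchikey, mw, logp, cas, dtxsid, None),
            )
            plant(code, tier, "mw", "susdat", mw)
            plant(code, tier, "logp", "susdat", logp)
            plant(code, tier, "cas", "susdat", cas)
            plant(code, tier, "dtxsid", "susdat", dtxsid)
            continue

        # rich/medium: full physicochemical record in the ChEMBL-like table,
        # identifiers additionally present in the SusDat-like table
        conn.execute(
            "INSERT INTO chembl VALUES (?,?,?,?,?,?,?,?,?)",
            (inchikey, mw, logp, dc.encode_pka_list(pkas) or None, None, psa,
             hbd, None, None),
        )
        conn.execute(
            "INSERT INTO susdat VALUES (?,?,?,?,?,?)",
            (inchikey, mw, logp, cas, dtxsid, None),
        )
        plant(code, tier, "mw", "chembl", mw)
        plant(code, tier, "logp", "chembl", logp)
        plant(code, tier, "psa", "chembl", psa)
        plant(code, tier, "hbd", "chembl", hbd)
        if pkas:
            plant(code, tier, "pka_values", "chembl", dc.encode_pka_list(pkas))
        plant(code, tier, "cas", "susdat", cas)
        plant(code, tier, "dtxsid", "susdat", dtxsid)

        clint = float(np.round(rng.uniform(2.0, 60.0), 2))
        conn.execute(
            "INSERT INTO wambaugh VALUES (?,?,?,?)", (cas, dtxsid, None, clint)
        )
        plant(code, tier, "clint", "wambaugh", clint)

        if tier == "rich":
            fu = float(np.round(rng.uniform(0.02, 0.6), 3))
            fu_ob = float(np.round(fu * rng.uniform(0.85, 1.15), 3))
            bp = float(np.round(rng.uniform(0.6, 1.5), 3))
            clint_cp = float(np.round(clint * rng.uniform(0.7, 1.3), 2))
            conn.execute(
                "UPDATE wambaugh SET fu = ? WHERE cas = ?", (fu, cas)
            )
            conn.execute("INSERT INTO obach VALUES (?,?,?)", (cas, fu_ob, None))
            # two replicate rows in the in-vitro table (same source)
            for rep in (0.97, 1.03):
                conn.execute(
                    "INSERT INTO chem_phys VALUES (?,?,?,?,?)",
                    (cas, dtxsid, None, float(np.round(clint_cp * rep, 3)),
                     float(np.round(bp * rep, 3))),
                )
            plant(code, tier, "fu", "wambaugh", fu)
            plant(code, tier, "fu", "obach", fu_ob)
            plant(code, tier, "clint", "chem_phys", clint_cp)
            plant(code, tier, "bp", "chem_phys", bp)

    conn.commit()
    conn.close()

    compound_path = directory / "compounds.csv"
    ios.write_compound_file(records, compound_path)
    truth = pd.DataFrame(truth_rows)
    truth_path = directory / "truth.csv"
    truth.to_csv(truth_path, index=False)
    return FixturePaths(snapshot_path, compound_path, truth_path), truth


# ---------------------------------------------------------------------------
# end-to-end workflow
# ---------------------------------------------------------------------------


@dataclass
class WorkflowConfig:
    """Declarative configuration of one batch run."""

    compound_file: str | Path = ""
    snapshot: str | Path = ""
    output_dir: str | Path = "results"
    experimental_file: Optional[str | Path] = None
    additional_file: Optional[str | Path] = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    assumptions: AssumptionSettings = field(default_factory=AssumptionSettings)
    db_flags: Optional[dict[str, bool]] = None
    fu_operation: Optional[str] = "arithmetic mean"
    clint_operation: Optional[str] = "arithmetic mean"
    mean_flag: bool = False
    thresholds: Optional[dict[str, float]] = None
    override_additional: bool = False
    run_prediction: bool = True
    run_simulation: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "WorkflowConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        assume = AssumptionSettings(**raw.pop("assumptions", {}))
        return cls(simulation=sim, assumptions=assume, **raw)


@dataclass
class WorkflowResult:
    curated: dict[str, dc.CuratedParameters]
    sim_ready: dict[str, SimReadyCompound]
    predictions: Optional[pd.DataFrame]
    simulations: dict[str, CompoundSimulation]
    summaries: dict[str, pd.DataFrame]  # per-subject parameter rows
    population_summaries: dict[str, pd.DataFrame]
    store_paths: dict[str, Path]
    skipped: dict[str, str]  # code -> reason
    errors: dict[str, str]  # code -> simulation error message
    warnings: list[str]

    @property
    def summary_table(self) -> pd.DataFrame:
        """One row per compound: population mean/SD of every parameter."""
        frames = []
        for code, pop in self.population_summaries.items():
            wide: dict[str, object] = {"code": code}
            for _, row in pop.iterrows():
                wide[f"{row['parameter']}_mean"] = row["mean"]
                wide[f"{row['parameter']}_sd"] = row["sd"]
            frames.append(wide)
        return pd.DataFrame(frames)


def run_workflow(config: WorkflowConfig) -> WorkflowResult:
    """Execute collection -> assumptions -> prediction -> simulation -> stores.

    Compounds without any physicochemical data are skipped with a logged
    reason; a failing per-compound simulation is recorded and the batch
    continues.  Configuration and schema errors raise immediately.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not out_dir.is_dir():
        raise dc.ConfigError(f"output directory {out_dir} is not writable")
    warnings: list[str] = []

    records, w = ios.parse_compound_file(config.compound_file)
    warnings.extend(w)

    with dc.SnapshotDB(config.snapshot) as snapshot:
        table, not_found, _ = dc.collect_physchem(records, snapshot)
        if not_found:
            warnings.append(
                "not found in any physicochemical source: " + ", ".join(not_found)
            )
        if config.additional_file:
            add_rows, w = ios.parse_additional_file(config.additional_file)
            warnings.extend(w)
            warnings.extend(
                dc.merge_additional(table, add_rows, config.override_additional)
            )
        warnings.extend(
            dc.collect_experimental(
                table, snapshot, config.db_flags,
                config.fu_operation, config.clint_operation,
            )
        )
        if config.experimental_file:
            exp_rows, w = ios.parse_experimental_file(
                config.experimental_file, known_codes={r.code for r in records}
            )
            warnings.extend(w)
            warnings.extend(
                dc.merge_user_experimental(
                    table, exp_rows, config.mean_flag, config.thresholds
                )
            )

    dc.export_curated_table(table, out_dir / "curated_data.csv")

    sim_ready: dict[str, SimReadyCompound] = {}
    skipped: dict[str, str] = {}
    for code, row in table.items():
        if not row.inchikey:
            skipped[code] = "no InChIKey: compound will not be simulated"
            continue
        if row.mw is None or row.logp is None:
            skipped[code] = "no physicochemical data: compound will not be simulated"
            continue
        sim_ready[code] = prepare_sim_ready(row, config.assumptions)

    predictions: Optional[pd.DataFrame] = None
    if config.run_prediction:
        pred_rows = []
        for cmpd in sim_ready.values():
            pred = predict_parameters(cmpd)
            pred_rows.append(
                {
                    "code": pred.code,
                    "fu_pred": pred.fu_pred,
                    "bp_pred": pred.bp_pred,
                    "vss_pred": pred.vss_pred,
                    "kd_hsa": pred.kd_hsa,
                    "kd_agp": pred.kd_agp,
                }
            )
        predictions = pd.DataFrame(pred_rows)
        predictions.to_csv(out_dir / "predictions.csv", index=False)

    simulations: dict[str, CompoundSimulation] = {}
    summaries: dict[str, pd.DataFrame] = {}
    population_summaries: dict[str, pd.DataFrame] = {}
    store_paths: dict[str, Path] = {}
    errors: dict[str, str] = {}

    if config.run_simulation and sim_ready:
        sim_cfg = config.simulation
        shared_subjects = (
            generate_population(sim_cfg.n_subjects, sim_cfg.seed)
            if sim_cfg.seed is not None
            else None
        )
        for code, cmpd in sim_ready.items():
            subjects = (
                shared_subjects
                if shared_subjects is not None
                else generate_population(sim_cfg.n_subjects)
            )
            try:
                sim = simulate_compound(cmpd, sim_cfg, subjects)
            except SimulationError as exc:  # batch robustness: record, continue
                errors[code] = str(exc)
                continue
            simulations[code] = sim
            predicted = predict_parameters(cmpd)
            per_subject = extract_pk_summary(sim, predicted)
            summaries[code] = per_subject
            population_summaries[code] = summarize_population(per_subject)
            store_paths[code] = write_result_store(
                out_dir / "stores",
                sim,
                per_subject,
                population_frame(subjects),
                cmpd.assumptions_applied,
            )

        result = WorkflowResult(
            curated=table, sim_ready=sim_ready, predictions=predictions,
            simulations=simulations, summaries=summaries,
            population_summaries=population_summaries, store_paths=store_paths,
            skipped=skipped, errors=errors, warnings=warnings,
        )
        result.summary_table.to_csv(out_dir / "summary.csv", index=False)
        return result

    return WorkflowResult(
        curated=table, sim_ready=sim_ready, predictions=predictions,
        simulations={}, summaries={}, population_summaries={},
        store_paths={}, skipped=skipped, errors={}, warnings=warnings,
    )
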