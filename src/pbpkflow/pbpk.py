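"""Whole-body PBPK engine: partitioning, prediction and population simulation.

The model is a perfusion-limited whole-body circuit: venous blood -> lung ->
arterial blood -> parallel tissues -> venous blood, with the splanchnic
organs (gut, spleen, pancreas) draining through the portal vein into the
liver.  Kinetics are linear.

Tissue:plasma partition coefficients (Kp) come from tissue-composition
models selectable per compound:

* **Method 1** — Poulin & Theil partitioning with the Berezhkovskiy
  tissue-binding correction; lipophilicity only, ionisation ignored.
* **Method 2** — Rodgers & Rowland composition equations: moderate-to-strong
  bases bind acidic phospholipids (association constant back-calculated from
  the blood-cell partitioning implied by the BP ratio); acids, neutrals and
  weak bases bind extracellular protein.  Only the neutral species crosses
  membranes.
* **Method 3** — as Method 2, but a small fraction of the ionised species
  also partitions into membrane lipids (attenuation factor
  :data:`IONIC_MEMBRANE_FACTOR`); collapses to Method 2 for neutrals.

Clearance follows the availability of hepatic intrinsic clearance (CLint):
with CLint the liver is the only eliminating organ under the well-stirred
assumption; without it the compound is conservatively assumed to be cleared
only renally at CLR = fu * GFR.

Oral absorption is first-order with ka and fa derived from the predicted
jejunal permeability; the intravenous bolus is a 30-second zero-order
infusion into venous blood; dermal dosing uses a single-layer formulation
depot on the back (60 cm², 0.005 cm, 1 g/mL) transferring first-order into
the skin compartment at a Potts-Guy permeation rate.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .assumptions import IonisationType, SimReadyCompound, fraction_unionised_ph74
from .data_collection import ConfigError
from .physiology import (
    PORTAL_TISSUES,
    REPORTING_TISSUES,
    TISSUES,
    SubjectPhysiology,
    generate_population,
    reference_subject,
)

__all__ = [
    "SimulationConfig",
    "PredictedParameters",
    "ClearanceModel",
    "SubjectSeries",
    "CompoundSimulation",
    "SimulationError",
    "predict_parameters",
    "compute_kp_vss",
    "select_clearance_model",
    "resolve_dose",
    "simulate_compound",
    "generate_population",
]


# ---------------------------------------------------------------------------
# run configuration (user-modifiable parameters and their defaults)
# ---------------------------------------------------------------------------

ROUTES = ("oral", "dermal", "iv_bolus")

# fixed administration-route constants (not user-settable)
IV_INFUSION_S = 30.0
DERMAL_SITE = "back"
DERMAL_AREA_CM2 = 60.0
DERMAL_THICKNESS_CM = 0.005
DERMAL_DENSITY_G_PER_ML = 1.0

OUTPUT_GRID_STEP_H = 0.1
# the intravenous route adds a refined sampling window so the short infusion
# peak (and hence AUC) is resolved on the output grid
IV_EARLY_WINDOW_H = 0.5
IV_EARLY_STEP_H = 0.002
ODE_RTOL = 1e-8
ODE_ATOL = 1e-10


@dataclass
class SimulationConfig:
    """Batch-level trial design (defaults are the standard run settings)."""

    route: str = "oral"
    dose: float = 100.0
    dose_units: str = "mg"
    vss_method: int = 3
    n_subjects: int = 10
    duration_h: float = 24.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.route not in ROUTES:
            raise ConfigError(f"route must be one of {ROUTES} (got {self.route!r})")
        if self.dose <= 0:
            raise ConfigError(f"dose must be > 0 (got {self.dose})")
        if self.dose_units not in ("mg", "mg/kg", "mg.m-2"):
            raise ConfigError(f"dose units must be mg, mg/kg or mg.m-2")
        if self.vss_method not in (1, 2, 3):
            raise ConfigError(f"vss_method must be 1, 2 or 3 (got {self.vss_method})")
        if not 1 <= self.n_subjects <= 1000:
            raise ConfigError(
                f"n_subjects must be in [1, 1000] (got {self.n_subjects})"
            )
        if self.duration_h < 4 or round(self.duration_h * 2) != self.duration_h * 2:
            raise ConfigError(
                "duration must be >= 4 h in 0.5-h increments "
                f"(got {self.duration_h})"
            )


class ClearanceModel(str, enum.Enum):
    HEPATIC_WELLSTIRRED = "hepatic_wellstirred"
    RENAL_ONLY = "renal_only"


class SimulationError(RuntimeError):
    """ODE integration failed for one compound/subject."""


# ---------------------------------------------------------------------------
# tissue composition (fractional volumes; acidic phospholipids in mg/g)
# ---------------------------------------------------------------------------

# columns: f_ew (extracellular water), f_iw (intracellular water),
#          f_nl (neutral lipid), f_np (neutral phospholipid),
#          ap (acidic phospholipid, mg/g), alb (tissue:plasma albumin ratio)
TISSUE_COMPOSITION: dict[str, dict[str, float]] = {
    "adipose":  {"f_ew": 0.135, "f_iw": 0.017, "f_nl": 0.853,  "f_np": 0.0016, "ap": 0.40, "alb": 0.037},
    "brain":    {"f_ew": 0.162, "f_iw": 0.620, "f_nl": 0.039,  "f_np": 0.0015, "ap": 0.40, "alb": 0.048},
    "gut":      {"f_ew": 0.282, "f_iw": 0.475, "f_nl": 0.038,  "f_np": 0.0125, "ap": 2.41, "alb": 0.158},
    "heart":    {"f_ew": 0.320, "f_iw": 0.456, "f_nl": 0.014,  "f_np": 0.0111, "ap": 2.25, "alb": 0.157},
    "kidney":   {"f_ew": 0.273, "f_iw": 0.483, "f_nl": 0.012,  "f_np": 0.0242, "ap": 5.03, "alb": 0.130},
    "liver":    {"f_ew": 0.161, "f_iw": 0.573, "f_nl": 0.014,  "f_np": 0.0240, "ap": 4.56, "alb": 0.086},
    "lung":     {"f_ew": 0.336, "f_iw": 0.446, "f_nl": 0.022,  "f_np": 0.0128, "ap": 3.91, "alb": 0.212},
    "muscle":   {"f_ew": 0.118, "f_iw": 0.630, "f_nl": 0.010,  "f_np": 0.0072, "ap": 1.53, "alb": 0.064},
    "pancreas": {"f_ew": 0.120, "f_iw": 0.664, "f_nl": 0.041,  "f_np": 0.0093, "ap": 1.67, "alb": 0.060},
    "skin":     {"f_ew": 0.382, "f_iw": 0.291, "f_nl": 0.060,  "f_np": 0.0044, "ap": 1.32, "alb": 0.277},
    "spleen":   {"f_ew": 0.207, "f_iw": 0.579, "f_nl": 0.0077, "f_np": 0.0113, "ap": 3.18, "alb": 0.097},
    # carcass-like remainder: muscle-like composition
    "rest":     {"f_ew": 0.118, "f_iw": 0.630, "f_nl": 0.010,  "f_np": 0.0072, "ap": 1.53, "alb": 0.064},
}

BLOOD_CELLS = {"f_iw": 0.603, "f_nl": 0.0017, "f_np": 0.0029, "ap": 0.50}
PLASMA = {"f_w": 0.945, "f_nl": 0.0023, "f_np": 0.0013}

PH_PLASMA = 7.4
PH_INTRACELLULAR = 7.0
PH_BLOOD_CELLS = 7.22

#: fraction of ionised species allowed into membrane lipids under Method 3
IONIC_MEMBRANE_FACTOR = 0.05

# plasma binding-protein concentrations (µM) used for Kd back-calculation
HSA_PLASMA_UM = 646.0  # 43 g/L / 66.5 kDa
AGP_PLASMA_UM = 22.0  # 0.9 g/L / 41 kDa

# fu prediction: logit-linear lipophilicity regression (acids/ampholytes use
# logD7.4, bases/neutrals logP, mirroring the binding conventions elsewhere)
FU_PRED_SLOPE = 0.52
FU_PRED_INTERCEPT = -0.20

# oral absorption geometry (first-order model)
SMALL_INTESTINE_RADIUS_CM = 1.75
SMALL_INTESTINE_TRANSIT_H = 3.32

# hepatocyte scaling
HEPATOCELLULARITY_CELLS_PER_G = 99.0  # 10^6 cells per g liver


# ---------------------------------------------------------------------------
# ionisation helpers
# ---------------------------------------------------------------------------


def _ionisation_ratio(
    ion_type: IonisationType, pka_selected: Sequence[float], ph: float
) -> float:
    """Total ionised:neutral concentration ratio at the given pH."""
    pkas = sorted(pka_selected)
    if ion_type is IonisationType.NEUTRAL or not pkas:
        return 0.0
    if ion_type is IonisationType.MONOPROTIC_ACID:
        return 10 ** (ph - pkas[0])
    if ion_type is IonisationType.MONOPROTIC_BASE:
        return 10 ** (pkas[0] - ph)
    if ion_type is IonisationType.DIPROTIC_ACID:
        pka1, pka2 = pkas
        return 10 ** (ph - pka1) + 10 ** (2 * ph - pka1 - pka2)
    if ion_type is IonisationType.DIPROTIC_BASE:
        low, high = pkas
        return 10 ** (high - ph) + 10 ** (high + low - 2 * ph)
    pka_acid, pka_base = pkas  # ampholyte
    return 10 ** (ph - pka_acid) + 10 ** (pka_base - ph)


def _is_ap_binding_base(cmpd: SimReadyCompound) -> bool:
    """Moderate-to-strong bases partition into acidic phospholipids."""
    return (
        cmpd.type.is_base
        and bool(cmpd.pka_selected)
        and max(cmpd.pka_selected) >= 7.0
    )


# ---------------------------------------------------------------------------
# parameter prediction
# ---------------------------------------------------------------------------


@dataclass
class PredictedParameters:
    """In-silico parameter set computed for every compound regardless of
    measured-data availability (the prediction module ignores measured fu/BP)."""

    code: str
    fu_pred: float
    bp_pred: float
    vss_pred: float  # L/kg
    kd_hsa: float  # µM; inf marks the fu -> 1 infinite-dilution limit
    kd_agp: float


def predict_fu(cmpd: SimReadyCompound) -> float:
    """Fraction unbound in plasma from the lipophilicity logit regression."""
    if cmpd.type.is_acid or cmpd.type is IonisationType.AMPHOLYTE:
        x = cmpd.logd74
    else:
        x = cmpd.logp
    fu = 1.0 / (1.0 + 10 ** (FU_PRED_SLOPE * x + FU_PRED_INTERCEPT))
    return float(min(max(fu, 1e-4), 1.0))


def predict_bp(cmpd: SimReadyCompound, fu: float, hct: float = 0.45) -> float:
    """BP ratio from red-cell partitioning of the unionised unbound fraction.

    BP = (1 - hct) + hct * E:P with E:P = fu * (f_ni * 10^(0.3 logP) + 0.5);
    ionised acids barely enter the cells, so their BP stays near 1 - hct.
    """
    f_ni = fraction_unionised_ph74(cmpd.type, cmpd.pka_selected)
    ep = fu * (f_ni * 10 ** (0.3 * cmpd.logp) + 0.5)
    return float((1.0 - hct) + hct * ep)


def predict_kd(fu: float, protein_um: float) -> float:
    """Equilibrium dissociation constant from the binding isotherm
    Kd = fu*[P]/(1-fu); fu = 1 yields the infinite-dilution marker."""
    if fu >= 1.0:
        return math.inf
    return fu * protein_um / (1.0 - fu)


def resolve_fu_bp(
    cmpd: SimReadyCompound, hct: float = 0.45
) -> tuple[float, str, float, str]:
    """Measured/assumed values win; prediction fills the gaps."""
    if cmpd.fu is not None:
        fu, fu_src = float(cmpd.fu), cmpd.fu_source
    else:
        fu, fu_src = predict_fu(cmpd), "predicted"
    if cmpd.bp is not None:
        bp, bp_src = float(cmpd.bp), cmpd.bp_source
    else:
        bp, bp_src = predict_bp(cmpd, fu, hct), "predicted"
    return fu, fu_src, bp, bp_src


def predict_parameters(
    cmpd: SimReadyCompound, subject: Optional[SubjectPhysiology] = None
) -> PredictedParameters:
    """Run the prediction module for one compound (no simulation involved).

    Predictions are computed from physicochemical data only — measured fu/BP
    values are deliberately ignored, so the module shows what the in-silico
    route would give for every compound.
    """
    subject = subject or reference_subject()
    fu = predict_fu(cmpd)
    bp = predict_bp(cmpd, fu, subject.hct)
    method = cmpd.vss_method or 3
    _, vss = compute_kp_vss(cmpd, method, subject, fu=fu, bp=bp)
    return PredictedParameters(
        code=cmpd.code,
        fu_pred=fu,
        bp_pred=bp,
        vss_pred=vss,
        kd_hsa=predict_kd(fu, HSA_PLASMA_UM),
        kd_agp=predict_kd(fu, AGP_PLASMA_UM),
    )


# ---------------------------------------------------------------------------
# tissue partition coefficients and Vss
# ---------------------------------------------------------------------------


def _lipid_term(p: float, f_nl: float, f_np: float, y: float, method: int) -> float:
    """Membrane-lipid partitioning contribution of one compartment.

    Method 2 admits only the neutral species (denominator 1+y); Method 3 also
    admits an IONIC_MEMBRANE_FACTOR fraction of the ionised species.
    """
    base = p * f_nl + (0.3 * p + 0.7) * f_np
    if method == 3:
        return base * (1.0 + IONIC_MEMBRANE_FACTOR * y) / (1.0 + y)
    return base / (1.0 + y)


def compute_kp_vss(
    cmpd: SimReadyCompound,
    method: int,
    subject: SubjectPhysiology,
    fu: Optional[float] = None,
    bp: Optional[float] = None,
) -> tuple[dict[str, float], float]:
    """Tissue:plasma partition coefficients and Vss (L/kg) for one subject.

    ``fu``/``bp`` default to the measured-else-predicted resolution.  Vss is
    the plasma-referenced steady-state volume
    (V_plasma + V_cells*E:P + sum_t V_t*Kp_t) / BW.
    """
    if method not in (1, 2, 3):
        raise ConfigError(f"unknown Vss prediction method {method!r}")
    if fu is None or bp is None:
        fu_r, _, bp_r, _ = resolve_fu_bp(cmpd, subject.hct)
        fu = fu if fu is not None else fu_r
        bp = bp if bp is not None else bp_r

    p = 10.0 ** cmpd.logp
    kp: dict[str, float] = {}

    if method == 1:
        # Poulin & Theil with Berezhkovskiy tissue-binding correction;
        # lipophilicity only (pKa never enters)
        plasma_term = p * (PLASMA["f_nl"] + 0.3 * PLASMA["f_np"]) + (
            PLASMA["f_w"] + 0.7 * PLASMA["f_np"]
        )
        for tissue, comp in TISSUE_COMPOSITION.items():
            f_w = comp["f_ew"] + comp["f_iw"]
            tissue_term = p * (comp["f_nl"] + 0.3 * comp["f_np"]) + (
                f_w + 0.7 * comp["f_np"]
            )
            if tissue == "adipose":
                fu_t = 1.0
            else:
                fu_t = 1.0 / (1.0 + 0.5 * (1.0 - fu) / fu)
            kp[tissue] = tissue_term / plasma_term * fu / fu_t
    else:
        y_p = _ionisation_ratio(cmpd.type, cmpd.pka_selected, PH_PLASMA)
        if _is_ap_binding_base(cmpd):
            pka_max = max(cmpd.pka_selected)
            # association to acidic phospholipids back-calculated from the
            # blood-cell partitioning implied by the BP ratio
            kpu_bc = max((bp - (1.0 - subject.hct)) / (subject.hct * fu), 1e-6)
            x_bc = 10 ** (pka_max - PH_BLOOD_CELLS)
            ka_ap = (
                kpu_bc
                - (1.0 + x_bc) / (1.0 + y_p) * BLOOD_CELLS["f_iw"]
                - _lipid_term(p, BLOOD_CELLS["f_nl"], BLOOD_CELLS["f_np"], y_p, method)
            ) * (1.0 + y_p) / (BLOOD_CELLS["ap"] * x_bc)
            ka_ap = max(ka_ap, 0.0)
            for tissue, comp in TISSUE_COMPOSITION.items():
                x_t = 10 ** (pka_max - PH_INTRACELLULAR)
                kpu = (
                    comp["f_ew"]
                    + (1.0 + x_t) / (1.0 + y_p) * comp["f_iw"]
                    + ka_ap * comp["ap"] * x_t / (1.0 + y_p)
                    + _lipid_term(p, comp["f_nl"], comp["f_np"], y_p, method)
                )
                kp[tissue] = kpu * fu
        else:
            # acids, neutrals, weak bases: extracellular-protein binding
            plasma_lipid = _lipid_term(p, PLASMA["f_nl"], PLASMA["f_np"], y_p, method)
            ka_pr = max(1.0 / fu - 1.0 - plasma_lipid, 0.0)
            for tissue, comp in TISSUE_COMPOSITION.items():
                y_iw = _ionisation_ratio(
                    cmpd.type, cmpd.pka_selected, PH_INTRACELLULAR
                )
                kpu = (
                    comp["f_ew"]
                    + (1.0 + y_iw) / (1.0 + y_p) * comp["f_iw"]
                    + _lipid_term(p, comp["f_nl"], comp["f_np"], y_p, method)
                    + ka_pr * comp["alb"]
                )
                kp[tissue] = kpu * fu

    ep = max((bp - (1.0 - subject.hct)) / subject.hct, 0.0)
    vss_l = (
        subject.plasma_volume
        + subject.blood_cell_volume * ep
        + sum(subject.tissue_volumes[t] * kp[t] for t in TISSUES)
    )
    return kp, vss_l / subject.bw


# ---------------------------------------------------------------------------
# clearance and dosing
# ---------------------------------------------------------------------------


def select_clearance_model(clint: Optional[float]) -> ClearanceModel:
    """With CLint the liver clears (well-stirred); without it the compound is
    conservatively cleared only renally at CLR = fu * GFR."""
    if clint is None:
        return ClearanceModel.RENAL_ONLY
    return ClearanceModel.HEPATIC_WELLSTIRRED


def whole_liver_clint_l_h(
    clint_ul_min_1e6: float, fu_hep: float, liver_weight_g: float
) -> float:
    """Scale incubation CLint (µL/min/10^6 cells) to unbound whole-liver L/h."""
    per_g = clint_ul_min_1e6 / max(fu_hep, 1e-6) * HEPATOCELLULARITY_CELLS_PER_G
    return per_g * liver_weight_g * 60.0 / 1e6


def wellstirred_hepatic_clearance(
    qh: float, fu_blood: float, clint_whole_l_h: float
) -> float:
    """Well-stirred hepatic blood clearance, bounded above by liver flow."""
    num = qh * fu_blood * clint_whole_l_h
    return num / (qh + fu_blood * clint_whole_l_h)


def resolve_dose(dose: float, units: str, subject: SubjectPhysiology) -> float:
    """Convert a dose in mg, mg/kg or mg.m-2 to absolute mg for a subject."""
    if dose <= 0:
        raise ConfigError(f"dose must be > 0 (got {dose})")
    if units == "mg":
        return float(dose)
    if units == "mg/kg":
        return float(dose * subject.bw)
    if units == "mg.m-2":
        return float(dose * subject.bsa)
    raise ConfigError(f"unknown dose units {units!r}")


def absorption_parameters(peff_1e4_cm_s: float) -> tuple[float, float]:
    """First-order ka (1/h) and fraction absorbed fa from jejunal Peff."""
    peff_cm_h = peff_1e4_cm_s * 1e-4 * 3600.0
    ka = 2.0 * peff_cm_h / SMALL_INTESTINE_RADIUS_CM
    fa = 1.0 - math.exp(-ka * SMALL_INTESTINE_TRANSIT_H)
    return ka, fa


def dermal_transfer_rate(logp: float, mw: float) -> float:
    """First-order formulation->skin rate (1/h) from Potts-Guy permeation."""
    log_kp_cm_h = -2.7 + 0.71 * logp - 0.0061 * mw
    kp_cm_h = 10.0 ** log_kp_cm_h
    return kp_cm_h / DERMAL_THICKNESS_CM


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


@dataclass
class SubjectSeries:
    """Concentration-time grid for one subject (ng/mL per reporting tissue)."""

    subject_id: int
    time_h: np.ndarray
    conc: dict[str, np.ndarray]
    mass_balance_rel_err: float


@dataclass
class CompoundSimulation:
    """All per-subject series plus the clearance/absorption ledger."""

    code: str
    series: list[SubjectSeries]
    ledger: "object"  # pandas.DataFrame, one row per subject
    clearance_model: ClearanceModel
    config: SimulationConfig


def _state_index() -> dict[str, int]:
    idx = {"depot": 0, "sink": 1, "venous": 2, "arterial": 3}
    for i, t in enumerate(TISSUES):
        idx[t] = 4 + i
    idx["eliminated_h"] = 4 + len(TISSUES)
    idx["eliminated_r"] = 5 + len(TISSUES)
    return idx


_IDX = _state_index()
_N_STATES = len(_IDX)
_NONPORTAL = tuple(
    t for t in TISSUES if t not in PORTAL_TISSUES and t not in ("lung", "liver")
)


def _rhs_factory(
    subject: SubjectPhysiology,
    kp_blood: dict[str, float],
    route: str,
    ka: float,
    fa: float,
    k_dermal: float,
    cl_uint: float,
    fu_blood: float,
    clr_blood: float,
    infusion_rate: float,
):
    q = subject.tissue_flows
    v = subject.tissue_volumes
    co = subject.cardiac_output
    v_ven = subject.blood_volume * 2.0 / 3.0
    v_art = subject.blood_volume / 3.0
    qh_total = subject.qh
    idx = _IDX

    def rhs(t: float, a: np.ndarray) -> np.ndarray:
        da = np.zeros(_N_STATES)
        c_ven = a[idx["venous"]] / v_ven
        c_art = a[idx["arterial"]] / v_art

        # lung in series with the blood pool
        c_lung_out = a[idx["lung"]] / (v["lung"] * kp_blood["lung"])
        da[idx["lung"]] = co * (c_ven - c_lung_out)
        da[idx["arterial"]] = co * c_lung_out - clr_blood * c_art
        da[idx["venous"]] = -co * c_ven + infusion_rate
        da[idx["eliminated_r"]] = clr_blood * c_art

        for t_name in _NONPORTAL:
            c_out = a[idx[t_name]] / (v[t_name] * kp_blood[t_name])
            da[idx[t_name]] = q[t_name] * (c_art - c_out)
            da[idx["arterial"]] -= q[t_name] * c_art
            da[idx["venous"]] += q[t_name] * c_out

        portal_in = 0.0
        for t_name in PORTAL_TISSUES:
            c_out = a[idx[t_name]] / (v[t_name] * kp_blood[t_name])
            da[idx[t_name]] = q[t_name] * (c_art - c_out)
            da[idx["arterial"]] -= q[t_name] * c_art
            portal_in += q[t_name] * c_out

        c_liv_out = a[idx["liver"]] / (v["liver"] * kp_blood["liver"])
        elim_h = cl_uint * fu_blood * c_liv_out
        da[idx["liver"]] = (
            q["liver"] * c_art + portal_in - qh_total * c_liv_out - elim_h
        )
        da[idx["arterial"]] -= q["liver"] * c_art
        da[idx["venous"]] += qh_total * c_liv_out
        da[idx["eliminated_h"]] = elim_h

        if route == "oral":
            release = ka * a[idx["depot"]]
            da[idx["depot"]] = -release
            da[idx["liver"]] += fa * release  # portal delivery
            da[idx["sink"]] = (1.0 - fa) * release
        elif route == "dermal":
            release = k_dermal * a[idx["depot"]]
            da[idx["depot"]] = -release
            da[idx["skin"]] += release

        # balance: the rest-flow closure guarantees sum(non-lung Q) = CO
        return da

    return rhs


def simulate_subject(
    cmpd: SimReadyCompound,
    config: SimulationConfig,
    subject: SubjectPhysiology,
) -> tuple[SubjectSeries, dict[str, float]]:
    """Integrate the whole-body model for one subject; returns the sampled
    series and the per-subject ledger row (clearances, ka/fa, predictions)."""
    fu, fu_src, bp, bp_src = resolve_fu_bp(cmpd, subject.hct)
    method = cmpd.vss_method or config.vss_method
    kp, vss = compute_kp_vss(cmpd, method, subject, fu=fu, bp=bp)
    kp_blood = {t: max(kp[t], 1e-9) / bp for t in TISSUES}

    dose_value = cmpd.dose if cmpd.dose is not None else config.dose
    dose_units = cmpd.dose_units if cmpd.dose_units is not None else config.dose_units
    dose_mg = resolve_dose(dose_value, dose_units, subject)

    model = select_clearance_model(cmpd.clint)
    fu_blood = fu / bp
    if model is ClearanceModel.HEPATIC_WELLSTIRRED:
        cl_uint = whole_liver_clint_l_h(cmpd.clint, cmpd.fu_hep, subject.liver_weight_g)
        cl_h_blood = wellstirred_hepatic_clearance(subject.qh, fu_blood, cl_uint)
        clr_plasma = 0.0
    else:
        cl_uint = 0.0
        cl_h_blood = 0.0
        clr_plasma = fu * subject.gfr_abs_l_per_h
    clr_blood = clr_plasma / bp

    ka, fa = absorption_parameters(cmpd.peff)
    k_dermal = dermal_transfer_rate(cmpd.logp, cmpd.mw)

    grid = np.round(
        np.arange(0.0, config.duration_h + OUTPUT_GRID_STEP_H / 2, OUTPUT_GRID_STEP_H),
        10,
    )
    if config.route == "iv_bolus":
        early = np.round(np.arange(0.0, IV_EARLY_WINDOW_H, IV_EARLY_STEP_H), 10)
        grid = np.unique(np.concatenate([early, grid]))
    y0 = np.zeros(_N_STATES)

    if config.route == "iv_bolus":
        t_inf = IV_INFUSION_S / 3600.0
        rate = dose_mg / t_inf
        rhs_inf = _rhs_factory(
            subject, kp_blood, config.route, ka, fa, k_dermal,
            cl_uint, fu_blood, clr_blood, rate,
        )
        eval_inf = np.append(grid[grid < t_inf], t_inf)
        sol_inf = solve_ivp(
            rhs_inf, (0.0, t_inf), y0, method="LSODA", t_eval=eval_inf,
            rtol=ODE_RTOL, atol=ODE_ATOL, max_step=t_inf / 5,
        )
        if not sol_inf.success:
            raise SimulationError(f"{cmpd.code}: infusion phase failed: {sol_inf.message}")
        lead_states = sol_inf.y[:, :-1]  # samples taken during the infusion
        y0 = sol_inf.y[:, -1]
        t_start = t_inf
    else:
        y0[_IDX["depot"]] = dose_mg
        lead_states = np.zeros((_N_STATES, 0))
        t_start = 0.0

    rhs = _rhs_factory(
        subject, kp_blood, config.route, ka, fa, k_dermal,
        cl_uint, fu_blood, clr_blood, 0.0,
    )
    t_eval = grid[grid >= t_start]
    sol = solve_ivp(
        rhs, (t_start, float(grid[-1])), y0, method="LSODA",
        t_eval=t_eval, rtol=ODE_RTOL, atol=ODE_ATOL,
    )
    if not sol.success:
        raise SimulationError(f"{cmpd.code}: integration failed: {sol.message}")

    states = np.concatenate([lead_states, sol.y], axis=1)

    # mass balance: everything in the body + eliminated + unabsorbed equals
    # the dose delivered up to each output time
    totals = states.sum(axis=0)
    if config.route == "iv_bolus":
        expected = rate * np.minimum(grid, t_inf)
        mb_err = float(np.max(np.abs(totals[1:] - expected[1:]) / expected[1:]))
    else:
        expected = np.full_like(totals, dose_mg)
        mb_err = float(np.max(np.abs(totals - expected)) / dose_mg)

    v_ven = subject.blood_volume * 2.0 / 3.0
    conc: dict[str, np.ndarray] = {}
    c_ven_blood = states[_IDX["venous"]] / v_ven
    conc["plasma"] = np.maximum(c_ven_blood / bp, 0.0) * 1000.0  # mg/L -> ng/mL
    for t_name in REPORTING_TISSUES:
        if t_name == "plasma":
            continue
        c_tissue = states[_IDX[t_name]] / subject.tissue_volumes[t_name]
        conc[t_name] = np.maximum(c_tissue, 0.0) * 1000.0

    cl_h_plasma = cl_h_blood * bp
    ledger = {
        "subject_id": subject.subject_id,
        "age": subject.age,
        "sex": subject.sex,
        "bw": subject.bw,
        "bsa": subject.bsa,
        "gfr": subject.gfr,
        "dose_mg": dose_mg,
        "fu_used": fu,
        "fu_source": fu_src,
        "bp_used": bp,
        "bp_source": bp_src,
        "vss_pred": vss,
        "ka": ka,
        "fa": fa,
        "fg": 1.0,
        "fh": 1.0 - cl_h_blood / subject.qh,
        "cl_h": cl_h_plasma,
        "cl_r": clr_plasma,
        "cl_tot": cl_h_plasma + clr_plasma,
        "clearance_model": model.value,
        "mass_balance_rel_err": mb_err,
    }
    series = SubjectSeries(
        subject_id=subject.subject_id,
        time_h=grid,
        conc=conc,
        mass_balance_rel_err=mb_err,
    )
    return series, ledger


def simulate_compound(
    cmpd: SimReadyCompound,
    config: SimulationConfig,
    subjects: Sequence[SubjectPhysiology],
) -> CompoundSimulation:
    """Run the whole-body model for every subject of the virtual population."""
    import pandas as pd

    all_series: list[SubjectSeries] = []
    rows: list[dict] = []
    for subject in subjects:
        series, row = simulate_subject(cmpd, config, subject)
        all_series.append(series)
        rows.append(row)
    return CompoundSimulation(
        code=cmpd.code,
        series=all_series,
        ledger=pd.DataFrame(rows),
        clearance_model=select_clearance_model(cmpd.clint),
        config=config,
    )
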