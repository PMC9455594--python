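"""Rule-based assumption engine turning curated data into simulator-ready input.

The rules encode conservative chemical-risk-assessment defaults:

* ionisation classification from raw pKa lists (acid < 7 < base), keeping at
  most two pKa values clamped to [0, 14];
* missing PSA/HBD assumed 0, with caps at 300 Å² and 20 donors;
* acids without a measured blood-to-plasma ratio assumed BP = 0.55 (ionised
  acids cannot enter erythrocytes, and haematocrit:plasma is 0.45:0.55);
* bases with pKa above a threshold (default 7) bind AGP, everything else HSA;
* LogD at pH 7.4 recomputed from logP and the selected pKa values via
  Henderson-Hasselbalch rather than trusting extracted LogD values;
* fraction unbound in the hepatocyte incubation (fu,hep) from the Kilford
  lipophilicity regression;
* human jejunal effective permeability (Peff) from the PSA/HBD regression
  of Winiwarter and colleagues, with an applicability-envelope warning.

All constants live in this module so a reviewer can audit every assumption
in one place.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .data_collection import CuratedParameters
from .io_schemas import CompoundType

__all__ = [
    "IonisationType",
    "AssumptionSettings",
    "SimReadyCompound",
    "TO_PREDICT",
    "classify_ionisation",
    "clamp_pka",
    "apply_psa_hbd_rules",
    "assign_bp_default",
    "assign_binding_protein",
    "logd_at_ph74",
    "fraction_unionised_ph74",
    "derive_logd_fuhep",
    "predict_peff",
    "peff_envelope_warnings",
    "prepare_sim_ready",
]


class IonisationType(str, enum.Enum):
    MONOPROTIC_ACID = "monoprotic acid"
    DIPROTIC_ACID = "diprotic acid"
    MONOPROTIC_BASE = "monoprotic base"
    DIPROTIC_BASE = "diprotic base"
    AMPHOLYTE = "ampholyte"
    NEUTRAL = "neutral"

    @property
    def is_acid(self) -> bool:
        return self in (self.MONOPROTIC_ACID, self.DIPROTIC_ACID)

    @property
    def is_base(self) -> bool:
        return self in (self.MONOPROTIC_BASE, self.DIPROTIC_BASE)


#: Marker for a parameter left to the in-silico prediction module.
TO_PREDICT = "to-predict"

# pKa acceptance window of the simulator input layer
PKA_MIN, PKA_MAX = 0.0, 14.0
PSA_MAX = 300.0  # Å²
HBD_MAX = 20

# Kilford hepatocyte-incubation binding regression:
#   fu,hep = 1 / (1 + 125 * VR * 10^(0.072 X^2 + 0.067 X - 1.126))
# with X = logD7.4 for acids/ampholytes and logP for bases/neutrals, and
# VR the hepatocyte volume ratio at 10^6 cells/mL.
KILFORD_VR = 0.005
KILFORD_A, KILFORD_B, KILFORD_C = 0.072, 0.067, -1.126

# PSA/HBD regression for human jejunal effective permeability (cm/s):
#   log10 Peff = -2.546 - 0.011 PSA - 0.278 HBD
WINIWARTER_INTERCEPT = -2.546
WINIWARTER_PSA = -0.011
WINIWARTER_HBD = -0.278

# applicability envelope of the Peff model
PEFF_PSA_RANGE = (16.2, 154.4)
PEFF_MW_RANGE = (60.0, 455.0)
PEFF_HBD_RANGE = (0, 5)


@dataclass
class AssumptionSettings:
    """Tunable knobs of the rule set (one config-file section)."""

    bp_acids: float = 0.55
    agp_pka_threshold: float = 7.0
    use_bp_prediction: bool = False  # abandon the 0.55 rule, predict instead
    use_extracted_logd: bool = False  # trust source LogD over the recomputation
    literal_diprotic_rule: bool = False  # honour the inverted two-pKa wording

    def __post_init__(self) -> None:
        if self.bp_acids <= 0:
            raise ValueError(f"bp_acids must be > 0 (got {self.bp_acids})")


@dataclass
class SimReadyCompound:
    """All inputs the simulator needs for one compound, rules applied."""

    code: str
    name: str
    mw: float
    logp: float
    type: IonisationType
    pka_selected: list[float]
    psa: float
    hbd: int
    logd74: float
    fu_hep: float
    peff: float  # 10^-4 cm/s
    bp: Optional[float]  # None => to-predict
    bp_source: str
    fu: Optional[float]  # None => to-predict
    fu_source: str
    clint: Optional[float]  # µL/min/10^6 cells; None => renal-only clearance
    clint_sd: Optional[float]
    fu_sd: Optional[float]
    binding_protein: str  # "HSA" | "AGP"
    dose: Optional[float] = None
    dose_units: Optional[str] = None
    vss_method: Optional[int] = None
    warnings: list[str] = field(default_factory=list)
    assumptions_applied: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# ionisation classification and pKa selection
# ---------------------------------------------------------------------------


def clamp_pka(value: float) -> float:
    """Clamp a pKa into the accepted [0, 14] window (idempotent)."""
    return min(max(float(value), PKA_MIN), PKA_MAX)


def _two_value_type(pkas: Sequence[float], literal: bool) -> IonisationType:
    below = sum(1 for p in pkas if p < 7)
    above = len(pkas) - below
    if below and above:
        return IonisationType.AMPHOLYTE
    if literal:
        # the inverted wording: both > 7 -> diprotic acid, both < 7 -> diprotic base
        return IonisationType.DIPROTIC_ACID if above == 2 else IonisationType.DIPROTIC_BASE
    return IonisationType.DIPROTIC_ACID if below == 2 else IonisationType.DIPROTIC_BASE


def classify_ionisation(
    pka_list: Sequence[float],
    declared_type: Optional[CompoundType] = None,
    literal_diprotic_rule: bool = False,
) -> tuple[IonisationType, list[float]]:
    """Classify a compound and select at most two pKa values.

    Without a declared type: no pKa -> neutral; one pKa -> monoprotic acid if
    below 7 else monoprotic base; two pKa -> diprotic acid (both acid-side),
    diprotic base (both base-side) or ampholyte (one each side); more than
    two -> the two values farthest from 7 are kept (all base-side: two
    largest; all acid-side: two lowest) and the two-value rules applied.
    Equidistant ties prefer the larger pKa.  A declared characterisation is
    honoured and pKa selection proceeds within it.  Selected values are
    clamped to [0, 14] after selection.
    """
    pkas = sorted(float(p) for p in pka_list)

    if declared_type is not None:
        ion, selected = _classify_declared(pkas, declared_type)
    elif not pkas:
        ion, selected = IonisationType.NEUTRAL, []
    elif len(pkas) == 1:
        ion = (
            IonisationType.MONOPROTIC_ACID
            if pkas[0] < 7
            else IonisationType.MONOPROTIC_BASE
        )
        selected = pkas
    else:
        if len(pkas) == 2:
            selected = pkas
        elif all(p > 7 for p in pkas):
            selected = pkas[-2:]  # two largest
        elif all(p < 7 for p in pkas):
            selected = pkas[:2]  # two lowest
        else:
            # two farthest from 7; ties broken towards the larger pKa
            selected = sorted(
                sorted(pkas, key=lambda p: (abs(p - 7), p), reverse=True)[:2]
            )
        ion = _two_value_type(selected, literal_diprotic_rule)

    return ion, [clamp_pka(p) for p in selected]


def _classify_declared(
    pkas: list[float], declared: CompoundType
) -> tuple[IonisationType, list[float]]:
    if declared is CompoundType.NEUTRAL or not pkas:
        return IonisationType.NEUTRAL, []
    if declared is CompoundType.ACID:
        if len(pkas) == 1:
            return IonisationType.MONOPROTIC_ACID, pkas
        return IonisationType.DIPROTIC_ACID, pkas[:2]
    if declared is CompoundType.BASE:
        if len(pkas) == 1:
            return IonisationType.MONOPROTIC_BASE, pkas
        return IonisationType.DIPROTIC_BASE, pkas[-2:]
    # ampholyte: most acidic and most basic pKa; degenerates to monoprotic
    if len(pkas) == 1:
        ion = (
            IonisationType.MONOPROTIC_ACID
            if pkas[0] < 7
            else IonisationType.MONOPROTIC_BASE
        )
        return ion, pkas
    return IonisationType.AMPHOLYTE, [pkas[0], pkas[-1]]


# ---------------------------------------------------------------------------
# range rules
# ---------------------------------------------------------------------------


def apply_psa_hbd_rules(
    psa: Optional[float], hbd: Optional[float]
) -> tuple[float, int]:
    """Missing PSA/HBD assumed 0; PSA clamped to [0, 300], HBD to [0, 20]."""
    psa_out = 0.0 if psa is None else min(max(float(psa), 0.0), PSA_MAX)
    hbd_out = 0 if hbd is None else int(round(min(max(float(hbd), 0.0), HBD_MAX)))
    return psa_out, hbd_out


def assign_bp_default(
    ion_type: IonisationType,
    measured_bp: Optional[float],
    bp_acids: float = 0.55,
    use_prediction: bool = False,
):
    """Measured BP wins; acids without one default to ``bp_acids`` (0.55)
    unless the user opted into prediction; all else is left to-predict."""
    if bp_acids <= 0:
        raise ValueError(f"bp_acids must be > 0 (got {bp_acids})")
    if measured_bp is not None:
        return measured_bp
    if ion_type.is_acid and not use_prediction:
        return bp_acids
    return TO_PREDICT


def assign_binding_protein(
    ion_type: IonisationType,
    pka_selected: Sequence[float],
    agp_pka_threshold: float = 7.0,
) -> str:
    """Basic compounds with pKa above the threshold bind AGP; all else HSA."""
    if ion_type.is_base and pka_selected and max(pka_selected) > agp_pka_threshold:
        return "AGP"
    return "HSA"


# ---------------------------------------------------------------------------
# LogD7.4, fu,hep, Peff
# ---------------------------------------------------------------------------

PH_PLASMA = 7.4


def logd_at_ph74(
    logp: float, ion_type: IonisationType, pka_selected: Sequence[float]
) -> float:
    """Henderson-Hasselbalch distribution coefficient at pH 7.4.

    Monoprotic acid:  logP - log10(1 + 10^(7.4 - pKa))
    Monoprotic base:  logP - log10(1 + 10^(pKa - 7.4))
    Diprotic species use the two-proton extension; ampholytes the
    zwitterion-free approximation (acidic and basic corrections combined).
    Neutral compounds are returned unchanged.
    """
    ph = PH_PLASMA
    pkas = sorted(pka_selected)
    if ion_type is IonisationType.NEUTRAL or not pkas:
        return float(logp)
    if ion_type is IonisationType.MONOPROTIC_ACID:
        ion = 10 ** (ph - pkas[0])
    elif ion_type is IonisationType.MONOPROTIC_BASE:
        ion = 10 ** (pkas[0] - ph)
    elif ion_type is IonisationType.DIPROTIC_ACID:
        pka1, pka2 = pkas  # pka1 <= pka2
        ion = 10 ** (ph - pka1) + 10 ** (2 * ph - pka1 - pka2)
    elif ion_type is IonisationType.DIPROTIC_BASE:
        pka2, pka1 = pkas  # pka1 = higher pKa protonates first
        ion = 10 ** (pka1 - ph) + 10 ** (pka1 + pka2 - 2 * ph)
    else:  # ampholyte: one acidic (lower) and one basic (higher) pKa
        pka_acid, pka_base = pkas
        ion = 10 ** (ph - pka_acid) + 10 ** (pka_base - ph)
    return float(logp) - math.log10(1.0 + ion)


def fraction_unionised_ph74(
    ion_type: IonisationType, pka_selected: Sequence[float]
) -> float:
    """Neutral-species fraction at pH 7.4 under the same ionisation model."""
    shift = logd_at_ph74(0.0, ion_type, pka_selected)
    return 10.0 ** shift


def kilford_fu_hep(x: float) -> float:
    """Fraction unbound in a hepatocyte incubation at 10^6 cells/mL."""
    return 1.0 / (
        1.0
        + 125.0 * KILFORD_VR * 10 ** (KILFORD_A * x * x + KILFORD_B * x + KILFORD_C)
    )


def derive_logd_fuhep(
    logp: float, ion_type: IonisationType, pka_selected: Sequence[float]
) -> tuple[float, float]:
    """LogD7.4 from the ionisation correction, then fu,hep from Kilford.

    Following the source regression's convention, acids and ampholytes enter
    the binding regression with logD7.4, bases and neutrals with logP.
    """
    logd74 = logd_at_ph74(logp, ion_type, pka_selected)
    if ion_type.is_acid or ion_type is IonisationType.AMPHOLYTE:
        x = logd74
    else:
        x = float(logp)
    return logd74, kilford_fu_hep(x)


def predict_peff(psa: float, hbd: float) -> float:
    """Human jejunal effective permeability in 10^-4 cm/s from PSA and HBD."""
    log_peff_cm_s = WINIWARTER_INTERCEPT + WINIWARTER_PSA * psa + WINIWARTER_HBD * hbd
    return 10.0 ** (log_peff_cm_s + 4.0)  # cm/s -> 10^-4 cm/s


def peff_envelope_warnings(
    psa: float, mw: Optional[float], hbd: float
) -> list[str]:
    """Applicability-envelope check of the PSA/HBD permeability model."""
    out: list[str] = []
    if not PEFF_PSA_RANGE[0] <= psa <= PEFF_PSA_RANGE[1]:
        out.append(
            f"Peff extrapolation: PSA {psa:g} outside [{PEFF_PSA_RANGE[0]}, {PEFF_PSA_RANGE[1]}]"
        )
    if mw is not None and not PEFF_MW_RANGE[0] <= mw <= PEFF_MW_RANGE[1]:
        out.append(
            f"Peff extrapolation: MW {mw:g} outside [{PEFF_MW_RANGE[0]:g}, {PEFF_MW_RANGE[1]:g}]"
        )
    if not PEFF_HBD_RANGE[0] <= hbd <= PEFF_HBD_RANGE[1]:
        out.append(
            f"Peff extrapolation: HBD {hbd:g} outside [{PEFF_HBD_RANGE[0]}, {PEFF_HBD_RANGE[1]}]"
        )
    return out


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def prepare_sim_ready(
    curated: CuratedParameters,
    settings: Optional[AssumptionSettings] = None,
) -> SimReadyCompound:
    """Apply the full rule set to one curated compound.

    Requires MW and LogP (a compound with no physicochemical data cannot be
    simulated); everything else is defaulted, clamped or marked to-predict.
    """
    settings = settings or AssumptionSettings()
    if curated.mw is None or curated.logp is None:
        raise ValueError(
            f"compound {curated.code!r} lacks MW and/or LogP; cannot be simulated"
        )
    log: list[str] = []

    ion_type, pka_selected = classify_ionisation(
        curated.pka_values, curated.type, settings.literal_diprotic_rule
    )
    log.append(
        f"classified as {ion_type.value} with pKa {pka_selected}"
        + (" (declared type honoured)" if curated.type else "")
    )

    psa, hbd = apply_psa_hbd_rules(curated.psa, curated.hbd)
    if curated.psa is None:
        log.append("missing PSA assumed 0")
    if curated.hbd is None:
        log.append("missing HBD assumed 0")

    bp = assign_bp_default(
        ion_type, curated.bp, settings.bp_acids, settings.use_bp_prediction
    )
    if bp is TO_PREDICT:
        bp_value, bp_source = None, TO_PREDICT
        log.append("BP ratio left to the prediction module")
    elif curated.bp is not None:
        bp_value, bp_source = float(bp), curated.provenance.get("bp", "measured")
    else:
        bp_value, bp_source = float(bp), "assumed"
        log.append(f"acid without measured BP assumed BP = {settings.bp_acids}")

    if curated.fu is not None:
        fu_value, fu_source = curated.fu, curated.provenance.get("fu", "measured")
    else:
        fu_value, fu_source = None, TO_PREDICT
        log.append("fu left to the prediction module")

    binding_protein = assign_binding_protein(
        ion_type, pka_selected, settings.agp_pka_threshold
    )
    log.append(f"binding protein: {binding_protein}")

    if settings.use_extracted_logd and curated.logd74_extracted is not None:
        logd74 = curated.logd74_extracted
        _, fu_hep = derive_logd_fuhep(curated.logp, ion_type, pka_selected)
        log.append("extracted LogD7.4 used (user override)")
    else:
        logd74, fu_hep = derive_logd_fuhep(curated.logp, ion_type, pka_selected)
        log.append(f"LogD7.4 recomputed = {logd74:.3f}; fu,hep = {fu_hep:.3f}")

    peff = predict_peff(psa, hbd)
    warnings = peff_envelope_warnings(psa, curated.mw, hbd)

    if curated.clint is None:
        log.append("no CLint: renal-only clearance (CLR = fu * GFR) will be used")

    return SimReadyCompound(
        code=curated.code,
        name=curated.name,
        mw=float(curated.mw),
        logp=float(curated.logp),
        type=ion_type,
        pka_selected=pka_selected,
        psa=psa,
        hbd=hbd,
        logd74=logd74,
        fu_hep=fu_hep,
        peff=peff,
        bp=bp_value,
        bp_source=bp_source,
        fu=fu_value,
        fu_source=fu_source,
        clint=curated.clint,
        clint_sd=curated.clint_sd,
        fu_sd=curated.fu_sd,
        binding_protein=binding_protein,
        dose=curated.dose,
        dose_units=curated.dose_units,
        vss_method=curated.vss_method,
        warnings=warnings,
        assumptions_applied=log,
    )
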