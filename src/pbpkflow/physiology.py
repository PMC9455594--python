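"""Reference human physiology and virtual-population sampling.

Healthy adults aged 20-55 with equal male/female probability.  Organ volumes
and blood-flow fractions follow standard reference-human compilations
(ICRP-style reference male/female), scaled to each sampled subject by body
weight (volumes) and body surface area (flows/cardiac output).  Body weight
is lognormal per sex, height normal per sex, BSA by the Du Bois relation and
GFR normal around an age-adjusted mean, normalised to 1.73 m².

All constants are collected here so the physiological basis of the simulator
is auditable and versionable in one file.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TISSUES",
    "REPORTING_TISSUES",
    "SubjectPhysiology",
    "generate_population",
    "reference_subject",
    "population_frame",
]

# perfusion-limited compartments of the whole-body model (lung is in series
# with the blood pool; "rest" closes the mass balance of the reference body)
TISSUES = (
    "lung", "brain", "heart", "gut", "spleen", "pancreas", "liver",
    "kidney", "skin", "muscle", "adipose", "rest",
)

# tissues whose concentration-time profiles are reported
REPORTING_TISSUES = (
    "plasma", "skin", "liver", "kidney", "lung", "spleen", "brain",
    "heart", "gut", "pancreas",
)

# splanchnic organs drain through the portal vein into the liver
PORTAL_TISSUES = ("gut", "spleen", "pancreas")

# --------------------------------------------------------------------------
# reference bodies (volumes in L, flows as fractions of cardiac output)
# --------------------------------------------------------------------------

REFERENCE = {
    "M": {
        "bw": 73.0,          # kg, reference male body weight
        "height": 176.0,     # cm
        "cardiac_output": 390.0,  # L/h (6.5 L/min)
        "hct": 0.45,
        "plasma": 3.0,
        "blood_cells": 2.5,
        "volumes": {
            "lung": 0.53, "brain": 1.45, "heart": 0.33, "gut": 1.65,
            "spleen": 0.15, "pancreas": 0.14, "liver": 1.80, "kidney": 0.31,
            "skin": 3.30, "muscle": 29.0, "adipose": 18.2, "rest": 5.0,
        },
    },
    "F": {
        "bw": 60.0,
        "height": 163.0,
        "cardiac_output": 354.0,  # L/h (5.9 L/min)
        "hct": 0.40,
        "plasma": 2.6,
        "blood_cells": 1.9,
        "volumes": {
            "lung": 0.42, "brain": 1.30, "heart": 0.25, "gut": 1.50,
            "spleen": 0.13, "pancreas": 0.12, "liver": 1.40, "kidney": 0.28,
            "skin": 2.30, "muscle": 17.5, "adipose": 22.0, "rest": 4.5,
        },
    },
}

# organ blood-flow fractions of cardiac output (non-lung flows sum to 1;
# the lung receives the entire cardiac output in series)
FLOW_FRACTIONS = {
    "brain": 0.120, "heart": 0.040, "gut": 0.150, "spleen": 0.020,
    "pancreas": 0.010, "liver": 0.065,  # hepatic artery only
    "kidney": 0.190, "skin": 0.050, "muscle": 0.170, "adipose": 0.050,
}
FLOW_FRACTIONS["rest"] = 1.0 - sum(FLOW_FRACTIONS.values())

# body-weight lognormal (median kg, sigma of log) and height normal (cm)
BW_MEDIAN = {"M": 78.0, "F": 65.0}
BW_SIGMA = {"M": 0.15, "F": 0.17}
HEIGHT_MEAN = {"M": 176.0, "F": 163.0}
HEIGHT_SD = {"M": 7.0, "F": 6.5}
HCT_SD = 0.02

# GFR (mL/min/1.73 m²): age-adjusted mean with inter-subject spread
GFR_AT_20 = 115.0
GFR_SLOPE_PER_YEAR = 0.4
GFR_SD = 12.0
GFR_FLOOR = 40.0

AGE_RANGE = (20.0, 55.0)


def du_bois_bsa(bw_kg: float, height_cm: float) -> float:
    """Du Bois body surface area (m²)."""
    return 0.007184 * bw_kg**0.425 * height_cm**0.725


@dataclass
class SubjectPhysiology:
    """Sampled anatomy, flows and renal function for one virtual subject."""

    subject_id: int
    age: float  # years
    sex: str  # "M" | "F"
    bw: float  # kg
    bsa: float  # m²
    hct: float  # fraction
    gfr: float  # mL/min/1.73 m²
    plasma_volume: float  # L
    blood_cell_volume: float  # L
    cardiac_output: float  # L/h
    tissue_volumes: dict[str, float] = field(default_factory=dict)  # L
    tissue_flows: dict[str, float] = field(default_factory=dict)  # L/h

    @property
    def blood_volume(self) -> float:
        return self.plasma_volume + self.blood_cell_volume

    @property
    def qh(self) -> float:
        """Total hepatic blood flow (hepatic artery + portal inflow), L/h."""
        return self.tissue_flows["liver"] + sum(
            self.tissue_flows[t] for t in PORTAL_TISSUES
        )

    @property
    def gfr_abs_l_per_h(self) -> float:
        """Absolute GFR in L/h (de-normalised by the subject's BSA)."""
        return self.gfr * (self.bsa / 1.73) * 60.0 / 1000.0

    @property
    def liver_weight_g(self) -> float:
        # liver density ~1.05 g/mL
        return self.tissue_volumes["liver"] * 1050.0


def _build_subject(
    subject_id: int, age: float, sex: str, bw: float, height: float,
    hct: float, gfr: float
) -> SubjectPhysiology:
    ref = REFERENCE[sex]
    size = bw / ref["bw"]
    bsa = du_bois_bsa(bw, height)
    co = ref["cardiac_output"] * (bsa / du_bois_bsa(ref["bw"], ref["height"]))
    volumes = {t: v * size for t, v in ref["volumes"].items()}
    flows = {t: co * f for t, f in FLOW_FRACTIONS.items()}
    # exact closure: non-lung flows sum to the cardiac output
    flows["rest"] = co - sum(v for t, v in flows.items() if t != "rest")
    flows["lung"] = co
    return SubjectPhysiology(
        subject_id=subject_id,
        age=age,
        sex=sex,
        bw=bw,
        bsa=bsa,
        hct=hct,
        gfr=gfr,
        plasma_volume=ref["plasma"] * size,
        blood_cell_volume=ref["blood_cells"] * size,
        cardiac_output=co,
        tissue_volumes=volumes,
        tissue_flows=flows,
    )


def generate_population(
    n: int, seed: int | None = None
) -> list[SubjectPhysiology]:
    """Sample ``n`` healthy virtual subjects (1 <= n <= 1000).

    Deterministic under a seed; with a fixed seed the same subjects can be
    reused across every compound of a batch.
    """
    if not 1 <= n <= 1000:
        raise ValueError(f"number of subjects must be in [1, 1000] (got {n})")
    rng = np.random.default_rng(seed)
    subjects = []
    for i in range(n):
        age = float(rng.uniform(*AGE_RANGE))
        sex = "M" if rng.random() < 0.5 else "F"
        bw = float(BW_MEDIAN[sex] * np.exp(rng.normal(0.0, BW_SIGMA[sex])))
        height = float(rng.normal(HEIGHT_MEAN[sex], HEIGHT_SD[sex]))
        hct = float(np.clip(rng.normal(REFERENCE[sex]["hct"], HCT_SD), 0.30, 0.55))
        gfr_mean = GFR_AT_20 - GFR_SLOPE_PER_YEAR * (age - 20.0)
        gfr = float(max(rng.normal(gfr_mean, GFR_SD), GFR_FLOOR))
        subjects.append(_build_subject(i + 1, age, sex, bw, height, hct, gfr))
    return subjects


def reference_subject() -> SubjectPhysiology:
    """The deterministic reference male (used for population-independent
    predictions such as Vss)."""
    return _build_subject(
        subject_id=0, age=30.0, sex="M", bw=REFERENCE["M"]["bw"],
        height=REFERENCE["M"]["height"], hct=REFERENCE["M"]["hct"],
        gfr=GFR_AT_20 - GFR_SLOPE_PER_YEAR * 10.0,
    )


def population_frame(subjects: list[SubjectPhysiology]):
    """Demographic summary table (one row per subject)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "age": [s.age for s in subjects],
            "sex": [s.sex for s in subjects],
            "bw": [s.bw for s in subjects],
            "bsa": [s.bsa for s in subjects],
            "hct": [s.hct for s in subjects],
            "gfr": [s.gfr for s in subjects],
            "cardiac_output": [s.cardiac_output for s in subjects],
        }
    )
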