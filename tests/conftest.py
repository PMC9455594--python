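"""Shared fixtures: synthetic snapshot batches and hand-built compounds."""

from __future__ import annotations

import pytest

from pbpkflow.assumptions import IonisationType, SimReadyCompound
from pbpkflow.fixtures import FixtureSpec, build_snapshot_fixture
from pbpkflow.physiology import generate_population, reference_subject


def make_compound(
    code: str = "X1",
    mw: float = 300.0,
    logp: float = 2.0,
    ion_type: IonisationType = IonisationType.NEUTRAL,
    pka_selected: list[float] | None = None,
    psa: float = 60.0,
    hbd: int = 1,
    logd74: float | None = None,
    fu_hep: float = 0.9,
    peff: float = 2.0,
    bp: float | None = 1.0,
    fu: float | None = 0.2,
    clint: float | None = 10.0,
    binding_protein: str = "HSA",
    dose: float | None = None,
    dose_units: str | None = None,
    vss_method: int | None = None,
) -> SimReadyCompound:
    """Directly assemble a simulator-ready compound for engine-level tests."""
    from pbpkflow.assumptions import logd_at_ph74

    pka_selected = pka_selected or []
    if logd74 is None:
        logd74 = logd_at_ph74(logp, ion_type, pka_selected)
    return SimReadyCompound(
        code=code, name=code, mw=mw, logp=logp, type=ion_type,
        pka_selected=pka_selected, psa=psa, hbd=hbd, logd74=logd74,
        fu_hep=fu_hep, peff=peff, bp=bp, bp_source="measured", fu=fu,
        fu_source="measured", clint=clint, clint_sd=None, fu_sd=None,
        binding_protein=binding_protein, dose=dose, dose_units=dose_units,
        vss_method=vss_method,
    )


@pytest.fixture(scope="session")
def nine_compound_fixture(tmp_path_factory):
    """The default nine-compound batch (4 rich / 4 medium / 1 poor, seed 3)."""
    directory = tmp_path_factory.mktemp("fixture9")
    spec = FixtureSpec()
    paths, truth = build_snapshot_fixture(spec, directory)
    return spec, paths, truth


@pytest.fixture(scope="session")
def small_population():
    return generate_population(3, seed=42)


@pytest.fixture(scope="session")
def ref_subject():
    return reference_subject()
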