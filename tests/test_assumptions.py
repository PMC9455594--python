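"""Rule-engine tests: ionisation classification, clamps, defaults, LogD/fu,hep/Peff."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pbpkflow.assumptions import (
    TO_PREDICT,
    AssumptionSettings,
    IonisationType,
    apply_psa_hbd_rules,
    assign_binding_protein,
    assign_bp_default,
    classify_ionisation,
    derive_logd_fuhep,
    kilford_fu_hep,
    logd_at_ph74,
    peff_envelope_warnings,
    predict_peff,
    prepare_sim_ready,
)
from pbpkflow.data_collection import CuratedParameters
from pbpkflow.io_schemas import CompoundType

A = IonisationType


def oracle_classify(pkas: list[float]) -> tuple[IonisationType, list[float]]:
    """Independent re-derivation of the undeclared-type classification rules.

    Boundary convention: a pKa of exactly 7 counts as base-side, matching the
    one-value rule (acid only when strictly below 7).
    """
    pkas = sorted(pkas)
    if len(pkas) == 0:
        return A.NEUTRAL, []
    if len(pkas) == 1:
        kind = A.MONOPROTIC_ACID if pkas[0] < 7 else A.MONOPROTIC_BASE
        return kind, [min(max(pkas[0], 0.0), 14.0)]
    if len(pkas) > 2:
        if all(p > 7 for p in pkas):
            pkas = pkas[-2:]
        elif all(p < 7 for p in pkas):
            pkas = pkas[:2]
        else:
            ranked = sorted(pkas, key=lambda p: (abs(p - 7), p), reverse=True)
            pkas = sorted(ranked[:2])
    n_acid_side = sum(1 for p in pkas if p < 7)
    if n_acid_side == 1:
        kind = A.AMPHOLYTE
    elif n_acid_side == 2:
        kind = A.DIPROTIC_ACID
    else:
        kind = A.DIPROTIC_BASE
    return kind, [min(max(p, 0.0), 14.0) for p in pkas]


class TestClassifyIonisation:
    @pytest.mark.parametrize(
        "pkas, expected_type, expected_sel",
        [
            ([], A.NEUTRAL, []),
            ([4.2], A.MONOPROTIC_ACID, [4.2]),
            ([8.1], A.MONOPROTIC_BASE, [8.1]),
            ([3.0, 10.0], A.AMPHOLYTE, [3.0, 10.0]),
            ([2.0, 5.0], A.DIPROTIC_ACID, [2.0, 5.0]),
            ([8.0, 10.0], A.DIPROTIC_BASE, [8.0, 10.0]),
            # distances from 7: 6, 4, 3 -> keep {1, 3}, both acid-side
            ([1.0, 3.0, 10.0], A.DIPROTIC_ACID, [1.0, 3.0]),
            ([8.0, 9.0, 10.0], A.DIPROTIC_BASE, [9.0, 10.0]),
            ([1.0, 2.0, 3.0], A.DIPROTIC_ACID, [1.0, 2.0]),
            # mixed, farthest from 7: 13 (d=6) and 1 (d=6) and 6.5 -> {1, 13}
            ([1.0, 6.5, 13.0], A.AMPHOLYTE, [1.0, 13.0]),
            ([-2.0, 16.0], A.AMPHOLYTE, [0.0, 14.0]),  # clamped after selection
        ],
    )
    def test_rule_examples(self, pkas, expected_type, expected_sel):
        kind, selected = classify_ionisation(pkas)
        assert kind is expected_type
        assert selected == pytest.approx(expected_sel)

    def test_declared_type_honoured_with_clamp(self):
        kind, selected = classify_ionisation([16.0], declared_type=CompoundType.BASE)
        assert kind is A.MONOPROTIC_BASE
        assert selected == [14.0]

    def test_declared_acid_selects_lowest_two(self):
        kind, selected = classify_ionisation(
            [2.0, 5.0, 9.0], declared_type=CompoundType.ACID
        )
        assert kind is A.DIPROTIC_ACID
        assert selected == [2.0, 5.0]

    def test_declared_ampholyte_takes_extremes(self):
        kind, selected = classify_ionisation(
            [3.0, 6.0, 10.0], declared_type=CompoundType.AMPHOLYTE
        )
        assert kind is A.AMPHOLYTE
        assert selected == [3.0, 10.0]

    def test_literal_diprotic_switch_inverts_two_value_rule(self):
        kind, _ = classify_ionisation([8.0, 10.0], literal_diprotic_rule=True)
        assert kind is A.DIPROTIC_ACID
        kind, _ = classify_ionisation([2.0, 5.0], literal_diprotic_rule=True)
        assert kind is A.DIPROTIC_BASE
        # ampholytes unaffected by the wording inversion
        kind, _ = classify_ionisation([3.0, 10.0], literal_diprotic_rule=True)
        assert kind is A.AMPHOLYTE

    def test_exhaustive_grid_against_oracle(self):
        grid = [-1.0, 0.5, 2.0, 4.5, 6.9, 7.1, 9.0, 11.5, 14.5]
        from itertools import combinations

        for n in (1, 2, 3, 4):
            for combo in combinations(grid, n):
                expected = oracle_classify(list(combo))
                got = classify_ionisation(list(combo))
                assert got[0] is expected[0], combo
                assert got[1] == pytest.approx(expected[1]), combo

    @settings(max_examples=100, deadline=None)
    @given(
        pkas=st.lists(
            st.floats(min_value=-3, max_value=17, allow_nan=False), max_size=6
        ),
        seed=st.integers(0, 1000),
    )
    def test_permutation_invariance_and_bounds(self, pkas, seed):
        rng = np.random.default_rng(seed)
        shuffled = list(rng.permutation(pkas)) if pkas else []
        base = classify_ionisation(pkas)
        perm = classify_ionisation(shuffled)
        assert perm[0] is base[0]
        assert perm[1] == pytest.approx(base[1])
        assert len(base[1]) <= 2
        assert all(0.0 <= p <= 14.0 for p in base[1])


class TestRangeRules:
    @pytest.mark.parametrize(
        "psa, hbd, expected",
        [
            (None, None, (0.0, 0)),
            (450.0, 25.0, (300.0, 20)),
            (87.5, 3.0, (87.5, 3)),
            (-5.0, -1.0, (0.0, 0)),
        ],
    )
    def test_psa_hbd_rules(self, psa, hbd, expected):
        assert apply_psa_hbd_rules(psa, hbd) == expected

    def test_clamps_idempotent(self):
        for psa, hbd in [(450.0, 25.0), (None, None), (100.0, 2.0), (-3.0, 7.0)]:
            once = apply_psa_hbd_rules(psa, hbd)
            assert apply_psa_hbd_rules(*once) == once


class TestBPAndBindingProtein:
    def test_acid_without_measurement_gets_default(self):
        assert assign_bp_default(A.DIPROTIC_ACID, None) == 0.55
        assert assign_bp_default(A.MONOPROTIC_ACID, None, bp_acids=0.7) == 0.7

    def test_base_without_measurement_goes_to_prediction(self):
        assert assign_bp_default(A.MONOPROTIC_BASE, None) is TO_PREDICT
        assert assign_bp_default(A.NEUTRAL, None) is TO_PREDICT

    def test_measured_value_always_wins(self):
        for kind in A:
            assert assign_bp_default(kind, 0.8) == 0.8

    def test_prediction_opt_out_of_acid_default(self):
        assert assign_bp_default(A.MONOPROTIC_ACID, None, use_prediction=True) is TO_PREDICT

    def test_nonpositive_default_rejected(self):
        with pytest.raises(ValueError):
            assign_bp_default(A.MONOPROTIC_ACID, None, bp_acids=0.0)

    @pytest.mark.parametrize(
        "kind, pkas, threshold, expected",
        [
            (A.MONOPROTIC_BASE, [9.1], 7.0, "AGP"),
            (A.MONOPROTIC_BASE, [7.3], 7.5, "HSA"),
            (A.MONOPROTIC_BASE, [7.3], 7.0, "AGP"),
            (A.NEUTRAL, [], 7.0, "HSA"),
            (A.MONOPROTIC_ACID, [4.0], 7.0, "HSA"),
            (A.DIPROTIC_BASE, [8.0, 10.5], 7.0, "AGP"),
        ],
    )
    def test_binding_protein_rule(self, kind, pkas, threshold, expected):
        assert assign_binding_protein(kind, pkas, threshold) == expected


class TestLogDFuHepPeff:
    def test_neutral_logd_equals_logp(self):
        assert logd_at_ph74(2.0, A.NEUTRAL, []) == 2.0

    def test_monoprotic_acid_closed_form(self):
        expected = 3.0 - math.log10(1 + 10 ** (7.4 - 4.0))
        assert logd_at_ph74(3.0, A.MONOPROTIC_ACID, [4.0]) == pytest.approx(expected)
        assert expected == pytest.approx(-0.4, abs=0.01)

    def test_monoprotic_base_closed_form(self):
        expected = 3.0 - math.log10(1 + 10 ** (9.0 - 7.4))
        assert logd_at_ph74(3.0, A.MONOPROTIC_BASE, [9.0]) == pytest.approx(expected)

    def test_diprotic_collapses_to_monoprotic_when_second_pka_extreme(self):
        # a second deprotonation far above the pH contributes nothing
        mono = logd_at_ph74(2.0, A.MONOPROTIC_ACID, [4.0])
        di = logd_at_ph74(2.0, A.DIPROTIC_ACID, [4.0, 14.0])
        assert di == pytest.approx(mono, abs=1e-6)

    def test_logd_never_exceeds_logp(self):
        for kind, pkas in [
            (A.MONOPROTIC_ACID, [5.0]),
            (A.DIPROTIC_BASE, [8.0, 10.0]),
            (A.AMPHOLYTE, [4.0, 9.0]),
        ]:
            assert logd_at_ph74(2.5, kind, pkas) <= 2.5

    def test_fu_hep_monotone_decreasing_in_lipophilicity(self):
        grid = np.linspace(0.0, 6.0, 61)
        values = [kilford_fu_hep(x) for x in grid]
        assert all(b < a for a, b in zip(values, values[1:]))
        assert all(0 < v <= 1 for v in values)

    def test_derive_uses_logd_for_acids_and_logp_for_bases(self):
        logd_acid, fu_acid = derive_logd_fuhep(3.0, A.MONOPROTIC_ACID, [4.0])
        assert fu_acid == pytest.approx(kilford_fu_hep(logd_acid))
        logd_base, fu_base = derive_logd_fuhep(3.0, A.MONOPROTIC_BASE, [9.0])
        assert fu_base == pytest.approx(kilford_fu_hep(3.0))
        assert logd_base < 3.0

    def test_peff_monotone_in_psa_and_hbd_and_positive(self):
        psa_grid = np.linspace(0, 300, 31)
        assert predict_peff(0, 0) > predict_peff(300, 0)
        for psa in psa_grid:
            assert predict_peff(psa, 0) >= predict_peff(psa, 5)
            assert predict_peff(psa, 5) > 0

    @pytest.mark.parametrize(
        "psa, mw, hbd, n_warnings",
        [
            (80.0, 300.0, 2, 0),
            (10.0, 300.0, 2, 1),  # PSA below 16.2
            (80.0, 500.0, 2, 1),  # MW above 455
            (80.0, 300.0, 7, 1),  # HBD above 5
            (200.0, 30.0, 9, 3),
        ],
    )
    def test_peff_extrapolation_envelope(self, psa, mw, hbd, n_warnings):
        warnings = peff_envelope_warnings(psa, mw, hbd)
        assert len(warnings) == n_warnings
        assert all("Peff extrapolation" in w for w in warnings)


class TestPrepareSimReady:
    def _curated(self, **kwargs) -> CuratedParameters:
        base = dict(code="C1", mw=300.0, logp=2.5, pka_values=[4.0], psa=70.0,
                    hbd=2.0)
        base.update(kwargs)
        return CuratedParameters(**base)

    def test_missing_physchem_rejected(self):
        with pytest.raises(ValueError, match="cannot be simulated"):
            prepare_sim_ready(self._curated(logp=None))

    def test_acid_pipeline_end_to_end(self):
        cmpd = prepare_sim_ready(self._curated())
        assert cmpd.type is A.MONOPROTIC_ACID
        assert cmpd.bp == 0.55 and cmpd.bp_source == "assumed"
        assert cmpd.fu is None and cmpd.fu_source == TO_PREDICT
        assert cmpd.binding_protein == "HSA"
        assert cmpd.clint is None
        assert cmpd.assumptions_applied  # audit trail populated

    def test_measured_values_survive(self):
        curated = self._curated(fu=0.1, bp=0.8, clint=12.0)
        curated.provenance.update({"fu": "user", "bp": "chem_phys"})
        cmpd = prepare_sim_ready(curated)
        assert cmpd.fu == 0.1 and cmpd.bp == 0.8 and cmpd.clint == 12.0

    def test_settings_validation(self):
        with pytest.raises(ValueError):
            AssumptionSettings(bp_acids=-1.0)
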