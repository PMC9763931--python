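"""Component scoring and VHI aggregation, including the unclamped-score rule."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from vhi.model import (
    Bed,
    Component,
    Group,
    IncompleteAnimalError,
    MissingStandardError,
    Variant,
)
from vhi.scoring import (
    COMPONENT_DIRECTION,
    Direction,
    aggregate_vhi,
    component_score,
    compute_vhi,
    group_mean_vhi,
    standard_of_health,
)

C = Component
DEC, INC = Direction.DECREASES_WITH_DISEASE, Direction.INCREASES_WITH_DISEASE


class TestComponentScore:
    @pytest.mark.parametrize(
        "m, s, direction, expected",
        [
            (3.1, 3.1, INC, 100.0),        # identity, inverted component
            (136.5, 136.5, DEC, 100.0),    # identity
            (6.2, 3.1, INC, 0.0),          # ratio 200% zeroes the score
            (5.4, 2.2, INC, 200 - 5.4 / 2.2 * 100),  # negative, unclamped
            (122.6, 136.5, DEC, 122.6 / 136.5 * 100),
        ],
    )
    def test_known_scores(self, m, s, direction, expected):
        assert component_score(m, s, direction) == pytest.approx(expected, abs=1e-9)

    def test_negative_score_is_not_clamped(self):
        assert component_score(5.4, 2.2, INC) == pytest.approx(-45.4545, abs=1e-3)
        assert component_score(5.4, 2.2, INC) < 0

    def test_direction_map_covers_all_components(self):
        assert set(COMPONENT_DIRECTION) == set(Component)
        assert COMPONENT_DIRECTION[C.STIFFNESS_BETA] == INC

    @given(m=st.floats(0.1, 1e3), s=st.floats(0.1, 1e3))
    def test_directions_sum_to_200_at_any_ratio(self, m, s):
        """The inverted score mirrors the plain score around 100."""
        assert component_score(m, s, DEC) + component_score(m, s, INC) == pytest.approx(200.0)


class TestStandardOfHealth:
    def test_single_control(self):
        std = standard_of_health([135.2], "S1", Bed.CEREBRAL, 13, C.ACH_DILATION)
        assert std.standard_value == 135.2
        assert std.n_controls == 1

    def test_mean_of_controls(self):
        std = standard_of_health([100.0, 110.0, 120.0], "S1", Bed.PERIPHERAL, 7, C.MVD)
        assert std.standard_value == pytest.approx(110.0)

    def test_no_controls_raises(self):
        with pytest.raises(MissingStandardError):
            standard_of_health([], "S1", Bed.PERIPHERAL, 7, C.MVD)


class TestComputeVHI:
    def test_all_100(self):
        scores = {c: 100.0 for c in C}
        assert compute_vhi(scores, Variant.FIVE_COMPONENT).score_pct == pytest.approx(100.0)

    def test_five_component_mean_from_published_ratios(self):
        scores = {C.ACH_DILATION: 89.82, C.SNP_DILATION: 99.64, C.MVD: 76.04,
                  C.HYPOXIC_DILATION: 89.87, C.STIFFNESS_BETA: 0.0}
        res = compute_vhi(scores, Variant.FIVE_COMPONENT)
        assert res.score_pct == pytest.approx(71.074, abs=1e-3)

    def test_three_component_mean(self):
        scores = {C.ACH_DILATION: 90.53, C.MVD: 94.48, C.STIFFNESS_BETA: 87.5}
        res = compute_vhi(scores, Variant.THREE_COMPONENT)
        assert res.score_pct == pytest.approx(90.84, abs=0.01)

    def test_missing_component_raises(self):
        with pytest.raises(IncompleteAnimalError):
            compute_vhi({C.ACH_DILATION: 100.0}, Variant.THREE_COMPONENT)

    def test_variants_agree_when_extras_equal_core_mean(self):
        core = {C.ACH_DILATION: 80.0, C.MVD: 90.0, C.STIFFNESS_BETA: 70.0}
        m = np.mean(list(core.values()))
        full = {**core, C.SNP_DILATION: m, C.HYPOXIC_DILATION: m}
        assert compute_vhi(full, Variant.FIVE_COMPONENT).score_pct == pytest.approx(
            compute_vhi(core, Variant.THREE_COMPONENT).score_pct)

    @given(delta=st.floats(0.5, 50.0))
    def test_monotone_in_disease_direction(self, delta):
        """Worsening any single component strictly lowers the index."""
        means = {C.ACH_DILATION: 130.0, C.SNP_DILATION: 140.0, C.MVD: 800.0,
                 C.HYPOXIC_DILATION: 125.0, C.STIFFNESS_BETA: 3.0}
        base = group_mean_vhi(means, means, Variant.FIVE_COMPONENT).score_pct
        for comp in Component:
            worse = dict(means)
            worse[comp] += delta if comp is C.STIFFNESS_BETA else -delta
            assert group_mean_vhi(worse, means, Variant.FIVE_COMPONENT).score_pct < base


class TestAggregate:
    def test_equal_n_aggregate_matches_mean_of_age_means(self):
        from vhi.model import VHIResult

        age_means = [91.44, 87.84, 77.08, 65.56, 52.80]
        results = []
        for i, m in enumerate(age_means):
            scores = {c: m for c in C}
            results.append(VHIResult(f"a{i}", Bed.CEREBRAL, Variant.FIVE_COMPONENT,
                                     m, scores))
        assert aggregate_vhi(results) == pytest.approx(74.944, abs=1e-3)

    def test_single_result(self):
        from vhi.model import VHIResult

        r = VHIResult("a0", Bed.CEREBRAL, Variant.FIVE_COMPONENT, 88.0,
                      {c: 88.0 for c in C})
        assert aggregate_vhi([r]) == 88.0

    def test_empty_raises(self):
        from vhi.model import EmptyResultError

        with pytest.raises(EmptyResultError):
            aggregate_vhi([])


class TestLZRSelfStandard:
    def test_control_cohort_scores_exactly_100(self, rng):
        """Scoring lean controls against their own means gives a group mean
        of exactly 100 for every component and hence for the index."""
        from vhi.model import AnimalRecord
        from vhi.scoring import components_frame, score_cohort
        from vhi.model import ComponentValue

        animals = {}
        comps = []
        for i in range(12):
            aid = f"lzr{i}"
            animals[aid] = AnimalRecord(aid, Group.LZR, 13, "S1")
            for c in Component:
                comps.append(ComponentValue(aid, Bed.PERIPHERAL, c,
                                            float(rng.uniform(50, 150)), "u"))
        df = components_frame(comps)
        for variant in Variant:
            results = score_cohort(df, animals, variant, Bed.PERIPHERAL)
            assert len(results) == 12
            assert np.mean([r.score_pct for r in results]) == pytest.approx(100.0, abs=1e-9)
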