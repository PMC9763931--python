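"""Criterion and discriminant validity statistics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from vhi.model import (
    AnimalRecord,
    Bed,
    Biomarker,
    Component,
    Group,
    UndefinedCorrelationError,
    Variant,
    VHIResult,
)
from vhi.validity import criterion_validity, discriminant_validity, pearson_r, welch_t


def brute_force_r(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    cx, cy = x - x.mean(), y - y.mean()
    return float((cx * cy).sum() / np.sqrt((cx**2).sum() * (cy**2).sum()))


class TestPearson:
    def test_perfect_linear(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert pearson_r(x, [2 * v + 1 for v in x])[0] == pytest.approx(1.0)
        assert pearson_r(x, [-v for v in x])[0] == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        x, y = [1.0, 2.0, 3.0, 4.0], [2.0, 1.0, 4.0, 3.0]
        r, _ = pearson_r(x, y)
        assert r == pytest.approx(brute_force_r(x, y), abs=1e-12)

    def test_zero_variance_raises(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @given(
        a=st.floats(0.1, 10), b=st.floats(-5, 5),
        seed=st.integers(0, 2**16),
    )
    def test_affine_invariance_and_sign_flip(self, a, b, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        r0, _ = pearson_r(x, y)
        r1, _ = pearson_r(a * x + b, y)
        assert r1 == pytest.approx(r0, abs=1e-9)
        r2, _ = pearson_r(-x, y)
        assert r2 == pytest.approx(-r0, abs=1e-9)


def _mk_results(vals, bed=Bed.CEREBRAL, variant=Variant.FIVE_COMPONENT, prefix="a"):
    out = []
    for i, v in enumerate(vals):
        out.append(VHIResult(f"{prefix}{i}", bed, variant, float(v),
                             {c: float(v) for c in Component}))
    return out


class TestCriterion:
    def test_coupled_cohort_negative_correlation(self, rng):
        """Severity drives insulin up and the index down → r < 0, small p."""
        n = 40
        z = rng.standard_normal(n)
        vhi = 80 - 10 * z + rng.normal(0, 3, n)
        insulin = 6 + 2 * z + rng.normal(0, 1, n)
        animals = {
            f"a{i}": AnimalRecord(f"a{i}", Group.OZR, 13, "S1",
                                  insulin_ng_ml=float(max(insulin[i], 0.1)))
            for i in range(n)
        }
        res = criterion_validity(_mk_results(vhi), animals, Biomarker.INSULIN)
        assert len(res) == 1
        assert res[0].pearson_r < 0
        assert res[0].p_value < 0.05
        assert res[0].n == n

    def test_groups_with_too_few_pairs_skipped(self):
        animals = {
            "a0": AnimalRecord("a0", Group.OZR, 13, "S1", insulin_ng_ml=5.0),
            "a1": AnimalRecord("a1", Group.OZR, 13, "S1", insulin_ng_ml=6.0),
        }
        assert criterion_validity(_mk_results([80, 70]), animals, Biomarker.INSULIN) == []

    def test_missing_biomarker_excluded(self, rng):
        n = 10
        animals = {
            f"a{i}": AnimalRecord(f"a{i}", Group.OZR, 13, "S1",
                                  insulin_ng_ml=None if i < 4 else float(5 + i))
            for i in range(n)
        }
        res = criterion_validity(_mk_results(rng.normal(80, 5, n)), animals,
                                 Biomarker.INSULIN)
        assert res[0].n == 6


class TestDiscriminant:
    def test_separated_groups_significant(self, rng):
        animals = {}
        results = []
        for group, mean, nm in ((Group.LZR, 100.0, "l"), (Group.OZR, 65.0, "o")):
            vals = rng.normal(mean, 5, 10)
            results += _mk_results(vals, prefix=nm)
            for i in range(10):
                animals[f"{nm}{i}"] = AnimalRecord(f"{nm}{i}", group, 17, "S1")
        out = discriminant_validity(results, animals)
        assert len(out) == 1
        d = out[0]
        assert d.group is Group.OZR and d.comparison == "vs_LZR"
        assert d.significant and d.p_value < 0.05

    def test_identical_constant_groups_not_significant(self):
        animals = {}
        results = []
        for group, nm in ((Group.LZR, "l"), (Group.OZR, "o")):
            results += _mk_results([80.0] * 4, prefix=nm)
            for i in range(4):
                animals[f"{nm}{i}"] = AnimalRecord(f"{nm}{i}", group, 17, "S1")
        out = discriminant_validity(results, animals)
        assert out[0].p_value == 1.0
        assert not out[0].significant

    def test_treated_group_compared_to_both_references(self, rng):
        animals = {}
        results = []
        for group, mean, nm in ((Group.LZR, 100.0, "l"), (Group.OZR, 65.0, "o"),
                                (Group.OZR_CAPTOPRIL, 85.0, "c")):
            results += _mk_results(rng.normal(mean, 5, 8), prefix=nm)
            for i in range(8):
                animals[f"{nm}{i}"] = AnimalRecord(f"{nm}{i}", group, 17, "S1")
        out = discriminant_validity(results, animals)
        pairs = {(d.group, d.comparison) for d in out}
        assert pairs == {(Group.OZR, "vs_LZR"), (Group.OZR_CAPTOPRIL, "vs_LZR"),
                         (Group.OZR_CAPTOPRIL, "vs_OZR")}

    def test_holm_adjustment_only_raises_pvalues(self, rng):
        animals = {}
        results = []
        for age in (7, 13, 17):
            for group, mean in ((Group.LZR, 100.0), (Group.OZR, 80.0)):
                nm = f"{group.value}{age}"
                vals = rng.normal(mean, 8, 6)
                for i, v in enumerate(vals):
                    aid = f"{nm}-{i}"
                    animals[aid] = AnimalRecord(aid, group, age, "S1")
                    results.append(VHIResult(aid, Bed.CEREBRAL, Variant.FIVE_COMPONENT,
                                             float(v), {c: float(v) for c in Component}))
        raw = {(d.age_weeks): d.p_value for d in discriminant_validity(results, animals)}
        adj = {(d.age_weeks): d.p_value for d in discriminant_validity(results, animals, holm=True)}
        for k in raw:
            assert adj[k] >= raw[k] - 1e-12


def test_welch_t_matches_scipy_and_handles_constants(rng):
    from scipy import stats

    a, b = rng.normal(0, 1, 12), rng.normal(0.5, 2, 7)
    assert welch_t(a, b) == pytest.approx(
        stats.ttest_ind(a, b, equal_var=False).pvalue)
    assert welch_t([5.0, 5.0], [5.0, 5.0]) == 1.0
    assert welch_t([5.0, 5.0], [6.0, 6.0]) == 0.0
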