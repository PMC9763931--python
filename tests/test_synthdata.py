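"""Synthetic cohort generator: determinism, distribution match, round trips."""

import numpy as np
import pytest
from scipy import stats

from vhi.model import Agonist, Bed, Component, Group
from vhi.reactivity import fit_logistic
from vhi.synthdata import (
    CellSpec,
    GenerationError,
    SyntheticCohortSpec,
    default_spec,
    draw_component_values,
    generate_cohort,
    make_dose_response,
    make_pressure_series,
)


def small_cell(n=8, mean=6.2, se=0.4):
    return CellSpec(group=Group.OZR, age_weeks=17, bed=Bed.PERIPHERAL, n=n,
                    components={Component.STIFFNESS_BETA: (mean, se)})


class TestDrawComponentValues:
    def test_zero_se_gives_constant(self, rng):
        spec = SyntheticCohortSpec(cells=[])
        vals = draw_component_values(spec, small_cell(se=0.0), rng)
        assert np.allclose(vals[Component.STIFFNESS_BETA], 6.2)

    def test_sample_mean_tracks_cell_mean(self):
        """Across replicates the sample mean is within 2·SE of the cell mean
        about as often as the sampling distribution predicts (>=95%)."""
        spec = SyntheticCohortSpec(cells=[])
        cell = small_cell(n=28, mean=6.2, se=0.4)
        rng = np.random.default_rng(5)
        hits = sum(
            abs(draw_component_values(spec, cell, rng)[Component.STIFFNESS_BETA].mean() - 6.2)
            <= 2 * 0.4
            for _ in range(1000)
        )
        assert hits >= 950

    def test_distribution_matches_generating_normal(self):
        """KS test against the generating normal passes for (nearly) all of
        several independent draws at n=500; a single unlucky draw is allowed
        its expected false-positive rate."""
        spec = SyntheticCohortSpec(cells=[])
        cell = small_cell(n=500, mean=120.0, se=5.0 / np.sqrt(500))
        pvals = [
            stats.kstest(
                draw_component_values(spec, cell, np.random.default_rng(seed))[
                    Component.STIFFNESS_BETA],
                "norm", args=(120.0, 5.0)).pvalue
            for seed in range(5)
        ]
        assert sum(p > 0.01 for p in pvals) >= 4, pvals

    def test_negative_se_rejected(self):
        with pytest.raises(Exception):
            small_cell(se=-0.1)


class TestSeriesGenerators:
    def test_noiseless_dose_response_round_trip(self, rng):
        s = make_dose_response("a1", Bed.PERIPHERAL, Agonist.ACETYLCHOLINE,
                               136.5, rng, noise_um=0.0)
        fit = fit_logistic(s)
        assert fit.upper_bound_um == pytest.approx(136.5, rel=1e-3)

    def test_nonpositive_target_rejected(self, rng):
        with pytest.raises(GenerationError):
            make_dose_response("a1", Bed.PERIPHERAL, Agonist.ACETYLCHOLINE,
                               0.0, rng)

    def test_noisy_upper_bounds_unbiased(self, rng):
        errs = [
            fit_logistic(make_dose_response("a1", Bed.PERIPHERAL,
                                            Agonist.ACETYLCHOLINE, 130.0, rng,
                                            noise_um=2.0)).upper_bound_um - 130.0
            for _ in range(200)
        ]
        n_pos = int(np.sum(np.array(errs) > 0))
        assert stats.binomtest(n_pos, len(errs)).pvalue > 0.05

    def test_pressure_series_anchor_identity(self):
        s = make_pressure_series("a1", Bed.CEREBRAL, 3.1, 2.0e3, 100.0)
        assert s.pressure_mmHg[0] == 5.0
        assert s.inner_diameter_um[0] == 100.0
        # wall annulus conserved along the series (incompressible wall)
        annulus = [od**2 - idm**2 for od, idm in
                   zip(s.outer_diameter_um, s.inner_diameter_um)]
        assert np.allclose(annulus, annulus[0], rtol=1e-9)


class TestGenerateCohort:
    def test_seed_determinism(self):
        spec = default_spec(bed=Bed.CEREBRAL, groups=[Group.OZR])
        c1 = generate_cohort(spec, seed=3)
        c2 = generate_cohort(spec, seed=3)
        assert c1.animals_frame().equals(c2.animals_frame())
        assert c1.dose_response == c2.dose_response
        assert c1.pressure_diameter == c2.pressure_diameter

    def test_different_seeds_differ_but_share_means(self):
        spec = default_spec(bed=Bed.CEREBRAL, groups=[Group.OZR])
        c1 = generate_cohort(spec, seed=3)
        c2 = generate_cohort(spec, seed=4)
        m1 = np.array([m.value for m in c1.mvd])
        m2 = np.array([m.value for m in c2.mvd])
        assert not np.array_equal(m1, m2)
        assert stats.ttest_ind(m1, m2).pvalue > 1e-4  # same generating means

    def test_end_to_end_cell_means_within_2se(self, cerebral_cohort):
        """Pipeline-recovered per-cell means sit within 2 SE of the spec."""
        from vhi import pipeline

        spec, cohort = cerebral_cohort
        out = pipeline.compute_components(cohort)
        df = out.components.merge(
            cohort.animals_frame()[["animal_id", "group", "age_weeks"]], on="animal_id")
        misses = []
        for cell in spec.cells:
            for comp, (mean, se) in cell.components.items():
                sub = df[(df.group == cell.group.value)
                         & (df.age_weeks == cell.age_weeks)
                         & (df.component == comp.value)]
                assert len(sub) == cell.n
                # sampling error of the cell mean plus a margin for fit noise
                tol = max(2 * se, 1e-6) + 0.5
                if abs(sub.value.mean() - mean) > tol:
                    misses.append((cell.key, comp.value))
        # allow the expected ~5% of cells to fall outside +-2 SE
        n_cells = sum(len(c.components) for c in spec.cells)
        assert len(misses) <= max(2, int(0.1 * n_cells)), misses

    def test_biomarkers_present_and_positive(self, cerebral_cohort):
        _, cohort = cerebral_cohort
        for a in cohort.animals.values():
            assert a.insulin_ng_ml is not None and a.insulin_ng_ml > 0
            assert a.tnfa_pg_ml is not None and a.tnfa_pg_ml > 0
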