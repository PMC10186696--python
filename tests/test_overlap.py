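"""Coefficient of overlapping: estimators, bootstrap, comparison test."""

import numpy as np
import pytest
from scipy.stats import vonmises

from dieloverlap import (
    CircularSample,
    DensityCurve,
    InputError,
    bootstrap_delta,
    compare_overlaps,
    overlap_delta,
    overlap_from_samples,
)
from dieloverlap.overlap import OverlapResult, sample_from_curve
from conftest import TWO_PI, delta_quadrature, vm_draw


def vm_curve(kappa, mu, m=512):
    grid = np.arange(m) * TWO_PI / m
    return DensityCurve(grid, vonmises(kappa, loc=mu).pdf(grid)).normalized()


def bump_curve(center, halfwidth, m=512):
    """Density supported on a single arc."""
    grid = np.arange(m) * TWO_PI / m
    d = np.abs(np.angle(np.exp(1j * (grid - center))))
    return DensityCurve(grid, np.where(d < halfwidth, 1.0, 0.0)).normalized()


class TestOverlapDelta:
    def test_identical_densities_give_one(self):
        c = vm_curve(2.0, 1.0)
        assert overlap_delta(c, c) == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_supports_give_zero(self):
        assert overlap_delta(bump_curve(0.5, 0.4), bump_curve(3.5, 0.4)) == 0.0

    def test_matches_quadrature_oracle(self):
        d = overlap_delta(vm_curve(2.0, 0.0), vm_curve(2.0, np.pi))
        assert d == pytest.approx(delta_quadrature(2.0, 0.0, 2.0, np.pi), abs=1e-4)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(InputError):
            overlap_delta(vm_curve(2.0, 0.0, m=512), vm_curve(2.0, 0.0, m=256))

    def test_symmetry_and_joint_rotation_invariance(self):
        c1, c2 = vm_curve(3.0, 1.0), vm_curve(1.0, 4.0)
        assert overlap_delta(c1, c2) == pytest.approx(overlap_delta(c2, c1), abs=1e-12)
        shift = 41 * c1.step
        r1 = vm_curve(3.0, 1.0 + shift)
        r2 = vm_curve(1.0, 4.0 + shift)
        assert overlap_delta(r1, r2) == pytest.approx(overlap_delta(c1, c2), abs=1e-9)

    def test_monotone_under_mixing(self):
        f, g = vm_curve(2.0, 0.0), vm_curve(2.0, np.pi)
        base = overlap_delta(f, g)
        prev = 1.0  # lam=0 mixes nothing: overlap is 1 and decays from there
        for lam in (0.0, 0.25, 0.5, 0.75, 1.0):
            mix = DensityCurve(f.grid, (1 - lam) * f.values + lam * g.values)
            d = overlap_delta(f, mix)
            assert d >= base - 1e-12
            assert d <= prev + 1e-12  # moving mass away from f only lowers overlap
            prev = d

    def test_grid_estimator_converges_with_grid_size(self):
        oracle = delta_quadrature(2.0, 0.5, 1.0, 3.0)
        errs = [
            abs(overlap_delta(vm_curve(2.0, 0.5, m), vm_curve(1.0, 3.0, m)) - oracle)
            for m in (64, 256, 1024)
        ]
        assert errs[0] > errs[2]
        assert errs[2] < 1e-5


class TestOverlapFromSamples:
    def test_same_sample_gives_one(self, rng):
        s = CircularSample(vm_draw(rng, 1.0, 2.0, 300))
        assert overlap_from_samples(s, s) == pytest.approx(1.0, abs=1e-6)

    def test_symmetric_in_arguments(self, rng):
        s1 = CircularSample(vm_draw(rng, 1.0, 2.0, 200))
        s2 = CircularSample(vm_draw(rng, 4.0, 1.0, 150))
        for est in ("grid", "at_points"):
            assert overlap_from_samples(s1, s2, est) == pytest.approx(
                overlap_from_samples(s2, s1, est), abs=1e-12
            )

    def test_large_sample_recovery_against_oracle(self, rng):
        oracle = delta_quadrature(2.0, 0.0, 2.0, np.pi)
        s1 = CircularSample(vm_draw(rng, 0.0, 2.0, 5000))
        s2 = CircularSample(vm_draw(rng, np.pi, 2.0, 5000))
        assert overlap_from_samples(s1, s2) == pytest.approx(oracle, abs=0.02)

    def test_auto_switches_estimator_at_75(self, rng):
        small = CircularSample(vm_draw(rng, 0.0, 2.0, 74))
        large = CircularSample(vm_draw(rng, 0.0, 2.0, 80))
        r_small = bootstrap_delta(small, small, n_boot=2, seed=0)
        r_large = bootstrap_delta(large, large, n_boot=2, seed=0)
        assert r_small.estimator == "grid"
        assert r_large.estimator == "at_points"

    def test_unknown_estimator_rejected(self, rng):
        s = CircularSample(vm_draw(rng, 0.0, 2.0, 50))
        with pytest.raises(InputError):
            overlap_from_samples(s, s, estimator="banana")


class TestBootstrapDelta:
    def test_fixed_seed_is_deterministic(self, rng):
        s1 = CircularSample(vm_draw(rng, 0.0, 2.0, 100))
        s2 = CircularSample(vm_draw(rng, 2.0, 2.0, 100))
        r1 = bootstrap_delta(s1, s2, n_boot=50, seed=7)
        r2 = bootstrap_delta(s1, s2, n_boot=50, seed=7)
        assert r1.delta == r2.delta
        assert np.array_equal(r1.replicates, r2.replicates)
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)

    def test_zero_bootstrap_requested_is_usage_error(self, rng):
        s = CircularSample(vm_draw(rng, 0.0, 2.0, 100))
        with pytest.raises(InputError):
            bootstrap_delta(s, s, n_boot=0, seed=1)

    def test_percentile_interval_brackets_replicate_median(self, rng):
        s1 = CircularSample(vm_draw(rng, 0.0, 1.5, 120))
        s2 = CircularSample(vm_draw(rng, 1.5, 1.5, 120))
        r = bootstrap_delta(s1, s2, n_boot=100, seed=3, ci_method="percentile")
        med = float(np.median(r.replicates))
        assert 0.0 <= r.ci_low <= med <= r.ci_high <= 1.0
        assert r.replicates.size == r.n_boot

    def test_raw_bootstrap_flag(self, rng):
        s1 = CircularSample(vm_draw(rng, 0.0, 1.5, 90))
        s2 = CircularSample(vm_draw(rng, 1.0, 1.5, 90))
        r = bootstrap_delta(s1, s2, n_boot=20, seed=5, smoothed=False)
        assert r.estimator.endswith("+raw_bootstrap")
        assert np.all((r.replicates >= 0) & (r.replicates <= 1))

    def test_sampling_from_curve_respects_support(self, rng):
        curve = bump_curve(1.0, 0.3)
        draws = sample_from_curve(curve, 2000, rng)
        d = np.abs(np.angle(np.exp(1j * (draws - 1.0))))
        assert np.all(d < 0.3 + curve.step)


class TestCompareOverlaps:
    @staticmethod
    def _result(reps):
        reps = np.asarray(reps, dtype=float)
        return OverlapResult(
            delta=float(np.median(reps)),
            ci_low=float(reps.min()),
            ci_high=float(reps.max()),
            n_boot=reps.size,
            replicates=reps,
            estimator="test",
        )

    def test_complete_separation(self, rng):
        r_low = self._result(rng.uniform(0.1, 0.2, 200))
        r_high = self._result(rng.uniform(0.7, 0.8, 200))
        comp = compare_overlaps(r_low, r_high)
        assert comp.statistic == 0.0
        assert comp.pvalue < 1e-10
        assert comp.effect_size == 0.0

    def test_identical_replicates_give_p_one(self, rng):
        reps = rng.uniform(0.3, 0.5, 300)
        comp = compare_overlaps(self._result(reps), self._result(reps.copy()))
        assert comp.pvalue > 0.99
        assert comp.effect_size == pytest.approx(0.5, abs=1e-9)

    def test_all_tied_replicates(self):
        comp = compare_overlaps(
            self._result(np.full(50, 0.4)), self._result(np.full(50, 0.4))
        )
        assert comp.pvalue == 1.0

    def test_empty_replicates_rejected(self):
        good = self._result(np.linspace(0.2, 0.4, 10))
        bad = OverlapResult(
            delta=0.5, ci_low=0.4, ci_high=0.6, n_boot=0,
            replicates=np.array([]), estimator="test",
        )
        with pytest.raises(InputError):
            compare_overlaps(good, bad)
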