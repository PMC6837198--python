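import itertools
import math
import warnings

import numpy as np
import pytest
from scipy import special, stats

from driftorient.angles import Frame, wrap_deg
from driftorient.circstats import (
    AngleSeries,
    EXACT_RANKSUM_MAX_N,
    angular_difference,
    circular_mean,
    ci_contains,
    kappa_from_r,
    mean_ci95,
    rank_sum_test,
    rayleigh_p,
    rayleigh_second_order,
    rayleigh_test,
    vonmises_rbar,
    _bootstrap_ci,
    _dispersion_ci,
)


# ---------------------------------------------------------------------------
# circular_mean
# ---------------------------------------------------------------------------

class TestCircularMean:
    def test_identical_angles(self):
        s = AngleSeries(np.full(600, 90.0))
        out = circular_mean(s)
        assert out.mean_bearing == pytest.approx(90.0)
        assert out.resultant_length == pytest.approx(1.0)

    def test_antipodal_pair_has_undefined_mean(self):
        out = circular_mean(AngleSeries([0.0, 180.0]))
        assert out.resultant_length == pytest.approx(0.0, abs=1e-12)
        assert out.mean_bearing is None

    def test_symmetric_pair_hand_oracle(self):
        # vector sum of unit vectors at 10 and 350 deg: east components
        # cancel, north components add to 2 cos(10 deg)
        out = circular_mean(AngleSeries([10.0, 350.0]))
        assert out.mean_bearing == pytest.approx(0.0, abs=1e-9)
        assert out.resultant_length == pytest.approx(
            math.cos(math.radians(10.0)), abs=1e-12)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError, match="no samples"):
            AngleSeries([])

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            AngleSeries([0.0, np.nan])


# ---------------------------------------------------------------------------
# Rayleigh test
# ---------------------------------------------------------------------------

def _rayleigh_p_oracle(n, rbar):
    # independent transcription of the second-order series
    z = n * rbar**2
    correction = (1 + (2 * z - z**2) / (4 * n)
                  - (24 * z - 132 * z**2 + 76 * z**3 - 9 * z**4)
                  / (288 * n**2))
    return math.exp(-z) * correction


class TestRayleigh:
    @pytest.mark.parametrize("n,rbar", [(80, 0.38), (80, 0.22), (13, 0.64),
                                        (9, 0.49), (11, 0.09), (600, 0.3)])
    def test_matches_series_oracle(self, n, rbar):
        assert rayleigh_p(n, rbar) == pytest.approx(
            min(max(_rayleigh_p_oracle(n, rbar), 0.0), 1.0), rel=1e-12)

    def test_printed_small_sample_value(self):
        # n=11, Rbar=0.09 prints as 0.92 at two decimals
        assert round(rayleigh_p(11, 0.09), 2) == 0.92

    def test_degenerate_concentration_clamped(self):
        s = AngleSeries(np.full(10, 33.0))
        out = rayleigh_test(s)
        assert 0.0 <= out.p_value <= 1.0
        assert out.p_value < 1e-3

    def test_z_equals_n_rbar_squared(self):
        rng = np.random.default_rng(7)
        s = AngleSeries(rng.uniform(0, 360, 50))
        out = rayleigh_test(s)
        assert out.rayleigh_z == pytest.approx(
            out.n * out.resultant_length**2, rel=1e-12)

    def test_small_n_warns(self):
        with pytest.warns(UserWarning, match="little meaning"):
            rayleigh_test(AngleSeries([10.0, 20.0]))

    def test_null_rejection_rate(self):
        # Monte-Carlo null oracle at reduced size; the full-size version
        # (n=600, 2000 reps) runs in the acceptance suite
        rng = np.random.default_rng(42)
        angles = rng.uniform(0, 360, size=(500, 600))
        rad = np.deg2rad(angles)
        rbar = np.hypot(np.mean(np.sin(rad), axis=1),
                        np.mean(np.cos(rad), axis=1))
        rate = np.mean([rayleigh_p(600, r) < 0.05 for r in rbar])
        assert 0.025 <= rate <= 0.08


class TestRayleighSecondOrder:
    def test_group_too_small(self):
        with pytest.raises(ValueError, match="group too small"):
            rayleigh_second_order(AngleSeries([10.0]))

    def test_antipodal_pair(self):
        out = rayleigh_second_order(AngleSeries([0.0, 180.0]))
        assert out.resultant_length == pytest.approx(0.0, abs=1e-12)
        assert out.p_value > 0.95

    def test_consistency_with_first_order(self):
        rng = np.random.default_rng(3)
        angles = rng.uniform(0, 360, 12)
        a = rayleigh_second_order(AngleSeries(angles))
        b = rayleigh_test(AngleSeries(angles))
        assert a.p_value == b.p_value
        assert a.resultant_length == b.resultant_length

    def test_recovers_population_mean(self):
        # simulation oracle: 45 means from von Mises(195 deg, kappa with
        # E[Rbar] ~ 0.42). The large-sample arc slightly under-covers at
        # this size; the oracle puts coverage at 0.92, so assert the
        # frozen band around it rather than the nominal 0.95.
        kappa = kappa_from_r(0.42)
        rng = np.random.default_rng(11)
        hits = 0
        for _ in range(500):
            means = wrap_deg(np.rad2deg(
                rng.vonmises(np.deg2rad(195.0), kappa, size=45)))
            out = rayleigh_second_order(AngleSeries(means))
            if out.ci95_lower is None:
                continue
            hits += ci_contains(out.ci95_lower, out.ci95_upper, 195.0)
        assert 0.90 <= hits / 500 <= 0.97


# ---------------------------------------------------------------------------
# confidence intervals
# ---------------------------------------------------------------------------

class TestMeanCI:
    def test_zero_width_at_full_concentration(self):
        s = AngleSeries(np.full(30, 120.0))
        lo, hi = mean_ci95(s)
        assert lo == pytest.approx(120.0, abs=1e-5)
        assert hi == pytest.approx(120.0, abs=1e-5)

    def test_undefined_when_not_significant(self):
        rng = np.random.default_rng(0)
        s = AngleSeries(rng.uniform(0, 360, 40))
        assert rayleigh_test(s, ci=False).p_value > 0.05
        assert mean_ci95(s) == (None, None)

    def test_coverage_large_sample(self):
        # 1000 reps of n=600 von Mises(180, kappa=1); the arc should
        # contain 180 about 95% of the time
        rng = np.random.default_rng(21)
        z975 = stats.norm.ppf(0.975)
        hits = total = 0
        rad = rng.vonmises(np.deg2rad(180.0), 1.0, size=(1000, 600))
        for row in rad:
            s = AngleSeries(wrap_deg(np.rad2deg(row)))
            lo, hi = mean_ci95(s)
            if lo is None:
                continue
            total += 1
            hits += ci_contains(lo, hi, 180.0)
        assert total >= 990
        assert 0.93 <= hits / total <= 0.97

    def test_analytic_and_bootstrap_agree(self):
        rng = np.random.default_rng(5)
        angles = wrap_deg(np.rad2deg(
            rng.vonmises(np.deg2rad(90.0), 2.0, size=200)))
        s = AngleSeries(angles)
        lo_a, hi_a = _dispersion_ci(s)
        lo_b, hi_b = _bootstrap_ci(s, seed=1)
        half_a = wrap_deg(hi_a - lo_a) / 2
        half_b = wrap_deg(hi_b - lo_b) / 2
        assert abs(half_a - half_b) < 5.0

    def test_arc_width_below_full_circle(self):
        rng = np.random.default_rng(9)
        angles = wrap_deg(np.rad2deg(
            rng.vonmises(np.deg2rad(10.0), 0.8, size=60)))
        lo, hi = mean_ci95(AngleSeries(angles))
        if lo is not None:
            assert 0.0 <= wrap_deg(hi - lo) < 360.0


# ---------------------------------------------------------------------------
# angular arithmetic
# ---------------------------------------------------------------------------

class TestAngularDifference:
    @pytest.mark.parametrize("a,b,expected", [
        (10.0, 10.0, 0.0),
        (350.0, 10.0, 340.0),
        (195.0, 179.0, 16.0),  # arithmetic oracle: 195 - 179
    ])
    def test_examples(self, a, b, expected):
        assert angular_difference(a, b) == pytest.approx(expected)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            angular_difference(np.inf, 0.0)


# ---------------------------------------------------------------------------
# von Mises utilities
# ---------------------------------------------------------------------------

class TestKappaFromR:
    def test_zero(self):
        assert kappa_from_r(0.0) == 0.0

    def test_value_at_030(self):
        # Bessel oracle: solve I1(k)/I0(k) = 0.30 by bisection on scipy's
        # Bessel functions, independent of the implementation's solver
        lo, hi = 0.0, 10.0
        for _ in range(60):
            mid = (lo + hi) / 2
            if special.i1(mid) / special.i0(mid) < 0.30:
                lo = mid
            else:
                hi = mid
        assert kappa_from_r(0.30) == pytest.approx((lo + hi) / 2, abs=1e-6)
        assert kappa_from_r(0.30) == pytest.approx(0.63, abs=0.01)

    @pytest.mark.parametrize("rbar", np.round(np.arange(0.1, 0.95, 0.1), 2))
    def test_round_trip(self, rbar):
        assert vonmises_rbar(kappa_from_r(rbar)) == pytest.approx(
            rbar, abs=1e-6)

    def test_monotone(self):
        ks = [kappa_from_r(r) for r in np.linspace(0.0, 0.95, 20)]
        assert np.all(np.diff(ks) > 0)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            kappa_from_r(1.0)


# ---------------------------------------------------------------------------
# rank-sum test
# ---------------------------------------------------------------------------

def _enumeration_oracle(a, b):
    """Independent two-sided permutation p-value from scipy midranks."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n1 = len(a)
    obs = ranks[:n1].sum()
    center = n1 * ranks.sum() / len(pooled)
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        w = ranks[list(combo)].sum()
        if abs(w - center) >= abs(obs - center) - 1e-9:
            count += 1
        total += 1
    return count / total


class TestRankSum:
    def test_separated_triples(self):
        # full enumeration over C(6,3)=20 assignments: only the two
        # extreme splits are as extreme as the observed one
        out = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert out.method == "exact_enumeration"
        assert out.p_value == pytest.approx(0.10)

    def test_identical_groups(self):
        with pytest.warns(UserWarning, match="identical"):
            out = rank_sum_test([2.0, 2.0], [2.0, 2.0, 2.0])
        assert out.p_value == 1.0

    def test_medians_reported(self):
        out = rank_sum_test([1.0, 3.0, 5.0], [2.0, 4.0, 6.0, 8.0])
        assert out.median1 == 3.0
        assert out.median2 == 5.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])

    def test_exact_branch_threshold(self):
        rng = np.random.default_rng(2)
        small = rank_sum_test(rng.normal(size=10), rng.normal(size=10))
        large = rank_sum_test(rng.normal(size=11), rng.normal(size=5))
        assert small.method == "exact_enumeration"
        assert large.method == "normal_approximation"

    @pytest.mark.parametrize("n1,n2", [(2, 3), (3, 3), (4, 2), (5, 5),
                                       (4, 6), (3, 7)])
    def test_exact_matches_enumeration_oracle(self, n1, n2):
        rng = np.random.default_rng(n1 * 13 + n2)
        for _ in range(5):
            a = rng.integers(0, 4, size=n1).astype(float)  # forces ties
            b = rng.integers(0, 4, size=n2).astype(float)
            if np.all(np.concatenate([a, b]) == a[0]):
                continue
            out = rank_sum_test(a, b)
            assert out.p_value == pytest.approx(_enumeration_oracle(a, b))

    def test_normal_branch_against_scipy(self):
        rng = np.random.default_rng(8)
        a = rng.normal(size=40)
        b = rng.normal(0.5, size=35)
        out = rank_sum_test(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
        assert out.p_value == pytest.approx(ref.pvalue, rel=1e-6)
        assert out.statistic == pytest.approx(ref.statistic)

    def test_null_rejection_rate(self):
        rng = np.random.default_rng(15)
        rejections = 0
        reps = 2000
        for _ in range(reps):
            a = rng.normal(size=25)
            b = rng.normal(size=20)
            if rank_sum_test(a, b).p_value < 0.05:
                rejections += 1
        assert 0.04 <= rejections / reps <= 0.06
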