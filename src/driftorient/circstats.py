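"""Circular and rank statistics for orientation analysis.

Implements first- and second-order circular summaries (mean direction,
mean resultant length, Rayleigh uniformity test with the series-corrected
p-value), 95% confidence arcs for the mean direction, angular arithmetic,
von Mises concentration inversion and a two-sided Wilcoxon rank-sum test
with an exact small-sample branch.

Conventions: angles are degrees in [0, 360), clockwise from north.
The Rayleigh p-value uses the second-order series

    p = exp(-Z) * [1 + (2Z - Z^2)/(4n) - (24Z - 132Z^2 + 76Z^3 - 9Z^4)/(288n^2)]

with Z = n * Rbar^2, clamped into [0, 1] (the series goes negative for
large Z).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import special, optimize

from driftorient.angles import Frame, wrap_deg, wrap_signed_deg

#: Below this mean resultant length the mean direction is reported undefined.
EPS_RESULTANT = 1e-12

#: Largest group size for which the rank-sum test enumerates exactly.
EXACT_RANKSUM_MAX_N = 10

_Z975 = 1.959963984540054  # standard normal 97.5% quantile


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AngleSeries:
    """A sequence of bearings (degrees, [0, 360)) in a named frame."""

    angles: np.ndarray
    frame: Frame = Frame.MAGNETIC_NORTH

    def __post_init__(self):
        arr = np.asarray(self.angles, dtype=float)
        if arr.ndim != 1:
            raise ValueError("angles must be one-dimensional")
        if arr.size < 1:
            raise ValueError("no samples")
        if not np.all(np.isfinite(arr)):
            raise ValueError("non-finite angles")
        object.__setattr__(self, "angles", wrap_deg(arr))
        object.__setattr__(self, "frame", Frame(self.frame))

    @property
    def n(self) -> int:
        return int(self.angles.size)

    def rotated(self, offset_deg: float) -> "AngleSeries":
        """Return a copy with a constant added to every angle (mod 360)."""
        return AngleSeries(wrap_deg(self.angles + offset_deg), self.frame)


@dataclass(frozen=True)
class CircularSummary:
    """Mean direction, dispersion and Rayleigh uniformity test for one sample.

    ``mean_bearing`` is ``None`` when the resultant is numerically zero;
    ``ci95_lower``/``ci95_upper`` are ``None`` unless the Rayleigh test is
    significant at 0.05 and n >= 5.
    """

    mean_bearing: Optional[float]
    resultant_length: float
    rayleigh_z: float
    p_value: float
    n: int
    frame: Frame
    ci95_lower: Optional[float] = None
    ci95_upper: Optional[float] = None

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


@dataclass(frozen=True)
class RankTestResult:
    """Two-sided Wilcoxon/Mann-Whitney rank-sum comparison of two samples."""

    statistic: float  # Mann-Whitney U for the first sample
    p_value: float
    method: str  # "exact_enumeration" | "normal_approximation"
    n1: int
    n2: int
    median1: float
    median2: float


# ---------------------------------------------------------------------------
# first-order statistics
# ---------------------------------------------------------------------------

def _mean_vector(angles_deg: np.ndarray) -> tuple[float, float]:
    """Mean (east, north) components of the unit vectors of a sample."""
    rad = np.deg2rad(angles_deg)
    return float(np.mean(np.sin(rad))), float(np.mean(np.cos(rad)))


def circular_mean(series: AngleSeries) -> CircularSummary:
    """Mean direction and mean resultant length (no uniformity test).

    ``rayleigh_z`` is still n * Rbar^2, but ``p_value`` is NaN, signalling
    "not tested"; use :func:`rayleigh_test` for the full summary.
    """
    e, c = _mean_vector(series.angles)
    rbar = float(np.hypot(e, c))
    rbar = min(rbar, 1.0)
    if rbar < EPS_RESULTANT:
        mean = None
    else:
        mean = wrap_deg(np.rad2deg(np.arctan2(e, c)))
    return CircularSummary(
        mean_bearing=mean,
        resultant_length=rbar,
        rayleigh_z=series.n * rbar**2,
        p_value=float("nan"),
        n=series.n,
        frame=series.frame,
    )


def rayleigh_p(n: int, rbar: float) -> float:
    """Series-corrected Rayleigh p-value from sample size and Rbar."""
    z = n * rbar * rbar
    p = np.exp(-z) * (
        1.0
        + (2.0 * z - z**2) / (4.0 * n)
        - (24.0 * z - 132.0 * z**2 + 76.0 * z**3 - 9.0 * z**4) / (288.0 * n**2)
    )
    return float(min(max(p, 0.0), 1.0))


def rayleigh_test(series: AngleSeries, ci: bool = True) -> CircularSummary:
    """Rayleigh test of circular uniformity for one sample.

    A 95% confidence arc for the mean is attached when the test is
    significant at 0.05 and n >= 5 (and ``ci`` is not disabled).
    """
    if series.n < 3:
        warnings.warn(
            f"Rayleigh test with n={series.n} < 3 has little meaning",
            stacklevel=2,
        )
    base = circular_mean(series)
    p = rayleigh_p(series.n, base.resultant_length)
    lo = hi = None
    if ci and p < 0.05 and series.n >= 5 and base.mean_bearing is not None:
        lo, hi = mean_ci95(series, _p_value=p)
    return CircularSummary(
        mean_bearing=base.mean_bearing,
        resultant_length=base.resultant_length,
        rayleigh_z=base.rayleigh_z,
        p_value=p,
        n=series.n,
        frame=series.frame,
        ci95_lower=lo,
        ci95_upper=hi,
    )


def rayleigh_second_order(means: AngleSeries, ci: bool = True) -> CircularSummary:
    """Rayleigh test applied to one mean bearing per individual.

    Mathematically identical to :func:`rayleigh_test`; each individual
    contributes one equally weighted angle. The caller is responsible for
    restricting the input to individuals passing the significance filter.
    """
    if means.n < 2:
        raise ValueError("group too small")
    return rayleigh_test(means, ci=ci)


# ---------------------------------------------------------------------------
# confidence intervals
# ---------------------------------------------------------------------------

def _dispersion_ci(series: AngleSeries) -> Optional[tuple[float, float]]:
    """Large-sample circular-dispersion confidence arc (Fisher 1993, 4.4.4a)."""
    summary = circular_mean(series)
    if summary.mean_bearing is None:
        return None
    rbar = summary.resultant_length
    rad = np.deg2rad(series.angles)
    mean_rad = np.deg2rad(summary.mean_bearing)
    rho2 = float(np.hypot(np.mean(np.sin(2 * rad)), np.mean(np.cos(2 * rad))))
    dispersion = (1.0 - rho2) / (2.0 * rbar**2)
    sigma = np.sqrt(dispersion / series.n)
    arg = _Z975 * sigma
    if arg >= 1.0:
        return None  # arc would exceed the half-circle; caller falls back
    half = np.arcsin(arg)
    lo = wrap_deg(np.rad2deg(mean_rad - half))
    hi = wrap_deg(np.rad2deg(mean_rad + half))
    return lo, hi


def _bootstrap_ci(
    series: AngleSeries, n_boot: int = 2000, seed: int = 0
) -> Optional[tuple[float, float]]:
    """Percentile bootstrap arc around the sample mean direction."""
    summary = circular_mean(series)
    if summary.mean_bearing is None:
        return None
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, series.n, size=(n_boot, series.n))
    rad = np.deg2rad(series.angles[idx])
    means = np.rad2deg(np.arctan2(np.mean(np.sin(rad), axis=1),
                                  np.mean(np.cos(rad), axis=1)))
    dev = wrap_signed_deg(means - summary.mean_bearing)
    lo_dev, hi_dev = np.percentile(dev, [2.5, 97.5])
    if hi_dev - lo_dev >= 360.0:
        return None
    return (wrap_deg(summary.mean_bearing + lo_dev),
            wrap_deg(summary.mean_bearing + hi_dev))


def mean_ci95(
    series: AngleSeries,
    n_boot: int = 2000,
    seed: int = 0,
    _p_value: Optional[float] = None,
) -> tuple[Optional[float], Optional[float]]:
    """95% confidence arc for the mean direction.

    Uses the large-sample circular-dispersion method, falling back to a
    percentile bootstrap (``n_boot`` replicates, fixed ``seed``) when the
    sample is small (n < 25) or diffuse (Rbar < 0.2). Returns ``(None,
    None)`` when the preconditions (Rayleigh p < 0.05 and n >= 5) fail.
    """
    p = _p_value
    if p is None:
        p = rayleigh_p(series.n, circular_mean(series).resultant_length)
    if p >= 0.05 or series.n < 5:
        return None, None
    rbar = circular_mean(series).resultant_length
    out = None
    if series.n >= 25 and rbar >= 0.2:
        out = _dispersion_ci(series)
    if out is None:
        out = _bootstrap_ci(series, n_boot=n_boot, seed=seed)
    if out is None:
        return None, None
    return out


def ci_contains(lo: float, hi: float, angle: float) -> bool:
    """True if ``angle`` lies on the arc from ``lo`` to ``hi`` (clockwise)."""
    return wrap_deg(angle - lo) <= wrap_deg(hi - lo)


# ---------------------------------------------------------------------------
# angular arithmetic
# ---------------------------------------------------------------------------

def angular_difference(a: float, b: float) -> float:
    """wrap(a - b) into [0, 360); 0 = toward the cue at b, 180 = away."""
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite angle")
    return wrap_deg(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


# ---------------------------------------------------------------------------
# von Mises utilities
# ---------------------------------------------------------------------------

def vonmises_rbar(kappa: float) -> float:
    """Population mean resultant length A(kappa) = I1(kappa)/I0(kappa)."""
    if kappa == 0.0:
        return 0.0
    # exponentially scaled Bessel ratios avoid overflow for large kappa
    return float(special.i1e(kappa) / special.i0e(kappa))


def kappa_from_r(rbar: float) -> float:
    """Invert A(kappa) = rbar numerically (|A(k) - rbar| < 1e-6)."""
    if not 0.0 <= rbar < 1.0:
        raise ValueError("degenerate concentration")
    if rbar == 0.0:
        return 0.0
    hi = 2.0
    while vonmises_rbar(hi) < rbar:
        hi *= 2.0
        if hi > 1e8:  # pragma: no cover - rbar < 1 guards this
            raise ValueError("degenerate concentration")
    return float(optimize.brentq(
        lambda k: vonmises_rbar(k) - rbar, 0.0, hi, xtol=1e-9))


# ---------------------------------------------------------------------------
# rank-sum test
# ---------------------------------------------------------------------------

def _midranks(pooled: np.ndarray) -> np.ndarray:
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(pooled.size, dtype=float)
    sorted_vals = pooled[order]
    i = 0
    while i < pooled.size:
        j = i
        while j + 1 < pooled.size and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _exact_ranksum_p(ranks: np.ndarray, n1: int, observed: float) -> float:
    """Two-sided exact p by full enumeration over rank assignments.

    Works in doubled-integer rank units (midranks are multiples of 0.5) so
    all comparisons are exact; the deviation is measured from the
    permutation-null mean n1 * sum(ranks) / n, scaled by n to stay integer.
    """
    n = ranks.size
    r2 = np.rint(ranks * 2).astype(np.int64)  # 2 * midrank, integer
    s2 = int(r2.sum())
    obs_dev = abs(int(np.rint(2 * observed)) * n - n1 * s2)
    total = 0
    extreme = 0
    for combo in itertools.combinations(range(n), n1):
        w2 = int(sum(r2[i] for i in combo))
        if abs(w2 * n - n1 * s2) >= obs_dev:
            extreme += 1
        total += 1
    return extreme / total


def rank_sum_test(
    speeds_a: Sequence[float], speeds_b: Sequence[float]
) -> RankTestResult:
    """Two-sided Wilcoxon rank-sum test.

    Exact enumeration when both group sizes are <= 10; otherwise a normal
    approximation with tie and continuity corrections.
    """
    a = np.asarray(speeds_a, dtype=float)
    b = np.asarray(speeds_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    w = float(ranks[:n1].sum())
    u = w - n1 * (n1 + 1) / 2.0
    median1, median2 = float(np.median(a)), float(np.median(b))

    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical across both groups", stacklevel=2)
        return RankTestResult(u, 1.0, "degenerate", n1, n2, median1, median2)

    if max(n1, n2) <= EXACT_RANKSUM_MAX_N:
        p = _exact_ranksum_p(ranks, n1, w)
        method = "exact_enumeration"
    else:
        n = n1 + n2
        mu = n1 * (n1 + 1) / 2.0 + n1 * n2 / 2.0
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(counts**3 - counts))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var <= 0:
            p = 1.0
        else:
            dev = abs(w - mu)
            z = max(dev - 0.5, 0.0) / np.sqrt(var)  # continuity correction
            p = float(2.0 * special.ndtr(-z))
        p = min(p, 1.0)
        method = "normal_approximation"
    p = max(min(p, 1.0), np.nextafter(0.0, 1.0))
    return RankTestResult(u, p, method, n1, n2, median1, median2)
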