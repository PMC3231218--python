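"""Statistical sampling tests on reconstructed holographic images.

Recognition works on *sampling segments*: sets of n pixel values drawn at
random (without replacement within a segment) from one channel — real or
imaginary part — of the segmented complex reconstruction.  Two families of
two-sample tests compare a reference segment against an unknown-input
segment:

* **Parametric variance-ratio (F) test.**  Channel values are modelled as
  i.i.d. Gaussian; the statistic is the ratio of unbiased sample variances,
  F = V^[r]/V^[s], which under the null hypothesis of equal population
  variances follows an F distribution with (n_r-1, n_s-1) degrees of
  freedom.  The two-tailed decision rule at level alpha accepts the null
  when F lies inside [F_{alpha/2}, F_{1-alpha/2}]; the matching
  confidence interval for the population variance ratio sigma_r^2/sigma_s^2
  has coverage 1-alpha.  p-values come either from the analytic F
  distribution or from Monte-Carlo simulation of null ratios.

* **Nonparametric ECDF discriminant.**  Distribution-free: the statistic
  Lambda is the mean squared difference between the two segments' empirical
  CDFs over an evaluation grid (a Cramer-von-Mises-type quantity, bounded
  in [0, 1]).  Its null distribution Lambda-tilde is built empirically from
  disjoint pairs of reference segments, and the p-value is the add-one
  upper-tail proportion, so p is never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .optics import ComplexField
from .segment import TargetMask

__all__ = [
    "SamplingSegment",
    "VarianceRatioResult",
    "EcdfTestResult",
    "draw_segments",
    "variance_ratio_test",
    "ecdf",
    "ecdf_statistic",
    "ecdf_null_distribution",
    "ecdf_test",
]

CHANNELS = ("real", "imaginary")


@dataclass
class SamplingSegment:
    """n pixel values drawn from one channel of a masked reconstruction."""

    values: np.ndarray
    channel: str
    source_id: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("a sampling segment needs at least 2 scalar values")
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}")

    @property
    def n(self) -> int:
        return self.values.size


@dataclass
class VarianceRatioResult:
    """Outcome of the two-tailed variance-ratio (F) test."""

    statistic: float
    dof: tuple[int, int]
    sample_variances: tuple[float, float]
    alpha: float
    acceptance_interval: tuple[float, float]
    p_value: float
    decision: str
    ci_variance_ratio: tuple[float, float]

    @property
    def accepted(self) -> bool:
        return self.decision == "accept_H0"


@dataclass
class EcdfTestResult:
    """Outcome of the nonparametric ECDF discriminant test."""

    statistic: float
    null_statistics: np.ndarray = field(repr=False)
    p_value: float
    alpha: float
    decision: str

    @property
    def accepted(self) -> bool:
        return self.decision == "accept_H0"


def draw_segments(
    field_in: ComplexField,
    mask: TargetMask,
    n: int,
    m: int,
    channel: str,
    seed: int,
    source_id: str = "",
) -> list[SamplingSegment]:
    """Draw m sampling segments of n masked pixel values from one channel.

    Pixels within a segment are distinct sites (sampling without
    replacement); segments are drawn independently of one another, so
    overlap across segments is allowed.  Reproducible for a fixed seed.
    """
    if channel not in CHANNELS:
        raise ValueError(f"channel must be one of {CHANNELS}")
    if m < 1:
        raise ValueError("m must be >= 1")
    pool = field_in.values.real if channel == "real" else field_in.values.imag
    pool = pool[mask.mask]
    if n > pool.size:
        raise ValueError(
            f"n={n} exceeds the {pool.size} masked pixels; reduce n or enlarge "
            "the mask (sampling is without replacement within a segment)"
        )
    rng = np.random.default_rng(seed)
    out = []
    for j in range(m):
        idx = rng.choice(pool.size, size=n, replace=False)
        out.append(SamplingSegment(pool[idx], channel, source_id=source_id, seed=seed))
    return out


def variance_ratio_test(
    ref: SamplingSegment,
    inp: SamplingSegment,
    alpha: float = 0.01,
    p_mode: str = "analytic",
    n_mc: int = 10_000,
    seed: int = 0,
) -> VarianceRatioResult:
    """Two-tailed F test for equality of two population variances.

    F is the ratio of unbiased sample variances (reference over input).
    The null is accepted iff F lies inside the central 1-alpha interval of
    the F(n_r-1, n_s-1) distribution.  ``p_mode="monte_carlo"`` estimates
    the p-value from ``n_mc`` simulated null ratios (Gaussian samples at
    the pooled variance) with the add-one estimator; ``"analytic"`` uses
    the exact F distribution.  Also returns the 1-alpha confidence interval
    for the population variance ratio.
    """
    if ref.channel != inp.channel:
        raise ValueError("segments must come from the same channel")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if p_mode not in ("analytic", "monte_carlo"):
        raise ValueError("p_mode must be 'analytic' or 'monte_carlo'")
    v_ref = float(np.var(ref.values, ddof=1))
    v_inp = float(np.var(inp.values, ddof=1))
    if v_ref == 0 or v_inp == 0:
        raise ValueError("degenerate segment: zero sample variance")
    f_stat = v_ref / v_inp
    dfn, dfd = ref.n - 1, inp.n - 1
    dist = stats.f(dfn, dfd)
    lo, hi = dist.ppf(alpha / 2), dist.ppf(1 - alpha / 2)
    decision = "accept_H0" if lo <= f_stat <= hi else "reject_H0"

    if p_mode == "analytic":
        p = 2 * min(dist.cdf(f_stat), dist.sf(f_stat))
    else:
        rng = np.random.default_rng(seed)
        pooled = ((ref.n - 1) * v_ref + (inp.n - 1) * v_inp) / (ref.n + inp.n - 2)
        sd = np.sqrt(pooled)
        a = rng.normal(0.0, sd, size=(n_mc, ref.n)).var(axis=1, ddof=1)
        b = rng.normal(0.0, sd, size=(n_mc, inp.n)).var(axis=1, ddof=1)
        null = a / b
        p_lo = (1 + np.count_nonzero(null <= f_stat)) / (1 + n_mc)
        p_hi = (1 + np.count_nonzero(null >= f_stat)) / (1 + n_mc)
        p = 2 * min(p_lo, p_hi)
    p = float(min(p, 1.0))

    ci = (f_stat / hi, f_stat / lo)
    return VarianceRatioResult(
        statistic=f_stat,
        dof=(dfn, dfd),
        sample_variances=(v_ref, v_inp),
        alpha=alpha,
        acceptance_interval=(float(lo), float(hi)),
        p_value=p,
        decision=decision,
        ci_variance_ratio=(float(ci[0]), float(ci[1])),
    )


def ecdf(values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Empirical CDF of ``values`` sampled at the points of ``grid``.

    Right-continuous: at each grid point u, the fraction of values <= u.
    """
    values = np.asarray(values, dtype=np.float64)
    grid = np.asarray(grid, dtype=np.float64)
    if values.size == 0:
        raise ValueError("values must be nonempty")
    if grid.size == 0:
        raise ValueError("grid must be nonempty")
    if np.any(np.diff(grid) < 0):
        raise ValueError("grid must be sorted ascending")
    return np.searchsorted(np.sort(values), grid, side="right") / values.size


def _evaluation_grid(a: np.ndarray, b: np.ndarray, grid_mode: str, n_grid: int = 256) -> np.ndarray:
    if grid_mode == "pooled_points":
        return np.sort(np.concatenate([a, b]))
    if grid_mode == "fixed_linear":
        lo = min(a.min(), b.min())
        hi = max(a.max(), b.max())
        return np.linspace(lo, hi, n_grid)
    raise ValueError("grid_mode must be 'pooled_points' or 'fixed_linear'")


def ecdf_statistic(
    a: SamplingSegment, b: SamplingSegment, grid_mode: str = "pooled_points"
) -> float:
    """Mean squared ECDF difference Lambda between two segments, in [0, 1].

    The evaluation grid is the pooled sample points of the two segments by
    default (scale-free and symmetric in the two arguments), or a fixed
    linear grid spanning the pooled range.
    """
    if a.channel != b.channel:
        raise ValueError("segments must come from the same channel")
    grid = _evaluation_grid(a.values, b.values, grid_mode)
    fa = ecdf(a.values, grid)
    fb = ecdf(b.values, grid)
    return float(np.mean((fa - fb) ** 2))


def lambda_pairs_pooled(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise pooled-grid ECDF statistic for batches of segment pairs.

    ``a`` and ``b`` are (R, n) arrays; returns R statistics.  Equivalent to
    ``ecdf_statistic`` with ``grid_mode="pooled_points"`` for tie-free rows
    (within a tie run of pooled values the rank-based ECDFs are evaluated
    mid-run, which differs from the right-continuous convention only on
    exact duplicates).
    """
    a = np.atleast_2d(np.asarray(a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(b, dtype=np.float64))
    if a.shape != b.shape:
        raise ValueError("a and b must have the same shape")
    n = a.shape[1]
    pooled = np.concatenate([a, b], axis=1)
    order = np.argsort(pooled, axis=1, kind="stable")
    from_a = order < n
    cum_a = np.cumsum(from_a, axis=1)
    k = np.arange(1, 2 * n + 1)
    f_a = cum_a / n
    f_b = (k[None, :] - cum_a) / n
    return np.mean((f_a - f_b) ** 2, axis=1)


def ecdf_null_distribution(
    segments: Sequence[SamplingSegment], grid_mode: str = "pooled_points"
) -> np.ndarray:
    """Null statistics Lambda-tilde from disjoint pairs of reference segments.

    2k segments yield k null values (segment 0 vs 1, 2 vs 3, ...); an odd
    trailing segment is ignored.
    """
    k = len(segments) // 2
    if k < 1:
        raise ValueError("need at least 2 reference segments to form the null")
    return np.array(
        [ecdf_statistic(segments[2 * j], segments[2 * j + 1], grid_mode) for j in range(k)]
    )


def ecdf_test(
    ref_segments: Sequence[SamplingSegment],
    inp: SamplingSegment,
    alpha: float = 0.01,
    *,
    grid_mode: str = "pooled_points",
    null_statistics: np.ndarray | None = None,
) -> EcdfTestResult:
    """Nonparametric ECDF discriminant test of an input segment.

    The observed statistic compares the input against the reference *pivot*
    segment ``ref_segments[0]``; the null distribution is built from
    disjoint pairs of the remaining reference segments (or supplied
    precomputed via ``null_statistics``).  The add-one upper-tail p-value
    p = (1 + #{Lambda-tilde >= Lambda}) / (1 + K) rejects the null when
    p < alpha — note that rejection at level alpha therefore requires a
    null ensemble of K >= 1/alpha values.
    """
    if len(ref_segments) < 2 and null_statistics is None:
        raise ValueError("need at least 2 reference segments")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    pivot = ref_segments[0]
    if null_statistics is None:
        null_statistics = ecdf_null_distribution(ref_segments[1:], grid_mode)
        if null_statistics.size == 0:
            raise ValueError("need at least 3 reference segments (1 pivot + 1 pair)")
    null_statistics = np.asarray(null_statistics, dtype=np.float64)
    lam = ecdf_statistic(pivot, inp, grid_mode)
    p = float((1 + np.count_nonzero(null_statistics >= lam)) / (1 + null_statistics.size))
    decision = "reject_H0" if p < alpha else "accept_H0"
    return EcdfTestResult(
        statistic=lam,
        null_statistics=null_statistics,
        p_value=p,
        alpha=alpha,
        decision=decision,
    )
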