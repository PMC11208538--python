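"""Temporal-complexity features of ROI time series.

Four scalar features per series, as used throughout the package:

* ``hurst_rs``            — Hurst exponent by rescaled-range (R/S) analysis,
                            with the Anis–Lloyd–Peters small-sample correction;
* ``weighted_permutation_entropy`` — ordinal-pattern entropy with
                            amplitude-variance weights, normalized to [0, 1];
* ``range_entropy_B_auc`` — area under the RangeEn_B trajectory over the
                            tolerance axis r in (0, 1];
* ``multiscale_entropy_auc`` — area under the sample-entropy-vs-scale curve
                            divided by the maximum scale.

Sample entropy underlies the last two.  Undefined entropies (zero match
counts) are reported as NaN markers, never silently as numbers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import gamma as gamma_fn

logger = logging.getLogger(__name__)

MIN_SERIES_LENGTH = 32  # design center is 490 samples; override per call

__all__ = [
    "EmbeddingParams",
    "EntropyTrajectory",
    "hurst_rs",
    "weighted_permutation_entropy",
    "sample_entropy",
    "range_entropy_B",
    "range_entropy_B_trajectory",
    "range_entropy_B_auc",
    "coarse_grain",
    "multiscale_entropy_trajectory",
    "multiscale_entropy_auc",
    "default_r_grid",
]


@dataclass(frozen=True)
class EmbeddingParams:
    """Embedding dimension m, time delay tau, tolerance r (SD-relative)."""

    m: int = 2
    tau: int = 1
    r: float = 0.5

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("embedding dimension m must be >= 2")
        if self.tau < 1:
            raise ValueError("time delay tau must be >= 1")
        if self.r < 0:
            raise ValueError("tolerance r must be >= 0")


@dataclass
class EntropyTrajectory:
    """Entropy values along an ordered abscissa (r grid or scales)."""

    abscissa: np.ndarray
    entropy: np.ndarray
    kind: str  # {"range_r", "mse_scale"}

    def __post_init__(self) -> None:
        self.abscissa = np.asarray(self.abscissa, dtype=float)
        self.entropy = np.asarray(self.entropy, dtype=float)
        if self.abscissa.ndim != 1 or self.abscissa.shape != self.entropy.shape:
            raise ValueError("abscissa and entropy must be 1-D, same length")
        if np.any(np.diff(self.abscissa) <= 0):
            raise ValueError("abscissa must be strictly increasing")

    def auc(self) -> float:
        """Trapezoidal area; NaN (undefined) points are dropped and the area
        rescaled to the full abscissa span so trajectories with different
        numbers of defined points stay comparable."""
        defined = np.isfinite(self.entropy)
        if defined.sum() < 2:
            return float("nan")
        if not defined.all():
            logger.warning(
                "%d undefined entropy point(s) dropped from AUC",
                int((~defined).sum()),
            )
        x, y = self.abscissa[defined], self.entropy[defined]
        area = float(np.trapezoid(y, x))
        full_span = self.abscissa[-1] - self.abscissa[0]
        span = x[-1] - x[0]
        if span <= 0:
            return float("nan")
        return area * full_span / span


def _check_series(x: np.ndarray, min_length: int) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size < min_length:
        raise ValueError(f"series too short: {x.size} < {min_length}")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    return x


# ---------------------------------------------------------------------------
# Hurst exponent (rescaled range)
# ---------------------------------------------------------------------------

def _rs_statistic(x: np.ndarray, size: int) -> float:
    """Mean R/S over non-overlapping windows of the given size."""
    n_win = x.size // size
    w = x[: n_win * size].reshape(n_win, size)
    w = w - w.mean(axis=1, keepdims=True)
    z = np.cumsum(w, axis=1)
    R = z.max(axis=1) - z.min(axis=1)
    S = w.std(axis=1)
    ok = S > 0
    if not ok.any():
        raise ValueError("degenerate input: zero variance in every window")
    return float(np.mean(R[ok] / S[ok]))


def _expected_rs(size: int) -> float:
    """E[R/S] for iid Gaussian data (Anis–Lloyd, Peters' finite-n factor)."""
    n = size
    if n <= 340:
        front = gamma_fn((n - 1) / 2.0) / (math.sqrt(math.pi) * gamma_fn(n / 2.0))
    else:  # Stirling regime, avoids gamma overflow
        front = 1.0 / math.sqrt(n * math.pi / 2.0)
    i = np.arange(1, n)
    s = float(np.sum(np.sqrt((n - i) / i)))
    return (n - 0.5) / n * front * s


def hurst_rs(x: np.ndarray, min_length: int = 64) -> float:
    """Hurst exponent via corrected rescaled-range analysis.

    R/S is computed over >= 8 log-spaced window sizes from 16 to n/2, each
    window demeaned before taking the range of cumulative deviations.  The
    raw log-log slope of R/S overestimates H for anti-persistent series at
    finite n, so the estimate is debiased against the analytic iid-Gaussian
    expectation E[R/S]:  H = 0.5 + slope of (log R/S - log E[R/S]).

    Interpretation: ~0.5 memoryless, > 0.5 persistent (long-range dependent),
    < 0.5 anti-persistent.
    """
    x = _check_series(x, max(min_length, 64))
    if x.std() == 0:
        raise ValueError("degenerate input: constant series")
    n = x.size
    sizes = np.unique(
        np.geomspace(16, n // 2, num=max(8, int(np.log2(n))))
        .round()
        .astype(int)
    )
    log_rs = np.array([np.log(_rs_statistic(x, s)) for s in sizes])
    log_exp = np.array([np.log(_expected_rs(int(s))) for s in sizes])
    slope = np.polyfit(np.log(sizes.astype(float)), log_rs - log_exp, 1)[0]
    return float(0.5 + slope)


# ---------------------------------------------------------------------------
# weighted permutation entropy
# ---------------------------------------------------------------------------

def _embed(x: np.ndarray, m: int, tau: int) -> np.ndarray:
    n_vec = x.size - (m - 1) * tau
    if n_vec < 1:
        raise ValueError("series too short for embedding")
    idx = np.arange(n_vec)[:, None] + tau * np.arange(m)[None, :]
    return x[idx]


def weighted_permutation_entropy(
    x: np.ndarray, m: int = 4, tau: int = 1
) -> float:
    """Weighted permutation entropy, normalized by log2(m!) into [0, 1].

    Each length-m ordinal pattern occurrence is weighted by the variance of
    its embedded vector (flat segments carry no weight); the Shannon entropy
    of the weight-normalized pattern distribution is returned.  Ordinal ties
    are broken by order of occurrence (stable sort), so the map from vector
    to pattern is deterministic.
    """
    x = _check_series(x, m * tau + 1)
    vecs = _embed(x, m, tau)
    # stable argsort encodes each ordinal pattern as an integer
    patterns = np.argsort(vecs, axis=1, kind="stable")
    codes = patterns @ (m ** np.arange(m))
    weights = vecs.var(axis=1)
    total = weights.sum()
    if total <= 0:  # constant/flat series: single degenerate pattern
        return 0.0
    _, inv = np.unique(codes, return_inverse=True)
    p = np.bincount(inv, weights=weights) / total
    p = p[p > 0]
    H = -np.sum(p * np.log2(p))
    return float(H / np.log2(math.factorial(m)))


# ---------------------------------------------------------------------------
# sample entropy
# ---------------------------------------------------------------------------

def _template_pair_count(vecs: np.ndarray, radius: float) -> int:
    """Unordered template pairs within Chebyshev distance <= radius."""
    tree = cKDTree(vecs)
    total = tree.count_neighbors(tree, radius, p=np.inf)
    return int((total - vecs.shape[0]) // 2)


def sample_entropy(
    x: np.ndarray, m: int = 2, r: float = 0.5, min_length: int | None = None
) -> float:
    """Sample entropy -ln(A/B) with SD-relative tolerance.

    B counts template pairs (i != j) of length ``m`` within Chebyshev
    distance ``r * SD(x)``; A counts the same templates extended to length
    m + 1; self-matches excluded, both counts taken over the same n - m
    template start points.  Zero counts yield NaN (undefined marker), not an
    exception.
    """
    x = _check_series(x, min_length if min_length is not None else m + 2)
    sd = x.std()
    if sd == 0:
        raise ValueError("degenerate input: constant series")
    radius = r * sd
    n_templates = x.size - m
    vm = _embed(x, m, 1)[:n_templates]
    vm1 = _embed(x, m + 1, 1)  # exactly n - m vectors
    B = _template_pair_count(vm, radius)
    A = _template_pair_count(vm1, radius)
    if B == 0 or A == 0:
        return float("nan")
    return float(-np.log(A / B))


# ---------------------------------------------------------------------------
# range entropy (type B)
# ---------------------------------------------------------------------------

def _range_distances(vecs: np.ndarray) -> np.ndarray:
    """Pairwise normalized range distance, condensed upper-triangle order.

    d(x_i, x_j) = (max_k |x_ik - x_jk| - min_k |.|) / (max_k |.| + min_k |.|),
    bounded in [0, 1]; identical templates (0/0) are defined as distance 0.
    """
    n = vecs.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    diff = np.abs(vecs[iu] - vecs[ju])
    mx = diff.max(axis=1)
    mn = diff.min(axis=1)
    denom = mx + mn
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(denom > 0, (mx - mn) / denom, 0.0)
    return d


def _rangeen_counts(x: np.ndarray, m: int):
    """Sorted range-distance arrays at lengths m and m+1 (shared templates)."""
    n_templates = x.size - m
    vm = _embed(x, m, 1)[:n_templates]
    vm1 = _embed(x, m + 1, 1)
    return np.sort(_range_distances(vm)), np.sort(_range_distances(vm1))


def range_entropy_B(x: np.ndarray, m: int = 2, r: float = 1.0) -> float:
    """RangeEn_B at a single tolerance r in (0, 1].

    Sample-entropy counting with the Chebyshev distance replaced by the
    normalized range distance.  Because that distance is bounded by 1, every
    template pair matches at r = 1 and the value is exactly 0 for any finite
    non-constant series.
    """
    if not (0.0 < r <= 1.0):
        raise ValueError("RangeEn_B tolerance r must lie in (0, 1]")
    x = _check_series(x, m + 2)
    if x.std() == 0:
        raise ValueError("degenerate input: constant series")
    dm, dm1 = _rangeen_counts(x, m)
    B = int(np.searchsorted(dm, r, side="right"))
    A = int(np.searchsorted(dm1, r, side="right"))
    if B == 0 or A == 0:
        return float("nan")
    return float(-np.log(A / B))


def default_r_grid(n_points: int = 20) -> np.ndarray:
    """Equally spaced tolerances on (0, 1]: 0.05, 0.10, ..., 1.00 by default."""
    return np.linspace(1.0 / n_points, 1.0, n_points)


def range_entropy_B_trajectory(
    x: np.ndarray, m: int = 2, r_grid: np.ndarray | None = None
) -> EntropyTrajectory:
    """RangeEn_B over a tolerance grid, with pair distances computed once."""
    r_grid = default_r_grid() if r_grid is None else np.asarray(r_grid, float)
    if r_grid.size < 2 or np.any(np.diff(r_grid) <= 0):
        raise ValueError("r_grid must be strictly increasing")
    if r_grid[0] <= 0 or r_grid[-1] > 1:
        raise ValueError("r_grid must lie in (0, 1]")
    x = _check_series(x, m + 2)
    if x.std() == 0:
        raise ValueError("degenerate input: constant series")
    dm, dm1 = _rangeen_counts(x, m)
    B = np.searchsorted(dm, r_grid, side="right").astype(float)
    A = np.searchsorted(dm1, r_grid, side="right").astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = np.where((B > 0) & (A > 0), -np.log(A / B), np.nan)
    return EntropyTrajectory(abscissa=r_grid, entropy=ent, kind="range_r")


def range_entropy_B_auc(
    x: np.ndarray, m: int = 2, r_grid: np.ndarray | None = None
) -> float:
    """Trapezoidal area under the RangeEn_B trajectory along the r-axis."""
    r_grid = default_r_grid() if r_grid is None else np.asarray(r_grid, float)
    if r_grid.size < 10:
        raise ValueError("r_grid needs >= 10 points for a stable AUC")
    return range_entropy_B_trajectory(x, m=m, r_grid=r_grid).auc()


# ---------------------------------------------------------------------------
# multiscale entropy
# ---------------------------------------------------------------------------

def coarse_grain(x: np.ndarray, scale: int) -> np.ndarray:
    """Non-overlapping means of consecutive windows of length ``scale``;
    trailing remainder dropped (output length floor(n/scale))."""
    x = np.asarray(x, dtype=float).ravel()
    if scale < 1:
        raise ValueError("scale must be >= 1")
    if scale > x.size // 2:
        raise ValueError("scale must be <= n/2")
    if scale == 1:
        return x.copy()
    n_out = x.size // scale
    return x[: n_out * scale].reshape(n_out, scale).mean(axis=1)


def multiscale_entropy_trajectory(
    x: np.ndarray, m: int = 2, r: float = 0.5, tau_max: int = 10
) -> EntropyTrajectory:
    """Sample entropy of coarse-grained series at scales 1..tau_max.

    The tolerance is r times the SD of the *original* (scale-1) series, held
    fixed across scales — the standard multiscale convention, which makes the
    entropy decline of coarse-grained white noise visible.
    """
    x = _check_series(x, 2 * tau_max * (m + 2))
    sd = x.std()
    if sd == 0:
        raise ValueError("degenerate input: constant series")
    radius_in_sd_of_original = r  # applied as absolute radius below
    scales = np.arange(1, tau_max + 1)
    ent = np.empty(tau_max)
    for i, s in enumerate(scales):
        cg = coarse_grain(x, int(s))
        # fixed absolute tolerance r * sd(original); sample_entropy rescales
        # by the SD of its input, so compensate explicitly
        cg_sd = cg.std()
        if cg_sd == 0:
            ent[i] = np.nan
            continue
        ent[i] = sample_entropy(
            cg, m=m, r=radius_in_sd_of_original * sd / cg_sd
        )
    return EntropyTrajectory(
        abscissa=scales.astype(float), entropy=ent, kind="mse_scale"
    )


def multiscale_entropy_auc(
    x: np.ndarray, m: int = 2, r: float = 0.5, tau_max: int = 10
) -> float:
    """Trapezoidal area of the MSE scale-trajectory divided by tau_max."""
    traj = multiscale_entropy_trajectory(x, m=m, r=r, tau_max=tau_max)
    return traj.auc() / tau_max
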