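"""Functional-connectivity features.

ROI level: Pearson connectome, eigenvector centrality (EC) and the weighted
clustering coefficient (wCC).  Voxel level: fALFF, local correlation (LCOR)
and global correlation (GCOR), computed per voxel and then averaged within
ROIs (``parcellate``).

Graph measures operate on the connectome with negative correlations and the
diagonal zeroed, so the matrix is nonnegative and the leading eigenvector is
a Perron vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "FCMatrix",
    "VoxelImage",
    "ROIFeatureMap",
    "fc_matrix",
    "eigenvector_centrality",
    "weighted_clustering_coefficient",
    "falff",
    "gcor",
    "lcor",
    "parcellate",
]

FEATURE_NAMES = (
    "HE",
    "wPE",
    "RangeEnB_AUC",
    "MSE_AUC",
    "fALFF",
    "LCOR",
    "GCOR",
    "EC",
    "wCC",
)


@dataclass
class FCMatrix:
    """ROI-wise Pearson connectome: symmetric, unit diagonal, values in [-1, 1]."""

    values: np.ndarray
    roi_ids: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("FC matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("FC matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-10):
            raise ValueError("FC matrix diagonal must be 1")
        if v.min() < -1 - 1e-10 or v.max() > 1 + 1e-10:
            raise ValueError("FC entries must lie in [-1, 1]")
        self.values = v
        self.roi_ids = np.asarray(self.roi_ids)

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    def nonnegative_weights(self) -> np.ndarray:
        """Connectome preprocessed for graph measures: negatives and the
        diagonal set to zero."""
        w = np.clip(self.values, 0.0, None)
        np.fill_diagonal(w, 0.0)
        return w


@dataclass
class VoxelImage:
    """4D (x, y, z, t) volume with an integer ROI label volume (0 = background)."""

    data: np.ndarray
    labels: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    tr_seconds: float

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        lab = np.asarray(self.labels, dtype=int)
        if d.ndim != 4:
            raise ValueError("data must be 4-D (x, y, z, t)")
        if lab.shape != d.shape[:3]:
            raise ValueError("label volume shape must match data spatial dims")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")
        self.data = d
        self.labels = lab


@dataclass
class ROIFeatureMap:
    """One value per ROI for one named feature, for one subject."""

    feature_name: str
    values: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("feature map must be a vector over ROIs")


# ---------------------------------------------------------------------------
# ROI-level measures
# ---------------------------------------------------------------------------

def fc_matrix(series: np.ndarray, roi_ids: np.ndarray | None = None) -> FCMatrix:
    """Pairwise Pearson correlation between ROI time series.

    ``series`` is (n_rois, n_timepoints).  A constant ROI has no defined
    correlation and raises, naming the offending ROI.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2 or series.shape[0] < 2 or series.shape[1] < 3:
        raise ValueError("need >= 2 ROIs and >= 3 time points")
    sds = series.std(axis=1)
    if np.any(sds == 0):
        bad = np.flatnonzero(sds == 0)
        raise ValueError(f"constant time series in ROI index(es) {bad.tolist()}")
    c = np.corrcoef(series)
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    if roi_ids is None:
        roi_ids = np.arange(1, series.shape[0] + 1)
    return FCMatrix(values=c, roi_ids=roi_ids)


def eigenvector_centrality(fc: FCMatrix) -> ROIFeatureMap:
    """Leading eigenvector of the nonnegative connectome, unit Euclidean norm.

    ROI i's centrality is the i-th element of the eigenvector of the largest
    eigenvalue; by Perron–Frobenius it can be chosen nonnegative.
    """
    w = fc.nonnegative_weights()
    if not w.any():
        raise ValueError("degenerate input: connectome has no positive edges")
    eigvals, eigvecs = np.linalg.eigh(w)
    v = eigvecs[:, -1]
    if v.sum() < 0:
        v = -v
    v = np.clip(v, 0.0, None)
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError("degenerate leading eigenvector")
    return ROIFeatureMap(feature_name="EC", values=v / norm)


def weighted_clustering_coefficient(fc: FCMatrix) -> ROIFeatureMap:
    """Onnela-type weighted clustering coefficient per ROI.

    Weights are rescaled to [0, 1] by the global maximum; each node's
    geometric-mean triangle intensity is summed and divided by the
    k(k-1) maximal triangle count given its (binary) degree k.  Nodes with
    degree < 2 get CC = 0.
    """
    w = fc.nonnegative_weights()
    mx = w.max()
    if mx == 0:
        raise ValueError("degenerate input: connectome has no positive edges")
    cw = np.cbrt(w / mx)
    triangles = np.diag(cw @ cw @ cw)  # 2x each node's summed intensity
    k = (w > 0).sum(axis=0)
    denom = k * (k - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cc = np.where(denom > 0, triangles / denom, 0.0)
    return ROIFeatureMap(feature_name="wCC", values=cc)


# ---------------------------------------------------------------------------
# voxel-level measures
# ---------------------------------------------------------------------------

def falff(
    x: np.ndarray,
    tr_seconds: float,
    band_hz: tuple[float, float] = (0.008, 0.09),
) -> float:
    """Fractional amplitude of low-frequency fluctuations.

    Amplitude spectrum (square root of single-taper periodogram power) summed
    over ``band_hz``, divided by the sum over the full (0, Nyquist] range;
    the DC bin is excluded.  Invariant to amplitude scaling; lies in [0, 1].
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 8:
        raise ValueError("series too short for a spectrum")
    nyquist = 0.5 / tr_seconds
    lo, hi = band_hz
    if not (0.0 <= lo < hi <= nyquist):
        raise ValueError(
            f"band {band_hz} must lie inside (0, {nyquist:.4f}] Hz"
        )
    x = x - x.mean()
    amp = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(x.size, d=tr_seconds)
    positive = freqs > 0
    total = amp[positive].sum()
    if total == 0:
        raise ValueError("degenerate input: constant series")
    in_band = positive & (freqs >= lo) & (freqs <= hi)
    return float(amp[in_band].sum() / total)


def _normalized_voxel_series(img: VoxelImage):
    """In-mask voxel series normalized to zero mean, unit Euclidean norm,
    so dot products are Pearson correlations.  Constant voxels are dropped
    with a warning."""
    mask = img.labels > 0
    coords = np.argwhere(mask)
    series = img.data[mask]  # (n_vox, t)
    series = series - series.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(series, axis=1)
    keep = norms > 0
    if not keep.all():
        logger.warning(
            "%d constant voxel(s) excluded from correlation measures",
            int((~keep).sum()),
        )
    if keep.sum() < 2:
        raise ValueError("need >= 2 non-constant in-mask voxels")
    return coords, series, norms, keep


def gcor(img: VoxelImage, include_self: bool = False) -> np.ndarray:
    """Global correlation: per voxel, the mean Pearson correlation with all
    other in-mask voxels.

    Computed through normalized series (cost linear in voxel count per time
    point).  Returns a 3-D map, NaN outside the mask and at excluded
    (constant) voxels.  With ``include_self`` the self-correlation of 1 is
    kept in the average, shifting values by ~1/N_vox.
    """
    coords, series, norms, keep = _normalized_voxel_series(img)
    v = series[keep] / norms[keep, None]
    n = v.shape[0]
    s = v.sum(axis=0)  # (t,)
    corr_sums = v @ s - 1.0  # subtract self-correlation
    if include_self:
        values = (corr_sums + 1.0) / n
    else:
        values = corr_sums / (n - 1)
    out = np.full(img.labels.shape, np.nan)
    kept_coords = coords[keep]
    out[kept_coords[:, 0], kept_coords[:, 1], kept_coords[:, 2]] = values
    return out


def lcor(img: VoxelImage, fwhm_mm: float = 25.0) -> np.ndarray:
    """Local correlation: Gaussian-kernel-weighted mean correlation of each
    voxel with its in-mask neighbors.

    Gaussian weights use sigma = fwhm / (2 sqrt(2 ln 2)) in millimetres,
    truncated at 3 sigma; the self-correlation is excluded and weights are
    renormalized over the neighbors actually available (mask edges).  A voxel
    with no in-mask neighbor within 3 sigma is NaN (logged).

    The pairwise formulation targets the modest volumes this package works
    with; cost is O(n_vox^2) in memory-light blocks.
    """
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be positive")
    coords, series, norms, keep = _normalized_voxel_series(img)
    v = series[keep] / norms[keep, None]
    xyz = coords[keep] * np.asarray(img.voxel_size_mm)[None, :]
    sigma = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    cutoff2 = (3.0 * sigma) ** 2

    d2 = ((xyz[:, None, :] - xyz[None, :, :]) ** 2).sum(axis=-1)
    w = np.exp(-0.5 * d2 / sigma**2)
    w[d2 > cutoff2] = 0.0
    np.fill_diagonal(w, 0.0)

    wsum = w.sum(axis=1)
    corr = v @ v.T
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(wsum > 0, (w * corr).sum(axis=1) / wsum, np.nan)
    n_isolated = int(np.sum(wsum == 0))
    if n_isolated:
        logger.warning(
            "%d voxel(s) have no in-mask neighbor within 3 sigma", n_isolated
        )
    out = np.full(img.labels.shape, np.nan)
    kept_coords = coords[keep]
    out[kept_coords[:, 0], kept_coords[:, 1], kept_coords[:, 2]] = values
    return out


def parcellate(
    voxel_map: np.ndarray, labels: np.ndarray, feature_name: str = ""
) -> ROIFeatureMap:
    """Arithmetic mean of a voxel map within each ROI, ignoring NaN markers.

    ROIs with zero defined voxels raise, naming the ROI.
    """
    voxel_map = np.asarray(voxel_map, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if voxel_map.shape != labels.shape:
        raise ValueError("voxel map and label volume shapes differ")
    roi_ids = np.unique(labels)
    roi_ids = roi_ids[roi_ids > 0]
    values = np.empty(roi_ids.size)
    for i, rid in enumerate(roi_ids):
        vals = voxel_map[labels == rid]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError(f"ROI {rid} has no defined voxels")
        values[i] = vals.mean()
    return ROIFeatureMap(feature_name=feature_name, values=values)
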