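"""Synthetic rsfMRI cohorts with known ground truth.

Generates per-subject ROI time series (fractional Gaussian noise plus shared
latent factors), voxel-level 4D volumes, covariates (age, gender, TIV) and
behavioral targets that are noisy linear functions of ground-truth feature
maps and/or covariates.  Everything downstream of acquisition can be exercised
on these cohorts without any real data.

Fractional Gaussian noise is simulated *exactly* (circulant embedding of the
true autocovariance, Cholesky fallback), so Hurst-recovery checks against the
estimator are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import cholesky, toeplitz

__all__ = [
    "SyntheticCohortSpec",
    "SyntheticCohort",
    "VoxelVolumeSpec",
    "ROITimeSeriesSet",
    "generate_fgn",
    "generate_cohort",
    "generate_voxel_volume",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ROITimeSeriesSet:
    """Per-subject ROI x time matrices.

    data has shape (n_subjects, n_rois, n_timepoints); tr_seconds is the
    sampling interval of the time axis.
    """

    data: np.ndarray
    tr_seconds: float
    roi_ids: np.ndarray
    subject_ids: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_subjects, n_rois, n_timepoints)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("ROI time series must be finite")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[2]


@dataclass
class SyntheticCohortSpec:
    """Parameters of a synthetic cohort.

    Defaults mirror the acquisition this package is designed around: 490 time
    points at TR = 0.735 s.  ``roi_tsnr`` is the requested per-ROI temporal
    SNR (mean/SD), realized exactly by adding a constant offset to a demeaned
    fluctuation; ``roi_noise_sd`` scales additive white noise on top of the
    structured signal.  Targets are a β-weighted mix of a named ground-truth
    per-ROI quantity (default: the per-subject Hurst exponents) and the
    covariates, standardized, plus Gaussian noise; a null target independent
    of everything is always generated alongside.
    """

    n_subjects: int = 100
    n_rois: int = 20
    n_timepoints: int = 490
    tr_seconds: float = 0.735
    hurst_range: tuple[float, float] = (0.55, 0.85)
    n_latent_factors: int = 3
    factor_loading_scale: float = 0.5
    roi_noise_sd: float | Sequence[float] = 0.3
    roi_tsnr: float | Sequence[float] = 50.0
    age_range: tuple[float, float] = (45.0, 80.0)
    tiv_mean_female_ml: float = 1350.0
    tiv_mean_male_ml: float = 1500.0
    tiv_sd_ml: float = 110.0
    truth_feature: str = "hurst"
    beta_feature: float | Sequence[float] = 1.0
    beta_age: float = 0.0
    beta_gender: float = 0.0
    beta_tiv: float = 0.0
    target_noise_sd: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 2 or self.n_rois < 2:
            raise ValueError("need n_subjects >= 2 and n_rois >= 2")
        if self.n_timepoints < 32:
            raise ValueError("need n_timepoints >= 32")
        lo, hi = self.hurst_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("hurst_range must lie inside (0, 1)")
        if np.any(np.asarray(self.roi_noise_sd) < 0):
            raise ValueError("roi_noise_sd must be >= 0")
        if self.target_noise_sd < 0:
            raise ValueError("target_noise_sd must be >= 0")
        if self.truth_feature not in ("hurst", "factor_coupling"):
            raise ValueError(f"unknown truth_feature {self.truth_feature!r}")
        beta = np.atleast_1d(np.asarray(self.beta_feature, dtype=float))
        if beta.size not in (1, self.n_rois):
            raise ValueError("beta_feature must be scalar or length n_rois")


@dataclass
class SyntheticCohort:
    series: ROITimeSeriesSet
    covariates: "object"  # pandas.DataFrame; imported lazily to keep deps light
    targets: dict
    truth: dict


@dataclass
class VoxelVolumeSpec:
    """Spec for a small labeled 4D volume: each voxel carries its ROI's
    source signal plus iid noise.  Label 0 is background."""

    label_volume: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    n_timepoints: int = 490
    tr_seconds: float = 0.735
    source_hurst: float = 0.7
    voxel_noise_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        labels = np.asarray(self.label_volume)
        if labels.ndim != 3:
            raise ValueError("label_volume must be 3-D")
        ids = np.unique(labels)
        ids = ids[ids > 0]
        if ids.size == 0:
            raise ValueError("label_volume has no ROI voxels")
        if not np.array_equal(ids, np.arange(1, ids.size + 1)):
            raise ValueError("ROI ids must be contiguous positive integers")
        if self.voxel_noise_sd < 0:
            raise ValueError("voxel_noise_sd must be >= 0")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")


# ---------------------------------------------------------------------------
# fractional Gaussian noise
# ---------------------------------------------------------------------------

def fgn_autocovariance(lags: np.ndarray, hurst: float) -> np.ndarray:
    """Theoretical fGn autocovariance gamma(k) for unit variance."""
    k = np.abs(np.asarray(lags, dtype=float))
    h2 = 2.0 * hurst
    return 0.5 * ((k + 1.0) ** h2 - 2.0 * k**h2 + np.abs(k - 1.0) ** h2)


def _fgn_cholesky(n: int, hurst: float, rng: np.random.Generator) -> np.ndarray:
    gamma = fgn_autocovariance(np.arange(n), hurst)
    L = cholesky(toeplitz(gamma), lower=True)
    return L @ rng.standard_normal(n)


def generate_fgn(
    n: int, hurst: float, seed: int | np.random.Generator
) -> np.ndarray:
    """Exact sample of fractional Gaussian noise of length ``n``.

    Uses Davies–Harte circulant embedding of the true autocovariance
    gamma(k) = 0.5(|k+1|^{2H} - 2|k|^{2H} + |k-1|^{2H}); falls back to a
    Cholesky factorization of the Toeplitz covariance if the embedding is not
    nonnegative.  The process has zero mean and unit variance.
    """
    if not (0.0 < hurst < 1.0):
        raise ValueError("hurst must lie in (0, 1)")
    if n < 32:
        raise ValueError("need n >= 32")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if hurst == 0.5:  # white noise shortcut, still exact
        return rng.standard_normal(n)

    gamma = fgn_autocovariance(np.arange(n), hurst)
    circ = np.concatenate([gamma, gamma[-2:0:-1]])  # length 2n - 2
    lam = np.fft.fft(circ).real
    if lam.min() < -1e-8 * lam.max():
        return _fgn_cholesky(n, hurst, rng)
    lam = np.clip(lam, 0.0, None)

    m = lam.size
    w = np.zeros(m, dtype=complex)
    w[0] = np.sqrt(lam[0] / m) * rng.standard_normal()
    w[n - 1] = np.sqrt(lam[n - 1] / m) * rng.standard_normal()
    k = np.arange(1, n - 1)
    re = rng.standard_normal(n - 2)
    im = rng.standard_normal(n - 2)
    w[k] = np.sqrt(lam[k] / (2 * m)) * (re + 1j * im)
    w[m - k] = np.conj(w[k])
    return np.fft.fft(w).real[:n]


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def _covariate_table(spec: SyntheticCohortSpec, rng: np.random.Generator):
    import pandas as pd

    n = spec.n_subjects
    gender = np.zeros(n, dtype=int)
    gender[: n // 2] = 1  # balanced by construction; counts differ by <= 1
    rng.shuffle(gender)
    age = rng.uniform(*spec.age_range, size=n)
    tiv_mean = np.where(
        gender == 1, spec.tiv_mean_male_ml, spec.tiv_mean_female_ml
    )
    tiv = rng.normal(tiv_mean, spec.tiv_sd_ml)
    return pd.DataFrame(
        {
            "subject_id": [f"sub-{i:05d}" for i in range(n)],
            "age": age,
            "gender": gender,
            "tiv": tiv,
        }
    )


def generate_cohort(spec: SyntheticCohortSpec) -> SyntheticCohort:
    """Generate a full synthetic cohort: series, covariates, targets, truth.

    ROI series = loading-weighted shared latent fGn factors + per-ROI fGn +
    white noise, demeaned and offset so that mean/SD equals the requested
    per-ROI tSNR exactly.  Deterministic given the spec (including its seed).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    ns, nr, nt = spec.n_subjects, spec.n_rois, spec.n_timepoints

    noise_sd = np.broadcast_to(
        np.atleast_1d(np.asarray(spec.roi_noise_sd, dtype=float)), (nr,)
    ).copy()
    tsnr = np.broadcast_to(
        np.atleast_1d(np.asarray(spec.roi_tsnr, dtype=float)), (nr,)
    ).copy()

    loadings = spec.factor_loading_scale * rng.standard_normal(
        (nr, spec.n_latent_factors)
    )
    factor_hurst = rng.uniform(*spec.hurst_range, size=spec.n_latent_factors)
    roi_hurst = rng.uniform(*spec.hurst_range, size=(ns, nr))
    coupling = rng.uniform(0.5, 1.5, size=ns)  # per-subject factor strength

    data = np.empty((ns, nr, nt))
    for s in range(ns):
        factors = np.stack(
            [generate_fgn(nt, h, rng) for h in factor_hurst]
        )  # (k, t)
        shared = coupling[s] * loadings @ factors  # (r, t)
        for r in range(nr):
            x = shared[r] + generate_fgn(nt, roi_hurst[s, r], rng)
            if noise_sd[r] > 0:
                x = x + noise_sd[r] * rng.standard_normal(nt)
            x -= x.mean()
            sd = x.std()
            if sd == 0.0:  # pathological; keep finite
                sd = 1.0
            data[s, r] = x + tsnr[r] * sd

    covariates = _covariate_table(spec, rng)
    series = ROITimeSeriesSet(
        data=data,
        tr_seconds=spec.tr_seconds,
        roi_ids=np.arange(1, nr + 1),
        subject_ids=covariates["subject_id"].to_numpy(),
    )

    # ground-truth per-ROI feature entering the target
    if spec.truth_feature == "hurst":
        truth_maps = roi_hurst
    else:  # factor_coupling: per-subject coupling spread over loading norms
        truth_maps = coupling[:, None] * np.abs(loadings).sum(axis=1)[None, :]

    beta = np.broadcast_to(
        np.atleast_1d(np.asarray(spec.beta_feature, dtype=float)), (nr,)
    )
    raw = (
        truth_maps @ beta
        + spec.beta_age * covariates["age"].to_numpy()
        + spec.beta_gender * covariates["gender"].to_numpy()
        + spec.beta_tiv * covariates["tiv"].to_numpy()
    )
    sd = raw.std()
    latent = (raw - raw.mean()) / (sd if sd > 0 else 1.0)
    continuous = latent + spec.target_noise_sd * rng.standard_normal(ns)
    binary = (latent >= np.median(latent)).astype(int)

    targets = {
        "continuous": continuous,
        "binary": binary,
        "null": rng.standard_normal(ns),
        "null_binary": rng.permutation(np.arange(ns) % 2),
    }
    truth = {
        "roi_hurst": roi_hurst,
        "factor_hurst": factor_hurst,
        "loadings": loadings,
        "coupling": coupling,
        "truth_maps": truth_maps,
        "beta_feature": np.asarray(beta),
        "latent_target": latent,
    }
    return SyntheticCohort(
        series=series, covariates=covariates, targets=targets, truth=truth
    )


# ---------------------------------------------------------------------------
# voxel volumes
# ---------------------------------------------------------------------------

def generate_voxel_volume(spec: VoxelVolumeSpec):
    """4D (x, y, z, t) image: voxel series = ROI source signal + iid noise.

    Returns a :class:`fmricomplexity.connectivity.VoxelImage`.
    """
    from .connectivity import VoxelImage

    spec.validate()
    rng = np.random.default_rng(spec.seed)
    labels = np.asarray(spec.label_volume, dtype=int)
    roi_ids = np.unique(labels)
    roi_ids = roi_ids[roi_ids > 0]

    sources = {
        rid: generate_fgn(spec.n_timepoints, spec.source_hurst, rng)
        for rid in roi_ids
    }
    data = np.zeros(labels.shape + (spec.n_timepoints,))
    for rid in roi_ids:
        mask = labels == rid
        nvox = int(mask.sum())
        noise = (
            spec.voxel_noise_sd
            * rng.standard_normal((nvox, spec.n_timepoints))
            if spec.voxel_noise_sd > 0
            else 0.0
        )
        data[mask] = sources[rid][None, :] + noise
    return VoxelImage(
        data=data,
        labels=labels,
        voxel_size_mm=tuple(spec.voxel_size_mm),
        tr_seconds=spec.tr_seconds,
    )
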