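"""Temporal signal-to-noise ratio of parcellated series and ROI selection.

tSNR of an ROI is the mean of its time series divided by its temporal SD.
Subject profiles are normalized by their own maximum, averaged across the
cohort, renormalized, and thresholded at a percent-of-maximum level to pick
the suprathreshold ROIs that enter prediction.

The group map is computed once on the full cohort and reused at every sample
size — the convention this analysis follows; its data-leakage caveat is noted
in the methods document.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TSNRProfile",
    "roi_tsnr",
    "normalize_profile",
    "normalize_and_group_mean",
    "suprathreshold_rois",
    "suprathreshold_counts",
]


@dataclass
class TSNRProfile:
    values: np.ndarray
    normalized: bool = False
    n_subjects_averaged: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("tSNR profile must be a vector over ROIs")
        if self.normalized and not np.isclose(self.values.max(), 1.0):
            raise ValueError("normalized profile must have max 1")


def roi_tsnr(series: np.ndarray) -> TSNRProfile:
    """Per-ROI tSNR = mean / SD of each row of an (n_rois, t) matrix."""
    series = np.asarray(series, dtype=float)
    if series.ndim != 2:
        raise ValueError("series must be (n_rois, n_timepoints)")
    sds = series.std(axis=1)
    if np.any(sds == 0):
        bad = np.flatnonzero(sds == 0)
        raise ValueError(f"zero temporal SD in ROI index(es) {bad.tolist()}")
    return TSNRProfile(values=series.mean(axis=1) / sds, normalized=False)


def normalize_profile(profile: TSNRProfile) -> TSNRProfile:
    """Divide by the profile's own maximum so max = 1."""
    mx = profile.values.max()
    if mx <= 0:
        raise ValueError("cannot normalize a profile with non-positive max")
    return TSNRProfile(
        values=profile.values / mx,
        normalized=True,
        n_subjects_averaged=profile.n_subjects_averaged,
    )


def normalize_and_group_mean(profiles: list[TSNRProfile]) -> TSNRProfile:
    """Per-subject divide-by-max, element-wise mean, renormalized to max 1."""
    if not profiles:
        raise ValueError("empty profile list")
    n_rois = profiles[0].values.size
    if any(p.values.size != n_rois for p in profiles):
        raise ValueError("profiles must share the same ROI set")
    stacked = np.stack([normalize_profile(p).values for p in profiles])
    mean = stacked.mean(axis=0)
    return TSNRProfile(
        values=mean / mean.max(),
        normalized=True,
        n_subjects_averaged=len(profiles),
    )


def suprathreshold_rois(
    profile: TSNRProfile, level_percent: float
) -> np.ndarray:
    """Indices of ROIs whose normalized tSNR exceeds level_percent of max.

    Strictly greater-than, so a 0% level keeps every (positive) ROI and a
    100% level keeps none.
    """
    if not (0.0 <= level_percent <= 100.0):
        raise ValueError("level_percent must lie in [0, 100]")
    if not profile.normalized:
        raise ValueError("profile must be normalized (max = 1)")
    return np.flatnonzero(profile.values > level_percent / 100.0)


def suprathreshold_counts(
    profile: TSNRProfile, levels_percent: np.ndarray
) -> np.ndarray:
    """Suprathreshold ROI count at each level of a threshold sweep."""
    return np.array(
        [suprathreshold_rois(profile, lv).size for lv in levels_percent]
    )
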