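"""Feature-pair fingerprinting (identification analysis).

A subject's brain map of feature X is matched against every subject's map of
feature Y; the predicted identity is the subject whose Y map has the highest
spatial (Pearson, across ROIs) correlation with the X map.  Identification
accuracy is the proportion of self-matches over the population.  Individual
characteristics can first be regressed out of the maps at the ROI level
(whole-sample OLS — this analysis is descriptive, not predictive).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .prediction import residualize, validate_covariates

logger = logging.getLogger(__name__)

__all__ = ["IdentificationResult", "identify", "identification_matrix"]


@dataclass
class IdentificationResult:
    feature_x: str
    feature_y: str
    n_subjects: int
    accuracy_x_to_y: float
    accuracy_y_to_x: float

    @property
    def accuracy(self) -> float:
        """Headline accuracy: mean of the two match directions."""
        return 0.5 * (self.accuracy_x_to_y + self.accuracy_y_to_x)


def _deconfound_maps(maps: np.ndarray, confounds: np.ndarray) -> np.ndarray:
    idx = np.arange(maps.shape[0])
    return residualize(maps, confounds, idx, idx)


def _row_standardize(maps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Z-score each subject's map across ROIs; flag constant maps."""
    mu = maps.mean(axis=1, keepdims=True)
    sd = maps.std(axis=1, keepdims=True)
    ok = sd[:, 0] > 0
    sd = np.where(sd == 0, 1.0, sd)
    return (maps - mu) / sd, ok


def _direction_accuracy(zx: np.ndarray, zy: np.ndarray) -> float:
    """Fraction of subjects whose X map correlates best with their own Y map;
    exact ties in the argmax count as misses."""
    n, n_roi = zx.shape
    corr = zx @ zy.T / n_roi  # Pearson across ROIs
    best = corr.argmax(axis=1)
    row_max = corr.max(axis=1)
    ties = (np.isclose(corr, row_max[:, None]).sum(axis=1)) > 1
    hits = (best == np.arange(n)) & ~ties
    return float(hits.mean())


def identify(
    maps_x: np.ndarray,
    maps_y: np.ndarray,
    confounds: pd.DataFrame | np.ndarray | None = None,
    feature_x: str = "X",
    feature_y: str = "Y",
) -> IdentificationResult:
    """Match subjects between two feature-map families.

    ``maps_x`` and ``maps_y`` are (n_subjects, n_rois) with the same subject
    order and ROI set.  Subjects whose map is constant in either family are
    excluded with a warning.
    """
    maps_x = np.asarray(maps_x, dtype=float)
    maps_y = np.asarray(maps_y, dtype=float)
    if maps_x.shape != maps_y.shape:
        raise ValueError("map families must share subjects and ROI set")
    if maps_x.shape[0] < 2:
        raise ValueError("need at least 2 subjects")

    if confounds is not None:
        if isinstance(confounds, pd.DataFrame):
            confounds = validate_covariates(confounds)
        maps_x = _deconfound_maps(maps_x, confounds)
        maps_y = _deconfound_maps(maps_y, confounds)

    zx, ok_x = _row_standardize(maps_x)
    zy, ok_y = _row_standardize(maps_y)
    keep = ok_x & ok_y
    if not keep.all():
        logger.warning(
            "%d subject(s) with constant maps excluded", int((~keep).sum())
        )
    if keep.sum() < 2:
        raise ValueError("fewer than 2 usable subjects after exclusions")
    zx, zy = zx[keep], zy[keep]

    return IdentificationResult(
        feature_x=feature_x,
        feature_y=feature_y,
        n_subjects=int(keep.sum()),
        accuracy_x_to_y=_direction_accuracy(zx, zy),
        accuracy_y_to_x=_direction_accuracy(zy, zx),
    )


def identification_matrix(
    feature_maps: dict[str, np.ndarray],
    confounds: pd.DataFrame | np.ndarray | None = None,
) -> pd.DataFrame:
    """Symmetric table of pairwise identification accuracies.

    Entry (X, Y) is the mean of the two match directions; the diagonal
    (a feature against itself) is 1 by construction.
    """
    names = list(feature_maps)
    if len(names) < 2:
        raise ValueError("need at least 2 feature types")
    table = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for a, b in itertools.combinations(names, 2):
        res = identify(
            feature_maps[a], feature_maps[b], confounds=confounds,
            feature_x=a, feature_y=b,
        )
        table.loc[a, b] = table.loc[b, a] = res.accuracy
    return table
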