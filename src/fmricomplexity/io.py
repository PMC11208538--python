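"""Readers and writers for the package's on-disk formats.

TSV for tabular data (ROI series per subject, feature maps, covariates,
targets, result tables), NIfTI-1 for 4D volumes, label volumes, and tSNR
maps.  Every tabular output carries a header; subject-keyed tables carry a
``subject_id`` column.
"""

from __future__ import annotations

import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "write_roi_series",
    "read_roi_series",
    "write_feature_maps",
    "read_feature_maps",
    "write_table",
    "read_table",
    "read_nifti_4d",
    "read_label_volume",
    "write_nifti",
    "read_tsnr_profile_tsv",
    "read_tsnr_profile_nifti",
]


def write_roi_series(path, series: np.ndarray, roi_ids) -> None:
    """One subject's ROI x time matrix as TSV, header row = ROI ids."""
    df = pd.DataFrame(np.asarray(series).T, columns=[str(r) for r in roi_ids])
    df.to_csv(path, sep="\t", index=False)


def read_roi_series(path) -> tuple[np.ndarray, np.ndarray]:
    """Returns (series (n_rois, t), roi_ids)."""
    df = pd.read_csv(path, sep="\t")
    return df.to_numpy(dtype=float).T, np.asarray(df.columns)


def write_feature_maps(path, maps: np.ndarray, subject_ids, roi_ids) -> None:
    """(n_subjects, n_rois) feature matrix as subject-keyed TSV."""
    df = pd.DataFrame(
        np.asarray(maps), columns=[f"roi_{r}" for r in roi_ids]
    )
    df.insert(0, "subject_id", list(subject_ids))
    df.to_csv(path, sep="\t", index=False)


def read_feature_maps(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    if "subject_id" not in df.columns:
        raise ValueError(f"{path}: feature-map table lacks subject_id")
    subject_ids = df.pop("subject_id").to_numpy()
    return df.to_numpy(dtype=float), subject_ids


def write_table(path, df: pd.DataFrame) -> None:
    sep = "\t" if str(path).endswith(".tsv") else ","
    df.to_csv(path, sep=sep, index=False)


def read_table(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith(".tsv") else ","
    return pd.read_csv(path, sep=sep)


def read_nifti_4d(path) -> tuple[np.ndarray, tuple]:
    """Returns (4D data, voxel sizes in mm)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4-D volume, got {data.ndim}-D")
    zooms = img.header.get_zooms()[:3]
    return data, tuple(float(z) for z in zooms)


def read_label_volume(path) -> np.ndarray:
    """Integer ROI label volume; non-contiguous ids are remapped to 1..K
    with the mapping logged."""
    img = nib.load(str(path))
    labels = np.asanyarray(img.dataobj)
    if labels.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D label volume")
    labels = np.rint(labels).astype(int)
    ids = np.unique(labels)
    ids = ids[ids > 0]
    expected = np.arange(1, ids.size + 1)
    if not np.array_equal(ids, expected):
        mapping = dict(zip(ids.tolist(), expected.tolist()))
        logger.warning("remapping non-contiguous ROI ids: %s", mapping)
        out = np.zeros_like(labels)
        for old, new in mapping.items():
            out[labels == old] = new
        labels = out
    return labels


def write_nifti(path, data: np.ndarray, voxel_size_mm=(3.0, 3.0, 3.0)) -> None:
    affine = np.diag(list(voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def read_tsnr_profile_tsv(path):
    """Per-ROI tSNR TSV with columns roi_id, tsnr."""
    from .tsnr import TSNRProfile

    df = pd.read_csv(path, sep="\t")
    if "tsnr" not in df.columns:
        raise ValueError(f"{path}: expected a 'tsnr' column")
    values = df["tsnr"].to_numpy(dtype=float)
    normalized = bool(np.isclose(values.max(), 1.0))
    return TSNRProfile(values=values, normalized=normalized)


def read_tsnr_profile_nifti(map_path, label_path):
    """Mean tSNR within each ROI of a voxel-wise tSNR map + label volume."""
    from .connectivity import parcellate
    from .tsnr import TSNRProfile

    img = nib.load(str(map_path))
    vol = np.asanyarray(img.dataobj, dtype=float)
    if vol.ndim != 3:
        raise ValueError(f"{map_path}: expected a 3-D tSNR map")
    labels = read_label_volume(label_path)
    fmap = parcellate(vol, labels, feature_name="tSNR")
    values = fmap.values
    normalized = bool(np.isclose(values.max(), 1.0))
    return TSNRProfile(values=values, normalized=normalized)
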