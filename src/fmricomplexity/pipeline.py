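"""Experiment orchestration: config, feature extraction, end-to-end runs.

``run_experiment`` binds the stages together: synthesize (or load) a cohort,
extract the requested ROI feature maps, build the group tSNR map, run the
prediction sweep across scenarios/sizes/tSNR levels, run the identification
analysis, and write tidy result tables plus the resolved config next to them.
Deterministic given the master seed.

Voxel-native measures (LCOR) require voxel volumes; on parcellated input the
voxel-free analogs are used: fALFF on each ROI's mean series and GCOR as each
ROI's mean correlation with all other ROIs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import complexity, connectivity, prediction, tsnr
from .identification import identification_matrix
from .synthetic import ROITimeSeriesSet, SyntheticCohortSpec, generate_cohort

logger = logging.getLogger(__name__)

ROI_LEVEL_FEATURES = (
    "HE", "wPE", "RangeEnB_AUC", "MSE_AUC", "fALFF", "GCOR", "EC", "wCC",
)

__all__ = ["ExperimentConfig", "extract_feature_maps", "run_experiment"]


@dataclass
class ExperimentConfig:
    """Validated description of one experiment run."""

    input_mode: str = "synthetic"  # {"synthetic", "files"}
    cohort: dict = field(default_factory=dict)
    series_files: list = field(default_factory=list)
    covariates_file: str | None = None
    targets_file: str | None = None
    features: list = field(default_factory=lambda: list(ROI_LEVEL_FEATURES))
    targets: list = field(default_factory=lambda: ["continuous", "null"])
    scenarios: list = field(
        default_factory=lambda: list(prediction.SCENARIOS)
    )
    models: list = field(default_factory=lambda: ["ridge"])
    lambda_grid: list = field(
        default_factory=lambda: list(prediction.DEFAULT_LAMBDA_GRID)
    )
    n_repeats: int = 5
    n_outer_folds: int = 5
    n_inner_folds: int = 5
    sizes: list = field(default_factory=lambda: [100])
    tsnr_levels: list = field(default_factory=lambda: [0.0])
    seed: int = 0
    out_dir: str = "results"

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.input_mode not in ("synthetic", "files"):
            raise ValueError(f"unknown input_mode {self.input_mode!r}")
        if self.input_mode == "files":
            for p in [self.covariates_file, self.targets_file, *self.series_files]:
                if p is None or not Path(p).exists():
                    raise ValueError(f"missing input file: {p}")
        bad = [f for f in self.features if f not in ROI_LEVEL_FEATURES]
        if bad:
            raise ValueError(f"unsupported features for ROI input: {bad}")
        for s in self.scenarios:
            if s not in prediction.SCENARIOS:
                raise ValueError(f"unknown scenario {s!r}")
        if sorted(self.sizes) != list(self.sizes):
            raise ValueError("sizes must be sorted ascending")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------

def _roi_gcor(series: np.ndarray) -> np.ndarray:
    """ROI-level global correlation: each ROI's mean Pearson correlation
    with every other ROI."""
    c = connectivity.fc_matrix(series).values
    n = c.shape[0]
    return (c.sum(axis=1) - 1.0) / (n - 1)


def _extract_one(feature: str, series: np.ndarray, tr: float) -> np.ndarray:
    if feature == "HE":
        return np.array([complexity.hurst_rs(x) for x in series])
    if feature == "wPE":
        return np.array(
            [complexity.weighted_permutation_entropy(x, m=4, tau=1) for x in series]
        )
    if feature == "RangeEnB_AUC":
        return np.array(
            [complexity.range_entropy_B_auc(x, m=2) for x in series]
        )
    if feature == "MSE_AUC":
        return np.array(
            [
                complexity.multiscale_entropy_auc(x, m=2, r=0.5, tau_max=10)
                for x in series
            ]
        )
    if feature == "fALFF":
        return np.array([connectivity.falff(x, tr) for x in series])
    if feature == "GCOR":
        return _roi_gcor(series)
    if feature == "EC":
        fc = connectivity.fc_matrix(series)
        return connectivity.eigenvector_centrality(fc).values
    if feature == "wCC":
        fc = connectivity.fc_matrix(series)
        return connectivity.weighted_clustering_coefficient(fc).values
    raise ValueError(f"unknown feature {feature!r}")


def extract_feature_maps(
    series_set: ROITimeSeriesSet, features=ROI_LEVEL_FEATURES
) -> dict[str, np.ndarray]:
    """Per-subject ROI feature maps for each requested feature.

    Returns feature name -> (n_subjects, n_rois) matrix.  Extraction outputs
    stay on their physical scales; any z-scoring happens inside prediction.
    """
    out = {}
    for feature in features:
        maps = np.empty((series_set.n_subjects, series_set.n_rois))
        for s in range(series_set.n_subjects):
            maps[s] = _extract_one(
                feature, series_set.data[s], series_set.tr_seconds
            )
        out[feature] = maps
    return out


# ---------------------------------------------------------------------------
# end-to-end run
# ---------------------------------------------------------------------------

def _load_cohort(config: ExperimentConfig):
    if config.input_mode == "synthetic":
        spec = SyntheticCohortSpec(**{**config.cohort, "seed": config.seed})
        return generate_cohort(spec)
    from . import io as fio

    series = []
    roi_ids = None
    for p in config.series_files:
        mat, ids = fio.read_roi_series(p)
        if roi_ids is not None and not np.array_equal(ids, roi_ids):
            raise ValueError(f"{p}: ROI ids differ across subjects")
        roi_ids = ids
        series.append(mat)
    covariates = fio.read_table(config.covariates_file)
    targets_df = fio.read_table(config.targets_file)
    targets = {
        c: targets_df[c].to_numpy()
        for c in targets_df.columns
        if c != "subject_id"
    }
    sset = ROITimeSeriesSet(
        data=np.stack(series),
        tr_seconds=0.735,
        roi_ids=roi_ids,
        subject_ids=covariates["subject_id"].to_numpy(),
    )
    from .synthetic import SyntheticCohort

    return SyntheticCohort(
        series=sset, covariates=covariates, targets=targets, truth={}
    )


def run_experiment(config: ExperimentConfig) -> dict:
    """Run the full pipeline and write result tables under config.out_dir.

    Returns {"predictions": DataFrame, "identification": DataFrame,
    "feature_maps": dict, "tsnr_profile": TSNRProfile}.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    cohort = _load_cohort(config)
    feature_maps = extract_feature_maps(cohort.series, config.features)

    profiles = [tsnr.roi_tsnr(m) for m in cohort.series.data]
    group_profile = tsnr.normalize_and_group_mean(profiles)

    targets = {name: cohort.targets[name] for name in config.targets}
    task_by_target = {
        name: ("classification" if np.isin(v, (0, 1)).all() else "regression")
        for name, v in targets.items()
    }
    model_specs = [
        prediction.ModelSpec(
            model=m, task="regression", lambda_grid=tuple(config.lambda_grid)
        )
        for m in config.models
    ]
    cv = prediction.CVConfig(
        n_repeats=config.n_repeats,
        n_outer_folds=config.n_outer_folds,
        n_inner_folds=config.n_inner_folds,
        seed=config.seed,
    )
    predictions = prediction.sample_size_sweep(
        feature_maps,
        targets,
        cohort.covariates,
        config.scenarios,
        model_specs,
        config.sizes,
        tsnr_levels=config.tsnr_levels,
        tsnr_profile=group_profile,
        cv_config=cv,
        task_by_target=task_by_target,
    )
    ident = identification_matrix(feature_maps, confounds=cohort.covariates)

    from . import io as fio

    fio.write_table(out_dir / "predictions.csv", predictions)
    ident_out = ident.reset_index().rename(columns={"index": "feature"})
    fio.write_table(out_dir / "identification.csv", ident_out)
    pd.DataFrame(
        {
            "roi_id": cohort.series.roi_ids,
            "tsnr": group_profile.values,
        }
    ).to_csv(out_dir / "group_tsnr.tsv", sep="\t", index=False)
    config.to_yaml(out_dir / "resolved_config.yaml")

    n_failed = int((predictions["status"] != "ok").sum())
    if n_failed:
        logger.warning("%d prediction cell(s) failed", n_failed)
    return {
        "predictions": predictions,
        "identification": ident,
        "feature_maps": feature_maps,
        "tsnr_profile": group_profile,
    }
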