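"""Confound-aware predictive modeling with nested cross-validation.

Four scenarios for the role of individual characteristics (age, gender, TIV):

* S1_features_raw          — ROI features only, confounds ignored;
* S2_features_deconfounded — ROI features with the characteristics regressed
                             out (target-level for regression, feature-level
                             for classification), fold-wise;
* S3_features_plus_covariates — ROI features and the three characteristics
                             concatenated as predictors;
* S4_covariates_only       — the three characteristics alone.

Models are ridge regression/classification with a grid-searched penalty and a
linear SVM with a heuristic, data-derived C.  Evaluation is five repeats of
5-fold nested cross-validation; every data-dependent step (z-scoring,
confound residualization, hyperparameter choice) is fit on training rows only
and applied to held-out rows, at both nesting levels.

Scores: Spearman correlation between held-out predictions and targets
(regression) or balanced accuracy (classification), averaged over the
repeat x fold pairs.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.linear_model import LinearRegression, Ridge
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import LinearSVC, LinearSVR

logger = logging.getLogger(__name__)

SCENARIOS = (
    "S1_features_raw",
    "S2_features_deconfounded",
    "S3_features_plus_covariates",
    "S4_covariates_only",
)

#: Ridge penalty grid searched in the inner loop (39 values, 0 = unregularized
#: least squares with a pseudo-inverse fallback).
DEFAULT_LAMBDA_GRID = (
    0, 0.00001, 0.0001, 0.001, 0.004, 0.007, 0.01, 0.04, 0.07, 0.1,
    0.4, 0.7, 1, 1.5, 2, 2.5, 3, 3.5, 4, 5,
    10, 15, 20, 30, 40, 50, 60, 70, 80, 100,
    150, 200, 300, 500, 700, 1000, 10_000, 100_000, 1_000_000,
)

COVARIATE_COLUMNS = ("age", "gender", "tiv")

__all__ = [
    "SCENARIOS",
    "DEFAULT_LAMBDA_GRID",
    "ModelSpec",
    "CVConfig",
    "PredictionResult",
    "validate_covariates",
    "residualize",
    "assemble_design",
    "heuristic_c",
    "nested_cv_predict",
    "balanced_subsample",
    "default_size_grid",
    "default_tsnr_levels",
    "enumerate_grid",
    "sample_size_sweep",
]


@dataclass
class ModelSpec:
    model: str = "ridge"  # {"ridge", "linear_svm"}
    task: str = "regression"  # {"regression", "classification"}
    lambda_grid: tuple = DEFAULT_LAMBDA_GRID

    def __post_init__(self) -> None:
        if self.model not in ("ridge", "linear_svm"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.task not in ("regression", "classification"):
            raise ValueError(f"unknown task {self.task!r}")
        if len(self.lambda_grid) == 0 or min(self.lambda_grid) < 0:
            raise ValueError("lambda_grid must be nonempty and nonnegative")


@dataclass
class CVConfig:
    n_repeats: int = 5
    n_outer_folds: int = 5
    n_inner_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_outer_folds < 2 or self.n_inner_folds < 2:
            raise ValueError("folds must be >= 2")
        if self.n_repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass
class PredictionResult:
    feature_name: str
    target_name: str
    scenario: str
    model: str
    task: str
    n_subjects: int
    tsnr_level_percent: float
    score: float
    fold_scores: np.ndarray = field(default_factory=lambda: np.array([]))
    chosen_lambdas: list = field(default_factory=list)


def validate_covariates(covariates: pd.DataFrame) -> np.ndarray:
    """Return the (n, 3) age/gender/TIV design; rejects missing values."""
    missing = [c for c in COVARIATE_COLUMNS if c not in covariates.columns]
    if missing:
        raise ValueError(f"covariate table lacks columns {missing}")
    block = covariates.loc[:, list(COVARIATE_COLUMNS)].to_numpy(dtype=float)
    if np.isnan(block).any():
        raise ValueError("covariate table contains missing values")
    if not np.isin(block[:, 1], (0.0, 1.0)).all():
        raise ValueError("gender must be coded 0/1")
    return block


# ---------------------------------------------------------------------------
# confound removal
# ---------------------------------------------------------------------------

def residualize(
    values: np.ndarray,
    confounds: np.ndarray,
    train_idx: np.ndarray,
    apply_idx: np.ndarray,
) -> np.ndarray:
    """OLS residuals of ``values`` against the confounds, leak-free.

    Coefficients (including an intercept) are estimated on ``train_idx`` rows
    only and applied to ``apply_idx`` rows.  ``values`` may be a vector
    (target-level removal) or a matrix (feature-level removal, column-wise).
    """
    values = np.asarray(values, dtype=float)
    confounds = np.asarray(confounds, dtype=float)
    design = np.column_stack([np.ones(confounds.shape[0]), confounds])
    d_train = design[train_idx]
    if np.linalg.matrix_rank(d_train) < design.shape[1]:
        raise ValueError("rank-deficient confound design on training rows")
    squeeze = values.ndim == 1
    y = values[:, None] if squeeze else values
    beta, *_ = np.linalg.lstsq(d_train, y[train_idx], rcond=None)
    resid = y[apply_idx] - design[apply_idx] @ beta
    return resid[:, 0] if squeeze else resid


# ---------------------------------------------------------------------------
# design assembly
# ---------------------------------------------------------------------------

def assemble_design(
    feature_matrix: np.ndarray,
    covariates: pd.DataFrame,
    scenario: str,
    roi_subset: np.ndarray | None = None,
):
    """Predictor matrix for one scenario.

    ``feature_matrix`` is (n_subjects, n_rois) for one named feature;
    ``roi_subset`` selects the suprathreshold ROI columns (all if None).
    Returns (X, confounds-or-None): S2 passes the covariate block back for
    fold-wise removal, other scenarios return None.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    cov = validate_covariates(covariates)

    if scenario == "S4_covariates_only":
        return cov.copy(), None

    feature_matrix = np.asarray(feature_matrix, dtype=float)
    if roi_subset is None:
        roi_subset = np.arange(feature_matrix.shape[1])
    roi_subset = np.asarray(roi_subset, dtype=int)
    if roi_subset.size == 0:
        raise ValueError(f"empty ROI subset for scenario {scenario}")
    feats = feature_matrix[:, roi_subset]

    if scenario == "S1_features_raw":
        return feats, None
    if scenario == "S2_features_deconfounded":
        return feats, cov
    # S3: features + the three characteristics (n_roi + 3 columns)
    return np.column_stack([feats, cov]), None


def heuristic_c(design: np.ndarray) -> float:
    """SVM cost C = 1 / mean row Euclidean norm of the z-scored design."""
    design = np.asarray(design, dtype=float)
    norms = np.linalg.norm(design, axis=1)
    mean_norm = norms.mean()
    if mean_norm == 0:
        raise ValueError("all-zero design matrix")
    return float(1.0 / mean_norm)


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

def _fit_predict(
    model: str,
    task: str,
    lam: float | None,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
) -> np.ndarray:
    if model == "ridge":
        if task == "regression":
            est = (
                LinearRegression() if lam == 0 else Ridge(alpha=lam)
            )
            est.fit(X_train, y_train)
            return est.predict(X_test)
        # ridge classification: least-squares on +/-1 labels, sign decision;
        # lam = 0 falls back to the lstsq pseudo-inverse via LinearRegression
        y_pm = 2.0 * y_train - 1.0
        est = LinearRegression() if lam == 0 else Ridge(alpha=lam)
        est.fit(X_train, y_pm)
        return (est.predict(X_test) >= 0).astype(int)
    # linear SVM, heuristic C from the (z-scored) training design
    C = heuristic_c(X_train)
    if task == "regression":
        est = LinearSVR(C=C, max_iter=10_000)
    else:
        est = LinearSVC(C=C, max_iter=10_000)
    est.fit(X_train, y_train)
    return est.predict(X_test)


def _score(task: str, y_true: np.ndarray, y_pred: np.ndarray) -> float:
    if task == "classification":
        return float(balanced_accuracy_score(y_true, y_pred))
    if np.std(y_pred) == 0 or np.std(y_true) == 0:
        logger.warning("constant predictions; Spearman recorded as 0")
        return 0.0
    return float(spearmanr(y_true, y_pred).statistic)


def _zscore_train_apply(X_train, X_apply):
    mu = X_train.mean(axis=0)
    sd = X_train.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X_train - mu) / sd, (X_apply - mu) / sd


def _prepare_fold(X, y, confounds, task, train_idx, test_idx):
    """Leak-free per-fold preparation: confound removal then z-scoring,
    both fit on the training rows only."""
    y_train, y_test = y[train_idx], y[test_idx]
    X_train, X_test = X[train_idx], X[test_idx]
    if confounds is not None:
        if task == "regression":  # target-level removal
            y_train = residualize(y, confounds, train_idx, train_idx)
            y_test = residualize(y, confounds, train_idx, test_idx)
        else:  # feature-level removal
            X_train = residualize(X, confounds, train_idx, train_idx)
            X_test = residualize(X, confounds, train_idx, test_idx)
    X_train, X_test = _zscore_train_apply(X_train, X_test)
    return X_train, y_train, X_test, y_test


def _inner_select_lambda(
    X, y, confounds, spec: ModelSpec, n_inner: int, rng_seed: int
) -> float:
    """Grid-search the ridge penalty on inner folds of the outer-train set."""
    task = spec.task
    if task == "classification":
        splitter = StratifiedKFold(
            n_splits=n_inner, shuffle=True, random_state=rng_seed
        )
        splits = splitter.split(X, y)
    else:
        splitter = KFold(n_splits=n_inner, shuffle=True, random_state=rng_seed)
        splits = splitter.split(X)
    folds = [
        (np.asarray(tr), np.asarray(te)) for tr, te in splits
    ]
    scores = np.zeros(len(spec.lambda_grid))
    for tr, te in folds:
        Xtr, ytr, Xte, yte = _prepare_fold(X, y, confounds, task, tr, te)
        for j, lam in enumerate(spec.lambda_grid):
            pred = _fit_predict("ridge", task, lam, Xtr, ytr, Xte)
            scores[j] += _score(task, yte, pred)
    return float(spec.lambda_grid[int(np.argmax(scores))])


def nested_cv_predict(
    X: np.ndarray,
    y: np.ndarray,
    model_spec: ModelSpec,
    cv_config: CVConfig,
    confounds: np.ndarray | None = None,
    min_subjects: int = 50,
    **result_meta,
) -> PredictionResult:
    """Repeated nested cross-validation for one design/target pair.

    Per repeat, a shuffled outer split; per outer fold, confound removal and
    z-scoring fit on outer-train, ridge penalty chosen by inner grid search
    (the SVM's heuristic C needs no search), model refit on outer-train, and
    the held-out fold scored.  The headline score is the mean over the
    n_repeats x n_outer_folds fold scores.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if n < min_subjects:
        raise ValueError(f"need >= {min_subjects} subjects, got {n}")
    if y.shape[0] != n:
        raise ValueError("design and target disagree on n_subjects")
    task = model_spec.task
    if task == "classification":
        y = y.astype(int)
        if np.unique(y).size < 2:
            raise ValueError("classification target has a single class")

    fold_scores = []
    chosen = []
    for rep in range(cv_config.n_repeats):
        rep_seed = (cv_config.seed * 1009 + rep) % (2**31 - 1)
        if task == "classification":
            outer = StratifiedKFold(
                n_splits=cv_config.n_outer_folds,
                shuffle=True,
                random_state=rep_seed,
            ).split(X, y)
        else:
            outer = KFold(
                n_splits=cv_config.n_outer_folds,
                shuffle=True,
                random_state=rep_seed,
            ).split(X)
        for fold_i, (tr, te) in enumerate(outer):
            tr, te = np.asarray(tr), np.asarray(te)
            if model_spec.model == "ridge":
                lam = _inner_select_lambda(
                    X[tr],
                    y[tr],
                    None if confounds is None else confounds[tr],
                    model_spec,
                    cv_config.n_inner_folds,
                    rng_seed=(rep_seed + fold_i) % (2**31 - 1),
                )
            else:
                lam = None
            Xtr, ytr, Xte, yte = _prepare_fold(X, y, confounds, task, tr, te)
            pred = _fit_predict(model_spec.model, task, lam, Xtr, ytr, Xte)
            fold_scores.append(_score(task, yte, pred))
            chosen.append(lam)

    fold_scores = np.asarray(fold_scores)
    return PredictionResult(
        feature_name=result_meta.get("feature_name", ""),
        target_name=result_meta.get("target_name", ""),
        scenario=result_meta.get("scenario", ""),
        model=model_spec.model,
        task=task,
        n_subjects=n,
        tsnr_level_percent=result_meta.get("tsnr_level_percent", 0.0),
        score=float(fold_scores.mean()),
        fold_scores=fold_scores,
        chosen_lambdas=chosen,
    )


# ---------------------------------------------------------------------------
# sample-size machinery
# ---------------------------------------------------------------------------

def balanced_subsample(
    gender: np.ndarray, n: int, seed: int
) -> np.ndarray:
    """Seed-deterministic subject indices with n/2 per gender."""
    gender = np.asarray(gender).astype(int)
    if n % 2 != 0:
        raise ValueError("n must be even for a balanced subsample")
    rng = np.random.default_rng(seed)
    idx = []
    for g in (0, 1):
        pool = np.flatnonzero(gender == g)
        if pool.size < n // 2:
            raise ValueError(
                f"gender {g} has {pool.size} subjects, need {n // 2}"
            )
        idx.append(rng.choice(pool, size=n // 2, replace=False))
    return np.sort(np.concatenate(idx))


def default_size_grid() -> np.ndarray:
    """Sample sizes 100..2000 step 50, then 2500..20000 step 500 (75 sizes)."""
    return np.concatenate(
        [np.arange(100, 2001, 50), np.arange(2500, 20_001, 500)]
    )


def default_tsnr_levels() -> np.ndarray:
    """tSNR threshold levels 0..60% in 5% steps (13 levels)."""
    return np.arange(0.0, 61.0, 5.0)


def enumerate_grid(features, targets, sizes, tsnr_levels) -> list[dict]:
    """Full factorial cell list (per model type): feature x target x size x
    tSNR level.  Countable before any compute."""
    return [
        {
            "feature_name": f,
            "target_name": t,
            "n_subjects": int(n),
            "tsnr_level_percent": float(lv),
        }
        for f in features
        for t in targets
        for n in sizes
        for lv in tsnr_levels
    ]


def _cell_seed(master_seed: int, *parts) -> int:
    token = "|".join(str(p) for p in (master_seed, *parts))
    return zlib.crc32(token.encode()) % (2**31 - 1)


def sample_size_sweep(
    feature_maps: dict,
    targets: dict,
    covariates: pd.DataFrame,
    scenarios,
    model_specs,
    sizes,
    tsnr_levels=(0.0,),
    tsnr_profile=None,
    cv_config: CVConfig | None = None,
    task_by_target: dict | None = None,
) -> pd.DataFrame:
    """Run the full factorial sweep; one row per result cell, failures logged
    and recorded rather than aborting the sweep.

    ``feature_maps`` maps feature name -> (n_subjects, n_rois) matrix;
    ``targets`` maps target name -> vector; ``tsnr_profile`` (normalized) is
    used to select suprathreshold ROI columns at each level.
    """
    from .tsnr import suprathreshold_rois

    cv_config = cv_config or CVConfig()
    sizes = np.asarray(sizes, dtype=int)
    if np.any(np.diff(sizes) < 0):
        raise ValueError("sizes must be sorted ascending")
    gender = covariates["gender"].to_numpy()
    rows = []
    for spec in model_specs:
        for scenario in scenarios:
            cells = enumerate_grid(
                feature_maps.keys(), targets.keys(), sizes, tsnr_levels
            )
            for cell in cells:
                fname = cell["feature_name"]
                tname = cell["target_name"]
                n = cell["n_subjects"]
                level = cell["tsnr_level_percent"]
                task = (
                    task_by_target.get(tname, spec.task)
                    if task_by_target
                    else spec.task
                )
                cell_spec = ModelSpec(
                    model=spec.model, task=task, lambda_grid=spec.lambda_grid
                )
                try:
                    seed = _cell_seed(
                        cv_config.seed, fname, tname, scenario, n, level,
                        spec.model,
                    )
                    idx = balanced_subsample(gender, n, seed)
                    if tsnr_profile is not None:
                        roi_subset = suprathreshold_rois(tsnr_profile, level)
                    else:
                        roi_subset = None
                    X, conf = assemble_design(
                        feature_maps[fname][idx],
                        covariates.iloc[idx],
                        scenario,
                        roi_subset,
                    )
                    res = nested_cv_predict(
                        X,
                        targets[tname][idx],
                        cell_spec,
                        CVConfig(
                            n_repeats=cv_config.n_repeats,
                            n_outer_folds=cv_config.n_outer_folds,
                            n_inner_folds=cv_config.n_inner_folds,
                            seed=seed,
                        ),
                        confounds=conf,
                        feature_name=fname,
                        target_name=tname,
                        scenario=scenario,
                        tsnr_level_percent=level,
                    )
                    rows.append(
                        {
                            "feature": fname,
                            "target": tname,
                            "scenario": scenario,
                            "model": spec.model,
                            "task": task,
                            "n_subjects": n,
                            "tsnr_level_percent": level,
                            "score": res.score,
                            "status": "ok",
                        }
                    )
                except Exception as exc:  # failed cell: record, continue
                    logger.warning(
                        "cell failed (%s, %s, %s, n=%d, %s%%): %s",
                        fname, tname, scenario, n, level, exc,
                    )
                    rows.append(
                        {
                            "feature": fname,
                            "target": tname,
                            "scenario": scenario,
                            "model": spec.model,
                            "task": task,
                            "n_subjects": n,
                            "tsnr_level_percent": level,
                            "score": np.nan,
                            "status": f"failed: {exc}",
                        }
                    )
    return pd.DataFrame(rows)
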