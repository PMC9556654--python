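"""RBF-kernel SVM discrimination of patients vs. controls from regional
DC features.

A grid of (C, gamma) pairs is evaluated by cross-validated accuracy
(leave-one-out by default, the convention for LIBSVM studies at this
sample size); feature standardization is fit inside each training fold
only, so no test-fold statistics leak into the scaler.  Reports carry
integer confusion counts so accuracy / sensitivity / specificity are
exact fractions.

Two protocols are provided for region-based classification:

* ``paper`` — regions come from a group contrast on all subjects and the
  SVM is cross-validated on those same subjects (the circular protocol
  common in this literature; optimistically biased).
* ``nested`` — cluster selection is redone inside every training fold,
  giving an unbiased accuracy estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import LeaveOneOut, StratifiedKFold, cross_val_predict
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "SvmConfig",
    "ClassificationReport",
    "grid_search_svm",
    "evaluate_features",
    "evaluate_per_region",
    "nested_cv_classification",
    "confusion_metrics",
]


def _pow2_grid(lo: int = -10, hi: int = 10, step: int = 2) -> tuple[float, ...]:
    return tuple(float(2.0**e) for e in range(lo, hi + 1, step))


@dataclass(frozen=True)
class SvmConfig:
    """Hyperparameter search space and CV scheme.

    Default grids span powers of two from 2^-10 to 2^10 for both the
    penalty C and the RBF width gamma (the LIBSVM grid-tool convention).
    """

    C_grid: tuple[float, ...] = field(default_factory=_pow2_grid)
    gamma_grid: tuple[float, ...] = field(default_factory=_pow2_grid)
    cv_scheme: str = "leave_one_out"  # or "k_fold"
    k: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.C_grid or not self.gamma_grid:
            raise ValueError("hyperparameter grids must be nonempty")
        if any(c <= 0 for c in self.C_grid) or any(g <= 0 for g in self.gamma_grid):
            raise ValueError("C and gamma must be positive")
        if self.cv_scheme not in ("leave_one_out", "k_fold"):
            raise ValueError("cv_scheme must be 'leave_one_out' or 'k_fold'")
        if self.cv_scheme == "k_fold" and self.k < 2:
            raise ValueError("k must be >= 2 for k_fold")

    def splitter(self):
        if self.cv_scheme == "leave_one_out":
            return LeaveOneOut()
        return StratifiedKFold(n_splits=self.k, shuffle=True, random_state=self.seed)


@dataclass
class ClassificationReport:
    """Cross-validated confusion counts and rates for one feature set."""

    feature_set: str
    best_C: float
    best_gamma: float
    tp: int
    fn: int
    tn: int
    fp: int
    predictions: np.ndarray
    cv_scheme: str = "leave_one_out"
    protocol: str = "paper"

    @property
    def n_total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n_total

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    def summary(self) -> dict:
        acc, sens, spec = confusion_metrics(self.tp, self.fn, self.tn, self.fp)
        return dict(
            feature_set=self.feature_set, best_C=self.best_C, best_gamma=self.best_gamma,
            accuracy_pct=acc, sensitivity_pct=sens, specificity_pct=spec,
            tp=self.tp, fn=self.fn, tn=self.tn, fp=self.fp,
            cv_scheme=self.cv_scheme, protocol=self.protocol,
        )


def _validate_xy(features: np.ndarray, labels: np.ndarray):
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels).astype(int)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("labels contain a single class")
    if min((y == c).sum() for c in classes) < 2:
        raise ValueError("need at least 2 subjects per class")
    return X, y


def _cv_accuracy(X, y, C, gamma, splitter) -> float:
    model = make_pipeline(StandardScaler(), SVC(kernel="rbf", C=C, gamma=gamma))
    pred = cross_val_predict(model, X, y, cv=splitter)
    return float((pred == y).mean())


def grid_search_svm(
    features: np.ndarray,
    labels: np.ndarray,
    config: SvmConfig = SvmConfig(),
) -> tuple[float, float, float]:
    """Exhaustive (C, gamma) search maximizing cross-validated accuracy.

    Ties are broken toward smaller C, then smaller gamma (grids are
    scanned in ascending order and only strict improvements replace the
    incumbent).  Returns (best_C, best_gamma, best_cv_accuracy).
    """
    X, y = _validate_xy(features, labels)
    splitter = config.splitter()
    best = (None, None, -1.0)
    for C in sorted(config.C_grid):
        for gamma in sorted(config.gamma_grid):
            acc = _cv_accuracy(X, y, C, gamma, splitter)
            if acc > best[2]:
                best = (C, gamma, acc)
    return best


def evaluate_features(
    features: np.ndarray,
    labels: np.ndarray,
    config: SvmConfig = SvmConfig(),
    feature_set: str = "all",
    protocol: str = "paper",
) -> ClassificationReport:
    """Grid-search then cross-validate one feature set, reporting
    confusion counts (label 1 = patient/positive)."""
    X, y = _validate_xy(features, labels)
    best_C, best_gamma, _ = grid_search_svm(X, y, config)
    model = make_pipeline(StandardScaler(), SVC(kernel="rbf", C=best_C, gamma=best_gamma))
    pred = cross_val_predict(model, X, y, cv=config.splitter())
    return ClassificationReport(
        feature_set=feature_set,
        best_C=best_C,
        best_gamma=best_gamma,
        tp=int(((pred == 1) & (y == 1)).sum()),
        fn=int(((pred == 0) & (y == 1)).sum()),
        tn=int(((pred == 0) & (y == 0)).sum()),
        fp=int(((pred == 1) & (y == 0)).sum()),
        predictions=pred,
        cv_scheme=config.cv_scheme,
        protocol=protocol,
    )


def evaluate_per_region(
    feature_table: pd.DataFrame,
    labels: np.ndarray,
    config: SvmConfig = SvmConfig(),
    region_cols: list[str] | None = None,
) -> list[ClassificationReport]:
    """One report per single-region feature plus one joint all-region
    report, ordered by CV accuracy (best first; the joint model is ranked
    alongside the single regions)."""
    if region_cols is None:
        region_cols = [c for c in feature_table.columns if c.startswith("dc_")]
    if not region_cols:
        raise ValueError("no region feature columns found")
    y = np.asarray(labels).astype(int)
    reports = [
        evaluate_features(feature_table[col].to_numpy(), y, config, feature_set=col)
        for col in region_cols
    ]
    if len(region_cols) > 1:
        reports.append(
            evaluate_features(feature_table[region_cols].to_numpy(), y, config,
                              feature_set="all_regions"))
    reports.sort(key=lambda r: r.accuracy, reverse=True)
    return reports


def nested_cv_classification(
    dc_maps,
    cohort: pd.DataFrame,
    mask,
    config: SvmConfig = SvmConfig(),
    voxel_p: float = 0.01,
    alpha: float = 0.05,
    covariates: tuple[str, ...] = ("age_years", "sex"),
    min_cluster_voxels: int = 0,
) -> ClassificationReport:
    """Unbiased region-based classification: inside every training fold
    the group GLM and cluster correction are refit on the training
    subjects only, the surviving clusters define that fold's features,
    and the held-out subjects are predicted from them.

    Folds whose training contrast yields no surviving cluster predict the
    training majority class.  Grid search runs on the training fold with
    an inner stratified 5-fold split.
    """
    from .clinical import extract_region_features
    from .inference import (cluster_label_map, fit_voxelwise_glm,
                            grf_cluster_correct, make_group_design)

    y = np.where(cohort["group"].to_numpy() == "patient", 1, 0)
    n = len(y)
    pred = np.empty(n, dtype=int)
    inner_cfg = SvmConfig(C_grid=config.C_grid, gamma_grid=config.gamma_grid,
                          cv_scheme="k_fold", k=min(5, max(2, n // 4)), seed=config.seed)
    for test_idx in range(n):
        train = np.setdiff1d(np.arange(n), [test_idx])
        sub_cohort = cohort.iloc[train].reset_index(drop=True)
        design = make_group_design(sub_cohort, covariates)
        stat = fit_voxelwise_glm([dc_maps[i] for i in train], design, mask)
        table = grf_cluster_correct(stat, mask, voxel_p=voxel_p, alpha=alpha,
                                    min_cluster_voxels=min_cluster_voxels)
        if table.empty:
            counts = np.bincount(y[train], minlength=2)
            pred[test_idx] = int(np.argmax(counts))
            continue
        labels_map = cluster_label_map(table, stat, voxel_p=voxel_p)
        feats = extract_region_features([dc_maps[i] for i in train], labels_map)
        region_cols = [c for c in feats.columns if c.startswith("dc_")]
        X_train = feats[region_cols].to_numpy()
        best_C, best_gamma, _ = grid_search_svm(X_train, y[train], inner_cfg)
        model = make_pipeline(StandardScaler(),
                              SVC(kernel="rbf", C=best_C, gamma=best_gamma))
        model.fit(X_train, y[train])
        feats_test = extract_region_features([dc_maps[test_idx]], labels_map)
        pred[test_idx] = int(model.predict(feats_test[region_cols].to_numpy())[0])

    return ClassificationReport(
        feature_set="nested_clusters",
        best_C=np.nan, best_gamma=np.nan,
        tp=int(((pred == 1) & (y == 1)).sum()),
        fn=int(((pred == 0) & (y == 1)).sum()),
        tn=int(((pred == 0) & (y == 0)).sum()),
        fp=int(((pred == 1) & (y == 0)).sum()),
        predictions=pred,
        cv_scheme="leave_one_out",
        protocol="nested",
    )


def confusion_metrics(tp: int, fn: int, tn: int, fp: int) -> tuple[float, float, float]:
    """Accuracy, sensitivity, specificity as percentages to one decimal.

    accuracy = (tp+tn)/(tp+fn+tn+fp); sensitivity = tp/(tp+fn);
    specificity = tn/(tn+fp).
    """
    for name, v in (("tp", tp), ("fn", fn), ("tn", tn), ("fp", fp)):
        if v < 0 or int(v) != v:
            raise ValueError(f"{name} must be a nonnegative integer")
    if tp + fn < 1 or tn + fp < 1:
        raise ValueError("each class needs at least one subject")
    acc = 100.0 * (tp + tn) / (tp + fn + tn + fp)
    sens = 100.0 * tp / (tp + fn)
    spec = 100.0 * tn / (tn + fp)
    return round(acc, 1), round(sens, 1), round(spec, 1)
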