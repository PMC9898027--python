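"""Cohort-level analysis: PCA disease space, classification, statistics.

Per-sample fibrosis feature vectors (average CIF, four bin fractions,
heterogeneity, optionally topological statistics and external feature sets
such as megakaryocyte descriptors) are assembled into a samples x features
matrix. From it:

* a 2-D PCA "disease space" is fitted on z-scored features, with the
  standardization and component signs frozen so that new or sequential
  samples can be indexed into the same coordinates later;
* a random forest (100 trees, stratified 3-fold cross-validation) separates
  two diagnostic groups, reported as pooled out-of-fold AUC with per-fold
  AUCs and Gini importances;
* group differences in any single feature are tested with the two-sided
  Mann-Whitney-Wilcoxon test, Bonferroni-adjusted, with distribution-free
  95% confidence intervals of each group median.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .exceptions import DataError, InvalidArgumentError

FIBROSIS_FEATURES = ("avg_cif", "p0", "p1", "p2", "p3", "heterogeneity")


@dataclass
class CohortMatrix:
    sample_ids: list[str]
    labels: list[str]
    X: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.shape != (len(self.sample_ids), len(self.feature_names)):
            raise InvalidArgumentError("X shape inconsistent with ids/features")
        if np.isnan(self.X).any():
            raise InvalidArgumentError("cohort matrix contains missing values")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise InvalidArgumentError("feature names must be unique")

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        feature_names: list[str] | None = None,
        id_col: str = "sample_id",
        label_col: str = "class_label",
    ) -> "CohortMatrix":
        if feature_names is None:
            feature_names = [
                c for c in df.columns if c not in (id_col, label_col, "n_tiles")
            ]
        return cls(
            sample_ids=df[id_col].astype(str).tolist(),
            labels=df[label_col].astype(str).tolist() if label_col in df else [""] * len(df),
            X=df[feature_names].to_numpy(dtype=np.float64),
            feature_names=list(feature_names),
        )

    def as_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df.insert(0, "class_label", self.labels)
        df.insert(0, "sample_id", self.sample_ids)
        return df


@dataclass
class DiseaseSpace:
    """Frozen 2-D PCA embedding: z-scoring reference plus orthonormal loadings."""

    feature_names: list[str]
    mean: np.ndarray
    scale: np.ndarray
    loadings: np.ndarray  # (2, n_features), rows orthonormal
    explained_variance: np.ndarray  # (2,)

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        z = (X - self.mean) / self.scale
        return z @ self.loadings.T

    def to_json(self, path: str | Path) -> None:
        payload = {
            "feature_names": self.feature_names,
            "mean": self.mean.tolist(),
            "scale": self.scale.tolist(),
            "loadings": self.loadings.tolist(),
            "explained_variance": self.explained_variance.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "DiseaseSpace":
        d = json.loads(Path(path).read_text())
        return cls(
            feature_names=d["feature_names"],
            mean=np.array(d["mean"]),
            scale=np.array(d["scale"]),
            loadings=np.array(d["loadings"]),
            explained_variance=np.array(d["explained_variance"]),
        )


@dataclass
class ClassifierReport:
    auc: float
    fold_aucs: list[float]
    gini_importances: dict[str, float]
    n_trees: int
    folds: int
    seed: int
    positive_label: str


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    feature: str
    statistic: float
    p_raw: float
    p_adjusted: float
    median_a: float
    median_b: float
    median_ci_a: tuple[float, float]
    median_ci_b: tuple[float, float]
    n_a: int
    n_b: int


def fit_disease_space(cohort: CohortMatrix) -> DiseaseSpace:
    """Top-2 PCA of z-scored features with a deterministic sign convention.

    Zero-variance features are dropped with a warning; the feature mean and
    standard deviation are frozen so later samples index into identical
    coordinates. Each component's sign is fixed so its largest-magnitude
    loading is positive.
    """
    if len(cohort.sample_ids) < 3:
        raise DataError("need at least 3 samples to fit the disease space")
    X = cohort.X
    sd = X.std(axis=0, ddof=0)
    usable = sd > 0
    if (~usable).any():
        dropped = [n for n, u in zip(cohort.feature_names, usable) if not u]
        warnings.warn(f"dropping zero-variance features: {dropped}")
    names = [n for n, u in zip(cohort.feature_names, usable) if u]
    if len(names) < 2:
        raise DataError("fewer than 2 usable (non-constant) features")
    Xu = X[:, usable]
    mean = Xu.mean(axis=0)
    scale = sd[usable]
    Z = (Xu - mean) / scale
    # SVD-based PCA
    _, svals, vt = np.linalg.svd(Z, full_matrices=False)
    loadings = vt[:2]
    explained = (svals[:2] ** 2) / len(Z)
    for k in range(loadings.shape[0]):
        j = int(np.argmax(np.abs(loadings[k])))
        if loadings[k, j] < 0:
            loadings[k] = -loadings[k]
    return DiseaseSpace(
        feature_names=names,
        mean=mean,
        scale=scale,
        loadings=loadings,
        explained_variance=explained,
    )


def index_sample(space: DiseaseSpace, fv: dict | np.ndarray) -> np.ndarray:
    """Project one feature vector into the frozen disease space.

    Accepts a name->value mapping (missing features are reported by name) or
    an array already ordered like space.feature_names.
    """
    if isinstance(fv, dict):
        missing = [n for n in space.feature_names if n not in fv]
        if missing:
            raise InvalidArgumentError(f"missing features: {missing}")
        x = np.array([fv[n] for n in space.feature_names], dtype=np.float64)
    else:
        x = np.asarray(fv, dtype=np.float64)
        if x.shape[-1] != len(space.feature_names):
            raise InvalidArgumentError(
                f"expected {len(space.feature_names)} features, got {x.shape[-1]}"
            )
    return space.transform(x)[0]


def classify(
    cohort: CohortMatrix,
    positive_label: str,
    n_trees: int = 100,
    folds: int = 3,
    seed: int = 0,
    use_pca_coordinates: bool = False,
) -> ClassifierReport:
    """Random-forest discrimination with stratified k-fold cross-validation.

    Out-of-fold probabilities are pooled into the headline AUC; per-fold
    AUCs accompany it. Gini importances come from a forest refit on all
    samples. With use_pca_coordinates the classifier consumes the 2-D
    disease-space coordinates instead of the raw features.
    """
    y = np.array([1 if l == positive_label else 0 for l in cohort.labels])
    if y.sum() == 0 or y.sum() == len(y):
        raise DataError("both classes must be present")
    counts = np.bincount(y)
    if counts.min() < folds:
        raise DataError(
            f"smallest class has {counts.min()} samples; need >= folds ({folds})"
        )
    if use_pca_coordinates:
        space = fit_disease_space(cohort)
        X = space.transform(cohort.X[:, [cohort.feature_names.index(n) for n in space.feature_names]])
        feat_names = ["PC1", "PC2"]
    else:
        X = cohort.X
        feat_names = cohort.feature_names

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    oof = np.full(len(y), np.nan)
    fold_aucs: list[float] = []
    for k, (tr, te) in enumerate(skf.split(X, y)):
        rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed + k)
        rf.fit(X[tr], y[tr])
        prob = rf.predict_proba(X[te])[:, list(rf.classes_).index(1)]
        oof[te] = prob
        fold_aucs.append(float(roc_auc_score(y[te], prob)))
    auc = float(roc_auc_score(y, oof))

    rf_full = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    rf_full.fit(X, y)
    importances = dict(zip(feat_names, rf_full.feature_importances_.tolist()))
    return ClassifierReport(
        auc=auc,
        fold_aucs=fold_aucs,
        gini_importances=importances,
        n_trees=n_trees,
        folds=folds,
        seed=seed,
        positive_label=positive_label,
    )


def combine_features(
    fibrosis: CohortMatrix, external: pd.DataFrame, id_col: str = "sample_id"
) -> CohortMatrix:
    """Inner-join external per-sample vectors onto the fibrosis matrix.

    Feature names are namespaced fib.* / ext.*; samples without external
    features are dropped with a warning. Fewer than 3 overlapping samples
    is an error.
    """
    ext = external.set_index(external[id_col].astype(str)).drop(columns=[id_col])
    ids = [str(s) for s in fibrosis.sample_ids]
    keep = [i for i, s in enumerate(ids) if s in ext.index]
    if len(keep) < 3:
        raise DataError(
            f"only {len(keep)} samples overlap with the external table; need >= 3"
        )
    n_dropped = len(ids) - len(keep)
    if n_dropped:
        warnings.warn(f"dropping {n_dropped} samples without external features")
    ext_cols = list(ext.columns)
    Xf = fibrosis.X[keep]
    Xe = ext.loc[[ids[i] for i in keep], ext_cols].to_numpy(dtype=np.float64)
    return CohortMatrix(
        sample_ids=[ids[i] for i in keep],
        labels=[fibrosis.labels[i] for i in keep],
        X=np.hstack([Xf, Xe]),
        feature_names=[f"fib.{n}" for n in fibrosis.feature_names]
        + [f"ext.{n}" for n in ext_cols],
    )


def median_ci(values: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Distribution-free order-statistic CI for the median.

    Chooses the symmetric order-statistic pair with coverage >= level when
    achievable at the sample size; otherwise returns the sample range.
    """
    x = np.sort(np.asarray(values, dtype=np.float64))
    n = len(x)
    if n < 1:
        raise InvalidArgumentError("empty group")
    # P(x_(l+1) <= median <= x_(u)) = P(l < B < u), B ~ Binom(n, 1/2)
    best = None
    for l in range(n // 2, -1, -1):
        u = n - l
        cover = stats.binom.cdf(u - 1, n, 0.5) - stats.binom.cdf(l - 1, n, 0.5)
        if cover >= level:
            best = (l, u)
            break
    if best is None:
        return float(x[0]), float(x[-1])
    l, u = best
    return float(x[l]), float(x[u - 1])


def compare_groups(
    values_a: np.ndarray,
    values_b: np.ndarray,
    n_comparisons: int = 1,
    group_a: str = "A",
    group_b: str = "B",
    feature: str = "",
) -> GroupComparison:
    """Two-sided Mann-Whitney-Wilcoxon test with Bonferroni adjustment.

    The exact null distribution is used for small tie-free groups (both
    n <= 20); otherwise the normal approximation with tie correction.
    p_adjusted = min(1, p_raw * n_comparisons).
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise InvalidArgumentError("each group needs at least 2 values")
    if n_comparisons < 1:
        raise InvalidArgumentError("n_comparisons must be >= 1")
    no_ties = len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
    method = "exact" if (no_ties and max(len(a), len(b)) <= 20) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    p_raw = float(res.pvalue)
    return GroupComparison(
        group_a=group_a,
        group_b=group_b,
        feature=feature,
        statistic=float(res.statistic),
        p_raw=p_raw,
        p_adjusted=min(1.0, p_raw * n_comparisons),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        median_ci_a=median_ci(a),
        median_ci_b=median_ci(b),
        n_a=len(a),
        n_b=len(b),
    )
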