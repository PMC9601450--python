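"""Imbalance-aware epoch-wise cross-validated classification.

The protocol per fold: z-score with training-fold statistics, oversample the
minority class with SMOTE, reduce with PCA to 95% explained variance (fitted
on the oversampled training matrix only), fit one of four classifier
families, and score the untouched test fold with precision, recall, and
balanced accuracy (PNES is the positive class). Nothing fitted ever sees the
test fold.

SMOTE is implemented here directly: each synthetic sample is a convex
combination of a minority sample and one of its k nearest minority
neighbours.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors
from sklearn.svm import SVC

from .entropy import FeatureMatrix

__all__ = [
    "POSITIVE_CLASS",
    "KNN_K_GRID",
    "ClassifierSpec",
    "ConfusionCounts",
    "FoldModel",
    "CVResult",
    "smote_oversample",
    "pca_reduce",
    "compute_metrics",
    "run_cv",
]

POSITIVE_CLASS = "PNES"
NEGATIVE_CLASS = "epilepsy"

#: The fixed neighbour grid searched for kNN.
KNN_K_GRID = (2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 15, 20)


@dataclass(frozen=True)
class ClassifierSpec:
    """One classifier family and its hyperparameters.

    kind: "svm" (RBF kernel, gamma = 1/(n_features x variance of the
    standardized, oversampled training matrix)), "knn" (k selected per fold
    by an inner 10-fold balanced-accuracy search over KNN_K_GRID, Euclidean
    distance, uniform weights), "rf" (100 trees), or "gbm" (100 stages,
    learning rate 0.1).
    """

    kind: str = "knn"
    knn_k: int | str = "search"
    n_estimators: int = 100
    gbm_learning_rate: float = 0.1
    max_depth: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("svm", "knn", "rf", "gbm"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class FoldModel:
    """A fitted fold: standardize -> PCA -> classifier, over raw features."""

    mean: np.ndarray
    std: np.ndarray
    pca: PCA | None
    clf: object
    knn_k: int | None = None

    def transform(self, X: np.ndarray) -> np.ndarray:
        Z = (X - self.mean) / self.std
        return self.pca.transform(Z) if self.pca is not None else Z

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.clf.predict(self.transform(X))


@dataclass
class CVResult:
    """Per-fold confusion counts and metrics; means are unweighted."""

    counts: list[ConfusionCounts]
    spec: ClassifierSpec
    description: str = ""
    fold_models: list[FoldModel] = field(default_factory=list)
    fold_test_idx: list[np.ndarray] = field(default_factory=list)

    def _metric(self, i: int) -> list[float]:
        vals = [compute_metrics(c)[i] for c in self.counts]
        return [v for v in vals if not math.isnan(v)]

    @property
    def precisions(self) -> list[float]:
        return self._metric(0)

    @property
    def recalls(self) -> list[float]:
        return self._metric(1)

    @property
    def balanced_accuracies(self) -> list[float]:
        return self._metric(2)

    @property
    def mean_precision(self) -> float:
        return float(np.mean(self.precisions))

    @property
    def mean_recall(self) -> float:
        return float(np.mean(self.recalls))

    @property
    def mean_balanced_accuracy(self) -> float:
        return float(np.mean(self.balanced_accuracies))


def compute_metrics(c: ConfusionCounts) -> tuple[float, float, float]:
    """(precision, recall, balanced accuracy); NaN flags a zero denominator."""
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else float("nan")
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else float("nan")
    sens = recall
    spec_ = c.tn / (c.tn + c.fp) if (c.tn + c.fp) else float("nan")
    bal = 0.5 * (sens + spec_)
    return precision, recall, bal


def smote_oversample(
    X: np.ndarray,
    y: np.ndarray,
    k_neighbors: int = 5,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """SMOTE: upsample the minority class to the majority count.

    Each synthetic row is x_i + u * (x_j - x_i) with u ~ U(0, 1), x_j one of
    the k nearest minority neighbours of minority row x_i. Majority rows are
    returned untouched; synthetic rows are appended.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("SMOTE needs both classes present")
    if classes.size > 2:
        raise ValueError("binary SMOTE only")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    minority = classes[np.argmin(counts)]
    n_needed = counts.max() - counts.min()
    if n_needed == 0:
        return X.copy(), y.copy()
    Xm = X[y == minority]
    k = k_neighbors
    if len(Xm) <= k:
        k = max(len(Xm) - 1, 1)
        warnings.warn(
            f"minority count {len(Xm)} <= k_neighbors {k_neighbors}; using k={k}"
        )
    if len(Xm) == 1:
        synth = np.repeat(Xm, n_needed, axis=0)
    else:
        nn = NearestNeighbors(n_neighbors=k + 1).fit(Xm)
        _, idx = nn.kneighbors(Xm)  # column 0 is self
        base = rng.integers(len(Xm), size=n_needed)
        pick = idx[base, rng.integers(1, k + 1, size=n_needed)]
        u = rng.random((n_needed, 1))
        synth = Xm[base] + u * (Xm[pick] - Xm[base])
    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.repeat(minority, n_needed)])
    return X_out, y_out


def pca_reduce(
    X_train: np.ndarray,
    X_test: np.ndarray,
    variance: float = 0.95,
) -> tuple[np.ndarray, np.ndarray, int, PCA]:
    """PCA keeping the fewest components reaching ``variance``; train-fitted."""
    if len(X_train) < 2:
        raise ValueError("PCA needs at least 2 training samples")
    pca = PCA(n_components=variance, svd_solver="full")
    Z_train = pca.fit_transform(X_train)
    Z_test = pca.transform(X_test)
    return Z_train, Z_test, pca.n_components_, pca


def _make_classifier(spec: ClassifierSpec, Z_train: np.ndarray, y_train: np.ndarray,
                     rng: np.random.Generator):
    seed = int(rng.integers(2**31))
    if spec.kind == "svm":
        gamma = 1.0 / (Z_train.shape[1] * Z_train.var())
        return SVC(kernel="rbf", gamma=gamma, random_state=seed), None
    if spec.kind == "knn":
        if spec.knn_k == "search":
            k = _search_knn_k(Z_train, y_train, seed)
        else:
            k = int(spec.knn_k)
        return KNeighborsClassifier(n_neighbors=k, weights="uniform"), k
    if spec.kind == "rf":
        return RandomForestClassifier(
            n_estimators=spec.n_estimators, max_depth=spec.max_depth,
            random_state=seed,
        ), None
    if spec.kind == "gbm":
        return GradientBoostingClassifier(
            n_estimators=spec.n_estimators,
            learning_rate=spec.gbm_learning_rate,
            random_state=seed,
        ), None
    raise AssertionError(spec.kind)


def _search_knn_k(Z: np.ndarray, y: np.ndarray, seed: int, folds: int = 10) -> int:
    """Inner CV over the fixed neighbour grid, maximising balanced accuracy.

    One neighbour query at the largest k per inner fold serves every grid
    value: majority votes for smaller k are prefixes of the same neighbour
    list (Euclidean distance, uniform weights, ties to the first class in
    sorted order — the convention of the uniform-weight kNN predictor).
    """
    pos = POSITIVE_CLASS if POSITIVE_CLASS in y else np.unique(y)[0]
    classes = np.unique(y)
    min_class = np.unique(y, return_counts=True)[1].min()
    n_splits = int(min(folds, min_class))
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    splits = list(skf.split(Z, y))
    max_k = max(k for k in KNN_K_GRID if k < min(len(tr) for tr, _ in splits))
    scores = {k: [] for k in KNN_K_GRID if k <= max_k}
    for tr, va in splits:
        nn = NearestNeighbors(n_neighbors=max_k).fit(Z[tr])
        _, idx = nn.kneighbors(Z[va])
        neigh_is_pos = (y[tr][idx] == classes[-1])  # va x max_k
        votes = np.cumsum(neigh_is_pos, axis=1)
        for k in scores:
            # argmax-on-counts tie rule: positive (classes[-1]) only wins
            # a strict majority, matching sklearn's predict
            pred = np.where(votes[:, k - 1] > k / 2, classes[-1], classes[0])
            bal = compute_metrics(_confusion(y[va], pred, pos))[2]
            if not math.isnan(bal):
                scores[k].append(bal)
    best_k, best_score = KNN_K_GRID[0], -1.0
    for k, vals in scores.items():
        score = float(np.mean(vals)) if vals else -1.0
        if score > best_score:
            best_k, best_score = k, score
    return best_k


def _confusion(y_true: np.ndarray, y_pred: np.ndarray, pos) -> ConfusionCounts:
    t = np.asarray(y_true) == pos
    p = np.asarray(y_pred) == pos
    return ConfusionCounts(
        tp=int(np.sum(t & p)),
        fp=int(np.sum(~t & p)),
        tn=int(np.sum(~t & ~p)),
        fn=int(np.sum(t & ~p)),
    )


def fit_fold(
    X_train: np.ndarray,
    y_train: np.ndarray,
    spec: ClassifierSpec,
    rng: np.random.Generator,
    standardize: bool = True,
    use_pca: bool = True,
    pca_variance: float = 0.95,
    smote_k: int = 5,
) -> FoldModel:
    """Standardize -> SMOTE -> PCA -> fit, using training data only."""
    if standardize:
        mean = X_train.mean(axis=0)
        std = X_train.std(axis=0)
        std[std == 0] = 1.0
    else:
        mean = np.zeros(X_train.shape[1])
        std = np.ones(X_train.shape[1])
    Z = (X_train - mean) / std
    Z_os, y_os = smote_oversample(Z, y_train, k_neighbors=smote_k, seed=rng)
    pca = None
    if use_pca:
        pca = PCA(n_components=pca_variance, svd_solver="full").fit(Z_os)
        Z_os = pca.transform(Z_os)
    clf, k = _make_classifier(spec, Z_os, y_os, rng)
    clf.fit(Z_os, y_os)
    return FoldModel(mean=mean, std=std, pca=pca, clf=clf, knn_k=k)


def run_cv(
    features: FeatureMatrix,
    spec: ClassifierSpec,
    folds: int = 10,
    seed: int = 0,
    subject_wise: bool = False,
    standardize: bool = True,
    use_pca: bool = True,
    pca_variance: float = 0.95,
    keep_models: bool = False,
) -> CVResult:
    """Stratified epoch-wise (default) or grouped subject-wise k-fold CV.

    Epoch-wise folds replicate the original protocol, in which a subject's
    epochs can appear in both training and test folds; ``subject_wise=True``
    keeps each subject's epochs in a single fold (the methodologically safer
    option).
    """
    X, y = features.X, features.labels
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("run_cv expects exactly two classes")
    if counts.min() < folds and not subject_wise:
        raise ValueError(f"need at least {folds} epochs per class")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    cv_seed = int(rng.integers(2**31))
    if subject_wise:
        splitter = StratifiedGroupKFold(n_splits=folds, shuffle=True,
                                        random_state=cv_seed)
        splits = splitter.split(X, y, groups=features.subject_ids)
    else:
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=cv_seed)
        splits = splitter.split(X, y)

    result = CVResult(counts=[], spec=spec,
                      description=f"{features.measure}:{','.join(features.band_names)}")
    for tr, te in splits:
        if np.unique(y[tr]).size < 2:
            raise ValueError("a training fold lost one of the classes")
        fold_rng = np.random.default_rng(rng.integers(2**31))
        model = fit_fold(
            X[tr], y[tr], spec, fold_rng,
            standardize=standardize, use_pca=use_pca, pca_variance=pca_variance,
        )
        pred = model.predict(X[te])
        result.counts.append(_confusion(y[te], pred, POSITIVE_CLASS))
        if keep_models:
            result.fold_models.append(model)
            result.fold_test_idx.append(te)
    return result
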