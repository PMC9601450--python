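"""Grouped permutation band importance and the band-exclusion experiment.

The importance of a frequency band is the drop in validation balanced
accuracy when all of that band's feature columns are shuffled:
``i = s - (1/K) * sum_k s~_k``, where s is the un-corrupted reference score
and s~_k the score on the k-th corrupted copy. Columns within the band are
re-permuted independently by default (the stronger corruption); a single
shared row permutation per band is available, and tiny validation sets can
be scored exhaustively over all permutations.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import (
    ClassifierSpec,
    CVResult,
    _confusion,
    compute_metrics,
    run_cv,
)
from .entropy import FeatureMatrix

__all__ = [
    "ImportanceResult",
    "grouped_permutation_importance",
    "cv_band_importance",
    "band_exclusion_experiment",
]


@dataclass
class ImportanceResult:
    """Per-band importance with the reference score and repetition scores."""

    importances: dict[str, float]
    reference_score: float
    K: int
    rep_scores: dict[str, list[float]] = field(default_factory=dict)

    def ranked(self) -> list[tuple[str, float]]:
        return sorted(self.importances.items(), key=lambda kv: -kv[1])


def _balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray, pos) -> float:
    bal = compute_metrics(_confusion(y_true, y_pred, pos))[2]
    return 0.0 if math.isnan(bal) else bal


def _score(model, X, y, pos) -> float:
    return _balanced_accuracy(y, model.predict(X), pos)


def grouped_permutation_importance(
    model,
    X_val: np.ndarray,
    y_val: np.ndarray,
    groups: np.ndarray,
    K: int = 10,
    seed: int | np.random.Generator = 0,
    mode: str = "independent",
    exhaustive: bool = False,
    positive_class: str = "PNES",
) -> ImportanceResult:
    """Band importance on one fitted model and its validation split.

    ``model`` needs only a ``predict(X)`` over the raw feature space;
    ``groups`` assigns a band name to every column. ``mode`` picks whether
    the band's columns share one row permutation ("shared") or are permuted
    independently ("independent", default). With ``exhaustive=True`` every
    permutation (or product of per-column permutations) of the validation
    rows is scored instead of K Monte-Carlo draws — only sensible for a
    handful of rows.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if mode not in ("independent", "shared"):
        raise ValueError(f"unknown permutation mode {mode!r}")
    X_val = np.asarray(X_val, dtype=float)
    y_val = np.asarray(y_val)
    groups = np.asarray(groups)
    if groups.size != X_val.shape[1]:
        raise ValueError("groups must assign a band to every column")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    s = _score(model, X_val, y_val, positive_class)
    n = len(X_val)
    band_names = list(dict.fromkeys(groups))
    importances: dict[str, float] = {}
    rep_scores: dict[str, list[float]] = {}
    for band in band_names:
        cols = np.flatnonzero(groups == band)
        if cols.size == 0:
            raise ValueError(f"band {band!r} has no feature columns")
        scores: list[float] = []
        if exhaustive:
            perms = list(itertools.permutations(range(n)))
            if mode == "shared" or cols.size == 1:
                combos = ((p,) * cols.size for p in perms)
            else:
                combos = itertools.product(perms, repeat=cols.size)
            for combo in combos:
                Xc = X_val.copy()
                for c, p in zip(cols, combo):
                    Xc[:, c] = X_val[list(p), c]
                scores.append(_score(model, Xc, y_val, positive_class))
        else:
            for _ in range(K):
                Xc = X_val.copy()
                if mode == "shared":
                    p = rng.permutation(n)
                    Xc[:, cols] = X_val[np.ix_(p, cols)]
                else:
                    for c in cols:
                        Xc[:, c] = X_val[rng.permutation(n), c]
                scores.append(_score(model, Xc, y_val, positive_class))
        importances[band] = s - float(np.mean(scores))
        rep_scores[band] = scores
    return ImportanceResult(
        importances=importances, reference_score=s, K=K, rep_scores=rep_scores
    )


def cv_band_importance(
    features: FeatureMatrix,
    cv_result: CVResult,
    K: int = 10,
    seed: int = 0,
    mode: str = "independent",
) -> dict[str, float]:
    """Eq.-style band importance averaged over the CV folds of ``cv_result``.

    ``cv_result`` must have been produced with ``keep_models=True`` so every
    fold's fitted transform chain and test indices are available.
    """
    if not cv_result.fold_models:
        raise ValueError("cv_result lacks fold models; rerun with keep_models=True")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 23]))
    totals: dict[str, list[float]] = {}
    for model, te in zip(cv_result.fold_models, cv_result.fold_test_idx):
        res = grouped_permutation_importance(
            model, features.X[te], features.labels[te], features.groups,
            K=K, seed=rng, mode=mode,
        )
        for band, imp in res.importances.items():
            totals.setdefault(band, []).append(imp)
    return {band: float(np.mean(v)) for band, v in totals.items()}


def band_exclusion_experiment(
    features: FeatureMatrix,
    spec: ClassifierSpec,
    folds: int = 10,
    K: int = 10,
    seed: int = 0,
    ecg_channel: str = "ECG",
) -> pd.DataFrame:
    """Leave-one-band-out classification plus all-bands band importance.

    For each band the remaining bands' columns (with every band's ECG column
    retained) are classified by ``run_cv``; the "none" row uses every
    column. The Band Importance column comes from the all-bands model,
    averaged over its CV folds. Returns a table with one row per excluded
    band plus "none".
    """
    bands = features.band_names
    if len(bands) < 2:
        raise ValueError("band exclusion needs at least 2 bands")

    full_cv = run_cv(features, spec, folds=folds, seed=seed, keep_models=True)
    importances = cv_band_importance(features, full_cv, K=K, seed=seed)

    rows = []
    for excluded in bands:
        keep_cols = np.array([
            g != excluded or name.endswith(f"/{ecg_channel}")
            for g, name in zip(features.groups, features.feature_names)
        ])
        sub = FeatureMatrix(
            X=features.X[:, keep_cols],
            feature_names=[n for n, k in zip(features.feature_names, keep_cols) if k],
            groups=features.groups[keep_cols],
            labels=features.labels,
            subject_ids=features.subject_ids,
            measure=features.measure,
            params=features.params,
        )
        cv = run_cv(sub, spec, folds=folds, seed=seed)
        rows.append((excluded, cv.mean_precision, cv.mean_recall,
                     cv.mean_balanced_accuracy, importances[excluded]))
    rows.append(("none", full_cv.mean_precision, full_cv.mean_recall,
                 full_cv.mean_balanced_accuracy, float("nan")))
    return pd.DataFrame(
        rows,
        columns=["band_excluded", "precision", "recall",
                 "balanced_accuracy", "band_importance"],
    )
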