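"""Bag-of-Words featurization and feature-based baseline classifiers.

BoW collapses each symbol sequence into a histogram of token counts over
the dataset vocabulary (binary BoW keeps only presence/absence).  The
representation is deliberately order-blind — permuting a sequence leaves
its feature row unchanged — which is exactly the information loss the edit
kernels are designed to avoid.  Baselines are an ℓ2-regularized logistic
regression and SVMs with the standard feature-space kernels, both evaluated
with the same LOOCV/metrics code path as the kernel models.

The vocabulary is built from the full dataset before cross-validation
(mirroring the usual tabular "one column per distinct code" setup); this is
a mild form of leakage, acceptable because the vocabulary carries no label
information beyond token identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .classification import (
    DEFAULT_C_GRID,
    ClassificationResult,
    compute_metrics,
    loocv,
)
from .errors import ParameterError
from .kernel_builder import baseline_kernel
from .sequences import LabeledDataset

logger = logging.getLogger(__name__)

DEFAULT_LR_C_GRID = (0.01, 0.1, 1.0, 10.0)


@dataclass(frozen=True)
class FeatureTable:
    """Sequences × vocabulary count (or indicator) matrix.

    Columns follow the lexicographically sorted vocabulary, so the layout
    is deterministic for a given dataset.
    """

    values: np.ndarray
    ids: tuple
    vocabulary: tuple
    kind: str = "count"  # "count" | "binary"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "ids", tuple(self.ids))
        object.__setattr__(self, "vocabulary", tuple(self.vocabulary))
        if v.shape != (len(self.ids), len(self.vocabulary)):
            raise ParameterError(
                f"feature shape {v.shape} does not match {len(self.ids)} ids x "
                f"{len(self.vocabulary)} tokens"
            )
        if np.any(v < 0):
            raise ParameterError("feature counts must be non-negative")
        if self.kind not in ("count", "binary"):
            raise ParameterError(f"kind must be 'count' or 'binary', got {self.kind!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.vocabulary))


def bag_of_words(ds: LabeledDataset, l2_scale: bool = False) -> FeatureTable:
    """Token-count histogram per sequence over the sorted dataset alphabet.

    Row sums equal sequence lengths (unless ``l2_scale`` normalizes rows to
    unit Euclidean norm, off by default).
    """
    if len(ds) == 0:
        raise ParameterError("cannot featurize an empty dataset")
    vocab = tuple(sorted(ds.alphabet))
    col = {t: j for j, t in enumerate(vocab)}
    X = np.zeros((len(ds), len(vocab)))
    for i, s in enumerate(ds):
        for tok in s.symbols:
            X[i, col[tok]] += 1.0
    if l2_scale:
        norms = np.linalg.norm(X, axis=1, keepdims=True)
        X = X / np.where(norms == 0, 1.0, norms)
    return FeatureTable(X, ds.ids, vocab, kind="count")


def binary_bow(ds: LabeledDataset) -> FeatureTable:
    """Presence/absence indicator features."""
    bow = bag_of_words(ds)
    return FeatureTable((bow.values > 0).astype(float), bow.ids, bow.vocabulary, kind="binary")


def logistic_regression_loocv(
    X: FeatureTable,
    labels,
    C_grid: Sequence[float] = DEFAULT_LR_C_GRID,
) -> ClassificationResult:
    """LOOCV of an ℓ2-regularized linear logistic regression on features.

    Regularization strength is chosen from ``C_grid`` by LOOCV F1 (ties to
    the smaller C), matching the model-selection protocol of the kernel
    path.
    """
    Xv = X.values if isinstance(X, FeatureTable) else np.asarray(X, dtype=float)
    y = np.asarray(labels, dtype=int)
    n = len(y)
    if Xv.shape[0] != n:
        raise ParameterError(f"{Xv.shape[0]} feature rows but {n} labels")
    if len(np.unique(y)) != 2:
        raise ParameterError("LOOCV needs both classes present")
    idx = np.arange(n)
    best = None
    for C in sorted(float(c) for c in C_grid):
        preds = np.empty(n, dtype=int)
        for i in range(n):
            tr = idx != i
            ytr = y[tr]
            classes = np.unique(ytr)
            if classes.size == 1:
                logger.info("LR LOOCV fold %d: single-class training set", i)
                preds[i] = int(classes[0])
                continue
            lr = LogisticRegression(C=C, solver="lbfgs", tol=1e-8, max_iter=1000)
            lr.fit(Xv[tr], ytr)
            preds[i] = int(lr.predict(Xv[i][None, :])[0])
        m = compute_metrics(preds, y)
        if best is None or m.f1 > best[1].f1:
            best = (C, m, preds)
    C, m, preds = best
    return ClassificationResult(
        metrics=m, C=C,
        kernel_provenance={"model": "logistic_regression", "features": getattr(X, "kind", "count")},
        predictions=preds,
    )


def svm_bow_loocv(
    X: FeatureTable,
    labels,
    kernel_kind: str = "linear",
    params: Optional[dict] = None,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
) -> ClassificationResult:
    """Feature-space SVM baseline: build the standard kernel, then LOOCV.

    Delegates to :func:`edkernel.kernel_builder.baseline_kernel` and the
    shared precomputed-kernel LOOCV, so baseline and edit-kernel results
    are produced by the identical evaluation code.
    """
    K = baseline_kernel(X, kernel_kind, **(params or {}))
    return loocv(K, labels, C_grid)
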