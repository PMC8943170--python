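"""Precomputed-kernel SVM training, leave-one-out evaluation and the greedy
zero-vector search.

Evaluation follows the small-cohort protocol: leave-one-out cross-validation
(every point is the test example once), confusion counts aggregated over
folds, and a small grid of regularization values C with the winner chosen by
F1 (ties resolved toward the smaller C so results are deterministic).  The
reported support-vector count comes from a final fit on all data at the
selected C.

The zero-vector search selects the origin sequence of the distance
substitution kernel.  In *in-turn* mode each dataset member is excluded and
used as the origin in turn — n candidate evaluations, each a LOOCV over the
remaining n-1 points.  In *pool* mode a held-out set of candidate sequences
is scanned while the dataset stays intact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .edit_distance import (
    DEFAULT_COSTS,
    DistanceMatrix,
    EditCostScheme,
    distances_to_reference,
    pairwise_distances,
)
from .errors import ParameterError
from .kernel_builder import KernelMatrix, apply_chain, is_psd, substitution_kernel
from .sequences import LabeledDataset, SymbolSequence

logger = logging.getLogger(__name__)

DEFAULT_C_GRID = (0.1, 1.0, 10.0, 100.0)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Metrics:
    """Confusion counts and derived rates for a binary ±1 problem.

    ``accuracy_std`` is the standard deviation (ddof=1) of the per-example
    correctness indicator — the spread statistic usually printed next to a
    cross-validated accuracy.  ``undefined_rates`` flags a 0/0 precision or
    recall, which is reported as 0.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    precision: float
    sensitivity: float
    specificity: float
    f1: float
    accuracy_std: float
    n_sv: Optional[int] = None
    undefined_rates: bool = False

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def recall(self) -> float:
        return self.sensitivity

    def with_n_sv(self, n_sv: int) -> "Metrics":
        return Metrics(
            self.tp, self.fp, self.tn, self.fn, self.accuracy, self.precision,
            self.sensitivity, self.specificity, self.f1, self.accuracy_std,
            n_sv, self.undefined_rates,
        )


def compute_metrics(predicted, true) -> Metrics:
    """Confusion counts and rates from aligned ±1 prediction/truth vectors."""
    yp = np.asarray(predicted, dtype=int)
    yt = np.asarray(true, dtype=int)
    if yp.shape != yt.shape:
        raise ParameterError(f"prediction/truth length mismatch: {yp.shape} vs {yt.shape}")
    for name, v in (("predicted", yp), ("true", yt)):
        if not np.all(np.isin(v, (1, -1))):
            bad = sorted(set(v.tolist()) - {1, -1})
            raise ParameterError(f"{name} labels must be +1/-1; found {bad}")
    tp = int(np.sum((yp == 1) & (yt == 1)))
    fp = int(np.sum((yp == 1) & (yt == -1)))
    tn = int(np.sum((yp == -1) & (yt == -1)))
    fn = int(np.sum((yp == -1) & (yt == 1)))
    n = len(yt)
    correct = (yp == yt).astype(float)
    accuracy = float(correct.mean())
    acc_std = float(correct.std(ddof=1)) if n > 1 else 0.0

    undefined = False
    if tp + fp > 0:
        precision = tp / (tp + fp)
    else:
        precision, undefined = 0.0, True
    if tp + fn > 0:
        sensitivity = tp / (tp + fn)
    else:
        sensitivity, undefined = 0.0, True
    specificity = tn / (tn + fp) if tn + fp > 0 else 0.0
    f1 = (2 * precision * sensitivity / (precision + sensitivity)
          if precision + sensitivity > 0 else 0.0)
    if undefined:
        logger.info("compute_metrics: 0/0 precision or recall reported as 0")
    return Metrics(tp, fp, tn, fn, accuracy, precision, sensitivity, specificity,
                   f1, acc_std, undefined_rates=undefined)


@dataclass(frozen=True)
class ClassificationResult:
    """Outcome of one LOOCV evaluation of one kernel."""

    metrics: Metrics
    C: float
    kernel_provenance: dict = field(default_factory=dict)
    zero_vector_id: Optional[str] = None
    predictions: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.C <= 0:
            raise ParameterError(f"C must be positive, got {self.C}")


# ---------------------------------------------------------------------------
# SVM on a precomputed kernel
# ---------------------------------------------------------------------------

@dataclass
class SVMModel:
    """Thin wrapper around a fitted precomputed-kernel SVC.

    ``dual_coef`` is the full-length signed coefficient vector a_i = α_i y_i
    (zero off-support); a test point's decision value needs only its kernel
    row against the training ids.
    """

    dual_coef: np.ndarray
    intercept: float
    support: np.ndarray
    n_sv: int
    _svc: SVC

    def decision_function(self, k_rows: np.ndarray) -> np.ndarray:
        k_rows = np.atleast_2d(np.asarray(k_rows, dtype=float))
        return k_rows @ self.dual_coef + self.intercept

    def predict(self, k_rows: np.ndarray) -> np.ndarray:
        d = self.decision_function(k_rows)
        return np.where(d >= 0, 1, -1)


def _kernel_values(K) -> np.ndarray:
    return K.values if isinstance(K, KernelMatrix) else np.asarray(K, dtype=float)


def train_svm(K, labels, C: float = 1.0) -> SVMModel:
    """Fit a soft-margin SVM on a precomputed (possibly indefinite) kernel."""
    Kv = _kernel_values(K)
    y = np.asarray(labels, dtype=int)
    if C <= 0:
        raise ParameterError(f"C must be positive, got {C}")
    if not np.all(np.isfinite(Kv)):
        raise ParameterError("kernel contains non-finite entries")
    if Kv.shape != (len(y), len(y)):
        raise ParameterError(f"kernel shape {Kv.shape} does not match {len(y)} labels")
    if len(np.unique(y)) != 2:
        raise ParameterError("training labels must contain both classes")
    svc = SVC(C=C, kernel="precomputed")
    svc.fit(Kv, y)
    a = np.zeros(len(y))
    a[svc.support_] = svc.dual_coef_[0]
    # sklearn orders classes ascending (-1, +1); dual_coef is for the
    # positive class already, intercept likewise
    return SVMModel(
        dual_coef=a,
        intercept=float(svc.intercept_[0]),
        support=svc.support_.copy(),
        n_sv=int(svc.support_.size),
        _svc=svc,
    )


def svm_dual_objective(Kv: np.ndarray, y: np.ndarray, C: float):
    """Solve the SVM dual and return (objective value, signed dual vector).

    The objective is Σα − ½ aᵀKa with a = α∘y, the quantity multiple-kernel
    learning minimizes over kernel weights.
    """
    model = train_svm(Kv, y, C)
    a = model.dual_coef
    J = float(np.sum(np.abs(a)) - 0.5 * a @ Kv @ a)
    return J, a


# ---------------------------------------------------------------------------
# LOOCV
# ---------------------------------------------------------------------------

def _loocv_predictions(Kv: np.ndarray, y: np.ndarray, C: float) -> np.ndarray:
    n = len(y)
    preds = np.empty(n, dtype=int)
    idx = np.arange(n)
    for i in range(n):
        tr = idx != i
        ytr = y[tr]
        classes = np.unique(ytr)
        if classes.size == 1:
            logger.info("LOOCV fold %d: single-class training set, predicting %d", i, classes[0])
            preds[i] = int(classes[0])
            continue
        model = train_svm(Kv[np.ix_(tr, tr)], ytr, C)
        preds[i] = int(model.predict(Kv[i, tr])[0])
    return preds


def loocv(K, labels, C_grid: Sequence[float] = DEFAULT_C_GRID) -> ClassificationResult:
    """Leave-one-out evaluation over a C grid; best C selected by F1.

    Ties go to the smaller C.  The returned metrics carry the
    support-vector count of a final all-data fit at the selected C.
    """
    Kv = _kernel_values(K)
    y = np.asarray(labels, dtype=int)
    n = len(y)
    if n < 3:
        raise ParameterError("LOOCV needs at least 3 examples")
    if len(np.unique(y)) != 2:
        raise ParameterError("LOOCV needs both classes present")
    if not C_grid:
        raise ParameterError("C grid must be non-empty")
    report = is_psd(KernelMatrix(0.5 * (Kv + Kv.T), tuple(str(i) for i in range(n))))
    if not report.is_psd:
        logger.info("loocv: indefinite kernel passed to the solver as-is (min eig %.3g)",
                    report.min_eigenvalue)

    best = None
    for C in sorted(float(c) for c in C_grid):
        preds = _loocv_predictions(Kv, y, C)
        m = compute_metrics(preds, y)
        assert m.n == n
        if best is None or m.f1 > best[1].f1:
            best = (C, m, preds)
    C, m, preds = best
    final = train_svm(Kv, y, C)
    prov = K.provenance if isinstance(K, KernelMatrix) else {}
    return ClassificationResult(
        metrics=m.with_n_sv(final.n_sv),
        C=C,
        kernel_provenance=dict(prov),
        zero_vector_id=prov.get("zero_vector_id") if prov else None,
        predictions=preds,
    )


# ---------------------------------------------------------------------------
# greedy zero-vector search
# ---------------------------------------------------------------------------

def _result_row(res: ClassificationResult) -> dict:
    m = res.metrics
    return {
        "x0": res.zero_vector_id,
        "f1": m.f1,
        "accuracy_pct": 100.0 * m.accuracy,
        "accuracy_std_pct": 100.0 * m.accuracy_std,
        "sensitivity": m.sensitivity,
        "specificity": m.specificity,
        "n_sv": m.n_sv,
        "C": res.C,
    }


def greedy_zero_vector_search(
    ds: LabeledDataset,
    variant: str = "k_ed1",
    costs: EditCostScheme = DEFAULT_COSTS,
    post_chain: Sequence[str] = ("clip", "normalize"),
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    x0_pool: Optional[Sequence[SymbolSequence]] = None,
):
    """Scan zero-vector candidates; return (best result, per-candidate table).

    Without a pool, every dataset member is excluded and used as the origin
    in turn (n evaluations over n-1 points each).  With a pool, the dataset
    stays intact and the candidates come from the pool, whose ids must be
    disjoint from the dataset's.  The best candidate maximizes LOOCV F1;
    ties go to the earlier candidate.
    """
    y_all = ds.labels()
    D_full = pairwise_distances(ds, variant, costs)
    rows, results = [], []

    if x0_pool is not None:
        pool = list(x0_pool)
        if not pool:
            raise ParameterError("x0 pool must be non-empty")
        overlap = {s.id for s in pool} & set(ds.ids)
        if overlap:
            raise ParameterError(f"x0 pool overlaps dataset ids: {sorted(overlap)}")
        for cand in pool:
            d0 = distances_to_reference(ds, cand, variant, costs)
            K = apply_chain(substitution_kernel(D_full, d0, cand.id), post_chain)
            results.append(loocv(K, y_all, C_grid))
    else:
        if len(ds) < 4:
            raise ParameterError("in-turn search needs at least 4 sequences")
        idx = np.arange(len(ds))
        for i, cand in enumerate(ds):
            keep = idx != i
            Dsub = DistanceMatrix(
                D_full.values[np.ix_(keep, keep)],
                tuple(np.asarray(ds.ids, dtype=object)[keep]),
                variant,
                costs,
            )
            K = apply_chain(substitution_kernel(Dsub, D_full.values[keep, i], cand.id), post_chain)
            results.append(loocv(K, y_all[keep], C_grid))

    best = None
    for res in results:
        rows.append(_result_row(res))
        if best is None or res.metrics.f1 > best.metrics.f1:
            best = res
    return best, pd.DataFrame(rows)
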