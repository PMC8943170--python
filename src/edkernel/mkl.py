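"""Multiple kernel learning by reduced-gradient descent on the simplex.

Learns a convex combination K(w) = Σ_m w_m K_m of precomputed kernels
jointly with an SVM, in the SimpleMKL spirit: alternate between solving the
SVM dual on the current combination and taking a reduced-gradient step in
the kernel weights, constrained to the probability simplex.  The objective

    J(w) = max_α  Σα − ½ aᵀ K(w) a,   a = α∘y,  0 ≤ α ≤ C,  Σ α y = 0

is convex in w with gradient ∂J/∂w_m = −½ aᵀ K_m a at the dual optimizer,
so a monotone line search along a feasible descent direction converges to
the global optimum.  The ℓ1 (simplex) constraint induces sparse weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .classification import (
    DEFAULT_C_GRID,
    ClassificationResult,
    loocv,
    svm_dual_objective,
)
from .errors import ParameterError
from .kernel_builder import KernelMatrix, is_psd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MKLStop:
    """Stopping rule for the weight optimization."""

    max_iter: int = 200
    duality_gap_tol: float = 1e-2
    weight_tol: float = 1e-4


@dataclass(frozen=True)
class MKLResult:
    weights: np.ndarray
    combined: KernelMatrix
    result: ClassificationResult
    objective_trace: tuple
    iterations: int
    converged: bool


def _check_aligned(kernels: Sequence[KernelMatrix]) -> tuple:
    if not kernels:
        raise ParameterError("need at least one kernel")
    ids = kernels[0].ids
    for K in kernels[1:]:
        if K.ids != ids:
            raise ParameterError("kernels must share identical ids and ordering")
    return ids


def combine_kernels(kernels: Sequence[KernelMatrix], weights) -> KernelMatrix:
    """Element-wise convex (or conic) combination of aligned kernels."""
    ids = _check_aligned(kernels)
    w = np.asarray(weights, dtype=float)
    if w.shape != (len(kernels),):
        raise ParameterError(f"{len(kernels)} kernels but weight shape {w.shape}")
    if np.any(w < 0):
        raise ParameterError("kernel weights must be non-negative")
    V = np.zeros_like(kernels[0].values)
    for wm, K in zip(w, kernels):
        V += wm * K.values
    prov = {
        "mkl_weights": [float(x) for x in w],
        "components": [dict(K.provenance) for K in kernels],
        "postprocessing": ["raw"],
    }
    return KernelMatrix(V, ids, prov)


def _descent_direction(w: np.ndarray, grad: np.ndarray) -> np.ndarray:
    """SimpleMKL reduced gradient direction on the simplex.

    The component with the largest weight anchors the equality constraint;
    zero-weight components with a positive reduced gradient are frozen so
    the direction stays feasible.
    """
    mu = int(np.argmax(w))
    red = grad - grad[mu]
    D = np.where((w > 1e-12) | (red < 0), -red, 0.0)
    D[mu] = 0.0
    D[mu] = -D.sum()
    return D


def learn_weights(
    kernels: Sequence[KernelMatrix],
    labels,
    C: float = 1.0,
    stop: MKLStop = MKLStop(),
    eval_C_grid: Optional[Sequence[float]] = None,
) -> MKLResult:
    """Optimize simplex weights over component kernels, then LOOCV the result.

    Indefinite components are accepted with a warning (the combination's
    objective is then no longer guaranteed convex; spectrally correct
    first for the guaranteed path).  Weights below 1e-8 are zeroed and the
    simplex renormalized.  ``eval_C_grid`` controls the final LOOCV of the
    combined kernel and defaults to the single value ``C`` used during
    weight learning.
    """
    ids = _check_aligned(kernels)
    y = np.asarray(labels, dtype=int)
    if len(y) != len(ids):
        raise ParameterError(f"{len(ids)} kernel rows but {len(y)} labels")
    M = len(kernels)
    Ks = [K.values for K in kernels]
    for m, K in enumerate(kernels):
        rep = is_psd(K)
        if not rep.is_psd:
            logger.warning("MKL component %d is indefinite (min eig %.3g)", m, rep.min_eigenvalue)

    def objective(w):
        Kc = sum(wm * Km for wm, Km in zip(w, Ks))
        return svm_dual_objective(Kc, y, C)

    if M == 1:
        w = np.array([1.0])
        J, _ = objective(w)
        trace, iters, converged = (J,), 0, True
    else:
        w = np.full(M, 1.0 / M)
        J, a = objective(w)
        trace = [J]
        converged = False
        iters = 0
        for iters in range(1, stop.max_iter + 1):
            grad = np.array([-0.5 * a @ Km @ a for Km in Ks])
            # relative duality gap: distance between the current combination's
            # quadratic term and the best single-kernel quadratic term
            quad = np.array([0.5 * a @ Km @ a for Km in Ks])
            gap = float(quad.max() - quad @ w)
            if abs(J) > 0 and gap / abs(J) < stop.duality_gap_tol and iters > 1:
                converged = True
                break
            D = _descent_direction(w, grad)
            if np.max(np.abs(D)) < 1e-12:
                converged = True
                break
            neg = D < 0
            gamma_max = float(np.min(w[neg] / -D[neg])) if np.any(neg) else 0.0
            if gamma_max <= 0:
                converged = True
                break
            res = minimize_scalar(
                lambda g: objective(w + g * D)[0],
                bounds=(0.0, gamma_max),
                method="bounded",
                options={"xatol": max(gamma_max * 1e-3, 1e-12), "maxiter": 30},
            )
            gamma, J_new = float(res.x), float(res.fun)
            if J_new > J - 1e-12:  # no descent available along this direction
                converged = True
                break
            w_new = np.clip(w + gamma * D, 0.0, None)
            w_new /= w_new.sum()
            delta = float(np.max(np.abs(w_new - w)))
            w = w_new
            J, a = objective(w)  # refresh dual vector at the accepted point
            trace.append(J)
            if delta < stop.weight_tol:
                converged = True
                break
        if not converged:
            logger.warning("MKL did not converge within %d iterations", stop.max_iter)
        # sparsify and renormalize
        w = np.where(w < 1e-8, 0.0, w)
        w /= w.sum()
        trace = tuple(trace)

    combined = combine_kernels(kernels, w)
    grid = tuple(eval_C_grid) if eval_C_grid is not None else (C,)
    result = loocv(combined, y, grid)
    return MKLResult(
        weights=w,
        combined=combined,
        result=result,
        objective_trace=tuple(trace),
        iterations=iters,
        converged=converged,
    )


def strict_loocv(
    kernels: Sequence[KernelMatrix],
    labels,
    C: float = 1.0,
    stop: MKLStop = MKLStop(),
) -> ClassificationResult:
    """LOOCV that re-learns the MKL weights inside every fold.

    The unbiased but n-times-costlier alternative to the default protocol
    (weights learned once on all data, combined kernel then LOOCV'd).
    Each fold learns weights on the n-1 training points, combines the
    training submatrices, and predicts the held-out point from its
    weighted kernel row.
    """
    from .classification import compute_metrics, train_svm

    ids = _check_aligned(kernels)
    y = np.asarray(labels, dtype=int)
    n = len(y)
    if n < 3:
        raise ParameterError("LOOCV needs at least 3 examples")
    Ks = [K.values for K in kernels]
    idx = np.arange(n)
    preds = np.empty(n, dtype=int)
    for i in range(n):
        tr = idx != i
        ytr = y[tr]
        if np.unique(ytr).size == 1:
            preds[i] = int(ytr[0])
            continue
        sub = [KernelMatrix(Km[np.ix_(tr, tr)],
                            tuple(np.asarray(ids, dtype=object)[tr])) for Km in Ks]
        fold = learn_weights(sub, ytr, C, stop=stop)
        model = train_svm(fold.combined, ytr, C)
        row = sum(wm * Km[i, tr] for wm, Km in zip(fold.weights, Ks))
        preds[i] = int(model.predict(row)[0])
    m = compute_metrics(preds, y)
    full = learn_weights(kernels, y, C, stop=stop)
    final = train_svm(full.combined, y, C)
    return ClassificationResult(
        metrics=m.with_n_sv(final.n_sv), C=C,
        kernel_provenance={"mkl": "strict", "components": [dict(K.provenance) for K in kernels]},
        predictions=preds,
    )


def mkl_experiment(
    kernels: Sequence[KernelMatrix],
    labels,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    top_k: Optional[int] = None,
    stop: MKLStop = MKLStop(),
):
    """Single-kernel LOOCV of every component, optional top-k selection,
    then MKL on the selected family.

    Returns ``(MKLResult, table)`` where the table holds one row per
    component kernel (its own LOOCV metrics and learned weight) plus a
    final row for the combination.  The MKL run uses the C value that
    maximizes the combined kernel's LOOCV F1 over ``C_grid`` (ties to the
    smaller C).
    """
    y = np.asarray(labels, dtype=int)
    singles = [loocv(K, y, C_grid) for K in kernels]
    order = sorted(range(len(kernels)), key=lambda i: (-singles[i].metrics.f1, i))
    chosen = order[: top_k] if top_k is not None else list(range(len(kernels)))
    chosen = sorted(chosen)
    family = [kernels[i] for i in chosen]

    best_mkl = None
    for C in sorted(float(c) for c in C_grid):
        cand = learn_weights(family, y, C, stop=stop, eval_C_grid=C_grid)
        if best_mkl is None or cand.result.metrics.f1 > best_mkl.result.metrics.f1:
            best_mkl = cand

    weight_of = {i: w for i, w in zip(chosen, best_mkl.weights)}
    rows = []
    for i, (K, res) in enumerate(zip(kernels, singles)):
        m = res.metrics
        rows.append({
            "kernel": K.provenance.get("distance_variant", K.provenance.get("baseline", f"K{i}")),
            "role": "single",
            "selected": i in chosen,
            "weight": weight_of.get(i, 0.0),
            "f1": m.f1, "accuracy_pct": 100 * m.accuracy,
            "sensitivity": m.sensitivity, "specificity": m.specificity,
            "n_sv": m.n_sv, "C": res.C,
        })
    m = best_mkl.result.metrics
    rows.append({
        "kernel": f"MKL({len(family)})", "role": "mkl", "selected": True, "weight": 1.0,
        "f1": m.f1, "accuracy_pct": 100 * m.accuracy,
        "sensitivity": m.sensitivity, "specificity": m.specificity,
        "n_sv": m.n_sv, "C": best_mkl.result.C,
    })
    return best_mkl, pd.DataFrame(rows)
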