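"""Distance-substitution kernels and kernel post-processing.

The central construction replaces the squared norms of the translated
dot-product (polarization) identity

    <x_i - x_0, x_j - x_0> = 1/2 (||x_i - x_0||^2 + ||x_0 - x_j||^2
                                  - ||x_i - x_j||^2)

with an edit distance, relative to a designated origin sequence x0 (the
"zero vector"):

    K(i, j) = 1/2 ( d(i, x0) + d(x0, j) - d(i, j) ).

The resulting Gram matrix is symmetric but in general indefinite, because
the edit distance is not isometrically embeddable in an L2 space.  Spectral
modification repairs indefiniteness by eigendecomposing the matrix and
transforming the spectrum (clip / shift / flip / square) before
reconstruction.  Cosine normalization and (double) centering are the other
two post-processing steps; any subset may be chained in any order, and the
chain is recorded in the kernel's provenance.

Baseline kernels on numeric feature vectors (linear, polynomial, RBF,
exponential RBF, Laplace) are also built here so that feature-based and
sequence-based classifiers share one kernel container.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .edit_distance import (
    DEFAULT_COSTS,
    DistanceMatrix,
    EditCostScheme,
    distances_to_reference,
    pairwise_distances,
)
from .errors import ParameterError
from .sequences import LabeledDataset, SymbolSequence

logger = logging.getLogger(__name__)

SPECTRAL_MODES = ("clip", "shift", "flip", "square")
BASELINE_KINDS = ("linear", "poly", "rbf", "exp_rbf", "laplace")

#: steps accepted in a post-processing chain
CHAIN_STEPS = ("raw", "normalize", "center") + SPECTRAL_MODES

SYMMETRY_TOL = 1e-10


@dataclass(frozen=True)
class PSDReport:
    """Outcome of an eigenvalue check on a symmetric kernel matrix."""

    is_psd: bool
    min_eigenvalue: float
    #: fraction of total absolute eigenvalue mass carried by negative
    #: eigenvalues — 0 for a PSD matrix
    negative_mass_fraction: float
    tol: float


@dataclass(frozen=True)
class KernelMatrix:
    """Symmetric similarity matrix with provenance.

    ``provenance`` records how the kernel was built: the distance variant
    and zero-vector id for substitution kernels (or the baseline kind and
    parameters for feature kernels) plus the ordered post-processing chain.
    """

    values: np.ndarray
    ids: tuple
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "ids", tuple(self.ids))
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ParameterError(f"kernel matrix must be square, got shape {v.shape}")
        if v.shape[0] != len(self.ids):
            raise ParameterError("kernel matrix shape does not match id count")
        if not np.all(np.isfinite(v)):
            raise ParameterError("kernel matrix contains non-finite entries")
        if np.max(np.abs(v - v.T), initial=0.0) > 1e-8:
            raise ParameterError("kernel matrix is not symmetric")
        prov = dict(self.provenance)
        prov.setdefault("postprocessing", [])
        object.__setattr__(self, "provenance", prov)

    @property
    def n(self) -> int:
        return len(self.ids)

    def _derived(self, values: np.ndarray, step: str) -> "KernelMatrix":
        prov = dict(self.provenance)
        prov["postprocessing"] = list(prov.get("postprocessing", [])) + [step]
        return KernelMatrix(values, self.ids, prov)


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def substitution_kernel(
    D: DistanceMatrix, d_to_x0: np.ndarray, x0_id: str, *, x0_in_pool: bool = False
) -> KernelMatrix:
    """Distance-substitution kernel relative to the origin sequence ``x0``.

    ``K(i, j) = 1/2 (d(i, x0) + d(x0, j) - d(i, j))``; consequently
    ``K(i, i) = d(i, x0)``.

    ``x0`` must not be a member of ``D`` (the greedy search excludes the
    candidate from the dataset) unless ``x0_in_pool`` explicitly flags it.
    """
    d0 = np.asarray(d_to_x0, dtype=float)
    if d0.shape != (D.n,):
        raise ParameterError(
            f"d_to_x0 has shape {d0.shape}, expected ({D.n},) to match the distance matrix"
        )
    if x0_id in D.ids and not x0_in_pool:
        raise ParameterError(
            f"zero vector {x0_id!r} is a member of the distance matrix; "
            "drop it first or pass x0_in_pool=True"
        )
    K = 0.5 * (d0[:, None] + d0[None, :] - D.values)
    return KernelMatrix(
        K,
        D.ids,
        {"distance_variant": D.variant, "zero_vector_id": x0_id, "postprocessing": ["raw"]},
    )


def edit_substitution_kernel(
    ds: LabeledDataset,
    x0: SymbolSequence,
    variant: str = "k_ed1",
    costs: EditCostScheme = DEFAULT_COSTS,
    post: Sequence[str] = (),
) -> KernelMatrix:
    """Convenience pipeline: pairwise distances -> substitution kernel -> chain."""
    D = pairwise_distances(ds, variant, costs)
    d0 = distances_to_reference(ds, x0, variant, costs)
    K = substitution_kernel(D, d0, x0.id, x0_in_pool=x0.id in D.ids)
    return apply_chain(K, post)


# ---------------------------------------------------------------------------
# post-processing
# ---------------------------------------------------------------------------

def cosine_normalize(K: KernelMatrix, eps: float = 1e-12) -> KernelMatrix:
    """Normalize to unit self-similarity: K'(i,j) = K(i,j)/sqrt(K(i,i)K(j,j)).

    Rows whose diagonal entry is <= ``eps`` cannot be normalized; they are
    zeroed and the event logged (this can only happen for a degenerate
    origin choice, e.g. x0 identical to a dataset member).
    """
    d = np.diag(K.values).copy()
    bad = d <= eps
    if np.any(bad):
        logger.warning(
            "cosine_normalize: %d diagonal entries <= %g zeroed (ids %s)",
            int(bad.sum()), eps, [K.ids[i] for i in np.flatnonzero(bad)],
        )
    scale = np.where(bad, 0.0, 1.0 / np.sqrt(np.where(bad, 1.0, d)))
    V = K.values * scale[:, None] * scale[None, :]
    V[bad, :] = 0.0
    V[:, bad] = 0.0
    good = np.flatnonzero(~bad)
    V[good, good] = 1.0  # exact unit self-similarity for valid rows
    return K._derived(V, "normalize")


def center(K: KernelMatrix) -> KernelMatrix:
    """Double-center in feature space: K_c = H K H with H = I - 11ᵀ/n."""
    V = K.values
    row = V.mean(axis=0, keepdims=True)
    col = V.mean(axis=1, keepdims=True)
    Vc = V - row - col + V.mean()
    Vc = 0.5 * (Vc + Vc.T)
    return K._derived(Vc, "center")


def spectral_modify(K: KernelMatrix, mode: str, tol: float = 1e-8) -> KernelMatrix:
    """Repair an indefinite kernel by transforming its eigenvalue spectrum.

    ``clip``   zeroes negative eigenvalues;
    ``shift``  raises the whole spectrum so the least eigenvalue becomes 0;
    ``flip``   takes absolute values;
    ``square`` squares the spectrum (equivalently K @ K for symmetric K).

    All four produce a PSD matrix by construction.  The input must be
    symmetric to within ``SYMMETRY_TOL`` scale; the output is re-symmetrized
    against round-off.
    """
    if mode not in SPECTRAL_MODES:
        raise ParameterError(f"unknown spectral mode {mode!r}; expected one of {SPECTRAL_MODES}")
    V = K.values
    scale = max(1.0, float(np.max(np.abs(V))))
    if np.max(np.abs(V - V.T), initial=0.0) > 1e-8 * scale:
        raise ParameterError("spectral modification requires a symmetric matrix")
    S = 0.5 * (V + V.T)
    w, U = np.linalg.eigh(S)
    if mode == "clip":
        w = np.maximum(w, 0.0)
    elif mode == "shift":
        w = w - min(w.min(), 0.0)
    elif mode == "flip":
        w = np.abs(w)
    elif mode == "square":
        w = w ** 2
    R = (U * w) @ U.T
    R = 0.5 * (R + R.T)
    return K._derived(R, mode)


def apply_chain(K: KernelMatrix, chain: Sequence[str]) -> KernelMatrix:
    """Apply an ordered post-processing chain; ``raw`` is a no-op marker."""
    for step in chain:
        if step == "raw":
            continue
        elif step == "normalize":
            K = cosine_normalize(K)
        elif step == "center":
            K = center(K)
        elif step in SPECTRAL_MODES:
            K = spectral_modify(K, step)
        else:
            raise ParameterError(f"unknown post-processing step {step!r}; expected one of {CHAIN_STEPS}")
    return K


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def is_psd(K: KernelMatrix, tol: float = 1e-8) -> PSDReport:
    """Eigenvalue check: PSD iff the least eigenvalue >= -tol.

    Also reports the fraction of absolute eigenvalue mass that is negative,
    a scale-free measure of "how indefinite" the kernel is.
    """
    w = np.linalg.eigvalsh(0.5 * (K.values + K.values.T))
    total = float(np.sum(np.abs(w)))
    neg = float(np.sum(np.abs(w[w < 0]))) if total > 0 else 0.0
    return PSDReport(
        is_psd=bool(w.min() >= -tol),
        min_eigenvalue=float(w.min()),
        negative_mass_fraction=neg / total if total > 0 else 0.0,
        tol=tol,
    )


def kernel_alignment(K: KernelMatrix, labels: np.ndarray) -> float:
    """Uncentered kernel-target alignment <K, yyᵀ>_F / (||K||_F ||yyᵀ||_F).

    A training-free score in [-1, 1] of how well the kernel's similarity
    structure matches the label outer product.
    """
    y = np.asarray(labels, dtype=float)
    if y.shape != (K.n,):
        raise ParameterError(f"labels have shape {y.shape}, expected ({K.n},)")
    if not (np.any(y > 0) and np.any(y < 0)):
        raise ParameterError("kernel alignment needs both classes present")
    fro = float(np.linalg.norm(K.values))
    if fro <= 0:
        raise ParameterError("kernel alignment undefined for a zero matrix")
    num = float(y @ K.values @ y)
    return num / (fro * float(y @ y))  # ||yyᵀ||_F = yᵀy for a ±1 vector


# ---------------------------------------------------------------------------
# baseline kernels on feature vectors
# ---------------------------------------------------------------------------

def median_heuristic_sigma(X: np.ndarray) -> float:
    """Median of the positive pairwise Euclidean distances (fallback 1.0)."""
    d = pdist(np.asarray(X, dtype=float))
    pos = d[d > 0]
    return float(np.median(pos)) if pos.size else 1.0


def baseline_kernel(
    X,
    kind: str,
    *,
    c: float = 1.0,
    degree: int = 3,
    sigma: Optional[float] = None,
    ids: Optional[Sequence[str]] = None,
) -> KernelMatrix:
    """Standard kernels on numeric feature rows.

    linear    xᵀy
    poly      (xᵀy + c)^degree
    rbf       exp(-||x-y||² / (2σ))
    exp_rbf   exp(-||x-y|| / (2σ))
    laplace   exp(-||x-y|| / σ)

    ``X`` may be a 2-D array or anything exposing ``.values``/``.ids`` (a
    :class:`~edkernel.bow_baselines.FeatureTable`).  ``sigma`` defaults to
    the median heuristic.  Note the exponential-RBF and Laplace kernels
    differ only by the factor of 2 in the denominator, so one is the other
    at a reparameterized sigma.
    """
    if ids is None and hasattr(X, "ids"):
        ids = X.ids
    if hasattr(X, "values") and not isinstance(X, np.ndarray):
        X = X.values
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ParameterError(f"feature matrix must be 2-D, got shape {X.shape}")
    n = X.shape[0]
    if ids is None:
        ids = tuple(str(i) for i in range(n))
    if kind not in BASELINE_KINDS:
        raise ParameterError(f"unknown baseline kernel {kind!r}; expected one of {BASELINE_KINDS}")

    prov = {"baseline": kind, "postprocessing": ["raw"]}
    if kind == "linear":
        V = X @ X.T
    elif kind == "poly":
        if c < 0:
            raise ParameterError(f"poly offset c must be >= 0, got {c}")
        V = (X @ X.T + c) ** degree
        prov.update(c=c, degree=degree)
    else:
        if sigma is None:
            sigma = median_heuristic_sigma(X)
        if sigma <= 0:
            raise ParameterError(f"sigma must be positive, got {sigma}")
        dist = squareform(pdist(X))
        if kind == "rbf":
            V = np.exp(-(dist ** 2) / (2.0 * sigma))
        elif kind == "exp_rbf":
            V = np.exp(-dist / (2.0 * sigma))
        else:  # laplace
            V = np.exp(-dist / sigma)
        prov.update(sigma=float(sigma))
    V = 0.5 * (V + V.T)
    return KernelMatrix(V, tuple(ids), prov)
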