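"""Cumulative-weighted iterative NCA (CWINCA) feature selection.

Neighborhood component analysis (NCA) with one non-negative weight per
feature scores feature relevance by gradient ascent on the expected
leave-one-out accuracy of a soft (stochastic) nearest-neighbour classifier.
CWINCA then turns the weight profile into a self-organised search range:
after normalising the sorted weights to sum 1, the smallest k whose
cumulative weight reaches ``t_low`` (default 0.5) starts the iteration and
the smallest k reaching ``t_high`` (default 0.99) stops it.  Every top-k
candidate set in that range is scored with the downstream classifier and
the most accurate candidate is kept (ties broken toward fewer features).

The diagonal NCA here uses a weighted city-block distance
``d_w(i, j) = sum_r w_r^2 |x_ir - x_jr|`` on z-scored features, a softmax
neighbour kernel ``exp(-d/sigma)`` with ``sigma`` set to the mean pairwise
distance at initialisation, ridge regularisation ``lambda = 1/n`` and
full-batch gradient ascent with step halving.  It is deterministic: the
weights start at 1 and no sampling is involved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np

from .evaluation import cv_accuracy

__all__ = ["NcaWeights", "SelectionResult", "nca_weights", "threshold_range", "select"]

# Largest |x_i - x_j| tensor held in memory at once, in float32 entries.
_MAX_TENSOR_ENTRIES = 200_000_000


@dataclass(frozen=True)
class NcaWeights:
    """Per-feature relevance weights and their descending order."""

    weights: np.ndarray  # non-negative, one per feature
    order: np.ndarray  # 0-based feature indices by descending weight
    n_iterations: int = 0
    objective: float = float("nan")

    def __post_init__(self) -> None:
        w = np.asarray(self.weights)
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        if sorted(self.order) != list(range(w.size)):
            raise ValueError("order must be a permutation of all feature indices")


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of the iterative selection.

    ``ind`` holds the selected feature indices, 1-based and ordered by
    descending NCA weight (1-based so that the index arithmetic used by the
    symbolic-interpretation stage applies directly).  ``SX`` is the selected
    column sub-matrix, ``per_k_accuracy`` maps each evaluated candidate size
    to its accuracy in percent.
    """

    ind: np.ndarray
    SX: np.ndarray
    per_k_accuracy: dict[int, float]
    start_k: int
    stop_k: int
    weights: NcaWeights | None = None

    @property
    def nsf(self) -> int:
        return int(self.ind.size)

    def to_json_dict(self) -> dict:
        return {
            "ind": [int(i) for i in self.ind],
            "nsf": self.nsf,
            "start_k": self.start_k,
            "stop_k": self.stop_k,
            "per_k_accuracy": {str(k): v for k, v in self.per_k_accuracy.items()},
        }


def _pairwise_absdiff(Z: np.ndarray) -> np.ndarray:
    """|z_i - z_j| flattened to (n*n, d) float32."""
    n, d = Z.shape
    A = np.abs(Z[:, None, :] - Z[None, :, :]).astype(np.float32)
    return A.reshape(n * n, d)


def nca_weights(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-6,
    reg: float | None = None,
    seed: int = 0,
) -> NcaWeights:
    """Learn non-negative per-feature NCA relevance weights.

    Features are z-scored internally; constant features get weight that
    decays to ~0 under the ridge term.  ``reg`` defaults to ``1/n``.  The
    optimisation is deterministic; ``seed`` is accepted for interface
    uniformity only.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, d = X.shape
    if np.unique(y).size < 2:
        raise ValueError("need at least 2 classes")
    counts = [np.sum(y == c) for c in np.unique(y)]
    if min(counts) < 2:
        raise ValueError("need at least 2 samples per class")
    lam = (1.0 / n) if reg is None else reg

    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd

    if n * n * d > _MAX_TENSOR_ENTRIES:
        raise MemoryError(
            "pairwise tensor too large; reduce samples or features before NCA"
        )
    A = _pairwise_absdiff(Z)  # (n*n, d)
    same = (y[:, None] == y[None, :]).astype(float)
    np.fill_diagonal(same, 0.0)
    off_diag = ~np.eye(n, dtype=bool)

    def distances(w2: np.ndarray) -> np.ndarray:
        return (A @ w2.astype(np.float32)).astype(float).reshape(n, n)

    w = np.ones(d)
    sigma = float(distances(w**2)[off_diag].mean())
    if sigma <= 0:
        sigma = 1.0  # all samples identical

    def soft_neighbours(w: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
        D = distances(w**2) / sigma
        np.fill_diagonal(D, np.inf)
        D -= D.min(axis=1, keepdims=True)  # stabilise the softmax
        K = np.exp(-D)
        P = K / K.sum(axis=1, keepdims=True)
        p_i = (P * same).sum(axis=1)
        obj = p_i.mean() - lam * float(w @ w)
        return P, p_i, obj

    def gradient(w: np.ndarray, P: np.ndarray, p_i: np.ndarray) -> np.ndarray:
        C = (p_i[:, None] * P - P * same) / (sigma * n)
        main = (C.ravel().astype(np.float32) @ A).astype(float)
        return 2.0 * w * main - 2.0 * lam * w

    P, p_i, obj = soft_neighbours(w)
    step = 1.0
    iters = 0
    for iters in range(1, max_iter + 1):
        g = gradient(w, P, p_i)
        improved = False
        for _ in range(20):
            w_new = w + step * g
            P_new, p_new, obj_new = soft_neighbours(w_new)
            if obj_new > obj:
                improved = True
                break
            step *= 0.5
        if not improved:
            break
        w, P, p_i = w_new, P_new, p_new
        step *= 1.1
        if obj_new - obj < tol:
            obj = obj_new
            break
        obj = obj_new

    weights = w**2
    order = np.argsort(-weights, kind="stable")
    return NcaWeights(weights=weights, order=order, n_iterations=iters, objective=obj)


def threshold_range(w: NcaWeights, t_low: float = 0.5, t_high: float = 0.99) -> tuple[int, int]:
    """Candidate-size range from cumulative normalised weights.

    ``start_k`` is the smallest k whose top-k cumulative weight reaches
    ``t_low``; ``stop_k`` the smallest reaching ``t_high``.
    """
    if not (0 < t_low <= t_high <= 1):
        raise ValueError("need 0 < t_low <= t_high <= 1")
    weights = np.asarray(w.weights, dtype=float)
    total = weights.sum()
    if total <= 0:
        raise ValueError("all-zero weights: cumulative thresholds are undefined")
    c = np.cumsum(np.sort(weights)[::-1]) / total
    # guard against c[-1] = 1 - eps from rounding
    c[-1] = 1.0
    start_k = int(np.searchsorted(c, t_low) + 1)
    stop_k = int(np.searchsorted(c, t_high) + 1)
    return start_k, stop_k


def select(
    X: np.ndarray,
    y: np.ndarray,
    evaluator: Callable[[np.ndarray, np.ndarray], float] | None = None,
    t_low: float = 0.5,
    t_high: float = 0.99,
    step: int = 1,
    seed: int = 0,
    folds: int = 10,
    weights: NcaWeights | None = None,
) -> SelectionResult:
    """Run the full CWINCA loop and return the best top-k candidate.

    ``evaluator(X_subset, y) -> accuracy%`` defaults to ``folds``-fold CV
    accuracy of the 1-NN / city-block classifier.  Candidates are the top-k
    features by NCA weight for k = start_k, start_k + step, ..., capped at
    stop_k.  The maximal-accuracy candidate wins; ties go to the smallest k.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if step < 1:
        raise ValueError("step must be >= 1")
    if evaluator is None:
        evaluator = lambda XS, yy: cv_accuracy(XS, yy, folds=folds, seed=seed)
    w = weights if weights is not None else nca_weights(X, y, seed=seed)
    start_k, stop_k = threshold_range(w, t_low, t_high)

    per_k: dict[int, float] = {}
    best_k, best_acc = None, -np.inf
    for k in range(start_k, stop_k + 1, step):
        cols = w.order[:k]
        try:
            acc = float(evaluator(X[:, cols], y))
        except Exception as exc:  # pragma: no cover - contract propagation
            raise RuntimeError(f"candidate evaluation failed at k={k}") from exc
        per_k[k] = acc
        if acc > best_acc:
            best_k, best_acc = k, acc
    assert best_k is not None
    cols = w.order[:best_k]
    return SelectionResult(
        ind=cols + 1,  # 1-based
        SX=X[:, cols],
        per_k_accuracy=per_k,
        start_k=start_k,
        stop_k=stop_k,
        weights=w,
    )
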