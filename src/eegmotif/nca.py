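"""Thresholded neighborhood component analysis (NCA) feature selection.

A two-stage selector.  Stage one min-max normalises each feature to [0, 1]
and drops every feature whose normalised column sum is not above a
threshold (at the default threshold 0 this removes exactly the constant
features).  Stage two learns a nonnegative relevance weight per surviving
feature by maximising the NCA leave-one-out objective

    F(w) = (1/n) * sum_i p_i  -  lambda * sum_r w_r**2,

where p_i = sum_{j != i, y_j = y_i} p_ij is the probability that a softmax
nearest neighbour drawn for sample i shares its class,

    p_ij = exp(-D_w(x_i, x_j)) / sum_{l != i} exp(-D_w(x_i, x_l)),
    D_w(x_i, x_j) = sum_r w_r**2 * |x_ir - x_jr| / sigma.

The top-k features by weight (default k = 250) are kept.

Optimisation is deterministic full-batch gradient ascent from the all-ones
weight vector with an adaptive step (grow on improvement, shrink and retry
on failure), so the sequence of accepted objective values is
non-decreasing by construction.  For speed, the pairwise per-feature
absolute differences are precomputed as one float32 tensor when it fits in
a memory budget, turning each iteration into two BLAS contractions;
otherwise they are recomputed in feature chunks.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "NCAParams",
    "SelectionResult",
    "minmax_normalize",
    "eliminate_by_threshold",
    "nca_objective",
    "nca_weights",
    "select_top_k",
    "select_features",
]

log = logging.getLogger("eegmotif.nca")


@dataclass
class NCAParams:
    """Hyperparameters of the NCA weight optimisation.

    ``lam`` defaults to 1/n_records**2, which in the mean-form objective
    used here matches the customary sum-form regularisation
    ``sum_i p_i - (1/n) * sum_r w_r**2``; a much larger ``lam`` makes the
    quadratic penalty dominate the (at most 1) data term and collapses all
    weights to zero, destroying the ranking.  ``sigma`` defaults to
    "auto", the standard deviation of the off-diagonal pairwise distances
    at the initial all-ones weights, which keeps the softmax responsive
    regardless of feature count (a fixed kernel width collapses it to
    one-hot for wide feature matrices, and scaling by the distance mean
    flattens it instead).
    """

    lam: float | None = None
    sigma: float | str = "auto"
    max_iter: int = 60
    tol: float = 1e-6
    seed: int = 0
    initial_step: float = 0.1
    memory_budget_bytes: int = 3_000_000_000

    def __post_init__(self) -> None:
        if self.lam is not None and self.lam < 0:
            raise ValueError("lam must be >= 0")
        if isinstance(self.sigma, (int, float)) and self.sigma <= 0:
            raise ValueError("sigma must be > 0")


@dataclass
class SelectionResult:
    """Outcome of thresholded-NCA selection on one feature matrix."""

    surviving_indices: np.ndarray  # indices into the original columns
    weights: np.ndarray  # nonnegative, one per surviving feature
    ranked_indices: np.ndarray  # surviving indices sorted by weight desc
    selected_indices: np.ndarray  # first min(k, survivors) ranked indices

    def __post_init__(self) -> None:
        self.surviving_indices = np.asarray(self.surviving_indices, dtype=int)
        self.weights = np.asarray(self.weights, dtype=float)
        self.ranked_indices = np.asarray(self.ranked_indices, dtype=int)
        self.selected_indices = np.asarray(self.selected_indices, dtype=int)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "surviving_indices": self.surviving_indices.tolist(),
                    "weights": self.weights.tolist(),
                    "ranked_indices": self.ranked_indices.tolist(),
                    "selected_indices": self.selected_indices.tolist(),
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SelectionResult":
        d = json.loads(Path(path).read_text())
        return cls(
            surviving_indices=d["surviving_indices"],
            weights=d["weights"],
            ranked_indices=d["ranked_indices"],
            selected_indices=d["selected_indices"],
        )


def minmax_normalize(X: np.ndarray) -> np.ndarray:
    """Per-feature (column-wise) map onto [0, 1]; constant columns map to 0."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.size == 0:
        raise ValueError("expected a non-empty 2-D matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("matrix contains non-finite values")
    lo = X.min(axis=0)
    span = X.max(axis=0) - lo
    safe = np.where(span > 0, span, 1.0)
    out = (X - lo) / safe
    out[:, span == 0] = 0.0
    return out


def eliminate_by_threshold(
    XN: np.ndarray, th: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Drop features whose column sum is <= ``th``; returns (kept, indices)."""
    XN = np.asarray(XN, dtype=float)
    if XN.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    sums = XN.sum(axis=0)
    keep = np.flatnonzero(sums > th)
    if keep.size == 0:
        warnings.warn("threshold eliminated every feature", stacklevel=2)
    return XN[:, keep], keep


def _pairwise_abs(X32: np.ndarray, cols: slice) -> np.ndarray:
    """|x_ir - x_jr| for a feature slice; shape (n, n, width)."""
    block = X32[:, cols]
    return np.abs(block[:, None, :] - block[None, :, :])


class _DistanceEngine:
    """Weighted L1 pairwise distances and the matching gradient contraction.

    Precomputes the (n, n, d) float32 absolute-difference tensor when it
    fits in the budget; otherwise streams it per feature chunk.
    """

    def __init__(self, X: np.ndarray, budget_bytes: int, chunk: int = 512) -> None:
        self.X32 = np.ascontiguousarray(X, dtype=np.float32)
        n, d = self.X32.shape
        self.n, self.d = n, d
        self.chunk = chunk
        self._tensor: np.ndarray | None = None
        if n * n * d * 4 <= budget_bytes:
            self._tensor = np.empty((n * n, d), dtype=np.float32)
            for start in range(0, d, chunk):
                sl = slice(start, min(start + chunk, d))
                self._tensor[:, sl] = _pairwise_abs(self.X32, sl).reshape(n * n, -1)

    def distances(self, w2: np.ndarray) -> np.ndarray:
        """D_ij = sum_r w_r^2 |x_ir - x_jr| (unscaled by sigma)."""
        w2f = w2.astype(np.float32)
        if self._tensor is not None:
            return (self._tensor @ w2f).reshape(self.n, self.n).astype(np.float64)
        D = np.zeros((self.n, self.n), dtype=np.float32)
        for start in range(0, self.d, self.chunk):
            sl = slice(start, min(start + self.chunk, self.d))
            D += _pairwise_abs(self.X32, sl) @ w2f[sl]
        return D.astype(np.float64)

    def contract(self, B: np.ndarray) -> np.ndarray:
        """g_r = sum_ij B_ij |x_ir - x_jr| for a coefficient matrix B."""
        Bf = B.astype(np.float32).reshape(-1)
        if self._tensor is not None:
            return (Bf @ self._tensor).astype(np.float64)
        g = np.zeros(self.d, dtype=np.float64)
        Bm = B.astype(np.float32)
        for start in range(0, self.d, self.chunk):
            sl = slice(start, min(start + self.chunk, self.d))
            g[sl] = np.einsum("ij,ijc->c", Bm, _pairwise_abs(self.X32, sl))
        return g


def _softmax_rows(neg_d: np.ndarray) -> np.ndarray:
    """Row-wise softmax with the diagonal excluded (self is never a neighbour)."""
    z = neg_d.copy()
    np.fill_diagonal(z, -np.inf)
    z -= z.max(axis=1, keepdims=True)
    p = np.exp(z)
    np.fill_diagonal(p, 0.0)
    p /= p.sum(axis=1, keepdims=True)
    return p


def _objective_terms(
    D: np.ndarray, same: np.ndarray, sigma: float
) -> tuple[np.ndarray, np.ndarray]:
    p = _softmax_rows(-D / sigma)
    pi = (p * same).sum(axis=1)
    return p, pi


def nca_objective(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    sigma: float,
    lam: float,
) -> float:
    """The regularised NCA leave-one-out objective F(w) (to maximise).

    Direct definition, usable as an independent check of the optimiser.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    w = np.asarray(w, dtype=float)
    diffs = np.abs(X[:, None, :] - X[None, :, :])
    D = diffs @ (w * w)
    same = (y[:, None] == y[None, :]).astype(float)
    _, pi = _objective_terms(D, same, sigma)
    return float(pi.mean() - lam * np.sum(w * w))


def nca_weights(
    X: np.ndarray, y: np.ndarray, params: NCAParams | None = None
) -> np.ndarray:
    """Learn a nonnegative NCA relevance weight per feature.

    Deterministic gradient ascent on F(w) from w = 1.  Issues a warning and
    returns the best iterate if the iteration budget is exhausted before
    the relative objective change falls below ``tol``.
    """
    params = params or NCAParams()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    n, d = X.shape
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least two classes for NCA")
    if counts.min() < 2:
        raise ValueError("need at least 2 records per class for NCA")
    lam = params.lam if params.lam is not None else 1.0 / (n * n)
    same = (y[:, None] == y[None, :]).astype(float)
    np.fill_diagonal(same, 0.0)

    eng = _DistanceEngine(X, params.memory_budget_bytes)
    w = np.ones(d)
    D0 = eng.distances(w * w)
    if params.sigma == "auto":
        # bandwidth from the spread (not magnitude) of initial distances:
        # the distance mean grows ~ d while its spread grows ~ sqrt(d), so
        # scaling by the mean flattens the softmax for wide matrices
        off = D0[~np.eye(n, dtype=bool)]
        sigma = float(off.std())
        if sigma <= 0:
            sigma = float(off.mean()) if off.mean() > 0 else 1.0
    else:
        sigma = float(params.sigma)

    def evaluate(wv: np.ndarray, D: np.ndarray | None = None):
        if D is None:
            D = eng.distances(wv * wv)
        p, pi = _objective_terms(D, same, sigma)
        F = float(pi.mean() - lam * np.sum(wv * wv))
        return F, p, pi

    F, p, pi = evaluate(w, D0)
    step = params.initial_step
    converged = False
    for it in range(params.max_iter):
        # dF/dw_r = (2 w_r / (n sigma)) * sum_ij (pi_i - same_ij) p_ij |dx_r|
        #           - 2 lam w_r
        B = (pi[:, None] * p - same * p) / (n * sigma)
        grad = 2.0 * w * eng.contract(B) - 2.0 * lam * w
        if float(np.max(np.abs(grad))) == 0.0:
            converged = True
            break
        # line search along grad: grow the step while it keeps helping,
        # shrink it if the current step overshoots
        F_try, p_try, pi_try = evaluate(w + step * grad)
        if F_try > F:
            while True:
                F2, p2, pi2 = evaluate(w + 2.0 * step * grad)
                if F2 > F_try:
                    step *= 2.0
                    F_try, p_try, pi_try = F2, p2, pi2
                else:
                    break
        else:
            while step > 1e-12 and F_try <= F:
                step *= 0.5
                F_try, p_try, pi_try = evaluate(w + step * grad)
            if F_try <= F:
                converged = True  # no ascent step exists at any usable scale
                break
        rel = (F_try - F) / max(abs(F), 1e-12)
        w = w + step * grad
        F, p, pi = F_try, p_try, pi_try
        if rel < params.tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"NCA did not converge within {params.max_iter} iterations; "
            "returning best iterate",
            stacklevel=2,
        )
    log.debug("NCA finished: F=%.6f after %d iterations", F, it + 1)
    return np.abs(w)


def select_top_k(
    weights: np.ndarray, surviving_indices: np.ndarray, k: int = 250
) -> SelectionResult:
    """Rank survivors by weight (descending, ties to the lower original
    index) and keep the first ``min(k, survivors)``."""
    if k < 1:
        raise ValueError("k must be >= 1")
    weights = np.asarray(weights, dtype=float)
    surviving = np.asarray(surviving_indices, dtype=int)
    if weights.shape != surviving.shape:
        raise ValueError("weights and surviving_indices must align")
    order = np.lexsort((surviving, -weights))
    ranked = surviving[order]
    if k > ranked.size:
        warnings.warn(
            f"k={k} exceeds the {ranked.size} surviving features; keeping all",
            stacklevel=2,
        )
    selected = ranked[: min(k, ranked.size)]
    return SelectionResult(
        surviving_indices=surviving,
        weights=weights,
        ranked_indices=ranked,
        selected_indices=selected,
    )


def select_features(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 250,
    th: float = 0.0,
    params: NCAParams | None = None,
) -> SelectionResult:
    """Full thresholded-NCA selection: normalise, eliminate, weight, rank."""
    XN = minmax_normalize(X)
    reduced, surviving = eliminate_by_threshold(XN, th)
    if surviving.size == 0:
        return SelectionResult(surviving, np.empty(0), np.empty(0, int), np.empty(0, int))
    weights = nca_weights(reduced, y, params)
    return select_top_k(weights, surviving, k)
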