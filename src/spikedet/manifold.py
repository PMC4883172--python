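"""Stage-2 front end: intrinsic dimensionality and locality-preserving embedding.

The candidate waveforms (31-dimensional at default settings) are assumed to
lie near a low-dimensional manifold, with true spikes and nonspecific sharp
transients occupying different regions of it.  Two pieces implement this:

* a maximum-likelihood estimator of the intrinsic dimensionality ``l`` from
  nearest-neighbour distances (Levina–Bickel form, with the corrected
  averaging of inverse estimates);
* locality preserving projections (LPP): a linear map ``y = Aᵀx`` obtained
  from the generalized eigenproblem ``X L Xᵀ α = λ X D Xᵀ α`` on the graph
  Laplacian ``L = D − W`` of a k-nearest-neighbour affinity graph.  The
  columns of ``A`` are the eigenvectors of *smallest* eigenvalue — the
  directions along which graph-neighbouring waveforms stay close.

Because the map is linear it extends exactly to unseen data
(``Y_new = Aᵀ X_new``), so the embedding can be learnt on training
candidates alone and applied out-of-sample during cross-validation.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "GraphParams",
    "EmbeddingModel",
    "estimate_intrinsic_dim",
    "build_graph",
    "fit_lpp",
    "transform",
]


@dataclass
class GraphParams:
    """Affinity-graph construction parameters.

    n_neighbors
        k of the symmetric k-NN graph (edge if either endpoint lists the
        other); default 7.
    weight_mode
        ``"heat"`` for Gaussian weights ``exp(−‖xi−xj‖²/t)``, ``"binary"``
        for 0/1 adjacency.
    heat_t
        Heat-kernel width t; ``None`` (default) uses the mean squared k-NN
        distance of the data.
    """

    n_neighbors: int = 7
    weight_mode: str = "heat"
    heat_t: float | None = None

    def __post_init__(self) -> None:
        if self.n_neighbors < 1:
            raise ValueError("n_neighbors must be ≥ 1")
        if self.weight_mode not in ("heat", "binary"):
            raise ValueError(f"unknown weight_mode {self.weight_mode!r}")


@dataclass
class EmbeddingModel:
    """Learned linear embedding: columns of ``A`` map d-vectors to l-vectors."""

    A: np.ndarray                 # (d, l)
    eigenvalues: np.ndarray       # (l,) ascending
    graph: GraphParams
    d: int
    l: int

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "A": self.A.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "graph": {
                "n_neighbors": self.graph.n_neighbors,
                "weight_mode": self.graph.weight_mode,
                "heat_t": self.graph.heat_t,
            },
            "d": self.d,
            "l": self.l,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "EmbeddingModel":
        with open(path) as fh:
            p = json.load(fh)
        return cls(
            A=np.asarray(p["A"], dtype=float),
            eigenvalues=np.asarray(p["eigenvalues"], dtype=float),
            graph=GraphParams(**p["graph"]),
            d=int(p["d"]),
            l=int(p["l"]),
        )


def _check_matrix(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a d × m matrix of column waveforms")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    return X


def estimate_intrinsic_dim(X: np.ndarray, k_min: int = 6, k_max: int = 12) -> int:
    """Maximum-likelihood intrinsic dimensionality from k-NN distances.

    For each point x and neighbourhood size k, the local estimate is
    ``m̂_k(x) = [ (1/(k−1)) Σ_{j<k} log(T_k(x)/T_j(x)) ]⁻¹`` with ``T_j`` the
    distance to the j-th nearest neighbour.  Inverse estimates are averaged
    over points and over k ∈ [k_min, k_max] (the corrected form of the
    estimator), inverted, and rounded to the nearest integer ≥ 1.
    """
    X = _check_matrix(X)
    m = X.shape[1]
    if not 2 <= k_min <= k_max:
        raise ValueError("need 2 ≤ k_min ≤ k_max")
    if m <= k_max:
        raise ValueError(f"need more than k_max={k_max} points, got {m}")
    nn = NearestNeighbors(n_neighbors=k_max + 1).fit(X.T)
    dist, _ = nn.kneighbors(X.T)
    T = dist[:, 1:]  # drop self-distance; T[:, j-1] = distance to j-th NN
    if np.any(T <= 0):
        warnings.warn(
            "duplicate points produced zero neighbour distances; "
            "perturbing by machine epsilon"
        )
        tiny = np.finfo(float).tiny
        T = np.maximum(T, np.sqrt(tiny))
    logT = np.log(T)
    inv_estimates = []
    for k in range(k_min, k_max + 1):
        # (1/(k−1)) Σ_{j=1}^{k−1} log(T_k/T_j) per point = 1/m̂_k(x)
        inv_mk = (logT[:, k - 1:k] - logT[:, : k - 1]).mean(axis=1)
        inv_estimates.append(inv_mk.mean())
    dim = 1.0 / np.mean(inv_estimates)
    return max(1, int(round(dim)))


def build_graph(
    X: np.ndarray, params: GraphParams | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Symmetric k-NN affinity graph of the column waveforms.

    Returns ``(W, D, L)``: the m × m weight matrix (heat-kernel or binary,
    zero diagonal), the diagonal degree matrix of its column sums, and the
    graph Laplacian ``L = D − W`` (rows summing exactly to zero).
    """
    params = params or GraphParams()
    X = _check_matrix(X)
    m = X.shape[1]
    if m < 2:
        raise ValueError("need at least 2 waveforms to build a graph")
    k = min(params.n_neighbors, m - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X.T)
    dist, idx = nn.kneighbors(X.T)
    adj = np.zeros((m, m), dtype=bool)
    rows = np.repeat(np.arange(m), k)
    adj[rows, idx[:, 1:].ravel()] = True
    adj |= adj.T  # edge if either endpoint lists the other
    if params.weight_mode == "binary":
        W = adj.astype(float)
    else:
        t = params.heat_t
        if t is None:
            t = float(np.mean(dist[:, 1:] ** 2))
        if t <= 0:
            t = 1.0  # all points coincident; arbitrary positive width
        diff = X.T[:, None, :] - X.T[None, :, :]
        sq = np.einsum("ijk,ijk->ij", diff, diff)
        W = np.where(adj, np.exp(-sq / t), 0.0)
    np.fill_diagonal(W, 0.0)
    D = np.diag(W.sum(axis=0))
    L = D - W
    return W, D, L


def fit_lpp(
    X: np.ndarray, l: int, params: GraphParams | None = None
) -> EmbeddingModel:
    """Solve ``X L Xᵀ α = λ X D Xᵀ α`` and keep the l smallest eigenpairs.

    Each eigenvector is normalised so ``αᵀ (X D Xᵀ) α = 1`` with its first
    nonzero component positive, making the fitted map reproducible
    bit-for-bit.  A singular ``X D Xᵀ`` is ridge-regularised by
    ``1e-9 · trace/d`` on the diagonal (with a warning).
    """
    params = params or GraphParams()
    X = _check_matrix(X)
    d, m = X.shape
    if not 1 <= l <= d:
        raise ValueError(f"embedding dimensionality l={l} must be in [1, {d}]")
    _W, D, L = build_graph(X, params)
    Sl = X @ L @ X.T
    Sd = X @ D @ X.T
    Sl = (Sl + Sl.T) / 2.0
    Sd = (Sd + Sd.T) / 2.0
    try:
        evals, evecs = sla.eigh(Sl, Sd)
    except (sla.LinAlgError, ValueError):
        reg = 1e-9 * np.trace(Sd) / d
        if reg <= 0:
            reg = 1e-9
        warnings.warn("X D Xᵀ is singular; regularising its diagonal")
        evals, evecs = sla.eigh(Sl, Sd + reg * np.eye(d))
    A = evecs[:, :l].copy()
    lam = evals[:l].copy()
    # sign convention: first component of magnitude > tol is positive
    for j in range(l):
        col = A[:, j]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if len(nz) and col[nz[0]] < 0:
            A[:, j] = -col
    return EmbeddingModel(A=A, eigenvalues=lam, graph=params, d=d, l=l)


def transform(model: EmbeddingModel, X: np.ndarray) -> np.ndarray:
    """Embed columns of ``X``: ``Y = Aᵀ X`` (l × m'). Exact out-of-sample map."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != model.d:
        raise ValueError(
            f"waveform dimensionality {X.shape[0]} does not match the "
            f"embedding model (d={model.d})"
        )
    return model.A.T @ X
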