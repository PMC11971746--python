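"""Distance matrices, Gower double-centering, IAR coupling weights, PSD repair.

Both the taxon weight matrix ``W`` (m x m) and the sample kernel ``K``
(n x n) are obtained by double-centering an elementwise-squared distance
matrix, -1/2 J D^(2) J with J = I - 11'/d.  ``W`` feeds the pairwise-
difference prior that couples the log local shrinkage scales of similar
taxa; ``K`` becomes the covariance of the per-sample random effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from compmix.compositional import CompositionTable

__all__ = [
    "DistanceMatrix",
    "GramMatrix",
    "IARGraph",
    "PSDKernel",
    "bray_curtis",
    "double_center",
    "iar_weights",
    "psd_repair",
]


@dataclass
class DistanceMatrix:
    """Square symmetric pairwise distances over taxa or samples."""

    D: np.ndarray
    axis: str = "samples"  # "samples" | "taxa"
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        d = self.D
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distance matrix must be square")
        if self.axis not in ("samples", "taxa"):
            raise ValueError("axis must be 'samples' or 'taxa'")
        asym = np.abs(d - d.T)
        if asym.size and asym.max() > 1e-10:
            i, j = np.unravel_index(np.argmax(asym), asym.shape)
            raise ValueError(
                f"distance matrix not symmetric: worst pair ({i}, {j}) differs by {asym[i, j]:.3g}"
            )
        if np.any(np.abs(np.diag(d)) > 1e-10):
            raise ValueError("distance matrix must have a zero diagonal")
        if np.any(d < 0):
            raise ValueError("distances must be nonnegative")
        if not self.ids:
            self.ids = [f"{'S' if self.axis == 'samples' else 'T'}{i + 1}" for i in range(len(d))]
        if len(self.ids) != len(d):
            raise ValueError("id length does not match matrix size")

    @property
    def size(self) -> int:
        return self.D.shape[0]


@dataclass
class GramMatrix:
    """Double-centered (zero row/column sum) symmetric similarity matrix."""

    G: np.ndarray
    axis: str = "samples"
    ids: list[str] = field(default_factory=list)
    centered: bool = True

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=float)
        g = self.G
        if g.ndim != 2 or g.shape[0] != g.shape[1]:
            raise ValueError("Gram matrix must be square")
        if np.abs(g - g.T).max(initial=0.0) > 1e-8:
            raise ValueError("Gram matrix must be symmetric")
        if self.centered and g.size:
            rowsums = np.abs(g.sum(axis=1)).max()
            if rowsums > 1e-6 * max(1.0, np.abs(g).max()):
                raise ValueError("centered Gram matrix must have zero row sums")
        if not self.ids:
            self.ids = [f"{'S' if self.axis == 'samples' else 'T'}{i + 1}" for i in range(len(g))]

    @property
    def size(self) -> int:
        return self.G.shape[0]


@dataclass
class IARGraph:
    """Undirected weighted graph for the pairwise-difference prior.

    Edges are stored as parallel arrays ``(i, j, w)`` with ``i < j`` and
    ``w >= 0``.
    """

    n_nodes: int
    i: np.ndarray
    j: np.ndarray
    w: np.ndarray

    def __post_init__(self) -> None:
        self.i = np.asarray(self.i, dtype=np.intp)
        self.j = np.asarray(self.j, dtype=np.intp)
        self.w = np.asarray(self.w, dtype=float)
        if not (len(self.i) == len(self.j) == len(self.w)):
            raise ValueError("edge arrays must have equal length")
        if np.any(self.w < 0):
            raise ValueError("IAR edge weights must be nonnegative")
        if np.any(self.i == self.j):
            raise ValueError("IAR graph must not contain self-edges")
        if len(self.i) and (self.i.max(initial=0) >= self.n_nodes or self.j.max(initial=0) >= self.n_nodes):
            raise ValueError("edge index out of range")

    @property
    def n_edges(self) -> int:
        return len(self.w)

    def laplacian(self) -> np.ndarray:
        """Dense weighted graph Laplacian L with psi' L psi = sum w (psi_i - psi_j)^2."""
        L = np.zeros((self.n_nodes, self.n_nodes))
        np.add.at(L, (self.i, self.j), -self.w)
        np.add.at(L, (self.j, self.i), -self.w)
        deg = -L.sum(axis=1)
        L[np.diag_indices_from(L)] = deg
        return L


@dataclass
class PSDKernel:
    """A repaired positive-semidefinite kernel and its factorizations.

    Attributes
    ----------
    matrix:
        The repaired kernel (negative eigenvalues clipped, jitter added).
    factor:
        Symmetric factor ``L`` with ``L @ L.T == matrix``.
    normalized:
        ``matrix`` divided by its mean diagonal entry, the default
        covariance passed to the random effect so the variance parameter
        is comparable across distance choices.
    normalized_factor:
        Symmetric factor of ``normalized``.
    """

    matrix: np.ndarray
    factor: np.ndarray
    normalized: np.ndarray
    normalized_factor: np.ndarray
    ids: list[str] = field(default_factory=list)

    @property
    def size(self) -> int:
        return self.matrix.shape[0]

    def logdet(self, variance: float, normalized: bool = True) -> float:
        K = self.normalized if normalized else self.matrix
        sign, ld = np.linalg.slogdet(variance * K)
        if sign <= 0:
            raise np.linalg.LinAlgError("kernel is not positive definite")
        return float(ld)


def bray_curtis(table: CompositionTable, axis: str = "samples") -> DistanceMatrix:
    """Bray-Curtis dissimilarity d = sum|a-b| / sum(a+b) between rows or columns."""
    if axis == "samples":
        M = table.X
        ids = table.sample_ids
    elif axis == "taxa":
        M = table.X.T
        ids = table.taxon_ids
    else:
        raise ValueError("axis must be 'samples' or 'taxa'")
    totals = M.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError("Bray-Curtis undefined for an all-zero profile")
    D = squareform(pdist(M, metric="braycurtis"))
    if np.any(~np.isfinite(D)):
        raise ValueError("Bray-Curtis undefined: some pair has zero combined abundance")
    return DistanceMatrix(D, axis=axis, ids=list(ids))


def double_center(D: DistanceMatrix) -> GramMatrix:
    """Gower transform: G = -1/2 J D^(2) J with J = I - 11'/d.

    ``D^(2)`` is the elementwise square of the distance matrix.  The output
    has zero row and column sums and, for Euclidean-embeddable distances,
    is positive semidefinite (the classical-MDS Gram matrix).
    """
    d = D.size
    D2 = D.D**2
    rowmean = D2.mean(axis=1, keepdims=True)
    colmean = D2.mean(axis=0, keepdims=True)
    total = D2.mean()
    G = -0.5 * (D2 - rowmean - colmean + total)
    G = 0.5 * (G + G.T)  # kill rounding asymmetry
    return GramMatrix(G, axis=D.axis, ids=list(D.ids))


def iar_weights(
    W: GramMatrix, clip: float = 0.0, top_q: float | None = None
) -> IARGraph:
    """Derive nonnegative coupling weights from a centered similarity matrix.

    The Gram matrix of a double-centered distance contains negative entries
    for dissimilar pairs; the pairwise-difference prior needs ``w_ij >= 0``,
    so entries are clipped at ``clip`` (default 0).  With ``top_q`` in
    (0, 1), only the largest fraction ``top_q`` of the positive weights is
    retained (quantile sparsification).  Weights are monotone in ``W_ij``.
    """
    m = W.size
    iu, ju = np.triu_indices(m, k=1)
    w = W.G[iu, ju]
    keep = w > clip
    if top_q is not None:
        if not 0 < top_q <= 1:
            raise ValueError("top_q must lie in (0, 1]")
        pos = w[keep]
        if pos.size:
            thresh = np.quantile(pos, 1.0 - top_q)
            keep &= w >= thresh
    if not np.any(keep):
        warnings.warn(
            "no positive similarity weights: IAR coupling is empty and local scales "
            "are effectively independent",
            UserWarning,
            stacklevel=2,
        )
    return IARGraph(m, iu[keep], ju[keep], np.maximum(w[keep], 0.0))


def psd_repair(K: GramMatrix, jitter: float = 1e-8) -> PSDKernel:
    """Clip negative eigenvalues to zero and add diagonal jitter.

    Kernels from non-Euclidean distances (e.g. Bray-Curtis) need not be
    positive semidefinite; eigenvalue clipping is the standard deterministic
    repair.  The jitter added is ``jitter * trace(K_clipped) / d``, keeping
    the result strictly positive definite so that log-densities exist.
    """
    G = 0.5 * (K.G + K.G.T)
    if not np.any(G):
        raise ValueError("zero kernel matrix: no usable covariance")
    vals, vecs = np.linalg.eigh(G)
    clipped = np.maximum(vals, 0.0)
    if clipped.sum() == 0.0:
        raise ValueError("zero kernel matrix after clipping: no usable covariance")
    d = len(vals)
    eps = jitter * clipped.sum() / d
    lam = clipped + eps
    matrix = (vecs * lam) @ vecs.T
    factor = (vecs * np.sqrt(lam)) @ vecs.T
    scale = np.diag(matrix).mean()
    return PSDKernel(
        matrix=matrix,
        factor=factor,
        normalized=matrix / scale,
        normalized_factor=factor / np.sqrt(scale),
        ids=list(K.ids),
    )
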