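"""Random-walk-with-restart diffusion profiles and their SVD embedding.

Each node's diffusion profile is the stationary distribution of a random walk
with restart (RWR) seeded at that node: at every step the walker either
restarts at the seed (probability ``alpha``) or moves to a uniformly chosen
neighbour.  The profile captures the node's global topological context.  The
N x N profile matrix is then compressed to a k-dimensional embedding per node
by truncated singular value decomposition.

The walk propagates with the transpose of the row-stochastic transition
matrix so that every iterate remains a probability distribution.  Nodes with
no outgoing edges (dangling nodes) have their transition mass redirected to
the restart vector, which keeps the iteration stochastic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:
    from .hetnet import HetNet

__all__ = [
    "DiffusionProfile",
    "NodeEmbedding",
    "row_normalize",
    "rwr",
    "diffusion_profiles",
    "svd_reduce",
]

DEFAULT_ALPHA = 0.5
DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 1000
DEFAULT_SVD_K = 300


def row_normalize(
    adjacency: np.ndarray, *, weighted: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Row-stochastic transition matrix from a nonnegative adjacency.

    By default the adjacency is binarized first (an edge counts 1 whenever its
    weight is positive), so each step moves to a uniformly chosen neighbour;
    ``weighted=True`` normalizes the raw weights instead.  Returns
    ``(T, dangling)`` where ``dangling`` flags all-zero rows, which are kept
    all-zero.
    """
    A = np.asarray(adjacency, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if A.min(initial=0.0) < 0.0:
        raise ValueError("adjacency must be nonnegative")
    if not weighted:
        A = (A > 0).astype(float)
    degrees = A.sum(axis=1)
    dangling = degrees == 0.0
    T = np.divide(A, degrees[:, None], out=np.zeros_like(A), where=~dangling[:, None])
    return T, dangling


@dataclass(frozen=True)
class DiffusionProfile:
    """Stationary RWR distributions, one row per seed node in global order."""

    matrix: np.ndarray  # (N, N); row i sums to 1
    alpha: float
    iterations_used: int
    converged: bool

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class NodeEmbedding:
    """k-dimensional node vectors: left singular vectors scaled by the
    singular values of the diffusion profile matrix."""

    matrix: np.ndarray  # (N, k)
    singular_values: np.ndarray  # (k,), nonincreasing
    node_ids: tuple[str, ...]
    n_m: int
    n_p: int
    n_d: int

    @property
    def k(self) -> int:
        return self.matrix.shape[1]

    def mirna_vectors(self) -> np.ndarray:
        return self.matrix[: self.n_m]

    def disease_vectors(self) -> np.ndarray:
        return self.matrix[self.n_m + self.n_p :]


def _propagate(
    T: np.ndarray,
    dangling: np.ndarray,
    P0: np.ndarray,
    alpha: float,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, int, bool]:
    """Iterate P <- (1-a) (T' P + P0 * dangling_mass) + a P0 to a fixed point.

    ``P0`` and ``P`` have one column per seed; dangling-row mass restarts.
    """
    Tt = T.T.copy()
    P = P0.copy()
    for it in range(1, max_iter + 1):
        dangling_mass = P[dangling].sum(axis=0) if dangling.any() else 0.0
        P_next = (1.0 - alpha) * (Tt @ P + P0 * dangling_mass) + alpha * P0
        delta = np.abs(P_next - P).sum(axis=0).max()
        P = P_next
        if delta < tol:
            return P, it, True
    return P, max_iter, False


def rwr(
    T: np.ndarray,
    seed_node: int,
    alpha: float = DEFAULT_ALPHA,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    *,
    dangling: np.ndarray | None = None,
) -> tuple[np.ndarray, int, bool]:
    """Stationary RWR distribution for one seed node.

    Iterates ``P <- (1 - alpha) T' P + alpha P0`` from the one-hot ``P0`` until
    the L1 change drops below ``tol``.  Returns ``(distribution, iterations,
    converged)``; ``converged`` is False when ``max_iter`` was exhausted.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha={alpha} outside [0, 1]")
    N = T.shape[0]
    if dangling is None:
        dangling = T.sum(axis=1) == 0.0
    P0 = np.zeros((N, 1))
    P0[seed_node, 0] = 1.0
    if alpha == 1.0:
        return P0[:, 0], 0, True
    P, its, ok = _propagate(T, dangling, P0, alpha, tol, max_iter)
    return P[:, 0], its, ok


def diffusion_profiles(
    net: "HetNet",
    alpha: float = DEFAULT_ALPHA,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    *,
    weighted: bool = False,
) -> DiffusionProfile:
    """RWR profile for every node of the (thresholded) global network.

    Row ``i`` of the result is the stationary distribution seeded at global
    node ``i`` (miRNAs, then proteins, then diseases).  All seeds are iterated
    jointly as one matrix recurrence.
    """
    if not net.threshold_applied:
        raise ValueError("threshold the network before computing diffusion profiles")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha={alpha} outside [0, 1]")
    T, dangling = row_normalize(net.global_adjacency(), weighted=weighted)
    N = T.shape[0]
    P0 = np.eye(N)
    if alpha == 1.0:
        return DiffusionProfile(matrix=P0, alpha=alpha, iterations_used=0, converged=True)
    P, its, ok = _propagate(T, dangling, P0, alpha, tol, max_iter)
    if not ok:
        warnings.warn(
            f"RWR did not reach tol={tol} within {max_iter} iterations", stacklevel=2
        )
    # column j is the profile of seed j; profiles are stored row-wise
    return DiffusionProfile(matrix=P.T.copy(), alpha=alpha, iterations_used=its, converged=ok)


def svd_reduce(
    profile: DiffusionProfile,
    k: int = DEFAULT_SVD_K,
    *,
    node_ids: tuple[str, ...] | None = None,
    n_m: int | None = None,
    n_p: int | None = None,
    n_d: int | None = None,
) -> NodeEmbedding:
    """Compress the N x N profile matrix to N x k by truncated SVD.

    The embedding row for a node is ``U_k @ diag(s_k)``, which preserves the
    relative geometry of the profile rows (inner products converge to profile
    inner products as k approaches the rank).  Singular-vector signs are
    canonicalized so each component's largest-magnitude entry is positive.
    Requesting more components than the numerical rank yields rank columns
    and a warning.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    A = profile.matrix
    N = A.shape[0]
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    rank = int(np.sum(s > s[0] * max(A.shape) * np.finfo(float).eps)) if s.size else 0
    effective = min(k, rank) if rank else min(k, N)
    if k > rank:
        warnings.warn(
            f"requested k={k} exceeds matrix rank {rank}; embedding has "
            f"{effective} columns",
            stacklevel=2,
        )
    U, s = U[:, :effective], s[:effective]
    # sign canonicalization: largest-|entry| of each left singular vector > 0
    flip = np.sign(U[np.abs(U).argmax(axis=0), np.arange(effective)])
    flip[flip == 0] = 1.0
    U = U * flip
    if node_ids is None:
        node_ids = tuple(str(i) for i in range(N))
    if n_m is None or n_p is None or n_d is None:
        n_m, n_p, n_d = N, 0, 0
    return NodeEmbedding(
        matrix=U * s,
        singular_values=s,
        node_ids=tuple(node_ids),
        n_m=n_m,
        n_p=n_p,
        n_d=n_d,
    )


def embed_network(
    net: "HetNet",
    k: int = DEFAULT_SVD_K,
    alpha: float = DEFAULT_ALPHA,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    *,
    weighted: bool = False,
) -> NodeEmbedding:
    """Convenience: diffusion profiles followed by SVD reduction."""
    profile = diffusion_profiles(net, alpha=alpha, tol=tol, max_iter=max_iter, weighted=weighted)
    return svd_reduce(
        profile,
        k,
        node_ids=net.node_ids,
        n_m=net.n_m,
        n_p=net.n_p,
        n_d=net.n_d,
    )
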