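"""HeteSim metapath relevance features for miRNA-disease pairs.

A metapath is a sequence of node types, here always starting at miRNA (M) and
ending at disease (D), e.g. M-P-D "miRNA targets a protein associated with
the disease".  HeteSim scores the relevance of a concrete (miRNA, disease)
pair along a metapath as the cosine of their midpoint-reachability vectors:
the path is split in the middle, the reachable probability matrix (product of
per-step row-stochastic transition matrices) is computed for the left half
and for the reversed right half, and the two rows meeting at the midpoint
type are compared.

The 39 canonical metapaths are all type sequences of two to four edges from
M to D, ordered by length and then lexicographically with M < P < D.

Odd-length paths have two candidate midpoints.  When both midpoint types are
identical the two half-path reachability matrices are averaged before taking
the cosine; when they differ (the matrices then have incompatible shapes) a
score is computed per decomposition and the two scores are averaged.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse

if TYPE_CHECKING:
    from .hetnet import HetNet

__all__ = [
    "MetaPath",
    "TransitionMatrixSet",
    "HeteSimFeature",
    "enumerate_metapaths",
    "transition_matrix",
    "reachable",
    "split_path",
    "hetesim_score",
    "hetesim_features",
]

_TYPE_ORDER = "MPD"


@dataclass(frozen=True)
class MetaPath:
    """An M-to-D node-type sequence, e.g. ``MetaPath("MPPD")``."""

    types: str

    def __post_init__(self) -> None:
        if len(self.types) < 2:
            raise ValueError("a metapath needs at least one edge")
        if any(t not in _TYPE_ORDER for t in self.types):
            raise ValueError(f"metapath types must be over {{M,P,D}}: {self.types!r}")
        if self.types[0] != "M" or self.types[-1] != "D":
            raise ValueError(f"metapaths start at M and end at D: {self.types!r}")

    @property
    def length(self) -> int:
        """Edge count."""
        return len(self.types) - 1

    def __str__(self) -> str:
        return self.types


def enumerate_metapaths(min_edges: int = 2, max_edges: int = 4) -> list[MetaPath]:
    """All M...D metapaths with ``min_edges`` to ``max_edges`` edges.

    Ordered by length ascending, then lexicographically with M < P < D; with
    the defaults this is the canonical 39-path list (MMD, MPD, MDD, MMMD, ...,
    MDDDD).
    """
    if not 1 <= min_edges <= max_edges:
        raise ValueError("need 1 <= min_edges <= max_edges")
    paths = []
    for n_edges in range(min_edges, max_edges + 1):
        for interior in itertools.product(_TYPE_ORDER, repeat=n_edges - 1):
            paths.append(MetaPath("M" + "".join(interior) + "D"))
    return paths


def transition_matrix(adjacency: np.ndarray | sparse.spmatrix) -> sparse.csr_matrix:
    """Row-normalize a binary cross- or intra-type adjacency block.

    All-zero rows stay zero (a node with no neighbours of the target type has
    no outgoing transition along this step).
    """
    A = sparse.csr_matrix(adjacency, dtype=float)
    degrees = np.asarray(A.sum(axis=1)).ravel()
    inv = np.divide(1.0, degrees, out=np.zeros_like(degrees), where=degrees > 0)
    return sparse.diags(inv) @ A


class TransitionMatrixSet(Mapping):
    """Per-step transition matrices for every adjacent ordered type pair.

    Built from the thresholded network with binarized blocks (an edge counts
    whenever its weight is positive); intra-type blocks have zero diagonal so
    a step always moves to a different node.  Keys are two-letter strings
    ("MP", "PM", "MM", ...).
    """

    def __init__(self, matrices: dict[str, sparse.csr_matrix]):
        self._matrices = matrices

    @classmethod
    def from_network(cls, net: "HetNet", *, weighted: bool = False) -> "TransitionMatrixSet":
        if not net.threshold_applied:
            raise ValueError("threshold the network before building transition matrices")
        blocks = {
            "MM": net.M,
            "PP": net.P,
            "DD": net.D,
            "MP": net.B,
            "MD": net.C,
            "PD": net.W,
            "PM": net.B.T,
            "DM": net.C.T,
            "DP": net.W.T,
        }
        matrices = {}
        for key, block in blocks.items():
            adj = np.asarray(block, dtype=float)
            if not weighted:
                adj = (adj > 0).astype(float)
            matrices[key] = transition_matrix(adj)
        return cls(matrices)

    def __getitem__(self, key: str) -> sparse.csr_matrix:
        try:
            return self._matrices[key]
        except KeyError:
            raise KeyError(f"no transition matrix for type pair {key!r}") from None

    def __iter__(self):
        return iter(self._matrices)

    def __len__(self) -> int:
        return len(self._matrices)


def reachable(path: MetaPath | str, tset: TransitionMatrixSet) -> np.ndarray:
    """Reachable probability matrix along a metapath.

    The product of the per-step transition matrices; entry (i, j) is the
    probability that a walk following the path's type sequence from node i of
    the first type ends at node j of the last type.
    """
    types = str(path)
    if len(types) < 2:
        raise ValueError("reachability needs at least one edge")
    R = tset[types[0] + types[1]]
    for a, b in zip(types[1:], types[2:]):
        R = R @ tset[a + b]
    return np.asarray(R.todense()) if sparse.issparse(R) else np.asarray(R)


def split_path(path: MetaPath) -> list[tuple[str, str]]:
    """Decompose a metapath at its middle into (left, right) half-paths.

    Even edge counts have a unique middle node; odd edge counts have two
    candidate middle nodes and yield both decompositions.
    """
    types = str(path)
    n_edges = len(types) - 1
    if n_edges < 2:
        raise ValueError("only paths with at least two edges can be split")
    if n_edges % 2 == 0:
        mid = n_edges // 2
        return [(types[: mid + 1], types[mid:])]
    lo, hi = n_edges // 2, n_edges // 2 + 1
    return [(types[: lo + 1], types[lo:]), (types[: hi + 1], types[hi:])]


def _cosine_rows(left: np.ndarray, right: np.ndarray) -> np.ndarray:
    """Cosine of every row of ``left`` against every row of ``right``.

    Zero rows score 0 against everything: no midpoint reachability means no
    relevance.
    """
    ln = np.linalg.norm(left, axis=1)
    rn = np.linalg.norm(right, axis=1)
    num = left @ right.T
    denom = np.outer(ln, rn)
    scores = np.divide(num, denom, out=np.zeros_like(num), where=denom > 0)
    return np.clip(scores, 0.0, 1.0)


def _midpoint_matrices(
    path: MetaPath, tset: TransitionMatrixSet
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per decomposition: (R_left, R_right_reversed) midpoint matrices.

    ``R_left`` maps miRNAs to midpoint nodes, ``R_right_reversed`` maps
    diseases to midpoint nodes (the right half-path is walked backwards from
    the disease end).
    """
    out = []
    for left, right in split_path(path):
        out.append((reachable(left, tset), reachable(right[::-1], tset)))
    return out


def _score_matrix(path: MetaPath, tset: TransitionMatrixSet) -> np.ndarray:
    """HeteSim scores for all (miRNA, disease) pairs along one metapath."""
    decomps = split_path(path)
    halves = _midpoint_matrices(path, tset)
    if len(decomps) == 1:
        L, R = halves[0]
        return _cosine_rows(L, R)
    mid_types = [left[-1] for left, _ in decomps]
    if mid_types[0] == mid_types[1]:
        L = (halves[0][0] + halves[1][0]) / 2.0
        R = (halves[0][1] + halves[1][1]) / 2.0
        return _cosine_rows(L, R)
    s0 = _cosine_rows(*halves[0])
    s1 = _cosine_rows(*halves[1])
    return (s0 + s1) / 2.0


def hetesim_score(
    a: int, b: int, path: MetaPath | str, tset: TransitionMatrixSet
) -> float:
    """HeteSim relevance of miRNA ``a`` and disease ``b`` along one metapath."""
    if isinstance(path, str):
        path = MetaPath(path)
    return float(_score_matrix(path, tset)[a, b])


@dataclass(frozen=True)
class HeteSimFeature:
    """HeteSim scores for every pair and metapath: shape (n_m, n_d, n_paths)."""

    values: np.ndarray
    paths: tuple[MetaPath, ...]
    mirna_ids: tuple[str, ...]
    disease_ids: tuple[str, ...]

    @property
    def n_paths(self) -> int:
        return self.values.shape[2]

    def pair_vector(self, a: int, b: int) -> np.ndarray:
        return self.values[a, b]


def hetesim_features(
    net: "HetNet",
    paths: Iterable[MetaPath | str] | None = None,
    *,
    weighted: bool = False,
) -> HeteSimFeature:
    """HeteSim feature tensor for all miRNA-disease pairs.

    One score per pair per metapath (the canonical 39 by default), computed
    with matrix products rather than per-pair loops.
    """
    tset = TransitionMatrixSet.from_network(net, weighted=weighted)
    if paths is None:
        path_list: Sequence[MetaPath] = enumerate_metapaths()
    else:
        path_list = [p if isinstance(p, MetaPath) else MetaPath(p) for p in paths]
    values = np.empty((net.n_m, net.n_d, len(path_list)))
    for idx, path in enumerate(path_list):
        values[:, :, idx] = _score_matrix(path, tset)
    return HeteSimFeature(
        values=values,
        paths=tuple(path_list),
        mirna_ids=net.mirna_ids,
        disease_ids=net.disease_ids,
    )
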