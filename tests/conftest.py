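"""Shared fixtures and independent oracles for the test suite.

The oracles here re-derive quantities by routes independent of the package's
implementation: the RWR fixed point by a direct linear solve, HeteSim by
explicit enumeration of metapath instances, and AUC by exhaustive
concordance counting.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from hetmda import HetNet, apply_threshold, assemble_global


# ---------------------------------------------------------------------------
# network builders
# ---------------------------------------------------------------------------


def build_net(M, P, D, B, C, W, thresholded: bool = True) -> HetNet:
    """Assemble a network from raw blocks, optionally thresholding at 0.5."""
    M, P, D, B, C, W = (np.asarray(x, dtype=float) for x in (M, P, D, B, C, W))
    net = assemble_global(
        [f"m{i}" for i in range(M.shape[0])],
        [f"p{i}" for i in range(P.shape[0])],
        [f"d{i}" for i in range(D.shape[0])],
        M, P, D, B, C, W,
    )
    return apply_threshold(net) if thresholded else net


def random_net(rng: np.random.Generator, n_m: int, n_p: int, n_d: int,
               density: float = 0.5) -> HetNet:
    """Random thresholded network with binary blocks at the given density."""

    def sym(n):
        A = np.triu((rng.random((n, n)) < density).astype(float), k=1)
        return A + A.T

    return build_net(
        sym(n_m), sym(n_p), sym(n_d),
        (rng.random((n_m, n_p)) < density).astype(float),
        (rng.random((n_m, n_d)) < density).astype(float),
        (rng.random((n_p, n_d)) < density).astype(float),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


# ---------------------------------------------------------------------------
# RWR oracle: direct linear solve of the restart fixed point
# ---------------------------------------------------------------------------


def rwr_solve(adjacency: np.ndarray, seed_node: int, alpha: float) -> np.ndarray:
    """Fixed point of P = (1-a) M' P + a P0 by direct linear solve.

    ``M`` is the row-normalized binarized adjacency with dangling rows
    replaced by the restart vector (one-hot at the seed).
    """
    A = (np.asarray(adjacency) > 0).astype(float)
    n = A.shape[0]
    degrees = A.sum(axis=1)
    M = np.zeros_like(A)
    nz = degrees > 0
    M[nz] = A[nz] / degrees[nz, None]
    M[~nz, seed_node] = 1.0  # dangling mass restarts
    p0 = np.zeros(n)
    p0[seed_node] = 1.0
    return alpha * np.linalg.solve(np.eye(n) - (1 - alpha) * M.T, p0)


# ---------------------------------------------------------------------------
# HeteSim oracle: explicit enumeration of metapath instances
# ---------------------------------------------------------------------------


def _oracle_blocks(net: HetNet) -> dict[str, np.ndarray]:
    b = lambda x: (np.asarray(x) > 0).astype(float)
    return {
        "MM": b(net.M), "PP": b(net.P), "DD": b(net.D),
        "MP": b(net.B), "MD": b(net.C), "PD": b(net.W),
        "PM": b(net.B).T, "DM": b(net.C).T, "DP": b(net.W).T,
    }


def _oracle_midpoint_vector(
    blocks: dict[str, np.ndarray], sizes: dict[str, int], types: str, start: int
) -> np.ndarray:
    """Probability of reaching each midpoint node by walking ``types`` from
    ``start``, summed over every explicit node-level instantiation."""
    out = np.zeros(sizes[types[-1]])

    def walk(pos: int, node: int, prob: float) -> None:
        if pos == len(types) - 1:
            out[node] += prob
            return
        step = blocks[types[pos] + types[pos + 1]]
        row = step[node]
        deg = row.sum()
        if deg == 0:
            return
        for nxt in np.flatnonzero(row):
            walk(pos + 1, int(nxt), prob / deg)

    walk(0, start, 1.0)
    return out


def hetesim_brute_force(net: HetNet, a: int, b: int, path: str) -> float:
    """HeteSim by brute-force instance enumeration.

    Splits the metapath at the middle; for odd edge counts the two
    decompositions are combined by matrix averaging when the midpoint types
    agree and by score averaging otherwise (mirroring the documented
    convention, but computed through explicit path instantiation).
    """
    blocks = _oracle_blocks(net)
    sizes = {"M": net.n_m, "P": net.n_p, "D": net.n_d}
    n_edges = len(path) - 1

    def cos(u, v):
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu == 0 or nv == 0:
            return 0.0
        return float(np.clip(u @ v / (nu * nv), 0.0, 1.0))

    def halves(mid):
        left = path[: mid + 1]
        right_rev = path[mid:][::-1]
        u = _oracle_midpoint_vector(blocks, sizes, left, a)
        v = _oracle_midpoint_vector(blocks, sizes, right_rev, b)
        return u, v

    if n_edges % 2 == 0:
        return cos(*halves(n_edges // 2))
    m1, m2 = n_edges // 2, n_edges // 2 + 1
    if path[m1] == path[m2]:
        u1, v1 = halves(m1)
        u2, v2 = halves(m2)
        return cos((u1 + u2) / 2, (v1 + v2) / 2)
    return (cos(*halves(m1)) + cos(*halves(m2))) / 2.0


# ---------------------------------------------------------------------------
# AUC oracle: exhaustive pair concordance
# ---------------------------------------------------------------------------


def auc_concordance(labels, scores) -> float:
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))
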