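"""Typed miRNA-protein-disease heterogeneous network.

The global network is a three-layer graph whose node types are miRNAs (M),
proteins (P) and diseases (D).  Intra-type blocks hold similarity weights in
[0, 1] (Pearson correlation of expression for miRNAs, interaction confidence
for proteins, phenotype similarity for diseases); cross-type blocks hold
validated binary associations (miRNA-target, miRNA-disease, protein-disease).
The global adjacency is the symmetric block matrix

    T = [[M,  B,  C ],
         [B', P,  W ],
         [C', W', D ]]

with miRNAs first, then proteins, then diseases.  Weak similarity edges
(weight < 0.5 by default) are removed before any feature extraction.
"""

from __future__ import annotations

import enum
import hashlib
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "NodeType",
    "ExpressionTable",
    "HetNet",
    "pcc_similarity",
    "assemble_global",
    "apply_threshold",
    "read_edge_list",
    "write_edge_list",
    "read_node_ids",
    "write_node_ids",
    "read_bundle",
    "write_bundle",
]

_SYM_TOL = 1e-9


class NodeType(enum.IntEnum):
    """The three node types, in global ordering MIRNA < PROTEIN < DISEASE."""

    MIRNA = 0
    PROTEIN = 1
    DISEASE = 2

    @property
    def letter(self) -> str:
        return "MPD"[int(self)]


@dataclass(frozen=True)
class ExpressionTable:
    """miRNA expression profiles: one row per miRNA, one column per sample."""

    mirna_ids: tuple[str, ...]
    values: np.ndarray  # shape (n_m, n_samples)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if len(self.mirna_ids) != values.shape[0]:
            raise ValueError("one expression row per miRNA id is required")
        if len(set(self.mirna_ids)) != len(self.mirna_ids):
            raise ValueError("duplicate miRNA identifiers in expression table")
        if values.shape[1] < 2:
            raise ValueError("at least two samples are required to correlate profiles")


def pcc_similarity(expr: ExpressionTable) -> np.ndarray:
    """Pearson-correlation similarity block for miRNAs.

    Entries are ``max(0, PCC)`` of the two expression rows (negative edges are
    cut), the diagonal is forced to zero (no self-loops).  Rows with zero
    variance cannot be correlated; their similarities are set to 0 and a
    warning is emitted.
    """
    values = expr.values
    var = values.var(axis=1)
    degenerate = np.flatnonzero(var == 0.0)
    if degenerate.size:
        warnings.warn(
            "zero-variance expression rows, similarities set to 0: "
            + ", ".join(expr.mirna_ids[i] for i in degenerate),
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.corrcoef(values)
    sim = np.atleast_2d(sim)
    sim[np.isnan(sim)] = 0.0
    np.clip(sim, 0.0, 1.0, out=sim)
    sim[degenerate, :] = 0.0
    sim[:, degenerate] = 0.0
    np.fill_diagonal(sim, 0.0)
    return (sim + sim.T) / 2.0  # exact symmetry against fp round-off


@dataclass(frozen=True)
class HetNet:
    """The global three-layer network, stored as its six named blocks.

    ``M``, ``P``, ``D`` are symmetric intra-type similarity blocks with zero
    diagonal; ``B`` (miRNA-target), ``C`` (miRNA-disease) and ``W``
    (protein-disease) are cross-type association blocks.  Transposed blocks
    are derived, never stored.
    """

    mirna_ids: tuple[str, ...]
    protein_ids: tuple[str, ...]
    disease_ids: tuple[str, ...]
    M: np.ndarray
    P: np.ndarray
    D: np.ndarray
    B: np.ndarray
    C: np.ndarray
    W: np.ndarray
    threshold_applied: bool = False

    # -- sizes -------------------------------------------------------------
    @property
    def n_m(self) -> int:
        return len(self.mirna_ids)

    @property
    def n_p(self) -> int:
        return len(self.protein_ids)

    @property
    def n_d(self) -> int:
        return len(self.disease_ids)

    @property
    def n_nodes(self) -> int:
        return self.n_m + self.n_p + self.n_d

    @property
    def node_ids(self) -> tuple[str, ...]:
        """All node identifiers in global order (miRNAs, proteins, diseases)."""
        return self.mirna_ids + self.protein_ids + self.disease_ids

    def global_adjacency(self) -> np.ndarray:
        """Assemble the symmetric global block matrix T."""
        return np.block(
            [
                [self.M, self.B, self.C],
                [self.B.T, self.P, self.W],
                [self.C.T, self.W.T, self.D],
            ]
        )

    def mirna_index(self, mirna_id: str) -> int:
        try:
            return self.mirna_ids.index(mirna_id)
        except ValueError:
            raise KeyError(f"unknown miRNA identifier: {mirna_id!r}") from None

    def disease_index(self, disease_id: str) -> int:
        try:
            return self.disease_ids.index(disease_id)
        except ValueError:
            raise KeyError(f"unknown disease identifier: {disease_id!r}") from None

    def fingerprint(self) -> str:
        """SHA-256 over node ids and block contents; identifies the network."""
        h = hashlib.sha256()
        for ids in (self.mirna_ids, self.protein_ids, self.disease_ids):
            h.update("\x00".join(ids).encode())
            h.update(b"\x01")
        for block in (self.M, self.P, self.D, self.B, self.C, self.W):
            h.update(np.ascontiguousarray(block, dtype=float).tobytes())
        h.update(b"T" if self.threshold_applied else b"F")
        return h.hexdigest()

    def without_md_edges(self, pairs: Sequence[tuple[int, int]]) -> "HetNet":
        """Copy of the network with the given miRNA-disease edges deleted.

        Used by the leakage-controlled cross-validation protocol: validation
        associations are removed from C before features are re-extracted.
        """
        C = self.C.copy()
        for i, j in pairs:
            C[i, j] = 0.0
        return replace(self, C=C)


def _check_intra(name: str, block: np.ndarray, n: int) -> np.ndarray:
    block = np.asarray(block, dtype=float)
    if block.shape != (n, n):
        raise ValueError(f"block {name} has shape {block.shape}, expected {(n, n)}")
    if not np.allclose(block, block.T, atol=_SYM_TOL, rtol=0.0):
        raise ValueError(f"block {name} is not symmetric")
    if block.min(initial=0.0) < 0.0 or block.max(initial=0.0) > 1.0:
        raise ValueError(f"block {name} has weights outside [0, 1]")
    block = (block + block.T) / 2.0
    np.fill_diagonal(block, 0.0)  # no self-loops; restart supplies self-mass
    return block


def _check_cross(name: str, block: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    block = np.asarray(block, dtype=float)
    if block.shape != shape:
        raise ValueError(f"block {name} has shape {block.shape}, expected {shape}")
    if block.min(initial=0.0) < 0.0 or block.max(initial=0.0) > 1.0:
        raise ValueError(f"block {name} has weights outside [0, 1]")
    return block.copy()


def assemble_global(
    mirna_ids: Sequence[str],
    protein_ids: Sequence[str],
    disease_ids: Sequence[str],
    M: np.ndarray,
    P: np.ndarray,
    D: np.ndarray,
    B: np.ndarray,
    C: np.ndarray,
    W: np.ndarray,
) -> HetNet:
    """Validate the six blocks and assemble the global heterogeneous network.

    Raises ``ValueError`` naming the offending block on a shape mismatch, an
    asymmetric intra-type block, or a weight outside [0, 1].
    """
    n_m, n_p, n_d = len(mirna_ids), len(protein_ids), len(disease_ids)
    return HetNet(
        mirna_ids=tuple(mirna_ids),
        protein_ids=tuple(protein_ids),
        disease_ids=tuple(disease_ids),
        M=_check_intra("M", M, n_m),
        P=_check_intra("P", P, n_p),
        D=_check_intra("D", D, n_d),
        B=_check_cross("B", B, (n_m, n_p)),
        C=_check_cross("C", C, (n_m, n_d)),
        W=_check_cross("W", W, (n_p, n_d)),
    )


def apply_threshold(net: HetNet, tau: float = 0.5) -> HetNet:
    """Remove weak edges: every weight strictly below ``tau`` is set to 0.

    Weights equal to ``tau`` are kept ("less than" is read strictly).  The
    binary cross-type blocks are unaffected in practice since their entries
    are 0 or 1.  Thresholding twice is rejected: the operation is recorded in
    ``threshold_applied``.
    """
    if not 0.0 <= tau <= 1.0:
        raise ValueError(f"threshold tau={tau} outside [0, 1]")
    if net.threshold_applied:
        raise ValueError("network is already thresholded")

    def cut(block: np.ndarray) -> np.ndarray:
        out = block.copy()
        out[out < tau] = 0.0
        return out

    return replace(
        net,
        M=cut(net.M),
        P=cut(net.P),
        D=cut(net.D),
        B=cut(net.B),
        C=cut(net.C),
        W=cut(net.W),
        threshold_applied=True,
    )


# ---------------------------------------------------------------------------
# Edge-list and bundle I/O
#
# Edge lists are 3-column TSV (source_id, target_id, weight); '#' lines are
# comments.  Duplicate edges keep the maximum weight (strongest evidence
# wins).  A network bundle is a directory with one TSV per block, one id list
# per node type and an index.json naming the sizes.
# ---------------------------------------------------------------------------


def read_edge_list(
    path: str | Path,
    node_ids_a: Sequence[str],
    node_ids_b: Sequence[str],
    *,
    symmetrize: bool = False,
) -> np.ndarray:
    """Read a TSV edge list into a dense (len_a, len_b) block.

    Unknown identifiers, malformed lines and non-numeric weights raise
    ``ValueError`` with the line number.  ``symmetrize`` mirrors each edge,
    for intra-type blocks whose files list each undirected edge once.
    """
    path = Path(path)
    index_a = {v: i for i, v in enumerate(node_ids_a)}
    index_b = {v: i for i, v in enumerate(node_ids_b)}
    block = np.zeros((len(node_ids_a), len(node_ids_b)))
    n_edges = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 tab-separated columns, got {len(parts)}"
                )
            src, dst, weight_s = parts
            try:
                weight = float(weight_s)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric weight {weight_s!r}"
                ) from None
            if src not in index_a:
                raise ValueError(f"{path}:{lineno}: unknown source identifier {src!r}")
            if dst not in index_b:
                raise ValueError(f"{path}:{lineno}: unknown target identifier {dst!r}")
            i, j = index_a[src], index_b[dst]
            block[i, j] = max(block[i, j], weight)
            if symmetrize:
                block[j, i] = max(block[j, i], weight)
            n_edges += 1
    if n_edges == 0:
        warnings.warn(f"edge list {path} contains no edges", stacklevel=2)
    return block


def write_edge_list(
    block: np.ndarray,
    path: str | Path,
    node_ids_a: Sequence[str],
    node_ids_b: Sequence[str],
) -> None:
    """Write every nonzero entry of a block as a TSV edge list (full repr)."""
    block = np.asarray(block)
    with Path(path).open("w") as fh:
        fh.write("# source_id\ttarget_id\tweight\n")
        for i, j in zip(*np.nonzero(block)):
            fh.write(f"{node_ids_a[i]}\t{node_ids_b[j]}\t{float(block[i, j])!r}\n")


def read_node_ids(path: str | Path) -> tuple[str, ...]:
    with Path(path).open() as fh:
        return tuple(line.strip() for line in fh if line.strip())


def write_node_ids(ids: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{i}\n" for i in ids))


_BUNDLE_BLOCKS = ("M", "P", "D", "B", "C", "W")
_BLOCK_AXES = {
    "M": ("mirna", "mirna"),
    "P": ("protein", "protein"),
    "D": ("disease", "disease"),
    "B": ("mirna", "protein"),
    "C": ("mirna", "disease"),
    "W": ("protein", "disease"),
}


def write_bundle(net: HetNet, directory: str | Path) -> None:
    """Serialize a network as a bundle directory (one TSV per block)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ids = {
        "mirna": net.mirna_ids,
        "protein": net.protein_ids,
        "disease": net.disease_ids,
    }
    for kind, values in ids.items():
        write_node_ids(values, directory / f"{kind}_ids.txt")
    for name in _BUNDLE_BLOCKS:
        axis_a, axis_b = _BLOCK_AXES[name]
        write_edge_list(
            getattr(net, name), directory / f"{name}.tsv", ids[axis_a], ids[axis_b]
        )
    index = {
        "n_m": net.n_m,
        "n_p": net.n_p,
        "n_d": net.n_d,
        "threshold_applied": net.threshold_applied,
        "fingerprint": net.fingerprint(),
    }
    (directory / "index.json").write_text(json.dumps(index, indent=2) + "\n")


def read_bundle(directory: str | Path) -> HetNet:
    """Read a network bundle directory written by :func:`write_bundle`."""
    directory = Path(directory)
    index = json.loads((directory / "index.json").read_text())
    ids = {
        kind: read_node_ids(directory / f"{kind}_ids.txt")
        for kind in ("mirna", "protein", "disease")
    }
    for kind, key in (("mirna", "n_m"), ("protein", "n_p"), ("disease", "n_d")):
        if len(ids[kind]) != index[key]:
            raise ValueError(
                f"bundle {directory}: {key}={index[key]} but {len(ids[kind])} "
                f"{kind} ids listed"
            )
    blocks = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # empty blocks are legitimate in bundles
        for name in _BUNDLE_BLOCKS:
            axis_a, axis_b = _BLOCK_AXES[name]
            blocks[name] = read_edge_list(
                directory / f"{name}.tsv", ids[axis_a], ids[axis_b]
            )
    net = assemble_global(
        ids["mirna"], ids["protein"], ids["disease"], **blocks
    )
    if index.get("threshold_applied"):
        net = replace(net, threshold_applied=True)
    return net
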