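"""Labeled pair-feature tables for miRNA-disease classification.

A pair's feature vector is the concatenation of its miRNA diffusion
embedding (k values), its disease diffusion embedding (k values) and its
HeteSim metapath scores (39 values with the canonical paths), giving
2k + 39 features — 639 when k = 300.  Negative pairs are drawn uniformly
without replacement from all miRNA-disease pairs that are not known
associations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .diffusion import NodeEmbedding
from .hetesim import HeteSimFeature

__all__ = [
    "PairFeatureTable",
    "pair_features",
    "sample_negatives",
    "count_pairs",
    "read_pairs",
    "write_pairs",
]


@dataclass(frozen=True)
class PairFeatureTable:
    """Feature rows for (miRNA, disease) pairs with optional 0/1 labels.

    ``features`` has one row per pair; labels of -1 mean "unlabeled".
    ``provenance`` records the seed, the negative ratio and the fingerprint of
    the network the features were extracted from.
    """

    mirna_ids: tuple[str, ...]
    disease_ids: tuple[str, ...]
    labels: np.ndarray
    features: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.mirna_ids)
        if not (len(self.disease_ids) == len(self.labels) == self.features.shape[0] == n):
            raise ValueError("pair table columns have inconsistent lengths")
        pairs = list(zip(self.mirna_ids, self.disease_ids))
        if len(set(pairs)) != n:
            raise ValueError("duplicate (miRNA, disease) rows in pair table")

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def __len__(self) -> int:
        return len(self.mirna_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.features, columns=[f"f{i}" for i in range(self.n_features)]
        )
        df.insert(0, "label", self.labels)
        df.insert(0, "disease_id", self.disease_ids)
        df.insert(0, "miRNA_id", self.mirna_ids)
        return df

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def pair_features(
    embedding: NodeEmbedding,
    hfeat: HeteSimFeature,
    pairs: Sequence[tuple[str, str]],
    labels: Sequence[int] | None = None,
    provenance: dict | None = None,
) -> PairFeatureTable:
    """Assemble [miRNA embedding | disease embedding | HeteSim] rows.

    ``pairs`` are (miRNA_id, disease_id) tuples resolved against the ids the
    embedding and HeteSim tensor were computed with; an unknown identifier is
    an error.  Row order follows ``pairs`` exactly.
    """
    mirna_index = {v: i for i, v in enumerate(hfeat.mirna_ids)}
    disease_index = {v: i for i, v in enumerate(hfeat.disease_ids)}
    if tuple(embedding.node_ids[: embedding.n_m]) != hfeat.mirna_ids:
        raise ValueError("embedding and HeteSim features use different miRNA ids")
    m_vec = embedding.mirna_vectors()
    d_vec = embedding.disease_vectors()
    k = embedding.k
    rows = np.empty((len(pairs), 2 * k + hfeat.n_paths))
    for r, (m_id, d_id) in enumerate(pairs):
        if m_id not in mirna_index:
            raise KeyError(f"unknown miRNA identifier: {m_id!r}")
        if d_id not in disease_index:
            raise KeyError(f"unknown disease identifier: {d_id!r}")
        i, j = mirna_index[m_id], disease_index[d_id]
        rows[r, :k] = m_vec[i]
        rows[r, k : 2 * k] = d_vec[j]
        rows[r, 2 * k :] = hfeat.values[i, j]
    if labels is None:
        label_arr = np.full(len(pairs), -1, dtype=int)
    else:
        label_arr = np.asarray(labels, dtype=int)
    return PairFeatureTable(
        mirna_ids=tuple(p[0] for p in pairs),
        disease_ids=tuple(p[1] for p in pairs),
        labels=label_arr,
        features=rows,
        provenance=dict(provenance or {}),
    )


def count_pairs(n_m: int, n_d: int) -> int:
    """Total number of candidate miRNA-disease pairs."""
    return n_m * n_d


def sample_negatives(
    positives: Sequence[tuple[int, int]],
    n_m: int,
    n_d: int,
    ratio: int,
    seed: int,
) -> list[tuple[int, int]]:
    """Sample ``ratio * len(positives)`` negative (miRNA, disease) index pairs.

    Uniform without replacement from every pair that is not a known positive;
    deterministic for a fixed seed.  Raises when the non-positive pool is too
    small.
    """
    if ratio < 1 or int(ratio) != ratio:
        raise ValueError(f"ratio must be a positive integer, got {ratio}")
    positive_set = {i * n_d + j for i, j in positives}
    if len(positive_set) != len(positives):
        raise ValueError("duplicate positive pairs")
    total = count_pairs(n_m, n_d)
    n_neg = int(ratio) * len(positives)
    pool_size = total - len(positive_set)
    if n_neg > pool_size:
        raise ValueError(
            f"requested {n_neg} negatives but only {pool_size} non-positive pairs exist"
        )
    rng = np.random.default_rng(seed)
    if total <= 4_000_000:
        pool = np.setdiff1d(np.arange(total), np.fromiter(positive_set, dtype=int))
        chosen = rng.choice(pool, size=n_neg, replace=False)
    else:  # rejection sampling avoids materializing the full pair space
        chosen_set: set[int] = set()
        while len(chosen_set) < n_neg:
            draw = rng.integers(0, total, size=2 * (n_neg - len(chosen_set)))
            for lin in draw:
                lin = int(lin)
                if lin not in positive_set and lin not in chosen_set:
                    chosen_set.add(lin)
                    if len(chosen_set) == n_neg:
                        break
        chosen = np.fromiter(chosen_set, dtype=int)[:n_neg]
    return [(int(lin) // n_d, int(lin) % n_d) for lin in chosen]


def read_pairs(path: str | Path) -> list[tuple[str, str]]:
    """Read a 2-column TSV of (miRNA_id, disease_id) pairs."""
    pairs = []
    with Path(path).open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            pairs.append((parts[0], parts[1]))
    return pairs


def write_pairs(pairs: Sequence[tuple[str, str]], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("# miRNA_id\tdisease_id\n")
        for m, d in pairs:
            fh.write(f"{m}\t{d}\n")
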