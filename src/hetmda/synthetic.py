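"""Seeded synthetic heterogeneous networks with planted associations.

The generator emulates the structural traits of curated miRNA-protein-
disease data that matter to the prediction pipeline:

* symmetric weighted similarity blocks in [0, 1] for miRNAs, proteins and
  diseases, with weights drawn pre-threshold so the 0.5 edge cutoff is
  exercised;
* sparse binary cross-type background edges;
* planted miRNA-disease positives whose recoverable signal is mediated by
  shared protein neighbourhoods: proteins are partitioned into modules, each
  with a small core (a protein complex); every miRNA acts through one
  module, and a wired positive targets its module core (B edges) while the
  core associates with the disease (W edges), with strong intra-module
  protein-protein weights.  The wiring survives removal of the association
  edge itself, so the leakage-controlled protocol can in principle recover a
  held-out pair from its protein context;
* a heterogeneous association-degree structure, mixing three pair
  populations the way curated databases do: a few *hub* miRNAs/diseases
  carrying many associations (well-studied nodes), *triad groups* of miRNAs
  that share one disease and keep one private disease each (paralogous
  miRNA families), and uniformly spread singleton pairs.  The triad groups
  create non-associated pairs whose association-chain profile resembles a
  true pair's (a group mate's private disease), i.e. latent positives, which
  keeps label-adjacent path features from separating the training data
  outright.  The chains are one-sided: once a planted pair's own edge is
  held out, the association graph alone carries no trace of it, so at
  ``signal = 0`` held-out positives are indistinguishable from background.

``signal`` is the probability that a planted pair receives the module
wiring; it gates only the protein-layer signal, never the association
structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hetnet import HetNet, assemble_global

__all__ = ["SynthConfig", "generate"]

# wiring and population-shape constants (counts are capped by the network
# size, so small test instances degrade gracefully)
_CORE_SIZE = 4
_MODULE_PP_PROB = 0.7
_N_TRIAD_GROUPS = 8
_TRIAD_GROUP_SIZE = 4
_N_HUB_MIRNAS = 2
_N_HUB_DISEASES = 2
_HUB_DEGREE = 12


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; the defaults define the standard benchmark
    condition (50 miRNAs, 100 proteins, 40 diseases, 120 planted positives,
    fully wired signal)."""

    n_m: int = 50
    n_p: int = 100
    n_d: int = 40
    density_sim: float = 0.05
    density_cross: float = 0.02
    signal: float = 1.0
    n_modules: int = 32
    n_positives: int = 120
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("density_sim", "density_cross", "signal"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_positives > self.n_m * self.n_d:
            raise ValueError("more planted positives than miRNA-disease pairs")
        if self.n_modules < 1 or self.n_modules > self.n_p:
            raise ValueError(
                f"n_modules={self.n_modules} infeasible for {self.n_p} proteins "
                "(each module needs at least one protein to host the wiring)"
            )


def _random_similarity(rng: np.random.Generator, n: int, density: float) -> np.ndarray:
    """Symmetric block with uniform [0, 1] weights on a random edge set."""
    block = np.zeros((n, n))
    upper = np.triu_indices(n, k=1)
    mask = rng.random(len(upper[0])) < density
    weights = rng.random(len(upper[0])) * mask
    block[upper] = weights
    return block + block.T


def generate(config: SynthConfig) -> tuple[HetNet, list[tuple[int, int]]]:
    """Generate a network and its planted positive (miRNA, disease) pairs.

    Positives are drawn from three populations — triad groups, hubs and
    uniform singletons — and each is wired through its miRNA's module with
    probability ``signal``.  The same config and seed always reproduce the
    identical network.
    """
    rng = np.random.default_rng(config.seed)
    n_m, n_p, n_d = config.n_m, config.n_p, config.n_d

    M = _random_similarity(rng, n_m, config.density_sim)
    P = _random_similarity(rng, n_p, config.density_sim)
    D = _random_similarity(rng, n_d, config.density_sim)
    B = (rng.random((n_m, n_p)) < config.density_cross).astype(float)
    W = (rng.random((n_p, n_d)) < config.density_cross).astype(float)
    C = np.zeros((n_m, n_d))

    modules = np.array_split(np.arange(n_p), config.n_modules)
    cores = [
        rng.choice(members, size=min(_CORE_SIZE, len(members)), replace=False)
        for members in modules
    ]
    # one module per miRNA; random assignment lets modules recruit several
    # miRNAs, whose shared wiring supports each other's held-out pairs
    mirna_module = rng.integers(0, config.n_modules, size=n_m)

    seen: set[tuple[int, int]] = set()
    positives: list[tuple[int, int]] = []
    pair_module: list[int] = []

    def push(pair: tuple[int, int], mod: int) -> None:
        if pair not in seen and len(positives) < config.n_positives:
            seen.add(pair)
            positives.append(pair)
            pair_module.append(mod)

    # triad groups: miRNA families sharing one disease plus a private each;
    # the whole family acts through one module
    m_perm = list(rng.permutation(n_m))
    d_perm = list(rng.permutation(n_d))
    for _ in range(_N_TRIAD_GROUPS):
        if len(m_perm) < _TRIAD_GROUP_SIZE or len(d_perm) < _TRIAD_GROUP_SIZE + 1:
            break
        group = [m_perm.pop() for _ in range(_TRIAD_GROUP_SIZE)]
        shared = d_perm.pop()
        mod = int(rng.integers(0, config.n_modules))
        for m in group:
            private = d_perm.pop()
            for d in (shared, private):
                push((int(m), int(d)), mod)

    # hub nodes: a few well-studied miRNAs/diseases with many associations
    hub_ms = rng.choice(n_m, size=min(_N_HUB_MIRNAS, n_m), replace=False)
    hub_ds = rng.choice(n_d, size=min(_N_HUB_DISEASES, n_d), replace=False)
    for hm in hub_ms:
        for d in rng.choice(n_d, size=min(_HUB_DEGREE, n_d), replace=False):
            push((int(hm), int(d)), int(mirna_module[int(hm)]))
    for hd in hub_ds:
        for m in rng.choice(n_m, size=min(_HUB_DEGREE, n_m), replace=False):
            push((int(m), int(hd)), int(mirna_module[int(m)]))

    # uniform singleton remainder
    if len(positives) < config.n_positives:
        pool = [
            (i, j) for i in range(n_m) for j in range(n_d) if (i, j) not in seen
        ]
        extra = rng.choice(
            len(pool), size=config.n_positives - len(positives), replace=False
        )
        for idx in extra:
            pair = pool[int(idx)]
            push(pair, int(mirna_module[pair[0]]))

    for (i, j), mod in zip(positives, pair_module):
        C[i, j] = 1.0
        if rng.random() >= config.signal:
            continue
        core = cores[mod]
        members = modules[mod]
        B[i, core] = 1.0
        W[core, j] = 1.0
        # strong intra-module edges so M-P-P-D routes survive the threshold
        for a_i, a_p in enumerate(members):
            for b_p in members[a_i + 1 :]:
                if P[a_p, b_p] < 0.5 and rng.random() < _MODULE_PP_PROB:
                    w = 0.5 + 0.5 * rng.random()
                    P[a_p, b_p] = P[b_p, a_p] = w

    np.fill_diagonal(M, 0.0)
    np.fill_diagonal(P, 0.0)
    np.fill_diagonal(D, 0.0)

    net = assemble_global(
        [f"m{i}" for i in range(n_m)],
        [f"p{i}" for i in range(n_p)],
        [f"d{i}" for i in range(n_d)],
        M, P, D, B, C, W,
    )
    return net, positives
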