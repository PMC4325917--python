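"""Random Bayesian networks by iterated edge toggling (Ide-Cozman style).

The generator starts from the chain ``Z_1 → Z_2 → … → Z_K`` and repeatedly
draws an unordered node pair; the edge between the pair is added if absent
and removed if present, subject to two constraints that are checked before
accepting a toggle: no node may exceed a total degree cap (7 by default) and
the removal of an edge may not disconnect the graph.  Edges are stored
oriented from the lower to the higher node index, so the index order is a
topological order and the result is a DAG by construction.

Conditional probabilities ``p(Z_k = 1 | pa_k)`` are drawn i.i.d. from a
symmetric two-component Dirichlet — equivalently ``Beta(η, η)`` — for every
parent assignment.  Large ``η`` concentrates the conditionals near 0.5,
making the variables weakly coupled; small ``η`` pushes them toward the
extremes.  Draws are clipped to ``[1e-6, 1 − 1e-6]`` so downstream
compilation (which takes logs) stays finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph_model import BayesianNetwork

__all__ = ["GeneratorConfig", "generate_structure", "draw_conditionals", "generate"]

CLIP = 1e-6


@dataclass(frozen=True)
class GeneratorConfig:
    K: int = 5
    N: int = 50000
    eta: float = 1.0
    max_degree: int = 7
    seed: int = 0

    def __post_init__(self):
        if self.K < 2:
            raise ValueError("need at least two nodes")
        if self.N < 0:
            raise ValueError("iteration count must be nonnegative")
        if self.eta <= 0:
            raise ValueError("Dirichlet concentration must be positive")


def _connected(adj: np.ndarray) -> bool:
    """Weak connectivity of the undirected skeleton (boolean adjacency)."""
    K = adj.shape[0]
    seen = np.zeros(K, dtype=bool)
    stack = [0]
    seen[0] = True
    while stack:
        i = stack.pop()
        for j in np.flatnonzero(adj[i]):
            if not seen[j]:
                seen[j] = True
                stack.append(j)
    return bool(seen.all())


def generate_structure(config: GeneratorConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Edge-toggled random DAG as a boolean adjacency matrix.

    ``adj[i, j]`` (i < j) is True when the edge ``Z_i → Z_j`` exists.  With
    ``N = 0`` the initial chain is returned unchanged.  A toggle that would
    push a node past the degree cap or disconnect the graph is skipped (it
    still consumes an iteration).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    K = config.K
    adj = np.zeros((K, K), dtype=bool)
    for i in range(K - 1):
        adj[i, i + 1] = True
    for _ in range(config.N):
        i = int(rng.integers(K))
        j = int(rng.integers(K - 1))
        if j >= i:
            j += 1  # uniform unordered pair (i != j)
        lo, hi = (i, j) if i < j else (j, i)
        sym = adj | adj.T
        if adj[lo, hi]:
            adj[lo, hi] = False
            if not _connected(adj | adj.T):
                adj[lo, hi] = True
        else:
            if sym[lo].sum() >= config.max_degree or sym[hi].sum() >= config.max_degree:
                continue
            adj[lo, hi] = True
    return adj


def draw_conditionals(
    adj: np.ndarray, eta: float, rng: np.random.Generator | int | None = None
) -> BayesianNetwork:
    """Attach ``Beta(η, η)`` conditional probability tables to a DAG."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    K = adj.shape[0]
    node_ids = tuple(f"Z{k + 1}" for k in range(K))
    parents = {}
    cpt = {}
    for k in range(K):
        pa = tuple(node_ids[i] for i in np.flatnonzero(adj[:, k]))
        parents[node_ids[k]] = pa
        draws = rng.beta(eta, eta, size=2 ** len(pa))
        cpt[node_ids[k]] = np.clip(draws, CLIP, 1.0 - CLIP)
    return BayesianNetwork(node_ids, parents, cpt)


def generate(config: GeneratorConfig) -> BayesianNetwork:
    """Structure generation followed by conditional draws, fully seeded."""
    rng = np.random.default_rng(config.seed)
    adj = generate_structure(config, rng)
    return draw_conditionals(adj, config.eta, rng)
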