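"""Bayesian networks over binary random variables with exact inference.

A :class:`BayesianNetwork` is a DAG over binary RVs ``Z_k`` where every node
carries a conditional probability table (CPT) giving ``p(Z_k = 1 | pa_k)`` for
each assignment of its parents.  The joint distribution is the product of the
per-node conditionals.  For small networks the joint can be enumerated
exactly, which serves as the ground-truth oracle against which all samplers
in this package are judged.

State-index convention (shared by every module): a full assignment
``z = (z_0, ..., z_{K-1})`` maps to the integer ``sum_k z_k * 2**k``, i.e.
node 0 is the least-significant bit.  CPT rows are indexed the same way over
the node's parent list.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "BayesianNetwork",
    "JointDistribution",
    "enumerate_joint",
    "conditional_marginals",
    "read_network",
    "write_network",
]

#: Largest network size for which exact enumeration is attempted.
MAX_ENUMERABLE_NODES = 20


def _bits_to_index(bits: Sequence[int]) -> int:
    """Encode a binary vector as an integer, element 0 = least-significant bit."""
    idx = 0
    for pos, b in enumerate(bits):
        idx |= int(b) << pos
    return idx


@dataclass(frozen=True)
class BayesianNetwork:
    """Directed acyclic graphical model over binary random variables.

    Parameters
    ----------
    node_ids
        Ordered node labels; position in this list is the node index used in
        state vectors and bit encodings.
    parents
        For each node id, the list of parent node ids.
    cpt
        For each node id, an array of length ``2**len(parents)`` holding
        ``p(Z = 1 | pa)``; row ``r`` corresponds to the parent assignment
        whose bits (first parent = LSB) encode ``r``.
    """

    node_ids: tuple[str, ...]
    parents: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    cpt: Mapping[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "node_ids", tuple(self.node_ids))
        parents = {k: tuple(v) for k, v in self.parents.items()}
        cpt = {k: np.asarray(v, dtype=float).ravel() for k, v in self.cpt.items()}
        for nid in self.node_ids:
            parents.setdefault(nid, ())
            if nid not in cpt:
                raise ValueError(f"node {nid!r} has no CPT")
            n_rows = 2 ** len(parents[nid])
            if cpt[nid].size != n_rows:
                raise ValueError(
                    f"node {nid!r}: CPT has {cpt[nid].size} rows, expected {n_rows}"
                )
            if np.any(cpt[nid] < 0) or np.any(cpt[nid] > 1):
                raise ValueError(f"node {nid!r}: CPT entries must lie in [0, 1]")
            for p in parents[nid]:
                if p not in self.node_ids:
                    raise ValueError(f"node {nid!r}: unknown parent {p!r}")
        object.__setattr__(self, "parents", parents)
        object.__setattr__(self, "cpt", cpt)
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        # Kahn's algorithm on the parent relation.
        indeg = {nid: len(self.parents[nid]) for nid in self.node_ids}
        children: dict[str, list[str]] = {nid: [] for nid in self.node_ids}
        for nid in self.node_ids:
            for p in self.parents[nid]:
                children[p].append(nid)
        queue = [n for n, d in indeg.items() if d == 0]
        seen = 0
        while queue:
            n = queue.pop()
            seen += 1
            for c in children[n]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if seen != len(self.node_ids):
            raise ValueError("parent structure contains a cycle")

    # -- helpers ----------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def index_of(self, node_id: str) -> int:
        return self.node_ids.index(node_id)

    def parent_indices(self, node_id: str) -> tuple[int, ...]:
        return tuple(self.index_of(p) for p in self.parents[node_id])

    def node_conditional(self, node_id: str, z: Sequence[int]) -> float:
        """``p(z_k | pa_k)`` for the node's value in the full assignment ``z``."""
        k = self.index_of(node_id)
        row = _bits_to_index([z[i] for i in self.parent_indices(node_id)])
        p1 = float(self.cpt[node_id][row])
        return p1 if z[k] == 1 else 1.0 - p1

    def joint_probability(self, z: Sequence[int]) -> float:
        """Exact joint probability of a full assignment (product of conditionals)."""
        z = np.asarray(z, dtype=int).ravel()
        if z.size != self.n_nodes:
            raise ValueError(
                f"assignment has length {z.size}, expected {self.n_nodes}"
            )
        if np.any((z != 0) & (z != 1)):
            raise ValueError("assignment entries must be 0 or 1")
        prob = 1.0
        for nid in self.node_ids:
            prob *= self.node_conditional(nid, z)
        return prob


def joint_probability(bn: BayesianNetwork, z: Sequence[int]) -> float:
    """Functional alias for :meth:`BayesianNetwork.joint_probability`."""
    return bn.joint_probability(z)


@dataclass(frozen=True)
class JointDistribution:
    """Probabilities over all ``2**K`` full states, node 0 = LSB of the index."""

    node_ids: tuple[str, ...]
    probabilities: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.probabilities, dtype=float).ravel()
        if p.size != 2 ** len(self.node_ids):
            raise ValueError("probability vector has wrong length")
        if np.any(p < 0):
            raise ValueError("probabilities must be nonnegative")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1")
        object.__setattr__(self, "probabilities", p)
        object.__setattr__(self, "node_ids", tuple(self.node_ids))

    def marginals(self) -> np.ndarray:
        """Per-node ``p(Z_k = 1)``."""
        K = len(self.node_ids)
        states = _all_states(K)
        return states.T @ self.probabilities


def _all_states(K: int) -> np.ndarray:
    """(2**K, K) matrix of binary states; row ``s`` has bit k = (s >> k) & 1."""
    idx = np.arange(2**K)
    return ((idx[:, None] >> np.arange(K)[None, :]) & 1).astype(np.int8)


def enumerate_joint(bn: BayesianNetwork) -> JointDistribution:
    """Brute-force joint distribution of a Bayesian network.

    Guarded at :data:`MAX_ENUMERABLE_NODES` nodes; the result is normalized
    (the product of conditionals already sums to one, renormalization only
    guards round-off).
    """
    K = bn.n_nodes
    if K > MAX_ENUMERABLE_NODES:
        raise ValueError(f"{K} nodes exceed the enumeration guard ({MAX_ENUMERABLE_NODES})")
    states = _all_states(K)
    p = np.empty(2**K)
    for s in range(2**K):
        p[s] = bn.joint_probability(states[s])
    p /= p.sum()
    return JointDistribution(bn.node_ids, p)


def conditional_marginals(
    bn: BayesianNetwork, evidence: Mapping[str, int] | None = None
) -> dict[str, float]:
    """Exact ``p(Z_k = 1 | evidence)`` for every node, via enumeration.

    ``evidence`` maps node ids to observed values in {0, 1}; an empty or
    missing evidence dict yields the prior marginals.  Raises on evidence
    with zero probability.
    """
    evidence = dict(evidence or {})
    for nid, val in evidence.items():
        if nid not in bn.node_ids:
            raise ValueError(f"evidence on unknown node {nid!r}")
        if val not in (0, 1):
            raise ValueError("evidence values must be 0 or 1")
    joint = enumerate_joint(bn)
    K = bn.n_nodes
    states = _all_states(K)
    mask = np.ones(2**K, dtype=bool)
    for nid, val in evidence.items():
        mask &= states[:, bn.index_of(nid)] == val
    p_ev = joint.probabilities[mask].sum()
    if p_ev <= 0.0:
        raise ValueError("evidence has zero probability under the network")
    cond = joint.probabilities * mask / p_ev
    marg = states.T @ cond
    return {nid: float(marg[bn.index_of(nid)]) for nid in bn.node_ids}


def conditional_distribution(
    bn: BayesianNetwork, evidence: Mapping[str, int] | None = None
) -> JointDistribution:
    """Exact joint distribution conditioned on evidence (zero outside it)."""
    evidence = dict(evidence or {})
    joint = enumerate_joint(bn)
    states = _all_states(bn.n_nodes)
    mask = np.ones(states.shape[0], dtype=bool)
    for nid, val in evidence.items():
        mask &= states[:, bn.index_of(nid)] == val
    p = joint.probabilities * mask
    total = p.sum()
    if total <= 0.0:
        raise ValueError("evidence has zero probability under the network")
    return JointDistribution(bn.node_ids, p / total)


# -- JSON round trip -------------------------------------------------------


def distribution_to_dict(dist: JointDistribution) -> dict:
    """Distribution JSON: bitstring keys, node 0 first in each string."""
    K = len(dist.node_ids)
    return {
        "order": list(dist.node_ids),
        "p": {
            format(s, f"0{K}b")[::-1]: float(dist.probabilities[s])
            for s in range(2**K)
        },
    }


def distribution_from_dict(data: Mapping) -> JointDistribution:
    order = tuple(data["order"])
    K = len(order)
    p = np.zeros(2**K)
    for bits, prob in data["p"].items():
        p[_bits_to_index([int(c) for c in bits])] = prob
    return JointDistribution(order, p)


def network_to_dict(bn: BayesianNetwork) -> dict:
    return {
        "nodes": list(bn.node_ids),
        "parents": {nid: list(bn.parents[nid]) for nid in bn.node_ids},
        "cpt": {nid: [float(v) for v in bn.cpt[nid]] for nid in bn.node_ids},
    }


def network_from_dict(data: Mapping) -> BayesianNetwork:
    try:
        nodes = data["nodes"]
        parents = data.get("parents", {})
        cpt = data["cpt"]
    except (KeyError, TypeError) as exc:
        raise ValueError(f"malformed network description: {exc}") from exc
    return BayesianNetwork(tuple(nodes), parents, cpt)


def write_network(bn: BayesianNetwork, path) -> None:
    """Serialize a network to the package's JSON dialect."""
    with open(path, "w") as fh:
        json.dump(network_to_dict(bn), fh, indent=1)


def read_network(path) -> BayesianNetwork:
    """Load a network from the package's JSON dialect."""
    with open(path) as fh:
        data = json.load(fh)
    return network_from_dict(data)
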