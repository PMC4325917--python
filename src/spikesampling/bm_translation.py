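"""Compile Bayesian networks into Boltzmann machines with auxiliary units.

Every node of the Bayesian network contributes one factor over the node and
its parents.  First- and second-order factors translate directly into biases
and pairwise couplings of a binary Markov random field.  An order-``n``
factor with ``n > 2`` is expanded: one auxiliary binary unit per assignment
of the factor's member variables (``2**n`` of them), coupled to the member
("principal") units with large weights ``+M`` / ``-M`` so that exactly the
auxiliary unit matching the current principal assignment tends to be active,
and an auxiliary bias that encodes the factor value.  Marginalized over the
auxiliary units, the resulting Boltzmann distribution

    p(z) ∝ exp(½ zᵀ W z + zᵀ b)

approaches the network's joint over the principal units as ``M`` grows.

``M`` is set per factor to ``γ · max(Φ)`` with ``γ = 10`` by default
(``γ = 5`` in the noisy operating profile).  Factor tables are the raw
conditional probabilities; the auxiliary bias normalizes each table by its
minimum, with a guard factor ``μ = 1 + 1e-4`` keeping the logarithm finite
at the minimum entry.  Per-factor rescalings would cancel in the global
normalizer, so none is applied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .graph_model import BayesianNetwork, JointDistribution, _all_states

__all__ = [
    "FactorSpec",
    "BoltzmannMachine",
    "factors_from_network",
    "build_boltzmann",
    "boltzmann_distribution",
    "clamp",
    "GAMMA_DEFAULT",
    "MU_DEFAULT",
    "CLAMP_BIAS",
]

GAMMA_DEFAULT = 10.0   # coupling strength multiplier for auxiliary units
GAMMA_NOISY = 5.0
MU_DEFAULT = 1.0 + 1e-4  # keeps log(μ·Φ/min − 1) finite at the table minimum
CLAMP_BIAS = 20.0      # bias magnitude used to pin observed units


@dataclass(frozen=True)
class FactorSpec:
    """One factor of the network's product form (strictly positive table).

    ``members`` lists the indices of the RVs the factor depends on (the node
    itself first, then its parents); ``table[r]`` is the factor value for the
    member assignment whose bits (member 0 = LSB) encode ``r``.
    """

    factor_id: str
    members: tuple[int, ...]
    table: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.table, dtype=float).ravel()
        if t.size != 2 ** len(self.members):
            raise ValueError("factor table size does not match member count")
        if np.any(t <= 0.0):
            raise ValueError("factor tables must be strictly positive")
        object.__setattr__(self, "table", t)
        object.__setattr__(self, "members", tuple(int(m) for m in self.members))

    @property
    def order(self) -> int:
        return len(self.members)


def factors_from_network(bn: BayesianNetwork) -> list[FactorSpec]:
    """One factor per node, over (node, parents), from the CPT.

    Requires every CPT entry strictly inside (0, 1): a hard 0 or 1 would send
    a downstream log to −∞.
    """
    factors = []
    for nid in bn.node_ids:
        cpt = bn.cpt[nid]
        if np.any(cpt <= 0.0) or np.any(cpt >= 1.0):
            raise ValueError(
                f"node {nid!r}: CPT entries must lie strictly in (0, 1) for compilation"
            )
        k = bn.index_of(nid)
        pa = bn.parent_indices(nid)
        members = (k,) + pa
        n = len(members)
        table = np.empty(2**n)
        for r in range(2**n):
            zk = r & 1                 # member 0 (the node itself) is the LSB
            pa_row = r >> 1            # remaining bits encode the parent row
            p1 = cpt[pa_row]
            table[r] = p1 if zk == 1 else 1.0 - p1
        factors.append(FactorSpec(factor_id=nid, members=members, table=table))
    return factors


@dataclass(frozen=True)
class BoltzmannMachine:
    """Symmetric pairwise binary MRF with principal/auxiliary unit roles.

    ``W`` is symmetric with zero diagonal; ``b`` is the bias vector.  Units
    ``0..K-1`` are the principal units (one per source RV, same order);
    auxiliary units follow.  ``aux_map`` records, for each auxiliary unit,
    the originating factor id and the member assignment it encodes.
    ``clamp`` maps principal unit indices to pinned values in {0, 1}.
    """

    W: np.ndarray
    b: np.ndarray
    roles: tuple[str, ...]
    rv_map: Mapping[int, str] = field(default_factory=dict)
    aux_map: Mapping[int, tuple[str, int]] = field(default_factory=dict)
    clamp: Mapping[int, int] = field(default_factory=dict)

    def __post_init__(self):
        W = np.asarray(self.W, dtype=float)
        b = np.asarray(self.b, dtype=float).ravel()
        n = b.size
        if W.shape != (n, n):
            raise ValueError("W must be square and match b")
        if not np.allclose(W, W.T, atol=1e-12):
            raise ValueError("W must be symmetric")
        if np.any(np.abs(np.diag(W)) > 1e-12):
            raise ValueError("W must have zero diagonal")
        object.__setattr__(self, "W", W)
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "roles", tuple(self.roles))
        object.__setattr__(self, "rv_map", dict(self.rv_map))
        object.__setattr__(self, "aux_map", dict(self.aux_map))
        object.__setattr__(self, "clamp", dict(self.clamp))
        for u, v in self.clamp.items():
            if self.roles[u] != "principal":
                raise ValueError("clamping is only defined for principal units")
            if v not in (0, 1):
                raise ValueError("clamp values must be 0 or 1")

    @property
    def n_units(self) -> int:
        return self.b.size

    @property
    def principal_indices(self) -> tuple[int, ...]:
        return tuple(i for i, r in enumerate(self.roles) if r == "principal")

    def effective_bias(self) -> np.ndarray:
        """Biases with clamped units overridden by ±CLAMP_BIAS."""
        b = self.b.copy()
        for u, v in self.clamp.items():
            b[u] = CLAMP_BIAS if v == 1 else -CLAMP_BIAS
        return b


def direct_terms(factor: FactorSpec) -> tuple[np.ndarray, dict[int, float]]:
    """Couplings and biases for a factor of order 1 or 2.

    Returns ``(pairs, biases)`` where ``pairs`` is an array of rows
    ``(i, j, w)`` (empty for order 1) and ``biases`` maps unit index to bias
    increment.  For order 2 over members (i, j):

        W_ij = log[Φ(0,0)Φ(1,1) / (Φ(0,1)Φ(1,0))]
        b_i += log[Φ(1,0)/Φ(0,0)],  b_j += log[Φ(0,1)/Φ(0,0)]
    """
    t = factor.table
    if factor.order == 1:
        (i,) = factor.members
        return np.empty((0, 3)), {i: float(np.log(t[1] / t[0]))}
    if factor.order == 2:
        i, j = factor.members
        w = float(np.log(t[0] * t[3] / (t[1] * t[2])))
        biases = {
            i: float(np.log(t[1] / t[0])),   # member i is the LSB: Φ(1,0)/Φ(0,0)
            j: float(np.log(t[2] / t[0])),
        }
        return np.array([[i, j, w]]), biases
    raise ValueError("direct_terms handles only factors of order 1 or 2")


def expand_factor(
    factor: FactorSpec, gamma: float = GAMMA_DEFAULT, mu: float = MU_DEFAULT
) -> tuple[np.ndarray, np.ndarray, float]:
    """Auxiliary expansion of a factor of order n > 2.

    Returns ``(couplings, aux_biases, M)`` where ``couplings[a, i]`` is the
    weight between auxiliary unit ``a`` (encoding member assignment ``a``)
    and member ``i`` of the factor: ``+M`` if bit i of ``a`` is set, ``−M``
    otherwise, with ``M = γ · max(Φ)``.  The auxiliary bias is

        a_X = log(μ Φ(z) / min Φ − 1) − L¹(z) · M .
    """
    if factor.order <= 2:
        raise ValueError("expand_factor requires a factor of order > 2")
    t = factor.table
    n = factor.order
    M = gamma * float(t.max())
    n_aux = 2**n
    couplings = np.empty((n_aux, n))
    aux_biases = np.empty(n_aux)
    tmin = float(t.min())
    for a in range(n_aux):
        bits = [(a >> i) & 1 for i in range(n)]
        inner = mu * t[a] / tmin - 1.0
        if not inner > 0.0:
            raise ValueError("auxiliary bias undefined: factor entry at or below min/μ")
        aux_biases[a] = np.log(inner) - sum(bits) * M
        for i in range(n):
            couplings[a, i] = M if bits[i] else -M
    return couplings, aux_biases, M


def build_boltzmann(
    bn: BayesianNetwork,
    gamma: float = GAMMA_DEFAULT,
    mu: float = MU_DEFAULT,
) -> BoltzmannMachine:
    """Compile a Bayesian network into a Boltzmann machine.

    Principal units come first (one per node, same order as ``bn.node_ids``);
    each factor of order > 2 then appends its ``2**n`` auxiliary units.
    """
    factors = factors_from_network(bn)
    K = bn.n_nodes
    n_aux_total = sum(2**f.order for f in factors if f.order > 2)
    n = K + n_aux_total
    W = np.zeros((n, n))
    b = np.zeros(n)
    roles = ["principal"] * K
    rv_map = {i: bn.node_ids[i] for i in range(K)}
    aux_map: dict[int, tuple[str, int]] = {}
    next_aux = K
    for f in factors:
        if f.order <= 2:
            pairs, biases = direct_terms(f)
            for i, j, w in pairs:
                i, j = int(i), int(j)
                W[i, j] += w
                W[j, i] += w
            for i, db in biases.items():
                b[i] += db
        else:
            couplings, aux_biases, _M = expand_factor(f, gamma=gamma, mu=mu)
            for a in range(couplings.shape[0]):
                u = next_aux
                roles.append("auxiliary")
                aux_map[u] = (f.factor_id, a)
                b[u] = aux_biases[a]
                for pos, i in enumerate(f.members):
                    W[u, i] = couplings[a, pos]
                    W[i, u] = couplings[a, pos]
                next_aux += 1
    return BoltzmannMachine(W=W, b=b, roles=tuple(roles), rv_map=rv_map, aux_map=aux_map)


def boltzmann_distribution(bm: BoltzmannMachine) -> JointDistribution:
    """Exact Boltzmann distribution over all units by enumeration (≤ 20 units).

    Clamped units are conditioned on exactly: states violating a clamp get
    probability zero.
    """
    n = bm.n_units
    if n > 20:
        raise ValueError(f"{n} units exceed the enumeration guard (20)")
    states = _all_states(n).astype(float)
    b = bm.effective_bias()
    energies = 0.5 * np.einsum("si,ij,sj->s", states, bm.W, states) + states @ b
    energies -= energies.max()
    p = np.exp(energies)
    if bm.clamp:
        mask = np.ones(states.shape[0], dtype=bool)
        for u, v in bm.clamp.items():
            mask &= states[:, u] == v
        p *= mask
    p /= p.sum()
    unit_ids = tuple(
        bm.rv_map.get(i, f"aux{i}") if bm.roles[i] == "principal" else f"aux{i}"
        for i in range(n)
    )
    return JointDistribution(unit_ids, p)


def principal_distribution(bm: BoltzmannMachine) -> np.ndarray:
    """Marginal of the enumerated Boltzmann distribution over principal units.

    Returned as a vector over ``2**K`` principal states (principal unit 0 =
    LSB), marginalizing the auxiliary units.
    """
    dist = boltzmann_distribution(bm)
    principals = bm.principal_indices
    K = len(principals)
    n = bm.n_units
    states = _all_states(n)
    weights = 2 ** np.arange(K)
    idx = states[:, list(principals)] @ weights
    out = np.zeros(2**K)
    np.add.at(out, idx, dist.probabilities)
    return out


def clamp(bm: BoltzmannMachine, evidence: Mapping[str | int, int]) -> BoltzmannMachine:
    """Pin observed principal units by driving their biases to ±20.

    ``evidence`` maps RV names (or principal unit indices) to values in
    {0, 1}.  Returns a copy; the clamp is recorded so exact evaluation can
    condition on it.
    """
    rv_index = {name: i for i, name in bm.rv_map.items()}
    new_clamp = dict(bm.clamp)
    for key, val in evidence.items():
        u = rv_index.get(key, key if isinstance(key, int) else None)
        if u is None or not isinstance(u, (int, np.integer)):
            raise ValueError(f"unknown principal unit {key!r}")
        u = int(u)
        if bm.roles[u] != "principal":
            raise ValueError("cannot clamp an auxiliary unit")
        if val not in (0, 1):
            raise ValueError("clamp values must be 0 or 1")
        new_clamp[u] = int(val)
    return replace(bm, clamp=new_clamp)


# -- JSON round trip -------------------------------------------------------


def bm_to_dict(bm: BoltzmannMachine) -> dict:
    return {
        "W": bm.W.tolist(),
        "b": bm.b.tolist(),
        "roles": list(bm.roles),
        "rv_map": {str(k): v for k, v in bm.rv_map.items()},
        "aux_map": {str(k): list(v) for k, v in bm.aux_map.items()},
        "clamp": {str(k): v for k, v in bm.clamp.items()},
    }


def bm_from_dict(data: Mapping) -> BoltzmannMachine:
    return BoltzmannMachine(
        W=np.asarray(data["W"], dtype=float),
        b=np.asarray(data["b"], dtype=float),
        roles=tuple(data["roles"]),
        rv_map={int(k): v for k, v in data.get("rv_map", {}).items()},
        aux_map={int(k): tuple(v) for k, v in data.get("aux_map", {}).items()},
        clamp={int(k): int(v) for k, v in data.get("clamp", {}).items()},
    )


def write_bm(bm: BoltzmannMachine, path) -> None:
    with open(path, "w") as fh:
        json.dump(bm_to_dict(bm), fh)


def read_bm(path) -> BoltzmannMachine:
    with open(path) as fh:
        return bm_from_dict(json.load(fh))
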