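"""Abstract stochastic-neuron MCMC sampler for Boltzmann distributions.

Each binary unit ``Z_k`` carries a refractory variable ``ζ_k ∈ {0, …, τ}``:
a spike sets ``ζ_k = τ`` and the unit stays in state 1 while ``ζ_k ≥ 1``,
with ``ζ_k`` decreasing by one per time step.  A unit with ``ζ_k ∈ {0, 1}``
spikes with probability ``σ(v_k − log τ)`` where

    v_k = b_k + Σ_i W_ki Z_i(t)

is the membrane potential under rectangular postsynaptic potentials (PSPs).
One time step performs a full sweep over the units in random order; with
rectangular PSPs the chain's stationary state distribution is exactly the
Boltzmann distribution ``p(z) ∝ exp(½ zᵀWz + zᵀb)``, so this sampler is the
reference against which the LIF implementation is compared.

An alternative alpha-shaped PSP kernel (a biologically inspired,
non-rectangular interaction) replaces the state indicator ``Z_i(t)`` in the
potential by a superposition of kernels over past spikes; it is no longer
exact and serves as a comparison model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from numba import njit
from scipy.optimize import brentq

from .bm_translation import BoltzmannMachine

__all__ = [
    "PSPKernel",
    "SamplerTrace",
    "alpha_kernel_roots",
    "alpha_kernel",
    "membrane_potential",
    "update_step",
    "run_sampler",
    "TAU_DEFAULT",
]

#: Refractory period in update steps.  With one step per millisecond this
#: matches the 20 ms refractory period of the LIF regime, and keeps
#: ``log τ`` moderate.
TAU_DEFAULT = 20

ALPHA_Q1 = 2.3  # amplitude scale of the alpha kernel


def alpha_kernel_roots() -> tuple[float, float]:
    """The two positive solutions of ``e · t · exp(−t) = 1/2``, t1 < t2."""
    f = lambda t: np.e * t * np.exp(-t) - 0.5
    t1 = brentq(f, 1e-12, 1.0, xtol=1e-14)
    t2 = brentq(f, 1.0, 20.0, xtol=1e-14)
    return float(t1), float(t2)


@dataclass(frozen=True)
class PSPKernel:
    """Interaction kernel of the abstract sampler, in units of update steps.

    The rectangular kernel equals 1 on ``(0, τ_ref)`` and 0 elsewhere.  The
    alpha kernel is ``q1 · [e · (t/τ_α + t1) · exp(−t/τ_α − t1) − 1/2]`` on
    ``(0, (t2 − t1) τ_α)`` with ``q1 = 2.3`` and ``τ_α = 17 ms · τ_ref/30 ms``
    (expressed in steps at 1 ms per step).
    """

    kind: Literal["rectangular", "alpha"] = "rectangular"
    tau_ref: int = TAU_DEFAULT
    q1: float = ALPHA_Q1
    t1: float = field(default=None)  # type: ignore[assignment]
    t2: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.t1 is None or self.t2 is None:
            t1, t2 = alpha_kernel_roots()
            object.__setattr__(self, "t1", t1)
            object.__setattr__(self, "t2", t2)

    @property
    def tau_alpha(self) -> float:
        return 17.0 * self.tau_ref / 30.0

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        """Kernel value at time(s) ``t`` (in steps) after a presynaptic spike."""
        t = np.asarray(t, dtype=float)
        if self.kind == "rectangular":
            return ((t > 0) & (t < self.tau_ref)).astype(float)
        ta = self.tau_alpha
        support = (t > 0) & (t < (self.t2 - self.t1) * ta)
        x = t / ta + self.t1
        val = self.q1 * (np.e * x * np.exp(-x) - 0.5)
        return np.where(support, val, 0.0)

    def sampled(self) -> np.ndarray:
        """Kernel tabulated at integer step offsets (index 0 = spike step)."""
        if self.kind == "rectangular":
            # A unit is in state 1 for τ steps starting at its spike step, so
            # the tabulated indicator spans offsets 0..τ-1.
            k = np.zeros(self.tau_ref + 1)
            k[: self.tau_ref] = 1.0
            return k
        length = int(np.ceil((self.t2 - self.t1) * self.tau_alpha)) + 1
        return self.evaluate(np.arange(length, dtype=float))


def alpha_kernel(t: np.ndarray, tau_ref: int = TAU_DEFAULT) -> np.ndarray:
    """Convenience: alpha kernel values at times ``t`` (steps)."""
    return PSPKernel(kind="alpha", tau_ref=tau_ref).evaluate(t)


@dataclass
class SamplerTrace:
    """Output of a sampling run: per-step states plus spikes.

    ``z`` has shape (steps, units); ``spike_steps``/``spike_units`` list the
    spikes in order of occurrence.
    """

    z: np.ndarray
    spike_steps: np.ndarray
    spike_units: np.ndarray
    tau: int
    seed: int | None = None

    def save_spikes(self, path) -> None:
        """Two-column text output: step, unit id."""
        np.savetxt(
            path,
            np.column_stack([self.spike_steps, self.spike_units]),
            fmt="%d",
            header="step unit",
        )


def membrane_potential(
    z: np.ndarray, W: np.ndarray, b: np.ndarray, kernel: PSPKernel | None = None,
    spike_history: list[tuple[int, int]] | None = None, t: int | None = None,
) -> np.ndarray:
    """Membrane potentials of all units.

    Rectangular mode (default) depends only on the instantaneous state:
    ``v = b + W z``.  Alpha mode superposes kernel values over the spike
    history, a list of ``(step, unit)`` pairs, evaluated at time ``t``.
    """
    if kernel is None or kernel.kind == "rectangular":
        return b + W @ np.asarray(z, dtype=float)
    if spike_history is None or t is None:
        raise ValueError("alpha mode requires spike_history and current time")
    act = np.zeros_like(b)
    for ts, unit in spike_history:
        act[unit] += float(kernel.evaluate(np.array(t - ts, dtype=float)))
    return b + W @ act


def update_step(
    z: np.ndarray,
    zeta: np.ndarray,
    W: np.ndarray,
    b: np.ndarray,
    tau: int = TAU_DEFAULT,
    rng: np.random.Generator | None = None,
    order: np.ndarray | None = None,
    clamped: np.ndarray | None = None,
) -> list[int]:
    """One full sweep of the refractory-variable Markov chain, in place.

    Units are visited in random order (or the given ``order``).  A unit with
    ``ζ ≥ 2`` counts down and stays in state 1; a unit with ``ζ ∈ {0, 1}``
    spikes with probability ``σ(v − log τ)``.  Returns the indices of units
    that spiked during the sweep.  Reference implementation in pure Python;
    :func:`run_sampler` uses a compiled equivalent.
    """
    if tau < 2:
        raise ValueError("refractory length must be at least 2 steps")
    if rng is None:
        rng = np.random.default_rng()
    n = b.size
    if order is None:
        order = rng.permutation(n)
    log_tau = np.log(tau)
    spiked = []
    for k in order:
        if clamped is not None and clamped[k]:
            continue
        if zeta[k] >= 2:
            zeta[k] -= 1
            z[k] = 1
        else:
            v = b[k] + W[k] @ z
            p = 1.0 / (1.0 + np.exp(-np.clip(v - log_tau, -700.0, 700.0)))
            if rng.random() < p:
                zeta[k] = tau
                z[k] = 1
                spiked.append(int(k))
            else:
                zeta[k] = 0
                z[k] = 0
    return spiked


@njit(cache=True)
def _run_rect(W, b, tau, steps, seed, clamped, z0, zeta0):  # pragma: no cover
    np.random.seed(seed)
    n = b.size
    z = z0.copy()
    zeta = zeta0.copy()
    trace = np.zeros((steps, n), dtype=np.uint8)
    max_spikes = n * (steps // tau + 2)
    spike_steps = np.empty(max_spikes, dtype=np.int64)
    spike_units = np.empty(max_spikes, dtype=np.int64)
    ns = 0
    log_tau = np.log(tau)
    for t in range(steps):
        order = np.random.permutation(n)
        for oi in range(n):
            k = order[oi]
            if clamped[k]:
                continue
            if zeta[k] >= 2:
                zeta[k] -= 1
                z[k] = 1
            else:
                v = b[k]
                for i in range(n):
                    v += W[k, i] * z[i]
                p = 1.0 / (1.0 + np.exp(-(v - log_tau)))
                if np.random.random() < p:
                    zeta[k] = tau
                    z[k] = 1
                    spike_steps[ns] = t
                    spike_units[ns] = k
                    ns += 1
                else:
                    zeta[k] = 0
                    z[k] = 0
        # clamped-on units fire at the maximum rate (one spike per
        # refractory period); their state never changes
        for i in range(n):
            if clamped[i] and z[i] == 1 and t % tau == 0:
                spike_steps[ns] = t
                spike_units[ns] = i
                ns += 1
        for i in range(n):
            trace[t, i] = z[i]
    return trace, spike_steps[:ns], spike_units[:ns]


@njit(cache=True)
def _run_alpha(W, b, tau, steps, seed, clamped, z0, zeta0, kern):  # pragma: no cover
    np.random.seed(seed)
    n = b.size
    z = z0.copy()
    zeta = zeta0.copy()
    D = kern.size
    sched = np.zeros((D, n))
    trace = np.zeros((steps, n), dtype=np.uint8)
    max_spikes = n * (steps // tau + 2)
    spike_steps = np.empty(max_spikes, dtype=np.int64)
    spike_units = np.empty(max_spikes, dtype=np.int64)
    ns = 0
    log_tau = np.log(tau)
    act = np.zeros(n)
    for t in range(steps):
        row = t % D
        for i in range(n):
            act[i] = z[i] if clamped[i] else sched[row, i]
            sched[row, i] = 0.0
        order = np.random.permutation(n)
        for oi in range(n):
            k = order[oi]
            if clamped[k]:
                continue
            if zeta[k] >= 2:
                zeta[k] -= 1
                z[k] = 1
            else:
                v = b[k]
                for i in range(n):
                    v += W[k, i] * act[i]
                p = 1.0 / (1.0 + np.exp(-(v - log_tau)))
                if np.random.random() < p:
                    zeta[k] = tau
                    z[k] = 1
                    spike_steps[ns] = t
                    spike_units[ns] = k
                    ns += 1
                    for d in range(1, D):
                        sched[(t + d) % D, k] += kern[d]
                else:
                    zeta[k] = 0
                    z[k] = 0
        for i in range(n):
            if clamped[i] and z[i] == 1 and t % tau == 0:
                spike_steps[ns] = t
                spike_units[ns] = i
                ns += 1
        for i in range(n):
            trace[t, i] = z[i]
    return trace, spike_steps[:ns], spike_units[:ns]


def run_sampler(
    bm: BoltzmannMachine,
    steps: int,
    tau: int = TAU_DEFAULT,
    kernel: str | PSPKernel = "rectangular",
    seed: int = 0,
) -> SamplerTrace:
    """Sample from a Boltzmann machine with the stochastic-neuron chain.

    Clamped units never transition: their state is pinned to the clamp value
    (``ζ`` held at ``τ`` for value 1, at 0 for value 0) and they contribute
    their fixed state to every membrane potential.
    """
    if steps < 1:
        raise ValueError("need at least one step")
    if isinstance(kernel, str):
        kernel = PSPKernel(kind=kernel, tau_ref=tau)
    n = bm.n_units
    b = bm.effective_bias()
    clamped = np.zeros(n, dtype=np.bool_)
    z0 = np.zeros(n, dtype=np.uint8)
    zeta0 = np.zeros(n, dtype=np.int64)
    for u, v in bm.clamp.items():
        clamped[u] = True
        z0[u] = v
        zeta0[u] = tau if v == 1 else 0
    if kernel.kind == "rectangular":
        trace, ss, su = _run_rect(bm.W, b, tau, int(steps), int(seed), clamped, z0, zeta0)
    else:
        kern = kernel.sampled()
        trace, ss, su = _run_alpha(
            bm.W, b, tau, int(steps), int(seed), clamped, z0, zeta0, kern
        )
    return SamplerTrace(z=trace, spike_steps=ss, spike_units=su, tau=tau, seed=seed)
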