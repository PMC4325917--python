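"""Conductance-based LIF network simulation in the high-conductance state.

Neurons follow the leaky integrate-and-fire dynamics

    C_m du/dt = g_l (E_l − u) + Σ_syn w (E_rev − u) e^{−(t−t_s)/τ_syn}

with threshold θ, reset ρ and absolute refractory period τ_ref, driven into
a stochastic regime by intense Poisson background bombardment.  Recurrent
synapses are *renewing*: each presynaptic spike sets the synaptic
conductance to the weight rather than incrementing it (the Tsodyks-Markram
short-term-depression limit with full utilization, U0 = 1, τ_facil = 0,
τ_rec = 0.99 τ_syn), so PSPs of width ≈ τ_ref do not superpose — mirroring
the non-superposing rectangular interaction of the abstract sampler.

The refractory spike response defines the binary state: a neuron represents
``Z = 1`` during the τ_ref window following each of its spikes.

Two named operating profiles ship with the module: ``"standard"`` (the
reference parameter set) and ``"noisy"`` (a second operating point with
slower synapses and stronger background, used together with per-neuron
parameter jitter in the robustness experiments).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from ._lif_engine import run_network

__all__ = [
    "LIFParams",
    "Synapse",
    "BackgroundSource",
    "PoissonBackground",
    "StimulusSpike",
    "LIFNetworkSpec",
    "SimulationResult",
    "NoiseProfile",
    "integrate",
    "renewing_conductance",
    "states_from_spikes",
    "build_background",
    "build_correlated_background",
    "sample_background_counts",
    "apply_parameter_noise",
    "STANDARD_PROFILE",
    "NOISY_PROFILE",
]


@dataclass(frozen=True)
class LIFParams:
    """Single-neuron parameters (Table-style standard values as defaults).

    Units: capacitance nF, conductance μS, time ms, voltage mV.  ``tau_m``
    is the membrane time constant; the leak conductance is ``C_m / tau_m``.
    """

    C_m: float = 0.2            # nF
    tau_m: float = 0.1          # ms
    E_l: float = -50.0          # mV, set per neuron by the bias translation
    V_th: float = -50.0         # mV
    V_reset: float = -53.0      # mV
    tau_ref: float = 20.0       # ms
    tau_syn_exc: float = 10.0   # ms
    tau_syn_inh: float = 10.0   # ms
    E_rev_exc: float = 0.0      # mV
    E_rev_inh: float = -100.0   # mV
    U0: float = 1.0             # short-term plasticity: full utilization
    tau_facil: float = 0.0      # ms
    const_g_exc: float = 0.0    # μS, constant added conductance (deterministic drive)
    const_g_inh: float = 0.0    # μS

    def __post_init__(self):
        if min(self.tau_m, self.tau_ref, self.tau_syn_exc, self.tau_syn_inh) <= 0:
            raise ValueError("time constants must be positive")
        if not (self.E_rev_inh < self.V_th < self.E_rev_exc):
            raise ValueError("need E_rev_inh < V_th < E_rev_exc")

    @property
    def g_l(self) -> float:
        return self.C_m / self.tau_m

    @property
    def tau_rec(self) -> float:
        """Recovery time constant of the depressing synapse model."""
        return 0.99 * self.tau_syn_exc


@dataclass(frozen=True)
class Synapse:
    """Directed synapse; the sign of ``weight`` selects the reversal potential."""

    pre: int
    post: int
    weight: float        # μS, signed: > 0 excitatory, < 0 inhibitory
    delay: float = 0.1   # ms
    renewing: bool = True

    @property
    def excitatory(self) -> bool:
        return self.weight >= 0


@dataclass(frozen=True)
class BackgroundSource:
    """Poisson spike source projecting identical conductance kicks to targets."""

    rate: float            # Hz
    weight: float          # μS (magnitude)
    excitatory: bool
    targets: tuple[int, ...]


@dataclass(frozen=True)
class PoissonBackground:
    sources: tuple[BackgroundSource, ...] = ()

    def rate_onto(self, neuron: int, excitatory: bool = True) -> float:
        """Summed source rate projecting onto one neuron and polarity."""
        return sum(
            s.rate
            for s in self.sources
            if s.excitatory == excitatory and neuron in s.targets
        )


@dataclass(frozen=True)
class StimulusSpike:
    """Externally scheduled presynaptic spike (signed weight as for synapses)."""

    time: float    # ms
    target: int
    weight: float  # μS, signed


@dataclass(frozen=True)
class LIFNetworkSpec:
    neurons: tuple[LIFParams, ...]
    synapses: tuple[Synapse, ...] = ()
    background: PoissonBackground = PoissonBackground()
    stimuli: tuple[StimulusSpike, ...] = ()
    #: indices of the neurons whose spikes encode RV states (all by default)
    principal_neurons: tuple[int, ...] | None = None
    #: per-principal refractory window used for state read-out, ms
    state_tau_ref: float | None = None

    @property
    def n_neurons(self) -> int:
        return len(self.neurons)


@dataclass
class SimulationResult:
    spike_times: np.ndarray   # ms
    spike_units: np.ndarray
    dt: float
    duration: float
    u: np.ndarray | None = None          # (steps, recorded) voltage traces
    recorded: tuple[int, ...] = ()

    def spikes_of(self, neuron: int) -> np.ndarray:
        return self.spike_times[self.spike_units == neuron]

    def save_spikes(self, path) -> None:
        """Two-column text output sorted by time: time_ms, neuron_id."""
        order = np.argsort(self.spike_times, kind="stable")
        np.savetxt(
            path,
            np.column_stack([self.spike_times[order], self.spike_units[order]]),
            fmt=["%.3f", "%d"],
            header="time_ms neuron_id",
        )


#: Reference operating point: weak background (400 Hz per polarity at
#: 0.002 μS), 10 ms synapses, 0.1 ms delays, γ = 10.
STANDARD_PROFILE = {
    "params": LIFParams(),
    "nu": 400.0,
    "w_bg": 0.002,
    "delay": 0.1,
    "gamma": 10.0,
}

#: Second operating point used for the robustness study: slower membrane
#: (τ_m = 1 ms), 20 ms synapses, strong background (5 kHz at 0.001 μS),
#: 1.2 ms delays, γ = 5; per-neuron jitter comes on top (NoiseProfile).
NOISY_PROFILE = {
    "params": LIFParams(tau_m=1.0, tau_syn_exc=20.0, tau_syn_inh=20.0),
    "nu": 5000.0,
    "w_bg": 0.001,
    "delay": 1.2,
    "gamma": 5.0,
}


def integrate(
    net: LIFNetworkSpec,
    duration: float,
    dt: float = 0.1,
    seed: int = 0,
    record_u: Sequence[int] | None = None,
    threshold: bool | Sequence[bool] = True,
) -> SimulationResult:
    """Simulate the network for ``duration`` ms at resolution ``dt`` ms.

    ``record_u`` selects neurons whose membrane potential is stored at every
    step; ``threshold`` may be a single flag or one per neuron (disabling
    the threshold yields the free membrane potential).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    N = net.n_neurons
    if dt > min(p.tau_m for p in net.neurons):
        raise ValueError("dt exceeds the smallest membrane time constant")
    n_steps = int(round(duration / dt))

    g_l = np.array([p.g_l for p in net.neurons])
    C_m = np.array([p.C_m for p in net.neurons])
    E_l = np.array([p.E_l for p in net.neurons])
    V_th = np.array([p.V_th for p in net.neurons])
    V_reset = np.array([p.V_reset for p in net.neurons])
    ref_steps = np.array([int(round(p.tau_ref / dt)) for p in net.neurons], dtype=np.int64)
    tau_se = np.array([p.tau_syn_exc for p in net.neurons])
    tau_si = np.array([p.tau_syn_inh for p in net.neurons])
    E_e = np.array([p.E_rev_exc for p in net.neurons])
    E_i = np.array([p.E_rev_inh for p in net.neurons])
    const_ge = np.array([p.const_g_exc for p in net.neurons])
    const_gi = np.array([p.const_g_inh for p in net.neurons])
    if isinstance(threshold, bool):
        thr_on = np.full(N, threshold, dtype=np.bool_)
    else:
        thr_on = np.asarray(threshold, dtype=np.bool_)

    S = len(net.synapses)
    syn_pre = np.array([s.pre for s in net.synapses], dtype=np.int64)
    syn_post = np.array([s.post for s in net.synapses], dtype=np.int64)
    syn_w = np.array([abs(s.weight) for s in net.synapses])
    syn_exc = np.array([s.excitatory for s in net.synapses], dtype=np.bool_)
    syn_delay = np.array(
        [max(1, int(round(s.delay / dt))) for s in net.synapses], dtype=np.int64
    )
    syn_renew = np.array([s.renewing for s in net.synapses], dtype=np.bool_)
    order = np.argsort(syn_pre, kind="stable") if S else np.empty(0, dtype=np.int64)
    syn_out_idx = order.astype(np.int64)
    syn_out_indptr = np.zeros(N + 1, dtype=np.int64)
    for s in range(S):
        syn_out_indptr[syn_pre[s] + 1] += 1
    syn_out_indptr = np.cumsum(syn_out_indptr).astype(np.int64)

    sources = net.background.sources
    src_lam = np.array([s.rate * dt * 1e-3 for s in sources])
    src_w = np.array([s.weight for s in sources])
    src_exc = np.array([s.excitatory for s in sources], dtype=np.bool_)
    src_indptr = np.zeros(len(sources) + 1, dtype=np.int64)
    tgt_list: list[int] = []
    for i, s in enumerate(sources):
        tgt_list.extend(s.targets)
        src_indptr[i + 1] = len(tgt_list)
    src_targets = np.array(tgt_list, dtype=np.int64)

    stims = sorted(net.stimuli, key=lambda s: s.time)
    stim_step = np.array([int(round(s.time / dt)) for s in stims], dtype=np.int64)
    stim_target = np.array([s.target for s in stims], dtype=np.int64)
    stim_w = np.array([abs(s.weight) for s in stims])
    stim_exc = np.array([s.weight >= 0 for s in stims], dtype=np.bool_)

    record_idx = np.array(
        [] if record_u is None else list(record_u), dtype=np.int64
    )

    spike_steps, spike_units, u_rec = run_network(
        n_steps, dt,
        g_l, C_m, E_l, V_th, V_reset, ref_steps,
        tau_se, tau_si, E_e, E_i, const_ge, const_gi, thr_on,
        syn_pre, syn_post, syn_w, syn_exc, syn_delay, syn_renew,
        syn_out_indptr, syn_out_idx,
        src_lam, src_w, src_exc, src_indptr, src_targets,
        stim_step, stim_target, stim_w, stim_exc,
        record_idx,
        int(seed) % (2**31 - 1),
    )
    return SimulationResult(
        spike_times=spike_steps * dt,
        spike_units=spike_units,
        dt=dt,
        duration=duration,
        u=u_rec if record_idx.size else None,
        recorded=tuple(int(i) for i in record_idx),
    )


def renewing_conductance(
    spike_times: Sequence[float],
    w: float,
    tau_syn: float,
    t_grid: np.ndarray,
    rule: str = "renew",
    tau_rec: float | None = None,
) -> np.ndarray:
    """Conductance trace of a depressing synapse for given presynaptic spikes.

    ``rule="renew"`` sets the conductance to ``w`` at each spike (the
    idealized renewing synapse); ``rule="tsodyks"`` evaluates the
    short-term-depression model with full utilization (U0 = 1, τ_facil = 0,
    τ_rec = 0.99 τ_syn by default), whose per-spike increment is
    ``w · [1 − exp(−Δt/τ_rec)]``.  The two agree whenever spikes are spaced
    by more than a few τ_syn, and the renewing rule never exceeds ``w``.
    """
    spike_times = np.sort(np.asarray(spike_times, dtype=float))
    t_grid = np.asarray(t_grid, dtype=float)
    g = np.zeros_like(t_grid)
    if rule == "renew":
        for i, ts in enumerate(spike_times):
            t_end = spike_times[i + 1] if i + 1 < spike_times.size else np.inf
            seg = (t_grid >= ts) & (t_grid < t_end)
            g[seg] = w * np.exp(-(t_grid[seg] - ts) / tau_syn)
        return g
    if rule != "tsodyks":
        raise ValueError("rule must be 'renew' or 'tsodyks'")
    if tau_rec is None:
        tau_rec = 0.99 * tau_syn
    jumps = np.empty(spike_times.size)
    for i, ts in enumerate(spike_times):
        if i == 0:
            R = 1.0
        else:
            R = 1.0 - np.exp(-(ts - spike_times[i - 1]) / tau_rec)
        jumps[i] = w * R
    for ts, j in zip(spike_times, jumps):
        seg = t_grid >= ts
        g[seg] += j * np.exp(-(t_grid[seg] - ts) / tau_syn)
    return g


def states_from_spikes(
    spike_times: np.ndarray,
    spike_units: np.ndarray,
    n_neurons: int,
    tau_ref: float | Sequence[float],
    duration: float,
    dt: float = 0.1,
) -> np.ndarray:
    """Binary state trace from spikes: ``z_k(t) = 1`` on ``[t_s, t_s + τ_ref)``.

    Overlapping refractory windows of one neuron merge.  Returns a
    (steps, n_neurons) uint8 array sampled on the ``dt`` grid.
    """
    n_steps = int(round(duration / dt))
    if np.isscalar(tau_ref):
        tau_ref = np.full(n_neurons, float(tau_ref))
    else:
        tau_ref = np.asarray(tau_ref, dtype=float)
    z = np.zeros((n_steps + 1, n_neurons), dtype=np.int32)
    spike_times = np.asarray(spike_times, dtype=float)
    spike_units = np.asarray(spike_units, dtype=np.int64)
    start = np.ceil(spike_times / dt - 1e-9).astype(np.int64)
    stop = np.ceil((spike_times + tau_ref[spike_units]) / dt - 1e-9).astype(np.int64)
    start = np.clip(start, 0, n_steps)
    stop = np.clip(stop, 0, n_steps)
    np.add.at(z, (start, spike_units), 1)
    np.subtract.at(z, (stop, spike_units), 1)
    z = np.cumsum(z[:-1], axis=0)
    return (z > 0).astype(np.uint8)


def build_background(
    n_neurons: int, nu: float = 400.0, w: float = 0.002
) -> PoissonBackground:
    """Independent background: one private excitatory and one private
    inhibitory Poisson source per neuron, each at rate ``nu``."""
    sources = []
    for n in range(n_neurons):
        sources.append(BackgroundSource(nu, w, True, (n,)))
        sources.append(BackgroundSource(nu, w, False, (n,)))
    return PoissonBackground(tuple(sources))


def _sharing_pairs(n_neurons: int) -> list[tuple[int, int]]:
    """Pairs such that every neuron appears in exactly three of them."""
    if n_neurons < 4 or n_neurons % 2:
        raise ValueError("shared-source pairing needs an even neuron count >= 4")
    pairs = [(i, (i + 1) % n_neurons) for i in range(n_neurons)]
    pairs += [(i, i + n_neurons // 2) for i in range(n_neurons // 2)]
    return pairs


def build_correlated_background(
    n_neurons: int,
    nu: float = 400.0,
    w: float = 0.002,
    pairing: Sequence[tuple[int, int]] | None = None,
) -> PoissonBackground:
    """Background with weak pairwise rate correlations.

    Per neuron and polarity the total rate ``nu`` is split over ten
    sub-sources at ``nu/10`` each: seven private and three shared, every
    shared source projecting onto exactly two neurons (so no higher-order
    correlations arise).  Two paired neurons share exactly one source per
    polarity, giving a 10% count correlation between their summed inputs.
    Excitatory and inhibitory pools are disjoint source sets, leaving each
    neuron's own activation function unaltered.
    """
    if pairing is None:
        pairing = _sharing_pairs(n_neurons)
    share_count = np.zeros(n_neurons, dtype=int)
    for a, b in pairing:
        share_count[a] += 1
        share_count[b] += 1
    if np.any(share_count != 3):
        raise ValueError("pairing must give every neuron exactly three shared sources")
    sources = []
    for exc in (True, False):
        for a, b in pairing:
            sources.append(BackgroundSource(nu / 10.0, w, exc, (a, b)))
        for n in range(n_neurons):
            for _ in range(7):
                sources.append(BackgroundSource(nu / 10.0, w, exc, (n,)))
    return PoissonBackground(tuple(sources))


def sample_background_counts(
    background: PoissonBackground,
    duration: float,
    bin_width: float,
    seed: int = 0,
    excitatory: bool = True,
    n_neurons: int | None = None,
) -> np.ndarray:
    """Binned spike counts of the summed background input per neuron.

    Draws Poisson counts per source and bin and accumulates them onto the
    source targets; returns a (n_bins, n_neurons) array.  Times in ms.
    """
    rng = np.random.default_rng(seed)
    n_bins = int(round(duration / bin_width))
    if n_neurons is None:
        n_neurons = 1 + max(max(s.targets) for s in background.sources)
    counts = np.zeros((n_bins, n_neurons))
    for s in background.sources:
        lam = s.rate * bin_width * 1e-3
        # one draw per source regardless of polarity, so a fixed seed
        # defines one realization of the whole background
        draws = rng.poisson(lam, size=n_bins)
        if s.excitatory != excitatory:
            continue
        for tgt in s.targets:
            counts[:, tgt] += draws
    return counts


@dataclass(frozen=True)
class NoiseProfile:
    """Per-neuron / per-synapse jitter magnitudes (standard deviations).

    The default values are the spreads of the noisy operating profile:
    Gaussian jitter on each neuron parameter and a multiplicative factor
    ``ε ~ N(1, weight_cv)`` on every synaptic weight.
    """

    E_l: float = 2.0          # mV (jitter on the translated resting potential)
    tau_m: float = 0.1        # ms
    tau_ref: float = 1.0      # ms
    tau_syn: float = 2.0      # ms
    E_rev_exc: float = 2.0    # mV
    E_rev_inh: float = 2.0    # mV
    V_th: float = 0.5         # mV
    V_reset: float = 0.5      # mV
    weight_cv: float = 0.1    # relative sd of the synaptic weight multiplier


def apply_parameter_noise(
    spec: LIFNetworkSpec,
    profile: NoiseProfile | None = None,
    seed: int = 0,
    max_tries: int = 100,
) -> LIFNetworkSpec:
    """Draw a jittered copy of a network spec (fixed-pattern parameter noise).

    Each neuron parameter is drawn from a Gaussian centered on its current
    value with the profile's spread; draws violating the parameter
    invariants are redrawn (up to ``max_tries``).  Every synapse weight is
    multiplied by an independent ``ε ~ N(1, weight_cv)``.
    """
    if profile is None:
        profile = NoiseProfile()
    rng = np.random.default_rng(seed)
    new_neurons = []
    for p in spec.neurons:
        for _ in range(max_tries):
            try:
                cand = replace(
                    p,
                    E_l=p.E_l + rng.normal(0.0, profile.E_l),
                    tau_m=p.tau_m + rng.normal(0.0, profile.tau_m),
                    tau_ref=p.tau_ref + rng.normal(0.0, profile.tau_ref),
                    tau_syn_exc=p.tau_syn_exc + rng.normal(0.0, profile.tau_syn),
                    tau_syn_inh=p.tau_syn_inh + rng.normal(0.0, profile.tau_syn),
                    E_rev_exc=p.E_rev_exc + rng.normal(0.0, profile.E_rev_exc),
                    E_rev_inh=p.E_rev_inh + rng.normal(0.0, profile.E_rev_inh),
                    V_th=p.V_th + rng.normal(0.0, profile.V_th),
                    V_reset=p.V_reset + rng.normal(0.0, profile.V_reset),
                )
            except ValueError:
                continue
            break
        else:
            raise RuntimeError("could not draw valid noisy parameters")
        new_neurons.append(cand)
    new_synapses = tuple(
        replace(s, weight=s.weight * rng.normal(1.0, profile.weight_cv))
        for s in spec.synapses
    )
    return replace(spec, neurons=tuple(new_neurons), synapses=new_synapses)


# -- JSON round trip -------------------------------------------------------


def spec_to_dict(spec: LIFNetworkSpec) -> dict:
    return {
        "neurons": [vars(p) | {} for p in spec.neurons],
        "synapses": [vars(s) | {} for s in spec.synapses],
        "background": [
            {"rate": s.rate, "weight": s.weight, "excitatory": s.excitatory,
             "targets": list(s.targets)}
            for s in spec.background.sources
        ],
        "stimuli": [vars(s) | {} for s in spec.stimuli],
        "principal_neurons": list(spec.principal_neurons or []),
        "state_tau_ref": spec.state_tau_ref,
    }


def spec_from_dict(data: dict) -> LIFNetworkSpec:
    return LIFNetworkSpec(
        neurons=tuple(LIFParams(**d) for d in data["neurons"]),
        synapses=tuple(Synapse(**d) for d in data.get("synapses", [])),
        background=PoissonBackground(
            tuple(
                BackgroundSource(
                    d["rate"], d["weight"], d["excitatory"], tuple(d["targets"])
                )
                for d in data.get("background", [])
            )
        ),
        stimuli=tuple(StimulusSpike(**d) for d in data.get("stimuli", [])),
        principal_neurons=tuple(data.get("principal_neurons") or []) or None,
        state_tau_ref=data.get("state_tau_ref"),
    )


def write_spec(spec: LIFNetworkSpec, path) -> None:
    with open(path, "w") as fh:
        json.dump(spec_to_dict(spec), fh)


def read_spec(path) -> LIFNetworkSpec:
    with open(path) as fh:
        return spec_from_dict(json.load(fh))
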