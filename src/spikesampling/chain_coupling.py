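"""Interneuron-chain coupling: sawtooth "mLIF" PSPs approximating a rectangle.

A single conductance-based PSP in the fast-membrane regime is practically a
decaying exponential — far from the rectangular interaction that makes the
abstract sampler exact.  Replacing each sampling neuron by a feed-forward
chain improves this: the first ("sampling") neuron still encodes the RV
state through its spikes, while the remaining ("forwarding") neurons relay
each of its spikes with staggered delays.  All chain neurons project onto
the sampling neuron of every coupled RV, so the target sees a superposition
of delayed PSP kernels — a sawtooth that tracks the rectangle — and the
*last* chain neuron projects with opposite sign, cutting off the tail of
the final PSP at the end of the refractory window.

The default configuration uses six chain neurons; the chain operating point
(29.5 ms refractory period and 30 ms synapses on the sampling neuron) and
the projection weights (0.180·w for forwarding neurons, −0.815·w for the
last one, 0.16 μS for the internal drive) define the shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .bm_translation import BoltzmannMachine
from .calibration import CalibrationResult, bias_to_leak, weight_conversion
from .lif_sampler import (
    LIFNetworkSpec,
    LIFParams,
    PoissonBackground,
    StimulusSpike,
    Synapse,
    build_background,
    integrate,
)

__all__ = [
    "ChainConfig",
    "SAMPLING_NEURON",
    "FORWARDING_NEURON",
    "build_chain_network",
    "composite_psp_trace",
    "psp_rectangle_distance",
]

#: First (sampling) chain neuron: near-threshold reset, slow synapses.
SAMPLING_NEURON = LIFParams(
    C_m=0.2, tau_m=0.1, tau_ref=29.5, tau_syn_exc=30.0, tau_syn_inh=30.0,
    V_th=-50.0, V_reset=-50.01, E_l=-50.0,
)

#: Forwarding chain neurons: fast synapses, reset = rest.
FORWARDING_NEURON = LIFParams(
    C_m=0.2, tau_m=0.1, tau_ref=29.3, tau_syn_exc=2.0, tau_syn_inh=2.0,
    V_th=-50.0, V_reset=-52.3, E_l=-52.3,
)


@dataclass(frozen=True)
class ChainConfig:
    """Wiring constants of the interneuron chain."""

    n_chain: int = 6
    sampling_params: LIFParams = field(default_factory=lambda: SAMPLING_NEURON)
    forwarding_params: LIFParams = field(default_factory=lambda: FORWARDING_NEURON)
    delay_ss: float = 0.1          # sampling → sampling neuron, ms
    delay_sf: float = 5.8          # sampling → forwarding, ms
    delay_fs: float = 0.1          # forwarding → sampling, ms
    delay_ff: float = 5.8          # forwarding → forwarding, ms
    delay_f_last: float = 5.9      # forwarding → last forwarding, ms
    w_forward: float = 0.16        # μS, internal chain drive
    proj_scale: float = 0.180      # forwarding → target sampling neuron, × w
    last_scale: float = -0.815     # last forwarding → target, × w (opposing)

    def __post_init__(self):
        if self.n_chain < 2:
            raise ValueError("a chain needs at least two neurons")
        if self.proj_scale * self.last_scale >= 0:
            raise ValueError("the last chain neuron must oppose the others")

    def to_dict(self) -> dict:
        d = {k: v for k, v in vars(self).items()
             if k not in ("sampling_params", "forwarding_params")}
        d["sampling_params"] = dict(vars(self.sampling_params))
        d["forwarding_params"] = dict(vars(self.forwarding_params))
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "ChainConfig":
        data = dict(data)
        sp = LIFParams(**data.pop("sampling_params"))
        fp = LIFParams(**data.pop("forwarding_params"))
        return cls(sampling_params=sp, forwarding_params=fp, **data)


def _chain_synapses(cfg: ChainConfig, base: int) -> list[Synapse]:
    """Internal feed-forward wiring of one chain starting at index ``base``."""
    syn = []
    n = cfg.n_chain
    for j in range(n - 1):
        pre = base + j
        post = base + j + 1
        if j == 0:
            d = cfg.delay_sf
        elif j == n - 2:
            d = cfg.delay_f_last
        else:
            d = cfg.delay_ff
        syn.append(Synapse(pre=pre, post=post, weight=cfg.w_forward, delay=d))
    return syn


def build_chain_network(
    bm: BoltzmannMachine,
    calib: CalibrationResult,
    config: ChainConfig | None = None,
    background: PoissonBackground | None = None,
) -> LIFNetworkSpec:
    """Chain-coupled LIF network for a Boltzmann machine.

    Each unit becomes a chain of ``n_chain`` neurons; only the sampling
    neuron of each chain carries the unit's bias (via its leak) and defines
    the state.  For every coupling ``W_ki`` with translated weight
    ``w = weight_conversion(W_ki)``, the sampling neuron of chain ``i``
    projects onto the sampling neuron of chain ``k`` with weight ``w``, the
    forwarding neurons with ``0.180 w``, and the last forwarding neuron
    with ``−0.815 w``.  ``calib`` must have been obtained with the chain's
    sampling-neuron parameters.
    """
    cfg = config or ChainConfig()
    n_units = bm.n_units
    nc = cfg.n_chain
    b_eff = bm.effective_bias()
    neurons: list[LIFParams] = []
    synapses: list[Synapse] = []
    for u in range(n_units):
        base = u * nc
        neurons.append(
            replace(cfg.sampling_params, E_l=bias_to_leak(b_eff[u], calib))
        )
        neurons.extend([cfg.forwarding_params] * (nc - 1))
        synapses.extend(_chain_synapses(cfg, base))
    for k in range(n_units):
        for i in range(n_units):
            if i == k or bm.W[k, i] == 0.0:
                continue
            w = weight_conversion(bm.W[k, i], calib)
            target = k * nc  # sampling neuron of chain k
            src = i * nc
            synapses.append(
                Synapse(pre=src, post=target, weight=w, delay=cfg.delay_ss)
            )
            for j in range(1, nc - 1):
                synapses.append(
                    Synapse(
                        pre=src + j, post=target,
                        weight=cfg.proj_scale * w, delay=cfg.delay_fs,
                    )
                )
            synapses.append(
                Synapse(
                    pre=src + nc - 1, post=target,
                    weight=cfg.last_scale * w, delay=cfg.delay_fs,
                )
            )
    if background is None:
        background = build_background(len(neurons), nu=calib.nu, w=calib.w_bg)
    return LIFNetworkSpec(
        neurons=tuple(neurons),
        synapses=tuple(synapses),
        background=background,
        principal_neurons=tuple(
            i * nc for i in range(n_units) if bm.roles[i] == "principal"
        ),
        state_tau_ref=cfg.sampling_params.tau_ref,
    )


def composite_psp_trace(
    calib: CalibrationResult,
    w: float,
    config: ChainConfig | None = None,
    trials: int = 100,
    duration: float = 120.0,
    pre_window: float = 20.0,
    dt: float = 0.1,
    seed: int = 0,
    background: str = "poisson",
) -> tuple[np.ndarray, np.ndarray]:
    """Background-subtracted average mLIF PSP on a target sampling neuron.

    One chain is driven to fire once (a strong external kick to its sampling
    neuron); the free membrane potential of a target sampling neuron
    receiving the chain's projections (translated weight ``w``) is recorded
    and averaged over ``trials`` seeds, subtracting the pre-stimulus mean.
    ``background="frozen"`` replaces the Poisson bombardment by constant
    conductances of equal mean — a single noise-free trial that resolves the
    PSP tail exactly.  Returns ``(t, deflection)`` with ``t = 0`` at the
    chain spike.
    """
    cfg = config or ChainConfig()
    nc = cfg.n_chain
    # The driver is biased strongly negative and given an over-long
    # refractory period so the slowly decaying kick conductance cannot
    # re-trigger it: the chain volleys exactly once per trial.
    neurons: list[LIFParams] = [
        replace(
            cfg.sampling_params,
            E_l=bias_to_leak(-10.0, calib),
            tau_ref=pre_window + duration,
        )
    ]
    neurons.extend([cfg.forwarding_params] * (nc - 1))
    target = nc
    neurons.append(
        replace(cfg.sampling_params, E_l=bias_to_leak(0.0, calib))
    )
    synapses = _chain_synapses(cfg, 0)
    synapses.append(Synapse(pre=0, post=target, weight=w, delay=cfg.delay_ss))
    for j in range(1, nc - 1):
        synapses.append(
            Synapse(pre=j, post=target, weight=cfg.proj_scale * w, delay=cfg.delay_fs)
        )
    synapses.append(
        Synapse(pre=nc - 1, post=target, weight=cfg.last_scale * w, delay=cfg.delay_fs)
    )
    kick = StimulusSpike(time=pre_window, target=0, weight=1.0)
    total = pre_window + duration
    n_steps = int(round(total / dt))
    acc = np.zeros(n_steps)
    thr = np.ones(len(neurons), dtype=bool)
    thr[target] = False  # free potential on the read-out neuron
    if background == "frozen":
        frozen = []
        for p in neurons:
            g_e = calib.nu * calib.w_bg * p.tau_syn_exc * 1e-3
            g_i = calib.nu * calib.w_bg * p.tau_syn_inh * 1e-3
            frozen.append(replace(p, const_g_exc=g_e, const_g_inh=g_i))
        neurons = frozen
        bg = PoissonBackground()
        trials = 1
    elif background == "poisson":
        bg = build_background(len(neurons), nu=calib.nu, w=calib.w_bg)
    else:
        raise ValueError("background must be 'poisson' or 'frozen'")
    spec = LIFNetworkSpec(
        neurons=tuple(neurons),
        synapses=tuple(synapses),
        background=bg,
        stimuli=(kick,),
    )
    n_ok = 0
    for tr in range(trials):
        res = integrate(
            spec, duration=total, dt=dt, seed=seed + 7919 * tr + 1,
            record_u=[target], threshold=list(thr),
        )
        t0 = res.spikes_of(0)
        if t0.size == 0:  # the kick failed to elicit a chain spike
            continue
        trace = res.u[:, 0]
        baseline = trace[: int(pre_window / dt)].mean()
        acc += trace - baseline
        n_ok += 1
    if n_ok == 0:
        raise RuntimeError("chain never fired; increase the stimulus weight")
    t = np.arange(n_steps) * dt - pre_window
    return t, acc / n_ok


def psp_rectangle_distance(
    t: np.ndarray,
    trace: np.ndarray,
    window: float,
    horizon: float | None = None,
) -> float:
    """Normalized L2 distance between a PSP trace and the ideal rectangle.

    Both the trace and the rectangle (1 on ``[0, window)``) are scaled to
    unit peak amplitude; the distance is the root-mean-square difference
    over ``[0, horizon]`` (1.5 windows by default) normalized per unit
    window, so it is invariant to amplitude scaling.
    """
    t = np.asarray(t, dtype=float)
    trace = np.asarray(trace, dtype=float)
    if horizon is None:
        horizon = 1.5 * window
    sel = (t >= 0) & (t <= horizon)
    ts, f = t[sel], trace[sel]
    peak = np.max(np.abs(f))
    if peak == 0:
        raise ValueError("flat trace has no amplitude to normalize")
    f = f / peak
    rect = ((ts >= 0) & (ts < window)).astype(float)
    dt = np.median(np.diff(ts))
    return float(np.sqrt(np.sum((f - rect) ** 2) * dt / window))
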