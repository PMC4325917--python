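"""Calibrating LIF neurons against the logistic activation function.

Under diffuse Poisson background the free membrane potential of a LIF
neuron in the fast-membrane regime is approximately an Ornstein-Uhlenbeck
process, and the probability of finding the neuron in its refractory state
(``Z = 1``) is a sigmoidal function σ̃ of the noise-free mean membrane
potential ``u_eff``.  Fitting the measured curve with a logistic

    p(Z = 1) = σ((u_eff − ⟨u⟩₀) / α)

yields the two translation constants between the abstract and the LIF
domain: the midpoint ``⟨u⟩₀`` (where p = 1/2) and the voltage scale ``α``
(mV per unit of abstract potential).  A Boltzmann bias ``b`` is then
realized by choosing the leak potential so that ``u_eff = α b + ⟨u⟩₀``, and
a Boltzmann weight ``W`` by choosing the synaptic weight ``w = β W`` such
that the time-average of the conductance-based PSP over one refractory
period equals ``α W``:

    β = α C_m τ_ref (1/τ_syn − 1/τ_eff) / (E_rev − ⟨u⟩)
        · [τ_syn (e^{−τ_ref/τ_syn} − 1) − τ_eff (e^{−τ_ref/τ_eff} − 1)]⁻¹

with the effective membrane time constant ``τ_eff = C_m / ⟨g_tot⟩``.

The calibration is purely empirical: the neuron is simulated, the
activation curve measured as the time fraction spent in the refractory
state (which accounts for spike bursts), and the constants fitted — no
first-passage-time formulae are evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .bm_translation import BoltzmannMachine
from .lif_sampler import (
    LIFNetworkSpec,
    LIFParams,
    PoissonBackground,
    Synapse,
    build_background,
    integrate,
    states_from_spikes,
)

__all__ = [
    "CalibrationResult",
    "mean_conductance",
    "measure_activation_curve",
    "fit_activation",
    "calibrate",
    "bias_to_leak",
    "weight_conversion",
    "psp_shape",
    "network_from_boltzmann",
]


def sigma(v):
    """Logistic function σ(v) = 1 / (1 + e^{−v})."""
    return 1.0 / (1.0 + np.exp(-np.asarray(v, dtype=float)))


def mean_conductance(params: LIFParams, nu: float, w_bg: float) -> float:
    """Analytic mean total conductance ⟨g_tot⟩ under Poisson background.

    Exponential synapses at rate ν and weight w contribute ν·w·τ_syn on
    average; both background polarities plus the leak are summed.
    """
    return (
        params.g_l
        + nu * w_bg * params.tau_syn_exc * 1e-3
        + nu * w_bg * params.tau_syn_inh * 1e-3
    )


@dataclass
class CalibrationResult:
    """Measured activation curve and fitted translation constants."""

    leak_grid: np.ndarray        # E_l settings, mV
    u_eff: np.ndarray            # measured mean free potential per setting, mV
    p_active: np.ndarray         # measured time fraction in state 1
    u_std: np.ndarray            # free-potential standard deviation, mV
    u0_mean: float               # ⟨u⟩₀: u_eff at which p = 1/2, mV
    alpha: float                 # mV per abstract unit
    g_tot_mean: float            # ⟨g_tot⟩, μS
    leak_slope: float            # d u_eff / d E_l of the affine leak map
    leak_intercept: float        # mV
    params: LIFParams = field(default_factory=LIFParams)
    nu: float = 400.0
    w_bg: float = 0.002
    seed: int = 0

    @property
    def u_mean(self) -> float:
        """Mean free membrane potential at the operating point (b = 0)."""
        return self.u0_mean

    @property
    def tau_eff(self) -> float:
        return self.params.C_m / self.g_tot_mean

    def midpoint_slope(self) -> float:
        """Central finite-difference slope of the *measured* curve at ⟨u⟩₀."""
        i = int(np.argmin(np.abs(self.u_eff - self.u0_mean)))
        i = min(max(i, 1), self.u_eff.size - 2)
        return float(
            (self.p_active[i + 1] - self.p_active[i - 1])
            / (self.u_eff[i + 1] - self.u_eff[i - 1])
        )

    def to_dict(self) -> dict:
        return {
            "leak_grid": self.leak_grid.tolist(),
            "u_eff": self.u_eff.tolist(),
            "p_active": self.p_active.tolist(),
            "u_std": self.u_std.tolist(),
            "u0_mean": self.u0_mean,
            "alpha": self.alpha,
            "g_tot_mean": self.g_tot_mean,
            "leak_slope": self.leak_slope,
            "leak_intercept": self.leak_intercept,
            "nu": self.nu,
            "w_bg": self.w_bg,
            "seed": self.seed,
        }


def _single_neuron_spec(params: LIFParams, nu: float, w_bg: float) -> LIFNetworkSpec:
    return LIFNetworkSpec(
        neurons=(params,), background=build_background(1, nu=nu, w=w_bg)
    )


def measure_activation_curve(
    params: LIFParams,
    leak_grid: Sequence[float] | None = None,
    duration: float = 20000.0,
    free_duration: float = 5000.0,
    nu: float = 400.0,
    w_bg: float = 0.002,
    dt: float = 0.1,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Measure ``(E_l, u_eff, p_active, u_std)`` over a grid of leak settings.

    For every leak setting the neuron is simulated twice: once with the
    threshold disabled (free membrane potential → mean and std) and once
    with the threshold active; the activation is the time fraction spent in
    the refractory state, read out via :func:`states_from_spikes` so that
    spike bursts extend the state-1 window.

    The default grid is centered on the spike threshold and scaled by the
    measured free-potential noise: it spans ±6 standard deviations with a
    dense core (0.3 σ spacing within ±3 σ) so the sigmoid transition is
    well resolved regardless of the operating profile.
    """
    g_tot = mean_conductance(params, nu, w_bg)
    # mean exc/inh conductances for the analytic leak↔u_eff map
    g_e = nu * w_bg * params.tau_syn_exc * 1e-3
    g_i = nu * w_bg * params.tau_syn_inh * 1e-3

    def leak_for(u_target: float) -> float:
        return (
            u_target * g_tot - g_e * params.E_rev_exc - g_i * params.E_rev_inh
        ) / params.g_l

    if leak_grid is None:
        # pilot run to estimate the noise scale at threshold
        import dataclasses

        pilot = dataclasses.replace(params, E_l=leak_for(params.V_th))
        res = integrate(
            _single_neuron_spec(pilot, nu, w_bg),
            duration=2000.0,
            dt=dt,
            seed=seed + 90001,
            record_u=[0],
            threshold=False,
        )
        sd = float(np.std(res.u[:, 0]))
        offsets = np.concatenate(
            [np.arange(-10, 11) * 0.3, np.array([-6.0, -4.5, 4.5, 6.0])]
        )
        offsets = np.sort(offsets)
        leak_grid = [leak_for(params.V_th + o * sd) for o in offsets]
    leak_grid = np.asarray(leak_grid, dtype=float)

    import dataclasses

    u_eff = np.empty(leak_grid.size)
    u_std = np.empty(leak_grid.size)
    p_active = np.empty(leak_grid.size)
    for i, el in enumerate(leak_grid):
        p = dataclasses.replace(params, E_l=float(el))
        spec = _single_neuron_spec(p, nu, w_bg)
        free = integrate(
            spec, duration=free_duration, dt=dt, seed=seed + 2 * i + 1,
            record_u=[0], threshold=False,
        )
        u_eff[i] = float(np.mean(free.u[:, 0]))
        u_std[i] = float(np.std(free.u[:, 0]))
        drive = integrate(
            spec, duration=duration, dt=dt, seed=seed + 2 * i + 2, threshold=True
        )
        z = states_from_spikes(
            drive.spike_times, drive.spike_units, 1, p.tau_ref, duration, dt
        )
        p_active[i] = float(z.mean())
    if p_active.max() < 0.01 or p_active.min() > 0.99:
        raise ValueError("leak grid does not span the activation transition")
    return leak_grid, u_eff, p_active, u_std


def fit_activation(u_eff: np.ndarray, p_active: np.ndarray) -> tuple[float, float]:
    """Fit the activation curve; returns ``(⟨u⟩₀, α)``.

    The voltage scale α is the least-squares logistic fit
    ``p = σ((u_eff − u0)/α)`` over the whole curve.  The midpoint ⟨u⟩₀ is
    then refined to its defining property — the ``u_eff`` at which the
    *measured* activation crosses 1/2 — by a local linear fit over the
    transition points (0.2 < p < 0.8); the measured curve is slightly
    asymmetric around the midpoint (the refractory duty cycle saturates
    below 1), which would otherwise bias the global fit's midpoint.
    """
    u_eff = np.asarray(u_eff, dtype=float)
    p_active = np.asarray(p_active, dtype=float)
    span = u_eff.max() - u_eff.min()
    if span <= 0 or np.ptp(p_active) < 0.2:
        raise ValueError("activation data are not sigmoidal")
    u0_guess = float(u_eff[np.argmin(np.abs(p_active - 0.5))])
    popt, _ = curve_fit(
        lambda u, u0, a: sigma((u - u0) / a),
        u_eff,
        p_active,
        p0=[u0_guess, max(span / 20.0, 1e-3)],
        maxfev=20000,
    )
    u0, alpha = float(popt[0]), float(abs(popt[1]))
    core = (p_active > 0.2) & (p_active < 0.8)
    if core.sum() >= 3:
        c1, c0 = np.polyfit(u_eff[core] - u0, p_active[core], 1)
        if c1 > 0:
            u0 = u0 + (0.5 - c0) / c1
    return u0, alpha


def calibrate(
    params: LIFParams | None = None,
    nu: float = 400.0,
    w_bg: float = 0.002,
    duration: float = 20000.0,
    free_duration: float = 5000.0,
    leak_grid: Sequence[float] | None = None,
    dt: float = 0.1,
    seed: int = 0,
) -> CalibrationResult:
    """Full calibration: measure the activation curve and fit the constants."""
    if params is None:
        params = LIFParams()
    leak_grid, u_eff, p_active, u_std = measure_activation_curve(
        params, leak_grid=leak_grid, duration=duration,
        free_duration=free_duration, nu=nu, w_bg=w_bg, dt=dt, seed=seed,
    )
    u0, alpha = fit_activation(u_eff, p_active)
    slope, intercept = np.polyfit(leak_grid, u_eff, 1)
    return CalibrationResult(
        leak_grid=leak_grid,
        u_eff=u_eff,
        p_active=p_active,
        u_std=u_std,
        u0_mean=u0,
        alpha=alpha,
        g_tot_mean=mean_conductance(params, nu, w_bg),
        leak_slope=float(slope),
        leak_intercept=float(intercept),
        params=params,
        nu=nu,
        w_bg=w_bg,
        seed=seed,
    )


def measure_midpoint_slope(
    calib: CalibrationResult,
    h_factor: float = 0.5,
    offsets: Sequence[float] = (-0.25, 0.0, 0.25),
    duration: float = 1_000_000.0,
    free_duration: float = 300_000.0,
    dt: float = 0.1,
    seed: int = 0,
) -> float:
    """High-precision central finite difference of the activation curve.

    For each offset ``c`` (in units of α around the fitted midpoint) a
    secant ``Δp / Δu_eff`` is measured between two fresh points at
    ``u_eff ≈ ⟨u⟩₀ + (c ± h_factor) α``, with long simulations so that both
    the activation fractions and the measured ``u_eff`` values have small
    errors.  The measured curve is close to linear within ±1 α of the
    midpoint, so averaging the offset secants is an unbiased low-variance
    estimate of the midpoint slope.
    """
    import dataclasses

    def measure_point(u_target: float, sd: int) -> tuple[float, float]:
        el = (u_target - calib.leak_intercept) / calib.leak_slope
        p = dataclasses.replace(calib.params, E_l=float(el))
        spec = _single_neuron_spec(p, calib.nu, calib.w_bg)
        free = integrate(
            spec, duration=free_duration, dt=dt, seed=sd + 1,
            record_u=[0], threshold=False,
        )
        drive = integrate(spec, duration=duration, dt=dt, seed=sd + 2)
        z = states_from_spikes(
            drive.spike_times, drive.spike_units, 1, p.tau_ref, duration, dt
        )
        return float(np.mean(free.u[:, 0])), float(z.mean())

    slopes = []
    for j, c in enumerate(offsets):
        lo = calib.u0_mean + (c - h_factor) * calib.alpha
        hi = calib.u0_mean + (c + h_factor) * calib.alpha
        u_lo, p_lo = measure_point(lo, seed + 101 * j)
        u_hi, p_hi = measure_point(hi, seed + 101 * j + 50)
        slopes.append((p_hi - p_lo) / (u_hi - u_lo))
    return float(np.mean(slopes))


def bias_to_leak(b: float, calib: CalibrationResult) -> float:
    """Leak potential realizing activation σ(b) for an isolated neuron.

    Targets ``u_eff = α b + ⟨u⟩₀`` and inverts the measured affine map from
    leak setting to mean free potential (slope ≈ g_l / ⟨g_tot⟩).
    """
    u_target = calib.alpha * b + calib.u0_mean
    return (u_target - calib.leak_intercept) / calib.leak_slope


def psp_shape(
    t: np.ndarray,
    w: float,
    params: LIFParams,
    u_mean: float,
    g_tot_mean: float,
    excitatory: bool = True,
) -> np.ndarray:
    """Closed-form conductance-based PSP in the fast-membrane regime.

    ``u_PSP(t) = w (E_rev − ⟨u⟩) / [C_m (1/τ_syn − 1/τ_eff)]
                 · (e^{−t/τ_eff} − e^{−t/τ_syn})`` for t ≥ 0.
    """
    t = np.asarray(t, dtype=float)
    tau_eff = params.C_m / g_tot_mean
    tau_syn = params.tau_syn_exc if excitatory else params.tau_syn_inh
    E_rev = params.E_rev_exc if excitatory else params.E_rev_inh
    amp = w * (E_rev - u_mean) / (params.C_m * (1.0 / tau_syn - 1.0 / tau_eff))
    out = amp * (np.exp(-t / tau_eff) - np.exp(-t / tau_syn))
    return np.where(t >= 0, out, 0.0)


def _beta(
    calib: CalibrationResult, excitatory: bool, params: LIFParams | None = None
) -> float:
    """Weight translation factor β (μS per abstract unit), signed by driving force."""
    p = params or calib.params
    tau_syn = p.tau_syn_exc if excitatory else p.tau_syn_inh
    tau_eff = calib.tau_eff
    E_rev = p.E_rev_exc if excitatory else p.E_rev_inh
    tau_ref = p.tau_ref
    if np.isclose(tau_syn, tau_eff, rtol=1e-9):
        # equal-time-constant limit: u_PSP ∝ t e^{−t/τ}
        tau = tau_syn
        integral = tau * tau * (1.0 - np.exp(-tau_ref / tau)) - tau * tau_ref * np.exp(
            -tau_ref / tau
        )
        return calib.alpha * tau_ref * p.C_m / ((E_rev - calib.u_mean) * integral)
    bracket = tau_syn * (np.exp(-tau_ref / tau_syn) - 1.0) - tau_eff * (
        np.exp(-tau_ref / tau_eff) - 1.0
    )
    return (
        calib.alpha
        * p.C_m
        * tau_ref
        * (1.0 / tau_syn - 1.0 / tau_eff)
        / (E_rev - calib.u_mean)
        / bracket
    )


def weight_conversion(
    W: float, calib: CalibrationResult, params: LIFParams | None = None
) -> float:
    """Translate an abstract coupling ``W`` into a signed synaptic weight (μS).

    Positive couplings use the excitatory reversal potential, negative ones
    the inhibitory one; the returned weight is signed in the package's
    convention (negative = inhibitory).
    """
    if W == 0:
        return 0.0
    if W > 0:
        return _beta(calib, True, params) * W
    # β is negative for the inhibitory driving force; the magnitude is
    # |β W| and the sign marks the synapse as inhibitory.
    return -abs(_beta(calib, False, params) * W)


def network_from_boltzmann(
    bm: BoltzmannMachine,
    calib: CalibrationResult,
    background: PoissonBackground | None = None,
    delay: float = 0.1,
) -> LIFNetworkSpec:
    """One LIF neuron per Boltzmann unit, single-synapse coupling.

    Leaks realize the (clamp-adjusted) biases, every nonzero coupling
    becomes a pair of renewing synapses, and each neuron receives the
    standard independent background unless one is supplied.
    """
    n = bm.n_units
    b_eff = bm.effective_bias()
    neurons = []
    import dataclasses

    for i in range(n):
        neurons.append(
            dataclasses.replace(calib.params, E_l=bias_to_leak(b_eff[i], calib))
        )
    synapses = []
    for k in range(n):
        for i in range(k + 1, n):
            if bm.W[k, i] != 0.0:
                w = weight_conversion(bm.W[k, i], calib)
                synapses.append(Synapse(pre=i, post=k, weight=w, delay=delay))
                synapses.append(Synapse(pre=k, post=i, weight=w, delay=delay))
    if background is None:
        background = build_background(n, nu=calib.nu, w=calib.w_bg)
    return LIFNetworkSpec(
        neurons=tuple(neurons),
        synapses=tuple(synapses),
        background=background,
        principal_neurons=bm.principal_indices,
        state_tau_ref=calib.params.tau_ref,
    )
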