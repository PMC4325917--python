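import dataclasses

import numpy as np
import pytest

from spikesampling.bm_translation import BoltzmannMachine, boltzmann_distribution
from spikesampling.calibration import (
    bias_to_leak,
    fit_activation,
    mean_conductance,
    network_from_boltzmann,
    psp_shape,
    sigma,
    weight_conversion,
)
from spikesampling.evaluation import dkl_norm, empirical_distribution
from spikesampling.lif_sampler import (
    LIFNetworkSpec,
    LIFParams,
    build_background,
    integrate,
    states_from_spikes,
)


class TestFitActivation:
    def test_recovers_exact_logistic(self):
        u = np.linspace(-51.0, -49.0, 41)
        p = sigma((u + 50.2) / 0.15)
        u0, alpha = fit_activation(u, p)
        assert u0 == pytest.approx(-50.2, abs=1e-6)
        assert alpha == pytest.approx(0.15, abs=1e-6)

    def test_non_sigmoidal_rejected(self):
        u = np.linspace(0, 1, 10)
        with pytest.raises(ValueError):
            fit_activation(u, np.full(10, 0.5))


class TestMeasuredCurve:
    def test_curve_is_sigmoidal_with_small_residual(self, std_calib):
        resid = std_calib.p_active - sigma(
            (std_calib.u_eff - std_calib.u0_mean) / std_calib.alpha
        )
        assert np.sqrt((resid**2).mean()) < 0.03

    def test_saturation_at_grid_ends(self, std_calib):
        assert std_calib.p_active[0] < 0.05
        assert std_calib.p_active[-1] > 0.9

    def test_midpoint_crosses_half(self, std_calib):
        """p interpolated at the fitted midpoint is 1/2 (its definition)."""
        order = np.argsort(std_calib.u_eff)
        p_at_u0 = np.interp(
            std_calib.u0_mean, std_calib.u_eff[order], std_calib.p_active[order]
        )
        assert p_at_u0 == pytest.approx(0.5, abs=0.03)

    def test_alpha_times_midpoint_slope_is_quarter(self, std_calib):
        """For a logistic of scale alpha the midpoint slope is 1/(4 alpha);
        the fitted alpha and the finite-difference slope of the measured
        curve must reproduce that product."""
        prod = std_calib.alpha * std_calib.midpoint_slope()
        assert prod == pytest.approx(0.25, rel=0.05)

    def test_leak_map_is_affine_with_conductance_ratio_slope(self, std_calib):
        expected = std_calib.params.g_l / std_calib.g_tot_mean
        assert std_calib.leak_slope == pytest.approx(expected, rel=0.02)


class TestBiasToLeak:
    def test_zero_bias_targets_midpoint(self, std_calib):
        el = bias_to_leak(0.0, std_calib)
        u = std_calib.leak_slope * el + std_calib.leak_intercept
        assert u == pytest.approx(std_calib.u0_mean, abs=1e-9)

    def test_clamp_bias_saturates(self, std_calib):
        """b = +20 drives the neuron to fire at its refractory-limited
        maximum: activity > 0.999 of the achievable duty cycle."""
        el = bias_to_leak(20.0, std_calib)
        p = dataclasses.replace(std_calib.params, E_l=el)
        spec = LIFNetworkSpec(neurons=(p,), background=build_background(1))
        res = integrate(spec, duration=20000.0, dt=0.1, seed=6)
        z = states_from_spikes(res.spike_times, res.spike_units, 1, 20.0,
                               20000.0, 0.1)
        assert z.mean() > 0.985
        el0 = bias_to_leak(-20.0, std_calib)
        p0 = dataclasses.replace(std_calib.params, E_l=el0)
        res0 = integrate(
            LIFNetworkSpec(neurons=(p0,), background=build_background(1)),
            duration=20000.0, dt=0.1, seed=6,
        )
        assert res0.spike_times.size == 0


class TestWeightConversion:
    def test_zero_weight_maps_to_zero(self, std_calib):
        assert weight_conversion(0.0, std_calib) == 0.0

    def test_sign_convention(self, std_calib):
        assert weight_conversion(1.0, std_calib) > 0
        assert weight_conversion(-1.0, std_calib) < 0

    def test_beta_matches_psp_integral_quadrature(self, std_calib):
        """The translation matches the PSP time-average to alpha*W: verify
        against numerical quadrature of the closed-form PSP."""
        W = 1.0
        w = weight_conversion(W, std_calib)
        t = np.linspace(0, std_calib.params.tau_ref, 200_001)
        u = psp_shape(t, w, std_calib.params, std_calib.u_mean,
                      std_calib.g_tot_mean)
        integral = np.trapezoid(u, t) / std_calib.alpha
        assert integral == pytest.approx(W * std_calib.params.tau_ref, rel=0.01)

    def test_psp_integral_linear_in_weight(self, std_calib):
        """Driving-force-frozen PSP integral scales linearly over the
        working weight range (R^2 > 0.99)."""
        ws = np.array([0.002, 0.005, 0.01, 0.02, 0.04])
        t = np.linspace(0, 20.0, 20_001)
        ints = [
            np.trapezoid(
                psp_shape(t, w, std_calib.params, std_calib.u_mean,
                          std_calib.g_tot_mean), t)
            for w in ws
        ]
        r = np.corrcoef(ws, ints)[0, 1]
        assert r**2 > 0.99

    def test_degenerate_time_constants_use_limit(self, std_calib):
        params = dataclasses.replace(
            std_calib.params, tau_syn_exc=std_calib.tau_eff
        )
        w = weight_conversion(1.0, std_calib, params=params)
        assert np.isfinite(w) and w > 0


class TestNetworkFromBoltzmann:
    def test_single_unit_zero_bias_near_half_activity(self, std_calib):
        bm = BoltzmannMachine(W=np.zeros((1, 1)), b=np.zeros(1),
                              roles=("principal",))
        spec = network_from_boltzmann(bm, std_calib)
        res = integrate(spec, duration=50_000.0, dt=0.1, seed=8)
        z = states_from_spikes(res.spike_times, res.spike_units, 1, 20.0,
                               50_000.0, 0.1)
        assert abs(z.mean() - 0.5) < 0.03

    def test_five_unit_random_machine_samples_accurately(self, std_calib):
        """Moderate random couplings (sd 0.5): the LIF network's stationary
        distribution lies close to the Boltzmann target."""
        rng = np.random.default_rng(7)
        W = rng.normal(0, 0.5, (5, 5))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0)
        bm = BoltzmannMachine(W=W, b=rng.normal(0, 0.5, 5),
                              roles=("principal",) * 5)
        spec = network_from_boltzmann(bm, std_calib)
        T = 50_000.0
        res = integrate(spec, duration=T, dt=0.1, seed=11)
        z = states_from_spikes(res.spike_times, res.spike_units, 5, 20.0, T, 0.1)
        q = empirical_distribution(z).probabilities
        p = boltzmann_distribution(bm).probabilities
        assert dkl_norm(q, p) < 0.15

    def test_synapses_are_renewing_and_paired(self, std_calib):
        bm = BoltzmannMachine(
            W=np.array([[0.0, 1.0], [1.0, 0.0]]), b=np.zeros(2),
            roles=("principal",) * 2,
        )
        spec = network_from_boltzmann(bm, std_calib)
        assert len(spec.synapses) == 2
        assert all(s.renewing for s in spec.synapses)
        assert {(s.pre, s.post) for s in spec.synapses} == {(0, 1), (1, 0)}


def test_mean_conductance_analytic():
    p = LIFParams()
    # leak 2 uS plus 2 polarities * 400 Hz * 0.002 uS * 10 ms
    assert mean_conductance(p, 400.0, 0.002) == pytest.approx(2.016)
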