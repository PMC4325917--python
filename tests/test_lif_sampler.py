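import dataclasses

import numpy as np
import pytest
from scipy import stats

from spikesampling.calibration import mean_conductance, psp_shape
from spikesampling.lif_sampler import (
    LIFNetworkSpec,
    LIFParams,
    NoiseProfile,
    StimulusSpike,
    Synapse,
    apply_parameter_noise,
    build_background,
    build_correlated_background,
    integrate,
    renewing_conductance,
    sample_background_counts,
    spec_from_dict,
    spec_to_dict,
    states_from_spikes,
)


class TestIntegration:
    def test_resting_fixed_point(self):
        spec = LIFNetworkSpec(neurons=(LIFParams(E_l=-60.0),))
        res = integrate(spec, duration=10.0, dt=0.1, seed=1,
                        record_u=[0], threshold=False)
        np.testing.assert_allclose(res.u[:, 0], -60.0, atol=1e-12)

    def test_exponential_relaxation_toward_leak(self):
        """A displaced membrane decays back to E_l with time constant tau_m."""
        p = LIFParams(E_l=-60.0, tau_m=5.0, V_th=-10.0, tau_syn_exc=0.2)
        dt = 0.01
        # displace u with a brief conductance kick (tau_syn = 0.2 ms: the
        # kick is gone after a few ms, leaving pure leak relaxation)
        spec = LIFNetworkSpec(
            neurons=(p,), stimuli=(StimulusSpike(1.0, 0, 50.0),)
        )
        res = integrate(spec, duration=50.0, dt=dt, seed=1,
                        record_u=[0], threshold=False)
        u = res.u[:, 0]
        i0 = int(10.0 / dt)
        seg = u[i0 : i0 + 1000] + 60.0
        assert seg[0] > 0.5  # still measurably displaced
        ratio = seg[1:] / seg[:-1]
        np.testing.assert_allclose(ratio, np.exp(-dt / 5.0), rtol=1e-5)

    def test_unstable_dt_rejected(self):
        spec = LIFNetworkSpec(neurons=(LIFParams(),))
        with pytest.raises(ValueError):
            integrate(spec, duration=10.0, dt=0.2, seed=0)

    def test_refractory_enforces_minimum_isi(self):
        p = LIFParams(E_l=-45.0)  # suprathreshold leak: fires at maximum rate
        spec = LIFNetworkSpec(neurons=(p,), background=build_background(1))
        res = integrate(spec, duration=2000.0, dt=0.1, seed=2)
        isi = np.diff(np.sort(res.spikes_of(0)))
        assert isi.size > 50
        assert isi.min() >= p.tau_ref

    def test_seeded_determinism(self):
        spec = LIFNetworkSpec(
            neurons=(LIFParams(E_l=-50.2),), background=build_background(1)
        )
        a = integrate(spec, duration=2000.0, dt=0.1, seed=7)
        b = integrate(spec, duration=2000.0, dt=0.1, seed=7)
        np.testing.assert_array_equal(a.spike_times, b.spike_times)
        c = integrate(spec, duration=2000.0, dt=0.1, seed=8)
        assert not np.array_equal(a.spike_times, c.spike_times)

    def test_psp_matches_closed_form(self):
        """Single presynaptic spike on the high-conductance operating point
        reproduces the two-exponential PSP within 2% peak error."""
        p = LIFParams()
        g_e = 400 * 0.002 * p.tau_syn_exc * 1e-3
        g_i = 400 * 0.002 * p.tau_syn_inh * 1e-3
        g_tot = mean_conductance(p, 400.0, 0.002)
        u_rest = -50.1
        el = (u_rest * g_tot - g_i * p.E_rev_inh) / p.g_l
        pp = dataclasses.replace(p, E_l=el, const_g_exc=g_e, const_g_inh=g_i)
        w = 0.01
        spec = LIFNetworkSpec(neurons=(pp,), stimuli=(StimulusSpike(5.0, 0, w),))
        dt = 0.01
        res = integrate(spec, duration=60.0, dt=dt, seed=1,
                        record_u=[0], threshold=False)
        meas = res.u[:, 0] - u_rest
        t = np.arange(meas.size) * dt - 5.0 - dt
        pred = psp_shape(t, w, p, u_rest, g_tot)
        assert abs(meas.max() - pred.max()) / pred.max() < 0.02

    def test_free_potential_is_approximately_gaussian(self):
        p = LIFParams(E_l=-50.0)
        spec = LIFNetworkSpec(neurons=(p,), background=build_background(1))
        res = integrate(spec, duration=100_000.0, dt=0.1, seed=3,
                        record_u=[0], threshold=False)
        u = res.u[5000:, 0]
        assert abs(stats.skew(u)) < 0.2


class TestRenewingSynapses:
    def test_conductance_is_set_not_incremented(self):
        t = np.arange(0, 20, 0.01)
        g = renewing_conductance([2.0, 3.0], 0.5, 10.0, t)
        just_after = g[np.searchsorted(t, 3.0) + 1]
        assert just_after == pytest.approx(0.5, rel=1e-3)
        assert g.max() <= 0.5 + 1e-9

    def test_single_spike_pure_exponential(self):
        t = np.arange(0, 50, 0.1)
        g = renewing_conductance([0.0], 0.3, 10.0, t)
        np.testing.assert_allclose(g, 0.3 * np.exp(-t / 10.0), atol=1e-12)

    def test_tsodyks_markram_agrees_for_sparse_spikes(self):
        """Widely spaced spikes: depressing-synapse recovery is complete, so
        the explicit short-term-plasticity rule matches the renewal rule."""
        t = np.arange(0, 400, 0.05)
        spikes = [10.0, 150.0, 300.0]
        g1 = renewing_conductance(spikes, 0.4, 10.0, t, rule="renew")
        g2 = renewing_conductance(spikes, 0.4, 10.0, t, rule="tsodyks")
        assert np.max(np.abs(g1 - g2)) / 0.4 < 0.01

    def test_network_renewal_never_exceeds_weight(self):
        """A bursting presynaptic neuron renews (not stacks) its conductance:
        the PSP deflection from a sustained burst stays bounded by the
        single-spike deflection."""
        p = LIFParams()
        g_tot = mean_conductance(p, 400.0, 0.002)
        g_e = 400 * 0.002 * p.tau_syn_exc * 1e-3
        driver = dataclasses.replace(p, E_l=-40.0)  # fires at max rate
        u_rest = -50.1
        el = (u_rest * g_tot - g_e * p.E_rev_inh) / p.g_l
        reader = dataclasses.replace(
            p, E_l=el, const_g_exc=g_e, const_g_inh=g_e
        )
        w = 0.01
        spec = LIFNetworkSpec(
            neurons=(driver, reader),
            synapses=(Synapse(pre=0, post=1, weight=w, renewing=True),),
        )
        res = integrate(spec, duration=500.0, dt=0.1, seed=1,
                        record_u=[1], threshold=[True, False])
        n_spikes = res.spikes_of(0).size
        assert n_spikes >= 20
        peak_single = psp_shape(np.arange(0, 30, 0.01), w, p, u_rest, g_tot).max()
        assert res.u[:, 0].max() - u_rest < 1.5 * peak_single


class TestStatesFromSpikes:
    def test_no_spikes_all_zero(self):
        z = states_from_spikes([], [], 2, 20.0, 100.0, 0.1)
        assert z.sum() == 0

    def test_single_spike_window(self):
        z = states_from_spikes([10.0], [0], 1, 20.0, 50.0, 0.1)
        t = np.arange(z.shape[0]) * 0.1
        expected = (t >= 10.0) & (t < 30.0)
        np.testing.assert_array_equal(z[:, 0].astype(bool), expected)

    def test_burst_windows_merge(self):
        z = states_from_spikes([0.0, 15.0], [0, 0], 1, 20.0, 60.0, 0.1)
        t = np.arange(z.shape[0]) * 0.1
        expected = (t >= 0.0) & (t < 35.0)
        np.testing.assert_array_equal(z[:, 0].astype(bool), expected)


class TestBackgrounds:
    def test_independent_background_structure(self):
        bg = build_background(3, nu=400.0, w=0.002)
        assert len(bg.sources) == 6
        for s in bg.sources:
            assert len(s.targets) == 1
        assert bg.rate_onto(1, True) == 400.0
        assert bg.rate_onto(1, False) == 400.0

    def test_poisson_rate(self):
        bg = build_background(1, nu=400.0)
        c = sample_background_counts(bg, 100_000.0, 100_000.0, seed=1)
        assert abs(c[0, 0] - 40_000) < 3 * np.sqrt(40_000)

    def test_exc_inh_streams_independent(self):
        bg = build_background(1, nu=400.0)
        ce = sample_background_counts(bg, 100_000.0, 10.0, seed=5, excitatory=True)
        ci = sample_background_counts(bg, 100_000.0, 10.0, seed=5, excitatory=False)
        r = np.corrcoef(ce[:, 0], ci[:, 0])[0, 1]
        assert abs(r) < 0.05

    def test_correlated_background_structure(self):
        bg = build_correlated_background(6, nu=400.0, w=0.002)
        for exc in (True, False):
            for n in range(6):
                assert bg.rate_onto(n, exc) == pytest.approx(400.0)
            shared = [s for s in bg.sources
                      if s.excitatory == exc and len(s.targets) == 2]
            private = [s for s in bg.sources
                       if s.excitatory == exc and len(s.targets) == 1]
            assert all(s.rate == pytest.approx(40.0) for s in shared + private)
            counts = np.zeros(6)
            for s in shared:
                counts[list(s.targets)] += 1
            np.testing.assert_array_equal(counts, 3)

    def test_sharing_pair_count_correlation_near_ten_percent(self):
        bg = build_correlated_background(4, nu=400.0, w=0.002)
        c = sample_background_counts(bg, 200_000.0, 10.0, seed=3)
        r = np.corrcoef(c[:, 0], c[:, 1])[0, 1]
        assert abs(r - 0.1) < 3.0 / np.sqrt(c.shape[0])

    def test_odd_neuron_count_rejected(self):
        with pytest.raises(ValueError):
            build_correlated_background(5)


class TestParameterNoise:
    def test_zero_spread_is_identity(self):
        spec = LIFNetworkSpec(
            neurons=(LIFParams(),),
            synapses=(Synapse(0, 0, 0.01),),
        )
        zero = NoiseProfile(**{f: 0.0 for f in (
            "E_l", "tau_m", "tau_ref", "tau_syn", "E_rev_exc",
            "E_rev_inh", "V_th", "V_reset", "weight_cv")})
        out = apply_parameter_noise(spec, zero, seed=1)
        assert out.neurons[0] == spec.neurons[0]
        assert out.synapses[0].weight == pytest.approx(0.01)

    def test_refractory_jitter_statistics(self):
        spec = LIFNetworkSpec(neurons=tuple(LIFParams() for _ in range(1000)))
        out = apply_parameter_noise(spec, NoiseProfile(), seed=2)
        taus = np.array([p.tau_ref for p in out.neurons])
        assert abs(taus.mean() - 20.0) < 0.15
        assert abs(taus.std() - 1.0) < 0.15

    def test_weight_multiplier_statistics(self):
        spec = LIFNetworkSpec(
            neurons=(LIFParams(),),
            synapses=tuple(Synapse(0, 0, 1.0) for _ in range(1000)),
        )
        out = apply_parameter_noise(spec, NoiseProfile(), seed=3)
        ws = np.array([s.weight for s in out.synapses])
        assert abs(ws.mean() - 1.0) < 0.02
        assert abs(ws.std() - 0.1) < 0.02


def test_spec_json_round_trip():
    spec = LIFNetworkSpec(
        neurons=(LIFParams(E_l=-51.0), LIFParams()),
        synapses=(Synapse(0, 1, -0.004, delay=0.3, renewing=True),),
        background=build_background(2),
        stimuli=(StimulusSpike(5.0, 0, 0.01),),
        principal_neurons=(0,),
        state_tau_ref=20.0,
    )
    back = spec_from_dict(spec_to_dict(spec))
    assert back == spec
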