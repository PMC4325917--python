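"""Calibrating a LIF neuron as a stochastic sampling unit.

Under intense Poisson background the deterministic LIF neuron becomes
effectively stochastic: the probability of finding it in its refractory
state is a sigmoidal function of the mean free membrane potential u_eff.
Calibration measures that activation curve, fits the logistic
p = sigma((u_eff - u0)/alpha), and the two constants translate Boltzmann
biases (via the leak potential) and weights (via the PSP-average matching
factor beta) into neuron parameters.
"""

import dataclasses

import numpy as np

from spikesampling import calibrate
from spikesampling.calibration import bias_to_leak, weight_conversion
from spikesampling.lif_sampler import (
    LIFNetworkSpec, build_background, integrate, states_from_spikes,
)

calib = calibrate(duration=50000.0, free_duration=10000.0, seed=42)
print(f"activation midpoint  <u>_0 = {calib.u0_mean:.3f} mV")
print(f"voltage scale        alpha = {calib.alpha * 1000:.1f} uV per unit")
print(f"mean conductance    <g_tot> = {calib.g_tot_mean:.3f} uS "
      f"(tau_eff = {calib.tau_eff * 1000:.1f} us)")
print(f"weight translation   beta = {weight_conversion(1.0, calib) * 1000:.2f} nS per unit")

# round trip: realize bias b = 1 and check the isolated activity
b = 1.0
el = bias_to_leak(b, calib)
p = dataclasses.replace(calib.params, E_l=el)
spec = LIFNetworkSpec(neurons=(p,), background=build_background(1))
T = 50_000.0
res = integrate(spec, duration=T, dt=0.1, seed=3)
z = states_from_spikes(res.spike_times, res.spike_units, 1, 20.0, T, 0.1)
print(f"\nbias b = {b}: leak set to {el:.3f} mV")
print(f"  measured activity {z.mean():.4f}  vs  sigma(b) = {1/(1+np.exp(-b)):.4f}")
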