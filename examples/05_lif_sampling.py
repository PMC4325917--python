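"""End-to-end sampling from a random Boltzmann distribution with LIF neurons.

Draws a 5-unit Boltzmann machine with weights and biases from N(0, 0.5),
translates it into a conductance-based LIF network (one neuron per unit,
renewing synapses, independent Poisson background) and samples for 100 s
of biological time.  The sampled distribution is compared with exact
enumeration via the entropy-normalized KL divergence.
"""

import numpy as np

from spikesampling import boltzmann_distribution, calibrate, dkl_norm
from spikesampling.bm_translation import BoltzmannMachine
from spikesampling.calibration import network_from_boltzmann
from spikesampling.evaluation import empirical_distribution
from spikesampling.lif_sampler import integrate, states_from_spikes

calib = calibrate(duration=20000.0, seed=42)

rng = np.random.default_rng(7)
W = rng.normal(0, 0.5, (5, 5))
W = (W + W.T) / 2
np.fill_diagonal(W, 0)
bm = BoltzmannMachine(W=W, b=rng.normal(0, 0.5, 5), roles=("principal",) * 5)

spec = network_from_boltzmann(bm, calib)
T = 100_000.0
res = integrate(spec, duration=T, dt=0.1, seed=11)
z = states_from_spikes(res.spike_times, res.spike_units, 5, 20.0, T, 0.1)
q = empirical_distribution(z).probabilities
p = boltzmann_distribution(bm).probabilities

print(f"network: 5 neurons, {len(spec.synapses)} synapses, "
      f"{res.spike_times.size} spikes in {T/1000:.0f} s")
print("\nstate   target   sampled")
for s in range(32):
    bits = format(s, "05b")[::-1]
    print(f"{bits}   {p[s]:.4f}   {q[s]:.4f}")
print(f"\nnormalized KL divergence D_KL(q||p)/H(p) = {dkl_norm(q, p):.4f}")
print("Values of a few 1e-3 mean the spike dynamics reproduce the target "
      "distribution almost exactly.")
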