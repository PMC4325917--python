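"""Sampling-based inference with the abstract stochastic-neuron network.

Clamps the Knill-Kersten evidence (Z3, Z4) = (1, 0), runs the
refractory-variable Markov chain for 10^6 update steps (rectangular PSPs,
which make the chain asymptotically exact), and compares the sampled
posterior with exact enumeration.  The alpha-PSP variant trades exactness
for biological realism.
"""

from spikesampling import run_knill_kersten

for mode in ("abstract-rect", "abstract-alpha"):
    r = run_knill_kersten(
        mode=mode, evidence={"Z3": 1, "Z4": 0}, duration=1000.0, seed=1
    )
    print(f"{mode} ({r['duration_s']:.0f} s of sampling):")
    for nid in ("Z1", "Z2"):
        print(
            f"  p({nid}=1 | e): sampled {r['inferred_marginals'][nid]:.4f}"
            f"  exact {r['exact_marginals'][nid]:.4f}"
        )
    print(f"  normalized KL over free variables: {r['dkl_norm_free']:.2e}\n")

print(
    "Rectangular PSPs sample the exact posterior (KL -> 0 with time);\n"
    "the alpha kernel deviates because its interaction is not constant\n"
    "over the refractory window."
)
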