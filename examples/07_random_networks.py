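"""Sampling quality across random Bayesian networks.

Generates random 5-variable networks by edge toggling (50000 iterations)
with Beta(eta, eta) conditionals and measures the final normalized KL of
the abstract samplers after 20 s.  Larger eta concentrates conditionals
near 0.5, decoupling the variables and making the task easier.
"""

from spikesampling import run_random_bn_sweep

r = run_random_bn_sweep(
    etas=(0.3, 1.0, 10.0), graphs_per_eta=5, duration=20.0,
    modes=("abstract-rect", "abstract-alpha"), seed=6,
)
print("median normalized KL after 20 s (5 graphs per eta):\n")
print("eta     rectangular   alpha")
for eta in r["etas"]:
    med_r = r["median"]["abstract-rect"][str(eta)]
    med_a = r["median"]["abstract-alpha"][str(eta)]
    print(f"{eta:4}    {med_r:10.4f}   {med_a:.4f}")
print(
    "\nBoth columns shrink as eta grows (weaker dependencies are easier\n"
    "to sample); the exact rectangular kernel beats the alpha kernel\n"
    "throughout."
)
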