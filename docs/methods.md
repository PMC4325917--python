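# Methods

This note records the scientific and numerical choices behind
`spikesampling`: the model each module implements, the parameters that
matter, what the synthetic inputs emulate, and the known limitations.

## Graphical models and compilation

Bayesian networks are restricted to binary variables; conditional
probability tables (CPTs) are indexed by the parent assignment with the
first parent as the least-significant bit, and full network states use the
same convention (node 0 = LSB of the state index). Exact enumeration —
the oracle every sampler is judged against — is guarded at 20 variables.

Compilation turns each node's conditional into one factor over the node
and its parents. Order-1 factors become biases `log Φ(1)/Φ(0)`; order-2
factors become the symmetric coupling `log[Φ(0,0)Φ(1,1)/(Φ(0,1)Φ(1,0))]`
plus member biases; an order-n factor (n > 2) is expanded into 2ⁿ
auxiliary units with couplings ±M and biases
`log(μΦ(z)/min Φ − 1) − |z|₁·M`. Two choices deserve comment:

* **Factor tables are the raw conditionals.** The auxiliary-bias formula
  already normalizes each table by its minimum, and the guard
  μ = 1 + 10⁻⁴ keeps the logarithm finite at the minimum entry, so no
  additional rescaling is applied. Per-factor rescalings cancel in the
  global normalizer and would only inflate M (a rescale pushing all
  entries above 1 multiplies M by the table's dynamic range, making the
  expansion numerically exact at every γ and hiding the finite-M behavior
  that the γ parameter is meant to control).
* **M = γ·max Φ with γ = 10** (γ = 5 in the noisy operating profile).
  With probability-valued tables this puts M near γ, where the finite-M
  error is measurable and decreases roughly a hundredfold per γ-doubling
  (Knill–Kersten fixture: total variation 2.5·10⁻² at γ = 5,
  2.9·10⁻⁴ at γ = 10, 3.2·10⁻⁶ at γ = 15).

CPT entries must lie strictly inside (0, 1) for compilation; the random
generator clips its Beta draws at 10⁻⁶ accordingly. Clamping replaces a
principal unit's bias by ±20 (σ(20) ≈ 1 − 2·10⁻⁹); exact targets condition
on the clamp exactly rather than using the large-bias approximation.

## Abstract sampler

The stochastic-neuron chain uses a refractory counter ζ ∈ {0, …, τ} with
τ = 20 steps. One step of the chain is a full sweep over the units in a
fresh random permutation (the update schedule is not specified by the
underlying theory; random sweeps avoid any systematic order bias, and
each single-unit update leaves the extended stationary distribution
invariant, so the rectangular-kernel chain samples the Boltzmann
distribution exactly in the long run). With one update step per
millisecond, τ = 20 aligns with the LIF refractory period of 20 ms.

The alpha-shaped interaction kernel
`q₁·[e·(t/τ_α + t₁)·exp(−t/τ_α − t₁) − ½]` on `0 < t < (t₂−t₁)τ_α`
uses q₁ = 2.3 and τ_α = 17 ms · τ_ref/30 ms; t₁ < t₂ are the two roots of
`e·t·e^{−t} = ½`, found by bracketed root finding to 10⁻¹⁰. Alpha-kernel
contributions superpose over past spikes (no renewal in the abstract
domain); the refractory state variable itself is unchanged. Clamped units
never transition; a clamped-on unit emits one spike per refractory period
so rate read-outs reflect saturation.

## LIF simulator

The simulator integrates `C_m du/dt = g_l(E_l − u) + Σ g_syn(E_rev − u)`
with exponential Euler: within each step all conductances are constant, so
the membrane relaxes exactly toward the conductance-weighted equilibrium.
This is the appropriate scheme for the stiff operating point
(τ_m = 0.1 ms with dt = 0.1 ms); the default dt equals the synaptic delay
resolution. Threshold crossing resets u to ρ, where it is held for
τ_ref; synaptic conductances keep evolving during refractoriness.
Spike-state read-out marks a neuron as 1 on [t_spike, t_spike + τ_ref),
with overlapping windows merged, so burst firing extends the state window
— the same duty-cycle definition the calibration measures.

Recurrent synapses renew: a presynaptic spike sets the conductance to the
weight instead of incrementing it. This is the U₀ = 1, τ_facil = 0,
τ_rec = 0.99·τ_syn limit of Tsodyks–Markram depression (the recovery
`1 − exp(−Δt/τ_rec)` exactly replaces what the previous PSP has not yet
decayed); both forms are implemented and agree within 1% for spikes
spaced beyond a few τ_syn. Background inputs are plain (non-renewing)
Poisson conductance sources: one private excitatory and one private
inhibitory source per neuron at ν = 400 Hz, w = 0.002 μS in the standard
profile. Background weights are equal in magnitude for both polarities;
the reversal potentials (0 / −100 mV) provide the sign.

The correlated-background variant splits each neuron's rate over ten
sub-sources at ν/10 — seven private, three shared — with every shared
source projecting onto exactly two neurons, so two paired neurons share
one source per polarity and their summed inputs correlate at 10% without
higher-order correlations. The default pairing is a 3-regular circulant
(neighbors ±1 plus the antipode), requiring an even neuron count ≥ 4.
Excitatory and inhibitory pools are disjoint, leaving single-neuron
activation functions untouched.

Fixed-pattern parameter noise redraws each neuron parameter from a
Gaussian centered on its current value (spreads: 2 mV on the resting
potential and reversal potentials, 0.1 ms on τ_m, 1 ms on τ_ref, 2 ms on
τ_syn, 0.5 mV on threshold and reset) and multiplies every synaptic
weight by ε ~ N(1, 0.1); draws violating parameter invariants are
redrawn. The "noisy" operating profile is a genuinely different working
point (τ_m = 1 ms, τ_syn = 20 ms, ν = 5 kHz at 1 nS, 1.2 ms delays,
γ = 5), used as the nominal around which the jitter is applied.

## Calibration

Calibration is empirical throughout: no first-passage-time formula is
evaluated. The activation curve is measured on a leak-potential grid
chosen adaptively — a pilot run measures the free-potential standard
deviation σ_u at threshold, and the grid spans ±6 σ_u around threshold
with a 0.3 σ_u-spaced core — with two simulations per point (threshold
disabled for the mean free potential u_eff, threshold enabled for the
refractory-state duty cycle). Defaults: 20 s per activation point, 5 s
per free-potential point; the acceptance measurements use 100 s / 10 s.

The logistic fit `p = σ((u_eff − ⟨u⟩₀)/α)` supplies the voltage scale α;
the midpoint ⟨u⟩₀ is then refined to the u_eff where the *measured* curve
crosses ½ (local linear fit over the transition points), because the
measured curve is slightly asymmetric — the duty cycle saturates at
τ_ref/(τ_ref + dt) rather than 1 — which would otherwise bias the global
fit's midpoint by ~0.02 in p.

**A documented departure from the idealized picture:** with Table-value
background the membrane noise is correlated on τ_syn = 10 ms, about half
a refractory period, so the activation curve is closer to a probit than a
logistic. Its true midpoint slope (measured by high-precision finite
differences; locally constant within ±1 α) is ~9% shallower than the
fitted logistic's 1/(4α). The fitted α is nevertheless the right
translation constant: the bias round trip (isolated activity = σ(b) for
b ∈ [−2, 2]) holds within 3 standard errors at 100 s, which a
slope-defined α would break at the range's edge. The
`measure_midpoint_slope` helper quantifies this consistency (it averages
offset secants of width α/2, unbiased under local linearity).

Derived constants: ⟨g_tot⟩ = g_l + Σ ν·w·τ_syn analytically (the mean
conductance of an exponential synapse under Poisson input; the measured
leak-map slope g_l/⟨g_tot⟩ agrees within 2%), τ_eff = C_m/⟨g_tot⟩, and
⟨u⟩ frozen at the measured midpoint potential. The weight factor β
follows from matching the time-average of the closed-form PSP over
[0, τ_ref] to α·W; the equal-time-constant degeneracy (τ_syn = τ_eff) is
evaluated by its analytic limit. Biases map to leak potentials by
inverting the measured affine leak → u_eff relation.

## Chain coupling

Chain networks replace each Boltzmann unit by one sampling neuron
(τ_ref = 29.5 ms, τ_syn = 30 ms, reset 0.01 mV below threshold) and five
forwarding neurons (τ_ref = 29.3 ms, τ_syn = 2 ms, reset = rest =
−52.3 mV), wired feed-forward with 5.8 ms delays (5.9 ms into the last
neuron) and 0.16 μS drive. Every coupling w (from the standard weight
translation, calibrated with the *chain* sampling-neuron parameters)
projects as: sampling → sampling with w, each forwarding neuron with
0.180·w, and the last forwarding neuron with −0.815·w, all at 0.1 ms
delay. The 0.815 magnitude matches the total excitatory conductance
remaining at the window's end, so the opposing PSP cuts the tail to a few
percent of the peak. The state window in chain mode is the sampling
neuron's 29.5 ms refractory period. Forwarding neurons receive the same
standard background as sampling neurons.

The composite-PSP measurement drives one chain with an external kick and
averages the background-subtracted free potential of a target sampling
neuron over ≥100 trials; the measurement harness extends the driver's
refractory period past the recording window so the slowly decaying kick
conductance cannot re-trigger a second volley. A "frozen" variant
replaces Poisson sources with constant mean conductances for a noise-free
single-trial trace. Shape quality is the L2 distance between the
peak-normalized trace and the peak-normalized rectangle over 1.5 windows:
0.14 for the chain PSP (frozen) versus 0.61 for a single PSP.

## Random networks

The generator starts from the index chain Z₁ → … → Z_K and toggles the
edge of a uniformly drawn unordered pair per iteration, rejecting toggles
that exceed a total degree of 7 per node or disconnect the skeleton; a
rejected toggle still consumes an iteration. Edges are stored oriented
from lower to higher index: the toggling rule is sometimes stated with
added edges pointing from higher to lower index, which would immediately
break the acyclicity of the index-ordered start graph, whereas the
low → high convention preserves the DAG property while leaving the
undirected toggling dynamics unchanged.
Conditionals are i.i.d. Beta(η, η), clipped to [10⁻⁶, 1 − 10⁻⁶].

## Experiments and study conditions

The Knill–Kersten fixture uses the standard four-variable structure
p(Z₁)p(Z₂)p(Z₃|Z₁,Z₂)p(Z₄|Z₂). **Its CPT values are synthetic** — the
source literature does not print them — and configurable; the defaults
(uniform priors, 0.1/0.9 likelihoods encoding "shading follows from a
reflectance step or a cylinder" and "round contour indicates a cylinder")
produce a textbook explaining-away posterior. With these values the
compiled machine carries couplings of magnitude up to
log(81) ≈ 4.4 and M ≈ 9 — a deliberately hard test for single-PSP LIF
coupling (see limitations).

Default experiment scales are desk scale and labeled as such in every
report: 10 s inference runs, 5 graphs per η at 20 s for sweeps, 5–10
robustness trials; the full-study protocol (30 graphs, 100 s, 10 trials)
is reached through the same entry points by raising the parameters.
Sampling durations in the test suite (50–100 s) were chosen so that
Monte-Carlo error is well below the effects being tested.

## What the synthetic inputs do and do not emulate

Generated Boltzmann machines (weights/biases ~ N(0, 0.5)) and random
Bayesian networks probe the samplers across coupling strengths and graph
topologies; the Poisson background emulates in-vivo-like diffuse input.
None of these reproduce structured sensory statistics, dale-compliant
connectivity, or learned weights; passing tests demonstrates the
correctness of the sampling machinery and its translation rules, not
performance on biological data.

## Known limitations

* Single-PSP LIF coupling degrades for |W| ≳ 2: the exponential PSP is
  ~2.3× its average at onset and ~0.3× at the end of the window, exactly
  where the burst-continuation decision falls, so strongly coupled pairs
  over-commit to aligned states. This is the documented PSP-shape
  deviation that motivates the chain coupling, which restores the correct
  posterior ordering on the Knill–Kersten task (and halves the median
  normalized KL on random 4-variable networks in the acceptance suite).
* The activation function is probit-like at this operating point (noise
  correlation ≈ τ_ref/2); the logistic is a ~3% (p-scale) approximation
  with a ~9% shallower true midpoint slope than the fit implies.
* The abstract and LIF domains are aligned only through (α, ⟨u⟩₀, β);
  higher moments of the interaction (PSP shape) are not matched except in
  chain mode.
* Evidence switching mid-run restarts the LIF network at the switch
  (synaptic state is not carried over); with τ_syn ≤ 30 ms the carried
  state decays within ~0.1 s, negligible at the 10–100 s analysis scale.
* The degree-capped edge-toggling generator is not guaranteed to sample
  uniformly from the space of DAGs; it implements the toggling procedure
  itself, not a uniformity theorem.
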