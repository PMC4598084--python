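# Methods

`repeatloop` models how an adapting positive auditory-feedback loop shapes
the number of times a songbird repeats a syllable. This note documents the
models, the free choices made where the design was genuinely open, the
numerical conventions, and what the tests do and do not establish.

## Short-term synaptic depression

A depressing synapse of base strength `g0` loses a fixed fraction `alpha`
of its current strength at every transmitted spike and recovers between
spikes with first-order kinetics, `tau_R dg/dt = -(g - g0)`. Both pieces
are analytic, so `simulate_depressing_synapse` is event-exact: it applies
the closed-form recovery between events and the multiplicative drop at each
spike, with no time-stepping error. For a regular train at rate `f` the
pre-spike relative strength obeys an affine map `A -> a + rA` with
`a = 1 - exp(-1/(tau_R f))` and `r = (1-alpha) exp(-1/(tau_R f))`, giving a
geometric decay toward `g_inf/g0 = a/(1-r)` with continuous-time constant
`tau = tau_R / (1 - tau_R f log(1-alpha))`. These closed forms also describe
the mean behaviour under Poisson drive at the same rate, which the tests
verify against the event-exact simulator using block-averaged standard
errors (pre-spike strengths are autocorrelated over ~`tau f` spikes, so a
naive s.e. would be badly optimistic).

`alpha = 0` makes the decay amplitude zero; `slow_scale_summary` flags this
degenerate case instead of raising because the Markov special case of the
statistical model needs it.

**Constituent matching.** A single model synapse driven at `f` stands in
for `N` lower-rate constituents at `f/N`. Matching both the steady state
and the decay constant gives two equations in `(alpha', tau_R')`. Given
`alpha'`, the decay-constant equation is linear in `tau_R'` and only has a
positive solution for `alpha'` below a critical value
`1 - exp(-1/(tau* f/N))`; the steady-state residual changes sign on that
interval and is solved by Brent's method (`xtol = 1e-14`), with the final
residual checked against 1e-10. With the default parameters
(`alpha = 0.006`, `tau_R = 3.25 s`, `f = 1340 Hz`) and `N = 50` this yields
`alpha' ~ 0.261`, `tau_R' ~ 3.75 s`.

## Sigmoidal adaptation model of repeat numbers

The repeat probability after `n` completed renditions is
`p_r(n) = 1 - c/(1 + a b^n)`, derived from a sigmoid of feedback strength
`p_r(A) = 1 - c/(1 + eta A^nu)` and exponential feedback decay
`A(n) = a0 exp(-n T / tau)`, with `a = eta a0^nu` and
`b = exp(-nu T / tau)`. The repeat-number distribution is
`P(N) = (1 - p_r(N)) prod_{n<N} p_r(n)`; probabilities plus the explicit
tail mass sum to one exactly. `b = 1` recovers the Markov (geometric)
model; `c = 1` with `a b << 1` recovers geometric adaptation
(`p_r(n) ~ a b^n`).

**Simulation.** `simulate_bouts` computes `tau` from the depression
parameters (`tau = tau_R / (1 - tau_R f log(1-alpha))`), then draws
uniforms sequentially against `p_r(k)` until the first exceedance.
Adaptation strengths below 0.001 are clamped (with a warning) because the
peak repeat number diverges as adaptation vanishes. Defaults: 10,000 bouts,
`T = 0.1 s`, `f = 1340 Hz`, `tau_R = 3.25 s`.

**Defaults for (eta, nu, c).** The sigmoid shape constants are not free
inputs of the theory; they summarise how strongly a chain's repeat
probability responds to feedback conductance. The packaged defaults
(`eta = 1.22e7`, `nu = 7.1`, `c = 0.633`, with `A` in mS/cm^2) are the
least-squares fit of the sigmoid to this package's own reduced-network
transition data (60 trials at the default reduced configuration), exposed
in `DEFAULT_STAT_CONSTANTS` and overridable everywhere they are used.

**Fitting.** `fit_sigmoidal` minimises the summed squared error between
model and observed repeat-number probabilities over `0 < a < 1e8`,
`0 < b < 1`, `0 < c < 1`, searching `a` on a log10 scale, with the best of
20 random restarts (`a ~ log-uniform(1e-2, 1e6)`, `b, c ~ U(0.01, 0.99)`).
The support is truncated at three times the largest observed repeat number
plus 20; the tail mass is tracked, never silently dropped. Because
`(a, b, c)` are near-degenerate (a ridge trades `a` against `b`), recovery
is assessed on the `p_r(n)` curve, not on raw parameters. Serial state
chains with geometric adaptation (single state, two repeating states,
prefix of forced states) are fitted the same way; their exact distributions
come from convolving per-state rendition-count laws.

**Distribution comparison.** The distance between two distributions is the
maximum absolute pointwise difference divided by the maximum of both
distributions; it is symmetric and lies in [0, 1]. The benchmark error —
the fit-quality yardstick — is the 80th percentile of that distance over
1000 random split-halves of the bout-level data (an odd leftover bout goes
to the first half). Both the fit objective `E` and the distance `d` are
reported in `FitResult`, since fit quality is judged by `d` against the
benchmark while the optimiser minimises `E`.

**Phase diagram.** `phase_diagram` simulates bouts on a grid of initial
feedback strength `a0` and adaptation strength `alpha` and records the peak
(modal) repeat number, with ties broken toward the smaller repeat number
(conservative toward the Markov classification). With the packaged
constants it reproduces the expected structure: peak 1 everywhere at
`a0 = 0`, non-decreasing in `a0`, non-increasing in `alpha`, and a sharp
Markov-to-non-Markov threshold along each adaptation row.

## Branched-chain spiking network

Syllables are encoded by feed-forward chains of 20-neuron pools (reduced
tier) or 60-neuron pools (full scale); the default topology is
`a -> b`, `b -> {b, c}`, `c` terminal, so chain b repeats a variable number
of times before activity exits to chain c.

**Neurons.** HVC_RA cells are two-compartment conductance-based models:
a soma with Na/K spiking currents (Wang-Buzsaki rate kinetics) and a
dendrite with a high-threshold Ca current plus a Ca-gated K current that
terminates the regenerative depolarisation after ~5 ms, ohmically coupled
so a dendritic Ca spike drives a short somatic burst. HVC_I cells are
single-compartment fast-spiking neurons with an added high-threshold K
current. The exact channel constants are free parameters of this package;
they were calibrated once against three phenomenological targets — ~3 mV
somatic subthreshold fluctuations under background noise (measured
2.98 mV), ~10 Hz inhibitory baseline rate (11.9 Hz), and a ~5 ms dendritic
Ca spike (5.3 ms) — and frozen in `network/engine.py`.
`scripts/calibrate_network.py` reproduces the measurements.

**Connectivity and inputs.** Pool-to-pool weights are uniform on
`(0, g_ee_max)`; chain-end to chain-start connections follow the branch
topology, optionally scaled by a per-branch multiplier — the relative
connection strengths at a branch set the baseline (no-feedback) transition
probabilities, and the reduced tier uses a 1.5x self-connection for chain
b. E->I and I->E connections are Bernoulli-sparse with uniform strengths.
Every compartment receives 500 Hz Poisson noise (each kick uniform up to
the printed ceiling, excitatory or inhibitory with equal probability) and
each HVC_RA soma a 1000 Hz excitatory drive.

**Winner-take-all.** Inhibition from HVC_I is delivered to the dendritic
compartment, where it gates Ca-spike ignition: two co-active chains drive
the interneuron population into a superlinear response (the reduced-tier
E->I ceilings are deliberately kept below saturation so one versus two
active chains are discriminable), and the laggard chain's next pool fails
to ignite. Routing the competition through the dendrite rather than the
soma is essential at reduced scale: somatic inhibition strong enough to
resolve the competition vetoes single-chain propagation outright.

**Feedback.** Each neuron of a target chain carries one depressing
feedback synapse per nonzero source chain, with base strength uniform on
`(0, G_ij)`, driven by an independent Poisson process at 1340 Hz while the
source syllable's feedback is active. Depression is updated event-exactly
(closed-form recovery between feedback spikes). Feedback is gated by an
online onset detector: when the 4th pool of a chain fires above
43 Hz/neuron within a 5 ms window, feedback from that syllable starts
after the sensory-motor delay and stays on for the configured feedback
duration. The full-scale configuration keeps the reference 40 ms delay and
a 100 ms duration (the traversal time of a 20-pool chain); the reduced
tier shortens the delay to 15 ms and duration to 40 ms because its
syllable lasts only ~37 ms and feedback arriving after the branch decision
could never influence it — the same delay-versus-syllable-duration
constraint discussed for very short syllables.

**Numerics.** Fourth-order Runge-Kutta at `dt = 0.02 ms` (reduced) or
0.01 ms (full) with synaptic conductances frozen over the step and decayed
analytically between steps; rate functions via lookup tables (0.05 mV
grid, linear interpolation); spikes detected by upward crossing of -20 mV
with a 2 ms refractory period; spike-triggered kicks delivered through a
3.5 ms conduction+synaptic delay buffer, which (with the burst rise time)
sets the ~4.7 ms pool-to-pool latency. Trials start with a 5 ms
suprathreshold current step into the first pool of chain a and end when
the last pool of the terminal chain fires, when the duration cap is
reached (`hit_cap`, the perseveration signature), or when excitatory
activity has been extinct for 150 ms (nothing can reignite the calibrated
network once propagation dies).

**Behaviour and known limitations.** With feedback off the repeat
histogram peaks at 1; at the reduced-tier default (`G_bb = 1.0 mS/cm^2`,
`alpha = 0.006`) bouts of 5-12 sequential renditions appear with a peaked
histogram, the mean feedback-synapse strength decays with a fitted time
constant of ~110-120 ms (closed-form prediction 119 ms), and the repeat
probability declines sigmoidally with feedback strength; with depression
disabled every trial perseverates to the cap. Two imperfections of the
reduced tier are documented rather than hidden: occasional transient
double waves circulate the repeating chain (inflating a bout's rendition
count by one or two), and in roughly one trial in twelve the final
b-to-c transition is contested, with both chains briefly co-propagating
beyond the nominal ~20 ms competition window before one dies; a minority
of such contests extinguish both chains, ending the trial without a
terminal traversal. The full-scale configuration preserves the reference
constants but is not exercised routinely; `scripts/full_scale_replication.py`
runs it as a long job, and exact reproduction of the reference full-scale
numbers (peak repeat 6, 148 ms fitted decay) is expected only
approximately because the channel constants are calibrated, not copied.
The reduced network does land on a peak of 6 and a ~110 ms decay under
the acceptance-script conditions.

## Sequence analytics

Repeat numbers are the lengths of maximal runs of identical consecutive
labels; runs never span bout boundaries, and runs truncated at bout edges
count as complete (how truncated songs were treated upstream is not
recoverable from label files). Syllables are classified NR (support only
at 1), MR (peak 1) or nMR (peak > 1). Double-peaked histograms — a sharp
peak at repeat number 1 plus a distant second mode, the signature of two
neural substrates mapping to one syllable — are flagged when the count at
1 is a local maximum, a second local maximum at `N >= 4` carries at least
5% of the total count, and the trough between them is at most half the
smaller peak; trimming removes only the `N = 1` bin. The prominence
floor exists because sampling noise in long geometric tails otherwise
registers spurious second modes. The flag is always reported so users can
override. Pseudo-random stimulus strings concatenate natural and
non-natural subsequences (k-mers present in, respectively absent from,
the supplied song corpus) of lengths 1-10 with equal probability until
each of 10 strings reaches 1000 labels.

## Synthetic data

`fixtures` generates labeled bouts of the form `a b^N c` with `N` drawn
from a named model (sigmoidal, Markov, geometric adaptation, or serial
state chain), homogeneous Poisson spike trains, and deterministic toy
rasters for the onset detector. All generators are reproducible under a
seed and emit the exact file dialects the analysis functions read. The
bout generator emulates the sequence statistics only: real song has
acoustic variability, intro notes, multi-syllable grammars and annotation
errors, none of which are modelled — passing tests demonstrate the
statistical machinery, not robustness to real-world labeling noise.

## What the tests show

The depression module is verified against its own closed forms (an
independent derivation path) and the reference constituent-matching
values; the statistical model against million-bout Monte-Carlo sampling
and parameter-recovery experiments; the network against the three
calibration targets, the depression module's closed forms (the fitted
feedback decay matches the slow-scale prediction within 30%), and the
Markov/non-Markov/perseveration dichotomy at reduced scale. None of this
establishes that the biological system works this way; it establishes
that the implementation faithfully realises the models it claims to.
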