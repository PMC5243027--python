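# Methods

## The model

`attractorchoice` simulates two-alternative perceptual decisions with a
spiking winner-take-all circuit. Two pools of 240 pyramidal cells — selective
for leftward and rightward motion — sit inside a population of 1600 pyramidal
cells, alongside 400 inhibitory interneurons. The selective pools excite
themselves through recurrent AMPA and NMDA synapses and suppress each other
through the shared interneuron pool; this combination makes the circuit settle
into a state where one pool fires vigorously and the other is silenced, which
is read out as the choice.

Neurons are conductance-based exponential integrate-and-fire units,

```
C dV/dt = −g_L (V − E_L) + g_L Δ_T exp((V − V_T)/Δ_T) − I_syn + I_inj
```

with a spike registered when V crosses V_s = −20 mV, reset to V_r = −53 mV
and a 2 ms (pyramidal) or 1 ms (interneuron) refractory period during which
V is clamped at V_r while synaptic states keep evolving. Synaptic currents
are ohmic, `I = g(t)(V − E)`, with exponential conductance decay for AMPA
(τ = 2 ms) and GABA_A (τ = 5 ms) and a bi-exponential rise/decay
(τ₁ = 2 ms, τ₂ = 100 ms) plus magnesium-block voltage gating
`1/(1 + [Mg²⁺] e^(−0.062V)/3.57)` for NMDA. The slow NMDA kinetics are what
lets the winning pool's activity linger for seconds after a decision — the
substance of every hysteresis result below. Per-contact maximal conductances,
reversal potentials and membrane constants are the standard values of this
model family and ship as the packaged `default` preset.

Simulated direct-current stimulation is a constant injected current per
neuron, applied at every integration step of a session: depolarizing
stimulation injects +0.75 pA into pyramidal cells and −0.375 pA into
interneurons; hyperpolarizing stimulation flips both signs. In the
physiological sign convention used by the interface (positive depolarizes)
the steady-state membrane shift is `I/g_L` — 0.0375 mV and 0.019 mV at these
magnitudes, deliberately subthreshold. Falsification controls
(pyramidal-only, interneuron-only, uniform-sign) zero or copy these
currents.

### Sign conventions

`I = g(V − E)` makes excitatory currents negative (inward); the membrane
equation subtracts the synaptic total, so excitation depolarizes. The
injected stimulation current uses the opposite (physiologist's) sign at the
interface, and the integrator subtracts it from the synaptic total. The
leak term is implemented with the stabilizing sign (−g_L(V − E_L)); the
positive-leak variant is dynamically unstable and cannot be what produced
winner-take-all behavior in this model family.

## Wiring and the contact-count calibration

Connectivity is Bernoulli at the standard probabilities: 0.08 for pyramidal
recurrence (selective recurrence stays within each pool), 0.1 for
pyramidal→interneuron and interneuron recurrence, 0.2 for
interneuron→pyramidal, with a 0.5 ms axonal delay (one integration step).
No autapses; identical wiring seeds give identical adjacency.

The per-contact conductances descend from a densely connected reference
circuit. At sparse Bernoulli wiring the per-neuron recurrent totals drop by
roughly the wiring probability, and the network then has no spontaneous
activity and no attractor competition at all. The package therefore treats
each realized connection as a bundle of synaptic contacts, with
pathway-specific counts chosen once so that per-neuron conductance totals
return to the dense-equivalent scale (≈ 1/p per pathway, doubled on the
GABA pathways to compensate the shorter GABA decay here):

| constant | value | pathway |
| --- | --- | --- |
| `contacts_ee` | 12.5 | pyramidal → pyramidal |
| `contacts_ei` | 6.8 | pyramidal → interneuron |
| `contacts_ie` | 7.0 | interneuron → pyramidal |
| `contacts_ii` | 20.0 | interneuron → interneuron |
| `w_plus` | 1.48 | extra potentiation of within-selective-pool contacts |
| `ampa_rec_scale` | 2.0 | extra efficacy of fast recurrent AMPA |

`w_plus` is the within-pool potentiation familiar from dense attractor
models; here it is the single most sensitive constant, because it sets the
lifetime of the decaying post-decision activity. The calibration targets
were fixed in advance and are properties the circuit must have, not outcomes
of any test: a stable spontaneous state with pyramidal cells at a few Hz and
interneurons below ~10 Hz; ignition of the stimulated pool above the 18–22 Hz
read-out band (on the smoothed trace) with the loser suppressed toward 0 Hz;
and post-offset tail activity that decays over roughly one to a few seconds —
present at a 2 s inter-stimulus interval, gone by 5 s. The calibrated values
sit deliberately close to the bifurcation between "tail dies instantly" and
"tail persists forever"; that marginality *is* the mechanism under study.

Non-selective pyramidal cells are passive by default: they receive background
input and project to the interneurons, but have no recurrent excitatory loops
of their own (`nonselective_policy="passive"`). With full recurrent coupling
a 1120-cell pool either ignites itself as a third attractor or routes its
tonic drive through the selective cells' saturating NMDA state and swamps
the within-pool feedback; both destroy the two-choice competition. The
`"recurrent"` policy is retained as a switch for sensitivity work.

## Synaptic state and saturation

One state variable is kept per (neuron, synapse kind). On presynaptic spike
arrival the conductance is, by default, *incremented* by the per-contact
maximum (`synaptic_update="add"` — the behavior of the simulator generation
this model family was built on); the saturating set-to-maximum variant is
available as `"set"`. Set-to-maximum cannot be the operative rule for the
external pathways here: a single ~900 Hz background train capped at 2.1 nS
leaves every neuron ~12 mV below threshold, permanently silent.

The NMDA state is the exception: its jumps are scaled by the remaining
capacity `1 − h/(in-degree × contacts)`, so accumulation is linear at low
rates but bounded by the value it would take if every afferent contact were
saturated. Unbounded NMDA accumulation makes the high-activity state
absorbing (the network never leaves it); the cap is the per-synapse
saturation of the dense reference model expressed at the per-neuron level.

## Inputs

Background: every neuron receives an independent Poisson train at the
subject's background rate (880–950 Hz; 855–870 Hz for the accumulator
variant) through its AMPA background synapse, via a convergence of 2.8
fibers per neuron (the dense reference drives neurons with ~2400 Hz of
background; the subject-level rate here is ~900 Hz, and the convergence
restores the operating point). A shared rate, not shared spike trains —
shared trains would synchronize the network.

Task input: during the input period each selective neuron receives an
independent Poisson train through its AMPA_ext synapse at the momentary
frame rate times a convergence of 8 fibers. Mean rates follow the linear
coherence scheme — `(total/2)(1±c)` with total = 80 Hz, so 60.48/19.52 Hz at
51.2% coherence and 40/40 Hz at zero — resampled every monitor frame
(60 Hz) with N(μ, 4²) jitter truncated at zero. Non-selective cells and
interneurons receive no task input.

Arrival probabilities per 0.5 ms step are `1 − exp(−rate·dt)` (at most one
event per train per step; at these rates the distinction from a raw Poisson
count is negligible).

## Trials, sessions, virtual subjects

A trial lasts 3 s with input from 1–2 s. The inter-stimulus interval is
measured from input offset to the next input onset; the 1 s post-input tail
is fixed and the following trial's pre-input period is stretched or shrunk,
so the default protocol (ISI 2 s) reproduces the 3 s trial grid and ISI
variants (1.5, 3, 5 s) change only the pre-input padding. Continuous
sessions carry the full network state across trials; reinitialized sessions
reset membrane potentials, conductances and delay queues at every trial
start. Blocks are balanced designs (5 coherences × 2 directions × n
repetitions, randomly ordered).

A virtual subject is one wiring realization plus a background rate
~U[880, 950] Hz and a response threshold ~U[18, 22] Hz (accumulator:
background ~U[855, 870] Hz with the threshold tied affinely, 855→19 and
870→36 Hz, since without mutual inhibition the circuit is far more
sensitive to the background level). All seeds derive deterministically from
a master seed, so every experiment is exactly reproducible.

Decisions: population rates of the two selective pools are smoothed with a
unit-area Gaussian kernel truncated at ±5 ms (σ = 5/3 ms, ≈1% of peak at
the cut-off; bin width = dt). The first smoothed trace to reach the
subject's threshold inside the window from input onset to trial end
determines the choice; the crossing time minus onset is the decision time.
Simultaneous crossings break on the higher rate, then a seeded coin flip.
No crossing is a non-response.

## Analysis pipeline

* **Outlier filtering** — within subject × condition, responded trials whose
  decision time deviates from the group median by more than
  3 × 1.4826 × MAD are invalid (epsilon floor on the MAD; never more than
  half a group removed). An approximation of the median-of-medians family
  of robust filters; k is configurable.
* **Accuracy threshold** — least-squares fit of
  `P(correct|c) = 1 − 0.5 e^(−(c/α)^β)` to per-coherence accuracy, inverted
  in closed form at 80%. Ceiling accuracy or accuracy above target at the
  lowest coherence without an upward trend flags the fit non-converged and
  clamps the threshold to the tested range.
* **Decision-time regression** — OLS of per-subject, per-coherence mean
  decision-time differences (stimulation minus none) on coherence, pooled
  across subjects.
* **Indecision points** — two-parameter logistic fits of P(right) against
  signed coherence, separately for trials following a left and a right
  choice; the shift (left-group midpoint minus right-group midpoint) is
  positive under repetition bias.
* **Hysteresis model** — maximum-likelihood logistic regression of the
  right-choice indicator on signed coherence (proportion units, so the
  coherence coefficient a1 is of order 10) and the ±1 previous-choice
  regressor; a2 > 0 indicates hysteresis and a2/a1 is the normalized
  measure compared across conditions. First trials of a block and trials
  after a non-response carry no history term and are excluded. Perfect
  separation falls back to a weak L2 penalty (λ = 10⁻³) and is flagged
  `regularized`.
* **Tests** — Wilcoxon signed-rank with W = min(W⁺, W⁻), exact by
  enumeration over sign patterns for n ≤ 12 (valid under ties) and a
  tie-corrected normal approximation with continuity correction above;
  Mann-Whitney U; one-way ANOVA. All two-sided, no multiple-comparison
  correction.

## Synthetic behavior generator

`synthetic.generate_session` draws trial tables from exactly the sequential
logistic model the analysis fits, plus a deliberately simple response-time
model (linear in |coherence| with Gaussian noise, floored at 50 ms) and
optional non-response/outlier injection. It emulates the statistical
structure the pipeline assumes — not response-time dynamics, learning,
lapses, or any network mechanism — so passing recovery tests validates the
estimators, not the circuit. `recovery_experiment` refits the model across
replicates and reports per-coefficient bias and RMSE.

## Numerical choices

* Forward Euler at dt = 0.5 ms, the integration scheme of the reference
  implementation. Subthreshold trajectories converge under dt halving
  (<0.1 mV); spike timing of a periodically firing neuron carries a
  systematic ~15% first-order bias at this step (the reset lies above V_T,
  keeping the trajectory in the nonlinear regime), which halves with dt.
  The tests assert the convergence order rather than a fixed-dt accuracy
  the scheme does not have.
* Internal units are mV, ms, nS, pA and pF (1 pA/pF = 1 mV/ms), keeping
  all state within a few orders of magnitude of unity.
* The compiled kernel evaluates the spike-initiation exponential and the
  NMDA gating through 0.02 mV lookup tables with linear interpolation, and
  draws external arrivals from an inline xorshift64* stream; a plain-numpy
  single-step integrator with identical semantics (modulo table
  interpolation at ~1e-6 relative error) serves as the reference path and
  is cross-checked in the tests.
* Spike delivery uses a (delay+1)-slot ring buffer so a spike can never
  reach a target in the step it was emitted.
* A step ending at or above V_s registers a spike at the end of that step
  (no threshold interpolation).

## Problem sizes

Simulation-backed checks run at a reduced scale chosen as the package's
default validation protocol: 10 virtual subjects with 70-trial blocks for the
stimulation battery, 4 subjects per inter-stimulus-interval group with
50-trial blocks, and 5 subjects each for the reinitialized and accumulator
controls (the reference design is 20 subjects with 100-trial blocks).
Analysis-only validation uses synthetic sessions up to 20,000 trials.

## Limitations

* The contact-count calibration is a structural reconstruction: the printed
  per-contact conductances underdetermine the circuit at sparse wiring, and
  a different calibration could shift effect sizes (though not the
  qualitative mechanism).
* Effects of the ±0.75 pA stimulation currents are fractions of a percent
  of the drive balance; at desk scale their behavioral signatures are noisy
  and sign-based rather than quantitative.
* Stimulation has a small secondary effect on accuracy in this calibration:
  by suppressing residual activity, hyperpolarizing stimulation tends to
  remove history-driven errors at low coherence and lower the accuracy
  threshold (about 0.04 coherence on average in a 100-trial-block probe).
  The paired common-random-numbers design is sensitive enough to resolve
  this as statistically significant at large trial counts, where an
  independent-blocks design of the same size would not.
* Neurons are point-like and stimulation is uniform within a class; no
  spatial morphology, heterogeneous fields, plasticity, or hemodynamics.
* The response-time model of the synthetic generator is plumbing, not a
  cognitive model.
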