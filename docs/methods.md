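# Methods

## Model overview

The circuit is a discrete-time rate network with twelve output-side
neurons: for each valence (attraction/avoidance) a *susceptible*, a
*restrained* and a *long-term-memory* (LTM) MBON, and a *discharging*, a
*charging* and a *forgetting* DAN.  Two projection neurons encode odour
identity as binary vectors (A = [1,0], B = [0,1]); ten Kenyon cells carry a
sparse overlapping code (four A-only, three B-only, three shared, synaptic
efficacy 0.8).  All fixed connectivity is hand-set, not fitted: signs encode
the known microcircuits and magnitudes their relative strength, identical
across every experiment in the package.

Activities follow a synchronous update: both DAN and MBON drives are
computed from the previous step's MBON vector, passed through a
rectified-linear activation bounded in [0, 2] (the bound prevents runaway
activity while the LTM loop charges).  The default integration is the
*literal* composition of the model's update equations, which is memoryless:
`x_new = ϱ(drive / τ)` with τ = 3.  Because the printed dynamics admit a
second reading, a `leaky` switch (`x_new = ϱ((1 − 1/τ)x + drive/τ)`) is
provided; all shipped results use `literal`.

Each experiment time-step performs the forward update four times with a
single KC draw, so the value-vs-weight update order does not bias the
result.  Trajectories are a pure function of (parameters, schedule, seed).

## Plasticity

The dopaminergic rule `ΔW = δ·(k + W − w_rest)/τ` is local to the synapse:
it needs only KC activity, net dopamine (δ, signed per target MBON) and the
deviation of the weight from its set-point.  Its four regimes — depression,
potentiation, recovery, saturation — follow from the signs of δ and of
`k + W − w_rest`.  Weights are clamped at zero.  The RPE alternative
`ΔW = k·(δ − m + w_rest)/τ` shares the clamp so the two rules differ only in
their update term; it is KC-gated rather than dopamine-gated, which is what
erases the susceptible-memory signature in the comparison tests: with RPE
the weights recover to rest during every odour-only step.

### Dopamine-factor kinetics

`DopamineKinetics` resolves δ in time as `δ = D_pot − D_dep`.  The
dopaminergic-effect matrix is split by sign; the depression component is
driven by the negative channel at rate `1/τ_short` and by the positive
channel at `1/τ_long`, and vice versa for the potentiation component.  The
discrete form retains `(1 − 1/τ_short − 1/τ_long)` of each component per
step.  This choice keeps both stated limits of the model: at
`τ_short = 1, τ_long = ∞` the components carry no memory and δ reduces
exactly to the static `dᵀ·W_d2km` (the form used by the paradigm and arena
simulations), and at long constants both components stay non-negative and
decay smoothly.  A literal forward-Euler subtraction of the
`(2 − 1/τ_short − 1/τ_long)` term would instead make the per-step factor
negative (≈ −0.98 at (60, 10⁴)), i.e. both components would flip sign every
sample — incompatible with their meaning as receptor occupancies — so the
multiplicative retention was adopted.  The constraint
`0 < 1/τ_short + 1/τ_long ≤ 2` is validated at construction; it is exactly
the stability bound of the discrete update.

### Backward conditioning

The high-resolution pairing model (`backward.run_pairing`, 100 Hz) uses a
single susceptible-memory motif: one KC, one depressing DAN terminal and an
MBON that inhibits the DAN (US drive 2, inhibition −0.3, bias −0.5 — the
circuit's own susceptible-motif values).  The two receptor channels are
first-order low-pass filters of the dopamine signal: the fast channel at
rate `1/τ_short` (≈ 0.6 s at the default τ_short = 60 samples) and the slow
channel at half that rate (≈ 1.2 s), matching the 2:1 ratio of the two
receptors' response durations the mechanism is based on; the slow channel's
contribution is scaled by `1 − 1/τ_short`, so at the collapse point
(τ_short = 1) it vanishes and the per-sample factor is again the static δ.
The distinct decay rates are what produce relief learning: after a dopamine
pulse the fast (depression) component drops below the slow (potentiation)
one roughly half a second after the US, so an odour arriving 1–3 s later
meets a net-positive factor and its synapse potentiates, while an odour
paired with the US meets a net-negative factor and depresses.  A shared
decay rate for both components (one reading of the low-resolution kinetics)
cannot cross over and would never produce the backward effect; the
two-channel filter abstraction was chosen for this module because the
sign-flip is the phenomenon it exists to model.

The ER-Ca²⁺ and cAMP proxies are linear read-outs
(`ER-Ca²⁺ = −D_pot(k−w_rest) − (D_pot−D_dep)W`, `cAMP = D_dep(k−w_rest)`,
proportionality constants 1) whose combination `−ER-Ca²⁺ − cAMP` recovers
the plasticity rule's update term exactly; the reported sweep value is its
time average, normalised across the Δs grid so the constants are
immaterial.  The weight-update time constant at 100 Hz is one second's
worth of samples; only the normalised curve is reported.  Traces are padded
after the stimuli until the kinetics fall below 10⁻⁶ of their peak.

## Conditioning paradigms

Experiments are 73 time-steps: an odour-free initialisation step plus 24
trials of 3 steps (no odour / odour / odour).  Odour A occupies even trials
(0-indexed), odour B odd trials.  The aversive schedule is 2 pre-training,
10 acquisition (shock on step 3 of B-trials), 2 resting and 10 forgetting
trials (extinction: nothing; unpaired: shock on the odour-free step 1 of
A-trials; reversal: shock on step 3 of A-trials).  The classic unpaired
conditioning schedule replaces acquisition with alternating odour-A-only
and shock-only trials and tests with alternating A/B presentations.
Per-trial summaries report the step-2 response (*off-shock*, odour only)
and the step-3 response (*on-shock*, where a paired US falls).

Interventions clamp a named neuron's activity (0 for silencing, the
activation cap for activation) after each neuron update and before
plasticity, during the specified phases.  The screen harness runs each
table row as intervention-vs-control, reads the preference from the
test-phase MBON responses (mean attraction minus mean avoidance per odour,
normalised by the summed magnitudes) and reports the Pearson correlation of
`PI(intervention) − PI(control)` against the experimental effect sizes.
The published 92-experiment table is third-party supplementary data and is
not redistributed here; the harness accepts any table in the documented
schema.

## Arena

Flies live on an unbounded plane (no walls are modelled).  Odour intensity
is the univariate Gaussian density of the distance to each source — this
convention, not a bivariate density, places the detection boundary
(density = 0.2, σ = 0.3) at 0.584 m, comfortably outside the 0.3 m
reinforcement radius.  The PN code is binary in detection, not graded in
intensity.  Per 1 Hz step each fly senses, runs one four-repeat brain
update, converts its MBON vector to a force (mean attraction minus mean
avoidance MBON, per odour, weighted by the posterior probability of being
nearer that source; zero contribution exactly at a source), then moves:
velocity plus force plus per-axis N(0, 0.1) noise, renormalised to 0.05 m/s
(noise is redrawn in the measure-zero case of a zero vector).  Each of 10
repeats lasts 100 s (20 pre / 30 training / 50 post); reinforcement is
delivered only during training steps [20, 50).  Positions reset to the
centre between repeats, brains persist, so preferences strengthen across
repeats through the LTM loop.  Population summaries keep only flies that
detected both odours for at least one step; preference is
`PI = (C_A − C_B)/(C_A + C_B)` over the normalised cumulative exposures,
undefined (and excluded) for flies with zero total exposure.  The runner
advances all flies with batched array arithmetic; a test pins the batched
update to the per-fly forward step.

## Problem sizes and tolerances

The shipped simulations use the model's native sizes: 73-step conditioning
runs, 100 flies × 10 repeats × 100 steps per arena condition, and a
21-point Δs grid at 100 Hz for the backward sweep.  Stochastic behavioural
claims (preference signs, sugar-vs-shock asymmetry) are asserted on PI
distributions pooled over five seeds.  The kinetics-collapse identity is
checked to 10⁻⁹; exact structural facts (step counts, window sizes, the
activation bound, zero initial memory) are asserted exactly.  KC noise
(σ = 0.001, interpreted as a standard deviation) exists to break
winner-take-all ties; with it, ties are measure-zero and the lowest-index
tie-break only matters in the noise-free limit.

## Synthetic data

`generate_synthetic_traces` emulates only the geometry of trial-aligned
imaging data — 100 samples at 5 Hz, odour window at samples 25–50, the
off-/on-shock windows at 28–42 and 44–48 — with flat window means plus
Gaussian noise.  It shares none of the temporal structure of real ΔF/F
signals (rise/decay kinetics, bleaching, motion artefacts), so passing the
summariser round-trip shows the windowing arithmetic is right, not that the
summariser is robust to real imaging noise.  Likewise the arena emulates
point-source Gaussian odour fields without plumes, walls or body
kinematics; its preference indices test the circuit's control of a simple
agent, not fly locomotion.

## Known limitations

- No APL/gain-control circuitry, KC–KC connections or direct DAN→MBON
  transmission; KC sparseness is enforced by the winner-take-all filter.
- The blank stimulus drives KCs with noise only, so fewer than half the
  KCs can be non-zero after rectification on odour-free steps.
- The memoryless `literal` integration makes neuron responses settle
  within a time-step; slow neural dynamics are not represented.
- The screen harness encodes one generic conditioning protocol; published
  screens mixing protocols need their rows expressed in terms of its
  phases and US identities.
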