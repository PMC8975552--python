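# mbcircuit

A simulator of associative memory dynamics in the *Drosophila melanogaster*
mushroom body.  The package implements a twelve-neuron rate model in which
sparse Kenyon-cell (KC) odour codes drive six mushroom-body output neurons
(MBONs) through plastic synapses, and six dopaminergic neurons (DANs) carry
reinforcement and MBON feedback that gates the plasticity.  It is aimed at
researchers studying insect olfactory learning who want a compact,
fully-inspectable model of how susceptible, short-term and long-term
memories form, transfer and fade — and at modellers comparing
dopamine-gated plasticity with reward-prediction-error learning.

## The model

Odour identity enters through two projection neurons and is recoded by a
winner-take-all filter that keeps the strongest half of ten KCs active:

    k(t) = WTA_0.5[ pᵀ·W_p2k + η ],    η ~ N(0, 0.001)

DAN and MBON activities follow a synchronous discrete-time update through a
rectified-linear activation bounded in [0, 2]:

    d(t) = ϱ[ (uᵀ·W_u2d + mᵀ·W_m2d + b_d) / τ ]
    m(t) = ϱ[ (kᵀ·W_k2m + mᵀ·W_m2m + b_m) / τ ],    τ = 3

The only plastic weights are KC→MBON.  They change under the
**dopaminergic plasticity rule**

    ΔW_k2m[i,j] = δ[j] · (k[i] + W_k2m[i,j] − w_rest) / τ,    δ = dᵀ·W_d2km

with the resting weight w_rest = 1 and a non-negativity clamp.  The signed
dopaminergic factor δ combined with KC activity yields four effects —
depression, potentiation, recovery toward rest and saturation away from it —
which, wired through the circuit's stereotyped microcircuits (susceptible,
restrained and long-term-memory MBONs; discharging, charging and forgetting
DANs), reproduce rapid acquisition, extinction, reversal, unpaired and
backward (relief) conditioning, and memory assimilation from short- to
long-term stores.  A reward-prediction-error rule
(`ΔW ∝ k·(δ − m + w_rest)`) is provided as a drop-in alternative for
comparison, and a time-resolved two-channel receptor model of δ accounts for
the opposite associations formed by forward and backward pairings.

An agent-based arena couples the circuit to behaviour: flies move on a
plane between two Gaussian odour fields (σ = 0.3 m, detection threshold
0.2, sources at ∓0.6 m), receive shock or sugar near a source during
training, and express their memories as an odour preference index
PI = (C_A − C_B)/(C_A + C_B) over cumulative odour exposure.

## Worked example

```python
import mbcircuit as mb

# 24-trial aversive paradigm: 73 time-steps, shock paired with odour B
log = mb.run_experiment(mb.build_aversive_paradigm("extinction"), seed=1)
summ = mb.extract_trial_summaries(log)
s_at = summ[(summ.neuron == "s_at") & (summ.step_kind == "off")
            & (summ.phase == "acquisition") & (summ.odour == "B")]
print(len(log))                                  # 73
print([round(v, 3) for v in s_at.value])         # [0.667, 0.162, 0.035, 0.0, 0.0]
print(round(mb.detection_radius(mb.ArenaParameters()), 4))   # 0.584
```

The first number is the experiment length (one initialisation step plus 24
three-step trials).  The sequence is the attraction-side *susceptible* MBON's
odour response across the five shock-paired acquisition trials: it collapses
from 0.667 already at the second pairing, the hallmark of a rapidly erasable
memory.  The last value is the distance (in metres) at which an odour field
stops being detectable, obtained by solving the Gaussian density against the
detection threshold.

The same machinery is available from the shell:

```sh
mbcircuit run-paradigm --forgetting reversal --rule dpr --seed 1 --out traces.csv
mbcircuit run-arena --condition shock_a --seed 1 --out arena
mbcircuit backward-sweep --ds-min -5 --ds-max 5 --ds-step 0.5 --out sweep.csv
mbcircuit summarise-traces --in imaging.csv --out summary.csv
mbcircuit screen --table screen.csv --out results.csv
```

## Layout

- `mbcircuit.circuit` — parameters, state, activation, KC coding, forward update
- `mbcircuit.plasticity` — dopaminergic and RPE rules, dopamine-factor kinetics
- `mbcircuit.paradigms` — trial schedulers, experiment runner, trial summaries
- `mbcircuit.arena` — fly agents, odour fields, exposure and preference statistics
- `mbcircuit.backward` — high-resolution second-messenger pairing model
- `mbcircuit.evaluation` — imaging-trace summariser, synthetic fixtures, screen harness
- `docs/methods.md` — model assumptions, parameter choices and limitations
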