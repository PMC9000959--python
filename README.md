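# yeastcons

Composable ODE models and automated design search for multicellular yeast
signaling circuits.

Instead of packing a whole genetic circuit into one cell, a consortium
divides the labor: engineered *S. cerevisiae* strains that each perform one
monotone activating or repressing transfer communicate through shared
extracellular signals — the mating pheromone α-factor, the plant hormone
auxin (IAA), and the exogenous inducer β-estradiol. `yeastcons` is for
people designing or analyzing such consortia: it models each strain with a
small Hill-stage ODE system, composes strain models into circuit models
coupled only through medium pools (scaled by per-strain cell-density gains
*K*), fits model parameters to cytometry-style measurement tables, analyzes
a four-strain bistable switch, and runs an automated
enumerate–score–optimize search for circuits that implement logic gates,
time pulses, and concentration band-pass filters.

The core single-strain model is three first-order stages,

```
dx1/dt = u − d1·x1                     (input sensing)
dx2/dt = V·hill(x1; K, n) − d2·x2      (Hill-stage processing)
dx3/dt = k3·x2 + c0 − d3·x3            (output / fluorescence)
```

with `hill(x; K, n) = xⁿ/(Kⁿ + xⁿ)` (or its complement for repression).
Composition replaces a sender's output stage with a flux `K·(k3·x2 + c0)`
into the medium pool its receivers sense; BAR1/GH3.3 attenuator enzymes mask
a signal multiplicatively via `K_E/(K_E + E)`. The bistable switch is the
steady-state system `I = f(A)`, `A = g(I)` of two mutually repressing arms
with enzymatic clearance; candidate circuits are scored with
`min(ON)/max(OFF)` against a gate truth table or with a non-monotonicity
metric (interior extremum minus the more extreme endpoint). Full model
descriptions are in [`docs/methods.md`](docs/methods.md).

## Worked example

Screen a reduced strain pool for AND-gate circuits
(`python examples/logic_gate_screen.py`):

```
screened 6 two-strain circuits (pool of 4, sensor IAA_rep_GFP):
  aF_rep_IAA+bE_rep_IAA    score  1.374 <- passes the score > 1 bar
  aF_rep_IAA+bE_act_IAA    score  0.639
  aF_act_IAA+bE_rep_IAA    score  0.558
  aF_act_IAA+aF_rep_IAA    score  0.369
  bE_act_IAA+bE_rep_IAA    score  0.358
  aF_act_IAA+bE_act_IAA    score  0.292

best architecture: aF_rep_IAA+bE_rep_IAA
gain optimization: 1.374 -> 1.396 with gains {'aF_rep_IAA': 0.98, 'bE_rep_IAA': 0.81}
```

The score is min(ON)/max(OFF) over the four truth-table input corners after
normalizing the sensor output to its own dynamic range: above 1 means every
expected-ON output exceeds every expected-OFF output. The winner is the
textbook realization — α-factor and β-estradiol each *repress* auxin
synthesis, so the auxin-repressed GFP sensor reads HIGH only when both
inputs are present.

Other example scripts cover sensor characterization and Hill fitting
(`sensor_dose_response.py`), cascade composition and gain tuning
(`cascade_modularity.py`), parameter recovery from synthetic cytometry data
(`fit_recovery.py`), the bistable switch design-and-toggle workflow
(`bistable_switch.py`), and the time-pulse search that rediscovers the
incoherent feed-forward loop (`time_pulse_search.py`).

A thin CLI wraps the same functions:

```sh
yeastcons library validate src/yeastcons/data/default_library.yaml
yeastcons simulate strain --id aF_rep_GFP --input alpha_factor:100 --t-end 12
yeastcons screen --behavior and_gate --sizes 2 --pool-size 4 --out ranking.csv
yeastcons bistability simulate --gains '{"K1": 10, "K2": 3.16}' \
    --stimuli "auxin@3h:5000nM,alpha@15h:1000nM" --out switch.csv
```

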