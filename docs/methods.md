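# Methods

`yeastcons` models engineered *Saccharomyces cerevisiae* consortia whose
members communicate through three extracellular molecules — the mating
pheromone α-factor, the plant hormone auxin (IAA), and β-estradiol (an
exogenous inducer that no strain can secrete). Each strain performs one
monotone input→output transfer: sensors express GFP, synthesizers secrete
α-factor or auxin, and attenuators express BAR1 (an α-factor protease) or
GH3.3 (an auxin-inactivating conjugase). Circuits are built by mixing
strains at chosen cell densities; all coupling is through the shared medium.

Units throughout: time in hours, extracellular concentrations in nM,
intracellular states and fluorescence in arbitrary units (a.u.).

## Single-strain models

A single-input strain is three first-order stages (sensing `x1`, Hill-stage
processing `x2`, output `x3`):

    dx1/dt = u − d1·x1
    dx2/dt = V·hill(x1; K, n) − d2·x2        hill = x^n/(K^n + x^n) or its
    dx3/dt = k3·x2 + c0 − d3·x3              complement for repression

The sensing influx coefficient is fixed at 1 — it is not separable from `K`
— leaving eight parameters. `c0` is basal promoter leak. The closed-form
steady state `(k3·(V/d2)·hill(u/d1; K, n) + c0)/d3` is used both for
dose-response prediction and as the oracle the simulation tests converge to.
The input EC50 in concentration units is `K·d1`.

Two-input strains duplicate the sensing and processing stages per input and
combine the two *normalized* branch activities multiplicatively in the
output stage, so either branch can veto the output. The form in which the
output combines its inputs is a modeling choice (an additive rule is
available via `combine="sum"`); the product was chosen because the measured
two-input strains pair one activating and one repressing input acting on the
same output. Opposite-sign branches with different processing timescales
produce transient output extrema, which is what makes two-input strains able
to represent non-monotonic kinetics.

`V` and `k3` enter the observable output only through their product, and a
`d2`↔`d3` exchange (with a compensating output stage) is a near-symmetry of
the linear part of the cascade. Fits therefore expose a `free` mask;
parameter-recovery work freezes `V` and reports recovery over the remaining
seven parameters.

## Composition

Consortium models concatenate member strain models and replace each
non-sensor member's output stage with a flux `K·(k3·x2 + c0)` into the
medium pool of its output species (or into an enzyme pool for attenuators).
The gain `K` is the member's cell density as a fold-change of the reference
density (30 events/µL); it multiplies the whole output flux, including the
basal leak. Medium pools have first-order clearance (default 0.05/h,
configurable per species) so unreplenished signals decay. Attenuation is
multiplicative masking: the input a downstream strain senses is
`pool × K_E/(K_E + E)` with `E` the enzyme pool and `K_E` = 100 a.u. by
default; a medium-sink variant was considered and rejected to keep
attenuation strictly a communication-layer effect.

Exogenous inputs come in two forms, and the distinction matters:

* **held** levels — clamped piecewise-constant schedules, used for
  dose-response and screening experiments, where the experimenter sets and
  maintains an inducer concentration. Because held inputs are clamped, a
  consortium containing only a sensor is *exactly* the bare three-state
  model (the composition identity tested in the suite).
* **spikes** — instantaneous additions to the medium pool, which then decay
  through clearance and dilution events. This is the bistable-switch
  stimulus protocol, where added inducer must fall below the sensor's
  detection range between stimuli.

Dilution is event-based: at each event the medium and enzyme pools are
multiplied by the retention fraction (a 1:3 dilution keeps 1/3). A 1:3
dilution every 40 min sends an inert 5000 nM bolus to
`5000·3⁻¹³ ≈ 3.1·10⁻³` nM in 9 h, which the event simulation reproduces to
machine precision.

Growth is not modeled in the composition layer: as long as there is no
dilution or resource competition, growth-rate differences only rescale all
fluxes together. Populations appear only in the switch model's
metabolic-load extension (below).

## Parameter fitting

All fits minimize the unweighted L2 norm between observed mean fluorescence
and simulation, with derivative-free Nelder–Mead search on log-parameters
(positivity by construction, rate constants span decades) and seeded
Latin-hypercube multi-start (default 8 restarts, ±0.5 in natural log around
the init; simplex tolerance 1e-6, 5000 evaluations per restart). Fits are
bit-reproducible per seed. Replicated designs are fitted once per replicate
(reported as mean ± sd) and once on the replicate average; the averaged-data
fit is the parameter set used for simulation.

Inside the loss loop the three-stage model is solved semi-analytically: the
sensing stage has a closed form, and the remaining two stages are linear
with a time-dependent Hill forcing, solved by variation of constants with
cumulative trapezoid quadrature on a log-dense-then-uniform grid. This is
~10³× faster than an adaptive stiff solver per evaluation and agrees with it
to ~1e-5 relative (asserted in the tests); outside fitting, all simulation
uses `scipy.integrate.solve_ivp` (LSODA, rtol 1e-8 / atol 1e-10).

When a sender strain's output is re-routed from GFP to a signaling molecule,
only its output stage {k3, c0, d3} is re-estimated from downstream-sensor
data; `d3` maps onto the clearance of the secreted-species pool, which is
the composed counterpart of the output-turnover equation. Everything else,
including the downstream sensor, stays frozen.

Endpoint dose-response curves are summarized by a four-parameter Hill fit
(floor, ceiling, EC50, Hill coefficient) via `scipy.optimize.curve_fit`,
with the direction auto-detected and an identifiability error when the curve
shows no transition (default minimum fold-change 1.2). Whether floor and
ceiling should instead be pinned from the data is a judgment call; fitting
all four is the default here and can shift fitted `n` on saturating ranges.

## The shipped strain library

The default library has 24 strains — 6 sensors, 12 synthesizers, 6
attenuators — with ids `input_sign_output` (e.g. `aF_act_IAA`). Sensor
EC50s and Hill coefficients follow the characterized pathway values
(β-estradiol: 12.6 nM/n 1.3 activating, 0.5 nM/n 2.2 repressing; α-factor:
6.0 nM/n 1.0 and 89.0 nM/n 0.8; auxin: 964.8 nM/n 0.8 and 276.5 nM/n 1.0),
and strains sharing a sensing/processing pathway share those parameters.
Rates default to d1 = 1/h, d2 = 0.5/h, d3 = 0.3/h with sensor dynamic
ranges spanning 3× to 42× ON/OFF fold-change; synthesizer output fluxes are
sized so each signal covers its receivers' operating ranges (max ~30 nM/h
for α-factor, ~200 nM/h for auxin at unit gain). These output-stage values
are package defaults, not measurements; the YAML schema exists precisely so
fitted parameter blocks can replace them.

The design-search **enumeration pool** is the 18 non-sensors minus the two
self-negative-feedback synthesizers (`aF_rep_aF`, `IAA_rep_IAA`), giving 16
strains and hence C(16, k) = 120 / 560 / 1820 member combinations for
network sizes 2 / 3 / 4. Pool membership is configurable in the library
file.

## Bistable switch

Four strains form a mutual-repression switch: an α-factor-sensing auxin
synthesizer (gain K1) and GH3.3 attenuator (K3) versus an auxin-sensing
α-factor synthesizer (K2) and BAR1 attenuator (K4). At steady state,

    I = f(A) = K1·(c_I + V_I·θ₁ⁿ¹/(θ₁ⁿ¹ + Aⁿ¹)) / (δ_I + K3·γ_G·A/(θ_G + A))
    A = g(I) = K2·(c_A + V_A·θ₂ⁿ²/(θ₂ⁿ² + Iⁿ²)) / (δ_A + K4·γ_B·I/(θ_B + I))

— decreasing Hill repression on production, Michaelis-type enzymatic
enhancement of clearance, one gain per strain. Equilibria are the roots of
`g(f(A)) − A`, located by sign-change bracketing on a 400-point log grid
plus Brent polishing, and classified through the induced relaxation dynamics
`dA/dt = δ_A(g(I) − A)`, `dI/dt = δ_I(f(A) − I)`: since both maps are
strictly decreasing, an equilibrium is stable iff `f′(A*)·g′(I*) < 1`. A
dense brute-force intersection scan serves as the independent oracle in the
tests.

The clearances δ absorb the time-averaged effect of the experimental 1:3 /
40 min dilution (≈ ln 3 / (2/3 h) ≈ 1.65/h), so the steady-state model
describes the diluted culture directly; in the dynamic simulation, stimulus
boluses are tracked as separate exogenous pools that decay only through the
discrete dilution events. This split keeps the dynamic fixed points
coincident with the nullcline intersections (asserted to 1%) while
reproducing the protocol in which spiked inducers fall below detection
within hours.

An important caveat discovered during validation: in this functional form
the enzymatic arms contribute up to one extra unit of effective
log-sensitivity each, so bistability is *not* strictly impossible for
repression Hill coefficients n1 ≤ 2, n2 ≤ 1 — about 0.5% of randomized
physiological parameter draws in that regime still produce three equilibria.
Low cooperativity makes bistability rare and fragile here rather than
impossible. With the arms disabled and n1 = n2 = 1 the circuit is monostable
at every stoichiometry, as expected for a toggle without cooperativity.

The shipped switch parameters (V_I = 900, V_A = 250 nM/h, θ₁ = 25, θ₂ = 150
nM, n1 = 3, n2 = 1.5, γ = 8/h arms, δ = 1.65/h) yield a contiguous bistable
region in the (K1, K2) gain plane; `select_operating_point` picks the
bistable cell maximizing the minimum log-space distance between stable
states, mirroring the robustness-driven choice a designer would make.

**Metabolic load.** Each strain carries a population `N_i` growing at
`μ0·(1 − ρ·e_i)` with `e_i` its normalized pathway activity (the repression
or Michaelis occupancy term, in [0, 1]), μ0 = 0.4/h (log-phase yeast) and
load coefficient ρ ∈ [0, 1]. Gains scale with relative population
`N_i/mean(N)`, so uniform growth changes nothing while activity-dependent
growth differences drift the stoichiometry. At the default operating point,
ρ ≥ 0.5 destabilizes the high-fluorescence state within ~30–40 h (the
strains active in that state slow down, tipping the balance), while ρ = 0
holds it indefinitely.

## Design search

The search enumerates all 2/3/4-subsets of the pool, pairs each with a
sensor, simulates 12 h against the input grids (α-factor
[0, 1, 5, 10, 50, 200, 1000] nM; auxin [0, 100, 500, 1000, 5000] nM;
β-estradiol [0, 1, 5, 10, 100] nM) restricted to the species the circuit
actually senses, and normalizes sensor endpoints onto [0, 1] by the sensor's
own steady-state dynamic range (clipped; repressing sensors are not
sign-flipped — ON/OFF is defined on fluorescence). All input combinations of
a circuit are integrated as one stacked batch (they are decoupled copies of
the same non-stiff system), which makes exhaustive small-pool screens cheap.

* **Gate score** = min(ON)/max(OFF, 1e-6) over the four truth-table corners
  (no input vs the highest grid concentration per input), evaluated for
  every pair of sensed species and maximized; single-input circuits cannot
  host a two-input gate and score 0. The score is a ratio, hence invariant
  to common scaling, and falls below 1 exactly when some expected-OFF output
  reaches an expected-ON output. Candidates above 1 proceed to optimization.
* **Non-monotonicity** = max(interior max − larger endpoint, smaller
  endpoint − interior min, 0): zero on every monotone or constant series.
  Applied along time per input combination (time pulses) or along the dose
  axis at the endpoint (band-pass/band-stop).

Gain optimization is Nelder–Mead on log-gains with proposals clipped to
[0.1, 10], seeded restarts, and a contract that the returned score is never
below the screened score. Failed simulations are logged and scored 0, never
fatal. Screens are deterministic: identical configurations produce identical
rankings, with ties broken by member ids then sensor id.

The full-scale screen (~10⁶ simulations) is supported but the shipped
analyses use reduced pools; the published fractions of non-monotonic
topologies (0.52% in time, 0.32% in dose) depend on the authors' fitted
parameter values and are not reproduction targets here.

## Synthetic data

Generators mirror the experimental designs: 8 doses covering the sensor
dynamic range × 6 time points (0.5–12 h: an early point to pin the sensing
turnover, a final point past 3.5 output half-lives) × 3 biological
replicates. Noise is `y·LogNormal(mean 1, cv) + background` per observation
— the minimal model consistent with positive mean-fluorescence data and a
subtractable background; the default cv is 0.05. Generators are
seed-deterministic and record full provenance. What they do *not* emulate:
event-level cytometry (gating, cell-size normalization), day effects or
correlated replicate structure, signal crosstalk, and growth-stage drift —
so passing recovery tests demonstrate estimator correctness under the stated
noise model, not robustness to all real-data pathology.

Empirically, at cv = 0.05 the averaged-data fit pins the threshold `K` and
cooperativity `n` to better than 10%, while the basal-floor decomposition
(`c0`, `d3`, and to a lesser degree `d2`) is the softest likelihood
direction and can deviate ~30–40% even at the global optimum — a property
of the model/design information content, not of the optimizer (the fitted
loss falls below the loss at the generating truth).

## Numerical conventions and degenerate inputs

Tiny negative solver excursions are clipped to 0; Hill evaluation is
overflow-safe at extreme ratios. Equilibrium deduplication merges roots
within 1e-6 relative; tangential (non-transversal) intersections are not
specially handled. Constant measurement tables and designs with fewer than
2 doses and 4 time points raise identifiability errors rather than
returning meaningless fits. Dose lists must be unique and non-negative;
empty dose lists are rejected. `simulate_switch` started exactly on an
unstable equilibrium stays there (it is a fixed point); stability tests
perturb by ±5%.

## Known limitations

* Self-secreting positive feedback does not increase the
  apparent Hill coefficient in this composition model (the loop's basal
  ignition adds a dose-offset that stretches the transition); the
  double-repression feedback architecture does show the boost. See the
  fitting tests.
* The switch equations are a reconstruction; they are isolated in
  `bistability.py` so they can be corrected against a primary-source
  derivation without touching the rest of the package.
* Attenuation as input masking (not a medium sink) slightly changes mass
  balance relative to a protease that actually consumes its substrate.
* No spatial structure, stochastic single-cell heterogeneity, or resource
  competition.
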