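# Methods

## Model and rule semantics

The shipped network has 42 nodes (3 pathogen, 13 host-cell, 19 mediator,
4 outcome, 3 other) and its update rules are plain text in
`src/sepsisbn/data/tlr4_rules.txt` with a YAML sidecar
(`tlr4_meta.yaml`) holding the delay map, node classification, initial
state, endpoint directions and the default screen set. Everything in the
sidecar is data, not code: the mediator/"other" split and the screen set
can be edited without touching the package.

Rules are parsed into an AST with operators NOT > AND > OR (left
associative); `A &! B` is sugar for `A & (!B)`. A `THR_X[tag]` term with
delay `d` is true at step `t` iff `X = 1` at steps `t−1 … t−d` of the
*committed* per-step history. Steps before 0 are taken to equal the raw
initial state, i.e. a node active at onset counts as having been active
arbitrarily long; this makes self-sustaining sources (like `Infection`)
satisfy their threshold terms immediately. The all-zero state satisfies no
rule and is therefore absorbing.

## Update schemes

* `random_order` (default): each time step draws a fresh uniform
  permutation of all nodes and updates them sequentially, each update
  reading the freshest within-step values. One step therefore advances
  every node once, which keeps the THR delays (2–3 steps) on the same
  footing as the network's functional timescale.
* `single_node`: one uniformly chosen node updates per step from the
  committed previous state; all others carry over.

THR terms always read committed whole-step rows, never within-step partial
values, so delay semantics are identical under both schemes. The two
schemes genuinely differ in their long-run behaviour; the test suite pins
this with a three-node fixture whose exact stationary activation is 1/3
under `single_node` and 7/24 under `random_order`.

Knock-out/over-expression clamps hold a node at 0/1 over a step interval
and dominate everything: rule evaluation, polymorphism draws and the
initial state (a clamp starting at step 0 rewrites row 0). A polymorphism
with activity `p` turns a firing rule into an independent Bernoulli(`p`)
switch; `p = 1` bypasses the random number generator entirely, so the
unaltered condition is bit-identical to a sweep level of 100 %.

## Randomness and reproducibility

Repetition `r` of a run with seed `s` uses its own Mersenne-Twister stream
seeded `s + r`, so repetitions are independently reproducible and extend
deterministically when the horizon grows. All draws are uniform doubles,
which lets a pure-Python reference backend (AST evaluation, NumPy
`RandomState`) consume the identical stream as the compiled numba kernel;
the suite asserts bit-identical trajectories between the two backends, on
delay-free toys and on the shipped delayed model, under both schemes.

Screen conditions draw their seeds from a stable 32-bit hash of a
canonical, order-independent condition descriptor combined with the master
seed. Consequences: screen results do not depend on the order conditions
are evaluated in, adding conditions never changes existing rows, and a
condition that normalises to "no perturbation" (a clamp starting beyond
the horizon, a polymorphism at 100 %) reuses the baseline stream and
reproduces it exactly. When comparing two *different* non-baseline
conditions the estimates are independent, so differences carry
Monte-Carlo noise of a few percentage points at 100 repetitions — relevant
when reading hit counts near the cut-off (below).

## Attractor readout

`estimate_attractor` simulates `reps` trajectories (default 100) for
`steps` rounds (default 60), discards the first half as burn-in and
averages each node over the remaining window and all repetitions. Burn-in
scales with the horizon (`steps // 2`) so the window stays clear of
transients when the horizon grows.

Stationarity is checked with a Geweke-style diagnostic: for each node, the
difference between its first- and second-half window means is computed per
repetition; these differences are iid across repetitions, so drift is
declared only where the mean difference exceeds both 2 percentage points
and four standard errors. (A raw threshold on the max across 42 nodes
would sit inside the Monte-Carlo noise floor at 100 repetitions and flag
stationary systems at random.) On drift the horizon doubles — same seeds,
trajectories extend — up to 480 steps; an estimate still drifting at the
cap is returned with `stationary=False` plus a warning. Window
time-averaging is used instead of per-trajectory cycle detection, which is
ill-defined under stochastic updating; for periodic or multi-attractor
toys the exact oracle accordingly reports the Cesàro (time-average) limit.

The readout is horizon-sensitive in exactly one regime that matters for
interpretation: after a late Bacteria knock-out the network enters a
metastable, partially active state (NETs, activated platelets and TNF-α
persist) while tissue factor and Thrombosis decay stochastically with a
half-life of roughly 30 steps. A short fixed window reports a partial
Thrombosis reduction; the adaptive window follows the decay and reports a
near-complete one. The adaptive estimate is the package's contract; the
profiles are invariant (≈ 0.5 pp) to *when* the late knock-out starts, for
any start past the first few steps.

## Screens

* `mono_screen`: KO and OE of every screen-set node (default: the 19
  mediators), scored per endpoint by the relative change versus the
  unperturbed profile; a hit needs |rel| ≥ cut-off (default 0.2,
  inclusive) in the endpoint's beneficial direction. A change from a
  zero-activation baseline has no defined ratio and is reported with an
  infinite sentinel, excluded from hit calling.
* `pair_screen`: all unordered node pairs under KO+KO, OE+OE and both
  mixed assignments. Besides the raw hit flag, `combination_strategy`
  marks pair hits for which neither constituent mono perturbation was a
  hit on that endpoint — combinations that add value over mono-therapy.
  Both raw and filtered views are kept because near-cut-off mono effects
  (TLR4 and IL-1β knock-outs hover at 19–26 % Thrombosis reduction at 100
  repetitions) make the filtered count sensitive to Monte-Carlo noise.
* `antibiotic_screen`: a Bacteria knock-out from `ab_time` (default 20,
  the late-treatment regime; an antibiotic at step 0 silences the whole
  cascade and leaves nothing to combine with) alone and combined with each
  mediator clamp. Rows carry the relative change against both the
  unperturbed baseline and the antibiotic-only profile (`rel_vs_ab`),
  since "benefit of adding a mediator block to antibiotics" is a paired
  question.
* `timing_sweep`: any screen re-run over a grid of initiation times
  (default 0/4/8/12/20; for the antibiotic screen the grid moves the
  antibiotic start).
* `polymorphism_sweep` / `identify_cell_effects`: activity of each of the
  13 immune-cell nodes swept 0–100 % in 10 % steps from step 0; a
  cell→endpoint effect is "considerable" when |rel| at full deactivation
  passes the cut-off.

## Toy fixtures and the exact oracle

`make_toy_network` builds ≤ 10-node motifs (self-sustaining chain,
redundant-OR endpoint, negation oscillator, scheme-separating triplet,
delayed chain, seeded random rules). `exact_stationary` constructs the
full 2^n-state transition matrix — per-node averaging for `single_node`
(n ≤ 10), averaging over all n! within-step orders for `random_order`
(n ≤ 5) — and power-iterates the initial distribution through the lazy
chain (I+P)/2, which has the same absorption probabilities and stationary
distributions but is aperiodic, to 1e−10. The engine is required to match
these values to L∞ < 0.03 at 10,000 repetitions on every motif and both
schemes (observed ≲ 0.004).

## Numerical and design choices

* Defaults: 60 steps, 100 repetitions, random-order scheme, 20 %
  efficacy cut-off, burn-in = half the horizon, drift tolerance 2 pp,
  horizon cap 480. The repetition count and cut-off are the study
  conditions; horizon and diagnostics are package choices sized to the
  network's delays (≤ 3 steps) and mixing time.
* Hit direction per endpoint is metadata (`decrease` beneficial for
  Thrombosis and Ang2, `increase` for MAC and Phagocytosis).
* Degenerate inputs: clamping conflicts (same node, same step, different
  values) are fatal; duplicate identical clamps merge; a pair (X, X) with
  one mode is the mono condition; `relative_change(0, 0) = 0` and
  `PI(0, 0) = 1` keep `PI = 1 + rel` exact wherever the baseline is
  positive.
* BoolNet export is delay-free only; exporting the shipped model requires
  `flatten=True`, which replaces `THR_X[tag]` by `X` and is documented as
  lossy.

## What the toys do and do not show

The toy motifs validate update semantics, delay handling, clamp/
polymorphism contracts and Monte-Carlo convergence against exact chain
solutions. They do not validate the biology of the 42-node model (whose
2^42 state space admits no exact solution here), nor do passing toy tests
say anything about how faithfully a logical abstraction captures real
sepsis physiology — time steps are not calendar time, and endpoint nodes
are surrogates, not clinical outcomes.

## Known limitations

* Hit *counts* near the 20 % cut-off are not stable to Monte-Carlo noise
  at 100 repetitions: TLR4 and IL-1β knock-outs sit at the boundary, so
  the filtered combination-strategy count can swing by tens of conditions
  across master seeds while the strong hits (TNF-α, sTNF-R, C3b/C5b,
  TF, IFN-γ, IL-12) are robust (they persist at a 15 % cut-off under
  re-seeding).
* The `random_order` kernel's within-step sequential reads make one
  "step" an intensive unit; quantitative % activation values differ
  between schemes, and only the default scheme is calibrated against the
  screening results.
* No dose-response: clamps are all-or-nothing; partial inhibition exists
  only through the polymorphism mechanism.
* Multi-valued logic, ODE semantics and exact attractor enumeration of
  the full model are out of scope.
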