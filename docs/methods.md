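# Methods

## The core circuit

The network couples two microRNA/transcription-factor double-negative
feedback loops around SNAI1: miR-203 ⊣ SNAI1 ⊣ miR-203, and the
reciprocal repression between the miR-200 family and the ZEB factors,
with SNAI1 additionally repressing both miRNAs and activating ZEB1/2,
and E-cadherin (CDH1) as a pure epithelial readout repressed by
SNAI1/ZEB1/ZEB2. The two miR-200 clusters are collapsed into a single
`miR200` node; node classes (miRNA / transcription factor / gene) are
annotational only. The fixture has 6 nodes and 15 signed edges and is
the single source of truth for every dynamic analysis
(`emt_core_network()`; `synthetic.fixtures()` re-exports it with the
E/M state vectors).

## Boolean semantics

Update rules are compiled from edge signs alone, with inhibitor-dominant
logic: a node is on next step iff some activator is on (or it has
inhibitors but no activators) **and** no inhibitor is on. A node with no
regulators updates to 0. These two conventions are the standard default
for qualitative regulatory models, and they are the ones under which the
circuit's printed behaviour is reproduced: exactly two fixed points (E
and M), and exactly one (E-like) after the miR-203→SNAI1 edge is
deleted — the deletion leaves SNAI1 input-free, and only decay-to-off
semantics yields a single stable state. The inhibitor-only default-on
rule is what makes the miRNAs and CDH1 spontaneously active in the
absence of their repressors, the biologically intended behaviour of a
constitutively expressed epithelial program.

Fixed points are enumerated exhaustively over all 2ⁿ states (n ≤ 20;
the sweep is vectorised over packed integer states, bit i = node i in
lexicographic id order, which also fixes all output ordering). The full
synchronous state-transition graph yields attractors and basin sizes;
on the fixture these are M (basin 36), E (basin 4) and one synchronous
2-cycle (basin 24). Only fixed points count as "stable states" and only
they are ever labelled E (CDH1 = 1, SNAI1 = 0) or M (SNAI1 = 1,
CDH1 = 0); synchronous cycles are artefacts of simultaneous updating
and are reported but unlabelled.

## Robustness (transition probabilities)

Robustness is measured by a Monte-Carlo perturbation procedure: for
each attractor state and each node, flip that node and relax the
perturbed state by uniformly random single-node (asynchronous) updates
until it is absorbed by an attractor or a step cap of 10·2ⁿ is reached
(capped trials land in an explicit "unresolved" column, never dropped).
Defaults: 1000 trials per (state, flip), seeded generator, bit-identical
reports for a fixed seed. A relaxation is considered absorbed only at
attractors whose state set is closed under asynchronous updates — true
for every fixed point, generally false for synchronous cycles, which
therefore act as sources but never destinations. Per-flip return
probabilities and the aggregated attractor-to-attractor transition
matrix (rows summing to 1) quantify the claim that the circuit rarely
switches states without an external stimulus: on the fixture both E and
M have positive return probability from every single flip, with M the
more robust of the two.

## Continuous transformation

The Boolean model is mapped to ODEs in the standardised
qualitative-dynamics style: per node, a combined input
ω = A·(1−B) ∈ [0,1] with A = ((1+n)/n)·Σxₐ/(1+Σxₐ) over its n
activators (A = 1 if it has only inhibitors), B the symmetric term over
its m inhibitors (B = 0 if none), ω = 0 for input-free nodes; then
dx/dt = f(ω; h) − γx with the normalised sigmoid f satisfying f(0) = 0,
f(½) = ½, f(1) = 1. Interaction weights are 1. Defaults: gain h = 10,
decay γ = 1 per node, both configurable (γ per node if needed). With
these choices every Boolean fixed point of the fixture embeds exactly
as a 0/1 steady state, and the unit cube is forward-invariant.

Steady states are found by relaxation (LSODA, rtol 1e-8 / atol 1e-10)
to t = 200 from every embedded Boolean fixed point plus 100 seeded
uniform random starts; a state is accepted when ‖dx/dt‖∞ < 1e-6,
deduplicated at 0.05 per coordinate, and discretised at 0.5 for
labelling. Non-convergent relaxations are counted in the result. This
forward-relaxation scheme finds attracting steady states only — which
is what "stable state" means here; unstable interior equilibria are
deliberately out of reach.

The stimulus experiment clamps a node to a fixed level over a time
window (integration is split at event boundaries; samples every 0.05
time units plus the boundaries). The canonical pulse — SNAI1 clamped to
1 from t = 2 for 2 time units, horizon t = 20 — drives the continuous E
state into a state that discretises to M, with miR-203 and miR-200
falling monotonically during the clamp. Edgetic experiments rerun the
steady-state search on the edge-deleted network and report which
original states persist (coordinate-wise match within 0.05).

One derived expectation deserves a note: deleting SNAI1 ⊣ CDH1 does
*not* move CDH1's level in the M-like state. With ZEB1 = ZEB2 = 1 the
inhibitor term already saturates (B = 1 at Σx_b = m), so the third
inhibitor is redundant there; the deletion is dynamically silent and
both steady states persist unchanged. The test suite asserts this
actual behaviour.

## Signature procedures

* **Differential direction calls.** Per miRNA, a two-sided two-sample
  t-test between epithelial and mesenchymal log-intensities; direction
  UP/DOWN by the sign of mean(M) − mean(E); significant iff p < α
  (default 0.01, raw — matching the original procedure; Benjamini–
  Hochberg is available as an explicitly optional extension). Welch's
  test is the default because group variances are not assumed equal;
  the pooled-variance flavour is exposed since the original description
  says only "t-test". Features with < 2 non-missing values in either
  group are reported untested, not dropped.
* **Consensus intersection.** Per miRNA, the number of studies calling
  it significant in each direction; the consensus keeps those at or
  above `min_studies` (default 3) in the requested direction, and the
  pairwise/overall overlap counts are emitted alongside.
* **Replicate merging.** Probe rows sharing a canonical (miRBase-style)
  id are replaced by their per-sample mean, NaNs ignored.
* **Family correlation ranking.** Full Pearson correlation matrix over
  features; per miRNA the average correlation with the miR-200 family
  members (miR-200a/b/c, miR-141, miR-429 by default — both clusters;
  the list is an input), excluding self-correlation for family members;
  ranks descend by average (rank 1 = highest), NaN averages
  (zero-variance features) rank last, ties break lexicographically.
* **Time-course replicate filter.** A replicate enters the per-time-point
  average iff |log-ratio| ≥ 0.5 and its p-value ≤ 0.01; p-values are
  taken from an input column when supplied (vendor-processed data) or
  recomputed as a one-sample t-test of probe-level ratios against 0.
  Time points with no passing replicate are flagged absent; those with
  < 2 replicates are flagged untestable.

## Synthetic data

The generators produce the statistical structure those procedures
assume, nothing more: Gaussian noise throughout (the downstream
statistics are t-tests and Pearson correlations), miRBase-style feature
ids so the default family list resolves, and bit-reproducibility from
the seed.

* E/M studies: baseline log2 intensities uniform in [6, 12], noise
  σ = 1, 10 samples per group by default, planted features shifted by
  ±(effect·σ) in the mesenchymal group with standardised effect 2 —
  conditions at which the t-test at α = 0.01 recovers planted-DOWN
  features with sensitivity ≳ 0.9.
* Correlated modules: a single latent factor per sample, module loading
  0.9, residual σ = 0.5, 60 samples; non-members get matched marginal
  variance so the ranking is not driven by scale.
* Time-course ratios: 8 probe-level ratios per replicate, 3 replicates,
  2 time points, planted log-fold-change −1.0 with σ = 0.1 (safely
  detectable by the 0.5/0.01 filter).

What passing these tests shows is that the pipeline's statistics behave
as designed under their own assumptions — they do not show robustness
to the features of real microarray data the generators deliberately
omit (probe chemistry, normalisation artefacts, heavy tails, correlated
noise between features outside the planted module).

## Numerical and design choices

* All enumeration, output and tie-breaking is in lexicographic node-id
  order; every stochastic routine takes an explicit seed and reports it.
* The Boolean/continuous correspondence (steady states ↔ fixed points
  under 0.5-thresholding) is asserted strictly on the fixture; on random
  networks it is checked but only flagged when broken, since it is not
  guaranteed in general for arbitrary topologies.
* Problem sizes in the test and acceptance runs — 200 random networks
  of ≤ 10 nodes for the oracle sweep, 1000 robustness trials, studies
  of 200 features — were chosen as the smallest sizes at which the
  statistical assertions have comfortable margins.
* The pipeline writes a provenance block (config hash, seeds, package
  version) with every report so any artifact regenerates from its own
  config.

## Limitations

Exhaustive attractor analysis stops at 20 nodes (no BDD/symbolic
backend); the logic is strictly two-valued and inhibitor-dominant (no
multi-valued or weighted variants); the ODE layer does no parameter
fitting and no bifurcation analysis; the signature tools assume
pre-normalised expression matrices and perform no array preprocessing.
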