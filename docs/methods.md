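# Methods

This note documents the models, numerical choices and known limitations
behind `berryopt`, in the order the pipeline runs.

## Process metrics

Dry-basis moisture content is computed literally as
MC_t = (M_t − M₀(1 − MC₀)) / (M₀(1 − MC₀)). This formula is algebraically
consistent only if MC₀ is a *wet-basis* fraction (so that M₀(1 − MC₀) is
the dry-solids mass), even though drying controllers conventionally report
MC on a dry basis. The package keeps the formula as printed in the source
field's convention, interprets MC₀ as wet-basis, and ships explicit
`wet_to_dry_basis` / `dry_to_wet_basis` converters rather than silently
"fixing" either side of the inconsistency.

The drying-time stopping rule is evaluated only at logged sample points
(10-minute logging in the reference equipment) with a strict `<` test
against the 0.05 kg/kg threshold, and no interpolation between points —
this mirrors how a touch-screen controller actually stops a dryer. A run
that never crosses the threshold raises `NotDriedError` rather than
returning a sentinel number.

## Synthetic experiment generator

No raw data from the underlying pilot-scale study is deposited anywhere,
so downstream stages are developed and tested against a generator that
reproduces the study's *published statistical structure*. The design is
the study's factorial: BT ∈ {30, 60, 90, 120} s, T ∈ {50, 60, 70, 80, 90} °C,
v ∈ {0.01, 0.5, 1.5, 2.5} m/s, three replicates (80 conditions, 240 rows).
The text lists a fifth forced-convection velocity in one place while
counting 80 total conditions and listing four velocities elsewhere; the
four-level set consistent with the 80-condition count is used.

Each response r is a separable multiplicative surface

    r(BT, T, v) = r_a · p_BT(BT)/p_BT(90) · p_T(T)/p_T(80) · p_v(v)/p_v(1.5)

anchored at (90 s, 80 °C, 1.5 m/s), with each p a piecewise-linear
interpolant through the published slice means. By construction the surface
is exact at every published slice point. Published slices exist for: DT
and SEC versus BT and versus v; VC and RC versus BT and versus T. Where
only a qualitative trend was published, monotone profiles anchored at the
80 °C published value are assumed (DT: 905→498 min over 50–90 °C,
decreasing; SEC: 7.6→4.4 MJ/kg, decreasing; RC: 2.58→3.31, increasing).
The published SEC-versus-velocity slice lists its second value at a
velocity level that is not part of the four-level design; that value
(5.3 MJ/kg) is assigned to the second design level (0.5 m/s), matching the
layout of the DT slice. VC and RC are flat in velocity (the study found no
significant velocity effect, p > 0.05).

Replicate scatter is multiplicative Gaussian noise with a default
coefficient of variation of 3 % (the study reports scatter only as figure
error bars; 3 % is a typical replicate CV for drying endpoints), truncated
by resampling to keep responses positive. Separability is the key
simplification: no interaction structure beyond the multiplicative
coupling is represented, because none is published. Passing tests on this
generator therefore demonstrate correctness of the pipeline mechanics and
recoverability of a smooth factorial surface — not fidelity to real
blueberry interaction effects.

## Surrogate network

The surrogate is a single-hidden-layer 3–n–4 perceptron. Activations are
tansig 2/(1+e^(−2n))−1, logsig 1/(1+e^(−n)) and pureline n. Inputs are
min–max scaled to [−1, 1] over the optimization bounds; training targets
are scaled to [−1, 1] over the training data range per response. One
printed activation equation in the source collapses two symbols in
typesetting; the footer definition of tansig is treated as authoritative.

Training is damped Gauss–Newton (Levenberg–Marquardt) on the summed
squared error of all four scaled outputs with an analytic Jacobian.
Damping starts at 1e−3 and moves by factors of 10 (rejected step → up,
accepted → down); iteration stops at 1000 epochs, an infinity-norm
gradient below 1e−7, damping above 1e10, or six consecutive
validation-error increases; the best-validation weights are returned.
Weights initialise uniformly in ±0.5 and five random restarts are kept-best
by validation error. None of these training details were published; all
are surfaced in `LMConfig`.

The 70/15/15 split is row-level (replicates of the same condition may land
in different subsets, matching a 240-observation count with no grouping),
with largest-remainder rounding of subset sizes. The topology search
trains all 16 grid cells and selects the cell whose *minimum* adjusted R²
across the four responses on the test set is largest (ties → fewer
neurons) — the "every response must fit" rule that selects the 3–8–4
tansig/pureline cell. Because targets are scaled to [−1, 1], cells with a
logsig output layer (range (0, 1)) cannot reach half the target range and
reliably lose the search, as they did in the source study. Metrics are
reported on train, test and validation subsets since the original
reporting subset is unstated. Adjusted R² is the standard
1 − (1 − R²)(N − 1)/(N − k − 1) with k = 3 predictors; one printed form of
the formula has a typeset denominator that would make a perfect fit score
less than 1 and is not used.

### Reconstructing the published network

The published hidden weights (8×3), hidden biases, output weights (4×8)
and output constants are packaged exactly as printed. Two things were
*not* published: the input scaling and the output scaling. The hidden
weights are order-1, so raw physical inputs (BT up to 120) would saturate
every tansig neuron — scaling must have been used; inputs are scaled
min–max over the optimization bounds, the de-facto default of the
toolchain the study used. The output affine transforms are recovered by
least squares of the network's raw outputs against the published
30-solution front and frozen into the packaged fixture
(`_data/published_network.json`). On those 30 points the reconstruction
achieves mean relative residuals of ≈2.4 % (DT), ≈13 % (SEC), ≈1.5 % (VC)
and ≈0.9 % (RC); at the published optimum (93 s, 89 °C, 1.2 m/s) it
predicts DT ≈ 386 min, SEC ≈ 1.74 MJ/kg, VC ≈ 4.18 mg/100 g, RC ≈ 3.35
against tabulated predictions of 366.7, 1.43, 4.19, 3.35. The quality
responses reconstruct tightly, DT moderately, SEC only loosely — the
affine-output hypothesis is evidently not the whole story for SEC, and
the residual report is treated as a documented, deterministic quantity
rather than a pass/fail gate. The fitted RC transform has a negative
gain, which is why output transforms are stored as general affine maps
rather than min–max ranges.

## NSGA-II

The optimizer is a standard elitist real-coded NSGA-II: fast
nondominated sorting (vectorised dominance matrix), crowding distance
with infinite boundary distance, binary tournament (rank, then crowding,
then uniform random), intermediate crossover (per-gene
`c = p1 + u·ratio·(p2 − p1)`, u ~ U(0,1), pair rate 0.90, ratio default
1.0), and uniform within-bounds mutation at gene rate 0.10. Maximised
objectives are negated internally and un-negated on output. Bound
handling is by clipping. The published parameter table names a uniform
*migration* function but no mutation function; since no subpopulations
are described, migration is taken as out of scope and the 10 % rate is
read as uniform gene-replacement mutation. Population is 30 × n_vars = 90
and the generation cap 500 × n_vars = 1500, with a stall stop (relative
change of the archive front's ideal and mean objective vectors below
1e−6 for 50 consecutive generations) because converged runs should not
burn the full cap.

Three additions address a structural weakness of plain NSGA-II on this
problem — with four objectives and only three decision variables, nearly
the whole population becomes rank-1 and in-population dominance pressure
vanishes:

* **Nondominated archive.** Every evaluated point feeds an external
  archive pruned by dominance (capped at 2000 by crowding), so the
  best-known front never degrades; the returned front is drawn from the
  archive, not from the final population.
* **Boundary-enriched initialisation.** Intermediate crossover is
  contractive and can never place a gene exactly on a bound, yet part of
  the Pareto set lies on the faces of the box; a sixth of initial genes
  are therefore placed exactly on a randomly chosen bound so face values
  exist in the gene pool and are inheritable.
* **Dominance polish.** The selected front points are refined by a
  two-pass local search (global dominating-sample repair, then a
  shrinking-radius ladder of axis steps, exact bound projections,
  face-pinned and anisotropic Gaussian moves) in which a move is accepted
  only if it Pareto-dominates the current point — a polished point is
  never worse in any objective. This repairs the locally suboptimal
  points that crowding-based selection tends to draw from sparsely
  searched regions.

The front size is 30 by default: the published fraction 0.30 of
population 90 would give 27, but the published front has 30 rows, so the
truncation target is an explicit `front_size` override (both behaviours
are available). Runs are deterministic under a fixed seed.

## Pareto post-processing

Two denominator conventions coexist deliberately: reference-relative
changes (how front groups are compared) divide by the *reference*
solution's value and round half-up to 1 decimal; validation errors (how
predictions are scored against a confirmation experiment) divide by the
*measured* value and round half-up to 2 decimals. Both reproduce the
published worked examples, with two documented exceptions: the published
DT validation error (1.43 %) and SEC validation error (2.06 %) are not
reproducible from the printed operand values under either convention
(they recompute to 1.42 % and 2.05 %); both are asserted as discrepancies,
not forced. Rounding happens at the reporting layer only.

The packaged 30-row reference front is *not* mutually nondominated under
strict Pareto dominance at printed precision: 18 ordered pairs formally
dominate, every one of them through a tie created by two-decimal rounding
of VC or RC. The fixture-integrity check therefore uses rounding-aware
dominance — each printed value carries ±half a unit in its last printed
digit, and a row counts as dominated only if it is certainly dominated
under that uncertainty. Under this semantics no row dominates another.

Selection policies are deterministic: `min_DT` (the study's choice, which
picks front solution 1), `min_SEC`, `max_VC`, `max_RC`, and `knee`
(maximises the minimum normalized margin from the front's worst value
across objectives). Percent comparisons between a reported "0.1 %" and
the recomputed 0.6 % for one RC pair in the study's narrative is a source
inconsistency; the package reports recomputed values only.

## Problem sizes used in tests and the acceptance script

The default test run trains single cells or reduced grids with shortened
epoch budgets; the full 16-cell search at full budget is available through
the API and CLI. The acceptance script runs the complete pipeline at the
study's published sizes: the 80×3 factorial, a 3–8–4 network with five
restarts, and a full 90-individual NSGA-II run with the 1500-generation
cap, validated against a 50³ grid scan (125 000 surrogate evaluations).

## Known limitations

* The synthetic surface is separable; real interaction effects between
  blanching, temperature and velocity are not represented, so surrogate
  accuracies on synthetic data overestimate what the same pipeline would
  achieve on real measurements.
* The published network's SEC output is reconstructed only to ~13 % mean
  relative error; conclusions that depend on absolute SEC values from the
  reconstruction should use a freshly trained network instead.
* The optimizer handles box bounds only — the underlying problem has no
  other constraints — and objective evaluations are assumed cheap, as
  they are for a small perceptron.
* Weight identifiability is not claimed anywhere: hidden-neuron
  permutation and sign symmetry make trained weights non-unique, and all
  recovery claims are about the fitted function.
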