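# Methods

This note records the model, the conventions and the design choices behind
`pentahyb`, in the spirit of a statistical package's methods appendix. It
states no empirical numbers beyond those the test suite and
`scripts/acceptance.py` compute themselves.

## Intensity model and identifiability

The observed linear-scale intensity of probe *j* on array *i* is

    I_ij = theta_i(g(j)) * phi_j + eps_ij,   eps_ij ~ N(0, sigma^2)

with `g(j)` the locus measured by probe *j*. The model is deliberately fit
on the **linear** intensity scale: the mean structure is a product of
expression and affinity with additive Gaussian error, and a log transform
would change the error model, not merely the parametrization. The pair
(theta, phi) is only identified up to a per-locus scale (doubling phi and
halving theta leaves every intensity unchanged), so theta is pinned by the
constraint `sum_i theta_i^2 = N` per locus, N the number of arrays; the
fitted phi then absorbs the scale and multiplying all intensities by c
multiplies fitted affinities by c. Expression is treated as per
(array, locus); a per-array global abundance would not let probes of
different loci share an array.

## Affinity decomposition

`phi_j = sum_l sum_k beta_k^l X_jk^l + sum_m delta_m Z_jm`, a sparse linear
form over tokens extracted from the probe-target duplex alignment:

- **Windows.** A 5-column window slides over the alignment (21 windows for
  an ungapped 25-mer). Pentamers rather than dimers carry stacking context;
  this is the smallest k at which both neighbours of a mispair are visible.
- **Regions.** Each window is tagged with one of three equal contiguous
  blocks of window starts (7/7/7 for 25-mers). This coarse position
  dependence approximates per-position k-mer effects at one third of a
  per-position model's cost; the boundary rule (blocks of *window starts*,
  not probe bases) is a package convention.
- **Token classes.** A window with no event emits a PM token (its target
  5-mer). Exactly one mismatch emits an MM token: the target 5-mer, the
  offset of the mispair within the window, and the offending probe base
  (3 alternatives per position). Exactly one gap emits a GAP token: the
  4-base context, the gap offset, and which strand carries the gap.
  Per orientation and region this yields 4^5 = 1,024 PM, 4^5*5*3 = 15,360
  MM and 4^4*5*2 = 2,560 GAP tokens (18,944); across two synthesis
  orientations and three regions, 113,664 parameters.
- **Multi-event windows** emit no k-mer token. Additivity of k-mer effects
  breaks down when mispairs crowd together, so their contribution is
  delegated to interaction indicators `Z_jm`: one flag per unordered
  mismatch pair, keyed by separation class — adjacent (<= 2 columns), near
  (3–7) or far (>= 8). The coarse 3-class encoding keeps the interaction
  block estimable from small training sets.

## Duplex alignment

Free-form probe/target pairs are aligned by a global dynamic program
minimizing `n_mismatches + 1.5 * n_gaps` subject to budgets (default <= 3
mismatches, <= 1 gap). The 1.5 gap penalty makes a gap dearer than a
mismatch — a bulged base destabilizes a duplex more than a mispair — while
keeping one gap cheaper than two mismatches. Ties are broken toward the
leftmost gap placement, which makes alignment, and hence feature
extraction, a pure deterministic function. The DP carries the gap count as
a state, so a within-budget alignment is found whenever one exists even if
the unconstrained optimum overspends a budget.

## Fitting

Estimation alternates two steps until the relative change in training RSS
falls below 1e-6 (at most 100 iterations; both configurable):

1. **Coefficient step.** Given theta, every observation (j, i) is a row
   `theta_i(g(j)) * X_j` of a sparse design; (beta, delta) solve the
   L1-penalized least-squares problem. The penalty is chosen by k-fold
   cross-validation (default 10) with folds over *probes*, stratified by
   locus so every fold sees every locus, and all arrays of a probe share a
   fold (otherwise the same probe would appear in train and test). The
   1-SE rule picks the sparsest model within one standard error of the
   minimum CV error. The penalty is selected at the first iteration and
   held fixed thereafter: theta changes little between iterations, and
   re-running CV each round multiplies cost for no measurable benefit
   (`reselect_penalty=True` restores per-iteration selection).
2. **Expression step.** Given phi, theta for each (array, locus) is the
   closed-form least-squares slope over that locus's probes, then each
   locus vector is renormalized to the constraint. Theta is initialized
   from per-(array, locus) mean intensities — positive, data-driven and
   deterministic. An all-zero locus receives the constraint-satisfying
   constant and is flagged rather than failing the fit.

The residual noise estimate is `sqrt(RSS / n_obs)`. Held-out evaluation
follows the two-thirds/one-third protocol: per locus, expression is
re-estimated by regressing intensities on affinities over two-thirds of
the probes, intensities of the remaining third are predicted as
`theta * phi`, and the squared Pearson correlation over all held-out cells
is reported. Probesets with fewer than 3 probes are skipped with a warning.

## Hybridization threshold

The threshold T separates stable from unstable duplexes in design: among
probes with affinity < T, at least 90% must have median intensity (across
arrays) below the supplied background level. T is found by scanning the
observed affinity values — no parametric fit — and the largest qualifying
value is returned; the scan never extrapolates beyond observed affinities,
so ties resolve conservatively. Raising the background level can only
raise T. When no probe is sub-background the data cannot calibrate a
threshold and an error is raised rather than a default returned.

Background levels come from either estimator: the 15th percentile of
designated control-probe intensities (linear-interpolation quantile,
numpy's default definition), or the median intensity of antigenomic probes
with matching GC count, with an empty GC bin falling back to the nearest
populated bin (ties toward lower GC, the conservative side since
non-specific binding grows with GC).

## Probe and probeset design

- **Tiling.** Candidates at offsets 0, step, 2*step, ... (step 1–4 nt);
  windows containing ambiguous symbols are masked. Coordinates are 0-based
  half-open internally and in BED output.
- **Self-affinity filter.** Perfect-match affinity >= T keeps a candidate.
  The boundary is inclusive so the calibration boundary case is retained
  (configurable).
- **Hit search.** The aligner is a pluggable contract (probe in, hit list
  out). The built-in backend cuts the probe into `max_mm + max_gaps + 1`
  disjoint seeds; by pigeonhole any within-budget hit leaves one seed
  intact, whose exact occurrence anchors the site up to a gap shift. Every
  candidate site is verified by the optimal duplex alignment, and
  gap-shifted duplicates of one physical site are clustered to a single
  best hit. This is exhaustive at desk scale; genome-scale searches would
  swap in an external mapper behind the same interface.
- **Classification.** Hits with affinity >= T are counted: 1 = specific,
  2–3 = potentially cross-hybridizing, >= 4 = non-specific (discarded).
  Lowering T can only move probes toward less specific classes.
- **Assembly.** A greedy left-to-right scan anchors a 400-nt window at the
  first admissible probe and admits probes in position order, skipping any
  probe starting fewer than 8 nt after the previous one (the <= 30%
  overlap rule for 25-mers; generalized as `ceil(0.3 * length)` spacing
  floor) and any cross-hybridizing probe sharing a partner locus with an
  admitted one. A window is emitted only with 3–6 probes including at
  least one specific member; oversized windows keep the highest
  self-affinity probes (never dropping the last specific one), and emitted
  probesets never overlap. The greedy scan and its tie-breaks
  (position-first, self-affinity second) are package conventions — the
  structural rules admit many selection algorithms and first-window-wins
  is the deterministic choice. Every emitted probeset is re-validated
  against all structural rules at emission time.

## Titration statistics

- **Summarization.** Probe-level intensities are summarized per probeset
  by Tukey median polish (deterministic, outlier-resistant); the per-array
  value is the overall effect plus the array effect. Medians of even
  counts are midpoints throughout.
- **Titration response.** A probeset titrates when its four sample means
  are strictly ordered A > C > D > B or B > D > C > A; ties fail. Under
  pure noise the four means are exchangeable, so exactly 2 of the 24
  orderings pass (1/12). The response curve bins probesets by the
  symmetric fold change max(A/B, B/A) and reports the passing percentage
  per bin; the fold change at which the curve reaches a level (default
  75%) is read off by linear interpolation between bin midpoints.
- **Mixture estimation.** Per probeset, the mixture identity
  `c = alpha*a + beta*b` is one equation; without the constraint
  `alpha + beta = 1` the two fractions are not identifiable from a single
  probeset, so the estimator solves the constrained form
  `beta = (a - c)/(a - b)` per probeset, skips probesets with a ≈ b
  (degenerate denominator), and reports the median over probesets. An
  unconstrained pooled OLS across probesets (`method="pooled"`) is offered
  for comparison. Only probesets passing the DE filter should be supplied:
  non-differential probesets carry no mixture information.
- **DE filter.** Welch's t-test per probeset between the A and B replicate
  groups with Benjamini–Hochberg adjustment, kept when q <= 0.01, fold
  change >= 2 in either direction, and median replicate intensity >= 2^4
  in at least one sample. The moderated-t machinery used in full array
  pipelines is deliberately replaced by this simple, dependency-free test;
  the function is the single place to substitute another.

## Synthetic data

The generators emulate the two study designs the methods assume:

- **Degenerate training design.** Per parent 25-mer: all 75 single-MM
  variants, all single-base deletions, and distinct random double-MM
  variants up to the requested count (default 180 variants per parent, so
  ten parents yield 1,800 degenerate probes). Deleting either base of an
  adjacent repeat yields the same oligo, so deletion variants are
  deduplicated by sequence (leftmost gap kept) and the shortfall is filled
  with additional double-MM variants — the variant count is always exact
  while no duplicate oligo is ever emitted. "Single gap" means a deletion
  in the probe relative to its target; double-MM variants are sampled, not
  exhaustively enumerated (full enumeration of C(25,2)*9 pairs is
  available by requesting that many variants).
- **Ground truth.** PM coefficients are positive uniform draws; MM and GAP
  coefficients are the same draws shifted negative (mispairing lowers
  affinity); interaction coefficients are negative; theta is positive then
  constraint-renormalized. Noise is homoscedastic Gaussian exactly as the
  intensity model assumes.
- **Titration.** Mixture expression is blended at the concentration level
  (`theta_C = 0.75 theta_A + 0.25 theta_B`) and every replicate array gets
  independent noise.
- **Families.** One random ancestor is mutated independently into n
  paralogs at a per-site substitution rate; divergence 0 gives identical
  paralogs — the worst case, in which no probe can be specific and no
  probeset is emitted.

What the generators do **not** emulate: probe-level variance heterogeneity
and saturation, spatial scanner artifacts, indel-rich family evolution and
LTR structure, and the background's GC dependence. Tests passing on these
generators therefore demonstrate correctness of the algorithms under the
stated model, not performance on a physical array. An optional
intensity-proportional noise mode exists for robustness exercises and is
labelled as such.

## Problem sizes and numerics

The test suite and acceptance script run at desk scale by choice: model
recovery uses 200 probes x 8 arrays x 20 loci at noise sd equal to 5% of
the mean signal; threshold calibration uses ~2,000 probes on 6 arrays;
titration checks use 200 probesets in triplicate (3,000 for the pure-noise
rate, whose binomial standard error is then ~0.5%). Convergence tolerances:
alternating-fit RSS 1e-6 relative; constraint conservation is tracked every
iteration and held to 1e-9 relative. Seeds are mandatory arguments of every
stochastic routine; identical seeds give byte-identical outputs.

## Known limitations

- The affinity scale is arbitrary (constraint-pinned), so thresholds are
  only meaningful relative to a fitted model and its training intensities.
- The exhaustive hit search is quadratic at worst and meant for reference
  libraries of kilobase-to-megabase scale, not whole genomes.
- The interaction vocabulary covers mismatch pairs only; mismatch-gap and
  gap-gap interactions fall into multi-event windows and are absorbed by
  the (coarser) distance classes of their mismatch content, if any.
- LASSO shrinkage biases coefficients toward zero; fitted affinities are
  best interpreted through correlation and ranking, not absolute value.
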