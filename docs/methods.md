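# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind `soilvir`, in the order the pipeline runs.

## Induction assay model

An induction assay compares a mitomycin-C-treated aliquot of a washed soil
cell suspension against an un-induced control.  With latent lysogen
fraction `f`, burst size `β` and starting cell count `b`, the lysed-cell
count is `L = f·b` and, before noise,

    Vm = Vc + β·L        Bc = b·g        Bm = (b − L)·g

where `g ≥ 1` is a growth factor applied equally to both tubes (the cells
in both tubes come from the same suspension and experience the same
overnight incubation).  Each of the four counts then receives independent
multiplicative lognormal noise with mean exactly 1 and coefficient of
variation `cv` (`σ² = ln(1+cv²)`, `μ = −σ²/2`); the mean-1 convention makes
the IF estimators unbiased to first order, which the bias tests rely on.

Consequences of the equal-growth model worth knowing:

* the calculated burst size without noise is `β/g`, so growth *dilutes*
  burst-size estimates; with count noise it pushes estimates below 1
  (`low_burst`) and, in the no-lysis limit, ties the tubes
  (`growth_dominated`).  The flagged fraction rises monotonically with `g`,
  which the acceptance suite verifies with common random numbers across
  growth levels;
* `IF` from the calculated burst size is algebraically
  `100·(Bc − Bm)/Bc` — independent of the viral counts — and the identity
  is enforced to 1e-12 relative tolerance.

The denominator of both IF conventions is the post-incubation control
count `Bc`, the only control bacterial count the assay produces; a caller
holding a separate assay-start count can pass it explicitly.  Negative
statistics (e.g. `Vm < Vc`) are reported with a `no_induction` flag, never
clipped: they are the quality-control signal.

The control tube's viral background defaults to 0.25 VLP per cell
(`induction_background_vbr`), far below the bulk-soil virus-to-bacteria
ratio of ~5, because the suspension is density-gradient washed before
incubation.  This is what lets a community with a 2–4 % inducible fraction
show a multi-hundred-percent increase in countable viruses: the percent
increase is `100·β·f / vbr_tube`, so IF20 ≈ 3 % with a tube background of
0.25 gives ≈ 240 %, which is the regime field assays report.

## T-RFLP pipeline

Stage order: replicate alignment → reproducibility filter → reiterative
normalization → minor-peak removal → consensus → cross-sample binning →
Shannon diversity.

* **Alignment** pools all replicate peaks, sorts by fragment size, and
  grows groups greedily: a peak joins the open group iff it lies within
  `tol` (default 0.5 nt) of the group's running mean.  After sorting the
  procedure is independent of input peak order.
* **Reproducibility** keeps only groups with exactly one peak from every
  replicate; a fragment that PCR or detection missed in any replicate is
  treated as unreliable.
* **Reiterative normalization** scales every trace to the minimum total
  fluorescence, deletes peaks strictly below 0.1 % of the trace's new
  total, and repeats until a pass deletes nothing.  The loop terminates
  because the retained peak count strictly decreases on every non-final
  pass; at convergence all totals agree with the minimum to 1e-9 relative
  and no retained peak is sub-threshold.  The 0.1 % rule is a strict
  inequality: a peak at exactly 0.1 % stays.
* **Binning across samples** reuses the greedy running-mean rule (default
  0.5 nt) on the pooled consensus peaks; ties at exactly the tolerance
  stay with the earlier (smaller-size) bin.  Rows are normalized to
  relative fluorescence.
* **Diversity** is natural-log Shannon `H = −Σ pᵢ ln pᵢ` (base
  configurable).  Peak height, not area, is the abundance proxy
  throughout.

The order of the 0.1 % filter relative to the reproducibility filter is
not canonical in the field; here reproducibility runs first and the
threshold is re-applied inside the normalization loop, and both tolerances
are configurable.

## Fingerprint analysis

Band calling from a densitometric trace uses local-maximum prominence
relative to the trace maximum: ≥ 5 % ("minimum profiling") is a band,
2–5 % ("grey zone") is recorded as uncertain and excluded by default.
This is a documented approximation of the screening criteria commercial
gel software applies; exact semantics of those tools are proprietary.

Band matching across lanes clusters pooled positions greedily with a
tolerance proportional to fragment size (default 2 %), since gel mobility
error grows with size; an absolute-bp mode is available.  Similarity is
Dice's coefficient in percent, dissimilarity the involution
`y = 100 − x`, and the average dissimilarity is the mean of the
n(n−1)/2 strictly-upper-triangle entries (the maximum is reported
alongside).

**UPGMA** merges the closest pair of clusters under unweighted
arithmetic-mean linkage (size-weighted Lance–Williams update).  The merge
height recorded — and written as Newick branch lengths — is the *full*
average distance at merging, not half of it, so the cophenetic distance of
two leaves equals the height of their lowest common ancestor.  Ties break
on the lexicographically smallest pair of cluster labels (a cluster is
labelled by its smallest leaf).  Dendrograms are computed on dissimilarity;
topology is identical to clustering on similarity.

**Nonmetric MDS** is Kruskal's stress-1 formulation: initialize from
classical (Torgerson) scaling, then alternate (a) monotone regression of
configuration distances onto the dissimilarity rank order
(pool-adjacent-violators; primary treatment of ties, with tied blocks
ordered once by the initial metric distances for determinism) and (b) a
backtracking gradient step on stress-1 that only accepts a configuration
with strictly lower stress — so the reported stress sequence is
non-increasing by construction.  Three seeded perturbed restarts (four
starts total) guard against local minima.  Exact-zero off-diagonal
dissimilarities (identical fingerprints) break rank-based scaling and are
replaced by half the smallest positive dissimilarity with a logged
warning; an entirely degenerate (all-identical) profile set skips the MDS
stage.  For 30 near-binary band profiles a 2-D stress around 0.15–0.2 is
typical; values below 0.2 are conventionally taken as interpretable.

## Statistics

* **Spearman correlation** is the Pearson correlation of mid-ranks.  The
  two-sided p-value uses the t approximation for n ≥ 10, exhaustive
  permutation enumeration for n ≤ 7, and 10⁴ Monte Carlo permutations
  (add-one convention) for n = 8–9.  Missing values are handled
  pairwise-complete; summary tables mark the conventional 0.05 / 0.01 /
  0.001 reporting tiers.
* **Repeated-measures ANOVA** is the balanced one-way within-subjects
  decomposition (`F = MS_groups / MS_error`, error df `(k−1)(n−1)`),
  computed from sums of squares directly and cross-checked against an
  independent implementation in the tests.  The Tukey HSD post-hoc uses
  studentized-range quantiles with the within-subjects MS error — the
  appropriate error term for this design, which generic independent-groups
  Tukey routines do not take.
* **Seasonal-variability analysis**: per treatment, the sample SD of
  monthly mean abundances paired with the treatment-mean organic carbon,
  correlated by Spearman.
* **CCA** follows the chi-square/weighted-projection construction: the
  community matrix is converted to standardized chi-square residuals, its
  site dimension projected onto the span of the weighted-centered
  environmental predictors, and the projection eigen-decomposed.
  Constrained eigenvalues are reported as percentages of the total
  correspondence-analysis inertia, which is invariant to score scaling.
  Site scores use Hill's scaling (weighted-average scores divided by
  `sqrt(1 − λ)`, the inter-sample-distance focus).  Optional rare-species
  down-weighting multiplies a species column by
  `frequency / (max frequency / 5)` when its occurrence frequency falls
  below a fifth of the maximum.  Rank-deficient predictors raise an error
  naming the offending column.
* **Permutation test**: the statistic is the constrained trace; sample
  rows of the predictor matrix are permuted, and
  `p = (1 + #{trace_perm ≥ trace_obs}) / (1 + n_perm)` (add-one, never
  exactly zero).  Null p-values are uniform within Monte Carlo error,
  which the acceptance suite checks with a KS test over 500 null data
  sets.

## Synthetic-study generator

The generator emulates a five-treatment (two crop rotations, two early
plant successional treatments, one mid-successional forest), six-month
(May–November), triplicate-plot design with the forest site unreplicated.
Defaults were chosen once to match the regimes such field campaigns
report, and every generator is a pure function of (parameters, seed):

* abundances: lognormal around 5×10⁷ cells/g with VBR 5; log-abundance
  rises with treatment organic carbon (slope 0.5 per % C), and the monthly
  deviation of log viral abundance has SD proportional to organic carbon
  (0.15 per % C) so that seasonal variability of viral abundance increases
  with carbon content; count CV 0.25;
* organic carbon 0.9 / 1.1 / 1.3 / 1.6 / 2.5 % from the tilled
  agricultural soils to the forest; total N derived via C:N ≈ 11; moisture
  increases with carbon; P and pH uninformative noise;
* induction: per-treatment lysogen fractions 2–4 %, burst size 20,
  non-induced growth factor 1.2, tube background 0.25 VLP/cell;
* communities: a 30-taxon hierarchical Dirichlet (treatment cores,
  seasonal drift, plot heterogeneity), taxon fragment sizes 3 nt apart
  (safely beyond twice the 0.5-nt bin tolerance); triplicate T-RFLP
  profiles with 10 % height noise, 0.15-nt size jitter and 2 % dropout;
* fingerprints: 60 log-spaced fragment positions (100–1000 bp), a global
  core modified per treatment, monthly Bernoulli band turnover, and a
  plot-heterogeneity flip per lane.  The free assemblage uses treatment
  divergence 0.15 and turnover 0.05; the induced assemblage 0.35 and 0.10,
  reflecting that induced prophage pools differ more between land uses and
  vary more month to month.  Splitting the extra induced dissimilarity
  between spatial structure and temporal turnover keeps the 2-D ordination
  interpretable (stress near 0.2) at an average dissimilarity in the
  high-40s, the regime reported for induced assemblages.

What the generator does *not* emulate: pore-scale hydrology and
virus-mineral adsorption, infection dynamics (lysogeny is a static latent
fraction), taxon-specific induction, electropherogram baseline/size-calling
artifacts, gel-image distortions, and non-lognormal count outliers.
Passing tests therefore demonstrate the correctness and calibration of the
computational chain under the declared statistical structure, not the
behaviour of any particular real soil.

## Problem sizes and numerical choices

The default study is 78 samples (4 treatments × 3 plots + 1 × 1 plot, 6
months), 30 taxa, triplicate T-RFLP profiles, and 30 fingerprint labels
per assemblage — small enough that the full suite and the reproduction
script each run in well under a minute while exercising every stage at
realistic shape.  Monte Carlo checks use 20–50 seeds and the permutation
test 99–999 permutations.  Numerical details: distances are floored at
1e-12 in the MDS gradient; eigenvalues below 1e-12 are discarded in CCA;
greedy bin/group ties go to the earlier bin; single-plot groups report SD
as missing rather than zero.

## Known limitations

* The calculated-burst-size IF cannot be validated against published field
  tables without the underlying raw counts; only its algebra and its
  zero-noise recovery are testable, which is what the suite does.
* GelCompare-style "minimum profiling"/"grey zone" semantics are
  approximated by prominence thresholds.
* The CCA permutation test permutes rows freely; it does not implement
  restricted permutation schemes for split-plot or time-series designs.
* NMDS is a local optimizer; restarts mitigate but cannot eliminate local
  minima, so only stress (not the embedding itself) is treated as a stable
  output.
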