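# Methods

This note documents the models and procedures implemented in `monoflame`,
the parameters that matter, the design choices made where the design was
genuinely open, and the limits of what the synthetic-data tests show.

## Study design being modeled

Two in vitro arms of human blood monocytes share a pre-divergence baseline
(6 donors at 0 h, 3 at 2 h) and then follow different stimulation
schedules: a *resolving* course sampled at 4, 14, 24 and 48 h (3 donors)
and a *persistent* course sampled at 4, 14, 24, 72 and 96 h (3 donors) —
36 RNA-seq samples in total. The biologically critical comparisons are
between-arm: persistent vs. resolving at 24 h, and the two endpoints
(96 h vs. 48 h). Supernatant cytokine panels are collected at the same
time points; supernatants are replaced at each medium change, so measured
totals accumulate only since the previous change.

## Expression preparation

**Replicate imputation.** Within a 3-replicate (arm, time) group, a single
missing value is set to the mean of the other two (rounded to the nearest
count); when only one replicate was observed the missing two are set to
zero; a fully missing group is an error. The rule presupposes triplicates;
for other group sizes the module generalizes to mean-of-observed for a
single hole and zeros otherwise. Imputation runs before normalization and
filtering, and never touches observed cells.

**TMM.** Normalization factors are the weighted trimmed mean of gene-wise
log2 expression ratios (M) against a reference sample: 30% two-sided trim
on M, 5% on average log abundance (A), weights equal to the inverse
asymptotic binomial variance `(N−y)/(Ny)` summed over the pair, factors
renormalized to geometric mean 1. The reference is the sample whose
upper-quartile count fraction is closest to the mean — the default of the
standard TMM implementation, which this module reproduces (cross-checked
against edgeR's `calcNormFactors` to ~1e-6 in the test suite). Exact
invariance to rescaling a sample holds for M and A but not for the
precision weights, so factors are only approximately depth-invariant —
same as the reference implementation.

**log-cpm and filter.** `log2((count + 0.5)/(libsize·factor + 1)·1e6)`;
the expression filter keeps genes with plain cpm (no offsets) strictly
above 1 in at least 4 samples, with factors computed on the full matrix
and the filter applied afterwards (the order is not dictated by the
procedure's description; computing factors on all genes uses the most
information and is the common practice). Precision weights of the
voom-style framework are deliberately not computed: the downstream checks
are property-based (calibration, FDR control), and unweighted OLS meets
them; see the calibration results below.

**PCA.** Gene-centered (unscaled) singular value decomposition of the
log-cpm matrix; sample scores are `VᵀS`. Signs are fixed by making the
largest-magnitude gene loading of each component positive, so results are
reproducible across linear-algebra backends.

## Differential statistics

One OLS model per gene with a mean per (arm, time) cell. Empirical-Bayes
moderation follows the standard limma scheme: `log s²_g` is moment-matched
to its theoretical scaled-F distribution via digamma/trigamma inversion,
yielding prior degrees of freedom d₀ and prior variance s₀²; the posterior
variance `(d₀s₀² + d_g s²_g)/(d₀+d_g)` feeds t statistics on d₀+d_g
degrees of freedom and an analogous joint F. When the observed spread of
`log s²_g` does not exceed its sampling noise the inversion has no
positive solution and d₀ = ∞ (complete shrinkage) is used with a logged
warning — this is the correct limit, not a failure, and arises routinely
on homoscedastic null data. The implementation is verified against limma's
`eBayes` to ~1e-6 on a shared fixture.

**Donor blocking.** The design supports an additive donor factor, but the
default contrast fits are unblocked. The critical contrasts compare cells
with *disjoint* donor sets (each arm has its own donors), so a donor
factor cannot cancel any donor effect in the contrast; it only transfers
donor variance out of the residual while doubling the contrast variance
multiplier (from 2/3 to 4/3 with n = 3 per cell), which costs roughly half
the effective power for nothing in return. Donor variability is instead
treated as part of the biological replicate noise. For within-donor
contrasts (e.g. consecutive time points of one arm) blocking is available
via the `blocking="donor"` argument and does pay off.

**q floor and ranking.** BH q-values are floored at 1e-300 before the
`s = −log10(q)·log2(FC)` score so s stays finite. Top-K selection by |s|
breaks ties deterministically: larger |log2FC| first, then lexicographic
gene id. Heat-map matrices use gene-wise z-scores with the n−1 sample
standard deviation; zero-variance genes become zero rows with a warning.

## Enrichment

**GSEA.** Weighted KS running sum with weight |metric|¹ over the list
ranked by the signed s score (the only ranking the analysis defines);
descending metric, ties broken by gene id. The ES is the maximum deviation
from zero. The null permutes gene labels — with 3 samples per group,
sample permutation is degenerate — with n_perm = 1000 by default and a
mandatory seed; p is add-one smoothed,
`(1 + #{|ES_perm| ≥ |ES_obs|})/(n_perm + 1)`.

**ORA.** Upper-tail hypergeometric test of the overlap between a gene set
and the top-750 |s| selection, per contrast. The universe is the filtered
expression universe (the genes that survived the cpm filter), not all
annotated genes: enrichment should be judged against what could have been
detected.

**Fusion and map.** GSEA sets are ordered by p then |ES|, ORA by p then
overlap; exact ties get average ranks; the fused statistic is
`√(r_GSEA·r_ORA)` and the final ordering is ascending in it. The
enrichment map takes the union of each comparison's top-500 fused sets;
node category records exclusive/shared membership, node size the set size,
and edges require overlap coefficient ≥ 0.7. Output is GraphML plus a TSV
edge list.

Gene sets are filtered to 10–500 members (inclusive) *after* intersection
with the universe.

## Cytokine equilibrium

All equilibria are computed in pM; pg/ml divided by the molar mass in kDa
gives pM exactly. Constants: Kd(IL-1β:sIL-1R2) = 2700 pM,
Kd(IL-18:IL-18BP) = 400 pM, ternary Kd = 5.6 pM; molar masses 17 (IL-1β),
18 (IL-18), 47 (sIL-1R2), 40 (IL-18BP), 47 (sIL-1R3) kDa. The 25 µM
sIL-1R2 affinity for IL-1Ra is stored for documentation but not used: the
model is one ligand, one receptor (IL-1Ra does not compete for the decoy
receptor).

**Single-site closed form.** The quadratic root of the binding isotherm is
evaluated in the cancellation-free branch: for `b = RT − LT + Kd ≥ 0`,
`LF = 2·LT·Kd / (b + √(b² + 4·LT·Kd))`, otherwise `(√(·) − b)/2`. Both are
algebraically identical to the textbook formula; the branch choice keeps
relative error at machine precision even when RT ≫ LT (the worst measured
deviation from a high-precision numeric root over 10⁻¹–10⁵ pM inputs is
~1e-15).

**Two-site IL-1β.** No R2–R3 association constant is given for the ternary
pool, so the default partition is stoichiometric: `C = min(R2T, R3T)`
sIL-1R2 molecules bind at the ternary Kd and the remainder at the binary
Kd; LF is the bracketed Brent root of the two-pool mass balance on
[0, LT]. This is the strongest-inhibition reading of "one part of sIL-1R2
is engaged with sIL-1R3". An optional `kd_r2_r3` argument replaces the
stoichiometric pairing with an equilibrium R2:R3 complex for sensitivity
analysis (a tight Kd recovers the default). The two-site free IL-1β feeds
the active index; totals and frees are mutually convertible to pg/ml.

**Rates and comparisons.** Production rate =
`conc·volume / ((viable cells/10⁶)·interval)` with the interval measured
from the last medium change. Group comparisons use one-way ANOVA and Tukey
HSD (Tukey–Kramer for unequal n, the scipy default); zero within-group
variance with unequal means is reported at the smallest positive float
with a warning rather than as an exact zero.

## Synthetic data

The count simulator draws gene-wise negative-binomial counts
(Var = μ + φμ²) with φ lognormal (median 0.1, log-sd 0.5 — a biological
CV of ~0.32 across human donors), additive N(0, 0.2²) donor effects on the
log2 mean shared across a donor's time points, base abundances lognormal
with log2-sd 2, and per-sample library sizes drawn from the middle of a
configurable range (default 5–15 million) so realized totals stay inside
it. Ten percent of genes are differentially expressed at |log2FC| = 1.5 by
default, split evenly across four temporal archetypes: *transient_up*
(pulses at 4–14 h in both arms), *resolving_up* (up through 14 h, back to
baseline by 24–48 h only in the resolving arm), and *persistent_up/down*
(arm divergence from 24 h on). Effect sizes and dispersions are free
parameters of the generator, chosen as realistic for donor-level bulk
RNA-seq; they are not estimates of any particular data set. Fold changes
enter before per-sample renormalization, so mild compositional distortion
is present — which is precisely what TMM exists to absorb.

The cytokine simulator uses gamma-shaped pulses
`peak·(t/t_peak)^a·exp(a(1−t/t_peak))` (a = 2) with agonist peaks at
4–14 h, inhibitor plateaus that keep sIL-1R2/IL-18BP in molar excess at
72–96 h, lognormal measurement noise with configurable CV (0.1 default),
cultures of 5×10⁶ cells in 2 ml, and piecewise-linear viability ≥ 0.85 at
48 h and ≥ 0.55 at 96 h. The noise-free truth computes free fractions with
the package's own equilibrium solvers, so the truth satisfies the isotherm
by construction; an independent root-finder confirms it in the tests.

**What the synthetic data does not emulate:** GC/length biases, batch
effects, isoform-level structure, count outliers, correlated gene modules
(beyond the archetype blocks), ELISA detection limits, and plate effects.
Passing tests demonstrate the statistical machinery is correct and
calibrated under the assumed generative model; they are not evidence about
any particular real data set.

## Problem sizes and calibration results

The test suite and the acceptance script use the full 36-sample design
with 10,000 genes for parameter recovery (5 seeds), 5,000-gene null
matrices for calibration (3 seeds), and a 6,000-gene demo; these sizes
give stable averages while keeping a full run in the tens of seconds.
Measured with seed 1: null moderated-t p-values have KS distance 0.013
from uniform with type-I error 0.054 at α = 0.05; the full
prep + DE chain at q < 0.05 shows empirical FDR 0.047 and sensitivity
0.59; GSEA permutation p-values flag 4.3% of null sets at p < 0.05.

## Known limitations

- The moderated fits are unweighted; very-low-count genes carry more
  variance than the model assumes (mitigated by the cpm filter).
- The GSEA gene-label permutation null ignores inter-gene correlation and
  is anti-conservative on strongly co-expressed sets.
- The stoichiometric ternary partition is an upper bound on the
  high-affinity pool; with a finite R2–R3 Kd free IL-1β lies between the
  single-site and default two-site answers.
- The active-IL-1β index is computed with both terms in pM; the index is
  scale-free only if both terms share units, and a pg/ml-based index
  differs by the MW ratio of IL-1β and IL-1Ra (1.0 here, as both are
  17 kDa, so the distinction is moot for the default constants).
- `impute_missing_replicates` rounds imputed means to whole counts to keep
  the matrix integral; the downstream log-cpm is insensitive to this.
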