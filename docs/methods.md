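# Methods

## The generative model

`xskew` models the fraction of expression signal carried by each parental
allele of a gene in the brain of an F1 female from a reciprocal cross
between two inbred mouse strains. Three effects are superimposed.

**Cell sampling at X inactivation.** X inactivation occurs when the pool of
cells committed to the brain lineage is small. Each of the `N` progenitors
independently inactivates its paternal X with probability `p_pat`, so the
realised fraction of cells with the maternal X active is `f = K/N`,
`K ~ Binomial(N, p_pat)`, with `E f = p_pat` and
`Var f = p_pat (1 − p_pat) / N`. One `f` is drawn per individual and shared
by every X-linked gene; this shared factor is what makes X-inactivated genes
covary across individuals, and it is the signal exploited by both the
escaper classifier and the progenitor-count estimator. Lineage expansion
after inactivation is not modelled: `f` is frozen at the draw, the same
assumption the variance-matching estimator makes.

**Cis-regulatory (eQTL) bias.** Each gene has a reference-allele
transcriptional strength `ρ ∈ (0, 1)` (the other allele has `1 − ρ`),
identical in both crosses. `ρ` is oriented by cross into maternal/paternal
strengths `(a_m, a_p)`.

**Escape level.** A gene transcribes from the inactive X at a relative rate
`λ` (0 = fully silenced, 1 = full escape). Per-allele output is allelic
strength × active-cell fraction, with inactive-X copies contributing a `λ`
multiple, giving the expected maternal fraction

    m(f) = a_m (f + (1−f) λ) / [ a_m (f + (1−f) λ) + a_p ((1−f) + f λ) ].

This single rational form reduces to every qualitative regime of interest:
escapers (`λ = 1`) give `m = a_m/(a_m+a_p)`, independent of `f`; fully
inactivated genes (`λ = 0`) give `m = a_m f / (a_m f + a_p (1−f))`;
autosomal genes are assigned `m = a_m/(a_m+a_p)` directly; an Xist-like
transcript expressed *from the inactive X* uses `m = a_m(1−f) /
(a_m(1−f) + a_p f)`, which anti-correlates with the inactivated genes.

**Measurement.** Observations are `clip(m + ε, 0, 1)` with
`ε ~ N(0, σ_meas)` — pyrosequencing reports a continuous ratio, and the
assay's replicate agreement quantifies a single additive SD. A Beta noise
option with matched mean/SD is exposed for users who want bounded
multiplicative error, but is not the default. Whether real assay error is
additive or proportional is unknown; additive is assumed. Males carry a
single (maternal) X, so their X-linked maternal fraction is exactly 1 plus
measurement noise; they serve as assay controls only and are excluded from
every analysis stage.

### Default parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `N` (`n_cells`) | 70 | cells | centre of the plausible 30–150 progenitor range for mouse brain |
| `p_pat` | 0.53 | probability | the observed ~6% excess maternal expression equals `2(p_pat − 0.5)` |
| `σ_meas` | 0.0168 | fraction | duplicate runs agree to a mean absolute difference of 1.90 points; for Gaussian error `E|X₁−X₂| = 2σ/√π` |
| replicates | 2 | — | duplicate assay runs per (gene, individual) |
| females per cross | 18 (PWD-AKR), 11 (B6-CAST) | — | the two reciprocal-cross study designs |
| `λ` (partial escaper) | 0.3 | rate | ~30% residual transcription from the inactive X (Jarid1c-like) |
| `ρ` roster | evenly spaced 0.35–0.65 | — | a realistic spread of cis effects across the inactivated roster; Xist-like gene `ρ = 0.10` (PWD-AKR) / `0.80` (B6-CAST) |

The packaged PWD-AKR roster has 41 genes: 29 inactivated, 2 escapers, 1
partial escaper, 1 Xist-like, 8 autosomal controls; B6-CAST has 18 X-linked
plus 2 autosomal controls.

### What the simulation does not emulate

Litter effects (litters are labelled but carry no variance component),
developmental timing of inactivation, cell-type heterogeneity within brain,
Xce choice mechanics (treated purely as a cis bias), and gene-specific
measurement error. Tests passing on these simulations therefore demonstrate
correctness of the estimators under the stated model, not robustness to
those unmodelled features of real data.

## Nested ANOVA

The response `y_ijk` (reference-allele fraction of gene *i*, individual *k*
in cross *j*, technical replicates at the residual level) is decomposed as

    y_ijk = μ + α_i + β_j + γ_k(j) + ε,

with gene (`α`, fixed), mother/cross (`β`, fixed) and individual nested in
cross (`γ`, random). Only genes of class `inactivated` enter the default
response set — escapers, partial escapers, Xist-like and autosomal genes do
not share the sampling factor and would dilute every stratum.

Sums of squares come from least-squares projection on an effect-coded
design matrix; individuals are effect-coded *within* their cross, keeping
the mother contrast estimable and the fit exact on unbalanced data.
Sequential (Type I) and Type III decompositions are available and coincide
on balanced designs. Degrees of freedom are counted from the coding
(`G−1`, `C−1`, `Σ_j (n_j − 1)`), which handles the nesting confound that
trips naive `C(individual)` formulations in general-purpose OLS ANOVA.

F tests use the mixed-model strata: mother against individual-within-mother,
gene and individual against the residual. This wiring is hard-coded,
exposed via `f_tests_from_mean_squares`, and asserted in tests.

**LS means.** The LS mean of a cross averages gene×cross cell means with
equal gene weights (individuals equally weighted within cells). Standard
errors use the individual stratum — the correct yardstick for between-cross
comparisons: `SE_j = sqrt(MS_ind / (n_j c_j))`. The residual stratum would
understate between-cross uncertainty and is not offered.

**Variance components.** Two labelled methods are always reported rather
than guessing one: `ems` solves the expected-mean-square equations
(`σ²_ind = (MS_ind − MS_res)/c`; fixed factors get the analogous average
squared effect size, e.g. `(MS_gene − MS_res)/n_g`), clamping negative
solutions to zero with a warning; `ss` is the naive share of the total sum
of squares. On strata shaped like the published reciprocal-cross analysis
the `ems` proportions reproduce the reported ~48/31/14/7 split
(cis / sampling / parent-of-origin / residual), so `ems` is the method of
record. A fit with no variation at all is flagged degenerate (proportions
NaN) rather than divided through by float noise.

**Rank transform.** The nonparametric variant replaces the response by
global midranks and refits unchanged; it is idempotent on rank-valued data
and invariant to monotone response transforms.

**Pooled fit.** Multiple strain pairs are combined with `strain_pair` as an
additional fixed factor and mother recoded as the cross *orientation*
(reference strain maternal vs paternal), a single 1-df contrast shared
across pairs; individuals nest in (pair × orientation) cells. Type III SS
is the default because the pooled design (18+18 vs 11+11) is unbalanced.
Because the orientation contrast is shared, exactly duplicating a dataset
doubles its mean square (and F) while leaving the individual stratum
unchanged — replication genuinely sharpens this test. Gene rosters are
intersected across pairs, with a warning when genes are dropped.

Interactions are omitted (the residual absorbs them), litters are not
modelled, and no multiple-testing correction is applied — there is a single
parent-of-origin test per fit.

## Escaper classification

Per-individual means (duplicates averaged, both crosses pooled, females
only) give a gene-by-individual matrix; its Pearson correlation matrix is
the profile. The cross-mean shift is deliberately not removed: the
parent-of-origin effect shifts all inactivated genes coherently and only
strengthens the shared covariation being measured.

Clustering is agglomerative with average linkage on the absolute-Pearson
distance `d = 1 − |r|`. The absolute value matters: an Xist-like gene is
perfectly *anti*-correlated with the inactivated set and must cluster with
it. Genes are sorted lexicographically before clustering so ties resolve
deterministically; zero-variance genes are excluded with a warning.

Cluster membership is made into an explicit rule: each gene's consensus
score is its median `|r|` against the known-inactivated seed set (self
excluded). Autosomal controls calibrate the null — the escaper ceiling is
their maximum score plus a margin (default 0.05). Scores at or below the
ceiling are `escaper`; at or above the floor (default 0.5), `inactivated`;
between, `partial`. Without at least two autosomal controls a fixed
fallback ceiling (0.25) applies, with a warning. Note that at the default
measurement SD a `λ = 0.3` partial escaper still correlates ≈0.92 with the
inactivated set: its score falls reliably *between* the class medians (the
property tests assert this) but above the 0.5 floor, so detecting partial
escape in practice means inspecting scores, not just the categorical call.

The direction statistic is an exact two-sided binomial sign test on
per-gene reciprocal differences oriented so positive means maternal-biased
(`p = 2 P(X ≥ max(k, n−k))` under `Bin(n, ½)`, capped at 1; zero
differences dropped). Chromosome-level shifts of the per-gene differences
are compared by pairwise two-sample Kolmogorov–Smirnov tests, with an
option to pool all autosomes into one group when per-chromosome counts are
small.

## Progenitor-count estimation

The observed among-individual variance of `f` comes from the ANOVA strata:
`σ̂²_ind = (MS_ind − MS_res)/c` — measurement noise is subtracted via the
EMS identity before matching, so the matched quantity is the variance of
`f` itself. A Monte-Carlo curve simulates, for each `N` on a grid (default
30–150, 1000 replicates), the mean of within-cross sample variances of
`M = 18` binomial fractions per cross over two crosses — the same estimand
as the ANOVA stratum. The point estimate inverts the mean curve at the
observed variance, interpolating linearly in `1/N` where the binomial law
is exact (minor Monte-Carlo non-monotonicity is ironed out isotonic-ly);
values outside the grid use the exact `c/N` scaling and are flagged
extrapolated. The 95% CI inverts the 2.5th/97.5th percentile curves of the
per-replicate variances: the interval of `N` whose replicate-variance
distribution is compatible with the observed value. Its replicate unit
matches the 34-df observed quantity closely enough that empirical coverage
of the true `N` exceeds 90% in end-to-end simulations (tests assert this).

Two knowingly accepted approximations, matching the estimator this package
formalises: genes with `ρ ≠ 0.5` attenuate the variance of `f` on the
observed scale (slope `4ρ(1−ρ)` at `f ≈ ½`), biasing `N̂` upward by a few
percent at the default `ρ` spread; and inverting a noisy variance is
convex, adding a comparable Jensen inflation. Both are visible in the
simulation studies and covered by the CI.

## Numerical and interface choices

* Fractions are stored in [0, 1]; percent exists only at I/O behind an
  explicit flag, never auto-detected.
* Written CSVs carry 17 significant digits, so write→read round-trips are
  bit-exact (the reader parses through numpy's correctly-rounded strtod).
* The pipeline splits one global seed into fixed per-stage substreams, so
  toggling a stage never changes another stage's draws; two runs with the
  same seed produce byte-identical outputs.
* Validation is pure and severity-split: duplicate measurement keys,
  unannotated genes and class/chromosome mismatches are errors (the
  pipeline refuses to analyse); single-cross tables and male-control
  deviations beyond a 0.05 tolerance are warnings naming gene and
  individual. Missing measurements are tolerated everywhere; every stage is
  unbalanced-safe.

## Problem sizes used by the test suite

The simulation studies run at the design scale they model: 41 genes and
18+18 females per dataset; 1000 replicate datasets for Type-I calibration
(reduced 10-gene, 8+8 design), 500 for parent-of-origin recovery, 200 for
escaper accuracy, and 200 end-to-end progenitor estimations against a
200-replicate curve. The acceptance script averages its stochastic
quantities over 30 replicate simulated studies and uses the full
1000-replicate curve.

## Known limitations

* The classifier's categorical boundary between `partial` and
  `inactivated` is threshold-based and, at default noise, conservative for
  weak escape (see above).
* `N̂` inherits the small upward bias described under progenitor-count
  estimation; the linearisation-free default matches the classical
  estimator deliberately.
* The KS shift tests treat genes as independent observations; since all
  inactivated genes share each individual's `f`, their differences are
  positively correlated and the X-vs-autosome p-values are optimistic.
  They are reported as descriptive statistics, mirroring their original
  use.
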