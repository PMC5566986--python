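# Methods

## Model and procedure

`dyadscan` treats a bulk expression study as a gene × sample matrix of
non-negative FPKM values plus a sample design (tumor cohorts vs normal
tissues, with brain and vital-organ annotations) and a gene × source table
of boolean plasma-membrane evidence. All statistics are computed on
log2(FPKM + c) with pseudocount c = 1 by default; c = 1 bounds the
transformed values below by 0, is the standard choice for FPKM-scale data,
and is configurable. The two FPKM-scale quantities — the screen's tumor
median gate and the vital-organ ceiling — are deliberately left on the raw
scale, because both are interpretability thresholds on expression
abundance, not model statistics.

### Surfaceome consensus

Each evidence source contributes one positive/negative vote per gene;
missing cells are negative votes (absence of annotation is absence of
evidence). A gene is surface-resident when votes ≥ `consensus_votes_min`
(default 7 of 9). Consensus voting is monotone in both evidence and
threshold: adding a positive call never removes a gene, and the surfaceome
at a stricter vote is a subset of the looser one. Genes present in the
expression matrix but absent from the evidence table are dropped with a
warning rather than an error, since evidence snapshots routinely lag
expression annotations.

### Single-gene screen

One tumor cohort is compared against the full normal panel per gene.
The log fold-change is the difference of group means on the log2 scale
(not the log of the ratio of means), matching log-scale linear modelling.
Two test modes:

* **welch** (default): unequal-variance t with Satterthwaite df.
* **moderated**: pooled variance shrunk toward an empirical-Bayes prior,
  posterior s̃² = (d₀s₀² + d·s²)/(d₀ + d) on d₀ + d df, with (d₀, s₀²)
  estimated by moment matching on the log sample variances across all
  genes (digamma/trigamma inversion). The posterior variance is a convex
  combination of prior and sample variance; d₀ → 0 recovers the pooled t,
  d₀ → ∞ a common-variance test.

Degenerate genes (zero variance in both groups) get p = 1 when the means
agree and the smallest positive double with a logged warning when they do
not; a p-value of exactly 0 is never emitted.

A gene passes the screen when logFC ≥ 2, tumor median FPKM > 2 and
p ≤ 10⁻³. The screen is monotone in each gate. The gates are the operative
selection device; the test mode only changes the p-value's df, and both
modes are recorded in output metadata.

### Pair statistics

For each unordered pair of screened surface genes (stored canonically,
lexicographic), the two-sample Hotelling T² compares tumor vs normal on
the bivariate log2 values:

    T² = (n₁n₂/(n₁+n₂)) d′S⁻¹d,  S = ((n₁−1)S₁ + (n₂−1)S₂)/(n₁+n₂−2),
    F = T²(n₁+n₂−p−1)/(p(n₁+n₂−2)),  df = (p, n₁+n₂−p−1),  p = 2.

The Hotelling–Lawley trace T²/(n₁+n₂−2) is carried in the result and
yields the identical F — the implementation asserts this algebraic route
in its tests. T² is invariant under any nonsingular linear transform
applied identically to both groups. A pooled covariance with condition
number above 10¹² (constant gene, collinear pair) marks the pair
not-evaluable; such pairs are skipped with a logged reason, never
assigned p = 0.

Tumor-only co-expression uses the Pearson r with two-sided p from
t = r√((n−2)/(1−r²)), df = n − 2.

### Filters and ranking

Filters (a)–(f) (defaults): (a) Hotelling p ≤ 0.01; (b) Pearson p ≤ 0.05;
(c) tumor median log2(FPKM) ≥ 2 for both genes; (d) logFC vs all normals
≥ 2 for both; (e) logFC vs brain alone ≥ 2 for both; (f) per-organ median
FPKM in heart, liver, lung and kidney ≤ 1.0 ("any vital organ" = max over
the four per-organ medians) for both. Every violated label is recorded, so
loosening a single threshold is auditable. Survivors are ranked by F
descending, ties broken by p ascending then pair name. A
Benjamini–Hochberg column over the Hotelling p-values is appended for
information only; raw p-values drive filtering, matching the convention of
reporting raw pair statistics in ranked candidate tables.

Design choices where the design was genuinely open:

* **Normal panel for the Hotelling test**: all normals by default
  (brain included), since brain is separately guarded by filter (e);
  `normals="nonbrain"` is available.
* **Correlation sign**: filter (b) is two-sided by default; co-targeting
  arguably presumes positive co-expression, so `--require-positive-r` is
  provided but off by default.
* **Vital ceiling scale**: the ceiling applies to the FPKM-scale per-organ
  median (1.0, 1.5 or 2.0 are the intended settings); the scale is recorded
  in the run summary.
* **Not-evaluable gene statistics** (no brain or no vital-organ samples in
  the design) are NaN and fail their filter: a candidate is never passed on
  an unverifiable safety criterion.

## Synthetic data

The generator emulates the target study shape: cohorts of 32 and 70 tumor
samples, 17 brain plus 46 other normals, the latter containing one sample
group per vital organ (⌊46/10⌋ = 4 samples each) and the remainder in
groups of 5 "other" tissues. Log2-scale values are
baseline + tissue offset + tumor shift + noise, back-transformed as
FPKM = 2^v − 1 floored at 0. Components:

* background gene baselines ~ N(3.0, 1.5²) log2 units (ordinary expressed
  genes); per-gene noise variance from a scaled inverse-chi-square prior
  σ² = d₀s₀²/χ²_{d₀} with d₀ = 4, s₀² = 0.25, which makes the moderated
  mode's moment-matching estimable from the data;
* per-(gene, tissue) normal offsets ~ N(0, 0.3²), giving the normal panel
  realistic tissue heterogeneity;
* planted dyads: pairs of consensus-surface genes shifted by δ = 3 log2
  units in both tumor cohorts with bivariate tumor noise correlated at
  ρ = 0.7 inside each cohort; their normal-tissue baseline is low
  (N(0.25, 0.15²), noise sd 0.2, damped offsets) because a bona fide
  surface target is near-silent across the normal panel — a shared
  baseline distribution would make the vital-organ ceiling reject planted
  genes at random, which is not the structure real candidates have;
* optional vital "leak": the first `n_vital_leak` planted genes are set to
  a controlled median FPKM (1.5 by default) in one vital organ, so the
  stringency cascade is exercised non-trivially; the default is 0 leaks.

Evidence votes are Bernoulli per source (0.95 for the ~30% of genes
designated surface, 0.05 otherwise); the ground truth's surface set is the
consensus outcome itself, so truth and analysis agree by construction and
recovery scoring isolates the expression stages. Every random draw comes
from a stream keyed on (seed, block, index): outputs are byte-identical
for identical parameters, and adding genes does not perturb earlier genes.

What the generator does **not** emulate: count-level sampling noise and
the mean–variance relation of real RNA-seq, library-size effects,
co-expression structure beyond the planted pairs, and transcript-level
ambiguity. Passing recovery tests therefore demonstrates that the pipeline
finds the signal it defines, under Gaussian log-scale noise at the study's
sample sizes — not that real tumor data would yield the same candidate
counts.

## Numerical choices

* p-values are floored at the smallest positive double; p ∈ (0, 1] always.
* Welch and moderated tests share one vectorised gene-wise path; the
  scalar API is the reference implementation for both.
* Trigamma inversion for the variance prior uses Newton iteration from a
  1/√y start (50-iteration cap, 1e-10 relative tolerance); an observed
  log-variance spread at or below pure sampling noise yields an infinite
  prior df (common-variance limit).
* T² is clipped at 0 to absorb roundoff on near-zero shifts; singularity
  is detected by condition number (10¹²) rather than exact determinant.
* TSV writers print floats with `%.17g` and the readers parse with
  round-trip precision, so write∘read∘write is byte-stable.

## Problem sizes in the tests

The suite validates calibration with 10,000 disjoint null pairs at the
study's 70-vs-63 sample shape, recovery on the default 2,000-gene /
20-dyad simulation, and the statistical core against brute-force and
100,000-replicate Monte-Carlo oracles on 50 random instances; these sizes
give binomial/Monte-Carlo error small enough for the stated bounds while
keeping the whole suite in the tens of seconds.

## Known limitations

* FPKM flooring at zero mildly truncates the log-scale noise of
  near-silent genes; fully silenced genes become constant vectors and
  their pairs are skipped as not-evaluable (≈0.4% of pairs in the null
  calibration).
* The moderated mode moderates variances only; it does not reweight
  observations by predicted count precision, so it is not a drop-in for
  count-model pipelines.
* Pairs are tested marginally; the C(G, 2) scan reports raw p-values by
  design, and the BH column is informational.
* Only pairs are considered — no triads or higher-order combinations.
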