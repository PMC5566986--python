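# dyadscan

Discovery of **paired** tumor cell-surface antigens ("dyads") from bulk
expression data.

Single surface markers that distinguish a solid tumor from every normal
tissue are rare: the best individually overexpressed transcripts are often
also expressed somewhere vital. Dual-antigen ("AND-gate") immunotherapies —
CAR-T cells or antibody combinations that require engagement of *two*
antigens for full activation — relax this constraint: each member of a pair
only needs to be jointly tumor-restricted. `dyadscan` finds such pairs from
a gene × sample FPKM matrix by testing every pair of screened surface genes
for joint tumor-vs-normal separation and for co-expression inside the tumor.

## Method

The pipeline runs in five stages for one tumor cohort against a
normal-tissue panel:

1. **Surfaceome consensus.** Each gene carries boolean plasma-membrane calls
   from several independent annotation sources (nine by default). A gene
   enters the analysis only if at least `consensus_votes_min` (default 7)
   sources call it surface-resident.
2. **Single-gene overexpression screen.** On the log2(FPKM + 1) scale, a
   gene passes when its log fold-change (difference of group means) vs all
   normals is ≥ 2, its tumor median FPKM is > 2, and its two-sample p-value
   is ≤ 10⁻³ (Welch t by default, or an empirical-Bayes variance-moderated
   t).
3. **Pairwise Hotelling T².** Every unordered pair (x₁, x₂) of screened
   surface genes is tested for a joint tumor-vs-normal mean shift:

       T² = (n₁n₂/(n₁+n₂)) · d′ S⁻¹ d,
       F  = T² (n₁+n₂−p−1) / (p (n₁+n₂−2)) ~ F(p, n₁+n₂−p−1),  p = 2,

   with d the difference of group mean vectors and S the pooled covariance.
   For two groups this is equivalent to the Hotelling–Lawley MANOVA trace
   T²/(n₁+n₂−2).
4. **Tumor-only Pearson coupling.** The pair's correlation r is computed
   across tumor samples only, with the two-sided p from
   t = r√((n−2)/(1−r²)).
5. **Filter cascade and ranking.** A pair survives iff (a) Hotelling
   p ≤ 0.01, (b) Pearson p ≤ 0.05, (c) both tumor medians ≥ 2 on the log2
   scale, (d) both logFC vs normals ≥ 2, (e) both logFC vs brain alone ≥ 2,
   and (f) both genes' median FPKM in every vital organ (heart, liver,
   lung, kidney) stays below a ceiling (1.0 by default, loosenable to 1.5
   or 2.0). Survivors are ranked by F descending.

A synthetic-data generator (`dyadscan.simulate`) reproduces the assumed
study shape — two tumor cohorts (32 + 70 samples) vs 63 normals (17 brain,
46 other including the four vital organs) — with planted correlated
overexpressed dyads, so every stage is testable end to end without any
external download.

## Worked example

Simulate a dataset and run the full pipeline, requiring positively
correlated pairs:

```sh
dyadscan simulate --seed 17 --out demo/data
dyadscan run \
    --expression demo/data/expression.tsv \
    --samples demo/data/samples.tsv \
    --evidence demo/data/evidence.tsv \
    --cohort MYCN_NA --require-positive-r --out demo/run
```

which prints

```
surface=621 screened=40 passing_dyads=37 unique_genes=40
```

meaning: 621 of 2,000 genes met the 7-of-9 surfaceome consensus, 40 of
them passed the single-gene overexpression screen, and 37 of the 780
candidate pairs survived all six filters. The top of `demo/run/dyads.tsv`:

```
pair           f_value      p_value        r         r_p_value  rank
G01374_G01977  3597.951216  1.550045e-114  0.237709  4.753481e-02  1
G01036_G01374  3540.175987  4.356600e-114  0.732659  5.629240e-13  2
G00420_G01036  3236.785866  1.320351e-111  0.240299  4.509653e-02  3
```

`f_value`/`p_value` are the Hotelling T²-derived F statistic and its
upper-tail probability (joint tumor-vs-normal separation of the pair);
`r`/`r_p_value` measure co-expression within the tumor cohort only. All 40
genes appearing in ranked pairs are members of the 20 dyads the simulation
planted. Per-stage outputs (`surfaceome.tsv`, `screen.tsv`, `summary.txt`)
land in the same directory; `dyadscan annotate` joins an optional per-gene
risk-category table onto the ranked pairs.

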