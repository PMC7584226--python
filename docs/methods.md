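# Methods

`rieqtl` implements the statistical core of a "genetical genomics" study
design: a panel of recombinant-inbred (RI) mouse strains, derived from
two inbred progenitors, is profiled by bulk RNA-seq under two
pretreatments (saline vs ethanol), and gene expression is analyzed as a
heritable quantitative trait — filtered, variance-stabilized, tested for
strain-specific treatment response, mapped to expression QTLs by
Haley-Knott regression with permutation thresholds, and genetically
correlated with behavioral phenotypes.  This note records the models,
the defaults, and the design choices that were genuinely open.

## Synthetic RI panel

The generator is first-class, tested code; all recovery and calibration
claims in the test suite are statements about this generative model.

**Genotypes.**  Each strain is an independent two-state Markov chain
along each autosome.  The first marker allele is Bernoulli(1/2); the
probability that adjacent markers carry different progenitor alleles is
the sib-mating RI map-expansion value

    R = 4r / (1 + 6r),    r = (1 − e^(−2d)) / 2   (Haldane, d in Morgans),

so tightly linked loci recombine ~4× more often than in a single
meiosis, and R → 1/2 at large distance.  Haldane's map function (no
interference) is used throughout because it is closed-form and matches
the regression approximation used for mapping.  Only the 19 autosomes
are modeled (the design it emulates used males only and the published
analysis does not specify X handling); strains are fully inbred with no
residual heterozygosity.  When a physical map lacks genetic positions,
they are derived at the mouse genome-average rate of 0.5 cM/Mb.

Default panel dimensions mirror the study design: 40 strains, 2,661
markers, 2–3 libraries per strain × pretreatment, each library a pool of
3 mice.

**Expression.**  For gene *g*, strain *s*, group *t* the strain genetic
value is

    G_gst = Σ_k β_k · x_sk + sqrt(max(V_B_target − Var_s(Σβx), 0)) · u_s

where x_sk ∈ {0,1} are marker alleles, β_k the planted cis/trans effects
(log2 units), and u_s a standardized polygenic deviate drawn **once per
gene** and shared between groups — the genetic architecture is common to
both pretreatments unless an explicit GxE shift is planted.  Each mouse
adds N(0, σ_w²) noise (σ_w = 0.5 by default); a library's latent
abundance is the mean of its `pool_size` mouse values, so pooling
divides within-strain latent variance by the pool size.  Ethanol
libraries add the planted gene×strain GxE log2 shift.  Counts are drawn
negative-binomial (gamma–Poisson) with mean `libsize_factor ·
2^(baseline + latent)`; library size factors are lognormal with CV 0.15
and dispersion defaults to 0.02.

**Heritability targets.**  `h2_target` is defined at the *library*
level, the unit the downstream estimator actually sees:
V_B_target = h²/(1−h²) · V_W_lib with V_W_lib = σ_w²/pool_size plus the
delta-method counting-noise variance of log2(X+1) at the gene's baseline
mean.  Genes/groups without a target receive no polygenic top-up (their
between-strain variance is purely QTL-driven), which is how cis-only
recovery scenarios are constructed.  The mouse-level heritability
implied by the same parameters is lower — the generator thereby exposes
the inflation that RNA pooling induces in the estimator, which the
analysis deliberately does **not** correct (it reports what the data
deliver, as the estimator would on real pooled libraries).

**Behaviors.**  Four strain-level behaviors (sleep time and acute
functional tolerance, each under saline or ethanol) are linear in a
planted marker locus and in the realized genetic values of weighted
genes of the matching group, plus N(0, noise²) with noise 0.5 by
default.  Weighted genes therefore have a nonzero expected genetic
correlation with the behavior by construction; weights default to 1.5 on
strong planted cis genes so the candidate-gene intersection has true
positives.

**What the generator does not emulate:** batch structure, GC/length
biases, isoform-level variation, linkage disequilibrium with untyped
causal variants, selection or segregation distortion during inbreeding,
and sex effects.  Passing recovery tests therefore demonstrates
correctness of the estimators under the stated model, not robustness to
those real-data artifacts.

## Quantification

RPLG (reads per length of gene) = reads × read_length / gene_length,
with read_length 100 bp, so RPLG = 1 is ~1× coverage.  A gene is
expressed when its median RPLG across libraries is **strictly** greater
than 1 in the saline group or the ethanol group (the rule's wording is
"greater than"; a median of exactly 1 drops the gene).  Medians over an
even number of libraries average the two central order statistics.

Size factors use the median-of-ratios estimator over reference genes
with no zero count in any library, falling back to total-count ratios
with a warning when no reference gene exists.  The variance-stabilizing
transform is the shifted log of normalized counts, log2(count/factor+1)
— not the parametric NB VST; it is closed-form, monotone, and preserves
the property the downstream linear models rely on (flattening of the
mean–variance trend), which the tests verify directly.  All genetics run
on per-strain arithmetic means of these values within each pretreatment.

## Heritability

One-way random-intercept model per gene and group, strains random:
V_B (between-strain) and V_W (within-strain) estimated by REML with
V_B ≥ 0, H² = V_B/(V_B+V_W).  The implementation profiles the REML
log-likelihood over the variance ratio λ = V_B/V_W (closed-form
V_W given λ), maximized by a log-spaced grid plus bounded refinement;
on balanced designs with interior optima this reproduces the ANOVA
method-of-moments components exactly, and it matches statsmodels
`MixedLM` on unbalanced data (both are test oracles).

Because the null H² = 0 lies on the parameter boundary, the LRT null is
the 50:50 mixture ½χ²₀ + ½χ²₁: p = ½·P(χ²₁ ≥ LRT), and p = 1 when the
statistic is 0.  BH FDR is applied across genes separately within each
pretreatment group (the design reports per-group significant counts).
Degenerate inputs: all values equal → H² = 0 with a flag; zero
within-strain spread with distinct strain means → H² = 1 with a flag.

## Differential expression

DE is called per strain: one-way pretreatment ANOVA on that strain's
2–3 vs 2–3 libraries (equivalent to the pooled-variance t², which the
tests assert), BH across genes **within the strain** at FDR < 0.05.
Strains with a single library in either cell are excluded.  Fold change
is the ratio of size-factor-normalized count means (ethanol/saline) with
an up/down direction flag.  The whole-panel strain×pretreatment two-way
ANOVA (sequential sums of squares via nested OLS projections shared
across genes; full-model MSE denominators) is implemented and reported
but not used for DE calls — the per-strain test is the deliberately
conservative definition.  Zero residual variance with unequal means is
flagged degenerate (p missing) rather than forced to p = 0.

## eQTL mapping

Haley-Knott regression of strain means on expected dosage.  At markers
the dosage is the observed allele; at pseudomarkers it is the
conditional expectation given the flanking genotypes under the RI
Markov chain, with per-flank transition probabilities R = 4r/(1+6r)
(normalized over the two allele states).  The default grid adds a
pseudomarker every 1 cM; scans also run marker-only, which is what the
large simulation suites use for speed.

Association is LRS = n·ln(RSS₀/RSS₁) = −n·ln(1−r²); LOD = LRS/(2 ln 10).
Constant dosage columns or a constant trait score 0; fits with
1−r² < 1e−12 are capped at n·ln(1e12) and flagged.  Genome-wide
significance is per-trait: trait values are permuted across strains
(1,000 permutations by default; the scaled suites use 200), the maximum
LRS of each rescan is recorded, and thresholds are the empirical 0.90 /
0.95 / 0.999 quantiles (type-7 interpolation) for genome-wide p < 0.10 /
0.05 / 0.001; the peak's p-value is (1 + #{max ≥ peak})/(1 + N).
Permutation seeds derive deterministically from (global seed, gene,
group) via CRC32 so per-gene thresholds are reproducible under any
execution order.

A significant peak is **cis** when it lies on the gene's chromosome
within 5 Mb of the gene start (inclusive — "within" is read as ≤; the
boundary is covered by tests), else **trans**.  Distances are measured
from the annotated gene start in Mb.

**Golden (pretreatment-unique) eQTLs.**  Defined only for calls
significant in exactly one pretreatment.  cis: golden iff the other
condition's scan stays below its own suggestive (p < 0.10) threshold at
every position within 25 Mb of the gene on the gene's chromosome.
trans: the peak must be > 25 Mb from the gene or on another chromosome,
and the other condition's scan must stay below its suggestive threshold
within 25 Mb of the peak on the peak's chromosome.  "A peak (p < 0.10)
in the other condition" is operationalized as position-wise exceedance
of that trait's own permutation T_0.10 — no local-maximum detection —
which is the simplest faithful reading; the published rule's phrase
"regardless of whether it was on the same or different chromosome" is
resolved as the window on the peak's own chromosome (a 25 Mb window is
undefined across chromosomes).  Both 25 Mb comparisons are inclusive.

## Genetic correlation and candidates

Pearson correlations on strain means (strains are replicable genetic
units, so the correlation estimates shared genetic variance), two-sided
p from t = r√((n−2)/(1−r²)), strains missing a value pairwise-dropped,
constant vectors flagged undefined.  Expression↔behavior correlations
are BH-corrected across genes within one behavior×group family at
FDR < 0.10.  The hub-gene analysis uses nominal p < 0.01 (no FDR, as in
the published procedure) and annotates each correlate as distal when it
is on another chromosome or more than 20 Mb from the hub — far enough
that linkage disequilibrium is an unlikely explanation.  The
behavior-vs-DE-count analysis correlates each behavior with the number
of significant DE genes per strain.  Candidate genes are the
intersection: significant cis-eQTL (genome-wide p < 0.05) AND behavior
correlation q < 0.10, with the golden flag carried through and an
optional membership flag for supplied behavioral-QTL intervals.

## Numerical and design choices

- All cutoffs live in `PipelineConfig`: RPLG cutoff 1, DE and H² FDR
  0.05, correlation FDR 0.10, hub nominal p 0.01, cis 5 Mb, golden
  window 25 Mb, LD distance 20 Mb, eQTL α 0.05 / suggestive 0.10,
  1,000 permutations, 1 cM pseudomarker step.
- Every stochastic operation takes an explicit integer seed; the
  pipeline's manifest plus a seed reproduce all outputs byte-for-byte.
- Reported percentages round half-up to integers, matching how such
  counts are conventionally printed.
- BH q-values come from the standard step-up procedure (statsmodels);
  rejection is q < α; missing p-values propagate and are never rejected.
- The simulation suites scale the study design down (60–800 markers,
  150–200 permutations, 200–600 genes per scenario) while keeping 40
  strains and n = 3 libraries; the generator's own defaults keep the
  full design (2,661 markers, 1,000 permutations).

## Known limitations

- The shifted-log VST under-stabilizes very low counts; the RPLG filter
  removes most such genes before any model is fit.
- The two-way ANOVA uses sequential sums of squares, exact under the
  (near-)balanced designs generated here but order-dependent under
  severe unbalance.
- H² from pooled libraries over-estimates mouse-level heritability by
  construction; no correction is attempted.
- The golden rule inherits the arbitrariness of its distance windows;
  boundary behavior is pinned by tests rather than by any claim of
  biological meaning.
- Trait permutation assumes exchangeable strains (no kinship structure
  beyond strain identity), which is exact for the simulated panel.
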