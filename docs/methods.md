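# Methods

This note documents the statistical models implemented in `crisprqtl`, the
defaults and why they were chosen, what the synthetic-data generators do and
do not emulate, and the numerical choices that affect results.

## Screen ranking (`screen_rank`)

Guide read counts from a pooled survival screen are normalized to
counts-per-million per sample (the minimal between-sample normalization;
configurable in principle, CPM is the only method shipped). Replicates are
averaged on the normalized scale, and the per-guide fold-change is
log2((infected + 1) / (control + 1)); the pseudocount of 1 CPM keeps
zero-count guides finite. Enrichment is *high* fold-change: loss-of-function
of a gene required for infection lets the cell survive, so its guides
accumulate in the infected pool.

Three aggregation methods score a gene from its guides:

- **sbScore**: the second-highest guide fold-change. Using the 2nd order
  statistic instead of the maximum discounts single-guide artifacts
  (off-target or outlier guides). Genes with fewer than two guides have no
  second-best value and are excluded, with their ids reported.
- **RRA**: guide ranks within the full guide list are normalized to (0, 1];
  with the gene's k sorted normalized ranks r₍₁₎ ≤ … ≤ r₍ₖ₎, the statistic
  is ρ = minⱼ F_Beta(r₍ⱼ₎; j, k−j+1) — the probability that the j-th order
  statistic of k uniforms falls this low, minimized over j. No p-value or
  FDR is attached to ρ; only the induced ranking is used.
- **RIGER weighted-sum**: w·r₍₁₎ + (1−w)·r₍₂₎ with w = 0.25 by default. The
  original software's weights are not documented in an accessible form, so
  w is an explicit, configurable parameter; at w = 0 it degrades to the
  rank-space analogue of sbScore.

Guide ranks must form a strict permutation for the order-statistic
arguments to be valid, so fold-change ties are broken lexically by guide
id; gene-score ties are likewise broken by gene id, making all rank columns
exact permutations of 1..G and every run deterministic.

The top-gene set is the union of each method's top-N genes (N = 500 at
study scale), optionally intersected with a caller-supplied gene universe
(e.g. protein-coding ids).

## Inflation of GWAS signal at lead cis-eQTLs (`inflation`)

The statistic λ_q = Q_χ²₁(1 − quantile_q(p)) / Q_χ²₁(1 − q) with q = 0.1
measures association-signal excess among the 10% most significant GWAS
p-values of a variant set. The empirical quantile uses linear interpolation
(numpy's default); the convention is recorded in every result because other
interpolation rules shift λ by O(1/n).

The permutation null draws |target| lead eQTLs uniformly *without
replacement* from the background set per draw — the target is a set of
distinct genes, so a draw is too. Genes sharing a lead variant each
contribute their own entry (gene-level resampling). log λ is used for the
extremity comparison because the null distribution of λ is right-skewed and
the log transform symmetrizes it; "as extreme or more extreme" is
operationalized as distance from a center c, by default the permutation
mean of log λ (c = 0 is available via `center="zero"`). The reported
p-value is (1 + #extreme) / (k + 1), so it is never zero and the test is
valid at finite k. Type-I error at α = 0.05 measured over 500 null
replicates (k = 500, 100 target / 1,000 background genes) falls within
0.05 ± 0.02 (see `scripts/acceptance.py`).

Draw index matrices are generated in chunks capped at 10⁷ random keys so a
study-scale run (k = 10,000 draws from ~10⁴ background genes) stays within
ordinary memory.

## Colocalization (`coloc`)

Per-variant evidence is Wakefield's approximate Bayes factor in log form:
with z = β/SE, V = SE², W the prior effect variance and r = W/(V+W),
log ABF = ½ log(1−r) + ½ r z². The prior effect SD defaults to 0.15 on the
log-odds scale for case-control traits and 0.2·sd(Y) for quantitative
traits; expression traits are assumed rank-normalized (sd(Y) = 1), with
`estimate_sdY` available as an opt-in summary-statistic estimator
(through-origin regression of 2·n·f(1−f) on 1/var(β̂)).

The five hypothesis weights over the shared variant panel are

    S0 = 1                S1 = p1 Σ BF1ᵢ          S2 = p2 Σ BF2ᵢ
    S4 = p12 Σ BF1ᵢBF2ᵢ   S3 = p1 p2 (Σ BF1ᵢ Σ BF2ⱼ − Σ BF1ᵢBF2ᵢ)

with priors p1 = p2 = 10⁻⁴ and p12 = 5×10⁻⁶. All sums run in log space
(log-sum-exp); S3's difference uses a stable log-diff whose argument is
clamped to zero mass when the two log-sums agree within 10⁻¹², which is the
exact single-variant limit rather than a numerical error. Posteriors are
renormalized after exponentiation so ΣPP = 1 to machine precision; the
log-space path agrees with naive long-double direct summation to < 10⁻¹⁰
on ≤ 50-variant panels.

Gene eligibility (an eQTL p < 10⁻⁴ within 100 kb of the lead GWAS variant)
and the analysis region (± 500 kb; ± 1 Mb in masking mode) use closed
1-based intervals: a variant exactly at the window edge counts. The panel
is the intersection of the two datasets' harmonized variants; records with
missing effects are dropped with counts logged.

**Masking.** Cis allelic heterogeneity breaks the one-causal-variant
assumption. Independent trait-1 (eQTL) signals are found greedily: take the
smallest-p unmasked variant while p < 10⁻⁴ and fewer than 3 leads are
taken, masking everything with r² > 0.01 to any selected lead. Each signal
is then re-tested by single-mode colocalization on a panel with variants in
LD with the *other* leads removed; the per-signal results and max PP4 are
reported. The GWAS side is always treated as single-signal. Conditioning
(regression-based adjustment rather than variant removal) is not
implemented: masking covers the secondary-signal question this package
asks, and in practice max PP4 under masking closely tracks the standard
single run when no secondary signal exists (the mode reduces exactly to
single-mode with ≤ 1 detected signal).

PP4 > 0.5 is exposed as a labeled *suggestive colocalization* flag; it is a
screening threshold, not a posterior-odds decision rule.

## LD and prioritization (`prioritize`)

r² is the squared Pearson correlation of dosage vectors. Monomorphic
variants have undefined correlation; their rows/columns are NaN and their
ids flagged rather than raising, since reference panels routinely contain
them. Multi-population panels are combined as an elementwise weighted mean
(weights = population sample counts, renormalized pairwise over
non-missing entries). Population subsetting of the reference panel is the
caller's responsibility via the dosage input; no population list is
hard-coded.

The priority table joins, per (gene, dataset): the eQTL p-value of the lead
GWAS variant (the *lead variant's* p in that dataset, not the gene's own
best eQTL), the PP4 and its flag where colocalization was run, and the
gene's sbScore ranks in the low- and high-MOI screen arms. Row order is
deterministic — genes in caller-supplied (genomic) order, datasets lexical —
and missing values are written as "NA". Gene coordinates arrive as BED
(0-based half-open) and are converted to 1-based closed internally. Ties in
per-dataset p-value ranking break lexically by gene id.

## Summary-statistic I/O (`sumstats_io`)

Variant identity is the full `chrom:pos:ref:alt` string (1-based, GRCh38
convention, `chr` prefix stripped); rsIDs are annotation only, never join
keys, because rsID assignment is inconsistent across GWAS meta-analyses and
eQTL resources. When two datasets carry the same chrom:pos with swapped
ref/alt, the record is aligned by negating β and complementing the effect
allele frequency; swapped strand-ambiguous pairs (A/T, C/G) are
indistinguishable from strand flips and are dropped with a logged count, as
are records matching neither orientation. Rows violating value contracts
(SE ≤ 0, p ∉ (0,1], MAF ∉ (0,0.5], duplicate keys) fail loudly with 1-based
row numbers. No liftover, tabix access, or binary formats; VCF dosage
ingestion is optional via cyvcf2.

## Synthetic data (`simulate`)

- **Genotypes**: per haplotype, a latent AR(1) Gaussian vector
  (corr ρ^|i−j|, ρ = 0.95 default) thresholded at each variant's
  allele-frequency quantile (frequencies uniform on [0.05, 0.5]); dosage =
  sum of two independent haplotypes. This gives Hardy–Weinberg marginals
  and distance-decaying LD with one interpretable knob, at the cost of
  realism: no recombination hotspots, no allele-frequency spectrum, no
  population structure — which is why LD-sensitive conclusions from these
  tests (masking, scenario recovery) demonstrate engine correctness, not
  performance on real panels.
- **Marginal summary statistics**: per-variant simple linear regression
  (Wald t) for quantitative traits; per-variant logistic regression for
  case-control, fit by Newton/IRLS vectorized across variants with
  closed-form 2×2 information inverses (agreement with a general-purpose
  logistic fitter is asserted in the tests to 10⁻⁶). Monomorphic variants
  are emitted with missing effects and a flag. P-values are floored at
  10⁻³⁰⁰ to honour the p ∈ (0,1] contract.
- **Trait pairs**: the GWAS phenotype is a liability-threshold model
  (liability = β_gwas·dosage + N(0,1), default case fraction 0.5 — a
  balanced case-control design, not a population prevalence); expression is
  β_eqtl·dosage + noise, standardized to unit variance as rank-normalized
  expression would be. Default effects (β_gwas = 0.5 log-odds,
  β_eqtl = 0.8 sd) give z ≈ 8–25 at the causal variant for n = 2,000 —
  strong, clearly-powered signals appropriate for testing hypothesis
  *discrimination*.
- **Screen counts**: negative-binomial (NB2, dispersion α = 0.25) around
  depth/n_guides ≈ 400 reads per guide; infected samples multiply hit-gene
  guide means by 2^enrichment (default 2³). One control and two infected
  samples per arm by default, matching the small-replicate reality of
  survival screens.
- **Inflation background**: background GWAS p-values uniform; target
  genes' p = SF_χ²₁(m·X) with X ~ χ²₁, which makes the target's expected
  λ_q equal m exactly at every q — a construction, not a model of
  polygenic architecture.

Every generator is a pure function of its spec including the seed; bitwise
reproducibility of the full demo manifest is asserted in the tests.

## Problem sizes

Test and acceptance runs use: 200-variant / 2,000-individual LD blocks with
50 scenario replicates; 500 null replicates (k = 500, 100/1,000 genes) for
permutation-test calibration; 50 replicate 1,000-gene screens; and a demo
with a 9,557-gene background, 364 target leads and k = 10,000 permutations.
These sizes give stable medians and calibration estimates while keeping a
full run in the low minutes on one CPU.

## Known limitations

- Single-causal-variant engine: no SuSiE-style multi-signal
  colocalization; masking mitigates but does not model allelic
  heterogeneity.
- No conditioning mode (approximate conditional analysis) for either trait.
- Synthetic LD is AR(1); conclusions about masking behaviour under real,
  block-structured LD require a real reference panel.
- No genome-build liftover; all inputs must share coordinates.
- The inflation test treats lead eQTLs as exchangeable under permutation;
  LD between lead variants of nearby genes is not modeled (no LD-aware
  pruning).
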