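"""Named analysis defaults, shared by the library, CLI and demo pipeline.

These are the standard operating values of the integrative locus-triage
workflow; every one is overridable per call.
"""

#: quantile of the inflation statistic (lambda over the top 10% of tests)
LAMBDA_Q = 0.1
#: permutations for the inflation test's null distribution
N_PERMUTATIONS = 10_000

#: colocalization priors: per-variant causal for trait 1 / trait 2 / both
PRIOR_P1 = 1e-4
PRIOR_P2 = 1e-4
PRIOR_P12 = 5e-6

#: colocalization region half-width around the lead GWAS variant (1 Mb region)
REGION_HALFWIDTH = 500_000
#: masking mode uses a wider region (2 Mb)
MASKED_REGION_HALFWIDTH = 1_000_000

#: a gene enters colocalization testing iff it has an eQTL with p below this
#: within this window of the lead GWAS variant
ELIGIBILITY_WINDOW = 100_000
ELIGIBILITY_P = 1e-4

#: LD-masking: r² above this ties a variant to a signal; secondary signals
#: must reach this p; at most this many signals are masked
MASK_R2_THRESHOLD = 0.01
MASK_P_THRESHOLD = 1e-4
MASK_MAX_SIGNALS = 3

#: suggestive colocalization support flag
PP4_FLAG_THRESHOLD = 0.5

#: screen ranking: per-method top-N genes entering the union set
SCREEN_TOP_N = 500
#: guides per gene in the GeCKOv2 A+B library
GUIDES_PER_GENE = 6
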