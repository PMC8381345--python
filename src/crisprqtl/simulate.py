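"""Synthetic-data generators with the statistical structure the pipeline
assumes, so every stage runs end-to-end without external downloads.

Four generators emulate the four input classes:

* an LD block of genotype dosages (latent-Gaussian AR(1) copula haplotypes),
* marginal per-variant summary statistics for a quantitative trait (simple
  linear regression) or a case-control trait (liability threshold phenotype,
  per-variant logistic regression),
* shared / distinct / null causal-variant scenario pairs of GWAS + eQTL
  summary statistics over one LD block,
* negative-binomial guide counts for a pooled CRISPR screen with planted hit
  genes, and a lead-eQTL background set with a controlled GWAS-signal
  inflation for the target subset.

Every generator is a pure function of its spec (seed included): the same
spec reproduces its output bitwise.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats_io import VariantKey

__all__ = [
    "LdBlockSpec",
    "ScenarioSpec",
    "ScreenSpec",
    "GenotypeBlock",
    "simulate_genotypes",
    "marginal_sumstats",
    "simulate_trait_pair",
    "simulate_screen_counts",
    "simulate_inflation_background",
]

# non-strand-ambiguous allele pairs cycled along the block
_ALLELE_CYCLE = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]


@dataclasses.dataclass(frozen=True)
class LdBlockSpec:
    """A 1000 Genomes-like LD block.

    ``rho`` is the latent adjacent-variant correlation of the AR(1) Gaussian
    copula; realized dosage r² between neighbours increases with it.  Allele
    frequencies are drawn uniformly from ``maf_range``.
    """

    n_individuals: int = 2_000
    n_variants: int = 200
    maf_range: tuple[float, float] = (0.05, 0.5)
    rho: float = 0.95
    seed: int = 0
    chrom: str = "3"
    start_pos: int = 45_323_240
    pos_step: int = 5_000

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must lie in [0, 1)")


@dataclasses.dataclass(frozen=True)
class ScenarioSpec:
    """A GWAS/eQTL trait pair over one LD block.

    ``shared``: one variant is causal for both traits; ``distinct``: each
    trait has its own causal variant; ``null``: neither trait has a causal
    variant in the block.  GWAS effects are log-odds via a liability
    threshold; eQTL effects are in trait-SD units.
    """

    scenario: str = "shared"
    causal_index_1: int = 100
    causal_index_2: int = 100
    beta_gwas: float = 0.5
    beta_eqtl: float = 0.8
    case_fraction: float = 0.5
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in ("shared", "distinct", "null"):
            raise ValueError("scenario must be shared | distinct | null")
        if self.scenario == "shared" and self.causal_index_1 != self.causal_index_2:
            raise ValueError("shared scenario requires equal causal indices")
        if self.scenario == "distinct" and self.causal_index_1 == self.causal_index_2:
            raise ValueError("distinct scenario requires different causal indices")


@dataclasses.dataclass(frozen=True)
class ScreenSpec:
    """A pooled CRISPR survival screen.

    Guide representation in the uninfected control is negative-binomial
    around ``depth_per_sample / n_guides``; in infected samples, guides of
    hit genes have their mean multiplied by ``2**hit_log2_enrichment``
    (survivor enrichment).  ``dispersion`` is the NB2 alpha
    (var = mu + alpha mu²).
    """

    n_genes: int = 1_000
    guides_per_gene: int = 6
    hit_genes: tuple[str, ...] = ()
    hit_log2_enrichment: float = 3.0
    dispersion: float = 0.25
    depth_per_sample: float = 2_400_000.0
    n_control: int = 1
    n_infected: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.guides_per_gene < 2:
            raise ValueError("guides_per_gene must be >= 2")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")


@dataclasses.dataclass
class GenotypeBlock:
    variants: list[VariantKey]
    dosages: np.ndarray  # (n_variants, n_individuals)
    mafs: np.ndarray  # target allele frequencies used in the copula

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[1]


def _block_variants(spec: LdBlockSpec) -> list[VariantKey]:
    return [
        VariantKey(spec.chrom, spec.start_pos + i * spec.pos_step,
                   *_ALLELE_CYCLE[i % len(_ALLELE_CYCLE)])
        for i in range(spec.n_variants)
    ]


def simulate_genotypes(spec: LdBlockSpec) -> GenotypeBlock:
    """Dosages over an LD block via a latent-Gaussian AR(1) copula.

    Per haplotype, a latent AR(1) Gaussian vector x (corr(x_i, x_j) =
    rho^|i-j|) is thresholded at each variant's allele-frequency quantile:
    the haplotype carries the alternate allele where x < Phi^-1(f_i).
    Dosage = sum of two independent haplotypes, so dosages are in {0, 1, 2}
    with Hardy-Weinberg marginals and LD decaying with distance.
    """
    rng = np.random.default_rng(spec.seed)
    n_hap = 2 * spec.n_individuals
    m = spec.n_variants
    f = rng.uniform(spec.maf_range[0], spec.maf_range[1], size=m)
    z = rng.standard_normal((n_hap, m))
    x = np.empty_like(z)
    x[:, 0] = z[:, 0]
    c = np.sqrt(1.0 - spec.rho**2)
    for i in range(1, m):
        x[:, i] = spec.rho * x[:, i - 1] + c * z[:, i]
    alt = (x < stats.norm.ppf(f)).astype(np.int8)  # (n_hap, m)
    dosages = (alt[: spec.n_individuals] + alt[spec.n_individuals:]).T.astype(float)
    return GenotypeBlock(_block_variants(spec), dosages, f)


def _ols_sumstats(dosages: np.ndarray, y: np.ndarray):
    """Vectorized per-variant simple linear regression (intercept + dosage)."""
    n = y.size
    x = dosages - dosages.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sxx = (x**2).sum(axis=1)
    mono = sxx == 0
    sxx_safe = np.where(mono, 1.0, sxx)
    sxy = x @ yc
    beta = sxy / sxx_safe
    syy = float(yc @ yc)
    dof = n - 2
    sigma2 = np.maximum(syy - beta * sxy, 0.0) / dof
    se = np.sqrt(sigma2 / sxx_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / se
    pval = 2.0 * stats.t.sf(np.abs(tstat), dof)
    beta[mono] = np.nan
    se[mono] = np.nan
    pval[mono] = np.nan
    return beta, se, pval, mono


def _logistic_sumstats(dosages: np.ndarray, y: np.ndarray, max_iter: int = 50,
                       tol: float = 1e-10):
    """Vectorized per-variant logistic regression (intercept + dosage).

    Newton/IRLS run simultaneously across variants; each variant's 2×2
    information matrix is inverted in closed form.  Wald beta, se and
    normal-approximation p are returned.
    """
    n = y.size
    m = dosages.shape[0]
    x = dosages  # (m, n)
    ybar = y.mean()
    a = np.full(m, np.log(ybar / (1 - ybar)))  # intercepts
    b = np.zeros(m)
    active = np.ones(m, dtype=bool)
    for _ in range(max_iter):
        eta = a[:, None] + b[:, None] * x
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        # score
        resid = y[None, :] - mu
        g_a = resid.sum(axis=1)
        g_b = (resid * x).sum(axis=1)
        # information
        i_aa = w.sum(axis=1)
        i_ab = (w * x).sum(axis=1)
        i_bb = (w * x * x).sum(axis=1)
        det = i_aa * i_bb - i_ab**2
        det = np.where(det <= 0, np.nan, det)
        da = (i_bb * g_a - i_ab * g_b) / det
        db = (i_aa * g_b - i_ab * g_a) / det
        da = np.nan_to_num(da)
        db = np.nan_to_num(db)
        a += np.where(active, da, 0.0)
        b += np.where(active, db, 0.0)
        active = (np.abs(da) > tol) | (np.abs(db) > tol)
        if not active.any():
            break
    eta = a[:, None] + b[:, None] * x
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    i_aa = w.sum(axis=1)
    i_ab = (w * x).sum(axis=1)
    i_bb = (w * x * x).sum(axis=1)
    det = i_aa * i_bb - i_ab**2
    var_b = np.where(det > 0, i_aa / det, np.nan)
    se = np.sqrt(var_b)
    mono = dosages.var(axis=1) == 0
    beta = b.copy()
    with np.errstate(invalid="ignore"):
        zstat = beta / se
    pval = 2.0 * stats.norm.sf(np.abs(zstat))
    beta[mono] = np.nan
    se[mono] = np.nan
    pval[mono] = np.nan
    return beta, se, pval, mono


def marginal_sumstats(block: GenotypeBlock, phenotype: np.ndarray,
                      trait_type: str = "quant",
                      gene_id: str | None = None,
                      clip_p: float = 1e-300) -> pd.DataFrame:
    """Per-variant marginal association summary statistics.

    ``trait_type="quant"`` fits simple linear regression per variant (Wald t
    p-values); ``"cc"`` fits logistic regression per variant (Wald normal
    p-values) on a 0/1 phenotype.  Monomorphic variants are emitted with
    missing effect estimates and flagged in the ``monomorphic`` column.
    P-values are clipped below at ``clip_p`` to honour the p ∈ (0, 1]
    contract of downstream consumers.
    """
    y = np.asarray(phenotype, dtype=float)
    if y.size != block.n_individuals:
        raise ValueError("phenotype length must equal the number of individuals")
    if trait_type == "quant":
        beta, se, pval, mono = _ols_sumstats(block.dosages, y)
    elif trait_type == "cc":
        if not set(np.unique(y)) <= {0.0, 1.0}:
            raise ValueError("case-control phenotype must be 0/1")
        beta, se, pval, mono = _logistic_sumstats(block.dosages, y)
    else:
        raise ValueError("trait_type must be 'quant' or 'cc'")
    pval = np.clip(pval, clip_p, 1.0)
    freq = block.dosages.mean(axis=1) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    df = pd.DataFrame({
        "chrom": [v.chrom for v in block.variants],
        "pos": [v.pos for v in block.variants],
        "ref": [v.ref for v in block.variants],
        "alt": [v.alt for v in block.variants],
        "beta": beta,
        "se": se,
        "pvalue": pval,
        "maf": np.where(maf > 0, maf, np.nan),
        "monomorphic": mono,
    })
    df["n"] = block.n_individuals
    if gene_id is not None:
        df.insert(0, "gene_id", gene_id)
    return df


def simulate_trait_pair(block: GenotypeBlock,
                        scenario: ScenarioSpec) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """GWAS + eQTL summary statistics over one block under a causal scenario.

    The GWAS phenotype is a liability threshold model: liability =
    beta_gwas · dosage(causal_1) + N(0, 1), cases are the top
    ``case_fraction`` of liability.  Expression = beta_eqtl ·
    dosage(causal_2) + N(0, noise_sd).  Under ``null`` both causal effects
    are zero.  Returns (gwas table, eqtl table, truth labels).
    """
    rng = np.random.default_rng(scenario.seed)
    n = block.n_individuals
    m = len(block.variants)
    for idx in (scenario.causal_index_1, scenario.causal_index_2):
        if not 0 <= idx < m:
            raise ValueError("causal index outside the variant panel")
    bg = 0.0 if scenario.scenario == "null" else scenario.beta_gwas
    be = 0.0 if scenario.scenario == "null" else scenario.beta_eqtl

    liability = bg * block.dosages[scenario.causal_index_1] + rng.standard_normal(n)
    thresh = np.quantile(liability, 1.0 - scenario.case_fraction)
    y_cc = (liability > thresh).astype(float)
    expression = (be * block.dosages[scenario.causal_index_2]
                  + rng.normal(0.0, scenario.noise_sd, size=n))
    # standardize expression: rank-normalized eQTL traits have unit variance
    expression = (expression - expression.mean()) / expression.std()

    gwas = marginal_sumstats(block, y_cc, trait_type="cc")
    gwas["n_cases"] = int(y_cc.sum())
    gwas["n_controls"] = int(n - y_cc.sum())
    eqtl = marginal_sumstats(block, expression, trait_type="quant", gene_id="simulated_gene")
    truth = {
        "scenario": scenario.scenario,
        "causal_variant_gwas": block.variants[scenario.causal_index_1].id,
        "causal_variant_eqtl": block.variants[scenario.causal_index_2].id,
        "beta_gwas": bg,
        "beta_eqtl": be,
    }
    return gwas, eqtl, truth


def simulate_screen_counts(spec: ScreenSpec) -> tuple[pd.DataFrame, set[str]]:
    """Guide × sample counts for a pooled screen with planted hits.

    Returns a DataFrame indexed by guide_id with a ``gene_id`` column and one
    integer column per sample (``control_1``, ..., ``infected_1``, ...), and
    the hit-gene set.  Hit genes absent from the gene universe raise.
    """
    rng = np.random.default_rng(spec.seed)
    genes = [f"GENE{i + 1:05d}" for i in range(spec.n_genes)]
    hits = set(spec.hit_genes)
    unknown = hits - set(genes)
    if unknown:
        raise ValueError(f"hit genes outside the gene universe: {sorted(unknown)[:5]}")
    n_guides = spec.n_genes * spec.guides_per_gene
    gene_col = np.repeat(genes, spec.guides_per_gene)
    guide_ids = [f"{g}_sg{j + 1}" for g in genes for j in range(spec.guides_per_gene)]
    mu0 = spec.depth_per_sample / n_guides
    is_hit = np.isin(gene_col, list(hits))
    mu_inf = np.where(is_hit, mu0 * 2.0**spec.hit_log2_enrichment, mu0)
    size = 1.0 / spec.dispersion  # NB2: var = mu + dispersion * mu^2

    def _nb(mu: np.ndarray, n_samples: int) -> np.ndarray:
        lam = rng.gamma(shape=size, scale=mu[:, None] / size,
                        size=(n_guides, n_samples))
        return rng.poisson(lam)

    counts = np.hstack([
        _nb(np.full(n_guides, mu0), spec.n_control),
        _nb(mu_inf, spec.n_infected),
    ])
    cols = ([f"control_{i + 1}" for i in range(spec.n_control)]
            + [f"infected_{i + 1}" for i in range(spec.n_infected)])
    df = pd.DataFrame(counts, columns=cols,
                      index=pd.Index(guide_ids, name="guide_id"))
    df.insert(0, "gene_id", gene_col)
    return df, hits


def simulate_inflation_background(n_genes: int = 2_000,
                                  n_target: int = 400,
                                  target_lambda_multiplier: float = 1.0,
                                  seed: int = 0,
                                  chrom: str = "1",
                                  ) -> tuple[pd.DataFrame, list[str], pd.DataFrame]:
    """Background lead-eQTL set with a GWAS whose signal at target genes is
    inflated by a controlled factor.

    Each gene gets one lead variant.  Background genes' GWAS p-values are
    uniform; target genes' p-values are built by scaling a chi-square(1)
    draw, p = sf(multiplier · X), which makes the target set's expected
    lambda_q equal the multiplier at any q.  Returns (lead table, target
    gene ids, GWAS table); the target is a random subset of the background.
    """
    if not n_target < n_genes:
        raise ValueError("n_target must be smaller than n_genes")
    rng = np.random.default_rng(seed)
    genes = [f"BG{i + 1:05d}" for i in range(n_genes)]
    target = sorted(rng.choice(genes, size=n_target, replace=False).tolist())
    pos = 1_000_000 + 1_000 * np.arange(n_genes)
    alleles = [_ALLELE_CYCLE[i % len(_ALLELE_CYCLE)] for i in range(n_genes)]

    p = rng.uniform(0.0, 1.0, size=n_genes)
    p = np.clip(p, 1e-300, 1.0)
    t_idx = np.isin(genes, target)
    chi = rng.chisquare(df=1, size=int(t_idx.sum()))
    p[t_idx] = np.clip(stats.chi2.sf(target_lambda_multiplier * chi, df=1), 1e-300, 1.0)

    se = np.full(n_genes, 0.05)
    zabs = stats.norm.isf(p / 2.0)
    beta = np.where(rng.random(n_genes) < 0.5, -1.0, 1.0) * zabs * se

    leads = pd.DataFrame({
        "gene_id": genes,
        "chrom": chrom,
        "pos": pos,
        "ref": [a[0] for a in alleles],
        "alt": [a[1] for a in alleles],
        "fdr": rng.uniform(0.0, 0.05, size=n_genes),
    })
    gwas = pd.DataFrame({
        "chrom": chrom,
        "pos": pos,
        "ref": [a[0] for a in alleles],
        "alt": [a[1] for a in alleles],
        "beta": beta,
        "se": se,
        "pvalue": p,
    })
    return leads, target, gwas
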