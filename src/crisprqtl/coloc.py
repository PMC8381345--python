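"""Bayesian colocalization of two association signals under a
single-causal-variant model, with iterative LD-masking for secondary signals.

Given marginal summary statistics (beta, se) for two traits over a shared
variant panel, each variant's evidence of association is summarized by
Wakefield's log approximate Bayes factor.  With z = beta/se, V = se² and a
N(0, W) prior on the true effect, the shrinkage factor is r = W / (V + W) and

    log ABF = 0.5 * log(1 - r) + 0.5 * r * z²

Five hypotheses partition the single-causal-variant space: H0 no association
with either trait; H1/H2 association with one trait only; H3 two distinct
causal variants; H4 one shared causal variant.  Their unnormalized weights
combine the per-variant Bayes factors with priors p1, p2 (variant causal for
one trait) and p12 (causal for both); posteriors PP0–PP4 follow by
normalization.  All sums run in log space (log-sum-exp) for stability.

Allelic heterogeneity violates the one-causal-variant assumption; the
masking mode addresses it by greedily identifying independent signals
(pairwise LD r² below a threshold, each with p below a significance
threshold) and re-running colocalization per signal on a panel with the
other signals' LD partners removed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .sumstats_io import VariantKey, variant_ids

__all__ = [
    "ColocPriors",
    "AbfDataset",
    "ColocResult",
    "MaskedColocResult",
    "compute_labf",
    "estimate_sdY",
    "coloc_single",
    "eligibility_filter",
    "region_subset",
    "find_signals_masked",
    "coloc_masked",
    "DEFAULT_PRIOR_SD_CC",
    "DEFAULT_PRIOR_SD_QT",
]

#: prior effect-size SD on the log-odds scale (case-control traits)
DEFAULT_PRIOR_SD_CC = 0.15
#: prior effect-size SD in trait-SD units (quantitative traits): 0.2 * sdY
DEFAULT_PRIOR_SD_QT = 0.2


@dataclasses.dataclass(frozen=True)
class ColocPriors:
    """Per-variant causality priors: p1/p2 for each single trait, p12 shared."""

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 5e-6

    def __post_init__(self) -> None:
        if not (0 < self.p12 <= min(self.p1, self.p2)):
            raise ValueError("require 0 < p12 <= min(p1, p2)")
        if self.p1 + self.p2 + self.p12 >= 1:
            raise ValueError("p1 + p2 + p12 must be < 1")


def compute_labf(beta, se, prior_sd: float) -> np.ndarray:
    """Per-variant log approximate Bayes factor for association.

    labf = 0.5 log(1 - r) + 0.5 r z², with z = beta/se and
    r = prior_sd² / (se² + prior_sd²).  At z = 0 this is negative (evidence
    against association); it vanishes as prior_sd → 0.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if prior_sd <= 0:
        raise ValueError("prior_sd must be > 0")
    if np.any(se <= 0):
        raise ValueError("all standard errors must be > 0")
    z2 = (beta / se) ** 2
    r = prior_sd**2 / (se**2 + prior_sd**2)
    return 0.5 * np.log1p(-r) + 0.5 * r * z2


def estimate_sdY(vbeta, maf, n) -> float:
    """Estimate a quantitative trait's SD from summary statistics.

    For a marginal regression on a variant with allele frequency f in a
    sample of size n, var(beta_hat) ≈ sdY² / (n * 2f(1-f)), so sdY² is the
    slope of the through-origin regression of 2·n·f·(1-f) on 1/var(beta_hat).
    Rank-normalized expression has sdY = 1 by construction; this estimator is
    the fallback when the trait scale is unknown.
    """
    vbeta = np.asarray(vbeta, dtype=float)
    maf = np.asarray(maf, dtype=float)
    if np.any(vbeta <= 0):
        raise ValueError("vbeta must be positive")
    if np.any((maf <= 0) | (maf > 0.5)):
        raise ValueError("maf must lie in (0, 0.5]")
    x = 1.0 / vbeta
    y = 2.0 * np.asarray(n, dtype=float) * maf * (1.0 - maf)
    slope = float(np.sum(x * y) / np.sum(x * x))
    if slope <= 0:
        raise ValueError(
            "non-positive sdY^2 estimate; supply sdY explicitly (sdY=1 is "
            "appropriate for rank-normalized expression)"
        )
    return float(np.sqrt(slope))


@dataclasses.dataclass
class AbfDataset:
    """One trait's summary statistics over a variant panel, with log-ABFs.

    ``trait_type`` is ``"cc"`` (case-control, effects on the log-odds scale)
    or ``"quant"`` (quantitative, prior scaled by the trait SD ``sdY``).
    """

    variants: list[VariantKey]
    beta: np.ndarray
    se: np.ndarray
    labf: np.ndarray
    trait_type: str = "quant"
    sdY: float = 1.0
    pvalue: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        self.labf = np.asarray(self.labf, dtype=float)
        n = len(self.variants)
        if not (self.beta.shape == self.se.shape == self.labf.shape == (n,)):
            raise ValueError("variants, beta, se, labf must have equal length")
        if np.any(self.se <= 0):
            raise ValueError("all standard errors must be > 0")

    @classmethod
    def from_sumstats(cls, df: pd.DataFrame, trait_type: str = "quant",
                      sdY: float = 1.0, prior_sd: float | None = None) -> "AbfDataset":
        """Build from a canonical summary-statistic table.

        The effect-size prior SD defaults to 0.15 for case-control traits and
        0.2·sdY for quantitative traits.
        """
        if trait_type not in ("cc", "quant"):
            raise ValueError("trait_type must be 'cc' or 'quant'")
        if prior_sd is None:
            prior_sd = DEFAULT_PRIOR_SD_CC if trait_type == "cc" else DEFAULT_PRIOR_SD_QT * sdY
        sub = df.dropna(subset=["beta", "se"])
        variants = [VariantKey(c, int(p), r, a) for c, p, r, a in
                    zip(sub["chrom"], sub["pos"], sub["ref"], sub["alt"])]
        beta = sub["beta"].to_numpy(dtype=float)
        se = sub["se"].to_numpy(dtype=float)
        pvalue = sub["pvalue"].to_numpy(dtype=float) if "pvalue" in sub.columns else None
        return cls(variants, beta, se, compute_labf(beta, se, prior_sd),
                   trait_type=trait_type, sdY=sdY, pvalue=pvalue)

    def subset(self, mask: np.ndarray) -> "AbfDataset":
        mask = np.asarray(mask)
        return AbfDataset(
            [v for v, m in zip(self.variants, mask) if m],
            self.beta[mask], self.se[mask], self.labf[mask],
            trait_type=self.trait_type, sdY=self.sdY,
            pvalue=None if self.pvalue is None else self.pvalue[mask],
        )

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]


@dataclasses.dataclass
class ColocResult:
    """Posterior probabilities of the five colocalization hypotheses."""

    pp0: float
    pp1: float
    pp2: float
    pp3: float
    pp4: float
    n_variants: int
    priors: ColocPriors
    signal_index: int = 0  # 0 = single mode; 1-based signal number when masking
    masked_variants: int = 0
    lead1: str | None = None  # min-p (or max-|z|) variant of trait 1 on the panel

    @property
    def suggestive(self) -> bool:
        """Suggestive support for colocalization: PP4 > 0.5."""
        return self.pp4 > 0.5

    def to_dict(self) -> dict:
        return {
            "pp0": self.pp0, "pp1": self.pp1, "pp2": self.pp2,
            "pp3": self.pp3, "pp4": self.pp4,
            "n_variants": self.n_variants,
            "signal_index": self.signal_index,
            "masked_variants": self.masked_variants,
            "lead1": self.lead1,
            "suggestive_colocalization": self.suggestive,
            "priors": {"p1": self.priors.p1, "p2": self.priors.p2,
                       "p12": self.priors.p12},
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def _logdiff(a: float, b: float) -> float:
    """log(exp(a) - exp(b)) computed stably; tiny negative differences
    (|a - b| below fp tolerance) collapse to zero mass (-inf)."""
    if b >= a - 1e-12:
        return -np.inf
    return a + np.log1p(-np.exp(b - a))


def coloc_single(ds1: AbfDataset, ds2: AbfDataset,
                 priors: ColocPriors | None = None) -> ColocResult:
    """Single-causal-variant colocalization of two traits.

    The two datasets are intersected on variant identity (alleles are assumed
    harmonized upstream); the hypothesis weights combine each trait's
    log-ABFs over the shared panel:

        S0 = 1
        S1 = p1 Σ_i BF1_i
        S2 = p2 Σ_i BF2_i
        S3 = p1 p2 (Σ_i BF1_i Σ_j BF2_j − Σ_i BF1_i BF2_i)
        S4 = p12 Σ_i BF1_i BF2_i

    PPh = Sh / Σ S, evaluated in log space.
    """
    priors = priors or ColocPriors()
    ids1 = {v.id: i for i, v in enumerate(ds1.variants)}
    idx1, idx2 = [], []
    for j, v in enumerate(ds2.variants):
        i = ids1.get(v.id)
        if i is not None:
            idx1.append(i)
            idx2.append(j)
    if not idx1:
        raise ValueError("no shared variants between the two datasets")
    l1 = ds1.labf[idx1]
    l2 = ds2.labf[idx2]

    lsum1 = logsumexp(l1)
    lsum2 = logsumexp(l2)
    lsum12 = logsumexp(l1 + l2)
    log_s = np.array([
        0.0,
        np.log(priors.p1) + lsum1,
        np.log(priors.p2) + lsum2,
        np.log(priors.p1) + np.log(priors.p2) + _logdiff(lsum1 + lsum2, lsum12),
        np.log(priors.p12) + lsum12,
    ])
    pp = np.exp(log_s - logsumexp(log_s))
    pp /= pp.sum()  # exact normalization after exponentiation

    lead1 = ds1.variants[idx1[int(np.argmax(l1))]].id
    return ColocResult(
        pp0=float(pp[0]), pp1=float(pp[1]), pp2=float(pp[2]),
        pp3=float(pp[3]), pp4=float(pp[4]),
        n_variants=len(idx1), priors=priors, lead1=lead1,
    )


def eligibility_filter(eqtl: pd.DataFrame, lead_gwas_variant: VariantKey,
                       window: int = 100_000,
                       p_thresh: float = 1e-4) -> list[str]:
    """Genes eligible for colocalization testing.

    A gene qualifies iff it has a cis-eQTL record with nominal p below
    ``p_thresh`` within ``window`` bp of the lead GWAS variant (closed
    window: a variant exactly ``window`` bp away counts).
    """
    near = (
        (eqtl["chrom"] == lead_gwas_variant.chrom)
        & ((eqtl["pos"] - lead_gwas_variant.pos).abs() <= window)
        & (eqtl["pvalue"] < p_thresh)
    )
    return sorted(eqtl.loc[near, "gene_id"].unique())


def region_subset(records: pd.DataFrame, center_variant: VariantKey,
                  halfwidth: int = 500_000) -> pd.DataFrame:
    """Records within the closed interval [center − halfwidth, center + halfwidth]
    on the center variant's chromosome."""
    if halfwidth <= 0:
        raise ValueError("halfwidth must be > 0")
    keep = (
        (records["chrom"] == center_variant.chrom)
        & (records["pos"] >= center_variant.pos - halfwidth)
        & (records["pos"] <= center_variant.pos + halfwidth)
    )
    return records[keep].reset_index(drop=True)


def find_signals_masked(ds: AbfDataset, ld, p_thresh: float = 1e-4,
                        r2_thresh: float = 0.01,
                        max_signals: int = 3) -> list[VariantKey]:
    """Greedy identification of independent association signals.

    Iteratively select the smallest-p unmasked variant; stop when its p is
    not below ``p_thresh`` or ``max_signals`` leads have been taken.  After
    each selection, mask every variant in LD (r² > ``r2_thresh``) with any
    selected lead.  Selected leads are therefore pairwise independent at the
    r² threshold.
    """
    if ds.pvalue is None:
        raise ValueError("dataset must carry p-values for signal detection")
    r2 = ld.submatrix(ds.variants)  # raises if the LD panel misses a variant
    p = ds.pvalue.copy()
    masked = np.zeros(len(p), dtype=bool)
    leads: list[VariantKey] = []
    while len(leads) < max_signals and not masked.all():
        cand = np.where(~masked, p, np.inf)
        i = int(np.argmin(cand))
        if not cand[i] < p_thresh:
            break
        leads.append(ds.variants[i])
        with np.errstate(invalid="ignore"):
            in_ld = r2[i] > r2_thresh
        in_ld[i] = True  # a variant is always in LD with itself
        masked |= in_ld
    return leads


@dataclasses.dataclass
class MaskedColocResult:
    """Per-signal colocalization results and the max-PP4 summary."""

    results: list[ColocResult]
    leads: list[VariantKey]

    @property
    def max_pp4(self) -> float:
        return max((r.pp4 for r in self.results), default=0.0)

    @property
    def suggestive(self) -> bool:
        return self.max_pp4 > 0.5

    def to_dict(self) -> dict:
        return {
            "n_signals": len(self.results),
            "leads": [v.id for v in self.leads],
            "max_pp4": self.max_pp4,
            "suggestive_colocalization": self.suggestive,
            "signals": [r.to_dict() for r in self.results],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def coloc_masked(ds1: AbfDataset, ds2: AbfDataset, ld1,
                 priors: ColocPriors | None = None,
                 p_thresh: float = 1e-4, r2_thresh: float = 0.01,
                 max_signals: int = 3) -> MaskedColocResult:
    """Colocalization with iterative masking of trait-1 secondary signals.

    Trait 1 (the trait with LD information, typically the eQTL) may violate
    the single-causal-variant assumption.  Independent trait-1 signals are
    found greedily; for each signal the engine re-runs single-mode
    colocalization on a panel from which variants in LD (r² > ``r2_thresh``)
    with the *other* signals' leads are removed, so each run sees one
    trait-1 signal.  Trait 2 is treated as single-signal throughout.  With
    one (or zero) detected signals this reduces exactly to
    :func:`coloc_single`.
    """
    priors = priors or ColocPriors()
    leads = find_signals_masked(ds1, ld1, p_thresh=p_thresh,
                                r2_thresh=r2_thresh, max_signals=max_signals)
    if len(leads) <= 1:
        res = coloc_single(ds1, ds2, priors)
        return MaskedColocResult([res], leads)

    r2 = ld1.submatrix(ds1.variants)
    lead_rows = [ds1.variant_ids.index(v.id) for v in leads]
    results = []
    for s, row in enumerate(lead_rows):
        other = [r for r in lead_rows if r != row]
        with np.errstate(invalid="ignore"):
            drop = np.zeros(len(ds1.variants), dtype=bool)
            for o in other:
                drop |= r2[o] > r2_thresh
        drop[row] = False  # never mask the signal under test
        sub1 = ds1.subset(~drop)
        res = coloc_single(sub1, ds2, priors)
        res.signal_index = s + 1
        res.masked_variants = int(drop.sum())
        results.append(res)
    return MaskedColocResult(results, leads)
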