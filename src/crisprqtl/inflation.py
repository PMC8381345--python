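"""Quantile-based inflation of GWAS signal at lead cis-eQTLs, with a
permutation null.

The question: do the lead cis-eQTL variants of a *target* gene set (e.g. the
top-ranked genes of a CRISPR screen) carry more GWAS association signal than
expected?  Signal is summarized by the inflation statistic

    lambda_q = Q_chi2(1)(1 - quantile_q(p)) / Q_chi2(1)(1 - q)

the ratio of the chi-square(1 df) quantile matching the empirical q-quantile
of the observed GWAS p-values to the chi-square quantile at 1 - q.  At
q = 0.1 this measures inflation among the 10% most significant tests;
lambda > 1 means excess signal.

Significance comes from a permutation null: draw |target| lead eQTLs from
the background gene set (all genes with a significant lead cis-eQTL) many
times, recompute lambda on each draw, and compare log(lambda) — the log
transform symmetrizes the null — between the observed set and the draws.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats_io import variant_ids

logger = logging.getLogger(__name__)

__all__ = [
    "InflationConfig",
    "InflationResult",
    "lambda_quantile",
    "match_leads_to_gwas",
    "permutation_inflation_test",
]


@dataclasses.dataclass
class InflationConfig:
    """Tunables of the permutation inflation test.

    q : quantile of the statistic (0.1 = inflation among the top 10% of tests)
    k : number of permutations (the study-scale default is 10,000)
    seed : RNG seed; identical seed and inputs reproduce the permuted
        distribution bitwise
    center : centering of the two-sided extremity rule on the log scale,
        ``"mean"`` (distance from the permutation mean) or ``"zero"``
    """

    q: float = 0.1
    k: int = 10_000
    seed: int = 0
    center: str = "mean"

    def __post_init__(self) -> None:
        if not 0 < self.q < 1:
            raise ValueError("q must be in (0, 1)")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.center not in ("mean", "zero"):
            raise ValueError("center must be 'mean' or 'zero'")


@dataclasses.dataclass
class InflationResult:
    lambda_obs: float
    log_lambda_obs: float
    perm_log_lambdas: np.ndarray
    p_two_sided: float
    n_target: int
    n_background: int
    config: InflationConfig
    quantile_method: str = "linear"  # empirical-quantile interpolation convention

    def to_dict(self) -> dict:
        return {
            "lambda_obs": self.lambda_obs,
            "log_lambda_obs": self.log_lambda_obs,
            "p_two_sided": self.p_two_sided,
            "n_target": self.n_target,
            "n_background": self.n_background,
            "q": self.config.q,
            "k": self.config.k,
            "seed": self.config.seed,
            "center": self.config.center,
            "quantile_method": self.quantile_method,
            "perm_log_lambdas": [float(x) for x in self.perm_log_lambdas],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def lambda_quantile(pvalues, q: float = 0.1, axis: int = -1):
    """Inflation statistic lambda_q of a p-value collection.

    lambda_q = isf_chi2(quantile_q(p); 1) / isf_chi2(q; 1), where isf is the
    chi-square(1) inverse survival function: the observed q-quantile of the
    p-values, expressed as a chi-square quantile, relative to its null
    expectation.  Uniform p-values give lambda ≈ 1.

    Accepts an array of p-values; with a 2-D array the statistic is taken
    along ``axis`` (used to vectorize permutation draws).
    """
    p = np.asarray(pvalues, dtype=float)
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    if p.size == 0 or np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if p.shape[axis] < int(np.ceil(1.0 / q)):
        raise ValueError(
            f"need at least ceil(1/q) = {int(np.ceil(1.0 / q))} p-values for q={q}"
        )
    pq = np.quantile(p, q, axis=axis)  # default linear interpolation
    return stats.chi2.isf(pq, df=1) / stats.chi2.isf(q, df=1)


def match_leads_to_gwas(leads: pd.DataFrame,
                        gwas: pd.DataFrame) -> tuple[np.ndarray, int]:
    """GWAS p-value of each lead cis-eQTL variant, in lead order.

    Leads absent from the GWAS are dropped (their count is returned and
    logged); genes sharing a lead variant each contribute their own entry,
    i.e. resampling is gene-level.  Raises if no lead matches.
    """
    gwas_p = pd.Series(gwas["pvalue"].to_numpy(), index=variant_ids(gwas))
    lead_ids = variant_ids(leads)
    matched = lead_ids.isin(gwas_p.index)
    dropped = int((~matched).sum())
    if dropped:
        logger.info("%d lead cis-eQTL(s) absent from the GWAS", dropped)
    if matched.sum() == 0:
        raise ValueError("no lead cis-eQTL variant matches the GWAS")
    pvals = gwas_p.loc[lead_ids[matched]].to_numpy()
    return pvals, dropped


def _draw_without_replacement(rng: np.random.Generator, n_pool: int,
                              n_draw: int, k: int,
                              max_cells: int = 10_000_000) -> np.ndarray:
    """k index sets of size n_draw, each drawn uniformly without replacement.

    Draws are vectorized (random keys + argpartition) in chunks so the
    transient key matrix stays below ``max_cells`` entries.
    """
    chunk = max(1, max_cells // n_pool)
    out = np.empty((k, n_draw), dtype=np.intp)
    for start in range(0, k, chunk):
        stop = min(start + chunk, k)
        keys = rng.random((stop - start, n_pool))
        out[start:stop] = np.argpartition(keys, n_draw - 1, axis=1)[:, :n_draw]
    return out


def permutation_inflation_test(target_leads: pd.DataFrame,
                               background_leads: pd.DataFrame,
                               gwas: pd.DataFrame,
                               config: InflationConfig | None = None) -> InflationResult:
    """Permutation test of GWAS-signal inflation at a gene set's lead eQTLs.

    The observed lambda_q is computed from the GWAS p-values of the target
    genes' lead cis-eQTLs.  Each of k permutations draws |target| lead eQTLs
    uniformly without replacement from the background set (of which the
    target is a subset) and recomputes lambda_q.  The two-sided permutation p
    is the proportion of permuted log(lambda) at least as far from the center
    (the permutation mean by default) as the observed log(lambda), with the
    standard +1 correction so p is never 0:

        p = (1 + #{|log l_perm - c| >= |log l_obs - c|}) / (k + 1)
    """
    cfg = config or InflationConfig()
    target_p, _ = match_leads_to_gwas(target_leads, gwas)
    background_p, _ = match_leads_to_gwas(background_leads, gwas)
    n_target, n_background = len(target_p), len(background_p)
    min_n = int(np.ceil(1.0 / cfg.q))
    if n_target < min_n:
        raise ValueError(
            f"target set too small: {n_target} matched leads < ceil(1/q) = {min_n}"
        )
    if n_background < n_target:
        raise ValueError("background must be at least as large as the target set")

    lam_obs = float(lambda_quantile(target_p, cfg.q))
    log_obs = float(np.log(lam_obs))

    rng = np.random.default_rng(cfg.seed)
    idx = _draw_without_replacement(rng, n_background, n_target, cfg.k)
    perm_lam = lambda_quantile(background_p[idx], cfg.q, axis=1)
    perm_log = np.log(perm_lam)

    c = float(np.mean(perm_log)) if cfg.center == "mean" else 0.0
    extreme = np.abs(perm_log - c) >= abs(log_obs - c)
    p = (1.0 + int(extreme.sum())) / (cfg.k + 1.0)

    return InflationResult(
        lambda_obs=lam_obs,
        log_lambda_obs=log_obs,
        perm_log_lambdas=perm_log,
        p_two_sided=float(p),
        n_target=n_target,
        n_background=n_background,
        config=cfg,
    )
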