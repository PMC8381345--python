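"""Gene-level ranking of a pooled CRISPR loss-of-function screen.

In a survival screen, cells carrying a knockout that confers resistance to
infection survive and their guides become over-represented in the infected
pool relative to the uninfected control.  Enrichment is therefore a *high*
guide fold-change (infected over control).  Three rank-aggregation methods
score each gene from its guides' log2 fold-changes:

* **sbScore** — the second-highest guide fold-change among the gene's guides;
  genes are ranked descending.  Robust to a single outlier guide.
* **RRA** (robust rank aggregation) — with the gene's k guide ranks among all
  n guides converted to normalized ranks r in (0, 1] and sorted ascending,
  rho = min_j Beta.cdf(r_(j); j, k - j + 1): the most surprising order
  statistic under the uniform null.  Genes are ranked ascending by rho.
* **RIGER weighted-sum** — w * r_(1) + (1 - w) * r_(2) over the two best
  normalized guide ranks; genes ranked ascending.

Guide ranks are made a strict permutation 1..n by breaking fold-change ties
with guide id (lexical), which RRA's order statistics require.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "normalize_counts",
    "guide_log2fc",
    "sbscore",
    "rra_rho",
    "riger_weighted_sum",
    "score_genes",
    "top_ranked_union",
]


def normalize_counts(counts: pd.DataFrame, method: str = "cpm") -> pd.DataFrame:
    """Normalize a guide × sample count matrix between samples.

    ``cpm`` scales each sample column to counts-per-million so that library
    depth differences cancel before fold-changes are formed.
    """
    if method != "cpm":
        raise ValueError(f"unknown normalization method {method!r}")
    numeric = counts.select_dtypes(include=[np.number])
    if (numeric < 0).to_numpy().any():
        raise ValueError("counts must be non-negative")
    totals = numeric.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValueError(f"all-zero sample column(s): {zero}")
    out = counts.copy()
    out[numeric.columns] = numeric / totals * 1e6
    return out


def guide_log2fc(norm_infected: pd.DataFrame,
                 norm_control: pd.DataFrame,
                 pseudocount: float = 1.0) -> pd.Series:
    """Per-guide log2 fold-change of normalized counts, infected vs. control.

    Replicate samples are averaged on the normalized scale before the ratio;
    the pseudocount keeps the ratio finite for zero counts.
    Returns a Series indexed by guide_id.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    inf_num = norm_infected.select_dtypes(include=[np.number])
    ctl_num = norm_control.select_dtypes(include=[np.number])
    only_inf = inf_num.index.difference(ctl_num.index)
    only_ctl = ctl_num.index.difference(inf_num.index)
    if len(only_inf) or len(only_ctl):
        raise ValueError(
            "guides present in one condition only: "
            f"{sorted(only_inf.tolist() + only_ctl.tolist())[:10]}"
        )
    ctl_num = ctl_num.loc[inf_num.index]
    inf_mean = inf_num.mean(axis=1)
    ctl_mean = ctl_num.mean(axis=1)
    lfc = np.log2((inf_mean + pseudocount) / (ctl_mean + pseudocount))
    lfc.name = "log2fc"
    return lfc


def _second_highest(values: np.ndarray) -> float:
    return float(np.partition(values, -2)[-2])


def sbscore(log2fc: pd.Series, gene_ids: pd.Series) -> pd.Series:
    """Second-best guide score per gene: the 2nd-highest guide log2fc.

    Genes with fewer than 2 guides are excluded (a second-best statistic is
    undefined for them).  Returns a Series indexed by gene_id, descending =
    more enriched.
    """
    df = pd.DataFrame({"log2fc": log2fc.to_numpy(), "gene_id": gene_ids.to_numpy()})
    sizes = df.groupby("gene_id").size()
    ok = sizes.index[sizes >= 2]
    grouped = df[df["gene_id"].isin(ok)].groupby("gene_id")["log2fc"]
    out = grouped.apply(lambda v: _second_highest(v.to_numpy()))
    out.name = "sbscore"
    return out


def rra_rho(normalized_ranks: Sequence[float]) -> float:
    """Robust rank aggregation rho for one gene's k normalized guide ranks.

    With the ranks sorted ascending, rho = min over j of the Beta(j, k-j+1)
    CDF at the j-th smallest rank — the tail probability that the j-th order
    statistic of k uniforms is this small.  Smaller rho = more enriched.
    """
    r = np.sort(np.asarray(normalized_ranks, dtype=float))
    k = r.size
    if k == 0:
        raise ValueError("rra_rho requires at least one guide rank")
    if np.any((r <= 0) | (r > 1)):
        raise ValueError("normalized ranks must lie in (0, 1]")
    j = np.arange(1, k + 1)
    return float(np.min(stats.beta.cdf(r, j, k - j + 1)))


def riger_weighted_sum(normalized_ranks: Sequence[float], w: float = 0.25) -> float:
    """Weighted sum of the best and second-best normalized guide ranks.

    score = w * r_(1) + (1 - w) * r_(2); ascending = more enriched.  At w=0
    this reduces to the rank analogue of the second-best score.
    """
    r = np.sort(np.asarray(normalized_ranks, dtype=float))
    if r.size < 2:
        raise ValueError("riger_weighted_sum requires >= 2 guide ranks")
    return float(w * r[0] + (1.0 - w) * r[1])


def _strict_guide_ranks(log2fc: pd.Series) -> pd.Series:
    """1-based guide ranks, 1 = highest log2fc; ties broken by guide id."""
    # mergesort is stable; pre-sorting the index makes the tie-break lexical
    order = (
        pd.DataFrame({"log2fc": log2fc}).sort_index()
        .sort_values(by="log2fc", ascending=False, kind="mergesort")
    )
    ranks = pd.Series(np.arange(1, len(order) + 1), index=order.index, name="rank")
    return ranks.loc[log2fc.index]


def score_genes(log2fc: pd.Series,
                gene_ids: pd.Series,
                riger_w: float = 0.25) -> tuple[pd.DataFrame, list[str]]:
    """Aggregate guide log2 fold-changes into per-gene scores and ranks.

    Parameters
    ----------
    log2fc
        Per-guide log2 fold-change, indexed by guide_id.
    gene_ids
        Gene targeted by each guide, aligned with ``log2fc``.

    Returns
    -------
    (scores, excluded) where ``scores`` has one row per gene with columns
    ``n_guides``, ``sbscore``, ``rra_rho``, ``riger_ws`` and 1-based ranks
    ``rank_sbscore``, ``rank_rra``, ``rank_riger`` (1 = most enriched; ties
    broken by gene id so each rank column is a permutation of 1..G), and
    ``excluded`` lists genes dropped for having < 2 guides.
    """
    df = pd.DataFrame({
        "log2fc": log2fc.to_numpy(),
        "gene_id": gene_ids.to_numpy(),
    }, index=log2fc.index)
    n_total = len(df)
    df["rank"] = _strict_guide_ranks(df["log2fc"])
    df["norm_rank"] = df["rank"] / n_total

    sizes = df.groupby("gene_id").size()
    excluded = sorted(sizes.index[sizes < 2].tolist())
    df = df[~df["gene_id"].isin(excluded)]

    # vectorized over all guides: sort by (gene, normalized rank) so that the
    # per-gene beta-CDF order statistics line up via cumcount
    srt = df.sort_values(["gene_id", "norm_rank"], kind="mergesort")
    grp = srt.groupby("gene_id", sort=True)
    k = grp["norm_rank"].transform("size").to_numpy()
    j = (grp.cumcount() + 1).to_numpy()
    betacdf = stats.beta.cdf(srt["norm_rank"].to_numpy(), j, k - j + 1)
    rho = pd.Series(betacdf, index=srt["gene_id"].to_numpy()).groupby(level=0).min()

    r1 = grp["norm_rank"].nth(0).to_numpy()
    r2 = grp["norm_rank"].nth(1).to_numpy()
    # second-highest log2fc = second entry of the per-gene descending sort
    srt_fc = df.sort_values(["gene_id", "log2fc"], ascending=[True, False],
                            kind="mergesort")
    sb = srt_fc.groupby("gene_id", sort=True)["log2fc"].nth(1).to_numpy()

    scores = pd.DataFrame({
        "n_guides": grp.size(),
        "sbscore": sb,
        "rra_rho": rho,
        "riger_ws": riger_w * r1 + (1 - riger_w) * r2,
    })
    scores.index.name = "gene_id"

    def _ranks(col: str, ascending: bool) -> np.ndarray:
        order = scores[col].reset_index().sort_values(
            by=[col, "gene_id"], ascending=[ascending, True], kind="mergesort"
        )
        ranks = pd.Series(np.arange(1, len(order) + 1), index=order["gene_id"])
        return ranks.loc[scores.index].to_numpy()

    scores["rank_sbscore"] = _ranks("sbscore", ascending=False)
    scores["rank_rra"] = _ranks("rra_rho", ascending=True)
    scores["rank_riger"] = _ranks("riger_ws", ascending=True)
    return scores, excluded


_METHOD_RANK_COL = {
    "sbscore": "rank_sbscore",
    "rra": "rank_rra",
    "riger": "rank_riger",
}


def top_ranked_union(scores: pd.DataFrame,
                     top_n: int = 500,
                     methods: Iterable[str] = ("sbscore", "rra", "riger"),
                     gene_universe: Iterable[str] | None = None) -> set[str]:
    """Union of each method's top-``top_n`` genes, optionally restricted to a
    gene universe (e.g. protein-coding ids)."""
    if top_n > len(scores):
        raise ValueError(f"top_n={top_n} exceeds number of scored genes ({len(scores)})")
    out: set[str] = set()
    for m in methods:
        col = _METHOD_RANK_COL.get(m)
        if col is None:
            raise ValueError(f"unknown ranking method {m!r}")
        out |= set(scores.index[scores[col] <= top_n])
    if gene_universe is not None:
        out &= set(gene_universe)
    return out
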