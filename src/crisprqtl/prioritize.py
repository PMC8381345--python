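"""Locus gene prioritization: integrate screen ranks, per-dataset eQTL
p-values at the lead GWAS variant, and colocalization flags into one table;
LD r² utilities for regional association plots.

The prioritization view of a locus asks, for each protein-coding gene and
each eQTL dataset (cell type / tissue): how strongly is the lead GWAS
variant associated with the gene's expression there, does that signal
colocalize with the GWAS (PP4 > 0.5), and how enriched was the gene in the
CRISPR screen?  Genes supported on all three axes are the prioritized
candidates.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .sumstats_io import VariantKey, variant_ids

__all__ = [
    "LdMatrix",
    "ld_r2",
    "weighted_r2",
    "lead_variant_pvalues",
    "build_priority_table",
    "regional_plot_data",
    "read_genes_bed",
]


@dataclasses.dataclass
class LdMatrix:
    """Symmetric LD r² over an ordered variant panel.

    Entries for monomorphic variants (zero dosage variance) are undefined and
    stored as NaN; their ids are listed in ``monomorphic``.
    """

    variants: list[VariantKey]
    r2: np.ndarray
    population_label: str | None = None
    monomorphic: list[str] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        n = len(self.variants)
        if self.r2.shape != (n, n):
            raise ValueError("r2 matrix must be square over the variant panel")
        if np.nanmax(np.abs(self.r2 - self.r2.T), initial=0.0) > 1e-12:
            raise ValueError("r2 matrix must be symmetric")

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def submatrix(self, variants: Sequence[VariantKey]) -> np.ndarray:
        """r² restricted to the given variants, in their order; raises if any
        variant is absent from the panel."""
        index = {v.id: i for i, v in enumerate(self.variants)}
        try:
            rows = [index[v.id] for v in variants]
        except KeyError as exc:
            raise KeyError(f"variant {exc.args[0]} absent from the LD panel") from exc
        rows = np.asarray(rows)
        return self.r2[np.ix_(rows, rows)]

    def r2_with(self, variant: VariantKey) -> pd.Series:
        """r² of every panel variant with one reference variant."""
        index = {v.id: i for i, v in enumerate(self.variants)}
        if variant.id not in index:
            raise KeyError(f"variant {variant.id} absent from the LD panel")
        return pd.Series(self.r2[index[variant.id]], index=self.variant_ids)


def ld_r2(dosages: np.ndarray, variants: Sequence[VariantKey],
          population_label: str | None = None) -> LdMatrix:
    """LD matrix from a variant × individual dosage matrix.

    r²(i, j) is the squared Pearson correlation of the two dosage vectors.
    Monomorphic variants get NaN rows/columns (undefined correlation) and are
    flagged rather than erroring.
    """
    dosages = np.asarray(dosages, dtype=float)
    if dosages.ndim != 2 or dosages.shape[1] < 2:
        raise ValueError("need a 2-D dosage matrix with >= 2 individuals")
    x = dosages - dosages.mean(axis=1, keepdims=True)
    sd = np.sqrt((x**2).sum(axis=1))
    mono = sd == 0
    sd_safe = np.where(mono, 1.0, sd)
    corr = (x @ x.T) / np.outer(sd_safe, sd_safe)
    r2 = np.clip(corr, -1.0, 1.0) ** 2
    np.fill_diagonal(r2, 1.0)  # exact unit diagonal for polymorphic variants
    r2[mono, :] = np.nan
    r2[:, mono] = np.nan
    flagged = [v.id for v, m in zip(variants, mono) if m]
    return LdMatrix(list(variants), r2, population_label, flagged)


def weighted_r2(matrices: Sequence[LdMatrix], weights: Sequence[float]) -> LdMatrix:
    """Elementwise weighted average of per-population LD matrices.

    Weights (e.g. per-population sample counts) are normalized to sum to 1;
    entries missing (NaN) in some populations are averaged over the others
    with the weights renormalized pairwise.  All matrices must share the
    variant panel.
    """
    if len(matrices) != len(weights):
        raise ValueError("one weight per matrix required")
    if not matrices:
        raise ValueError("need at least one LD matrix")
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    panel = matrices[0].variant_ids
    for m in matrices[1:]:
        if m.variant_ids != panel:
            raise ValueError("all LD matrices must share the same variant panel")
    stack = np.stack([m.r2 for m in matrices])  # (pop, v, v)
    w3 = w[:, None, None] * np.ones_like(stack)
    w3[np.isnan(stack)] = 0.0
    denom = w3.sum(axis=0)
    with np.errstate(invalid="ignore"):
        avg = np.nansum(stack * w3, axis=0) / denom
    avg[denom == 0] = np.nan
    mono = [vid for vid, d in zip(panel, np.diagonal(denom)) if d == 0]
    return LdMatrix(list(matrices[0].variants), avg, "weighted", mono)


def lead_variant_pvalues(eqtl_datasets: Mapping[str, pd.DataFrame],
                         lead_variant: VariantKey,
                         genes: Sequence[str],
                         highlight_p: float = 1e-4) -> tuple[pd.DataFrame, set[str]]:
    """Per-gene, per-dataset eQTL p-value of the lead GWAS variant.

    Returns a genes × datasets table of nominal p-values (NaN where the
    gene-variant pair is absent) and the highlight set: datasets where the
    lead variant's p is below ``highlight_p`` for at least one gene.
    Raises if the lead variant is absent from every dataset.
    """
    table = pd.DataFrame(index=pd.Index(genes, name="gene_id"),
                         columns=sorted(eqtl_datasets), dtype=float)
    seen = False
    for name, df in eqtl_datasets.items():
        hits = df[(variant_ids(df) == lead_variant.id) & df["gene_id"].isin(genes)]
        if len(df[variant_ids(df) == lead_variant.id]):
            seen = True
        for g, p in zip(hits["gene_id"], hits["pvalue"]):
            table.loc[g, name] = p
    if not seen:
        raise ValueError(f"lead variant {lead_variant.id} absent from every dataset")
    highlight = {name for name in table.columns
                 if (table[name] < highlight_p).any()}
    return table, highlight


def build_priority_table(pvalue_table: pd.DataFrame,
                         screen_ranks_low: Mapping[str, int] | pd.Series | None = None,
                         screen_ranks_high: Mapping[str, int] | pd.Series | None = None,
                         coloc_results: Mapping[tuple[str, str], float] | None = None,
                         gene_order: Sequence[str] | None = None,
                         pp4_flag_threshold: float = 0.5) -> pd.DataFrame:
    """Assemble the integrated gene-prioritization table.

    One row per (gene, dataset): the lead-variant eQTL p-value, the
    colocalization posterior PP4 where a test was run, the PP4 > 0.5 support
    flag, and the gene's screen ranks (second-best-guide score) in the low-
    and high-MOI arms.  Row order is deterministic: genes in ``gene_order``
    (genomic position order by convention; default = table order), datasets
    lexically within gene.  ``coloc_results`` maps (gene, dataset) to PP4, or
    is an iterable of (gene, dataset, pp4) triples; duplicate (gene, dataset)
    entries raise.
    """
    if coloc_results is None:
        coloc_results = {}
    elif not isinstance(coloc_results, Mapping):
        triples = list(coloc_results)
        keys = [(g, d) for g, d, _ in triples]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate (gene, dataset) colocalization results")
        coloc_results = {(g, d): pp4 for g, d, pp4 in triples}
    else:
        coloc_results = dict(coloc_results)
    genes = list(gene_order) if gene_order is not None else list(pvalue_table.index)
    if set(genes) != set(pvalue_table.index):
        raise ValueError("gene_order must be a permutation of the table's genes")

    def _rank(ranks, gene):
        if ranks is None:
            return np.nan
        r = ranks.get(gene) if isinstance(ranks, Mapping) else (
            ranks[gene] if gene in ranks.index else None)
        return np.nan if r is None else float(r)

    rows = []
    for gene in genes:
        for ds in sorted(pvalue_table.columns):
            pp4 = coloc_results.get((gene, ds))
            rows.append({
                "gene_id": gene,
                "dataset_id": ds,
                "lead_variant_p": pvalue_table.loc[gene, ds],
                "pp4": np.nan if pp4 is None else float(pp4),
                "coloc_flag": bool(pp4 is not None and pp4 > pp4_flag_threshold),
                "rank_low_moi": _rank(screen_ranks_low, gene),
                "rank_high_moi": _rank(screen_ranks_high, gene),
            })
    return pd.DataFrame(rows)


def regional_plot_data(sumstats: pd.DataFrame, ld: LdMatrix,
                       lead_variant: VariantKey) -> pd.DataFrame:
    """Plot-ready table for a locuszoom-style regional association plot:
    position, -log10 p, and (weighted) r² with the lead variant.

    Variants absent from the LD panel get NaN r².
    """
    r2_lead = ld.r2_with(lead_variant)
    vids = variant_ids(sumstats)
    out = pd.DataFrame({
        "variant_id": vids,
        "pos": sumstats["pos"].to_numpy(),
        "pvalue": sumstats["pvalue"].to_numpy(),
        "neglog10_p": -np.log10(sumstats["pvalue"].to_numpy()),
        "r2_lead": [r2_lead.get(v, np.nan) for v in vids],
    })
    return out


def read_genes_bed(path: str | Path) -> pd.DataFrame:
    """Read gene coordinates from BED (0-based half-open) and convert to the
    1-based closed convention used throughout: start_1based = start + 1.

    Columns used: chrom, start, end, name.  Returns a DataFrame sorted by
    (chrom, start) with columns gene_id, chrom, start, end (1-based closed).
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2, 3],
                     names=["chrom", "start", "end", "gene_id"],
                     dtype={"chrom": str})
    df["chrom"] = df["chrom"].str.replace("^chr", "", regex=True)
    df["start"] = df["start"].astype(np.int64) + 1
    df["end"] = df["end"].astype(np.int64)
    return (df[["gene_id", "chrom", "start", "end"]]
            .sort_values(["chrom", "start"], kind="mergesort")
            .reset_index(drop=True))
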