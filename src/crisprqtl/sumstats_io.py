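"""Readers and writers for tabular summary-statistic formats.

Every downstream stage consumes one of four tables:

* GWAS summary statistics — one marginal association per variant,
* cis-eQTL summary statistics — one marginal association per (gene, variant),
* guide-level read counts from a pooled CRISPR screen,
* genotype dosage matrices used for LD computation.

All tables are tab-delimited with a header.  Variant identity is the full
``chrom:pos:ref:alt`` string (GRCh38, 1-based positions); rsIDs, when present,
are carried as annotation only and never used for joining, because rsID
assignment is unreliable across GWAS meta-analyses and eQTL resources.
Chromosome labels are normalized by stripping a leading ``chr``.

Region filters are closed intervals ``[start, end]`` in 1-based coordinates —
the convention of GWAS summary statistics — so a ±100 kb window around
position p includes both ``p - 100000`` and ``p + 100000`` exactly.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "VariantKey",
    "SumstatsFormatError",
    "GWAS_COLUMNS",
    "EQTL_COLUMNS",
    "LEAD_COLUMNS",
    "HGI_R5_COLUMN_MAP",
    "GTEX_V8_COLUMN_MAP",
    "read_gwas",
    "write_gwas",
    "read_eqtl",
    "write_eqtl",
    "read_leads",
    "write_leads",
    "read_guide_counts",
    "write_guide_counts",
    "read_dosages",
    "write_dosages",
    "read_dosages_vcf",
    "harmonize_to_reference",
    "variant_ids",
]


class SumstatsFormatError(ValueError):
    """A summary-statistics table violates its column or value contract."""


def _norm_chrom(c: str) -> str:
    c = str(c)
    return c[3:] if c.lower().startswith("chr") else c


@dataclasses.dataclass(frozen=True, order=True)
class VariantKey:
    """Identity of a biallelic variant: chromosome, 1-based position, alleles.

    The canonical string form is ``chrom:pos:ref:alt``, e.g. ``3:45823240:T:C``.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", _norm_chrom(self.chrom))
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt alleles are identical: {self.ref}")

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @classmethod
    def from_id(cls, vid: str) -> "VariantKey":
        parts = vid.split(":")
        if len(parts) != 4:
            raise ValueError(f"variant id must be chrom:pos:ref:alt, got {vid!r}")
        chrom, pos, ref, alt = parts
        return cls(chrom, int(pos), ref, alt)

    def __str__(self) -> str:
        return self.id


#: canonical column order for GWAS tables (optional columns may be absent)
GWAS_COLUMNS = ["chrom", "pos", "ref", "alt", "beta", "se", "pvalue"]
GWAS_OPTIONAL = ["eaf", "n_cases", "n_controls", "rsid"]

#: canonical column order for cis-eQTL tables
EQTL_COLUMNS = ["gene_id", "chrom", "pos", "ref", "alt", "beta", "se", "pvalue"]
EQTL_OPTIONAL = ["maf", "n", "rsid"]

#: canonical columns for lead cis-eQTL tables (one row per gene)
LEAD_COLUMNS = ["gene_id", "chrom", "pos", "ref", "alt", "fdr"]

#: column map matching COVID-19 HGI release-5 summary-statistic headers
HGI_R5_COLUMN_MAP = {
    "chrom": "#CHR",
    "pos": "POS",
    "ref": "REF",
    "alt": "ALT",
    "beta": "all_inv_var_meta_beta",
    "se": "all_inv_var_meta_sebeta",
    "pvalue": "all_inv_var_meta_p",
    "eaf": "all_meta_AF",
}

#: column map matching GTEx v8 / eQTL Catalogue association headers
GTEX_V8_COLUMN_MAP = {
    "gene_id": "molecular_trait_id",
    "chrom": "chromosome",
    "pos": "position",
    "ref": "ref",
    "alt": "alt",
    "beta": "beta",
    "se": "se",
    "pvalue": "pvalue",
    "maf": "maf",
    "n": "an",
}


def variant_ids(df: pd.DataFrame) -> pd.Series:
    """Canonical ``chrom:pos:ref:alt`` id per row of a canonical table."""
    return (
        df["chrom"].astype(str)
        + ":"
        + df["pos"].astype(str)
        + ":"
        + df["ref"].astype(str)
        + ":"
        + df["alt"].astype(str)
    )


def _load_table(path: str | Path, column_map: Mapping[str, str] | None,
                required: Sequence[str], optional: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    column_map = dict(column_map or {})
    # identity map for canonical names not explicitly remapped
    rename = {}
    for canon in list(required) + list(optional):
        src = column_map.get(canon, canon)
        if src in df.columns:
            rename[src] = canon
    missing = [c for c in required if column_map.get(c, c) not in df.columns]
    if missing:
        raise SumstatsFormatError(
            f"{path}: missing required column(s) "
            + ", ".join(f"{c!r} (mapped from {column_map.get(c, c)!r})" for c in missing)
        )
    df = df.rename(columns=rename)
    keep = [c for c in list(required) + list(optional) if c in df.columns]
    return df[keep].copy()


def _check_numeric(df: pd.DataFrame, path: str | Path, cols: Iterable[str]) -> None:
    for col in cols:
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise SumstatsFormatError(
                f"{path}: non-numeric value in column {col!r} at data row(s) "
                f"{[int(i) + 1 for i in bad[:5]]}"
            )
        df[col] = coerced


def _check_rows(df: pd.DataFrame, path: str | Path, *, p_col: str = "pvalue") -> None:
    """Raise on rows violating the record invariants, naming 1-based data rows."""
    violations = []
    if "se" in df.columns:
        bad = df.index[~(df["se"] > 0)]
        violations += [(int(i) + 1, "se must be > 0") for i in bad]
    if p_col in df.columns:
        bad = df.index[~((df[p_col] > 0) & (df[p_col] <= 1))]
        violations += [(int(i) + 1, f"{p_col} must be in (0, 1]") for i in bad]
    if "maf" in df.columns:
        m = df["maf"].dropna()
        bad = m.index[~((m > 0) & (m <= 0.5))]
        violations += [(int(i) + 1, "maf must be in (0, 0.5]") for i in bad]
    if "eaf" in df.columns:
        e = df["eaf"].dropna()
        bad = e.index[~((e >= 0) & (e <= 1))]
        violations += [(int(i) + 1, "eaf must be in [0, 1]") for i in bad]
    if "pos" in df.columns:
        bad = df.index[~(df["pos"] >= 1)]
        violations += [(int(i) + 1, "pos must be >= 1") for i in bad]
    if violations:
        violations.sort()
        msgs = "; ".join(f"row {r}: {m}" for r, m in violations[:10])
        raise SumstatsFormatError(f"{path}: invalid record(s): {msgs}")


def read_gwas(path: str | Path,
              column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read GWAS summary statistics into the canonical per-variant table.

    Parameters
    ----------
    path
        Tab-delimited file with a header row.
    column_map
        Maps canonical names (``chrom``, ``pos``, ``ref``, ``alt``, ``beta``,
        ``se``, ``pvalue``, optionally ``eaf``/``n_cases``/``n_controls``) to
        the file's column names.  Canonical names present in the file need no
        entry.  :data:`HGI_R5_COLUMN_MAP` matches COVID-19 HGI release 5.

    Returns
    -------
    DataFrame with canonical columns, row order preserved, indexed 0..n-1.
    Duplicate variant keys or invariant violations raise
    :class:`SumstatsFormatError` naming the offending 1-based data row.
    """
    df = _load_table(path, column_map, GWAS_COLUMNS, GWAS_OPTIONAL)
    _check_numeric(df, path, ["pos", "beta", "se", "pvalue", "eaf", "n_cases", "n_controls"])
    df["chrom"] = df["chrom"].map(_norm_chrom)
    df["pos"] = df["pos"].astype(np.int64)
    _check_rows(df, path)
    vids = variant_ids(df)
    dup = vids[vids.duplicated()]
    if len(dup):
        raise SumstatsFormatError(
            f"{path}: duplicate variant key(s): {sorted(set(dup))[:5]}"
        )
    return df.reset_index(drop=True)


def write_gwas(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in GWAS_COLUMNS + GWAS_OPTIONAL if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False)


def read_eqtl(path: str | Path,
              column_map: Mapping[str, str] | None = None,
              gene_filter: Iterable[str] | None = None,
              region_filter: tuple[str, int, int] | None = None) -> pd.DataFrame:
    """Read cis-eQTL summary statistics, optionally filtered.

    ``gene_filter`` is a set of gene ids; ``region_filter`` is
    ``(chrom, start, end)`` with a closed interval ``[start, end]``.  The two
    filters compose conjunctively and are order-independent.
    """
    df = _load_table(path, column_map, EQTL_COLUMNS, EQTL_OPTIONAL)
    _check_numeric(df, path, ["pos", "beta", "se", "pvalue", "maf", "n"])
    df["chrom"] = df["chrom"].map(_norm_chrom)
    df["pos"] = df["pos"].astype(np.int64)
    _check_rows(df, path)
    if gene_filter is not None:
        df = df[df["gene_id"].isin(set(gene_filter))]
    if region_filter is not None:
        chrom, start, end = region_filter
        chrom = _norm_chrom(chrom)
        df = df[(df["chrom"] == chrom) & (df["pos"] >= start) & (df["pos"] <= end)]
    return df.reset_index(drop=True)


def write_eqtl(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in EQTL_COLUMNS + EQTL_OPTIONAL if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False)


def read_leads(path: str | Path,
               column_map: Mapping[str, str] | None = None,
               fdr_threshold: float | None = None) -> pd.DataFrame:
    """Read a lead cis-eQTL table (one row per gene: the gene's best variant).

    ``fdr_threshold`` keeps only genes whose study-level FDR is below it
    (the significance criterion for a gene to enter the analysis is FDR < 0.05).
    """
    df = _load_table(path, column_map, LEAD_COLUMNS, [])
    _check_numeric(df, path, ["pos", "fdr"])
    df["chrom"] = df["chrom"].map(_norm_chrom)
    df["pos"] = df["pos"].astype(np.int64)
    bad = df.index[~((df["fdr"] >= 0) & (df["fdr"] <= 1))]
    if len(bad):
        raise SumstatsFormatError(
            f"{path}: fdr outside [0, 1] at data row(s) {[int(i) + 1 for i in bad[:5]]}"
        )
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if len(dup):
        raise SumstatsFormatError(f"{path}: duplicate gene_id(s): {sorted(set(dup))[:5]}")
    if fdr_threshold is not None:
        df = df[df["fdr"] < fdr_threshold]
    return df.reset_index(drop=True)


def write_leads(df: pd.DataFrame, path: str | Path) -> None:
    df[LEAD_COLUMNS].to_csv(path, sep="\t", index=False)


def read_guide_counts(path: str | Path) -> pd.DataFrame:
    """Read a guide-level count table.

    Expected columns: ``guide_id``, ``gene_id``, then one integer column per
    sample.  Sample labels conventionally carry a condition tag (``control`` /
    ``infected``) and, for multi-arm screens, an MOI tag (``low`` / ``high``),
    e.g. ``infected_low_1``.  Returns a DataFrame indexed by ``guide_id`` with
    ``gene_id`` first and count columns after.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("guide_id", "gene_id"):
        if col not in df.columns:
            raise SumstatsFormatError(f"{path}: missing column {col!r}")
    dup = df["guide_id"][df["guide_id"].duplicated()]
    if len(dup):
        raise SumstatsFormatError(f"{path}: duplicate guide_id(s): {sorted(set(dup))[:5]}")
    sample_cols = [c for c in df.columns if c not in ("guide_id", "gene_id")]
    if not sample_cols:
        raise SumstatsFormatError(f"{path}: no sample columns")
    counts = df[sample_cols].to_numpy()
    if not np.issubdtype(counts.dtype, np.number) or np.any(counts != np.floor(counts)):
        raise SumstatsFormatError(f"{path}: counts must be integers")
    if np.any(counts < 0):
        raise SumstatsFormatError(f"{path}: counts must be non-negative")
    out = df.set_index("guide_id")
    out[sample_cols] = out[sample_cols].astype(np.int64)
    return out


def write_guide_counts(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=True, index_label="guide_id")


@dataclasses.dataclass
class DosagePanel:
    """Genotype dosages for a variant panel: ``dosages[i, j]`` is the expected
    alternate-allele count (in [0, 2]) of variant i in individual j."""

    variants: list[VariantKey]
    dosages: np.ndarray  # (n_variants, n_individuals)
    samples: list[str]
    populations: list[str] | None = None  # per-individual ancestry label

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.variants), len(self.samples)):
            raise ValueError("dosage matrix shape does not match variants x samples")
        if np.any((self.dosages < 0) | (self.dosages > 2)):
            raise SumstatsFormatError("dosages must lie in [0, 2]")
        if self.populations is not None and len(self.populations) != len(self.samples):
            raise ValueError("one population label per individual required")


def read_dosages(path: str | Path) -> DosagePanel:
    """Read a variant × individual dosage matrix from TSV.

    Columns: ``chrom``, ``pos``, ``ref``, ``alt``, then one column per
    individual.  An optional ``#population`` comment line directly under the
    header assigns a population label to each individual column.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        second = fh.readline()
    populations = None
    skiprows = [0]
    if second.startswith("#population"):
        populations = second.rstrip("\n").split("\t")[4:]
        skiprows = [0, 1]
    df = pd.read_csv(path, sep="\t", names=header, skiprows=skiprows,
                     dtype={"chrom": str})
    for col in ("chrom", "pos", "ref", "alt"):
        if col not in df.columns:
            raise SumstatsFormatError(f"{path}: missing column {col!r}")
    samples = [c for c in df.columns if c not in ("chrom", "pos", "ref", "alt")]
    variants = [VariantKey(r.chrom, int(r.pos), r.ref, r.alt)
                for r in df.itertuples(index=False)]
    dosages = df[samples].to_numpy(dtype=float)
    if np.any((dosages < 0) | (dosages > 2)):
        bad = np.argwhere((dosages < 0) | (dosages > 2))[0]
        raise SumstatsFormatError(
            f"{path}: dosage outside [0, 2] at variant row {bad[0] + 1}, "
            f"sample {samples[bad[1]]!r}"
        )
    return DosagePanel(variants, dosages, samples, populations)


def write_dosages(panel: DosagePanel, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(["chrom", "pos", "ref", "alt"] + panel.samples) + "\n")
        if panel.populations is not None:
            fh.write("\t".join(["#population", "", "", ""] + panel.populations) + "\n")
        for v, row in zip(panel.variants, panel.dosages):
            vals = "\t".join(format(x, ".17g") for x in row)
            fh.write(f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{vals}\n")


def read_dosages_vcf(path: str | Path) -> DosagePanel:
    """Read dosages from a VCF (DS field if present, else GT allele counts).

    Requires the optional ``cyvcf2`` dependency.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("VCF ingestion requires cyvcf2 (pip install crisprqtl[vcf])") from exc
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variants: list[VariantKey] = []
    rows = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            continue  # biallelic panel only
        variants.append(VariantKey(rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
        try:
            ds = np.asarray(rec.format("DS"), dtype=float).ravel()
        except (KeyError, TypeError, ValueError):
            gt = np.asarray(rec.genotype.array())[:, :2]
            ds = np.clip(gt, 0, 1).sum(axis=1).astype(float)
        rows.append(ds)
    return DosagePanel(variants, np.asarray(rows, dtype=float), samples)


_AMBIGUOUS = {frozenset({"A", "T"}), frozenset({"C", "G"})}


def harmonize_to_reference(df: pd.DataFrame,
                           reference: pd.DataFrame) -> tuple[pd.DataFrame, int, int]:
    """Align a summary-statistic table's alleles to a reference table.

    Rows sharing ``chrom:pos`` with the reference but carrying swapped
    ref/alt alleles are flipped: beta changes sign and, when present, the
    effect-allele frequency becomes ``1 - eaf``.  Swapped rows whose allele
    pair is strand-ambiguous (A/T or C/G) cannot be distinguished from a
    strand flip and are dropped.  Rows whose alleles match neither orientation
    are dropped.  Rows at positions absent from the reference pass through
    unchanged.

    Returns ``(harmonized, n_flipped, n_dropped)``.
    """
    ref_alleles = {(c, p): (r, a) for c, p, r, a in
                   zip(reference["chrom"], reference["pos"],
                       reference["ref"], reference["alt"])}
    keep = np.ones(len(df), dtype=bool)
    flip = np.zeros(len(df), dtype=bool)
    for i, (c, p, r, a) in enumerate(zip(df["chrom"], df["pos"], df["ref"], df["alt"])):
        ra = ref_alleles.get((c, p))
        if ra is None or ra == (r, a):
            continue
        if ra == (a, r):
            if frozenset({r, a}) in _AMBIGUOUS:
                keep[i] = False
            else:
                flip[i] = True
        else:
            keep[i] = False
    out = df.copy()
    if flip.any():
        out.loc[flip, ["ref", "alt"]] = out.loc[flip, ["alt", "ref"]].to_numpy()
        out.loc[flip, "beta"] = -out.loc[flip, "beta"]
        if "eaf" in out.columns:
            out.loc[flip, "eaf"] = 1.0 - out.loc[flip, "eaf"]
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("harmonization dropped %d row(s) with unresolvable alleles", n_dropped)
    out = out[keep].reset_index(drop=True)
    return out, int(flip.sum()), n_dropped
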