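"""End-to-end demo pipeline on synthetic data.

``run_demo`` exercises every stage — screen simulation and ranking,
inflation testing, scenario simulation, eligibility filtering,
colocalization (single and masked), and locus prioritization — writing all
intermediate and final artifacts plus a content-hash manifest.  Everything
is a pure function of the seed, so two runs with the same seed produce
byte-identical artifacts.

The synthetic locus mirrors the structure of a real triage: a lead GWAS
variant inside an LD block; one gene whose cis-eQTL shares the causal
variant with the GWAS (the colocalizing candidate), one gene with a distinct
causal variant (high eQTL signal, no shared cause), and null genes; plus a
genome-wide background of lead cis-eQTLs in which the screen's top genes
carry inflated GWAS signal.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import defaults
from .sumstats_io import VariantKey, write_gwas, write_eqtl, write_guide_counts, write_leads
from .screen_rank import normalize_counts, guide_log2fc, score_genes
from .inflation import InflationConfig, permutation_inflation_test
from .coloc import (AbfDataset, ColocPriors, coloc_single, coloc_masked,
                    eligibility_filter, region_subset)
from .prioritize import ld_r2, lead_variant_pvalues, build_priority_table, regional_plot_data
from .simulate import (LdBlockSpec, ScenarioSpec, ScreenSpec,
                       simulate_genotypes, simulate_trait_pair,
                       simulate_screen_counts, simulate_inflation_background)

__all__ = ["run_demo"]

# demo problem sizes: large enough for clear scenario recovery, small enough
# for a single-CPU run in well under five minutes
_DEMO = {
    "screen_n_genes": 1000,
    "screen_n_hits": 20,
    "bg_n_genes": 9557,   # background lead-eQTL genes
    "bg_n_target": 364,   # target leads matched to the GWAS
    "bg_lambda": 1.78,    # target-set inflation of the synthetic background
    "inflation_k": 10_000,
    "ld_n_individuals": 2000,
    "ld_n_variants": 200,
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _rank_series(scores: pd.DataFrame) -> pd.Series:
    return scores["rank_sbscore"]


def run_demo(out_dir: str | Path, seed: int = 0) -> dict:
    """Run the full synthetic triage pipeline; return the artifact manifest.

    Writes TSV/JSON artifacts under ``out_dir`` and a ``manifest.json``
    listing every file with its sha256 content hash alongside the resolved
    configuration.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_seeds = np.random.SeedSequence(seed).generate_state(8) % (2**31)
    files: dict[str, Path] = {}

    # --- 1. pooled CRISPR screen, low- and high-MOI arms -------------------
    hit_genes = tuple(f"GENE{i + 1:05d}" for i in range(_DEMO["screen_n_hits"]))
    arms = {}
    for arm, s in (("low", rng_seeds[0]), ("high", rng_seeds[1])):
        spec = ScreenSpec(n_genes=_DEMO["screen_n_genes"], hit_genes=hit_genes,
                          seed=int(s))
        counts, _ = simulate_screen_counts(spec)
        write_guide_counts(counts, out / f"screen_counts_{arm}_moi.tsv")
        files[f"screen_counts_{arm}_moi"] = out / f"screen_counts_{arm}_moi.tsv"
        norm = normalize_counts(counts)
        ctl = [c for c in norm.columns if c.startswith("control")]
        inf = [c for c in norm.columns if c.startswith("infected")]
        lfc = guide_log2fc(norm[inf], norm[ctl])
        scores, _ = score_genes(lfc, counts["gene_id"])
        scores.to_csv(out / f"screen_scores_{arm}_moi.tsv", sep="\t")
        files[f"screen_scores_{arm}_moi"] = out / f"screen_scores_{arm}_moi.tsv"
        arms[arm] = scores

    # --- 2. inflation of GWAS signal at lead cis-eQTLs ---------------------
    leads, target_genes, bg_gwas = simulate_inflation_background(
        n_genes=_DEMO["bg_n_genes"], n_target=_DEMO["bg_n_target"],
        target_lambda_multiplier=_DEMO["bg_lambda"], seed=int(rng_seeds[2]))
    write_leads(leads, out / "background_leads.tsv")
    files["background_leads"] = out / "background_leads.tsv"
    target_leads = leads[leads["gene_id"].isin(target_genes)]
    infl = permutation_inflation_test(
        target_leads, leads, bg_gwas,
        InflationConfig(q=defaults.LAMBDA_Q, k=_DEMO["inflation_k"],
                        seed=int(rng_seeds[3])))
    infl.to_json(out / "inflation.json")
    files["inflation"] = out / "inflation.json"

    # --- 3. locus scenarios and colocalization -----------------------------
    block = simulate_genotypes(LdBlockSpec(
        n_individuals=_DEMO["ld_n_individuals"],
        n_variants=_DEMO["ld_n_variants"], seed=int(rng_seeds[4])))
    lead_idx = _DEMO["ld_n_variants"] // 2
    lead_variant = block.variants[lead_idx]
    # distinct-scenario causal variant: near enough to keep the gene eligible
    # (strong eQTL signal within 100 kb of the lead) yet in low LD with it
    distinct_idx = min(lead_idx + 30, _DEMO["ld_n_variants"] - 1)

    gene_shared = "GENE00001"    # a planted screen hit: the triage candidate
    gene_distinct = "GENE00500"
    gene_null = "GENE00600"
    locus_genes = [gene_shared, gene_distinct, gene_null]

    gwas, eqtl_shared, _ = simulate_trait_pair(block, ScenarioSpec(
        scenario="shared", causal_index_1=lead_idx, causal_index_2=lead_idx,
        seed=int(rng_seeds[5])))
    _, eqtl_distinct, _ = simulate_trait_pair(block, ScenarioSpec(
        scenario="distinct", causal_index_1=lead_idx, causal_index_2=distinct_idx,
        seed=int(rng_seeds[6])))
    _, eqtl_null, _ = simulate_trait_pair(block, ScenarioSpec(
        scenario="null", seed=int(rng_seeds[7])))
    eqtl_shared["gene_id"] = gene_shared
    eqtl_distinct["gene_id"] = gene_distinct
    eqtl_null["gene_id"] = gene_null

    write_gwas(gwas, out / "gwas_locus.tsv")
    files["gwas_locus"] = out / "gwas_locus.tsv"
    datasets = {
        "cell_type_A": pd.concat([eqtl_shared, eqtl_null], ignore_index=True),
        "cell_type_B": eqtl_distinct,
    }
    for name, df in datasets.items():
        write_eqtl(df, out / f"eqtl_{name}.tsv")
        files[f"eqtl_{name}"] = out / f"eqtl_{name}.tsv"

    priors = ColocPriors(defaults.PRIOR_P1, defaults.PRIOR_P2, defaults.PRIOR_P12)
    gwas_region = region_subset(gwas, lead_variant, defaults.REGION_HALFWIDTH)
    ds_gwas = AbfDataset.from_sumstats(gwas_region.dropna(subset=["beta"]),
                                       trait_type="cc")
    coloc_pp4: dict[tuple[str, str], float] = {}
    for name, df in datasets.items():
        eligible = eligibility_filter(df, lead_variant,
                                      defaults.ELIGIBILITY_WINDOW,
                                      defaults.ELIGIBILITY_P)
        for gene in eligible:
            sub = region_subset(df[df["gene_id"] == gene], lead_variant,
                                defaults.REGION_HALFWIDTH).dropna(subset=["beta"])
            ds_eqtl = AbfDataset.from_sumstats(sub, trait_type="quant", sdY=1.0)
            res = coloc_single(ds_gwas, ds_eqtl, priors)
            res.to_json(out / f"coloc_{gene}_{name}.json")
            files[f"coloc_{gene}_{name}"] = out / f"coloc_{gene}_{name}.json"
            coloc_pp4[(gene, name)] = res.pp4

    # masked mode on the shared-scenario eQTL (LD from the simulated panel)
    ld = ld_r2(block.dosages, block.variants)
    ds_shared = AbfDataset.from_sumstats(
        eqtl_shared.dropna(subset=["beta"]), trait_type="quant")
    masked = coloc_masked(ds_shared, ds_gwas, ld, priors,
                          p_thresh=defaults.MASK_P_THRESHOLD,
                          r2_thresh=defaults.MASK_R2_THRESHOLD,
                          max_signals=defaults.MASK_MAX_SIGNALS)
    masked.to_json(out / "coloc_masked_shared.json")
    files["coloc_masked_shared"] = out / "coloc_masked_shared.json"

    # --- 4. integrated prioritization table --------------------------------
    ptable, highlight = lead_variant_pvalues(datasets, lead_variant, locus_genes,
                                             highlight_p=defaults.ELIGIBILITY_P)
    priority = build_priority_table(
        ptable,
        screen_ranks_low=_rank_series(arms["low"]),
        screen_ranks_high=_rank_series(arms["high"]),
        coloc_results=coloc_pp4,
        gene_order=locus_genes,
        pp4_flag_threshold=defaults.PP4_FLAG_THRESHOLD)
    priority.to_csv(out / "priority_table.tsv", sep="\t", index=False, na_rep="NA")
    files["priority_table"] = out / "priority_table.tsv"

    plot = regional_plot_data(gwas_region, ld, lead_variant)
    plot.to_csv(out / "regional_plot_data.tsv", sep="\t", index=False, na_rep="NA")
    files["regional_plot_data"] = out / "regional_plot_data.tsv"

    # --- 5. manifest --------------------------------------------------------
    from . import __version__
    manifest = {
        "tool": "crisprqtl",
        "version": __version__,
        "seed": int(seed),
        "config": {
            "lambda_q": defaults.LAMBDA_Q,
            "inflation_k": _DEMO["inflation_k"],
            "priors": {"p1": priors.p1, "p2": priors.p2, "p12": priors.p12},
            "region_halfwidth": defaults.REGION_HALFWIDTH,
            "eligibility": {"window": defaults.ELIGIBILITY_WINDOW,
                            "p": defaults.ELIGIBILITY_P},
            "mask": {"r2": defaults.MASK_R2_THRESHOLD,
                     "p": defaults.MASK_P_THRESHOLD,
                     "max_signals": defaults.MASK_MAX_SIGNALS},
            "pp4_flag": defaults.PP4_FLAG_THRESHOLD,
            "problem_sizes": dict(_DEMO),
            "lead_variant": lead_variant.id,
            "highlighted_datasets": sorted(highlight),
        },
        "artifacts": {name: {"path": p.name, "sha256": _sha256(p)}
                      for name, p in sorted(files.items())},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
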