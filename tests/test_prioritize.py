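"""LD utilities and the integrated prioritization table: correlation
oracles, weighted averaging with missingness, join semantics and ordering."""

import numpy as np
import pandas as pd
import pytest

from crisprqtl.prioritize import (
    LdMatrix,
    build_priority_table,
    ld_r2,
    lead_variant_pvalues,
    read_genes_bed,
    regional_plot_data,
    weighted_r2,
)
from crisprqtl.sumstats_io import VariantKey
from conftest import make_gwas_frame


def _variants(n):
    return [VariantKey("3", 1000 + 10 * i, "A", "G") for i in range(n)]


class TestLdR2:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, size=(3, 50)).astype(float)
        ld = ld_r2(d, _variants(3))
        np.testing.assert_allclose(np.diag(ld.r2), 1.0, atol=1e-12)

    def test_perfect_and_independent_pairs(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 3, size=1000).astype(float)
        b = rng.integers(0, 3, size=1000).astype(float)  # independent of a
        ld = ld_r2(np.vstack([a, 2 - a, b]), _variants(3))
        assert ld.r2[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert ld.r2[0, 2] < 0.05

    def test_matches_covariance_formula_oracle(self):
        rng = np.random.default_rng(2)
        d = rng.uniform(0, 2, size=(5, 20))
        ld = ld_r2(d, _variants(5))
        for i in range(5):
            for j in range(5):
                cov = np.cov(d[i], d[j])
                expect = cov[0, 1] ** 2 / (cov[0, 0] * cov[1, 1])
                assert ld.r2[i, j] == pytest.approx(expect, abs=1e-12)

    def test_monomorphic_flagged_not_fatal(self):
        d = np.vstack([np.zeros(10), np.arange(10, dtype=float) % 3])
        ld = ld_r2(d, _variants(2))
        assert ld.monomorphic == [_variants(2)[0].id]
        assert np.isnan(ld.r2[0, 1])
        assert ld.r2[1, 1] == 1.0

    def test_submatrix_missing_variant_raises(self):
        ld = ld_r2(np.random.default_rng(3).uniform(0, 2, (2, 10)), _variants(2))
        with pytest.raises(KeyError):
            ld.submatrix([VariantKey("9", 1, "A", "G")])


class TestWeightedR2:
    def test_single_population_identity(self):
        m = LdMatrix(_variants(2), np.array([[1.0, 0.3], [0.3, 1.0]]))
        out = weighted_r2([m], [7.0])
        np.testing.assert_allclose(out.r2, m.r2)

    def test_weighted_mean_arithmetic(self):
        a = LdMatrix(_variants(2), np.array([[1.0, 0.8], [0.8, 1.0]]))
        b = LdMatrix(_variants(2), np.array([[1.0, 0.4], [0.4, 1.0]]))
        out = weighted_r2([a, b], [3.0, 1.0])
        assert out.r2[0, 1] == pytest.approx(0.7)

    def test_missing_entries_renormalize_pairwise(self):
        a = LdMatrix(_variants(2), np.array([[1.0, np.nan], [np.nan, 1.0]]),
                     monomorphic=[])
        b = LdMatrix(_variants(2), np.array([[1.0, 0.4], [0.4, 1.0]]))
        out = weighted_r2([a, b], [3.0, 1.0])
        assert out.r2[0, 1] == pytest.approx(0.4)  # only b contributes

    def test_bounded_by_inputs_elementwise(self):
        rng = np.random.default_rng(4)
        mats = [LdMatrix(_variants(3), _sym(rng)) for _ in range(3)]
        out = weighted_r2(mats, [1.0, 2.0, 3.0])
        stack = np.stack([m.r2 for m in mats])
        assert (out.r2 >= stack.min(axis=0) - 1e-12).all()
        assert (out.r2 <= stack.max(axis=0) + 1e-12).all()
        assert ((out.r2 >= 0) & (out.r2 <= 1)).all()

    def test_elementwise_oracle(self):
        rng = np.random.default_rng(5)
        mats = [LdMatrix(_variants(4), _sym(rng, 4)) for _ in range(2)]
        w = [2.0, 5.0]
        out = weighted_r2(mats, w)
        expect = (2 * mats[0].r2 + 5 * mats[1].r2) / 7
        np.testing.assert_allclose(out.r2, expect, atol=1e-12)

    def test_mismatched_panels_rejected(self):
        a = LdMatrix(_variants(2), np.eye(2))
        b = LdMatrix([VariantKey("9", 5, "A", "G"), _variants(2)[1]], np.eye(2))
        with pytest.raises(ValueError, match="panel"):
            weighted_r2([a, b], [1.0, 1.0])


def _sym(rng, n=3):
    a = rng.uniform(0, 1, size=(n, n))
    m = (a + a.T) / 2
    np.fill_diagonal(m, 1.0)
    return m


def _eqtl_dataset(gene_ps: dict, lead: VariantKey, seed=0):
    """One dataset: per gene a row at the lead variant plus noise rows."""
    rows = []
    for g, p in gene_ps.items():
        rows.append(dict(gene_id=g, chrom=lead.chrom, pos=lead.pos,
                         ref=lead.ref, alt=lead.alt, beta=0.1, se=0.1, pvalue=p))
    rng = np.random.default_rng(seed)
    for g in gene_ps:
        rows.append(dict(gene_id=g, chrom=lead.chrom, pos=lead.pos + 500,
                         ref="A", alt="G", beta=0.1, se=0.1,
                         pvalue=rng.uniform()))
    return pd.DataFrame(rows)


LEAD = VariantKey("3", 45_823_240, "T", "C")


class TestLeadVariantPvalues:
    def test_highlight_and_ranking_rule(self):
        ds = {"d1": _eqtl_dataset({"A": 1e-5, "B": 0.3}, LEAD)}
        table, highlight = lead_variant_pvalues(ds, LEAD, ["A", "B"])
        assert highlight == {"d1"}
        assert table.loc["A", "d1"] < table.loc["B", "d1"]

    def test_lead_absent_column_missing_not_highlighted(self):
        present = _eqtl_dataset({"A": 1e-6}, LEAD)
        absent = _eqtl_dataset({"A": 1e-9}, LEAD)
        absent = absent[absent["pos"] != LEAD.pos]  # drop the lead rows
        table, highlight = lead_variant_pvalues(
            {"d1": present, "d2": absent}, LEAD, ["A"])
        assert np.isnan(table.loc["A", "d2"])
        assert highlight == {"d1"}

    def test_absent_everywhere_rejected(self):
        ds = _eqtl_dataset({"A": 0.5}, LEAD)
        ds = ds[ds["pos"] != LEAD.pos]
        with pytest.raises(ValueError, match="absent from every dataset"):
            lead_variant_pvalues({"d1": ds}, LEAD, ["A"])

    def test_matches_scan_oracle(self):
        rng = np.random.default_rng(7)
        genes = [f"G{i}" for i in range(6)]
        datasets = {
            f"d{k}": _eqtl_dataset(
                {g: 10.0 ** rng.uniform(-6, 0) for g in genes}, LEAD, seed=k)
            for k in range(4)
        }
        table, highlight = lead_variant_pvalues(datasets, LEAD, genes)
        for name, df in datasets.items():
            at_lead = df[(df["pos"] == LEAD.pos) & (df["ref"] == LEAD.ref)]
            expect_hl = (at_lead["pvalue"] < 1e-4).any()
            assert (name in highlight) == expect_hl
            for g in genes:
                expect = at_lead.loc[at_lead["gene_id"] == g, "pvalue"]
                assert table.loc[g, name] == pytest.approx(float(expect.iloc[0]))


class TestPriorityTable:
    @staticmethod
    def _ptable(genes=8, datasets=2, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            rng.uniform(size=(genes, datasets)),
            index=pd.Index([f"G{i}" for i in range(genes)], name="gene_id"),
            columns=[f"d{k}" for k in range(datasets)],
        )

    def test_join_cardinality(self):
        pt = self._ptable()
        coloc = {("G0", "d0"): 0.9, ("G1", "d1"): 0.2, ("G3", "d0"): 0.7}
        out = build_priority_table(pt, coloc_results=coloc)
        assert len(out) == 16
        assert out["pp4"].notna().sum() == 3
        assert out["coloc_flag"].sum() == 2  # 0.9 and 0.7 exceed 0.5

    def test_empty_coloc_all_flags_false(self):
        out = build_priority_table(self._ptable())
        assert not out["coloc_flag"].any()

    def test_duplicate_coloc_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_priority_table(
                self._ptable(),
                coloc_results=[("G0", "d0", 0.9), ("G0", "d0", 0.1)])

    def test_deterministic_order_and_input_order_independence(self):
        pt = self._ptable(seed=1)
        order = [f"G{i}" for i in range(7, -1, -1)]
        a = build_priority_table(pt, coloc_results={("G2", "d1"): 0.8},
                                 gene_order=order)
        shuffled = pt[["d1", "d0"]].iloc[::-1]
        b = build_priority_table(shuffled, coloc_results={("G2", "d1"): 0.8},
                                 gene_order=order)
        pd.testing.assert_frame_equal(a, b)
        assert list(a["gene_id"][:2]) == ["G7", "G7"]
        assert list(a["dataset_id"][:2]) == ["d0", "d1"]

    def test_screen_ranks_attached_per_gene(self):
        pt = self._ptable(genes=3, datasets=1)
        low = pd.Series([5, 2, 9], index=["G0", "G1", "G2"])
        out = build_priority_table(pt, screen_ranks_low=low)
        assert list(out["rank_low_moi"]) == [5, 2, 9]
        assert out["rank_high_moi"].isna().all()


def test_read_genes_bed_converts_to_one_based(tmp_path):
    bed = tmp_path / "genes.bed"
    bed.write_text("chr3\t100\t200\tGENE_A\n3\t50\t80\tGENE_B\n")
    out = read_genes_bed(bed)
    assert list(out["gene_id"]) == ["GENE_B", "GENE_A"]  # position-sorted
    assert out.loc[out["gene_id"] == "GENE_A", "start"].iloc[0] == 101
    assert out.loc[out["gene_id"] == "GENE_A", "end"].iloc[0] == 200


def test_regional_plot_data_aligns_r2(small_block):
    gwas = make_gwas_frame(n=5)
    gwas[["chrom", "pos", "ref", "alt"]] = pd.DataFrame(
        [(v.chrom, v.pos, v.ref, v.alt) for v in small_block.variants[:5]])
    ld = ld_r2(small_block.dosages, small_block.variants)
    out = regional_plot_data(gwas, ld, small_block.variants[0])
    assert out.loc[0, "r2_lead"] == pytest.approx(1.0)
    assert len(out) == 5
    assert np.allclose(out["neglog10_p"], -np.log10(gwas["pvalue"]))
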