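"""Colocalization engine: Bayes-factor arithmetic against scalar and
long-double direct-summation oracles, posterior invariants, eligibility and
region windows, and LD-masked multi-signal analysis."""

import numpy as np
import pandas as pd
import pytest

from crisprqtl.coloc import (
    AbfDataset,
    ColocPriors,
    coloc_masked,
    coloc_single,
    compute_labf,
    eligibility_filter,
    estimate_sdY,
    find_signals_masked,
    region_subset,
)
from crisprqtl.prioritize import LdMatrix, ld_r2
from crisprqtl.simulate import (
    LdBlockSpec,
    ScenarioSpec,
    marginal_sumstats,
    simulate_genotypes,
    simulate_trait_pair,
)
from crisprqtl.sumstats_io import VariantKey
from conftest import make_gwas_frame


def _variants(n, chrom="3", start=1000, step=10):
    return [VariantKey(chrom, start + i * step, "A", "G") for i in range(n)]


def _dataset(labf, seed=0, **kw):
    labf = np.asarray(labf, dtype=float)
    rng = np.random.default_rng(seed)
    n = labf.size
    return AbfDataset(_variants(n), rng.normal(size=n),
                      rng.uniform(0.05, 0.2, size=n), labf, **kw)


def _random_pair(seed, n):
    rng = np.random.default_rng(seed)
    beta1, beta2 = rng.normal(0, 0.3, size=(2, n))
    se1, se2 = rng.uniform(0.05, 0.2, size=(2, n))
    v = _variants(n)
    ds1 = AbfDataset(v, beta1, se1, compute_labf(beta1, se1, 0.15))
    ds2 = AbfDataset(v, beta2, se2, compute_labf(beta2, se2, 0.2))
    return ds1, ds2


def direct_sum_posteriors(l1, l2, priors):
    """Naive long-double direct summation — the independent oracle."""
    b1 = np.exp(np.asarray(l1, dtype=np.longdouble))
    b2 = np.exp(np.asarray(l2, dtype=np.longdouble))
    s0 = np.longdouble(1.0)
    s1 = priors.p1 * b1.sum()
    s2 = priors.p2 * b2.sum()
    s4 = priors.p12 * (b1 * b2).sum()
    s3 = priors.p1 * priors.p2 * (b1.sum() * b2.sum() - (b1 * b2).sum())
    s = np.array([s0, s1, s2, max(s3, 0), s4], dtype=np.longdouble)
    return (s / s.sum()).astype(float)


class TestLabf:
    def test_null_effect_is_negative(self):
        r = 0.15**2 / (0.1**2 + 0.15**2)
        labf = compute_labf([0.0], [0.1], 0.15)
        assert labf[0] == pytest.approx(0.5 * np.log(1 - r))
        assert labf[0] < 0

    def test_scalar_re_derivation(self):
        labf = compute_labf([0.3], [0.1], 0.15)
        assert labf[0] == pytest.approx(2.526, abs=1e-3)

    def test_vanishing_prior_limit(self):
        labf = compute_labf(np.linspace(-1, 1, 9), np.full(9, 0.1), 1e-9)
        np.testing.assert_allclose(labf, 0.0, atol=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            compute_labf([1.0], [0.0], 0.15)
        with pytest.raises(ValueError):
            compute_labf([1.0], [0.1], 0.0)


class TestSdY:
    def test_exact_noiseless_inversion(self):
        rng = np.random.default_rng(0)
        maf = rng.uniform(0.05, 0.5, size=200)
        for sdy in (1.0, 2.0):
            vbeta = sdy**2 / (2 * 500 * maf * (1 - maf))
            assert estimate_sdY(vbeta, maf, 500) == pytest.approx(sdy, rel=1e-12)

    @pytest.mark.parametrize("sdy,lo,hi", [(1.0, 0.9, 1.1), (2.0, 1.8, 2.2)])
    def test_simulation_recovery(self, sdy, lo, hi):
        block = simulate_genotypes(LdBlockSpec(n_individuals=500, n_variants=200,
                                               rho=0.0, seed=3))
        rng = np.random.default_rng(4)
        y = sdy * rng.standard_normal(500)
        ss = marginal_sumstats(block, y, "quant").dropna(subset=["se"])
        est = estimate_sdY(ss["se"]**2, ss["maf"], 500)
        assert lo < est < hi

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            estimate_sdY([-1.0, 1.0], [0.2, 0.2], 100)
        with pytest.raises(ValueError, match="maf"):
            estimate_sdY([0.01, 0.01], [0.2, 0.7], 100)


class TestColocSingle:
    def test_hand_derived_single_variant_null(self):
        priors = ColocPriors(1e-4, 1e-4, 5e-6)
        ds = _dataset([0.0])
        res = coloc_single(ds, _dataset([0.0], seed=1), priors)
        assert res.pp0 == pytest.approx(1 / (1 + 1e-4 + 1e-4 + 5e-6), abs=1e-9)
        assert res.pp3 == 0.0
        assert res.pp4 == pytest.approx(4.999e-6, abs=1e-8)

    def test_strong_shared_variant_colocalizes(self):
        labf = np.zeros(100)
        labf[40] = 0.5 * 8.0**2  # z = 8 at one variant, same in both traits
        res = coloc_single(_dataset(labf), _dataset(labf, seed=1))
        assert res.pp4 > 0.99

    def test_trait_swap_symmetry(self):
        ds1, ds2 = _random_pair(2, 30)
        a = coloc_single(ds1, ds2)
        b = coloc_single(ds2, ds1)
        assert a.pp1 == pytest.approx(b.pp2, rel=1e-12)
        assert a.pp2 == pytest.approx(b.pp1, rel=1e-12)
        for h in ("pp0", "pp3", "pp4"):
            assert getattr(a, h) == pytest.approx(getattr(b, h), rel=1e-12)

    @pytest.mark.parametrize("seed,n", [(0, 2), (1, 10), (2, 50), (3, 37)])
    def test_matches_direct_sum_oracle(self, seed, n):
        ds1, ds2 = _random_pair(seed, n)
        res = coloc_single(ds1, ds2)
        expect = direct_sum_posteriors(ds1.labf, ds2.labf, ColocPriors())
        got = [res.pp0, res.pp1, res.pp2, res.pp3, res.pp4]
        np.testing.assert_allclose(got, expect, atol=1e-10)

    def test_posteriors_normalized(self):
        for seed in range(5):
            ds1, ds2 = _random_pair(seed + 50, 25)
            r = coloc_single(ds1, ds2)
            assert abs(r.pp0 + r.pp1 + r.pp2 + r.pp3 + r.pp4 - 1) < 1e-12

    def test_prior_monotonicity_in_p12(self):
        ds1, ds2 = _random_pair(9, 40)
        pp4s = [coloc_single(ds1, ds2, ColocPriors(1e-4, 1e-4, p12)).pp4
                for p12 in (1e-7, 1e-6, 5e-6, 5e-5)]
        assert all(a <= b + 1e-15 for a, b in zip(pp4s, pp4s[1:]))

    def test_empty_intersection_rejected(self):
        ds1 = _dataset([1.0, 2.0])
        ds2 = AbfDataset(_variants(2, start=99_000), [0.1, 0.1], [0.1, 0.1],
                         [0.0, 0.0])
        with pytest.raises(ValueError, match="no shared variants"):
            coloc_single(ds1, ds2)

    def test_intersection_uses_shared_panel_only(self):
        ds1, ds2 = _random_pair(4, 30)
        sub2 = ds2.subset(np.arange(30) < 20)
        res = coloc_single(ds1, sub2)
        assert res.n_variants == 20
        expect = direct_sum_posteriors(ds1.labf[:20], sub2.labf, ColocPriors())
        np.testing.assert_allclose([res.pp0, res.pp1, res.pp2, res.pp3, res.pp4],
                                   expect, atol=1e-10)


class TestWindows:
    def test_eligibility_boundary_inclusive(self):
        lead = VariantKey("3", 45_823_240, "T", "C")
        eqtl = pd.DataFrame({
            "gene_id": ["A", "B"],
            "chrom": ["3", "3"],
            "pos": [lead.pos + 100_000, lead.pos + 100_001],
            "ref": "A", "alt": "G", "beta": 0.1, "se": 0.1,
            "pvalue": [9.9e-5, 1e-6],
        })
        assert eligibility_filter(eqtl, lead) == ["A"]

    def test_eligibility_matches_linear_scan(self):
        rng = np.random.default_rng(1)
        lead = VariantKey("3", 45_823_240, "T", "C")
        n = 200
        eqtl = pd.DataFrame({
            "gene_id": rng.choice([f"G{i}" for i in range(10)], size=n),
            "chrom": "3",
            "pos": lead.pos + rng.integers(-300_000, 300_000, size=n),
            "ref": "A", "alt": "G", "beta": 0.1, "se": 0.1,
            "pvalue": 10.0 ** rng.uniform(-8, 0, size=n),
        })
        got = eligibility_filter(eqtl, lead)
        expect = sorted({r.gene_id for r in eqtl.itertuples()
                         if abs(r.pos - lead.pos) <= 100_000 and r.pvalue < 1e-4})
        assert got == expect

    def test_region_subset_closed_interval(self):
        gwas = make_gwas_frame(n=11, start=1_000_000, step=100)
        center = VariantKey("3", 1_000_500, "A", "G")
        out = region_subset(gwas, center, halfwidth=200)
        assert out["pos"].min() == 1_000_300 and out["pos"].max() == 1_000_700
        with pytest.raises(ValueError):
            region_subset(gwas, center, halfwidth=0)


def _naive_find_signals(pvals, r2, p_thresh=1e-4, r2_thresh=0.01, max_signals=3):
    """Independent plain-loop implementation of iterative masking."""
    masked = [False] * len(pvals)
    leads = []
    while len(leads) < max_signals:
        best, best_p = None, p_thresh
        for i, p in enumerate(pvals):
            if not masked[i] and p < best_p:
                best, best_p = i, p
        if best is None:
            break
        leads.append(best)
        for j in range(len(pvals)):
            if r2[best][j] > r2_thresh or j == best:
                masked[j] = True
    return leads


class TestMasking:
    @staticmethod
    def _ds_with_p(pvals, seed=0):
        n = len(pvals)
        rng = np.random.default_rng(seed)
        return AbfDataset(_variants(n), rng.normal(size=n),
                          rng.uniform(0.05, 0.2, size=n),
                          rng.normal(size=n), pvalue=np.asarray(pvals, float))

    def test_total_ld_gives_single_lead(self):
        n = 6
        ds = self._ds_with_p([1e-8, 1e-6, 1e-5, 1e-7, 1e-6, 1e-5])
        ld = LdMatrix(ds.variants, np.full((n, n), 0.9) + 0.1 * np.eye(n))
        leads = find_signals_masked(ds, ld)
        assert leads == [ds.variants[0]]

    def test_two_independent_signals_in_p_order(self):
        n = 4
        r2 = np.eye(n)
        r2[0, 1] = r2[1, 0] = 0.9  # variants 0-1 linked; 2-3 independent
        r2[2, 3] = r2[3, 2] = 0.9
        ds = self._ds_with_p([1e-9, 1e-5, 1e-7, 0.5])
        ld = LdMatrix(ds.variants, r2)
        leads = find_signals_masked(ds, ld)
        assert leads == [ds.variants[0], ds.variants[2]]

    @pytest.mark.parametrize("seed", range(8))
    def test_greedy_matches_naive_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        a = rng.uniform(size=(n, n))
        r2 = np.clip((a + a.T) / 2, 0, 1)
        np.fill_diagonal(r2, 1.0)
        r2 = np.where(r2 < 0.5, 0.001, r2)  # mix of linked/unlinked pairs
        pvals = 10.0 ** rng.uniform(-9, -2, size=n)
        ds = self._ds_with_p(pvals, seed=seed)
        ld = LdMatrix(ds.variants, r2)
        got = [v.id for v in find_signals_masked(ds, ld)]
        expect = [ds.variants[i].id for i in _naive_find_signals(pvals, r2)]
        assert got == expect

    def test_leads_pairwise_independent(self):
        rng = np.random.default_rng(12)
        block = simulate_genotypes(LdBlockSpec(n_individuals=800, n_variants=60,
                                               seed=12))
        ld = ld_r2(block.dosages, block.variants)
        pvals = 10.0 ** rng.uniform(-8, -3, size=60)
        ds = AbfDataset(block.variants, rng.normal(size=60),
                        rng.uniform(0.05, 0.2, size=60), rng.normal(size=60),
                        pvalue=pvals)
        leads = find_signals_masked(ds, ld, p_thresh=1e-2, max_signals=3)
        sub = ld.submatrix(leads)
        off_diag = sub[~np.eye(len(leads), dtype=bool)]
        assert (off_diag <= 0.01).all()

    def test_missing_ld_variant_rejected(self):
        ds = self._ds_with_p([1e-8, 1e-5])
        ld = LdMatrix(ds.variants[:1], np.eye(1))
        with pytest.raises(KeyError, match="absent"):
            find_signals_masked(ds, ld)


def _two_signal_scenario(seed=0):
    """eQTL with two independent causal variants, the weaker one shared with
    the GWAS: single-mode PP4 is diluted, masking recovers it."""
    block = simulate_genotypes(LdBlockSpec(n_individuals=2000, n_variants=120,
                                           seed=seed))
    c_shared, c_extra = 30, 95  # far apart: r2 well below 0.01
    rng = np.random.default_rng(seed + 1)
    expr = (0.35 * block.dosages[c_shared] + 0.8 * block.dosages[c_extra]
            + rng.standard_normal(2000))
    expr = (expr - expr.mean()) / expr.std()
    eqtl = marginal_sumstats(block, expr, "quant")
    gwas_y = 0.6 * block.dosages[c_shared] + rng.standard_normal(2000)
    gwas = marginal_sumstats(block, gwas_y, "quant")
    ds_eqtl = AbfDataset.from_sumstats(eqtl, "quant")
    ds_gwas = AbfDataset.from_sumstats(gwas, "quant")
    ld = ld_r2(block.dosages, block.variants)
    return ds_eqtl, ds_gwas, ld


class TestColocMasked:
    def test_single_signal_reduces_to_coloc_single(self):
        block = simulate_genotypes(LdBlockSpec(n_individuals=1000, n_variants=80,
                                               seed=21))
        gwas, eqtl, _ = simulate_trait_pair(block, ScenarioSpec(
            scenario="shared", causal_index_1=40, causal_index_2=40, seed=21))
        ds_g = AbfDataset.from_sumstats(gwas, "cc")
        ds_e = AbfDataset.from_sumstats(eqtl, "quant")
        ld = ld_r2(block.dosages, block.variants)
        masked = coloc_masked(ds_e, ds_g, ld)
        single = coloc_single(ds_e, ds_g)
        assert len(masked.results) == 1
        assert masked.results[0].masked_variants == 0
        assert masked.max_pp4 == pytest.approx(single.pp4, rel=1e-12)

    def test_secondary_signal_recovered_by_masking(self):
        ds_eqtl, ds_gwas, ld = _two_signal_scenario(seed=31)
        single = coloc_single(ds_gwas, ds_eqtl)
        masked = coloc_masked(ds_eqtl, ds_gwas, ld)
        assert len(masked.results) >= 2
        assert masked.max_pp4 > 0.5
        assert masked.max_pp4 > single.pp4

    def test_variant_order_invariance(self):
        ds_eqtl, ds_gwas, ld = _two_signal_scenario(seed=32)
        perm = np.random.default_rng(0).permutation(len(ds_eqtl.variants))
        ds_p = AbfDataset([ds_eqtl.variants[i] for i in perm],
                          ds_eqtl.beta[perm], ds_eqtl.se[perm],
                          ds_eqtl.labf[perm], pvalue=ds_eqtl.pvalue[perm])
        a = coloc_masked(ds_eqtl, ds_gwas, ld)
        b = coloc_masked(ds_p, ds_gwas, ld)
        assert sorted(v.id for v in a.leads) == sorted(v.id for v in b.leads)
        assert a.max_pp4 == pytest.approx(b.max_pp4, rel=1e-9)


class TestPriors:
    @pytest.mark.parametrize("p1,p2,p12", [
        (1e-4, 1e-4, 2e-4),   # p12 > min(p1, p2)
        (1e-4, 1e-4, 0.0),    # p12 must be positive
        (0.5, 0.5, 0.1),      # total prior mass >= 1
    ])
    def test_invalid_priors_rejected(self, p1, p2, p12):
        with pytest.raises(ValueError):
            ColocPriors(p1, p2, p12)
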