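"""Pair enumeration, scans, FDR families, conditional adjustment, sharing."""

import numpy as np
import pandas as pd
import pytest

from mseqtl.eqtl_pipeline import (
    classify_attenuation,
    conditional_adjust,
    enumerate_cis_pairs,
    find_best_local_snp,
    run_eqtl_scan,
    run_interaction_scan,
    run_phenotype_scan,
    sharing_region_counts,
    summarize_sharing,
)
from mseqtl.containers import ExpressionSet, GenotypeTable
from mseqtl.ruv_core import bh_fdr
from mseqtl.synthetic_data import CohortConfig, annotate_genes, simulate_cohort


def _snps(rows):
    return pd.DataFrame(rows, columns=["snp_id", "chrom", "pos"]).set_index("snp_id")


def _genes(rows):
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "tss"]).set_index("gene_id")
    df["strand"] = "+"
    return df


class TestEnumerateCisPairs:
    def test_boundary_inclusive(self):
        snps = _snps([("s1", "chr1", 1_000_000)])
        genes = _genes([("g_in", "chr1", 500_000), ("g_out", "chr1", 1_500_001)])
        pairs = enumerate_cis_pairs(snps, genes)
        assert list(pairs.gene_id) == ["g_in"]
        assert pairs.distance.iloc[0] == 500_000

    def test_chromosome_mismatch_excluded(self):
        snps = _snps([("s1", "chr1", 1_000_000)])
        genes = _genes([("g", "chr2", 1_000_000)])
        assert enumerate_cis_pairs(snps, genes).empty

    def test_missing_tss_skipped(self, caplog):
        snps = _snps([("s1", "chr1", 1_000_000)])
        genes = _genes([("g1", "chr1", 900_000), ("g2", "chr1", np.nan)])
        pairs = enumerate_cis_pairs(snps, genes)
        assert list(pairs.gene_id) == ["g1"]

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(0)
        snps = _snps([(f"s{i}", f"chr{rng.integers(1, 4)}", int(rng.integers(1, 5_000_000)))
                      for i in range(20)])
        genes = _genes([(f"g{i}", f"chr{rng.integers(1, 4)}", int(rng.integers(1, 5_000_000)))
                        for i in range(100)])
        pairs = enumerate_cis_pairs(snps, genes, window=500_000)
        brute = {
            (s, g)
            for s, srow in snps.iterrows()
            for g, grow in genes.iterrows()
            if srow.chrom == grow.chrom and abs(grow.tss - srow.pos) <= 500_000
        }
        assert set(zip(pairs.snp_id, pairs.gene_id)) == brute
        assert len(pairs) == len(brute)


@pytest.fixture(scope="module")
def scanned(small_cohort):
    es = next(iter(small_cohort.expression.values()))
    return run_eqtl_scan(es, small_cohort.genotypes)


class TestEqtlScan:
    def test_sign_convention_positive_risk_effect(self, small_cohort, scanned):
        planted = small_cohort.truth.pair_effects
        additive = planted[(planted.beta_g > 0) & (planted.beta_gp == 0)]
        res = scanned.set_index(["snp_id", "gene_id"])
        signs = [np.sign(res.loc[(r.snp_id, r.gene_id)].beta) for r in additive.itertuples()]
        assert np.mean(np.asarray(signs) > 0) >= 0.9

    def test_q_is_bh_over_family(self, scanned):
        ok = scanned.p.notna()
        assert np.allclose(scanned.q[ok], bh_fdr(scanned.p[ok].to_numpy()), atol=1e-12)

    def test_deterministic_rerun(self, small_cohort, scanned):
        es = next(iter(small_cohort.expression.values()))
        again = run_eqtl_scan(es, small_cohort.genotypes)
        pd.testing.assert_frame_equal(scanned, again)

    def test_monomorphic_snp_reported_na(self, small_cohort):
        cohort = small_cohort
        es = next(iter(cohort.expression.values()))
        dosage = cohort.genotypes.dosage.copy()
        dosage.iloc[:, 2] = 0.0  # kill one SNP
        table = GenotypeTable(dosage, cohort.genotypes.snps.copy())
        res = run_eqtl_scan(es, table)
        dead = res[res.snp_id == dosage.columns[2]]
        if len(dead):
            assert dead.p.isna().all()
        alive = res[res.snp_id != dosage.columns[2]]
        assert alive.p.notna().all()


class TestInteractionScan:
    def test_eqtl_subset_family_restricts_pairs(self, small_cohort, scanned):
        es = next(iter(small_cohort.expression.values()))
        sub = run_interaction_scan(es, small_cohort.genotypes, family="eqtl_subset",
                                   eqtl_results=scanned)
        sig = set(map(tuple, scanned.loc[scanned.q < 0.05, ["snp_id", "gene_id"]].values))
        assert set(map(tuple, sub[["snp_id", "gene_id"]].values)) <= sig
        assert (sub.family_id == f"{es.cell_type}:eqtl_subset:GxP").all()

    def test_families_never_mixed(self, small_cohort, scanned):
        es = next(iter(small_cohort.expression.values()))
        full = run_interaction_scan(es, small_cohort.genotypes, family="all_pairs")
        assert full.family_id.nunique() == 1
        ok = full.p.notna()
        assert np.allclose(full.q[ok], bh_fdr(full.p[ok].to_numpy()), atol=1e-12)


class TestPhenotypeScan:
    def test_gene_families_nest(self, small_cohort):
        es = next(iter(small_cohort.expression.values()))
        near = run_phenotype_scan(es, small_cohort.genotypes, family="near_snp_genes")
        wide = run_phenotype_scan(es, family="transcriptome")
        assert set(near.gene_id) <= set(wide.gene_id)
        assert len(wide) == len(es.gene_ids)

    def test_log2_shift_backtransforms(self, small_cohort):
        """A planted +0.3 log2 case shift back-transforms to ~2^0.3 = 23%."""
        es = next(iter(small_cohort.expression.values()))
        res = run_phenotype_scan(es, family="transcriptome").set_index("gene_id")
        planted = small_cohort.truth.gene_info.query("beta_p != 0").index
        est = res.loc[planted, "beta"].mean()
        assert 2**est == pytest.approx(2**0.3, abs=0.04)


class TestBestLocalSnp:
    def test_single_snp_panel(self, small_cohort):
        cohort = small_cohort
        es = next(iter(cohort.expression.values()))
        planted = cohort.truth.pair_effects.iloc[0]
        panel = cohort.genotypes.subset_snps([planted.snp_id])
        snp, p = find_best_local_snp(planted.gene_id, es, panel)
        assert snp == planted.snp_id
        assert 0 < p <= 1

    def test_tie_broken_by_tss_distance(self):
        cfg = CohortConfig(n_snps=2, ld_pairs=[(0, 1, 1.0)], n_genes=60,
                           n_controls_genes=20, effect_grid=[0.6], effect_fraction=0.1,
                           missing_rate=0.0, seed=13)
        cohort = simulate_cohort(cfg)
        es = next(iter(cohort.expression.values()))
        gene = cohort.truth.pair_effects.iloc[0].gene_id
        snp, _ = find_best_local_snp(gene, es, cohort.genotypes)
        tss = es.genes.loc[gene, "tss"]
        dists = (cohort.genotypes.snps.pos - tss).abs()
        assert snp == dists.idxmin()  # duplicate dosages: nearer SNP wins

    def test_no_local_snp_returns_none(self, small_cohort):
        es = next(iter(small_cohort.expression.values()))
        ctl_gene = es.controls.index[es.controls][0]  # chrHK: no SNPs there
        snp, p = find_best_local_snp(ctl_gene, es, small_cohort.genotypes)
        assert snp is None and np.isnan(p)


class TestConditionalRule:
    @pytest.mark.parametrize(
        "unadj,adj,expected,reduction",
        [
            (1.0, 0.2, "attenuated_major", 0.8),
            (1.0, -0.1, "attenuated_major", None),
            (1.0, 0.5, "attenuated_minor", 0.5),
            (-0.8, -0.7, "attenuated_minor", 0.125),
        ],
    )
    def test_rule_application(self, unadj, adj, expected, reduction):
        cls, red = classify_attenuation(unadj, adj)
        assert cls == expected
        if reduction is None:
            assert red is None
        else:
            assert red == pytest.approx(reduction)

    def test_scale_invariance(self, small_cohort):
        cohort = small_cohort
        es = next(iter(cohort.expression.values()))
        planted = cohort.truth.pair_effects.iloc[0]
        rec1 = conditional_adjust(planted.snp_id, planted.gene_id, es, cohort.genotypes)
        scaled = ExpressionSet(values=es.values * 7.0, genes=es.genes, controls=es.controls,
                               samples=es.samples, cell_type=es.cell_type)
        rec2 = conditional_adjust(planted.snp_id, planted.gene_id, scaled, cohort.genotypes)
        assert rec1.attenuation_class == rec2.attenuation_class
        assert rec1.best_snp_id == rec2.best_snp_id

    def test_strong_proxy_shortcuts_to_lead_or_proxy(self):
        cfg = CohortConfig(n_snps=2, ld_pairs=[(0, 1, 1.0)], n_genes=60,
                           n_controls_genes=20, effect_grid=[0.6], effect_fraction=0.1,
                           missing_rate=0.0, seed=14)
        cohort = simulate_cohort(cfg)
        es = next(iter(cohort.expression.values()))
        planted = cohort.truth.pair_effects.iloc[0]
        rec = conditional_adjust(planted.snp_id, planted.gene_id, es, cohort.genotypes)
        assert rec.attenuation_class == "lead_or_proxy"


class TestSharing:
    def _results(self, cell, rows):
        df = pd.DataFrame(rows, columns=["snp_id", "gene_id", "beta", "p", "q"])
        df["cell_type"] = cell
        return df

    def test_specific_shared_and_discordant(self):
        mono = self._results("monocytes", [("s1", "gA", 1.0, 1e-8, 1e-6),
                                           ("s1", "gB", -0.5, 1e-4, 1e-3)])
        cd8 = self._results("cd8", [("s1", "gB", 0.6, 1e-5, 1e-4),
                                    ("s2", "gC", 0.3, 1e-3, 1e-2)])
        summary = summarize_sharing({"monocytes": mono, "cd8": cd8}).set_index("gene_id")
        assert summary.loc["gA", "cell_types"] == "monocytes"
        assert summary.loc["gC", "n_cell_types"] == 1
        assert summary.loc["gB", "n_cell_types"] == 2
        assert not summary.loc["gB", "concordant"]  # MANBA-style opposite signs
        counts = sharing_region_counts(summary.reset_index())
        assert counts["cd8,monocytes"] == 1

    def test_direction_from_most_significant_pair(self):
        mono = self._results("monocytes", [("s1", "gA", -1.0, 1e-9, 1e-8),
                                           ("s2", "gA", 0.2, 1e-3, 1e-2)])
        nk = self._results("nk", [("s1", "gA", -0.8, 1e-6, 1e-5)])
        summary = summarize_sharing({"monocytes": mono, "nk": nk}).set_index("gene_id")
        assert summary.loc["gA", "directions"] == "-,-"
        assert summary.loc["gA", "concordant"]

    def test_planted_shared_eqtl_concordant(self):
        cfg = CohortConfig(n_snps=8, n_genes=200, n_controls_genes=60, cis_fraction=0.7,
                           ld_pairs=[], effect_grid=[0.6], effect_fraction=0.15,
                           cell_types=("monocytes", "cd8"), seed=15)
        cohort = simulate_cohort(cfg)
        results = {
            cell: run_eqtl_scan(es, cohort.genotypes)
            for cell, es in cohort.expression.items()
        }
        summary = summarize_sharing(results)
        shared = summary[summary.n_cell_types == 2]
        assert len(shared) > 0
        assert shared.concordant.all()
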