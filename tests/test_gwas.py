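"""Association-engine contracts: closed-form OLS, null calibration, mixed-model
collapse, threshold formula, FDR, QTL merging and scan comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from funcgwas.genotypes import GenotypeMatrix
from funcgwas.gwas import (
    NoEffectiveSnpsError,
    compare_scans,
    fdr_adjust,
    genomic_inflation,
    merge_qtls,
    run_glm,
    run_mlm,
    significance_threshold,
)
from funcgwas.simulate import (
    SimConfig,
    simulate_genome,
    simulate_phenotype,
    simulate_population,
)
from funcgwas.structure import compute_kinship, compute_pca, filter_variants


def _matrix(dosage, pos=None, chrom=None):
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    pos = np.asarray(pos) if pos is not None else np.arange(1, m + 1) * 100
    chrom = (
        np.asarray(chrom, dtype=object) if chrom is not None
        else np.array(["chr1"] * m, dtype=object)
    )
    return GenotypeMatrix(
        accessions=[f"a{i:03d}" for i in range(n)],
        snp_ids=np.array([f"{c}_{p}" for c, p in zip(chrom, pos)], dtype=object),
        chrom=chrom, pos=pos,
        ref=np.array(["A"] * m, dtype=object),
        alt=np.array(["T"] * m, dtype=object),
        dosage=dosage,
    )


class TestGlm:
    def test_eight_accession_worked_example(self):
        """Simple regression against the closed-form OLS oracle computed here."""
        dosage = np.array([[0], [0], [0], [0], [2], [2], [2], [2]])
        y = np.array([1.0, 1.2, 0.9, 1.1, 3.0, 3.2, 2.9, 3.1])
        res = run_glm(_matrix(dosage), y)
        g = dosage[:, 0] / 2.0
        gc, yc = g - g.mean(), y - y.mean()
        beta = gc @ yc / (gc @ gc)
        resid = yc - beta * gc
        df = len(y) - 2
        se = np.sqrt((resid @ resid) / df / (gc @ gc))
        t = beta / se
        p = 2 * stats.t.sf(abs(t), df)
        row = res.table.iloc[0]
        assert row["beta"] == pytest.approx(beta, rel=1e-12)
        assert row["se"] == pytest.approx(se, rel=1e-12)
        assert row["t"] == pytest.approx(t, rel=1e-12)
        assert row["p"] == pytest.approx(p, rel=1e-10)

    def test_perfect_fit_is_guarded(self):
        dosage = np.array([[0], [0], [2], [2], [0], [2]])
        y = 2.0 + 1.5 * dosage[:, 0] / 2.0
        res = run_glm(_matrix(dosage), y)
        row = res.table.iloc[0]
        assert row["beta"] == pytest.approx(1.5, abs=1e-9)
        assert row["p"] <= 1e-12 and np.isfinite(row["neglog10p"])

    def test_null_pvalues_are_uniform(self):
        rng = np.random.default_rng(5)
        dosage = (rng.random((150, 2000)) < rng.uniform(0.1, 0.5, 2000)) * 2
        y = rng.normal(size=150)
        res = run_glm(_matrix(dosage), y)
        ks = stats.kstest(res.table["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_monomorphic_snp_is_skipped_with_reason(self):
        dosage = np.array([[0, 0], [0, 2], [0, 0], [0, 2]])
        res = run_glm(_matrix(dosage), np.array([1.0, 2.0, 1.5, 2.5]))
        assert len(res.table) == 1
        assert res.skipped and "monomorphic" in res.skipped[0][1]

    def test_missing_calls_are_dropped_casewise(self):
        rng = np.random.default_rng(9)
        dosage = ((rng.random((60, 1)) < 0.4) * 2).astype(np.int8)
        y = 1.0 + 0.8 * dosage[:, 0] / 2.0 + rng.normal(0, 0.3, 60)
        dosage_miss = dosage.copy()
        dosage_miss[:10, 0] = -1
        res = run_glm(_matrix(dosage_miss), y)
        oracle = run_glm(_matrix(dosage[10:]), y[10:])
        assert res.table.iloc[0]["beta"] == pytest.approx(
            oracle.table.iloc[0]["beta"], rel=1e-12
        )
        assert res.table.iloc[0]["p"] == pytest.approx(
            oracle.table.iloc[0]["p"], rel=1e-10
        )


class TestMlm:
    def test_identity_kinship_collapses_to_glm(self, small_study):
        gm, y = small_study["gm"], small_study["y"]
        pcs = compute_pca(filter_variants(gm), 3).pcs
        a = run_glm(gm, y, pcs).table
        b = run_mlm(gm, y, pcs, np.eye(gm.n_accessions)).table
        m = a.merge(b, on="snp_id")
        assert len(m) == len(a)
        assert np.abs(m["neglog10p_x"] - m["neglog10p_y"]).max() < 1e-6

    def test_full_compression_equals_uncompressed(self, small_study):
        gm, y = small_study["gm"], small_study["y"]
        sub = filter_variants(gm)
        pcs = compute_pca(sub, 3).pcs
        K = compute_kinship(sub)
        a = run_mlm(gm, y, pcs, K, compression_groups="none").table
        b = run_mlm(gm, y, pcs, K, compression_groups=gm.n_accessions).table
        np.testing.assert_allclose(
            a["neglog10p"].to_numpy(), b["neglog10p"].to_numpy(), rtol=0, atol=1e-10
        )

    def test_mixed_model_controls_structure_inflation(self):
        """Structured polygenic panel: MLM lambda near 1, naive GLM inflated."""
        cfg = SimConfig(n_chromosomes=1, chrom_length_bp=400_000, n_genes=40,
                        n_snps=2500, n_accessions_per_subpop=(120, 120), fst=0.3,
                        heritability=0.5, phenotype_skew=False, seed=17)
        genome = simulate_genome(cfg)
        gm, truth = simulate_population(cfg, genome)
        y = simulate_phenotype(gm, truth, cfg)["ML_cm"].to_numpy()
        sub = filter_variants(gm)
        pcs = compute_pca(sub, 3).pcs
        K = compute_kinship(sub)
        res = run_mlm(gm, y, pcs, K)
        lam = genomic_inflation(res.table["p"].to_numpy())
        assert 0.9 <= lam <= 1.1
        naive = run_glm(gm, y, None)
        assert genomic_inflation(naive.table["p"].to_numpy()) > 1.1

    def test_recovers_planted_effect(self, small_study):
        gm, y, truth = small_study["gm"], small_study["y"], small_study["truth"]
        sub = filter_variants(gm)
        res = run_mlm(gm, y, compute_pca(sub, 3).pcs, compute_kinship(sub))
        row = res.table[res.table["snp_id"] == truth.causal_ids[0]].iloc[0]
        assert row["beta"] == pytest.approx(4.0, abs=0.7)
        thr = significance_threshold(res.table["p"].to_numpy(), 0.01)
        assert row["neglog10p"] > thr

    def test_non_psd_kinship_raises(self):
        dosage = (np.random.default_rng(0).random((20, 50)) < 0.4) * 2
        K = -np.eye(20)
        with pytest.raises(ValueError, match="eigenvalue"):
            run_mlm(_matrix(dosage), np.random.default_rng(1).normal(size=20), None, K)


class TestThresholdAndFdr:
    @pytest.mark.parametrize(
        "m, expected",
        [(1, 2.0), (1000, 5.0), (50, -np.log10(0.01 / 50))],
    )
    def test_effective_count_formula(self, m, expected):
        """-log10(alpha / m) over the SNPs with p < alpha in the scan."""
        p = np.concatenate([np.full(m, 0.001), np.full(500, 0.5)])
        assert significance_threshold(p, 0.01) == pytest.approx(expected, abs=1e-9)

    def test_no_effective_snps(self):
        p = np.full(200, 0.5)
        with pytest.raises(NoEffectiveSnpsError):
            significance_threshold(p, 0.01)
        with pytest.warns(UserWarning, match="Bonferroni"):
            thr = significance_threshold(p, 0.01, fallback_bonferroni=True)
        assert thr == pytest.approx(-np.log10(0.01 / 200))

    def test_benjamini_hochberg_hand_example(self):
        np.testing.assert_allclose(
            fdr_adjust(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03]
        )
        np.testing.assert_allclose(fdr_adjust(np.array([0.2])), [0.2])
        np.testing.assert_allclose(fdr_adjust(np.ones(5)), np.ones(5))
        assert fdr_adjust(np.array([])).size == 0


class TestQtlMerging:
    def _sig(self, positions, values=None, chrom="chr1"):
        values = values if values is not None else np.full(len(positions), 6.0)
        return pd.DataFrame(
            {
                "chrom": [chrom] * len(positions),
                "pos": positions,
                "snp_id": [f"{chrom}_{p}" for p in positions],
                "neglog10p": values,
            }
        )

    def test_gap_rules(self):
        one = merge_qtls(self._sig([100_000, 250_000]))
        assert len(one) == 1 and (one[0].start, one[0].end) == (100_000, 250_000)
        two = merge_qtls(self._sig([100_000, 300_000]))
        assert len(two) == 2

    def test_transitive_chaining(self):
        qtls = merge_qtls(self._sig([0 + 1, 160_000, 320_000]))
        assert len(qtls) == 1 and len(qtls[0].snp_ids) == 3

    def test_single_snp_and_empty(self):
        qtls = merge_qtls(self._sig([5_000]))
        assert len(qtls) == 1 and qtls[0].start == qtls[0].end
        assert merge_qtls(self._sig([])) == []

    def test_peak_tie_breaks_to_smaller_position(self):
        qtls = merge_qtls(self._sig([1000, 2000], values=[7.0, 7.0]))
        assert qtls[0].peak_pos == 1000

    def test_compare_scans_identity_and_disjoint(self):
        qtls = merge_qtls(self._sig([1000, 400_000]))
        rep = compare_scans(qtls, qtls)
        assert len(rep["shared"]) == 2
        assert all(s["delta_peak"] == 0.0 for s in rep["shared"])
        other = merge_qtls(self._sig([1000], chrom="chr2"))
        rep2 = compare_scans(qtls, other)
        assert rep2["shared"] == [] and len(rep2["unique_a"]) == 2

    def test_causal_qtl_shared_between_functional_and_random_scans(self, small_study):
        gm, y, truth = small_study["gm"], small_study["y"], small_study["truth"]
        from funcgwas.annotate import GeneIndex, annotate_variants, build_snp_groups

        ann = annotate_variants(gm, GeneIndex(small_study["models"]), small_study["genome"])
        # group III sized so the random sample is guaranteed to keep the causal
        groups = build_snp_groups(ann, group_iii_size=gm.n_snps, seed=2)
        sub = filter_variants(gm)
        pcs, K = compute_pca(sub, 3).pcs, compute_kinship(sub)
        found = {}
        for label in ("I", "III"):
            ids = set(groups[label].snp_ids)
            mask = np.array([s in ids for s in gm.snp_ids])
            res = run_mlm(gm.subset(snp_idx=mask), y, pcs, K)
            thr = significance_threshold(res.table["p"].to_numpy(), 0.01)
            found[label] = merge_qtls(res.significant(thr))
        causal_pos = int(gm.pos[gm.snp_index(truth.causal_ids[0])])
        for label, qtls in found.items():
            assert any(
                q.start <= causal_pos <= q.end for q in qtls
            ), f"group {label} misses the causal QTL"
        rep = compare_scans(found["I"], found["III"])
        assert len(rep["shared"]) >= 1
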