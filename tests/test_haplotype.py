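"""LD, haplotype, ANOVA/Duncan and conditional-scan contracts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from funcgwas.genotypes import GenotypeMatrix
from funcgwas.haplotype import (
    ContractError,
    anova_oneway,
    assign_haplotypes,
    combine_haplotypes,
    conditional_scan,
    define_block,
    duncan_mrt,
    identify_functional_snp,
    pairwise_r2,
    r2_to_anchor,
)
from funcgwas.simulate import make_ld_block

from conftest import block_panel


def _matrix(dosage, ref=None, alt=None, pos=None):
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    pos = np.asarray(pos) if pos is not None else np.arange(1, m + 1) * 1000
    return GenotypeMatrix(
        accessions=[f"a{i:03d}" for i in range(n)],
        snp_ids=np.array([f"chr1_{p}" for p in pos], dtype=object),
        chrom=np.array(["chr1"] * m, dtype=object),
        pos=pos,
        ref=np.array(ref or ["G"] * m, dtype=object),
        alt=np.array(alt or ["A"] * m, dtype=object),
        dosage=dosage,
    )


class TestLd:
    def test_hand_cases(self):
        gm = _matrix(np.array([[0, 0, 0], [0, 2, 0], [2, 0, 2], [2, 2, 2]]))
        r2, reliable = pairwise_r2(gm, list(gm.snp_ids), min_complete=2)
        assert r2.iloc[0, 0] == 1.0
        assert r2.iloc[0, 1] == pytest.approx(0.0, abs=1e-12)  # independent pattern
        assert r2.iloc[0, 2] == pytest.approx(1.0)  # duplicated column
        vals = r2.to_numpy()
        np.testing.assert_allclose(vals, vals.T)
        assert np.nanmin(vals) >= 0 and np.nanmax(vals) <= 1 + 1e-12

    def test_anchored_r2_matches_pairwise(self):
        rng = np.random.default_rng(2)
        dosage = ((rng.random((60, 8)) < 0.4) * 2).astype(np.int8)
        dosage[rng.random(dosage.shape) < 0.1] = -1
        gm = _matrix(dosage)
        ids = list(gm.snp_ids)
        full, _ = pairwise_r2(gm, ids, min_complete=2)
        anchored = r2_to_anchor(gm, ids[0], ids[1:])
        np.testing.assert_allclose(
            anchored, full.iloc[0, 1:].to_numpy(), atol=1e-12, equal_nan=True
        )

    def test_block_recovers_planted_members(self):
        rng = np.random.default_rng(4)
        base = ((rng.random(300) < 0.4) * 2).astype(np.int8)
        linked = make_ld_block(base, 5, 0.02, rng)
        independent = ((rng.random((300, 5)) < 0.4) * 2).astype(np.int8)
        gm = _matrix(np.column_stack([base, linked, independent]))
        block = define_block(gm, gm.snp_ids[0], list(gm.snp_ids[1:]), r2_min=0.6)
        assert set(block.snp_ids) == set(gm.snp_ids[:6])
        loose = define_block(gm, gm.snp_ids[0], list(gm.snp_ids[1:]), r2_min=0.0)
        assert len(loose.snp_ids) == 11  # every candidate with defined r2

    def test_monomorphic_peak_raises(self):
        gm = _matrix(np.zeros((20, 2)))
        with pytest.raises(ContractError, match="monomorphic"):
            define_block(gm, gm.snp_ids[0], [gm.snp_ids[1]])


class TestHaplotypes:
    def _counting_fixture(self):
        """Allele strings GG:50, GA:30, AA:3 over two defining SNPs."""
        rows = [[0, 0]] * 50 + [[0, 2]] * 30 + [[2, 2]] * 3
        return _matrix(np.array(rows), ref=["G", "G"], alt=["A", "A"])

    def test_counting_fixture_with_min_count(self):
        gm = self._counting_fixture()
        table = assign_haplotypes(gm, list(gm.snp_ids), min_count=4)
        assert list(table.summary["alleles"]) == ["GG", "GA", "AA"]
        assert list(table.summary["label"]) == ["A", "B", "C"]
        assert list(table.summary["count"]) == [50, 30, 3]
        assert list(table.summary["minor"]) == [False, False, True]
        assert table.retained() == ["A", "B"]

    def test_labels_stable_under_accession_permutation(self):
        gm = self._counting_fixture()
        rng = np.random.default_rng(0)
        perm = rng.permutation(gm.n_accessions)
        gm_p = gm.subset(accession_idx=perm)
        t1 = assign_haplotypes(gm, list(gm.snp_ids))
        t2 = assign_haplotypes(gm_p, list(gm_p.snp_ids))
        pd.testing.assert_frame_equal(t1.summary, t2.summary)
        pd.testing.assert_series_equal(t1.assignments, t2.assignments)

    def test_het_and_missing_excluded_and_counts_sum(self):
        gm = self._counting_fixture()
        gm.dosage[0, 0] = 1
        gm.dosage[1, 1] = -1
        table = assign_haplotypes(gm, list(gm.snp_ids))
        assert len(table.assignments) == gm.n_accessions - 2
        assert table.summary["count"].sum() == len(table.assignments)

    def test_single_haplotype_panel(self):
        gm = _matrix(np.zeros((12, 2)))
        table = assign_haplotypes(gm, list(gm.snp_ids))
        assert len(table.summary) == 1 and table.summary["count"].iloc[0] == 12


class TestAnova:
    def test_separated_groups(self):
        y = np.array([0.0] * 10 + [10.0] * 10)
        res = anova_oneway(y, np.array(["a"] * 10 + ["b"] * 10))
        assert res.p < 1e-6

    def test_f_equals_squared_t_for_balanced_two_groups(self):
        rng = np.random.default_rng(1)
        y = np.concatenate([rng.normal(0, 1, 15), rng.normal(0.5, 1, 15)])
        labels = np.array(["a"] * 15 + ["b"] * 15)
        res = anova_oneway(y, labels)
        t = stats.ttest_ind(y[:15], y[15:]).statistic
        assert res.F == pytest.approx(t**2, abs=1e-10)
        scipy_f = stats.f_oneway(y[:15], y[15:])
        assert res.F == pytest.approx(scipy_f.statistic, abs=1e-10)
        assert res.p == pytest.approx(scipy_f.pvalue, abs=1e-12)

    def test_null_pvalues_uniform_over_permutations(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=60)
        labels = np.array(["a", "b", "c"] * 20)
        ps = []
        for _ in range(300):
            ps.append(anova_oneway(y, rng.permutation(labels)).p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_small_groups_excluded_then_untestable(self):
        y = np.arange(5, dtype=float)
        res = anova_oneway(y, np.array(["a", "a", "a", "b", "c"]))
        assert set(res.excluded) == {"b", "c"}
        assert not res.testable and np.isnan(res.F)


class TestDuncan:
    def test_equal_means_share_a_letter(self):
        rng = np.random.default_rng(0)
        y = rng.normal(0, 1, 40)
        out = duncan_mrt(y, np.array(["a", "b"] * 20))
        assert out["letters"].iloc[0] == out["letters"].iloc[1]

    def test_well_separated_means_get_distinct_letters(self):
        rng = np.random.default_rng(1)
        y = np.concatenate(
            [rng.normal(0, 0.1, 10), rng.normal(10, 0.1, 10), rng.normal(20, 0.1, 10)]
        )
        labels = np.array(["g0"] * 10 + ["g1"] * 10 + ["g2"] * 10)
        out = duncan_mrt(y, labels)
        assert len(set(out["letters"])) == 3
        assert all(len(s) == 1 for s in out["letters"])

    def test_letters_invariant_to_input_order(self):
        rng = np.random.default_rng(2)
        y = np.concatenate([rng.normal(m, 1.0, 12) for m in (0, 0.8, 1.6, 5)])
        labels = np.array(sum(([f"g{k}"] * 12 for k in range(4)), []))
        a = duncan_mrt(y, labels)
        perm = rng.permutation(len(y))
        b = duncan_mrt(y[perm], labels[perm])
        pd.testing.assert_frame_equal(a, b)

    def test_compact_letter_display_matches_procedure(self):
        """Sharing a letter must coincide with Duncan's step-down declaring the
        pair non-significant (independent re-derivation per fixture)."""
        rng = np.random.default_rng(5)
        qcache: dict[tuple, float] = {}
        for _ in range(30):
            k = int(rng.integers(2, 6))
            sizes = rng.choice([5, 8, 10], k)  # discrete sizes keep df reusable
            means = rng.normal(0, rng.uniform(0.3, 3.0), k)
            y = np.concatenate([rng.normal(means[i], 1.0, sizes[i]) for i in range(k)])
            labels = np.concatenate([[f"g{i}"] * sizes[i] for i in range(k)])
            out = duncan_mrt(y, labels)
            an = anova_oneway(y, labels)
            order = out["mean"].to_numpy()
            n_h = k / np.sum(1.0 / out["n"].to_numpy())
            se = np.sqrt(an.ms_within / n_h)
            # independent recursion: a pair is non-significant iff contained in
            # a span whose range is below its critical value
            nonsig = np.zeros((k, k), bool)
            for span in range(k, 1, -1):
                key = (span, an.df_within)
                if key not in qcache:
                    qcache[key] = stats.studentized_range.ppf(
                        (1 - 0.05) ** (span - 1), span, an.df_within
                    )
                q = qcache[key]
                for i in range(0, k - span + 1):
                    j = i + span - 1
                    if nonsig[i, j]:
                        continue
                    if order[i] - order[j] <= q * se:
                        for a in range(i, j + 1):
                            for b in range(a, j + 1):
                                nonsig[a, b] = True
            for i in range(k):
                for j in range(i + 1, k):
                    share = bool(
                        set(out["letters"].iloc[i]) & set(out["letters"].iloc[j])
                    )
                    assert share == bool(nonsig[i, j]), (i, j, out)

    def test_single_group_gets_single_letter(self):
        out = duncan_mrt(np.arange(5, dtype=float), np.array(["a"] * 5))
        assert list(out["letters"]) == ["a"]


class TestConditionalScan:
    def test_conditioning_on_causal_extinguishes_block(self):
        gm, y, causal_id, tag_ids = block_panel(seed=0)
        block = define_block(gm, causal_id, tag_ids, r2_min=0.6)
        assert set(block.snp_ids) == {causal_id, *tag_ids}
        for allele in ("A", "T"):
            scan = conditional_scan(gm, y, block, causal_id, allele)
            others = scan[scan["snp_id"] != causal_id]
            testable = others[~others["untestable"]]
            assert (testable["p"] > 0.1).all()

    def test_conditioning_on_tag_retains_causal_signal(self):
        gm, y, causal_id, tag_ids = block_panel(seed=1)
        block = define_block(gm, causal_id, tag_ids, r2_min=0.6)
        scan = conditional_scan(gm, y, block, tag_ids[0], "T")
        row = scan[scan["snp_id"] == causal_id].iloc[0]
        assert not row["untestable"] and row["neglog10p"] > 3.0

    def test_monomorphic_member_flagged_untestable(self):
        gm, y, causal_id, tag_ids = block_panel(seed=2, flip_rate=0.0)
        block = define_block(gm, causal_id, tag_ids, r2_min=0.6)
        scan = conditional_scan(gm, y, block, causal_id, "T")
        others = scan[scan["snp_id"] != causal_id]
        assert others["untestable"].all()
        assert (others["reason"].str.contains("diversity") | others["reason"].str.contains("MAF")).all()

    def test_too_few_carriers_raise(self):
        gm, y, causal_id, tag_ids = block_panel(seed=3)
        block = define_block(gm, causal_id, tag_ids, r2_min=0.6)
        with pytest.raises(ContractError, match="carriers"):
            conditional_scan(gm, y, block, causal_id, "T", min_carriers=5000)

    def test_functional_snp_ranked_first(self):
        gm, y, causal_id, tag_ids = block_panel(seed=4)
        block = define_block(gm, causal_id, tag_ids, r2_min=0.6)
        ranks = identify_functional_snp(gm, y, block, signal_neglog10p=2.0)
        assert ranks.iloc[0]["snp_id"] == causal_id
        assert bool(ranks.iloc[0]["kills_block"])
        assert not ranks.iloc[1:]["kills_block"].any()


class TestCombos:
    def _two_gene_panel(self, seed=0, effect1=2.0, effect2=2.0):
        rng = np.random.default_rng(seed)
        n = 360
        g1 = ((rng.random(n) < 0.5) * 2).astype(np.int8)
        g2_u = rng.random(n)
        g2 = np.select([g2_u < 0.4, g2_u < 0.7, g2_u < 0.9], [0, 2, 0], 2).astype(np.int8)
        g2b = np.select([g2_u < 0.4, g2_u < 0.7, g2_u < 0.9], [0, 0, 2], 2).astype(np.int8)
        dosage = np.column_stack([g1, g2, g2b])
        gm = _matrix(dosage, ref=["G", "G", "G"], alt=["A", "A", "A"],
                     pos=[1000, 500_000, 500_500])
        y = (g1 / 2) * effect1 + (g2_u >= 0.9) * effect2 + rng.normal(0, 0.5, n)
        phen = pd.DataFrame({"accession_id": gm.accessions, "ML_cm": y})
        t1 = assign_haplotypes(gm, [gm.snp_ids[0]], phen, gene_id="gene1")
        t2 = assign_haplotypes(gm, list(gm.snp_ids[1:]), phen, gene_id="gene2")
        return gm, phen, t1, t2

    def test_combination_count_bound(self):
        _, phen, t1, t2 = self._two_gene_panel()
        combo = combine_haplotypes(t1, t2, phen)
        assert len(t1.retained()) * len(t2.retained()) >= len(combo.summary)
        assert (combo.summary["count"] > 0).all()

    def test_additive_effects_order_combinations(self):
        """Double-superior > single-superior > double-inferior combination means."""
        _, phen, t1, t2 = self._two_gene_panel(seed=3)
        combo = combine_haplotypes(t1, t2, phen)
        s = combo.summary.set_index("combo")["mean"]
        hi1 = t1.summary.sort_values("mean", ascending=False)["label"].iloc[0]
        lo1 = t1.summary.sort_values("mean")["label"].iloc[0]
        hi2 = t2.summary.sort_values("mean", ascending=False)["label"].iloc[0]
        lo2 = t2.summary.sort_values("mean")["label"].iloc[0]
        assert s[f"{hi1}+{hi2}"] > s[f"{hi1}+{lo2}"] > s[f"{lo1}+{lo2}"]
        assert s[f"{hi1}+{hi2}"] > s[f"{lo1}+{hi2}"] > s[f"{lo1}+{lo2}"]

    def test_identical_tables_degenerate_to_single_gene(self):
        _, phen, t1, _ = self._two_gene_panel()
        combo = combine_haplotypes(t1, t1, phen)
        assert all(
            c.split("+")[0] == c.split("+")[1] for c in combo.summary["combo"]
        )
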