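"""Self-contained validation experiments with known ground truth.

Each function builds its own synthetic study, runs the relevant pipeline
stage(s) and returns plain summary numbers.  They serve two audiences: the
acceptance test suite asserts on their outputs at fixed seeds, and
``scripts/acceptance.py`` reports them for an end-to-end reproducibility
check.  Problem sizes are chosen to finish on a single CPU in minutes while
leaving the measured properties (calibration, power, robustness) clearly
resolved; docs/methods.md discusses what these scales do and do not probe.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .annotate import (
    CODON_TABLE,
    GeneIndex,
    annotate_variants,
    build_snp_groups,
    classify_site,
)
from .bsa import PolarPools, allele_freq_chisq, classify_sds, permutation_threshold
from .genotypes import GenotypeMatrix
from .gwas import (
    genomic_inflation,
    merge_qtls,
    run_glm,
    run_mlm,
    significance_threshold,
)
from .haplotype import (
    anova_oneway,
    assign_haplotypes,
    combine_haplotypes,
    conditional_scan,
    define_block,
    duncan_mrt,
    identify_functional_snp,
)
from .selection import tajimas_d
from .simulate import (
    CausalVariant,
    SimConfig,
    simulate_block_panel,
    simulate_genome,
    simulate_neutral_panel,
    simulate_phenotype,
    simulate_population,
)
from .structure import compute_kinship, compute_pca, filter_variants


def _simple_matrix(dosage, pos=None, chrom="chr1", chrom_len=None):
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    pos = np.asarray(pos) if pos is not None else np.arange(1, m + 1) * 100
    return GenotypeMatrix(
        accessions=[f"acc{i + 1:04d}" for i in range(n)],
        snp_ids=np.array([f"{chrom}_{p}" for p in pos], dtype=object),
        chrom=np.array([chrom] * m, dtype=object),
        pos=pos.astype(np.int64),
        ref=np.array(["A"] * m, dtype=object),
        alt=np.array(["T"] * m, dtype=object),
        dosage=dosage,
        contig_lengths={chrom: int(chrom_len or pos.max() + 100)},
    )


# ---------------------------------------------------------------------------
# annotation


def annotation_oracle_agreement(n_snps: int = 1000, seed: int = 0) -> float:
    """Fraction of random coding SNPs whose consequence call matches a
    brute-force oracle that rebuilds both full coding sequences, translates
    the whole proteins and diffs them (both strands exercised)."""
    cfg = SimConfig(n_chromosomes=2, chrom_length_bp=400_000, n_genes=60,
                    n_snps=100, n_accessions_per_subpop=(5, 5), seed=seed)
    genome, models = simulate_genome(cfg)
    index = GeneIndex(models)
    rng = np.random.default_rng(seed + 1)

    def protein(seq: str, model) -> str:
        cds = "".join(seq[a:b] for a, b in model.cds_segments)
        if model.strand == "-":
            comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
            cds = "".join(comp[b] for b in reversed(cds))
        return "".join(CODON_TABLE[cds[i:i + 3]] for i in range(0, len(cds), 3))

    agree = 0
    for _ in range(n_snps):
        model = models[rng.integers(len(models))]
        tx = model.tx_positions()
        pos0 = int(tx[rng.integers(len(tx))])
        seq = genome[model.chrom]
        ref = seq[pos0]
        alt = "ACGT"[("ACGT".index(ref) + int(rng.integers(1, 4))) % 4]
        eff = next(
            e for e in classify_site(model.chrom, pos0 + 1, ref, alt, index, genome)
            if e.gene_id == model.gene_id
        )
        mutated = seq[:pos0] + alt + seq[pos0 + 1:]
        p_ref, p_alt = protein(seq, model), protein(mutated, model)
        diffs = [(i, a, b) for i, (a, b) in enumerate(zip(p_ref, p_alt)) if a != b]
        if not diffs:
            oracle = "synonymous"
        elif diffs[0][2] == "*":
            oracle = "stop_gained"
        elif diffs[0][1] == "*":
            oracle = "stop_lost"
        elif diffs[0][0] == 0 and diffs[0][1] == "M":
            oracle = "start_lost"
        else:
            oracle = "nonsynonymous"
        ok = eff.effect == oracle
        if ok and oracle not in ("synonymous",):
            ok = (eff.ref_aa, eff.alt_aa) == (diffs[0][1], diffs[0][2])
        agree += ok
    return agree / n_snps


# ---------------------------------------------------------------------------
# pool chi-squared


def chisq_worked_example() -> float:
    """Pool allele tables [30,10] vs [10,30] under the screen's chi-squared."""
    dosage = np.array([[2]] * 5 + [[0]] * 15 + [[2]] * 15 + [[0]] * 5)
    gm = _simple_matrix(dosage)
    pools = PolarPools("toy", gm.accessions[:20], gm.accessions[20:], 20)
    return float(allele_freq_chisq(gm, pools)["chi2"].iloc[0])


def sds_null_calibration(n_snps: int = 10_000, seed: int = 0) -> float:
    """SDS fraction on null common SNPs where the test's independent-allele
    sampling model holds (Hardy-Weinberg diploid genotypes); pools are
    phenotype extremes of a phenotype independent of every SNP."""
    rng = np.random.default_rng(seed)
    n = 200
    freq = rng.uniform(0.1, 0.5, n_snps)
    dosage = rng.binomial(2, freq, size=(n, n_snps)).astype(np.int8)
    gm = _simple_matrix(dosage)
    y = rng.normal(size=n)
    order = np.argsort(y)
    ids = np.array(gm.accessions)
    pools = PolarPools("null", list(ids[order[-20:]]), list(ids[order[:20]]), 20)
    res = classify_sds(allele_freq_chisq(gm, pools))
    return float(res.loc[~res["untestable"], "sds"].mean())


# ---------------------------------------------------------------------------
# thresholds and QTL merging


def threshold_examples() -> dict[str, float]:
    out = {}
    for m in (1, 50, 1000):
        p = np.concatenate([np.full(m, 1e-4), np.full(2000, 0.5)])
        out[f"m{m}"] = significance_threshold(p, alpha=0.01)
    return out


def qtl_merge_examples() -> dict[str, int]:
    def count(positions):
        df = pd.DataFrame({
            "chrom": ["chr1"] * len(positions), "pos": positions,
            "snp_id": [f"chr1_{p}" for p in positions],
            "neglog10p": [6.0] * len(positions),
        })
        return len(merge_qtls(df, merge_distance_bp=170_000))

    return {
        "gap_150kb": count([100_000, 250_000]),
        "gap_200kb": count([100_000, 300_000]),
        "chain_0_160_320kb": count([1, 160_001, 320_001]),
    }


# ---------------------------------------------------------------------------
# window enrichment permutation calibration


def _uniform_flag_panel(seed, n=40_000, frac=0.05, planted=None):
    rng = np.random.default_rng(seed)
    chrom_lens = {f"chr{i + 1}": 2_000_000 for i in range(5)}
    per = n // 5
    chroms = np.repeat(list(chrom_lens), per)
    pos = np.concatenate(
        [np.sort(rng.choice(1_999_999, per, replace=False)) + 1 for _ in chrom_lens]
    )
    flags = rng.random(n) < frac
    if planted is not None:
        chrom_p, start, end, k = planted
        inside = np.flatnonzero((chroms == chrom_p) & (pos >= start) & (pos < end))
        flags[rng.choice(inside, size=k, replace=False)] = True
    return (
        pd.DataFrame({"chrom": chroms, "pos": pos, "sds": flags, "esds": flags}),
        chrom_lens,
    )


def window_calibration(n_seeds: int = 20, n_perm: int = 1000, seed: int = 0) -> dict:
    """Null calibration of the 99th-percentile window threshold (5% random
    flags, uniform SNP density) and recovery of a planted 500 kb region
    holding 80% of the flagged SNPs."""
    null_calls = []
    recovered = 0
    for s in range(n_seeds):
        flagged, lens = _uniform_flag_panel(seed + s, frac=0.05)
        res = permutation_threshold(flagged, lens, n_perm=n_perm, seed=seed + s + 1)
        null_calls.append(res.windows["esds_enriched"].to_numpy())

        flagged, lens = _uniform_flag_panel(
            seed + s, frac=0.0025,  # ~100 scattered flags; the planted 400 are 80%
            planted=("chr3", 1_000_000, 1_500_000, 400),
        )
        res = permutation_threshold(flagged, lens, n_perm=n_perm, seed=seed + s + 1)
        win = res.windows
        region = win[(win["chrom"] == "chr3") & (win["start"] >= 600_000)
                     & (win["start"] < 1_500_000)]
        recovered += bool(region["esds_enriched"].any())
    return {
        "null_enriched_fraction": float(np.concatenate(null_calls).mean()),
        "planted_recovery_fraction": recovered / n_seeds,
    }


# ---------------------------------------------------------------------------
# mixed model


def _structured_panel(seed, n_snps=5000, per_subpop=(200, 200), causal=(),
                      heritability=0.5):
    cfg = SimConfig(
        n_chromosomes=2, chrom_length_bp=800_000, n_genes=80, n_snps=n_snps,
        n_accessions_per_subpop=per_subpop, fst=0.3, heritability=heritability,
        phenotype_skew=False, causal_spec=causal, seed=seed,
    )
    genome, models = simulate_genome(cfg)
    gm, truth = simulate_population(cfg, (genome, models))
    y = simulate_phenotype(gm, truth, cfg)["ML_cm"].to_numpy()
    return cfg, genome, models, gm, truth, y


def mlm_identity_collapse(seed: int = 0) -> float:
    """Max -log10(p) discrepancy between GLM and MLM with identity kinship."""
    _, _, _, gm, _, y = _structured_panel(seed, n_snps=1500, per_subpop=(80, 80))
    pcs = compute_pca(filter_variants(gm), 3).pcs
    a = run_glm(gm, y, pcs).table
    b = run_mlm(gm, y, pcs, np.eye(gm.n_accessions)).table
    m = a.merge(b, on="snp_id")
    return float(np.abs(m["neglog10p_x"] - m["neglog10p_y"]).max())


def mlm_inflation(seed: int = 0) -> dict[str, float]:
    """Genomic inflation on a structured polygenic panel (n=400, 5000 SNPs):
    kinship-aware MLM versus a covariate-free GLM."""
    _, _, _, gm, _, y = _structured_panel(seed)
    sub = filter_variants(gm)
    res = run_mlm(gm, y, compute_pca(sub, 3).pcs, compute_kinship(sub))
    naive = run_glm(gm, y, None)
    return {
        "lambda_mlm": genomic_inflation(res.table["p"].to_numpy()),
        "lambda_glm_no_covariates": genomic_inflation(naive.table["p"].to_numpy()),
    }


def power_experiment(n_seeds: int = 50, seed: int = 0) -> dict[str, float]:
    """Planted 4 cm non-synonymous SNP (MAF 0.3, n = 400, background h2 = 0.3)
    under compressed MLM with the scan-adaptive threshold."""
    hits, betas = 0, []
    for s in range(n_seeds):
        causal = (CausalVariant(10, 40, 4.0, alt_frequency=0.3),)
        cfg = SimConfig(
            n_chromosomes=2, chrom_length_bp=600_000, n_genes=60, n_snps=3000,
            n_accessions_per_subpop=(200, 200), fst=0.3, heritability=0.3,
            phenotype_skew=False, causal_spec=causal, seed=seed + s,
        )
        genome, models = simulate_genome(cfg)
        gm, truth = simulate_population(cfg, (genome, models))
        y = simulate_phenotype(gm, truth, cfg)["ML_cm"].to_numpy()
        sub = filter_variants(gm)
        res = run_mlm(gm, y, compute_pca(sub, 3).pcs, compute_kinship(sub),
                      compression_groups="auto")
        thr = significance_threshold(res.table["p"].to_numpy(), 0.01,
                                     fallback_bonferroni=True)
        row = res.table[res.table["snp_id"] == truth.causal_ids[0]].iloc[0]
        hits += bool(row["neglog10p"] > thr)
        betas.append(float(row["beta"]))
    return {
        "threshold_exceed_fraction": hits / n_seeds,
        "mean_beta_hat_cm": float(np.mean(betas)),
    }


def provenance_experiment(n_seeds: int = 20, seed: int = 0) -> dict[str, float]:
    """Peak signal at the causal SNP when PC/kinship come from the functional
    SNP set (group I) versus the genome-wide random set (group III)."""
    deltas = []
    for s in range(n_seeds):
        causal = (CausalVariant(12, 40, 0.6, alt_frequency=0.3),)
        cfg = SimConfig(
            n_chromosomes=2, chrom_length_bp=900_000, n_genes=90, n_snps=8000,
            n_accessions_per_subpop=(200, 200), fst=0.3, heritability=0.5,
            phenotype_skew=False, causal_spec=causal, seed=seed + s,
        )
        genome, models = simulate_genome(cfg)
        gm, truth = simulate_population(cfg, (genome, models))
        y = simulate_phenotype(gm, truth, cfg)["ML_cm"].to_numpy()
        ann = annotate_variants(gm, GeneIndex(models), genome)
        groups = build_snp_groups(ann, group_iii_size=gm.n_snps // 2, seed=seed + s)
        gm1 = gm.subset(snp_idx=np.isin(gm.snp_ids, groups["I"].snp_ids))
        peaks = []
        for label in ("I", "III"):
            sub = filter_variants(
                gm.subset(snp_idx=np.isin(gm.snp_ids, groups[label].snp_ids))
            )
            res = run_mlm(gm1, y, compute_pca(sub, 3).pcs, compute_kinship(sub))
            peaks.append(float(
                res.table.loc[res.table["snp_id"] == truth.causal_ids[0],
                              "neglog10p"].iloc[0]
            ))
        deltas.append(abs(peaks[0] - peaks[1]))
    return {
        "fraction_delta_below_1": float(np.mean(np.array(deltas) < 1.0)),
        "median_delta": float(np.median(deltas)),
    }


# ---------------------------------------------------------------------------
# conditional scan / functional-SNP isolation


def block_isolation_experiment(n_seeds: int = 40, seed: int = 0) -> dict[str, float]:
    """In a 7-SNP block with one causal member: does conditioning on the
    causal SNP silence every other member, and is the causal SNP ranked
    first by the joint conditional-scan + haplotype-consistency score?"""
    clean, ranked = 0, 0
    for s in range(n_seeds):
        gm, y, causal_id, tag_ids = simulate_block_panel(seed=seed + s)
        block = define_block(gm, causal_id, tag_ids, r2_min=0.6)
        ok = True
        for allele in ("A", "T"):
            scan = conditional_scan(gm, y, block, causal_id, allele)
            others = scan[scan["snp_id"] != causal_id]
            testable = others[~others["untestable"]]
            if len(testable) and (testable["p"] <= 0.1).any():
                ok = False
        clean += ok
        ranks = identify_functional_snp(gm, y, block, signal_neglog10p=2.0)
        top = ranks.iloc[0]
        ranked += bool(top["snp_id"] == causal_id and top["kills_block"])
    return {
        "conditioning_silences_fraction": clean / n_seeds,
        "causal_ranked_first_fraction": ranked / n_seeds,
    }


# ---------------------------------------------------------------------------
# diversity statistics


def tajima_suite(seed: int = 0, n_regions: int = 50) -> dict[str, float]:
    """Toy-alignment agreement with the transcribed 1989 formulas, the
    singleton-excess sign property, and neutral-panel calibration."""
    dosage = np.array(
        [[0, 0, 2, 2, 0], [2, 0, 0, 2, 0], [2, 2, 0, 0, 0], [0, 2, 0, 2, 2]]
    )
    gm = _simple_matrix(dosage, pos=np.array([3, 10, 25, 60, 99]), chrom_len=120)
    s = tajimas_d(gm, "chr1", 0, 120)
    n = 4
    k = dosage.sum(axis=0) // 2
    seg = (k > 0) & (k < n)
    S = int(seg.sum())
    pi_total = float(np.sum(2 * k[seg] * (n - k[seg]) / (n * (n - 1))))
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1, c2 = b1 - 1 / a1, b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1, e2 = c1 / a1, c2 / (a1**2 + a2)
    expected = (pi_total - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))
    toy_err = abs(s.tajimas_d - expected)

    n2, S2 = 20, 10
    singles = np.zeros((n2, S2), dtype=np.int8)
    for j in range(S2):
        singles[j, j] = 2
    gm2 = _simple_matrix(singles, pos=np.arange(1, S2 + 1) * 5, chrom_len=500)
    singleton_d = tajimas_d(gm2, "chr1", 0, 500).tajimas_d

    region = 1_000_000
    gm3 = simulate_neutral_panel(100, n_regions * 100, region, seed=seed)
    step = region // n_regions
    ds = []
    for start in range(0, region, step):
        st = tajimas_d(gm3, "chr1", start, start + step)
        if st.tajimas_d is not None:
            ds.append(st.tajimas_d)
    return {
        "toy_oracle_abs_error": float(toy_err),
        "singleton_d": float(singleton_d),
        "neutral_mean_d": float(np.mean(ds)),
        "neutral_regions_used": len(ds),
    }


# ---------------------------------------------------------------------------
# haplotype machinery


def haplotype_counting_fixture() -> dict[str, int]:
    """Allele strings GG:50, GA:30, AA:3 with min_count 4."""
    rows = [[0, 0]] * 50 + [[0, 2]] * 30 + [[2, 2]] * 3
    gm = _simple_matrix(np.array(rows))
    gm.ref[:] = "G"
    gm.alt[:] = "A"
    table = assign_haplotypes(gm, list(gm.snp_ids), min_count=4)
    return {
        "n_haplotypes_observed": len(table.summary),
        "n_haplotypes_retained": len(table.retained()),
    }


def cld_validity(n_fixtures: int = 100, seed: int = 0) -> float:
    """Fraction of random group fixtures whose Duncan letters form a valid
    compact letter display (letter sharing == step-down non-significance,
    re-derived independently)."""
    from scipy import stats as sps

    rng = np.random.default_rng(seed)
    qcache: dict[tuple, float] = {}
    valid = 0
    for _ in range(n_fixtures):
        k = int(rng.integers(2, 6))
        sizes = rng.choice([5, 8, 10], k)
        means = rng.normal(0, rng.uniform(0.3, 3.0), k)
        y = np.concatenate([rng.normal(means[i], 1.0, sizes[i]) for i in range(k)])
        labels = np.concatenate([[f"g{i}"] * sizes[i] for i in range(k)])
        out = duncan_mrt(y, labels)
        an = anova_oneway(y, labels)
        order = out["mean"].to_numpy()
        n_h = k / np.sum(1.0 / out["n"].to_numpy())
        se = np.sqrt(an.ms_within / n_h)
        nonsig = np.zeros((k, k), bool)
        for span in range(k, 1, -1):
            key = (span, an.df_within)
            if key not in qcache:
                qcache[key] = float(
                    sps.studentized_range.ppf((1 - 0.05) ** (span - 1), span,
                                              an.df_within)
                )
            for i in range(0, k - span + 1):
                j = i + span - 1
                if nonsig[i, j]:
                    continue
                if order[i] - order[j] <= qcache[key] * se:
                    for a in range(i, j + 1):
                        for b in range(a, j + 1):
                            nonsig[a, b] = True
        ok = True
        for i in range(k):
            for j in range(i + 1, k):
                share = bool(set(out["letters"].iloc[i]) & set(out["letters"].iloc[j]))
                if share != bool(nonsig[i, j]):
                    ok = False
        valid += ok
    return valid / n_fixtures


def additive_combo_experiment(n_seeds: int = 20, seed: int = 0) -> float:
    """Two genes with additive superior haplotypes: fraction of seeds where
    the double-superior combination outranks every single-superior one,
    which in turn outrank the double-inferior combination."""
    good = 0
    for s in range(n_seeds):
        rng = np.random.default_rng(seed + s)
        n = 360
        g1 = ((rng.random(n) < 0.5) * 2).astype(np.int8)
        u = rng.random(n)
        g2a = np.select([u < 0.4, u < 0.7, u < 0.9], [0, 2, 0], 2).astype(np.int8)
        g2b = np.select([u < 0.4, u < 0.7, u < 0.9], [0, 0, 2], 2).astype(np.int8)
        gm = _simple_matrix(np.column_stack([g1, g2a, g2b]),
                            pos=np.array([1000, 500_000, 500_500]))
        y = (g1 / 2) * 2.0 + (u >= 0.9) * 2.0 + rng.normal(0, 0.5, n)
        phen = pd.DataFrame({"accession_id": gm.accessions, "ML_cm": y})
        t1 = assign_haplotypes(gm, [gm.snp_ids[0]], phen, gene_id="geneA")
        t2 = assign_haplotypes(gm, list(gm.snp_ids[1:]), phen, gene_id="geneB")
        combo = combine_haplotypes(t1, t2, phen)
        summ = combo.summary.set_index("combo")["mean"]
        hi1 = t1.summary.sort_values("mean", ascending=False)["label"].iloc[0]
        lo1 = t1.summary.sort_values("mean")["label"].iloc[0]
        hi2 = t2.summary.sort_values("mean", ascending=False)["label"].iloc[0]
        lo2 = t2.summary.sort_values("mean")["label"].iloc[0]
        try:
            ordered = (
                summ[f"{hi1}+{hi2}"] > summ[f"{hi1}+{lo2}"] > summ[f"{lo1}+{lo2}"]
                and summ[f"{hi1}+{hi2}"] > summ[f"{lo1}+{hi2}"] > summ[f"{lo1}+{lo2}"]
            )
        except KeyError:
            ordered = False
        good += bool(ordered)
    return good / n_seeds
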