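"""Shared fixtures: a small structured synthetic study with one planted causal SNP."""

import numpy as np
import pytest

from funcgwas.simulate import (
    CausalVariant,
    SimConfig,
    simulate_genome,
    simulate_phenotype,
    simulate_population,
)


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(
        n_chromosomes=2,
        chrom_length_bp=600_000,
        n_genes=60,
        n_snps=3000,
        n_accessions_per_subpop=(150, 150),
        fst=0.3,
        seed=11,
        causal_spec=(CausalVariant(10, 40, 4.0, subpop_frequencies=(0.55, 0.10)),),
        heritability=0.3,
        phenotype_skew=False,
    )


@pytest.fixture(scope="session")
def small_study(small_cfg):
    genome, models = simulate_genome(small_cfg)
    gm, truth = simulate_population(small_cfg, (genome, models))
    phen = simulate_phenotype(gm, truth, small_cfg)
    return {
        "config": small_cfg,
        "genome": genome,
        "models": models,
        "gm": gm,
        "truth": truth,
        "phenotype": phen,
        "y": phen["ML_cm"].to_numpy(),
    }


def block_panel(seed: int = 0, **kw):
    """Shorthand for the conditional-scan fixture panel."""
    from funcgwas.simulate import simulate_block_panel

    return simulate_block_panel(seed=seed, **kw)


def hudson_fst(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float:
    """Hudson's Fst estimator averaged over SNPs (test oracle).

    Per SNP: N = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1),
    D = p1(1-p2) + p2(1-p1); the ratio-of-averages form is used.
    """
    def freqs(d):
        d = d.astype(float)
        d[d < 0] = np.nan
        n = np.sum(~np.isnan(d), axis=0).astype(float)
        p = np.nanmean(d, axis=0) / 2.0
        return p, n

    p1, n1 = freqs(dosage_a.copy())
    p2, n2 = freqs(dosage_b.copy())
    ok = (n1 > 1) & (n2 > 1)
    p1, p2, n1, n2 = p1[ok], p2[ok], n1[ok], n2[ok]
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    keep = den > 0
    return float(np.sum(num[keep]) / np.sum(den[keep]))
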