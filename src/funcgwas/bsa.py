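"""Bulked-segregant screening of pool allele-frequency differences.

Within each subpopulation, the accessions with the most extreme phenotypes
form a high pool and a low pool (only "typical" members of the
subpopulation are eligible, to avoid structure-driven allele-frequency
differences).  Every SNP is then tested with a Pearson chi-squared test on
the 2x2 pool-by-allele table of allele counts (each inbred accession
contributes two alleles).  SNPs with p < 0.05 are flagged SDS
("significantly different between pools") and p < 0.01 ESDS ("extremely
significantly different").  Flag counts are accumulated in 500 kb windows
sliding by 50 kb, and windows are called enriched when their count exceeds
a permutation-derived 99th-percentile threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import MISSING, GenotypeMatrix


class PoolSizingError(ValueError):
    """Not enough typical accessions to fill the polar pools."""


@dataclass
class PolarPools:
    """Phenotypically extreme accession pools within one subgroup."""

    subgroup: str
    high: list[str]
    low: list[str]
    pool_size: int

    def __post_init__(self) -> None:
        if set(self.high) & set(self.low):
            raise PoolSizingError("high and low pools overlap")


@dataclass
class WindowGrid:
    """Sliding windows [start, start + window) tiling each chromosome."""

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray

    def __len__(self) -> int:
        return len(self.start)


@dataclass
class PoolScreenResult:
    per_snp: pd.DataFrame  # snp_id, chrom, pos, chi2, p, untestable, sds, esds
    windows: pd.DataFrame  # chrom, start, end, sds_count, esds_count, calls
    thresholds: dict[str, float] = field(default_factory=dict)
    pools: PolarPools | None = None


def select_polar_pools(
    phenotype: pd.DataFrame,
    typical: np.ndarray,
    pool_size: int = 20,
    subgroup: str = "",
    id_col: str = "accession_id",
    value_col: str = "ML_cm",
) -> PolarPools:
    """Top/bottom ``pool_size`` accessions by phenotype among typical members.

    Phenotype ties break by accession id (lexicographic), which makes pool
    membership deterministic across runs.
    """
    df = phenotype.loc[np.asarray(typical, dtype=bool), [id_col, value_col]]
    if len(df) < 2 * pool_size:
        raise PoolSizingError(
            f"{len(df)} typical accessions < 2 x pool size {pool_size}"
        )
    asc = df.sort_values([value_col, id_col], ascending=[True, True], kind="stable")
    low = list(asc[id_col].iloc[:pool_size])
    desc = df.sort_values([value_col, id_col], ascending=[False, True], kind="stable")
    high = [a for a in desc[id_col] if a not in set(low)][:pool_size]
    if len(high) < pool_size:
        raise PoolSizingError("pools would overlap; not enough distinct accessions")
    return PolarPools(subgroup=subgroup, high=high, low=low, pool_size=pool_size)


def allele_freq_chisq(gm: GenotypeMatrix, pools: PolarPools) -> pd.DataFrame:
    """Per-SNP Pearson chi-squared (df=1, no continuity correction) between pools.

    Allele counts are dosage sums over non-missing pool members.  SNPs
    monomorphic across both pools are untestable: chi2 = 0, p = 1,
    ``untestable`` True.
    """
    if not pools.high or not pools.low:
        raise PoolSizingError("empty pool")
    acc_idx = {a: i for i, a in enumerate(gm.accessions)}
    hi = np.array([acc_idx[a] for a in pools.high])
    lo = np.array([acc_idx[a] for a in pools.low])

    def counts(rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        d = gm.dosage[rows].astype(np.int64)
        called = d != MISSING
        alt = np.where(called, d, 0).sum(axis=0)
        total = 2 * called.sum(axis=0)
        return total - alt, alt  # (ref count, alt count)

    a, b = counts(hi)  # high pool: ref, alt
    c, d = counts(lo)  # low pool: ref, alt
    n = a + b + c + d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    denom = r1 * r2 * c1 * c2
    untestable = denom == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(
            untestable, 0.0, n * (a * d - b * c) ** 2 / np.where(denom == 0, 1, denom)
        )
    p = np.where(untestable, 1.0, stats.chi2.sf(chi2, df=1))
    return pd.DataFrame(
        {
            "snp_id": gm.snp_ids,
            "chrom": gm.chrom,
            "pos": gm.pos,
            "high_ref": a,
            "high_alt": b,
            "low_ref": c,
            "low_alt": d,
            "chi2": chi2,
            "p": p,
            "untestable": untestable,
        }
    )


def classify_sds(
    results: pd.DataFrame, p_sds: float = 0.05, p_esds: float = 0.01
) -> pd.DataFrame:
    """Add SDS (p < 0.05) and ESDS (p < 0.01) flags; untestable SNPs are neither."""
    out = results.copy()
    testable = ~out["untestable"].to_numpy()
    out["sds"] = testable & (out["p"].to_numpy() < p_sds)
    out["esds"] = testable & (out["p"].to_numpy() < p_esds)
    return out


def make_windows(
    chrom_lengths: dict[str, int], window_bp: int = 500_000, step_bp: int = 50_000
) -> WindowGrid:
    """Half-open sliding windows; trailing partial windows are included."""
    import warnings

    if step_bp > window_bp:
        warnings.warn("step larger than window leaves gaps between windows", stacklevel=2)
    chroms, starts, ends = [], [], []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        start = 0
        while start < length:
            chroms.append(chrom)
            starts.append(start)
            ends.append(start + window_bp)
            start += step_bp
    return WindowGrid(
        chrom=np.array(chroms, dtype=object),
        start=np.array(starts, dtype=np.int64),
        end=np.array(ends, dtype=np.int64),
    )


def _window_counts_for(
    grid: WindowGrid, chrom: np.ndarray, pos0: np.ndarray
) -> np.ndarray:
    """Count positions (0-based) falling in each half-open window."""
    counts = np.zeros(len(grid), dtype=np.int64)
    for c in np.unique(grid.chrom):
        wmask = grid.chrom == c
        p = np.sort(pos0[chrom == c])
        counts[wmask] = np.searchsorted(p, grid.end[wmask]) - np.searchsorted(
            p, grid.start[wmask]
        )
    return counts


def window_counts(
    flagged: pd.DataFrame,
    chrom_lengths: dict[str, int],
    window_bp: int = 500_000,
    step_bp: int = 50_000,
) -> pd.DataFrame:
    """Per-window SDS and ESDS counts (plus total SNP occupancy)."""
    grid = make_windows(chrom_lengths, window_bp, step_bp)
    pos0 = flagged["pos"].to_numpy() - 1
    chrom = flagged["chrom"].to_numpy()
    out = pd.DataFrame({"chrom": grid.chrom, "start": grid.start, "end": grid.end})
    out["n_snps"] = _window_counts_for(grid, chrom, pos0)
    for col in ("sds", "esds"):
        mask = flagged[col].to_numpy(dtype=bool)
        out[f"{col}_count"] = _window_counts_for(grid, chrom[mask], pos0[mask])
    return out


def permutation_threshold(
    flagged: pd.DataFrame,
    chrom_lengths: dict[str, int],
    n_perm: int = 10_000,
    percentile: float = 99.0,
    seed: int = 0,
    window_bp: int = 500_000,
    step_bp: int = 50_000,
    null: str = "pooled",
) -> PoolScreenResult:
    """Permutation thresholds for window-level SDS/ESDS enrichment.

    Each iteration permutes the flag labels uniformly across all SNP
    positions genome-wide (preserving per-window SNP occupancy) and
    recomputes every window count.  The threshold is the stated percentile
    of the pooled permuted window-count distribution (``null="pooled"``,
    the default) or of the per-iteration maxima (``null="max"``, the
    family-wise alternative).  Windows with observed count strictly above
    the threshold are called enriched.  With zero flagged SNPs thresholds
    are 0 and nothing is enriched.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    rng = np.random.default_rng(seed)
    grid = make_windows(chrom_lengths, window_bp, step_bp)
    obs = window_counts(flagged, chrom_lengths, window_bp, step_bp)
    pos0 = flagged["pos"].to_numpy() - 1
    chrom = flagged["chrom"].to_numpy()
    n_snps = len(flagged)

    thresholds: dict[str, float] = {}
    for col in ("sds", "esds"):
        k = int(flagged[col].sum())
        if k == 0:
            thresholds[col] = 0.0
            obs[f"{col}_enriched"] = False
            continue
        stat = np.empty(n_perm * len(grid) if null == "pooled" else n_perm)
        for it in range(n_perm):
            pick = rng.choice(n_snps, size=k, replace=False)
            counts = _window_counts_for(grid, chrom[pick], pos0[pick])
            if null == "pooled":
                stat[it * len(grid) : (it + 1) * len(grid)] = counts
            else:
                stat[it] = counts.max()
        thresholds[col] = float(np.percentile(stat, percentile))
        obs[f"{col}_enriched"] = obs[f"{col}_count"].to_numpy() > thresholds[col]
    return PoolScreenResult(per_snp=flagged, windows=obs, thresholds=thresholds)


def run_screen(
    gm: GenotypeMatrix,
    phenotype: pd.DataFrame,
    typical: np.ndarray,
    pool_size: int = 20,
    subgroup: str = "",
    n_perm: int = 10_000,
    seed: int = 0,
    window_bp: int = 500_000,
    step_bp: int = 50_000,
) -> PoolScreenResult:
    """Full screen: pools -> chi-squared -> flags -> windows -> thresholds."""
    pools = select_polar_pools(phenotype, typical, pool_size, subgroup)
    flagged = classify_sds(allele_freq_chisq(gm, pools))
    result = permutation_threshold(
        flagged, gm.contig_lengths, n_perm=n_perm, seed=seed,
        window_bp=window_bp, step_bp=step_bp,
    )
    result.pools = pools
    return result
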