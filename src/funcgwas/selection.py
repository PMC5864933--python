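"""Nucleotide diversity, Tajima's D and between-population diversity ratios.

Inbred accessions contribute one haploid sequence each (dosage 0 -> ref,
2 -> alt; heterozygous or missing calls mask the site for that
accession).  Diversity is computed over a genomic region including its
invariant sites, so per-site pi is comparable across regions of different
length.  A selective sweep in a focal population shows up as an elevated
reference-to-focal diversity ratio and a strongly negative Tajima's D.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotate import GeneModel
from .genotypes import GenotypeMatrix


class ContractError(ValueError):
    pass


def tajima_constants(n: int) -> dict[str, float]:
    """Normalization constants for Tajima's D at sample size n (1989 form)."""
    if n < 2:
        raise ContractError("Tajima constants require n >= 2")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


@dataclass
class SelectionStats:
    chrom: str
    start: int  # 0-based half-open region
    end: int
    population: str
    n_sequences: int
    segregating_sites: int
    pi_per_site: float
    theta_w_per_site: float
    tajimas_d: float | None
    d_missing_reason: str | None = None

    @property
    def region_length(self) -> int:
        return self.end - self.start


def _region_haplotypes(
    gm: GenotypeMatrix, chrom: str, start: int, end: int, accession_idx=None
) -> tuple[np.ndarray, np.ndarray, int]:
    """(values 0/1, called mask) over variant sites in [start, end) plus region length.

    Heterozygous and missing calls are masked per accession-site.
    """
    if end <= start:
        raise ContractError("region length must be positive")
    ai = (
        np.arange(gm.n_accessions)
        if accession_idx is None
        else np.asarray(accession_idx)
    )
    if ai.dtype == bool:
        ai = np.flatnonzero(ai)
    if len(ai) < 2:
        raise ContractError("at least 2 sequences are required")
    pos0 = gm.pos - 1
    in_region = (gm.chrom == chrom) & (pos0 >= start) & (pos0 < end)
    D = gm.dosage[np.ix_(ai, np.flatnonzero(in_region))]
    called = (D == 0) | (D == 2)
    values = (D == 2).astype(np.int64)
    return values, called, end - start


def nucleotide_diversity(
    gm: GenotypeMatrix,
    chrom: str,
    start: int,
    end: int,
    accession_idx=None,
) -> float:
    """Per-site pi: mean over sequence pairs of (differences / comparable sites).

    Sites absent from the variant table are invariant and comparable for
    every pair; variant sites enter a pair's comparison only when both
    sequences are called there.
    """
    values, called, length = _region_haplotypes(gm, chrom, start, end, accession_idx)
    n = values.shape[0]
    A = values * called  # alt indicator among called
    R = (1 - values) * called  # ref indicator among called
    diff = A @ R.T + R @ A.T  # pairwise difference counts
    comp = called.astype(np.int64) @ called.astype(np.int64).T
    invariant = length - values.shape[1]
    iu = np.triu_indices(n, k=1)
    denom = comp[iu] + invariant
    if np.any(denom == 0):
        raise ContractError("a sequence pair has no comparable sites")
    return float(np.mean(diff[iu] / denom))


def tajimas_d(
    gm: GenotypeMatrix,
    chrom: str,
    start: int,
    end: int,
    population: str = "all",
    accession_idx=None,
) -> SelectionStats:
    """Tajima's D over a region: D = (pi - S/a1) / sqrt(e1 S + e2 S(S-1)).

    For internal consistency the numerator's pi (total, not per-site) and
    S are computed over the same complete-case site mask: only sites
    called in every sequence enter.
    """
    values, called, length = _region_haplotypes(gm, chrom, start, end, accession_idx)
    n = values.shape[0]
    complete = called.all(axis=0)
    v = values[:, complete]
    alt = v.sum(axis=0)
    seg = (alt > 0) & (alt < n)
    S = int(seg.sum())
    k = alt[seg]
    pi_total = float(np.sum(2.0 * k * (n - k) / (n * (n - 1))))
    const = tajima_constants(n)
    theta_w = S / const["a1"]
    # per-site estimates use pairwise-complete pi for reporting
    pi_site = nucleotide_diversity(gm, chrom, start, end, accession_idx)
    if S == 0:
        return SelectionStats(
            chrom, start, end, population, n, 0, pi_site, 0.0, None,
            d_missing_reason="no segregating sites",
        )
    var = const["e1"] * S + const["e2"] * S * (S - 1)
    if var <= 0:  # n = 2 degenerates: the D variance is identically zero
        return SelectionStats(
            chrom, start, end, population, n, S, pi_site, theta_w / length, None,
            d_missing_reason="variance undefined at this sample size",
        )
    D = (pi_total - theta_w) / np.sqrt(var)
    return SelectionStats(
        chrom, start, end, population, n, S, pi_site,
        theta_w / length, float(D),
    )


def diversity_ratio(
    stats_ref: SelectionStats, stats_focal: SelectionStats
) -> tuple[float, bool]:
    """pi_reference / pi_focal over one region; (ratio, is_infinite flag).

    An elevated ratio means the focal population lost diversity there -
    the footprint of a selective sweep or bottleneck.
    """
    if (stats_ref.chrom, stats_ref.start, stats_ref.end) != (
        stats_focal.chrom, stats_focal.start, stats_focal.end,
    ):
        raise ContractError("diversity ratio requires matching regions")
    if stats_focal.pi_per_site == 0.0:
        return float("inf"), True
    return stats_ref.pi_per_site / stats_focal.pi_per_site, False


def gene_region(model: GeneModel, flank_bp: int = 2000) -> tuple[str, int, int]:
    """Gene span plus a promoter-inclusive flank on both sides (0-based half-open)."""
    lo, hi = model.span
    return model.chrom, max(0, lo - flank_bp), hi + flank_bp
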