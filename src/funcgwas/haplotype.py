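"""Linkage disequilibrium, haplotype analysis and functional-SNP isolation.

After a GWAS peak is found, the SNPs in strong LD with it (r² > 0.6 to the
peak) form a candidate block.  Within a gene, the protein-altering SNPs
define haplotypes; haplotype phenotype differences are tested by one-way
ANOVA with Duncan's multiple range test for letter grouping, and a
conditional re-scan on carriers of one allele of a candidate SNP isolates
which block member actually drives the signal (the member whose
conditioning extinguishes every other association).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import MISSING, GenotypeMatrix


class ContractError(ValueError):
    pass


@lru_cache(maxsize=8192)
def _studentized_range_q(protection_level: float, span: int, df: int) -> float:
    """Cached studentized-range quantile (scipy's ppf is expensive)."""
    return float(stats.studentized_range.ppf(protection_level, span, df))


# ---------------------------------------------------------------------------
# linkage disequilibrium


def pairwise_r2(
    gm: GenotypeMatrix, snp_ids: list[str], min_complete: int = 10
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Squared Pearson correlation of dosages per SNP pair.

    Pairwise-complete accessions are used for each pair (the composite,
    inbred-panel convention - phase is trivial at homozygosity).  Pairs
    with a monomorphic SNP in the complete subset get NaN; pairs with
    fewer than ``min_complete`` complete accessions are flagged unreliable.
    """
    cols = [gm.snp_index(s) for s in snp_ids]
    D = gm.dosage[:, cols].astype(float)
    D[D == MISSING] = np.nan
    k = len(cols)
    r2 = np.full((k, k), np.nan)
    reliable = np.ones((k, k), dtype=bool)
    np.fill_diagonal(r2, 1.0)
    for i in range(k):
        for j in range(i + 1, k):
            both = ~np.isnan(D[:, i]) & ~np.isnan(D[:, j])
            n = int(both.sum())
            if n < min_complete:
                reliable[i, j] = reliable[j, i] = False
            x, y = D[both, i], D[both, j]
            if n < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            r = np.corrcoef(x, y)[0, 1]
            r2[i, j] = r2[j, i] = r * r
    idx = list(snp_ids)
    return (
        pd.DataFrame(r2, index=idx, columns=idx),
        pd.DataFrame(reliable, index=idx, columns=idx),
    )


def r2_to_anchor(
    gm: GenotypeMatrix, anchor_snp: str, snp_ids: list[str]
) -> np.ndarray:
    """Vectorized pairwise-complete r² of each SNP against one anchor SNP."""
    ja = gm.snp_index(anchor_snp)
    x = gm.dosage[:, ja].astype(float)
    x[gm.dosage[:, ja] == MISSING] = np.nan
    cols = [gm.snp_index(s) for s in snp_ids]
    Y = gm.dosage[:, cols].astype(float)
    Y[gm.dosage[:, cols] == MISSING] = np.nan
    both = ~np.isnan(x)[:, None] & ~np.isnan(Y)
    x0 = np.where(np.isnan(x), 0.0, x)
    y0 = np.where(np.isnan(Y), 0.0, Y)
    n = both.sum(axis=0).astype(float)
    sx = x0 @ both
    sy = (y0 * both).sum(axis=0)
    sxx = (x0**2) @ both
    syy = (y0**2 * both).sum(axis=0)
    sxy = x0 @ (y0 * both)
    with np.errstate(invalid="ignore", divide="ignore"):
        var_term = (n * sxx - sx**2) * (n * syy - sy**2)
        r = np.where(var_term > 0, (n * sxy - sx * sy) / np.sqrt(var_term), np.nan)
    r2 = r**2
    r2[n < 2] = np.nan
    return r2


@dataclass
class LdBlock:
    """SNPs in LD (r² above threshold) with a peak SNP."""

    peak_snp: str
    snp_ids: list[str]  # members sorted by position, peak included
    r2_to_peak: dict[str, float]
    r2_min: float
    start: int
    end: int


def define_block(
    gm: GenotypeMatrix,
    peak_snp: str,
    candidate_snp_ids: list[str],
    r2_min: float = 0.6,
) -> LdBlock:
    """Peak-anchored block: candidates with r²(candidate, peak) > ``r2_min``."""
    jp = gm.snp_index(peak_snp)
    peak_col = gm.dosage[:, jp]
    valid = peak_col[peak_col != MISSING]
    if valid.size == 0 or np.ptp(valid) == 0:
        raise ContractError(f"peak SNP {peak_snp} is monomorphic")
    ids = [s for s in candidate_snp_ids if s != peak_snp]
    vals = r2_to_anchor(gm, peak_snp, ids)
    to_peak = dict(zip(ids, vals))
    to_peak[peak_snp] = 1.0
    members = [peak_snp] + [
        s for s in ids if not np.isnan(to_peak[s]) and to_peak[s] > r2_min
    ]
    pos = {s: int(gm.pos[gm.snp_index(s)]) for s in members}
    members.sort(key=lambda s: pos[s])
    return LdBlock(
        peak_snp=peak_snp,
        snp_ids=members,
        r2_to_peak={s: float(to_peak[s]) for s in members},
        r2_min=r2_min,
        start=min(pos.values()),
        end=max(pos.values()),
    )


# ---------------------------------------------------------------------------
# haplotypes


@dataclass
class HaplotypeTable:
    """Haplotypes of a gene over its defining (protein-altering) SNPs.

    Labels A, B, C, ... are assigned by descending accession count (ties by
    allele string).  Haplotypes below ``min_count`` are reported but
    flagged minor and excluded from phenotype tests.
    """

    gene_id: str
    snp_ids: list[str]
    assignments: pd.Series  # accession -> label (labelable accessions only)
    summary: pd.DataFrame  # label, alleles, count, minor [, mean, sd, letter]
    min_count: int

    def retained(self) -> list[str]:
        return list(self.summary.loc[~self.summary["minor"], "label"])


def assign_haplotypes(
    gm: GenotypeMatrix,
    snp_ids: list[str],
    phenotype: pd.DataFrame | None = None,
    min_count: int = 4,
    gene_id: str = "",
    id_col: str = "accession_id",
    value_col: str = "ML_cm",
) -> HaplotypeTable:
    """Label each fully-called homozygous accession by its allele string.

    Accessions with a missing or heterozygous call at any defining SNP are
    excluded from labeling (heterozygotes in an inbred panel are most
    likely genotyping errors).
    """
    import warnings

    if not snp_ids:
        raise ContractError("at least one defining SNP is required")
    cols = [gm.snp_index(s) for s in snp_ids]
    D = gm.dosage[:, cols]
    labelable = np.all((D == 0) | (D == 2), axis=1)
    if not labelable.any():
        warnings.warn("no accession is fully called at the defining SNPs", stacklevel=2)
    ref = np.array([gm.ref[c] for c in cols], dtype=object)
    alt = np.array([gm.alt[c] for c in cols], dtype=object)
    strings = {}
    for i in np.flatnonzero(labelable):
        alleles = np.where(D[i] == 0, ref, alt)
        strings[gm.accessions[i]] = "".join(alleles)
    counts = pd.Series(strings).value_counts()
    ordered = sorted(counts.index, key=lambda s: (-counts[s], s))
    letters = {s: chr(ord("A") + i) for i, s in enumerate(ordered)}
    assignments = pd.Series({a: letters[s] for a, s in strings.items()}).sort_index()
    rows = []
    for s in ordered:
        rows.append(
            {
                "label": letters[s],
                "alleles": s,
                "count": int(counts[s]),
                "minor": int(counts[s]) < min_count,
            }
        )
    summary = pd.DataFrame(rows)
    if phenotype is not None and not summary.empty:
        ph = phenotype.set_index(id_col)[value_col]
        means, sds = [], []
        for s in ordered:
            members = [a for a, lab in assignments.items() if lab == letters[s]]
            vals = ph.reindex(members).dropna()
            means.append(float(vals.mean()) if len(vals) else np.nan)
            sds.append(float(vals.std(ddof=1)) if len(vals) > 1 else np.nan)
        summary["mean"] = means
        summary["sd"] = sds
    return HaplotypeTable(
        gene_id=gene_id,
        snp_ids=list(snp_ids),
        assignments=assignments,
        summary=summary,
        min_count=min_count,
    )


# ---------------------------------------------------------------------------
# ANOVA and Duncan's multiple range test


@dataclass
class AnovaResult:
    F: float
    p: float
    df_between: int
    df_within: int
    ms_within: float
    groups: pd.DataFrame  # label, n, mean
    excluded: list[str] = field(default_factory=list)
    testable: bool = True


def anova_oneway(values: np.ndarray, labels: np.ndarray) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA.

    Groups with fewer than 2 members are excluded (logged in
    ``excluded``); with fewer than 2 groups remaining the result is
    flagged untestable rather than raised.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    keep = ~np.isnan(values)
    values, labels = values[keep], labels[keep]
    uniq, counts = np.unique(labels, return_counts=True)
    excluded = [str(u) for u, c in zip(uniq, counts) if c < 2]
    mask = ~np.isin(labels, excluded)
    values, labels = values[mask], labels[mask]
    uniq = np.unique(labels)
    rows = [
        {"label": str(u), "n": int(np.sum(labels == u)), "mean": float(values[labels == u].mean())}
        for u in uniq
    ]
    groups = pd.DataFrame(rows)
    if len(uniq) < 2:
        return AnovaResult(np.nan, np.nan, 0, 0, np.nan, groups, excluded, testable=False)
    grand = values.mean()
    ssb = sum(r["n"] * (r["mean"] - grand) ** 2 for r in rows)
    ssw = sum(
        float(np.sum((values[labels == u] - values[labels == u].mean()) ** 2))
        for u in uniq
    )
    dfb = len(uniq) - 1
    dfw = len(values) - len(uniq)
    msb, msw = ssb / dfb, ssw / dfw
    F = msb / msw if msw > 0 else np.inf
    p = float(stats.f.sf(F, dfb, dfw)) if np.isfinite(F) else 0.0
    return AnovaResult(float(F), max(p, 1e-300), dfb, dfw, float(msw), groups, excluded)


def duncan_mrt(
    values: np.ndarray, labels: np.ndarray, alpha: float = 0.05
) -> pd.DataFrame:
    """Duncan's multiple range test with compact letter display.

    Critical ranges come from the studentized range distribution at the
    protection levels (1-alpha)^(k-1) for a span of k means; the harmonic
    mean group size handles unbalanced data.  Two groups share a letter
    exactly when Duncan's step-down procedure declares them not
    significantly different.  Letters are invariant to input ordering.
    """
    an = anova_oneway(values, labels)
    if not an.testable:
        out = an.groups.copy()
        out["letters"] = "a"
        return out
    g = len(an.groups)
    order = an.groups.sort_values(["mean", "label"], ascending=[False, True], kind="stable")
    means = order["mean"].to_numpy()
    ns = order["n"].to_numpy()
    n_h = g / np.sum(1.0 / ns)
    se = np.sqrt(an.ms_within / n_h)

    def crit(span: int) -> float:
        return _studentized_range_q((1.0 - alpha) ** (span - 1), span, an.df_within) * se

    intervals: list[tuple[int, int]] = []  # maximal non-significant runs

    def covered(i: int, j: int) -> bool:
        return any(a <= i and j <= b for a, b in intervals)

    for span in range(g, 1, -1):
        for i in range(0, g - span + 1):
            j = i + span - 1
            if covered(i, j):
                continue
            if means[i] - means[j] <= crit(span):
                intervals.append((i, j))
    letters = ["" for _ in range(g)]
    next_letter = 0
    for a, b in sorted(intervals):
        ch = chr(ord("a") + next_letter)
        next_letter += 1
        for i in range(a, b + 1):
            letters[i] += ch
    for i in range(g):
        if not letters[i]:
            letters[i] = chr(ord("a") + next_letter)
            next_letter += 1
    out = order.reset_index(drop=True).copy()
    out["letters"] = letters
    return out


# ---------------------------------------------------------------------------
# conditional scan and functional-SNP isolation


def conditional_scan(
    gm: GenotypeMatrix,
    phenotype: np.ndarray,
    block: LdBlock,
    condition_snp: str,
    condition_allele: str,
    covariates: np.ndarray | None = None,
    min_carriers: int = 30,
    subset_maf_min: float = 0.05,
) -> pd.DataFrame:
    """Re-scan block members among homozygous carriers of one allele.

    Subsetting to carriers of the conditioning allele removes the
    conditioning SNP's variation; any member whose signal survives is not
    explained by it.  Members monomorphic or below the standard MAF filter
    in the subset are reported untestable ("no allelic diversity"), not
    significant.
    """
    from .gwas import run_glm

    jc = gm.snp_index(condition_snp)
    if condition_allele == gm.ref[jc]:
        carriers = gm.dosage[:, jc] == 0
    elif condition_allele == gm.alt[jc]:
        carriers = gm.dosage[:, jc] == 2
    else:
        raise ContractError(
            f"allele {condition_allele!r} is neither REF nor ALT of {condition_snp}"
        )
    n_car = int(carriers.sum())
    if n_car < min_carriers:
        raise ContractError(
            f"only {n_car} homozygous carriers of {condition_snp}:{condition_allele} "
            f"(minimum {min_carriers})"
        )
    idx = np.flatnonzero(carriers)
    sub = gm.subset(accession_idx=idx, snp_idx=[gm.snp_index(s) for s in block.snp_ids])
    y = np.asarray(phenotype, dtype=float)[idx]
    cov = None if covariates is None else np.asarray(covariates)[idx]

    maf = sub.maf()
    rows = []
    testable_idx = []
    for k, sid in enumerate(sub.snp_ids):
        if np.isnan(maf[k]) or maf[k] == 0:
            rows.append((sid, int(sub.pos[k]), np.nan, np.nan, np.nan, True, "no allelic diversity"))
        elif maf[k] < subset_maf_min:
            rows.append((sid, int(sub.pos[k]), float(maf[k]), np.nan, np.nan, True,
                         f"subset MAF {maf[k]:.3f} below {subset_maf_min}"))
        else:
            testable_idx.append(k)
            rows.append(None)
    if testable_idx:
        res = run_glm(sub.subset(snp_idx=testable_idx), y, cov)
        by_id = res.table.set_index("snp_id")
        for k in testable_idx:
            sid = sub.snp_ids[k]
            if sid in by_id.index:
                r = by_id.loc[sid]
                rows[k] = (sid, int(sub.pos[k]), float(maf[k]), float(r["p"]),
                           float(r["neglog10p"]), False, "")
            else:
                rows[k] = (sid, int(sub.pos[k]), float(maf[k]), np.nan, np.nan, True,
                           "monomorphic after missing-call drops")
    out = pd.DataFrame(
        rows,
        columns=["snp_id", "pos", "subset_maf", "p", "neglog10p", "untestable", "reason"],
    )
    out.insert(0, "condition_allele", condition_allele)
    out.insert(0, "condition_snp", condition_snp)
    out["n_carriers"] = n_car
    return out


def identify_functional_snp(
    gm: GenotypeMatrix,
    phenotype: np.ndarray,
    block: LdBlock,
    covariates: np.ndarray | None = None,
    signal_neglog10p: float = 2.0,
    min_carriers: int = 30,
    min_count: int = 4,
) -> pd.DataFrame:
    """Rank block members by conditional-scan and haplotype evidence.

    A member "kills" the block when, conditioning on each of its alleles
    (with enough homozygous carriers), no *other* member retains a signal
    at ``signal_neglog10p``.  A haplotype-consistency score - the absolute
    correlation, across retained block haplotypes, between the member's
    allele and the haplotype phenotype mean - breaks ties: the functional
    SNP is the one whose alleles separate long- from short-phenotype
    haplotypes.  Rows are sorted best candidate first.
    """
    y = np.asarray(phenotype, dtype=float)
    phen_df = pd.DataFrame({"accession_id": gm.accessions, "ML_cm": y})
    table = assign_haplotypes(gm, block.snp_ids, phen_df, min_count=min_count)
    retained = table.summary.loc[~table.summary["minor"]]

    marginal = {}
    from .gwas import run_glm

    res = run_glm(
        gm.subset(snp_idx=[gm.snp_index(s) for s in block.snp_ids]), y, covariates
    )
    for _, r in res.table.iterrows():
        marginal[r["snp_id"]] = float(r["neglog10p"])

    rows = []
    for k, sid in enumerate(block.snp_ids):
        j = gm.snp_index(sid)
        kills = True
        any_side = False
        for allele in (gm.ref[j], gm.alt[j]):
            hom = 0 if allele == gm.ref[j] else 2
            if int(np.sum(gm.dosage[:, j] == hom)) < min_carriers:
                continue
            any_side = True
            scan = conditional_scan(
                gm, y, block, sid, allele, covariates, min_carriers
            )
            others = scan[scan["snp_id"] != sid]
            alive = others[
                (~others["untestable"]) & (others["neglog10p"] >= signal_neglog10p)
            ]
            if len(alive):
                kills = False
        if not any_side:
            kills = False
        # haplotype consistency across retained haplotypes
        consistency = 0.0
        if len(retained) >= 2:
            allele_states = np.array(
                [1.0 if s[k] == gm.alt[j] else 0.0 for s in retained["alleles"]]
            )
            means = retained["mean"].to_numpy(dtype=float)
            if np.ptp(allele_states) > 0 and np.ptp(means) > 0:
                consistency = abs(np.corrcoef(allele_states, means)[0, 1])
        rows.append(
            {
                "snp_id": sid,
                "kills_block": kills,
                "consistency": consistency,
                "marginal_neglog10p": marginal.get(sid, np.nan),
            }
        )
    out = pd.DataFrame(rows)
    out["score"] = 2.0 * out["kills_block"].astype(float) + out["consistency"]
    out = out.sort_values(
        ["score", "marginal_neglog10p"], ascending=[False, False], kind="stable"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


# ---------------------------------------------------------------------------
# haplotype combinations across two genes


@dataclass
class ComboResult:
    gene1: str
    gene2: str
    assignments: pd.Series  # accession -> "X+Y"
    summary: pd.DataFrame  # combo, count, mean, sd [, letters]
    anova: AnovaResult | None = None


def combine_haplotypes(
    table1: HaplotypeTable,
    table2: HaplotypeTable,
    phenotype: pd.DataFrame,
    alpha: float = 0.05,
    id_col: str = "accession_id",
    value_col: str = "ML_cm",
) -> ComboResult:
    """Joint haplotype combinations of two genes with ANOVA + Duncan letters.

    Only accessions labeled with a retained (non-minor) haplotype at both
    genes enter; unobserved combinations are omitted.
    """
    import warnings

    r1, r2 = set(table1.retained()), set(table2.retained())
    a1 = table1.assignments[table1.assignments.isin(r1)]
    a2 = table2.assignments[table2.assignments.isin(r2)]
    common = a1.index.intersection(a2.index)
    if len(common) == 0:
        warnings.warn("no accession is labeled at both genes", stacklevel=2)
    combos = pd.Series(
        {a: f"{a1[a]}+{a2[a]}" for a in common}, dtype=object
    ).sort_index()
    ph = phenotype.set_index(id_col)[value_col]
    vals = ph.reindex(combos.index)
    summary_rows = []
    for combo, members in combos.groupby(combos):
        v = vals.reindex(members.index).dropna()
        summary_rows.append(
            {
                "combo": combo,
                "count": int(len(members)),
                "mean": float(v.mean()) if len(v) else np.nan,
                "sd": float(v.std(ddof=1)) if len(v) > 1 else np.nan,
            }
        )
    summary = pd.DataFrame(summary_rows, columns=["combo", "count", "mean", "sd"])
    summary = summary.sort_values("combo").reset_index(drop=True)
    an = None
    if len(summary) >= 2:
        an = anova_oneway(vals.to_numpy(), combos.to_numpy())
        if an.testable:
            letters = duncan_mrt(vals.to_numpy(), combos.to_numpy(), alpha=alpha)
            summary = summary.merge(
                letters[["label", "letters"]], left_on="combo", right_on="label", how="left"
            ).drop(columns="label")
    return ComboResult(
        gene1=table1.gene_id,
        gene2=table2.gene_id,
        assignments=combos,
        summary=summary,
        anova=an,
    )
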