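"""Single-SNP association testing and QTL calling.

Two models are provided:

* ``run_glm``  - ordinary least squares of the phenotype on PC covariates
  plus the SNP genotype, the fast structure-naive baseline.
* ``run_mlm``  - mixed linear model y = Xb + u + e with cov(u) = s_g^2 K,
  fitted by REML through a single spectral decomposition of the kinship
  matrix (the EMMA device); optional *compression* clusters accessions by
  kinship (average linkage) and replaces K with the between-group mean
  kinship, the compressed-MLM idea that trades individual kinship for
  group kinship to gain power and speed.

Genotype is coded as dosage/2 (0, 0.5, 1 for inbred panels), so the
reported slope is the phenotype difference between alternate and reference
homozygotes in cm - the natural effect scale for inbred accessions.

Significance uses the scan-adaptive threshold
-log10(alpha / m) with m = number of SNPs with p < alpha in the scan at
hand (a Bonferroni correction over the "effective" SNPs), alongside
Benjamini-Hochberg q-values.  Significant SNPs closer than an LD-decay
informed merge distance (170 kb by default) chain into QTLs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import MISSING, GenotypeMatrix

P_FLOOR = 1e-300


class NoEffectiveSnpsError(ValueError):
    """No SNP reached p < alpha, so the adaptive threshold is undefined."""


class NumericalInputError(ValueError):
    """Kinship matrix is not positive semi-definite within tolerance."""


@dataclass
class AssociationResult:
    """Per-SNP association statistics for one model on one SNP set."""

    table: pd.DataFrame  # chrom, pos, snp_id, beta, se, t, p, neglog10p, q
    model: str  # "GLM" | "MLM" | "CMLM"
    snp_group: str | None = None
    covariate_source: str | None = None
    skipped: list[tuple[str, str]] = field(default_factory=list)
    reml: dict | None = None

    def significant(self, threshold_neglog10p: float) -> pd.DataFrame:
        return self.table[self.table["neglog10p"] > threshold_neglog10p]


@dataclass
class Qtl:
    """A merged run of significant SNPs on one chromosome."""

    qtl_id: str
    chrom: str
    start: int
    end: int
    snp_ids: list[str]
    peak_snp: str
    peak_pos: int
    peak_neglog10p: float


def _finalize(gm, used, rows, model, skipped, **meta) -> AssociationResult:
    tab = pd.DataFrame(
        rows, columns=["beta", "se", "t", "p"], index=np.flatnonzero(used)
    )
    idx = tab.index.to_numpy()
    tab.insert(0, "snp_id", gm.snp_ids[idx])
    tab.insert(0, "pos", gm.pos[idx])
    tab.insert(0, "chrom", gm.chrom[idx])
    tab["p"] = np.clip(tab["p"].to_numpy(), P_FLOOR, 1.0)
    tab["neglog10p"] = -np.log10(tab["p"])
    tab["q"] = fdr_adjust(tab["p"].to_numpy())
    tab = tab.reset_index(drop=True)
    return AssociationResult(table=tab, model=model, skipped=skipped, **meta)


def _design(n: int, covariates: np.ndarray | None) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    cov = np.atleast_2d(np.asarray(covariates, dtype=float))
    if cov.shape[0] != n:
        cov = cov.T
    return np.column_stack([np.ones(n), cov])


def _ols_block(y: np.ndarray, X: np.ndarray, G: np.ndarray):
    """OLS t-tests of each column of G added to design X (no missing values).

    Uses Frisch-Waugh-Lovell: residualize y and G against X once, then the
    slope test is a simple regression per column.
    """
    n, q = X.shape
    Q, _ = np.linalg.qr(X)
    ry = y - Q @ (Q.T @ y)
    RG = G - Q @ (Q.T @ G)
    sgg = np.einsum("ij,ij->j", RG, RG)
    ok = sgg > 1e-12
    beta = np.full(G.shape[1], np.nan)
    se = np.full(G.shape[1], np.nan)
    tval = np.full(G.shape[1], np.nan)
    pval = np.full(G.shape[1], np.nan)
    df = n - q - 1
    if df <= 0:
        raise ValueError("not enough residual degrees of freedom")
    syy = ry @ ry
    b = (RG[:, ok].T @ ry) / sgg[ok]
    rss = np.maximum(syy - b**2 * sgg[ok], 0.0)
    sigma2 = rss / df
    s = np.sqrt(np.maximum(sigma2 / sgg[ok], 1e-300))
    t = b / s
    beta[ok], se[ok], tval[ok] = b, s, t
    pval[ok] = 2.0 * stats.t.sf(np.abs(t), df)
    return beta, se, tval, pval, ok


def run_glm(
    gm: GenotypeMatrix,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
    snp_group: str | None = None,
    covariate_source: str | None = None,
) -> AssociationResult:
    """OLS association of phenotype on [intercept, covariates, dosage/2].

    Accessions with a missing call at a SNP are dropped for that SNP
    (casewise deletion); SNPs monomorphic after drops are skipped with a
    logged reason.
    """
    y = np.asarray(phenotype, dtype=float)
    n = gm.n_accessions
    if len(y) != n:
        raise ValueError("phenotype length does not match accessions")
    X = _design(n, covariates)
    G = gm.dosage.astype(float) / 2.0
    miss = gm.dosage == MISSING

    used = np.zeros(gm.n_snps, dtype=bool)
    rows = []
    skipped: list[tuple[str, str]] = []

    complete = ~miss.any(axis=0)
    if complete.any():
        beta, se, t, p, ok = _ols_block(y, X, G[:, complete])
        cols = np.flatnonzero(complete)
        for i, j in enumerate(cols):
            if ok[i]:
                used[j] = True
                rows.append((beta[i], se[i], t[i], p[i]))
            else:
                skipped.append((gm.snp_ids[j], "monomorphic"))
    for j in np.flatnonzero(~complete):
        keep = ~miss[:, j]
        g = G[keep, j]
        if keep.sum() <= X.shape[1] + 1 or np.ptp(g) == 0:
            skipped.append((gm.snp_ids[j], "monomorphic or too few calls"))
            continue
        b, s, t, p, ok = _ols_block(y[keep], X[keep], g.reshape(-1, 1))
        if not ok[0]:
            skipped.append((gm.snp_ids[j], "monomorphic"))
            continue
        used[j] = True
        rows.append((b[0], s[0], t[0], p[0]))

    return _finalize(
        gm, used, _reorder_rows(used, rows, complete), "GLM", skipped,
        snp_group=snp_group, covariate_source=covariate_source,
    )


def _reorder_rows(used, rows, complete):
    """Align accumulated rows with ascending SNP index."""
    cols = list(np.flatnonzero(used & complete)) + list(np.flatnonzero(used & ~complete))
    order = np.argsort(cols, kind="stable")
    return [rows[i] for i in order]


# ---------------------------------------------------------------------------
# mixed model


def _reml_loglik(delta: float, xi: np.ndarray, eta2: np.ndarray, nq: int) -> float:
    denom = xi + delta
    ss = np.sum(eta2 / denom)
    return 0.5 * (
        nq * (np.log(nq / (2.0 * np.pi)) - 1.0 - np.log(ss)) - np.sum(np.log(denom))
    )


def _reml_fit(y: np.ndarray, X: np.ndarray, K: np.ndarray) -> dict:
    """REML variance components for V = s_g^2 (K + delta I), EMMA-style.

    Profiles the likelihood over delta = s_e^2 / s_g^2 on a log grid
    [1e-5, 1e5] followed by golden-section refinement (tolerance 1e-6 on
    log10 delta).
    """
    n, q = X.shape
    XtX = X.T @ X
    S = np.eye(n) - X @ np.linalg.solve(XtX, X.T)
    M = S @ K @ S
    M = 0.5 * (M + M.T)
    w, V = np.linalg.eigh(M)
    xi = np.maximum(w[q:], 0.0)  # keep the n-q informative eigenvalues
    W = V[:, q:]
    eta2 = (W.T @ y) ** 2
    nq = n - q

    grid = np.logspace(-5, 5, 100)
    lls = [_reml_loglik(d, xi, eta2, nq) for d in grid]
    i = int(np.argmax(lls))
    lo = np.log10(grid[max(i - 1, 0)])
    hi = np.log10(grid[min(i + 1, len(grid) - 1)])
    phi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c, d = b - phi * (b - a), a + phi * (b - a)
    fc = _reml_loglik(10**c, xi, eta2, nq)
    fd = _reml_loglik(10**d, xi, eta2, nq)
    while (b - a) > 1e-6:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - phi * (b - a)
            fc = _reml_loglik(10**c, xi, eta2, nq)
        else:
            a, c, fc = c, d, fd
            d = a + phi * (b - a)
            fd = _reml_loglik(10**d, xi, eta2, nq)
    delta = 10 ** (0.5 * (a + b))
    ll = _reml_loglik(delta, xi, eta2, nq)
    sigma_g2 = float(np.sum(eta2 / (xi + delta)) / nq)
    return {
        "delta": float(delta),
        "loglik": float(ll),
        "sigma_g2": sigma_g2,
        "sigma_e2": float(delta * sigma_g2),
    }


def compress_kinship(K: np.ndarray, n_groups: int) -> tuple[np.ndarray, np.ndarray]:
    """Average-linkage clustering on (max(K) - K), group-mean kinship expanded back.

    Returns (expanded kinship, group index per accession).
    """
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform

    n = K.shape[0]
    if n_groups >= n:
        return K, np.arange(n)
    D = np.max(K) - K
    np.fill_diagonal(D, 0.0)
    D = 0.5 * (D + D.T)
    Z = linkage(squareform(D, checks=False), method="average")
    groups = fcluster(Z, t=n_groups, criterion="maxclust") - 1
    g = groups.max() + 1
    # group-mean kinship (diagonal blocks average within-group entries)
    M = np.zeros((g, n))
    for k in range(g):
        M[k, groups == k] = 1.0 / np.sum(groups == k)
    Kc = M @ K @ M.T
    return Kc[np.ix_(groups, groups)], groups


def run_mlm(
    gm: GenotypeMatrix,
    phenotype: np.ndarray,
    covariates: np.ndarray | None,
    kinship: np.ndarray,
    compression_groups: int | str = "none",
    snp_group: str | None = None,
    covariate_source: str | None = None,
) -> AssociationResult:
    """Mixed-model association with optional kinship compression.

    ``compression_groups`` is a group count, ``"none"`` (individual
    kinship) or ``"auto"`` (group count chosen among n, n/2, n/4, ..., 8 by
    maximum REML likelihood).  Variance components are estimated once on
    the null model and reused for every SNP test (the population-parameters
    previously-determined shortcut); each SNP is then tested by generalized
    least squares.  SNPs with missing calls are tested by casewise deletion
    against the matching sub-covariance.
    """
    y = np.asarray(phenotype, dtype=float)
    n = gm.n_accessions
    X = _design(n, covariates)
    K = np.asarray(kinship, dtype=float)
    if K.shape != (n, n):
        raise ValueError("kinship shape does not match accessions")
    wmin = np.linalg.eigvalsh(0.5 * (K + K.T)).min()
    if wmin < -1e-6 * max(1.0, np.abs(K).max()):
        raise NumericalInputError(f"kinship has negative eigenvalue {wmin:.3g}")

    model = "MLM"
    if compression_groups == "auto":
        model = "CMLM"
        candidates = []
        g = n
        while g >= 8:
            candidates.append(g)
            g //= 2
        best = None
        for g in candidates:
            Kg, _ = compress_kinship(K, g)
            fit = _reml_fit(y, X, Kg)
            if best is None or fit["loglik"] > best[0]:
                best = (fit["loglik"], g, Kg, fit)
        _, g_best, K_eff, reml = best
        reml = dict(reml, groups=g_best)
    elif compression_groups == "none" or (
        isinstance(compression_groups, (int, np.integer)) and compression_groups >= n
    ):
        K_eff = K
        reml = _reml_fit(y, X, K_eff)
    else:
        model = "CMLM"
        K_eff, _ = compress_kinship(K, int(compression_groups))
        reml = _reml_fit(y, X, K_eff)
        reml = dict(reml, groups=int(compression_groups))

    delta = reml["delta"]
    w, U = np.linalg.eigh(0.5 * (K_eff + K_eff.T))
    w = np.maximum(w, 0.0)
    inv_sd = 1.0 / np.sqrt(w + delta)

    G = gm.dosage.astype(float) / 2.0
    miss = gm.dosage == MISSING
    yt = inv_sd * (U.T @ y)
    Xt = inv_sd[:, None] * (U.T @ X)

    used = np.zeros(gm.n_snps, dtype=bool)
    rows = []
    skipped: list[tuple[str, str]] = []

    complete = ~miss.any(axis=0)
    if complete.any():
        Gt = inv_sd[:, None] * (U.T @ G[:, complete])
        beta, se, t, p, ok = _ols_block(yt, Xt, Gt)
        for i, j in enumerate(np.flatnonzero(complete)):
            if ok[i] and np.ptp(G[:, j]) > 0:
                used[j] = True
                rows.append((beta[i], se[i], t[i], p[i]))
            else:
                skipped.append((gm.snp_ids[j], "monomorphic"))
    # Casewise deletion against the matching sub-covariance without a per-SNP
    # factorization: (V[keep,keep])^-1 = P_kk - P_km P_mm^-1 P_mk with
    # P = V^-1 precomputed once.
    incomplete = np.flatnonzero(~complete)
    q = X.shape[1]
    if incomplete.size:
        P = (U * (1.0 / (w + delta))) @ U.T
    for j in incomplete:
        keep = ~miss[:, j]
        g = G[keep, j]
        if keep.sum() <= q + 1 or np.ptp(g) == 0:
            skipped.append((gm.snp_ids[j], "monomorphic or too few calls"))
            continue
        M = np.zeros((n, q + 2))
        M[keep, 0] = y[keep]
        M[keep, 1 : q + 1] = X[keep]
        M[keep, q + 1] = g
        T = P @ M
        mi = np.flatnonzero(~keep)
        A = M[keep].T @ T[keep]
        if mi.size:
            Tm = T[mi]  # = P_mk M_k since M is zero on missing rows
            A -= Tm.T @ np.linalg.solve(P[np.ix_(mi, mi)], Tm)
        # A = [y X g]' V_sub^-1 [y X g]; GLS on design D = [X g]
        Dq = A[1:, 1:]
        Dy = A[1:, 0]
        try:
            coef = np.linalg.solve(Dq, Dy)
            Dq_inv_last = np.linalg.solve(Dq, np.eye(q + 1)[:, -1])
        except np.linalg.LinAlgError:
            skipped.append((gm.snp_ids[j], "singular design"))
            continue
        df = int(keep.sum()) - q - 1
        rss = float(A[0, 0] - coef @ Dy)
        sigma2 = max(rss, 0.0) / df
        var_b = sigma2 * Dq_inv_last[-1]
        if var_b <= 0:
            skipped.append((gm.snp_ids[j], "degenerate variance"))
            continue
        b = float(coef[-1])
        s = float(np.sqrt(var_b))
        t = b / s
        p = float(2.0 * stats.t.sf(abs(t), df))
        used[j] = True
        rows.append((b, s, t, p))

    return _finalize(
        gm, used, _reorder_rows(used, rows, complete), model, skipped,
        snp_group=snp_group, covariate_source=covariate_source, reml=reml,
    )


# ---------------------------------------------------------------------------
# thresholds, FDR, QTLs


def significance_threshold(
    p_values: np.ndarray, alpha: float = 0.01, fallback_bonferroni: bool = False
) -> float:
    """Scan-adaptive threshold on -log10(p): -log10(alpha / m).

    m counts the SNPs with p < alpha in this scan.  With m = 0 the
    threshold is undefined; optionally fall back to plain Bonferroni over
    all tested SNPs.
    """
    p = np.asarray(p_values, dtype=float)
    m = int(np.sum(p < alpha))
    if m == 0:
        if fallback_bonferroni and len(p):
            import warnings

            warnings.warn(
                "no effective SNPs (p < alpha); falling back to Bonferroni over "
                "all tested SNPs",
                stacklevel=2,
            )
            return float(-np.log10(alpha / len(p)))
        raise NoEffectiveSnpsError(f"no SNP reached p < {alpha}")
    return float(-np.log10(alpha / m))


def fdr_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def merge_qtls(
    significant: pd.DataFrame, merge_distance_bp: int = 170_000
) -> list[Qtl]:
    """Chain-merge significant SNPs into QTLs per chromosome.

    A SNP joins the current QTL when its gap to the previous member is
    strictly below ``merge_distance_bp``; the QTL peak is the member with
    the largest -log10(p) (ties break to the smaller position).
    """
    qtls: list[Qtl] = []
    if significant.empty:
        return qtls
    df = significant.sort_values(["chrom", "pos"], kind="stable")
    for chrom, sub in df.groupby("chrom", sort=True):
        current: list[pd.Series] = []
        for _, row in sub.iterrows():
            if current and row["pos"] - current[-1]["pos"] >= merge_distance_bp:
                qtls.append(_make_qtl(chrom, current, len(qtls) + 1))
                current = []
            current.append(row)
        if current:
            qtls.append(_make_qtl(chrom, current, len(qtls) + 1))
    return qtls


def _make_qtl(chrom: str, members: list[pd.Series], number: int) -> Qtl:
    peak = max(members, key=lambda r: (r["neglog10p"], -r["pos"]))
    return Qtl(
        qtl_id=f"qML{number}",
        chrom=str(chrom),
        start=int(min(r["pos"] for r in members)),
        end=int(max(r["pos"] for r in members)),
        snp_ids=[str(r["snp_id"]) for r in members],
        peak_snp=str(peak["snp_id"]),
        peak_pos=int(peak["pos"]),
        peak_neglog10p=float(peak["neglog10p"]),
    )


def compare_scans(
    qtls_a: list[Qtl], qtls_b: list[Qtl], merge_distance_bp: int = 170_000
) -> dict:
    """Pair QTLs across two scans by span overlap or peak proximity.

    Returns shared pairs with peak -log10(p) deltas (a minus b) and the
    QTLs unique to each scan.
    """
    used_b: set[int] = set()
    shared = []
    for qa in qtls_a:
        match = None
        for i, qb in enumerate(qtls_b):
            if i in used_b or qa.chrom != qb.chrom:
                continue
            overlap = qa.start <= qb.end and qb.start <= qa.end
            near = abs(qa.peak_pos - qb.peak_pos) < merge_distance_bp
            if overlap or near:
                match = i
                break
        if match is None:
            continue
        used_b.add(match)
        qb = qtls_b[match]
        shared.append(
            {
                "qtl_a": qa.qtl_id,
                "qtl_b": qb.qtl_id,
                "chrom": qa.chrom,
                "peak_a": qa.peak_neglog10p,
                "peak_b": qb.peak_neglog10p,
                "delta_peak": qa.peak_neglog10p - qb.peak_neglog10p,
            }
        )
    shared_a = {s["qtl_a"] for s in shared}
    shared_b = {s["qtl_b"] for s in shared}
    return {
        "shared": shared,
        "unique_a": [q.qtl_id for q in qtls_a if q.qtl_id not in shared_a],
        "unique_b": [q.qtl_id for q in qtls_b if q.qtl_id not in shared_b],
    }


def genomic_inflation(p_values: np.ndarray) -> float:
    """Median-chi-square inflation factor (lambda_GC) of a scan."""
    p = np.asarray(p_values, dtype=float)
    chi2 = stats.chi2.isf(np.clip(p, P_FLOOR, 1.0), df=1)
    return float(np.median(chi2) / stats.chi2.isf(0.5, df=1))
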