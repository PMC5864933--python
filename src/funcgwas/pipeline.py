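"""End-to-end orchestration: one config, seven stages, one manifest.

Stage order follows the mapping workflow the library implements:
annotation -> structure -> GWAS per SNP group -> bulked-segregant screen ->
LD blocks around peaks -> haplotype analysis -> selection scan.  Each
stage's outputs are plain TSV/JSON/BED files under the run directory, and
a manifest records parameters, input hashes and completed stages so a run
can be audited and reproduced bit for bit.

The final candidate report joins, per QTL, every line of evidence the
pipeline produced (association signal, pool chi-squared, enriched-window
overlap, LD-block membership, haplotype ANOVA) and ranks candidates by
the number of supporting lines, ties broken by peak -log10(p).
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("funcgwas.pipeline")

STAGES = (
    "annotation",
    "structure",
    "gwas",
    "bsa",
    "blocks",
    "haplotypes",
    "selection",
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Paths and stage parameters of one pipeline run."""

    vcf: str = ""
    gff: str = ""
    fasta: str = ""
    phenotype: str = ""
    labels: str | None = None
    outdir: str = "funcgwas_run"
    seed: int = 0

    maf_min: float = 0.05
    missing_max: float = 0.5
    n_pcs: int = 3
    structure_mode: str = "quantile"
    pc1_cutoffs: tuple[float, float] | None = None
    quantiles: tuple[float, float] = (0.3, 0.7)

    model: str = "cmlm"  # cmlm | mlm | glm
    compression: int | str = "auto"
    snp_groups: tuple[str, ...] = ("I", "III")
    group3_size: int | None = None  # default: half of all SNPs
    promoter_kb: int = 1000
    include_stop_variants: bool = True
    alpha: float = 0.01
    merge_kb: float = 170.0

    pool_size: int = 20
    window_kb: float = 500.0
    step_kb: float = 50.0
    n_perm: int = 1000

    r2_min: float = 0.6
    block_flank_kb: float = 300.0
    min_hap_count: int = 4
    duncan_alpha: float = 0.05
    min_carriers: int = 30
    selection_flank_bp: int = 2000

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("pc1_cutoffs", "quantiles", "snp_groups"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def validate_config(config: RunConfig) -> list[str]:
    """Every violated constraint, as human-readable strings; empty == runnable."""
    v: list[str] = []
    for fieldname in ("vcf", "gff", "fasta", "phenotype"):
        path = getattr(config, fieldname)
        if not path:
            v.append(f"{fieldname}: path is required")
        elif not os.path.isfile(path):
            v.append(f"{fieldname}: file not found: {path}")
        elif not os.access(path, os.R_OK):
            v.append(f"{fieldname}: file not readable: {path}")
    if config.labels and not os.path.isfile(config.labels):
        v.append(f"labels: file not found: {config.labels}")
    if not 0.0 <= config.maf_min < 0.5:
        v.append("maf_min: must lie in [0, 0.5)")
    if not 0.0 < config.missing_max <= 1.0:
        v.append("missing_max: must lie in (0, 1]")
    if config.n_pcs < 1:
        v.append("n_pcs: must be >= 1")
    if config.model not in ("cmlm", "mlm", "glm"):
        v.append(f"model: unknown model {config.model!r}")
    if not 0.0 < config.alpha < 1.0:
        v.append("alpha: must lie in (0, 1)")
    if config.merge_kb < 0:
        v.append("merge_kb: must be non-negative")
    if config.pool_size < 1:
        v.append("pool_size: must be >= 1")
    if config.window_kb <= 0 or config.step_kb <= 0:
        v.append("window_kb/step_kb: must be positive")
    if config.n_perm < 100:
        v.append("n_perm: must be >= 100")
    if not 0.0 <= config.r2_min <= 1.0:
        v.append("r2_min: must lie in [0, 1]")
    for g in config.snp_groups:
        if g not in ("I", "II", "III"):
            v.append(f"snp_groups: unknown group {g!r}")
    return v


def _hash_file(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _params_hash(config: RunConfig) -> str:
    payload = {k: v for k, v in asdict(config).items() if k != "outdir"}
    for f in ("vcf", "gff", "fasta", "phenotype", "labels"):
        path = getattr(config, f)
        if path and os.path.isfile(path):
            payload[f"{f}_sha256"] = _hash_file(path)
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()


@dataclass
class _State:
    """Mutable cross-stage scratch space."""

    gm: object = None
    reference: object = None
    models: list = field(default_factory=list)
    phen: pd.DataFrame | None = None
    y: np.ndarray | None = None
    annotations: pd.DataFrame | None = None
    groups: dict = field(default_factory=dict)
    structures: dict = field(default_factory=dict)
    subpop_labels: np.ndarray | None = None
    typical: np.ndarray | None = None
    scans: dict = field(default_factory=dict)
    qtls: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    screens: dict = field(default_factory=dict)
    blocks: dict = field(default_factory=dict)
    block_ranks: dict = field(default_factory=dict)
    hap_tables: dict = field(default_factory=dict)
    hap_anova: dict = field(default_factory=dict)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in dependency order; returns the run manifest.

    On stage failure the pipeline halts with :class:`PipelineError` naming
    the stage; outputs of completed stages remain on disk.
    """
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    os.makedirs(config.outdir, exist_ok=True)
    manifest = {
        "params_hash": _params_hash(config),
        "seed": config.seed,
        "stages": [],
        "outputs": {},
    }
    state = _State()
    for stage in STAGES:
        t0 = time.time()
        logger.info("stage %s: start", stage)
        try:
            outputs = _STAGE_FUNCS[stage](config, state)
        except Exception as exc:  # halt, preserving partial outputs
            _write_manifest(manifest, config.outdir)
            raise PipelineError(stage, exc) from exc
        manifest["stages"].append(
            {"name": stage, "seconds": round(time.time() - t0, 3)}
        )
        manifest["outputs"][stage] = outputs
        logger.info("stage %s: done in %.2fs", stage, time.time() - t0)
    report_path = _candidate_report(config, state)
    manifest["outputs"]["report"] = [report_path]
    _write_manifest(manifest, config.outdir)
    return manifest


def _write_manifest(manifest: dict, outdir: str) -> None:
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# stages


def _stage_annotation(config: RunConfig, st: _State) -> list[str]:
    import pyfaidx

    from .annotate import GeneIndex, annotate_variants, build_snp_groups, load_gene_models
    from .genotypes import read_vcf

    st.gm = read_vcf(config.vcf)
    st.reference = pyfaidx.Fasta(config.fasta)
    st.models = load_gene_models(config.gff)
    st.phen = pd.read_csv(config.phenotype, sep="\t")
    ph = st.phen.set_index("accession_id")["ML_cm"]
    st.y = ph.reindex(st.gm.accessions).to_numpy(dtype=float)
    if np.isnan(st.y).any():
        raise ValueError("phenotype missing for some accessions in the VCF")
    index = GeneIndex(st.models, promoter_kb=config.promoter_kb)
    st.annotations = annotate_variants(st.gm, index, st.reference)
    size3 = config.group3_size or max(1, st.gm.n_snps // 2)
    excluded = {m.gene_id for m in st.models if m.is_transposon}
    st.groups = build_snp_groups(
        st.annotations, min(size3, st.gm.n_snps), seed=config.seed,
        include_stop_variants=config.include_stop_variants,
        excluded_genes=excluded,
    )
    out = os.path.join(config.outdir, "annotation.tsv")
    st.annotations.to_csv(out, sep="\t", index=False)
    outs = [out]
    for label, grp in st.groups.items():
        p = os.path.join(config.outdir, f"group_{label}.txt")
        pd.Series(grp.snp_ids).to_csv(p, index=False, header=False)
        outs.append(p)
    return outs


def _stage_structure(config: RunConfig, st: _State) -> list[str]:
    from .structure import (
        assign_subpopulations,
        compute_kinship,
        compute_pca,
        filter_variants,
    )

    outs = []
    for label in sorted(set(config.snp_groups) | {"I"}):
        ids = set(st.groups[label].snp_ids)
        mask = np.array([s in ids for s in st.gm.snp_ids])
        sub = filter_variants(
            st.gm.subset(snp_idx=mask), config.maf_min, config.missing_max
        )
        res = compute_pca(sub, k=config.n_pcs)
        res.kinship = compute_kinship(sub)
        res = assign_subpopulations(
            res,
            mode=config.structure_mode,
            cutoffs=config.pc1_cutoffs,
            quantiles=config.quantiles,
            seed=config.seed,
        )
        st.structures[label] = res
        p = os.path.join(config.outdir, f"pcs_group_{label}.tsv")
        pd.DataFrame(
            res.pcs, index=st.gm.accessions,
            columns=[f"PC{i + 1}" for i in range(res.pcs.shape[1])],
        ).to_csv(p, sep="\t")
        outs.append(p)
        pk = os.path.join(config.outdir, f"kinship_group_{label}.tsv")
        pd.DataFrame(res.kinship, index=st.gm.accessions, columns=st.gm.accessions).to_csv(
            pk, sep="\t"
        )
        outs.append(pk)
    base = st.structures["I"]
    if config.labels:
        lab = pd.read_csv(config.labels, sep="\t").set_index("accession_id")
        st.subpop_labels = lab["subpopulation"].reindex(st.gm.accessions).to_numpy()
        st.typical = base.typical
    else:
        st.subpop_labels = base.labels
        st.typical = base.typical
    p = os.path.join(config.outdir, "subpopulations.tsv")
    pd.DataFrame(
        {
            "accession_id": st.gm.accessions,
            "subpopulation": st.subpop_labels,
            "typical": st.typical,
        }
    ).to_csv(p, sep="\t", index=False)
    outs.append(p)
    return outs


def _run_one_scan(config: RunConfig, st: _State, group: str, covar_group: str):
    from .gwas import run_glm, run_mlm

    ids = set(st.groups[group].snp_ids)
    mask = np.array([s in ids for s in st.gm.snp_ids])
    gm_g = st.gm.subset(snp_idx=mask)
    struct = st.structures[covar_group]
    if config.model == "glm":
        return run_glm(gm_g, st.y, struct.pcs, snp_group=group, covariate_source=covar_group)
    compression = "none" if config.model == "mlm" else config.compression
    return run_mlm(
        gm_g, st.y, struct.pcs, struct.kinship, compression_groups=compression,
        snp_group=group, covariate_source=covar_group,
    )


def _stage_gwas(config: RunConfig, st: _State) -> list[str]:
    from .gwas import merge_qtls, significance_threshold

    outs = []
    pairs = [(g, g) for g in config.snp_groups]
    if "I" in config.snp_groups and "III" in config.snp_groups:
        pairs.append(("I", "III"))  # complementary covariate-provenance scan
    for group, covar in pairs:
        res = _run_one_scan(config, st, group, covar)
        key = f"{group}_cov{covar}"
        st.scans[key] = res
        thr = significance_threshold(
            res.table["p"].to_numpy(), config.alpha, fallback_bonferroni=True
        )
        st.thresholds[key] = thr
        sig = res.significant(thr)
        st.qtls[key] = merge_qtls(sig, int(config.merge_kb * 1000))
        p = os.path.join(config.outdir, f"gwas_{key}.tsv")
        res.table.to_csv(p, sep="\t", index=False)
        outs.append(p)
        pq = os.path.join(config.outdir, f"qtls_{key}.tsv")
        pd.DataFrame(
            [
                {
                    "qtl_id": q.qtl_id,
                    "chrom": q.chrom,
                    "start": q.start,
                    "end": q.end,
                    "n_snps": len(q.snp_ids),
                    "peak_snp": q.peak_snp,
                    "peak_neglog10p": q.peak_neglog10p,
                }
                for q in st.qtls[key]
            ]
        ).to_csv(pq, sep="\t", index=False)
        outs.append(pq)
    return outs


def _stage_bsa(config: RunConfig, st: _State) -> list[str]:
    from .bsa import run_screen

    ids = set(st.groups["I"].snp_ids)
    mask = np.array([s in ids for s in st.gm.snp_ids])
    gm_I = st.gm.subset(snp_idx=mask)
    outs = []
    for pop in sorted(pd.unique(st.subpop_labels)):
        members = st.subpop_labels == pop
        typical = members & st.typical
        if typical.sum() < 2 * config.pool_size:
            logger.warning("subgroup %s: too few typical accessions, skipped", pop)
            continue
        screen = run_screen(
            gm_I,
            st.phen,
            typical,
            pool_size=config.pool_size,
            subgroup=str(pop),
            n_perm=config.n_perm,
            seed=config.seed,
            window_bp=int(config.window_kb * 1000),
            step_bp=int(config.step_kb * 1000),
        )
        st.screens[str(pop)] = screen
        p1 = os.path.join(config.outdir, f"bsa_snps_{pop}.tsv")
        screen.per_snp.to_csv(p1, sep="\t", index=False)
        p2 = os.path.join(config.outdir, f"bsa_windows_{pop}.tsv")
        screen.windows.to_csv(p2, sep="\t", index=False)
        p3 = os.path.join(config.outdir, f"bsa_enriched_{pop}.bed")
        enriched = screen.windows[screen.windows.get("esds_enriched", False)]
        with open(p3, "w") as fh:
            for _, row in enriched.iterrows():
                fh.write(f"{row['chrom']}\t{row['start']}\t{row['end']}\n")
        p4 = os.path.join(config.outdir, f"bsa_thresholds_{pop}.json")
        with open(p4, "w") as fh:
            json.dump(screen.thresholds, fh, indent=2, sort_keys=True)
        outs += [p1, p2, p3, p4]
    return outs


def _primary_key(st: _State) -> str:
    return next(k for k in st.scans if k.startswith("I_covI"))


def _stage_blocks(config: RunConfig, st: _State) -> list[str]:
    from .haplotype import define_block, identify_functional_snp

    key = _primary_key(st)
    outs = []
    flank = int(config.block_flank_kb * 1000)
    struct = st.structures["I"]
    for q in st.qtls[key]:
        jp = st.gm.snp_index(q.peak_snp)
        near = (
            (st.gm.chrom == q.chrom)
            & (np.abs(st.gm.pos - st.gm.pos[jp]) <= flank)
            & np.isin(st.gm.snp_ids, st.groups["I"].snp_ids)
        )
        candidates = [s for s in st.gm.snp_ids[near] if s != q.peak_snp]
        block = define_block(st.gm, q.peak_snp, candidates, r2_min=config.r2_min)
        st.blocks[q.qtl_id] = block
        try:
            ranks = identify_functional_snp(
                st.gm, st.y, block, covariates=struct.pcs,
                signal_neglog10p=st.thresholds[key],
                min_carriers=config.min_carriers,
                min_count=config.min_hap_count,
            )
        except Exception as exc:
            logger.warning("block %s: functional-SNP isolation skipped (%s)", q.qtl_id, exc)
            ranks = pd.DataFrame(
                {"snp_id": block.snp_ids, "kills_block": False, "consistency": 0.0,
                 "marginal_neglog10p": np.nan, "score": 0.0,
                 "rank": np.arange(1, len(block.snp_ids) + 1)}
            )
        st.block_ranks[q.qtl_id] = ranks
        p = os.path.join(config.outdir, f"block_{q.qtl_id}.tsv")
        ranks.assign(
            qtl_id=q.qtl_id,
            r2_to_peak=[block.r2_to_peak[s] for s in ranks["snp_id"]],
        ).to_csv(p, sep="\t", index=False)
        outs.append(p)
    return outs


def _stage_haplotypes(config: RunConfig, st: _State) -> list[str]:
    from .haplotype import anova_oneway, assign_haplotypes, combine_haplotypes, duncan_mrt

    key = _primary_key(st)
    ann = st.annotations
    outs = []
    gene_tables = {}
    scan = st.scans[key].table
    significant = set(scan.loc[scan["neglog10p"] > st.thresholds[key], "snp_id"])
    for q in st.qtls[key]:
        gene_rows = ann[(ann["snp_id"] == q.peak_snp) & ann["gene_id"].notna()]
        for gene in gene_rows["gene_id"]:
            if gene in gene_tables:
                continue
            protein_altering = sorted(
                set(
                    ann.loc[
                        (ann["gene_id"] == gene)
                        & ann["effect"].isin(
                            ("nonsynonymous", "stop_gained", "stop_lost", "start_lost")
                        ),
                        "snp_id",
                    ]
                )
            )
            # haplotypes over the gene's above-threshold protein-altering
            # SNPs when any exist, otherwise over all of them
            defining = [s for s in protein_altering if s in significant] or protein_altering
            if not defining:
                continue
            table = assign_haplotypes(
                st.gm, defining, st.phen, min_count=config.min_hap_count, gene_id=gene
            )
            retained = table.assignments[table.assignments.isin(table.retained())]
            ph = st.phen.set_index("accession_id")["ML_cm"]
            vals = ph.reindex(retained.index).to_numpy(dtype=float)
            an = anova_oneway(vals, retained.to_numpy())
            st.hap_anova[gene] = an
            if an.testable:
                letters = duncan_mrt(vals, retained.to_numpy(), alpha=config.duncan_alpha)
                table.summary = table.summary.merge(
                    letters[["label", "letters"]], on="label", how="left"
                )
            gene_tables[gene] = table
            st.hap_tables[gene] = (q.qtl_id, table)
            p = os.path.join(config.outdir, f"haplotypes_{gene}.tsv")
            table.summary.assign(gene_id=gene).to_csv(p, sep="\t", index=False)
            outs.append(p)
    if len(gene_tables) >= 2:
        ranked = sorted(
            st.hap_tables.items(),
            key=lambda kv: -next(
                q.peak_neglog10p for q in st.qtls[key] if q.qtl_id == kv[1][0]
            ),
        )
        g1, (_, t1) = ranked[0]
        g2, (_, t2) = ranked[1]
        combo = combine_haplotypes(t1, t2, st.phen, alpha=config.duncan_alpha)
        p = os.path.join(config.outdir, f"combos_{g1}_{g2}.tsv")
        combo.summary.to_csv(p, sep="\t", index=False)
        outs.append(p)
    return outs


def _stage_selection(config: RunConfig, st: _State) -> list[str]:
    from .selection import diversity_ratio, gene_region, tajimas_d

    rows = []
    pops = sorted(pd.unique(st.subpop_labels))
    by_gene = {m.gene_id: m for m in st.models}
    for gene in st.hap_tables:
        model = by_gene.get(gene)
        if model is None:
            continue
        chrom, start, end = gene_region(model, config.selection_flank_bp)
        stats_all = tajimas_d(st.gm, chrom, start, end, population="all")
        per_pop = {}
        for pop in pops:
            idx = np.flatnonzero(st.subpop_labels == pop)
            if len(idx) < 2:
                continue
            per_pop[pop] = tajimas_d(
                st.gm, chrom, start, end, population=str(pop), accession_idx=idx
            )
        for tag, s in [("all", stats_all)] + list(per_pop.items()):
            rows.append(
                {
                    "gene_id": gene,
                    "population": tag,
                    "chrom": s.chrom,
                    "start": s.start,
                    "end": s.end,
                    "n_sequences": s.n_sequences,
                    "S": s.segregating_sites,
                    "pi_per_site": s.pi_per_site,
                    "theta_w_per_site": s.theta_w_per_site,
                    "tajimas_d": s.tajimas_d,
                }
            )
        if len(per_pop) == 2:
            (pa, sa), (pb, sb) = sorted(per_pop.items())
            for focal, ref in ((sa, sb), (sb, sa)):
                ratio, inf_flag = diversity_ratio(ref, focal)
                rows.append(
                    {
                        "gene_id": gene,
                        "population": f"ratio {ref.population}/{focal.population}",
                        "chrom": focal.chrom,
                        "start": focal.start,
                        "end": focal.end,
                        "n_sequences": focal.n_sequences,
                        "S": focal.segregating_sites,
                        "pi_per_site": np.inf if inf_flag else ratio,
                        "theta_w_per_site": np.nan,
                        "tajimas_d": None,
                    }
                )
    p = os.path.join(config.outdir, "selection.tsv")
    pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
    return [p]


_STAGE_FUNCS = {
    "annotation": _stage_annotation,
    "structure": _stage_structure,
    "gwas": _stage_gwas,
    "bsa": _stage_bsa,
    "blocks": _stage_blocks,
    "haplotypes": _stage_haplotypes,
    "selection": _stage_selection,
}


def _candidate_report(config: RunConfig, st: _State) -> str:
    """Joint-evidence candidate table: one row per QTL of the primary scan."""
    key = _primary_key(st)
    thr = st.thresholds[key]
    rows = []
    for q in st.qtls[key]:
        ranks = st.block_ranks.get(q.qtl_id)
        candidate = (
            str(ranks.iloc[0]["snp_id"]) if ranks is not None and len(ranks) else q.peak_snp
        )
        chi2_max, esds = 0.0, False
        for screen in st.screens.values():
            row = screen.per_snp[screen.per_snp["snp_id"] == candidate]
            if len(row):
                chi2_max = max(chi2_max, float(row["chi2"].iloc[0]))
                esds = esds or bool(row["esds"].iloc[0])
        enriched = False
        jc = st.gm.snp_index(candidate)
        for screen in st.screens.values():
            win = screen.windows
            if "esds_enriched" not in win:
                continue
            hit = win[
                (win["chrom"] == st.gm.chrom[jc])
                & (win["start"] <= st.gm.pos[jc] - 1)
                & (st.gm.pos[jc] - 1 < win["end"])
                & win["esds_enriched"]
            ]
            enriched = enriched or len(hit) > 0
        block = st.blocks.get(q.qtl_id)
        genes = {
            g for g, (qid, _) in st.hap_tables.items() if qid == q.qtl_id
        }
        hap_p = min(
            (st.hap_anova[g].p for g in genes if st.hap_anova[g].testable),
            default=np.nan,
        )
        evidence = sum(
            [
                q.peak_neglog10p > thr,
                esds,
                enriched,
                block is not None and len(block.snp_ids) > 1,
                (not np.isnan(hap_p)) and hap_p < 0.05,
            ]
        )
        rows.append(
            {
                "qtl_id": q.qtl_id,
                "chrom": q.chrom,
                "start": q.start,
                "end": q.end,
                "peak_snp": q.peak_snp,
                "candidate_snp": candidate,
                "peak_neglog10p": q.peak_neglog10p,
                "above_threshold": q.peak_neglog10p > thr,
                "pool_chi2": chi2_max,
                "esds": esds,
                "enriched_window": enriched,
                "block_size": 0 if block is None else len(block.snp_ids),
                "haplotype_anova_p": hap_p,
                "evidence": evidence,
            }
        )
    report = pd.DataFrame(rows)
    if len(report):
        report = report.sort_values(
            ["evidence", "peak_neglog10p"], ascending=[False, False], kind="stable"
        ).reset_index(drop=True)
        report["rank"] = np.arange(1, len(report) + 1)
    path = os.path.join(config.outdir, "candidates.tsv")
    report.to_csv(path, sep="\t", index=False)
    return path
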