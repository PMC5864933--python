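"""Synthetic study generator with known ground truth.

Generates a miniature inbred rice-like panel end to end: a random genome
with non-overlapping single-CDS gene models, a two-subpopulation genotype
panel under the Balding-Nichols model, planted protein-altering causal
variants of known effect, and a right-skewed quantitative phenotype
(mesocotyl length in cm).  All outputs are emitted in the same plain-text
formats the analysis stages consume (FASTA / GFF3 / VCF v4.2 / TSV), and a
single seed fixes every file bit for bit.

Randomness is split hierarchically from the one seed via
``numpy.random.SeedSequence.spawn`` into four independent streams
(genome, population, missingness, phenotype), so e.g. regenerating the
phenotype does not perturb the genotypes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotate import (
    CODON_TABLE,
    COMPLEMENT,
    SENSE_CODONS,
    STOP_CODONS,
    GeneModel,
    revcomp,
)
from .genotypes import MISSING, GenotypeMatrix, write_vcf


class SizingError(ValueError):
    """Requested genome/gene geometry cannot be packed."""


class ContractError(ValueError):
    """A generator precondition is violated."""


@dataclass(frozen=True)
class CausalVariant:
    """A planted protein-altering causal site.

    ``codon`` is the 1-based codon number within the gene's CDS; the effect
    is the phenotype difference (cm) between alternate and reference
    homozygotes.  ``alt_frequency`` fixes the ancestral alternate-allele
    frequency; ``subpop_frequencies`` overrides the per-subpopulation
    frequencies (for planting pool-differentiated signals).
    """

    gene_index: int
    codon: int
    effect_cm: float
    alt_frequency: float | None = None
    subpop_frequencies: tuple[float, float] | None = None


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults emulate a structured cultivated-rice panel: two diverged
    subpopulations of 390 and 231 inbred accessions, SNPs concentrated in
    annotated genes with a rare-variant-heavy frequency spectrum, and a
    right-skewed phenotype on the centimetre scale.
    """

    n_chromosomes: int = 2
    chrom_length_bp: int = 1_000_000
    n_genes: int = 100
    gene_length_bp: int = 300
    n_accessions_per_subpop: tuple[int, int] = (390, 231)
    n_snps: int = 6000
    fst: float = 0.3
    ancestral_maf_range: tuple[float, float] = (0.02, 0.5)
    causal_spec: tuple[CausalVariant, ...] = ()
    heritability: float = 0.5
    phenotype_skew: bool = True
    missing_rate: float = 0.02
    residual_het_rate: float = 0.0
    n_background_snps: int = 100
    baseline_variance_cm2: float = 1.0
    coding_fraction: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fst < 1.0:
            raise ContractError("fst must lie in [0, 1)")
        if not 0.0 <= self.heritability <= 1.0:
            raise ContractError("heritability must lie in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ContractError("missing_rate must lie in [0, 1)")
        lo, hi = self.ancestral_maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise ContractError("ancestral_maf_range must be within (0, 0.5]")
        if self.gene_length_bp % 3 != 0 or self.gene_length_bp < 12:
            raise SizingError("gene_length_bp must be a multiple of 3 and >= 12")

    def rngs(self) -> dict[str, np.random.Generator]:
        streams = np.random.SeedSequence(self.seed).spawn(4)
        names = ("genome", "population", "missing", "phenotype")
        return {n: np.random.default_rng(s) for n, s in zip(names, streams)}


@dataclass
class SimTruth:
    """Ground truth of a simulated study."""

    causal_ids: list[str]
    causal_effects: dict[str, float]
    labels: dict[str, str]
    heritability: float
    subpop_frequencies: np.ndarray  # (n_subpops, n_snps) alternate-allele freqs
    true_dosage: np.ndarray = field(default=None, repr=False)
    genetic_values: np.ndarray | None = field(default=None, repr=False)

    def label_array(self, accessions: list[str]) -> np.ndarray:
        return np.array([self.labels[a] for a in accessions], dtype=object)


_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def simulate_genome(config: SimConfig) -> tuple[dict[str, str], list[GeneModel]]:
    """Random genome plus non-overlapping single-CDS gene models.

    Each CDS starts with ATG, ends in a stop codon and contains no internal
    stop; roughly half the genes land on the reverse strand (the genomic
    sequence there is the reverse complement of the coding sequence).
    """
    rng = config.rngs()["genome"]
    per_chrom = [
        config.n_genes // config.n_chromosomes
        + (1 if c < config.n_genes % config.n_chromosomes else 0)
        for c in range(config.n_chromosomes)
    ]
    glen = config.gene_length_bp
    for c, g_c in enumerate(per_chrom):
        spacing = (config.chrom_length_bp - g_c * glen) // (g_c + 1)
        if spacing < 200:
            raise SizingError(
                f"chr{c + 1}: {g_c} genes of {glen} bp need more than "
                f"{config.chrom_length_bp} bp at >=200 bp spacing"
            )

    genome: dict[str, str] = {}
    models: list[GeneModel] = []
    gi = 0
    n_codons = glen // 3
    for c, g_c in enumerate(per_chrom):
        chrom = f"chr{c + 1}"
        seq = _BASE_BYTES[rng.integers(0, 4, size=config.chrom_length_bp)].copy()
        spacing = (config.chrom_length_bp - g_c * glen) // (g_c + 1)
        for k in range(g_c):
            start = spacing * (k + 1) + glen * k
            internal = rng.choice(len(SENSE_CODONS), size=n_codons - 2)
            cds = "ATG" + "".join(SENSE_CODONS[i] for i in internal)
            cds += STOP_CODONS[rng.integers(len(STOP_CODONS))]
            strand = "+" if rng.random() < 0.5 else "-"
            placed = cds if strand == "+" else revcomp(cds)
            seq[start : start + glen] = np.frombuffer(placed.encode(), dtype=np.uint8)
            models.append(
                GeneModel(
                    gene_id=f"gene{gi + 1:04d}",
                    chrom=chrom,
                    strand=strand,
                    cds_segments=[(start, start + glen)],
                    phases=[0],
                )
            )
            gi += 1
        genome[chrom] = seq.tobytes().decode()
    return genome, models


def _pick_nonsyn_substitution(
    coding_codon: str, rng: np.random.Generator
) -> tuple[int, str]:
    """(codon position 0..2, coding-strand alt base) giving a non-stop amino-acid change."""
    ref_aa = CODON_TABLE[coding_codon]
    options = []
    for within in range(3):
        for base in "ACGT":
            if base == coding_codon[within]:
                continue
            alt_codon = coding_codon[:within] + base + coding_codon[within + 1 :]
            alt_aa = CODON_TABLE[alt_codon]
            if alt_aa not in ("*", ref_aa) and ref_aa != "*":
                options.append((within, base))
    if not options:
        raise ContractError(f"codon {coding_codon} admits no non-synonymous substitution")
    return options[rng.integers(len(options))]


def simulate_population(
    config: SimConfig, genome: tuple[dict[str, str], list[GeneModel]]
) -> tuple[GenotypeMatrix, SimTruth]:
    """Structured inbred genotypes under the Balding-Nichols model.

    Per SNP an ancestral alternate-allele frequency is drawn from
    ``ancestral_maf_range`` (randomly folded to either allele), and each
    subpopulation's frequency is Beta-distributed around it with variance
    governed by ``fst``.  Inbred accessions carry dosage 0 or 2; residual
    heterozygosity and missingness are optional overlays.  Planted causal
    variants are guaranteed non-synonymous coding sites.
    """
    sequences, models = genome
    rngs = config.rngs()
    rng = rngs["population"]

    # -- choose SNP sites: causal first, then coding, then noncoding
    causal_sites: list[tuple[str, int, str, str]] = []  # (chrom, pos0, ref, alt)
    for cv in config.causal_spec:
        model = models[cv.gene_index]
        n_codons = model.cds_length // 3
        if not 2 <= cv.codon <= n_codons - 1:
            raise ContractError(
                f"causal codon {cv.codon} outside the internal codons of "
                f"{model.gene_id} (2..{n_codons - 1})"
            )
        tx = model.tx_positions()
        codon_pos0 = tx[(cv.codon - 1) * 3 : cv.codon * 3]
        bases = [sequences[model.chrom][p] for p in codon_pos0]
        if model.strand == "-":
            bases = [COMPLEMENT[b] for b in bases]
        within, coding_alt = _pick_nonsyn_substitution("".join(bases), rng)
        pos0 = int(codon_pos0[within])
        ref = sequences[model.chrom][pos0]
        alt = coding_alt if model.strand == "+" else COMPLEMENT[coding_alt]
        causal_sites.append((model.chrom, pos0, ref, alt))

    coding_positions: dict[str, np.ndarray] = {}
    cds_mask: dict[str, np.ndarray] = {}
    for chrom, seq in sequences.items():
        cds_mask[chrom] = np.zeros(len(seq), dtype=bool)
    for m in models:
        tx = m.tx_positions()
        internal = tx[3:-3]  # skip start and stop codons
        cds_mask[m.chrom][tx] = True
        coding_positions.setdefault(m.chrom, [])
        coding_positions[m.chrom].append(internal)
    for chrom in list(coding_positions):
        coding_positions[chrom] = np.sort(np.concatenate(coding_positions[chrom]))

    taken = {(c, p) for c, p, _, _ in causal_sites}
    n_coding = min(
        int(round(config.n_snps * config.coding_fraction)),
        sum(len(v) for v in coding_positions.values()),
    )
    n_noncoding = config.n_snps - len(causal_sites) - n_coding
    if n_noncoding < 0:
        raise ContractError("n_snps smaller than the number of causal sites")

    sites: list[tuple[str, int]] = []
    chrom_names = sorted(sequences)
    all_coding = np.concatenate(
        [np.stack([np.full(len(coding_positions[c]), i), coding_positions[c]], axis=1)
         for i, c in enumerate(chrom_names) if c in coding_positions]
    )
    pick = rng.choice(len(all_coding), size=n_coding, replace=False)
    for row in all_coding[np.sort(pick)]:
        site = (chrom_names[int(row[0])], int(row[1]))
        if site not in taken:
            sites.append(site)
            taken.add(site)
    noncoding_pool = np.concatenate(
        [np.stack([np.full(np.sum(~cds_mask[c]), i), np.flatnonzero(~cds_mask[c])], axis=1)
         for i, c in enumerate(chrom_names)]
    )
    if n_noncoding > len(noncoding_pool):
        raise ContractError("n_snps exceeds available polymorphic positions")
    pick = rng.choice(len(noncoding_pool), size=n_noncoding, replace=False)
    for row in noncoding_pool[np.sort(pick)]:
        site = (chrom_names[int(row[0])], int(row[1]))
        if site not in taken:
            sites.append(site)
            taken.add(site)

    records: list[tuple[str, int, str, str, int]] = []  # + causal index or -1
    for ci, (chrom, pos0, ref, alt) in enumerate(causal_sites):
        records.append((chrom, pos0, ref, alt, ci))
    for chrom, pos0 in sites:
        ref = sequences[chrom][pos0]
        alt = "ACGT"["ACGT".index(ref) - rng.integers(1, 4)]
        records.append((chrom, pos0, ref, alt, -1))
    records.sort(key=lambda r: (r[0], r[1]))

    n = len(records)
    chroms = np.array([r[0] for r in records], dtype=object)
    pos = np.array([r[1] + 1 for r in records], dtype=np.int64)  # to 1-based
    refs = np.array([r[2] for r in records], dtype=object)
    alts = np.array([r[3] for r in records], dtype=object)
    snp_ids = np.array([f"{c}_{p}" for c, p in zip(chroms, pos)], dtype=object)
    causal_col = {r[4]: j for j, r in enumerate(records) if r[4] >= 0}

    # -- allele frequencies
    lo, hi = config.ancestral_maf_range
    p_anc = rng.uniform(lo, hi, size=n)
    fold = rng.random(n) < 0.5
    p_anc = np.where(fold, 1.0 - p_anc, p_anc)
    n_subpops = len(config.n_accessions_per_subpop)
    if config.fst > 0:
        F = config.fst
        a = p_anc * (1 - F) / F
        b = (1 - p_anc) * (1 - F) / F
        subpop_freq = np.stack([rng.beta(a, b) for _ in range(n_subpops)])
    else:
        subpop_freq = np.tile(p_anc, (n_subpops, 1))
    for ci, cv in enumerate(config.causal_spec):
        j = causal_col[ci]
        if cv.alt_frequency is not None:
            subpop_freq[:, j] = cv.alt_frequency
        if cv.subpop_frequencies is not None:
            subpop_freq[:, j] = np.asarray(cv.subpop_frequencies)

    # -- inbred dosages
    blocks, accessions, labels = [], [], {}
    for k, n_k in enumerate(config.n_accessions_per_subpop):
        u = rng.random((n_k, n))
        dos = (u < subpop_freq[k]).astype(np.int8) * 2
        if config.residual_het_rate > 0:
            het = rng.random((n_k, n)) < config.residual_het_rate
            dos[het] = 1
        blocks.append(dos)
        for i in range(n_k):
            acc = f"acc{len(accessions) + 1:04d}"
            accessions.append(acc)
            labels[acc] = f"pop{k + 1}"
    dosage = np.concatenate(blocks, axis=0)
    true_dosage = dosage.copy()

    if config.missing_rate > 0:
        miss = config.rngs()["missing"].random(dosage.shape) < config.missing_rate
        dosage = dosage.copy()
        dosage[miss] = MISSING

    gm = GenotypeMatrix(
        accessions=accessions,
        snp_ids=snp_ids,
        chrom=chroms,
        pos=pos,
        ref=refs,
        alt=alts,
        dosage=dosage,
        contig_lengths={c: len(s) for c, s in sequences.items()},
    )
    truth = SimTruth(
        causal_ids=[snp_ids[causal_col[ci]] for ci in range(len(config.causal_spec))],
        causal_effects={
            snp_ids[causal_col[ci]]: cv.effect_cm
            for ci, cv in enumerate(config.causal_spec)
        },
        labels=labels,
        heritability=config.heritability,
        subpop_frequencies=subpop_freq,
        true_dosage=true_dosage,
    )
    return gm, truth


def simulate_phenotype(
    gm: GenotypeMatrix, truth: SimTruth, config: SimConfig
) -> pd.DataFrame:
    """Quantitative phenotype with planted causal effects and polygenic background.

    phenotype = sum_c (dosage_c / 2) * effect_c  +  polygenic term  +  noise.

    ``heritability`` is the variance fraction of the polygenic background
    within the baseline (background + noise) variance
    ``baseline_variance_cm2``; planted causal effects add on top on the
    absolute cm scale, so a 4 cm effect stays a 4 cm regression slope.
    With ``heritability = 0`` the phenotype is pure noise.  The optional
    skew transform maps the latent Gaussian-like trait through a monotone
    convex exponential and truncates at zero, reproducing the strongly
    right-skewed shape of mesocotyl-length panels (it is monotone, so
    rankings and pool selections are preserved, but cm-scale effect sizes
    are not).
    """
    rng = config.rngs()["phenotype"]
    dosage = truth.true_dosage if truth.true_dosage is not None else gm.dosage
    n_acc = dosage.shape[0]
    h2 = config.heritability
    base = config.baseline_variance_cm2

    g_causal = np.zeros(n_acc)
    for sid, eff in truth.causal_effects.items():
        j = gm.snp_index(sid)
        col = dosage[:, j].astype(float)
        if np.all(col == col[0]):
            raise ContractError(f"causal SNP {sid} is monomorphic")
        g_causal += col / 2.0 * eff

    if h2 == 0.0:
        genetic = np.zeros(n_acc)
        noise = rng.normal(0.0, np.sqrt(base), size=n_acc)
    else:
        causal_cols = {gm.snp_index(s) for s in truth.causal_ids}
        bg_pool = np.array(
            [j for j in range(gm.n_snps) if j not in causal_cols], dtype=int
        )
        n_bg = min(config.n_background_snps, len(bg_pool))
        g_poly = np.zeros(n_acc)
        if n_bg > 0:
            bg = rng.choice(bg_pool, size=n_bg, replace=False)
            betas = rng.normal(0.0, 1.0, size=n_bg)
            Z = dosage[:, bg].astype(float)
            Z -= Z.mean(axis=0)
            g_poly = Z @ betas
            sd = g_poly.std()
            if sd > 0:
                g_poly *= np.sqrt(base * h2) / sd
        if np.allclose(g_poly, 0.0) and not truth.causal_effects:
            raise ContractError(
                "heritability > 0 requested but no causal or background "
                "genetic variance is available"
            )
        genetic = g_causal + g_poly
        noise = rng.normal(0.0, np.sqrt(base * (1.0 - h2)), size=n_acc)

    y = genetic + noise
    truth.genetic_values = genetic
    if config.phenotype_skew:
        z = (y - y.mean()) / (y.std() if y.std() > 0 else 1.0)
        y = np.maximum(1.1 * np.exp(0.75 * z) - 0.35, 0.0)
    return pd.DataFrame({"accession_id": gm.accessions, "ML_cm": y})


def simulate_neutral_panel(
    n_accessions: int,
    n_snps: int,
    region_length_bp: int,
    seed: int = 0,
    chrom: str = "chr1",
) -> GenotypeMatrix:
    """Panmictic inbred panel with the neutral sample frequency spectrum.

    Segregating sites receive alternate-allele counts k with P(k) proportional
    to 1/k (k = 1..n-1), the standard neutral infinite-sites expectation for a
    sample of n sequences, and alleles are placed on random accessions.  Under
    this spectrum the pairwise and Watterson diversity estimators agree in
    expectation, so Tajima's D averages near zero - the reference condition
    for selection-scan calibration.  Sites are unlinked.
    """
    rng = np.random.default_rng(seed)
    n = n_accessions
    ks = np.arange(1, n)
    weights = (1.0 / ks) / np.sum(1.0 / ks)
    counts = rng.choice(ks, size=n_snps, p=weights)
    pos0 = np.sort(rng.choice(region_length_bp - 1, size=n_snps, replace=False))
    dosage = np.zeros((n, n_snps), dtype=np.int8)
    for j, k in enumerate(counts):
        carriers = rng.choice(n, size=k, replace=False)
        dosage[carriers, j] = 2
    pos = pos0 + 1
    return GenotypeMatrix(
        accessions=[f"acc{i + 1:04d}" for i in range(n)],
        snp_ids=np.array([f"{chrom}_{p}" for p in pos], dtype=object),
        chrom=np.array([chrom] * n_snps, dtype=object),
        pos=pos.astype(np.int64),
        ref=np.array(["A"] * n_snps, dtype=object),
        alt=np.array(["T"] * n_snps, dtype=object),
        dosage=dosage,
        contig_lengths={chrom: region_length_bp},
    )


def simulate_block_panel(
    n_accessions: int = 400,
    seed: int = 0,
    n_tags: int = 6,
    causal_freq: float = 0.30,
    minor_hap_freq: float = 0.025,
    flip_rate: float = 0.005,
    effect_cm: float = 4.0,
    noise_sd: float = 0.8,
    n_noise_snps: int = 40,
) -> tuple[GenotypeMatrix, np.ndarray, str, list[str]]:
    """Inbred panel with a 7-SNP LD block driven by exactly one causal member.

    Three block haplotypes: the causal alternate allele rides on haplotype C
    (frequency ``causal_freq``); the tag SNPs' alternate alleles ride on both
    C and a small extra haplotype D (``minor_hap_freq``), which keeps each
    tag's r² with the causal SNP around 0.85-0.9 without being identical to
    it.  Rare independent flips emulate genotyping error.  This is the
    fixture for conditional-scan validation: conditioning on the causal SNP
    leaves every tag without usable allelic diversity, while conditioning on
    a tag keeps the causal signal alive through the D carriers.

    Returns (genotypes, phenotype, causal SNP id, tag SNP ids).
    """
    rng = np.random.default_rng(seed)
    n = n_accessions
    u = rng.random(n)
    hap_c = u < causal_freq
    hap_d = (u >= causal_freq) & (u < causal_freq + minor_hap_freq)
    causal = (hap_c * 2).astype(np.int8)
    tags = np.tile(((hap_c | hap_d) * 2).astype(np.int8).reshape(-1, 1), (1, n_tags))
    flips = rng.random(tags.shape) < flip_rate
    tags[flips] = 2 - tags[flips]
    noise_freq = rng.uniform(0.1, 0.5, n_noise_snps)
    noise = ((rng.random((n, n_noise_snps)) < noise_freq) * 2).astype(np.int8)
    dosage = np.column_stack([causal, tags, noise])
    pos = np.concatenate(
        [[100_000], 101_000 + np.arange(n_tags) * 1_000,
         500_000 + np.arange(n_noise_snps) * 10_000]
    ).astype(np.int64)
    m = dosage.shape[1]
    gm = GenotypeMatrix(
        accessions=[f"acc{i + 1:04d}" for i in range(n)],
        snp_ids=np.array([f"chr1_{p}" for p in pos], dtype=object),
        chrom=np.array(["chr1"] * m, dtype=object),
        pos=pos,
        ref=np.array(["A"] * m, dtype=object),
        alt=np.array(["T"] * m, dtype=object),
        dosage=dosage,
        contig_lengths={"chr1": int(pos.max()) + 10_000},
    )
    y = causal / 2.0 * effect_cm + rng.normal(0.0, noise_sd, n)
    return gm, y, str(gm.snp_ids[0]), [str(s) for s in gm.snp_ids[1 : 1 + n_tags]]


def make_ld_block(
    base_dosage: np.ndarray,
    n_copies: int,
    flip_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Columns in strong LD with ``base_dosage``: homozygote copies with random flips.

    Returns an (n_accessions, n_copies) dosage matrix; each copy equals the
    base column except that a ``flip_rate`` fraction of accessions have
    their genotype toggled between 0 and 2, which dials pairwise r² down
    from 1.
    """
    out = np.tile(base_dosage.reshape(-1, 1), (1, n_copies)).astype(np.int8)
    flips = rng.random(out.shape) < flip_rate
    out[flips] = 2 - out[flips]
    return out


# ---------------------------------------------------------------------------
# serialization


def write_fasta(genome: dict[str, str], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(models: list[GeneModel], genome: dict[str, str], path: str) -> None:
    """GFF3 with gene/mRNA/CDS rows (1-based inclusive, phase column set)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in sorted(genome):
            fh.write(f"##sequence-region {chrom} 1 {len(genome[chrom])}\n")
        for m in sorted(models, key=lambda m: (m.chrom, m.span[0])):
            lo, hi = m.span
            gid, tid = m.gene_id, f"{m.gene_id}.1"
            note = ";Note=transposon" if m.is_transposon else ""
            fh.write(
                f"{m.chrom}\tfuncgwas\tgene\t{lo + 1}\t{hi}\t.\t{m.strand}\t.\t"
                f"ID={gid}{note}\n"
            )
            fh.write(
                f"{m.chrom}\tfuncgwas\tmRNA\t{lo + 1}\t{hi}\t.\t{m.strand}\t.\t"
                f"ID={tid};Parent={gid}\n"
            )
            segments = m.cds_segments if m.strand == "+" else list(reversed(m.cds_segments))
            phase = 0
            for a, b in segments:
                fh.write(
                    f"{m.chrom}\tfuncgwas\tCDS\t{a + 1}\t{b}\t.\t{m.strand}\t{phase}\t"
                    f"ID=cds.{tid};Parent={tid}\n"
                )
                phase = (3 - ((b - a) - phase) % 3) % 3
        fh.flush()


def write_study(config: SimConfig, outdir: str) -> dict[str, str]:
    """Generate and serialize a full synthetic study; returns output paths."""
    import os

    os.makedirs(outdir, exist_ok=True)
    genome, models = simulate_genome(config)
    gm, truth = simulate_population(config, (genome, models))
    phen = simulate_phenotype(gm, truth, config)

    paths = {
        "fasta": os.path.join(outdir, "genome.fa"),
        "gff": os.path.join(outdir, "genes.gff3"),
        "vcf": os.path.join(outdir, "genotypes.vcf"),
        "phenotype": os.path.join(outdir, "phenotype.tsv"),
        "labels": os.path.join(outdir, "labels.tsv"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    write_fasta(genome, paths["fasta"])
    write_gff3(models, genome, paths["gff"])
    write_vcf(gm, paths["vcf"])
    phen.to_csv(paths["phenotype"], sep="\t", index=False)
    pd.DataFrame(
        {"accession_id": gm.accessions, "subpopulation": truth.label_array(gm.accessions)}
    ).to_csv(paths["labels"], sep="\t", index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "causal_ids": truth.causal_ids,
                "causal_effects_cm": truth.causal_effects,
                "heritability": truth.heritability,
                "labels": truth.labels,
                "seed": config.seed,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
    return paths
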