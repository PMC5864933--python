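"""Genotype container and VCF input/output.

The whole toolkit operates on allele dosages of largely homozygous inbred
accessions: each accession carries dosage 0 (homozygous reference),
2 (homozygous alternate) or, rarely, 1 (residual heterozygosity).  Missing
calls are coded -1.  Positions follow the VCF convention (1-based) so that
SNP identifiers such as ``chr3_30603087`` can be compared directly with
published association tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Accessions x biallelic SNPs allele-dosage matrix.

    Attributes
    ----------
    accessions : list of str
        Accession identifiers, one per row of ``dosage``.
    snp_ids, chrom, ref, alt : ndarray of str
        Per-SNP identifier, chromosome, reference and alternate allele.
    pos : ndarray of int
        1-based positions (VCF convention).
    dosage : ndarray of int8, shape (n_accessions, n_snps)
        Alternate-allele dosage in {0, 1, 2}; -1 marks a missing call.
    """

    accessions: list[str]
    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    dosage: np.ndarray
    contig_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.accessions), len(self.snp_ids)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.accessions)} accessions x {len(self.snp_ids)} SNPs"
            )

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def alt_frequency(self) -> np.ndarray:
        """Alternate-allele frequency per SNP from non-missing calls (NaN if all missing)."""
        d = self.dosage.astype(float)
        d[self.dosage == MISSING] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        f = self.alt_frequency()
        return np.minimum(f, 1.0 - f)

    def missing_fraction(self) -> np.ndarray:
        return np.mean(self.dosage == MISSING, axis=0)

    def snp_index(self, snp_id: str) -> int:
        hits = np.flatnonzero(self.snp_ids == snp_id)
        if hits.size == 0:
            raise KeyError(f"SNP {snp_id!r} not present")
        return int(hits[0])

    def subset(self, accession_idx=None, snp_idx=None) -> "GenotypeMatrix":
        """Row/column subset; either argument may be an index array or boolean mask."""
        ai = np.arange(self.n_accessions) if accession_idx is None else np.asarray(accession_idx)
        si = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        if ai.dtype == bool:
            ai = np.flatnonzero(ai)
        if si.dtype == bool:
            si = np.flatnonzero(si)
        return GenotypeMatrix(
            accessions=[self.accessions[i] for i in ai],
            snp_ids=self.snp_ids[si],
            chrom=self.chrom[si],
            pos=self.pos[si],
            ref=self.ref[si],
            alt=self.alt[si],
            dosage=self.dosage[np.ix_(ai, si)],
            contig_lengths=dict(self.contig_lengths),
        )


def write_vcf(gm: GenotypeMatrix, path: str) -> None:
    """Serialize to an uncompressed VCF v4.2 with GT-only genotype fields."""
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=funcgwas\n")
        for name, length in sorted(gm.contig_lengths.items()):
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.accessions)
            + "\n"
        )
        for j in range(gm.n_snps):
            gts = "\t".join(gt_strings[int(d)] for d in gm.dosage[:, j])
            fh.write(
                f"{gm.chrom[j]}\t{gm.pos[j]}\t{gm.snp_ids[j]}\t{gm.ref[j]}\t"
                f"{gm.alt[j]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_vcf(path: str) -> GenotypeMatrix:
    """Load biallelic SNP dosages from a VCF.

    Multiallelic records are split into one biallelic record per alternate
    allele; star (spanning-deletion) alleles are dropped, and genotypes that
    carry a different alternate allele are treated as missing for the record
    at hand.  Non-SNP alleles (indels) are skipped.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    accessions = list(vcf.samples)
    contig_lengths = {}
    for raw in vcf.raw_header.splitlines():
        if raw.startswith("##contig"):
            inner = raw.split("<", 1)[1].rstrip(">")
            fields = dict(kv.split("=", 1) for kv in inner.split(","))
            if "ID" in fields and "length" in fields:
                contig_lengths[fields["ID"]] = int(fields["length"])

    snp_ids, chroms, poss, refs, alts, rows = [], [], [], [], [], []
    for v in vcf:
        if len(v.REF) != 1:
            continue
        genos = v.genotypes  # [[a0, a1, phased], ...]
        for k, alt in enumerate(v.ALT):
            if alt == "*" or len(alt) != 1:
                continue
            dos = np.full(len(accessions), MISSING, dtype=np.int8)
            code = k + 1
            for i, g in enumerate(genos):
                a0, a1 = g[0], g[1]
                if a0 < 0 or a1 < 0:
                    continue
                if (a0 not in (0, code)) or (a1 not in (0, code)):
                    continue  # carries a different alt allele
                dos[i] = (a0 == code) + (a1 == code)
            vid = v.ID if (v.ID and len(v.ALT) == 1) else f"{v.CHROM}_{v.POS}" + (
                f"_{alt}" if len(v.ALT) > 1 else ""
            )
            snp_ids.append(vid)
            chroms.append(v.CHROM)
            poss.append(v.POS)
            refs.append(v.REF)
            alts.append(alt)
            rows.append(dos)
    dosage = (
        np.stack(rows, axis=1) if rows else np.zeros((len(accessions), 0), dtype=np.int8)
    )
    return GenotypeMatrix(
        accessions=accessions,
        snp_ids=np.array(snp_ids, dtype=object),
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        dosage=dosage,
        contig_lengths=contig_lengths,
    )
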