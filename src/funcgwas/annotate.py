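"""Protein-coding consequence annotation and functional SNP-set construction.

Every SNP is classified by its effect on the encoded protein (synonymous,
non-synonymous, premature stop, ...) via strand-aware codon arithmetic
against single-representative gene models.  From the annotated panel three
SNP sets are assembled for association testing:

* group I   - protein-altering SNPs (non-synonymous plus stop/start changes),
* group II  - group I plus SNPs within 1 kb upstream of the coding start
              ("promoter" SNPs),
* group III - a seeded uniform random sample of all SNPs, the genome-wide
              benchmark set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G", "N": "N"}

_BASES = "TCAG"
_AA = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
#: Standard nuclear genetic code, codon -> one-letter amino acid ('*' = stop).
CODON_TABLE = {
    b1 + b2 + b3: _AA[16 * i + 4 * j + k]
    for i, b1 in enumerate(_BASES)
    for j, b2 in enumerate(_BASES)
    for k, b3 in enumerate(_BASES)
}

STOP_CODONS = tuple(c for c, a in CODON_TABLE.items() if a == "*")
SENSE_CODONS = tuple(c for c, a in CODON_TABLE.items() if a != "*")

PROTEIN_CHANGING = ("nonsynonymous", "stop_gained", "stop_lost", "start_lost")


class ReferenceMismatchError(ValueError):
    """VCF REF allele disagrees with the reference genome."""


class AnnotationError(ValueError):
    """A codon could not be reconstructed from the gene model."""


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))


def translate(seq: str) -> str:
    seq = seq.upper()
    return "".join(CODON_TABLE[seq[i : i + 3]] for i in range(0, len(seq) - 2, 3))


def fetch_seq(reference, chrom: str, start: int, end: int) -> str:
    """Sequence slice [start, end) 0-based from a dict of strings or pyfaidx.Fasta."""
    return str(reference[chrom][start:end]).upper()


@dataclass
class GeneModel:
    """Single-transcript protein-coding gene model.

    CDS segments are 0-based half-open genomic intervals sorted by start;
    transcription order is derived from ``strand``.
    """

    gene_id: str
    chrom: str
    strand: str
    cds_segments: list[tuple[int, int]]
    phases: list[int] = field(default_factory=list)
    is_transposon: bool = False
    _tx_positions: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.cds_segments = sorted((int(a), int(b)) for a, b in self.cds_segments)
        for (a0, b0), (a1, _) in zip(self.cds_segments, self.cds_segments[1:]):
            if a1 < b0:
                raise ValueError(f"{self.gene_id}: overlapping CDS segments")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")

    @property
    def cds_length(self) -> int:
        return sum(b - a for a, b in self.cds_segments)

    @property
    def span(self) -> tuple[int, int]:
        return self.cds_segments[0][0], self.cds_segments[-1][1]

    def tx_positions(self) -> np.ndarray:
        """Genomic positions of CDS bases in 5'->3' transcription order."""
        if self._tx_positions is None:
            if self.strand == "+":
                parts = [np.arange(a, b) for a, b in self.cds_segments]
            else:
                parts = [np.arange(b - 1, a - 1, -1) for a, b in reversed(self.cds_segments)]
            self._tx_positions = np.concatenate(parts) if parts else np.array([], dtype=int)
        return self._tx_positions

    def cds_offset(self, pos0: int) -> int | None:
        """0-based offset of a genomic position within the spliced CDS, or None."""
        off = 0
        if self.strand == "+":
            for a, b in self.cds_segments:
                if a <= pos0 < b:
                    return off + (pos0 - a)
                off += b - a
        else:
            for a, b in reversed(self.cds_segments):
                if a <= pos0 < b:
                    return off + (b - 1 - pos0)
                off += b - a
        return None

    def promoter_interval(self, kb: int = 1000) -> tuple[int, int]:
        """Strand-aware window upstream of the coding start (the first ATG)."""
        lo, hi = self.span
        if self.strand == "+":
            return max(0, lo - kb), lo
        return hi, hi + kb


@dataclass
class Effect:
    """Consequence of one SNP on one gene (or on no gene)."""

    effect: str
    gene_id: str | None = None
    strand: str | None = None
    codon_number: int | None = None  # 1-based codon within the CDS
    codon_pos: int | None = None  # 1..3 within the codon (coding strand)
    ref_aa: str | None = None
    alt_aa: str | None = None
    ref_codon: str | None = None
    alt_codon: str | None = None


class GeneIndex:
    """Interval lookup over gene models for CDS and promoter membership."""

    def __init__(self, models: list[GeneModel], promoter_kb: int = 1000):
        self.models = list(models)
        self.promoter_kb = promoter_kb
        self._cds: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self._prom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        cds_rows: dict[str, list[tuple[int, int, int]]] = {}
        prom_rows: dict[str, list[tuple[int, int, int]]] = {}
        for mi, m in enumerate(self.models):
            for a, b in m.cds_segments:
                cds_rows.setdefault(m.chrom, []).append((a, b, mi))
            pa, pb = m.promoter_interval(promoter_kb)
            prom_rows.setdefault(m.chrom, []).append((pa, pb, mi))
        for store, rows in ((self._cds, cds_rows), (self._prom, prom_rows)):
            for chrom, r in rows.items():
                arr = np.array(r, dtype=np.int64)
                store[chrom] = (arr[:, 0], arr[:, 1], arr[:, 2])

    def _hits(self, table, chrom: str, pos0: int) -> list[int]:
        if chrom not in table:
            return []
        starts, ends, idx = table[chrom]
        mask = (starts <= pos0) & (pos0 < ends)
        return sorted(set(int(i) for i in idx[mask]))

    def cds_hits(self, chrom: str, pos0: int) -> list[GeneModel]:
        return [self.models[i] for i in self._hits(self._cds, chrom, pos0)]

    def promoter_hits(self, chrom: str, pos0: int) -> list[GeneModel]:
        return [self.models[i] for i in self._hits(self._prom, chrom, pos0)]


def classify_site(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    index: GeneIndex,
    reference,
    check_reference: bool = True,
) -> list[Effect]:
    """Classify one biallelic SNP against every gene it touches.

    ``pos`` is 1-based (VCF convention); ``ref``/``alt`` are forward-strand
    alleles.  Returns one :class:`Effect` per affected gene, or a single
    promoter/noncoding record.
    """
    pos0 = pos - 1
    ref, alt = ref.upper(), alt.upper()
    if ref == alt or len(ref) != 1 or len(alt) != 1:
        raise ValueError(f"{chrom}:{pos}: ref/alt must be distinct single bases")
    if check_reference:
        genome_base = fetch_seq(reference, chrom, pos0, pos0 + 1)
        if genome_base != ref:
            raise ReferenceMismatchError(
                f"{chrom}:{pos}: VCF REF {ref} != reference base {genome_base}"
            )

    effects: list[Effect] = []
    for model in index.cds_hits(chrom, pos0):
        off = model.cds_offset(pos0)
        codon_idx, within = divmod(off, 3)
        tx = model.tx_positions()
        codon_pos0 = tx[codon_idx * 3 : codon_idx * 3 + 3]
        if len(codon_pos0) < 3:
            raise AnnotationError(
                f"{model.gene_id}: incomplete terminal codon at {chrom}:{pos}"
            )
        bases = [fetch_seq(reference, chrom, p, p + 1) for p in codon_pos0]
        if model.strand == "-":
            bases = [COMPLEMENT[b] for b in bases]
        ref_codon = "".join(bases)
        coding_ref = ref if model.strand == "+" else COMPLEMENT[ref]
        coding_alt = alt if model.strand == "+" else COMPLEMENT[alt]
        if ref_codon[within] != coding_ref:
            raise ReferenceMismatchError(
                f"{model.gene_id}: codon base {ref_codon[within]} != REF {coding_ref} "
                f"at {chrom}:{pos}"
            )
        alt_codon = ref_codon[:within] + coding_alt + ref_codon[within + 1 :]
        ref_aa, alt_aa = CODON_TABLE[ref_codon], CODON_TABLE[alt_codon]
        if ref_aa == alt_aa:
            kind = "synonymous"
        elif alt_aa == "*":
            kind = "stop_gained"
        elif ref_aa == "*":
            kind = "stop_lost"
        elif codon_idx == 0 and ref_aa == "M":
            kind = "start_lost"
        else:
            kind = "nonsynonymous"
        effects.append(
            Effect(
                effect=kind,
                gene_id=model.gene_id,
                strand=model.strand,
                codon_number=codon_idx + 1,
                codon_pos=within + 1,
                ref_aa=ref_aa,
                alt_aa=alt_aa,
                ref_codon=ref_codon,
                alt_codon=alt_codon,
            )
        )
    if effects:
        return effects

    prom = index.promoter_hits(chrom, pos0)
    if prom:
        return [Effect(effect="promoter", gene_id=m.gene_id, strand=m.strand) for m in prom]
    return [Effect(effect="noncoding")]


def annotate_variants(
    gm: GenotypeMatrix, index: GeneIndex, reference, check_reference: bool = True
) -> pd.DataFrame:
    """Annotate every SNP of a panel; one row per (SNP, affected gene)."""
    rows = []
    for j in range(gm.n_snps):
        for eff in classify_site(
            gm.chrom[j], int(gm.pos[j]), gm.ref[j], gm.alt[j], index, reference,
            check_reference=check_reference,
        ):
            rows.append(
                {
                    "snp_id": gm.snp_ids[j],
                    "chrom": gm.chrom[j],
                    "pos": int(gm.pos[j]),
                    "ref": gm.ref[j],
                    "alt": gm.alt[j],
                    "gene_id": eff.gene_id,
                    "strand": eff.strand,
                    "codon_number": eff.codon_number,
                    "codon_pos": eff.codon_pos,
                    "ref_aa": eff.ref_aa,
                    "alt_aa": eff.alt_aa,
                    "effect": eff.effect,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class SnpGroup:
    label: str
    snp_ids: np.ndarray
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.snp_ids)


def build_snp_groups(
    annotations: pd.DataFrame,
    group_iii_size: int,
    seed: int,
    include_stop_variants: bool = True,
    excluded_genes: set[str] | None = None,
) -> dict[str, SnpGroup]:
    """Assemble the three SNP sets used for association testing.

    Group I contains protein-altering SNPs, group II adds promoter SNPs and
    group III is a seeded random sample (without replacement) of all SNPs.
    SNPs whose only affected genes are in ``excluded_genes`` (e.g. transposon
    models) do not enter groups I/II through those genes.
    """
    excluded = excluded_genes or set()
    ann = annotations[~annotations["gene_id"].isin(excluded)]
    coding_effects = (
        set(PROTEIN_CHANGING) if include_stop_variants else {"nonsynonymous"}
    )
    group1 = np.array(
        sorted(set(ann.loc[ann["effect"].isin(coding_effects), "snp_id"]))
    )
    group2 = np.array(
        sorted(set(group1) | set(ann.loc[ann["effect"] == "promoter", "snp_id"]))
    )
    all_ids = np.array(sorted(set(annotations["snp_id"])))
    if group_iii_size > len(all_ids):
        raise ValueError(
            f"group III size {group_iii_size} exceeds panel size {len(all_ids)}"
        )
    rng = np.random.default_rng(seed)
    group3 = np.sort(rng.choice(all_ids, size=group_iii_size, replace=False))
    return {
        "I": SnpGroup("I", group1),
        "II": SnpGroup("II", group2),
        "III": SnpGroup("III", group3, seed=seed),
    }


def load_gene_models(gff_path: str) -> list[GeneModel]:
    """Read gene models from GFF3, keeping the longest-CDS transcript per gene.

    Ties on CDS length break by transcript id (lexicographic).  Gene models
    with a ``transposon`` biotype-like attribute are flagged for exclusion
    from functional grouping.
    """
    import gffutils

    db = gffutils.create_db(
        gff_path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models = []
    for gene in db.features_of_type("gene"):
        candidates = []
        for mrna in db.children(gene, featuretype="mRNA"):
            cds = [(c.start - 1, c.end) for c in db.children(mrna, featuretype="CDS")]
            if cds:
                candidates.append((sum(b - a for a, b in cds), mrna.id, cds))
        if not candidates:
            cds = [(c.start - 1, c.end) for c in db.children(gene, featuretype="CDS")]
            if cds:
                candidates.append((sum(b - a for a, b in cds), gene.id, cds))
        if not candidates:
            continue
        candidates.sort(key=lambda t: (-t[0], t[1]))
        _, _, cds = candidates[0]
        note = ";".join(gene.attributes.get("Note", []))
        models.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                cds_segments=cds,
                is_transposon="transposon" in note.lower(),
            )
        )
    return models
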