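"""Consequence-calling oracle tests: codon worked examples, whole-protein
brute-force equivalence, strand involution, and SNP-set construction."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from funcgwas.annotate import (
    COMPLEMENT,
    GeneIndex,
    GeneModel,
    ReferenceMismatchError,
    build_snp_groups,
    classify_site,
    load_gene_models,
    revcomp,
)


def _single_gene_setup(cds: str, strand: str, flank: int = 1500):
    """A genome with one gene whose coding sequence is ``cds``."""
    rng = np.random.default_rng(42)
    bases = "ACGT"
    left = "".join(rng.choice(list(bases), flank))
    right = "".join(rng.choice(list(bases), flank))
    placed = cds if strand == "+" else revcomp(cds)
    genome = {"chr1": left + placed + right}
    model = GeneModel("g1", "chr1", strand, [(flank, flank + len(cds))])
    return genome, model, GeneIndex([model])


class TestWorkedCodonExamples:
    def test_forward_nonsynonymous_second_position(self):
        """GCT codon, C->T at codon position 2: GCT->GTT is A/V."""
        cds = "ATG" + "GCT" + "TAA"
        genome, model, index = _single_gene_setup(cds, "+")
        pos = 1500 + 3 + 1 + 1  # 1-based position of the codon's second base
        [eff] = classify_site("chr1", pos, "C", "T", index, genome)
        assert (eff.effect, eff.ref_aa, eff.alt_aa) == ("nonsynonymous", "A", "V")
        assert (eff.codon_number, eff.codon_pos) == (2, 2)

    def test_forward_synonymous_third_position(self):
        """GCT->GCC at the degenerate third position stays alanine."""
        cds = "ATG" + "GCT" + "TAA"
        genome, model, index = _single_gene_setup(cds, "+")
        pos = 1500 + 6
        [eff] = classify_site("chr1", pos, "T", "C", index, genome)
        assert (eff.effect, eff.ref_aa, eff.alt_aa) == ("synonymous", "A", "A")

    def test_reverse_strand_alleles_are_complemented(self):
        """Genomic G/A at a reverse-strand site that is coding C/T at codon
        position 2 of GCG: A/V, the published Chr3 pattern."""
        cds = "ATG" + "GCG" + "TAA"
        genome, model, index = _single_gene_setup(cds, "-")
        # coding position 5 (codon 2, base 2) maps to genomic offset len(cds)-5
        pos = 1500 + len(cds) - 5 + 1
        assert genome["chr1"][pos - 1] == "G"  # complement of coding C
        [eff] = classify_site("chr1", pos, "G", "A", index, genome)
        assert (eff.effect, eff.ref_aa, eff.alt_aa) == ("nonsynonymous", "A", "V")

    def test_stop_gained_from_cag(self):
        """Coding CAG with C->T gives TAG: premature stop, Q/*."""
        cds = "ATG" + "CAG" + "TAA"
        genome, model, index = _single_gene_setup(cds, "+")
        pos = 1500 + 4
        [eff] = classify_site("chr1", pos, "C", "T", index, genome)
        assert (eff.effect, eff.ref_aa, eff.alt_aa) == ("stop_gained", "Q", "*")

    def test_promoter_window_is_strand_aware(self):
        cds = "ATG" + "GCT" + "TAA"
        genome, model, index = _single_gene_setup(cds, "+")
        [eff] = classify_site(
            "chr1", 1500 - 500 + 1, genome["chr1"][1500 - 500], "A"
            if genome["chr1"][1500 - 500] != "A" else "G", index, genome,
        )
        assert eff.effect == "promoter" and eff.gene_id == "g1"
        genome_r, model_r, index_r = _single_gene_setup(cds, "-")
        pos = 1500 + len(cds) + 500  # downstream in genomic coords = upstream on '-'
        ref = genome_r["chr1"][pos - 1]
        alt = "A" if ref != "A" else "G"
        [eff] = classify_site("chr1", pos, ref, alt, index_r, genome_r)
        assert eff.effect == "promoter"

    def test_reference_mismatch_names_position(self):
        cds = "ATG" + "GCT" + "TAA"
        genome, model, index = _single_gene_setup(cds, "+")
        with pytest.raises(ReferenceMismatchError, match="chr1:1504"):
            classify_site("chr1", 1504, "A", "T", index, genome)


class TestBruteForceEquivalence:
    def _oracle(self, genome, model, pos, ref, alt):
        """Rebuild both full CDS sequences, translate whole proteins, diff."""
        seq = genome[model.chrom]
        mutated = seq[: pos - 1] + alt + seq[pos:]
        def protein(s):
            parts = "".join(s[a:b] for a, b in model.cds_segments)
            if model.strand == "-":
                parts = str(Seq(parts).reverse_complement())
            return str(Seq(parts).translate())
        p_ref, p_alt = protein(seq), protein(mutated)
        assert len(p_ref) == len(p_alt)
        diffs = [(i, a, b) for i, (a, b) in enumerate(zip(p_ref, p_alt)) if a != b]
        if not diffs:
            return ("synonymous", None, None)
        (i, a, b) = diffs[0]
        if b == "*":
            return ("stop_gained", a, b)
        if a == "*":
            return ("stop_lost", a, b)
        if i == 0 and a == "M":
            return ("start_lost", a, b)
        return ("nonsynonymous", a, b)

    def test_random_coding_snps_match_whole_protein_diff(self, small_study):
        """300 random coding SNPs on both strands agree exactly with the
        brute-force whole-protein translation oracle."""
        genome, models = small_study["genome"], small_study["models"]
        index = GeneIndex(models)
        rng = np.random.default_rng(123)
        checked = 0
        strands = set()
        while checked < 300:
            model = models[rng.integers(len(models))]
            tx = model.tx_positions()
            pos0 = int(tx[rng.integers(len(tx))])
            ref = genome[model.chrom][pos0]
            alt = "ACGT"[(rng.integers(1, 4) + "ACGT".index(ref)) % 4]
            if alt == ref:
                continue
            effects = classify_site(model.chrom, pos0 + 1, ref, alt, index, genome)
            eff = next(e for e in effects if e.gene_id == model.gene_id)
            kind, ref_aa, alt_aa = self._oracle(genome, model, pos0 + 1, ref, alt)
            assert eff.effect == kind, (model.gene_id, pos0, ref, alt)
            if kind != "synonymous":
                assert (eff.ref_aa, eff.alt_aa) == (ref_aa, alt_aa)
            strands.add(model.strand)
            checked += 1
        assert strands == {"+", "-"}

    def test_strand_involution(self, small_study):
        """Re-expressing the gene on the reverse-complemented genome gives the
        same amino-acid change."""
        genome, models = small_study["genome"], small_study["models"]
        index = GeneIndex(models)
        rng = np.random.default_rng(7)
        L = {c: len(s) for c, s in genome.items()}
        flipped_genome = {c: revcomp(s) for c, s in genome.items()}
        for _ in range(40):
            model = models[rng.integers(len(models))]
            tx = model.tx_positions()
            pos0 = int(tx[rng.integers(len(tx))])
            ref = genome[model.chrom][pos0]
            alt = "ACGT"[(rng.integers(1, 4) + "ACGT".index(ref)) % 4]
            chrom = model.chrom
            flipped_model = GeneModel(
                model.gene_id, chrom, "-" if model.strand == "+" else "+",
                [(L[chrom] - b, L[chrom] - a) for a, b in model.cds_segments],
            )
            flipped_index = GeneIndex([flipped_model])
            [e1] = [e for e in classify_site(chrom, pos0 + 1, ref, alt, index, genome)
                    if e.gene_id == model.gene_id]
            pos0_f = L[chrom] - 1 - pos0
            [e2] = classify_site(
                chrom, pos0_f + 1, COMPLEMENT[ref], COMPLEMENT[alt],
                flipped_index, flipped_genome,
            )
            assert (e1.effect, e1.ref_aa, e1.alt_aa) == (e2.effect, e2.ref_aa, e2.alt_aa)


class TestSnpGroups:
    def _annotations(self):
        rows = []
        for i in range(10):
            rows.append({"snp_id": f"ns{i}", "gene_id": "g1", "effect": "nonsynonymous"})
        for i in range(5):
            rows.append({"snp_id": f"pr{i}", "gene_id": "g1", "effect": "promoter"})
        for i in range(85):
            rows.append({"snp_id": f"nc{i}", "gene_id": None, "effect": "noncoding"})
        return pd.DataFrame(rows)

    def test_group_sizes_from_counting_fixture(self):
        groups = build_snp_groups(self._annotations(), group_iii_size=50, seed=0)
        assert len(groups["I"]) == 10
        assert len(groups["II"]) == 15
        assert len(groups["III"]) == 50
        assert set(groups["I"].snp_ids) <= set(groups["II"].snp_ids)

    def test_group_iii_is_seed_deterministic(self):
        ann = self._annotations()
        a = build_snp_groups(ann, 50, seed=3)["III"].snp_ids
        b = build_snp_groups(ann, 50, seed=3)["III"].snp_ids
        np.testing.assert_array_equal(a, b)

    def test_stop_gain_belongs_to_group_i(self):
        ann = self._annotations()
        ann.loc[len(ann)] = {"snp_id": "sg1", "gene_id": "g1", "effect": "stop_gained"}
        groups = build_snp_groups(ann, 10, seed=0)
        assert "sg1" in set(groups["I"].snp_ids)
        without = build_snp_groups(ann, 10, seed=0, include_stop_variants=False)
        assert "sg1" not in set(without["I"].snp_ids)

    def test_oversized_group_iii_raises(self):
        with pytest.raises(ValueError, match="exceeds"):
            build_snp_groups(self._annotations(), group_iii_size=101, seed=0)

    def test_transposon_genes_are_excluded_from_functional_groups(self):
        ann = self._annotations()
        ann.loc[len(ann)] = {"snp_id": "tn1", "gene_id": "te1", "effect": "nonsynonymous"}
        groups = build_snp_groups(ann, 10, seed=0, excluded_genes={"te1"})
        assert "tn1" not in set(groups["I"].snp_ids)


def test_group_membership_matches_annotation_classes(small_study):
    """Every group-I SNP intersects a CDS; no promoter-class SNP does."""
    from funcgwas.annotate import GeneIndex, annotate_variants

    gm = small_study["gm"]
    index = GeneIndex(small_study["models"])
    ann = annotate_variants(gm, index, small_study["genome"])
    groups = build_snp_groups(ann, group_iii_size=100, seed=1)
    coding = ann[ann["effect"].isin(
        ("nonsynonymous", "stop_gained", "stop_lost", "start_lost", "synonymous")
    )]
    pos_by_id = dict(zip(ann["snp_id"], zip(ann["chrom"], ann["pos"])))
    cds_sets = {m.gene_id: set(map(int, m.tx_positions())) for m in small_study["models"]}
    for sid in groups["I"].snp_ids:
        chrom, pos = pos_by_id[sid]
        assert any(
            (pos - 1) in cds_sets[m.gene_id]
            for m in small_study["models"] if m.chrom == chrom
        )
    promoter_ids = set(ann.loc[ann["effect"] == "promoter", "snp_id"])
    assert not (promoter_ids & set(coding["snp_id"]))


def test_gff_round_trip_recovers_gene_models(tmp_path, small_study):
    """Models written to GFF3 and re-read via gffutils match the originals."""
    from funcgwas.simulate import write_gff3

    path = str(tmp_path / "genes.gff3")
    write_gff3(small_study["models"], small_study["genome"], path)
    loaded = {m.gene_id: m for m in load_gene_models(path)}
    assert len(loaded) == len(small_study["models"])
    for m in small_study["models"]:
        lm = loaded[m.gene_id]
        assert (lm.chrom, lm.strand, lm.cds_segments) == (
            m.chrom, m.strand, m.cds_segments
        )
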