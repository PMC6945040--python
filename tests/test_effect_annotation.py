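"""Impact classification, frameshift consequence prediction, truncation math."""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Seq import Seq

from mendelsieve.effect_annotation import (
    GeneModel,
    annotate_variant,
    classify_impact,
    frameshift_consequence,
    load_gene_models,
    normalize_insertion_3prime,
    premature_stop_fraction,
    truncation_fraction,
)
from mendelsieve.variant_model import GenotypeCall, GenotypeState, Variant

from conftest import make_variant

_STOPS = {"TAA", "TAG", "TGA"}
_NON_STOP = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]


def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    body = "".join(_NON_STOP[i] for i in rng.integers(0, len(_NON_STOP), n_codons - 2))
    return "ATG" + body + ("TAA", "TAG", "TGA")[rng.integers(0, 3)]


def single_exon_gene(cds: str, chrom: str = "chrS", start: int = 1) -> GeneModel:
    end = start + len(cds) - 1
    return GeneModel("G1", chrom, "+", ((start, end),), ((start, end),), cds)


def oracle_truncated_length(cds: str, p: int, inserted: str) -> int | None:
    """Naive oracle: translate the edited CDS; residues before the first stop."""
    edited = cds[:p] + inserted + cds[p:]
    usable = len(edited) - len(edited) % 3
    protein = str(Seq(edited[:usable]).translate())
    stop = protein.find("*")
    return None if stop == -1 else stop


class TestFrameshiftConsequence:
    def test_toy_cds_manual_translation(self, toy_gene):
        # ATG AAA GGT AAA TGA + T after c.4 -> ATG ATA AGG TAA: M-I-R-stop
        cons = frameshift_consequence(toy_gene, (4, 5), "T", kind="ins")
        assert cons.protein_notation == "p.(Lys2IlefsTer3)"
        assert cons.truncated_length == 3
        assert cons.full_length == 4
        assert cons.cdna_notation == "c.4_5insT"

    def test_inframe_insertion_has_no_fs(self, toy_gene):
        cons = frameshift_consequence(toy_gene, (6, 7), "ATT", kind="ins")
        assert "fs" not in cons.protein_notation
        assert "ins" in cons.protein_notation

    def test_no_downstream_stop_marks_ter_unknown(self):
        # after the edit the shifted frame reaches the CDS end without a stop
        gene = single_exon_gene("ATGAAAAAAAAATGA")
        cons = frameshift_consequence(gene, (4, 5), "C", kind="ins")
        assert cons.protein_notation.endswith("fsTer?)")
        assert cons.truncated_length is None
        assert cons.retained_fraction is None

    def test_insertion_outside_cds_is_coordinate_error(self, toy_gene):
        with pytest.raises(ValueError, match="outside CDS"):
            frameshift_consequence(toy_gene, (15, 16), "T", kind="ins")
        with pytest.raises(ValueError, match="outside CDS"):
            frameshift_consequence(toy_gene, (0, 1), "T", kind="ins")

    def test_three_prime_normalization_shifts_repeats(self):
        gene = single_exon_gene("ATGTTTGGGAAATGA")
        # inserting T after c.3 is equivalent to inserting after the T run
        p, _ = normalize_insertion_3prime(gene.cds_sequence, 3, "T")
        assert p == 6
        cons = frameshift_consequence(gene, (3, 4), "T", kind="ins")
        assert cons.cdna_notation == "c.6_7insT"

    def test_deletion_frameshift(self):
        gene = single_exon_gene("ATGAAAGGTAAATGA")
        cons = frameshift_consequence(gene, (4, 5), kind="del")
        assert cons.is_frameshift or "Ter" in cons.protein_notation
        assert cons.cdna_notation == "c.4_5del"

    def test_inframe_deletion_no_fs(self):
        gene = single_exon_gene("ATGAAAGGTAAATGA")
        cons = frameshift_consequence(gene, (4, 6), kind="del")  # deletes codon 2
        assert "fs" not in cons.protein_notation

    def test_predictor_matches_translation_oracle(self):
        """Truncated length equals naive translate-the-edited-CDS over random
        CDS/insertion pairs, and fsTer arithmetic is self-consistent."""
        rng = np.random.default_rng(2024)
        for _ in range(300):
            cds = random_cds(rng, int(rng.integers(10, 120)))
            gene = single_exon_gene(cds)
            p = int(rng.integers(1, len(cds)))
            ins = "".join("ACGT"[i] for i in rng.integers(0, 4, rng.integers(1, 3)))
            if len(ins) % 3 == 0:
                continue
            cons = frameshift_consequence(gene, (p, p + 1), ins, kind="ins")
            p_norm, _ = normalize_insertion_3prime(cds, p, ins)
            expected = oracle_truncated_length(cds, p_norm, ins)
            if "fsTer?" in cons.protein_notation:
                # shifted frame lost the stop, or the change starts at/after
                # the original terminator
                assert expected is None or expected >= cons.full_length
            else:
                assert cons.truncated_length == expected
                if "fs" in cons.protein_notation:
                    tf = truncation_fraction(cons.protein_notation, cons.full_length)
                    assert tf.truncated_length == cons.truncated_length

    def test_inframe_edits_never_produce_fster(self):
        rng = np.random.default_rng(77)
        for _ in range(200):
            cds = random_cds(rng, int(rng.integers(10, 60)))
            gene = single_exon_gene(cds)
            p = int(rng.integers(1, len(cds)))
            ins = "".join("ACGT"[i] for i in rng.integers(0, 4, 3))
            cons = frameshift_consequence(gene, (p, p + 1), ins, kind="ins")
            assert "fsTer" not in cons.protein_notation


class TestTruncationFraction:
    @pytest.mark.parametrize(
        "notation,full,truncated,percent",
        [
            ("Glu47GlyfsTer3", 490, 48, 10),
            ("Lys2IlefsTer3", 4, 3, 75),
            ("Met1ValfsTer2", 2, 1, 50),
        ],
    )
    def test_known_arithmetic(self, notation, full, truncated, percent):
        result = truncation_fraction(notation, full)
        assert result.truncated_length == truncated
        assert result.percent_retained_rounded == percent

    def test_accepts_full_p_notation(self):
        assert truncation_fraction("p.(Glu47GlyfsTer3)", 490).truncated_length == 48

    def test_non_fs_notation_is_an_error(self):
        with pytest.raises(ValueError, match="in-frame"):
            truncation_fraction("Lys2_Gly3insIle", 4)

    def test_premature_stop_fraction_thirds(self):
        frac = premature_stop_fraction(157, 490)
        assert frac.truncated_length == 156
        assert float(frac.removed_nearest_third) == pytest.approx(2 / 3)


@pytest.fixture(scope="module")
def spliced_gene():
    # two exons with 5' and 3' UTR; CDS ATG AAA GGT CCC TGA split over exons
    #   exon1: 101-115 (101-105 UTR, 106-115 CDS), intron 116-215,
    #   exon2: 216-225 (216-220 CDS, 221-225 UTR)
    return GeneModel(
        gene_id="GX",
        chrom="chr1",
        strand="+",
        exons=((101, 115), (216, 225)),
        cds_intervals=((106, 115), (216, 220)),
        cds_sequence="ATGAAAGGTCCCTGA",
    )


@pytest.fixture(scope="module")
def minus_gene():
    # minus-strand single-exon gene: transcript CDS = ATG AAA GGT AAA TGA,
    # genomic sequence is its reverse complement at 201-215
    return GeneModel(
        gene_id="GM",
        chrom="chr1",
        strand="-",
        exons=((201, 215),),
        cds_intervals=((201, 215),),
        cds_sequence="ATGAAAGGTAAATGA",
    )


class TestClassifyImpact:
    def classify(self, gene, pedigree, **kw):
        return classify_impact(make_variant(pedigree, {}, **kw), [gene])

    def test_intergenic_is_modifier(self, spliced_gene, pedigree):
        call = self.classify(spliced_gene, pedigree, pos=10_000)
        assert (call.category, call.reason) == ("MODIFIER", "intergenic")

    def test_chromosome_mismatch_is_modifier_not_error(self, spliced_gene, pedigree):
        call = self.classify(spliced_gene, pedigree, chrom="chr9", pos=110)
        assert call.category == "MODIFIER"

    def test_intronic_is_modifier(self, spliced_gene, pedigree):
        call = self.classify(spliced_gene, pedigree, pos=150)
        assert (call.category, call.reason) == ("MODIFIER", "intronic")

    def test_utr_is_low_noncoding(self, spliced_gene, pedigree):
        call = self.classify(spliced_gene, pedigree, pos=103)
        assert (call.category, call.reason) == ("LOW", "noncoding")

    def test_one_bp_cds_insertion_is_high_frameshift(self, spliced_gene, pedigree):
        call = self.classify(spliced_gene, pedigree, pos=110, ref="A", alt="AT")
        assert (call.category, call.reason) == ("HIGH", "frameshift")

    def test_three_bp_cds_insertion_is_moderate_inframe(self, spliced_gene, pedigree):
        call = self.classify(spliced_gene, pedigree, pos=110, ref="A", alt="AACT")
        assert (call.category, call.reason) == ("MODERATE", "inframe_indel")

    def test_synonymous_wobble_is_low(self, spliced_gene, pedigree):
        # c.6: AAA -> AAG is still Lys
        call = self.classify(spliced_gene, pedigree, pos=111, ref="A", alt="G")
        assert (call.category, call.reason) == ("LOW", "synonymous")

    def test_missense_is_moderate(self, spliced_gene, pedigree):
        # c.4: AAA -> CAA, Lys2Gln
        call = self.classify(spliced_gene, pedigree, pos=109, ref="A", alt="C")
        assert (call.category, call.reason) == ("MODERATE", "missense")

    def test_stop_gain_is_high(self, spliced_gene, pedigree):
        # c.4 A>T turns codon 2 AAA (Lys) into TAA
        call = self.classify(spliced_gene, pedigree, pos=109, ref="A", alt="T")
        assert (call.category, call.reason) == ("HIGH", "stop_gain")

    def test_start_loss_is_high(self, spliced_gene, pedigree):
        call = self.classify(spliced_gene, pedigree, pos=106, ref="A", alt="G")
        assert (call.category, call.reason) == ("HIGH", "start_lost")

    def test_snv_in_second_cds_exon_uses_spliced_coordinates(self, spliced_gene, pedigree):
        # genomic 216 is CDS c.11 (codon 4 CCC); C>G at c.11 -> CGC (Arg) missense
        call = self.classify(spliced_gene, pedigree, pos=216, ref="C", alt="G")
        assert (call.category, call.reason) == ("MODERATE", "missense")

    def test_determinism(self, spliced_gene, pedigree):
        v = make_variant(pedigree, {}, pos=110, ref="A", alt="AT")
        assert classify_impact(v, [spliced_gene]) == classify_impact(v, [spliced_gene])


class TestMinusStrand:
    def test_genomic_cds_mapping(self, minus_gene):
        assert minus_gene.genomic_to_cds(215) == 1
        assert minus_gene.genomic_to_cds(201) == 15
        assert minus_gene.cds_to_genomic(1) == 215

    def test_minus_strand_insertion_maps_to_transcript(self, minus_gene, pedigree):
        # genomic insertion of A between 210 and 211 = transcript insT between
        # c.5 and c.6 (revcomp); frameshift
        # genomic ref at 211 (= c.5, transcript 'A' -> genomic 'T')
        v = make_variant(pedigree, {}, pos=210, ref="T", alt="TA")
        ann = annotate_variant(v, [minus_gene])
        assert ann.impact.category == "HIGH"
        assert ann.impact.reason == "frameshift"
        assert "ins" in ann.cdna_notation

    def test_minus_strand_snv_uses_complemented_alleles(self, minus_gene, pedigree):
        # transcript c.4 A (codon 2 AAA); genomic position 212 carries 'T';
        # genomic T>A == transcript A>T -> TAA stop gain
        v = make_variant(pedigree, {}, pos=212, ref="T", alt="A")
        call = classify_impact(v, [minus_gene])
        assert (call.category, call.reason) == ("HIGH", "stop_gain")


class TestGeneModelValidation:
    def test_rejects_bad_cds(self):
        with pytest.raises(ValueError, match="ATG"):
            single_exon_gene("TTGAAATGA")
        with pytest.raises(ValueError, match="stop"):
            single_exon_gene("ATGAAAAAA")
        with pytest.raises(ValueError, match="divisible"):
            GeneModel("g", "c", "+", ((1, 4),), ((1, 4),), "ATGA")
        with pytest.raises(ValueError, match="internal stop"):
            single_exon_gene("ATGTAAAAATGA")

    def test_rejects_interval_inconsistency(self):
        with pytest.raises(ValueError, match="length"):
            GeneModel("g", "c", "+", ((1, 20),), ((1, 20),), "ATGAAATGA")
        with pytest.raises(ValueError, match="outside exons"):
            GeneModel("g", "c", "+", ((1, 5),), ((1, 9),), "ATGAAATGA")


def test_load_gene_models_round_trip(tmp_path, toy_gene):
    from mendelsieve.effect_annotation import format_intervals

    (tmp_path / "genes.tsv").write_text(
        "gene_id\tchrom\tstrand\texons\tcds_intervals\tcds_fasta_id\n"
        f"TOY\tchrT\t+\t{format_intervals(toy_gene.exons)}\t"
        f"{format_intervals(toy_gene.cds_intervals)}\tTOY\n"
    )
    (tmp_path / "cds.fasta").write_text(">TOY\nATGAAAGGTAAATGA\n")
    genes = load_gene_models(tmp_path / "genes.tsv", tmp_path / "cds.fasta")
    assert genes == [toy_gene]


def test_load_gene_models_gff(tmp_path):
    gff = (
        "##gff-version 3\n"
        "chrT\tsrc\tgene\t11\t25\t.\t+\t.\tID=TOY\n"
        "chrT\tsrc\texon\t11\t25\t.\t+\t.\tID=TOY.e1;Parent=TOY\n"
        "chrT\tsrc\tCDS\t11\t25\t.\t+\t0\tID=TOY.c1;Parent=TOY\n"
    )
    (tmp_path / "g.gff3").write_text(gff)
    (tmp_path / "cds.fasta").write_text(">TOY\nATGAAAGGTAAATGA\n")
    from mendelsieve.effect_annotation import load_gene_models_gff

    genes = load_gene_models_gff(tmp_path / "g.gff3", tmp_path / "cds.fasta")
    assert len(genes) == 1
    assert genes[0].cds_sequence == "ATGAAAGGTAAATGA"
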