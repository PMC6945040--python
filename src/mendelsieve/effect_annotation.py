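"""Simplified coding-impact classification and frameshift consequence prediction.

This is a deliberately small stand-in for a full variant-effect annotator.
It covers exactly what recessive candidate triage needs:

* an impact category per variant (``HIGH`` / ``MODERATE`` / ``LOW`` /
  ``MODIFIER``) with a stable reason code, from a single transcript model
  per gene;
* HGVS-style ``c.`` / ``p.`` naming of coding insertions and deletions,
  including the fsTer arithmetic for frameshifts: the first changed residue
  counts as 1 and the premature stop as N, so a ``p.(Xaa P Yaa fsTer N)``
  protein retains ``P + N - 2`` residues.

Splice sites, UTR/regulatory subtleties and multi-transcript isoforms are
out of scope; those categories collapse into the simplified table below.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .variant_model import Variant

__all__ = [
    "GeneModel",
    "ImpactCall",
    "ProteinConsequence",
    "Annotation",
    "classify_impact",
    "frameshift_consequence",
    "truncation_fraction",
    "premature_stop_fraction",
    "annotate_variant",
    "load_gene_models",
    "load_gene_models_gff",
    "HIGH",
    "MODERATE",
    "LOW",
    "MODIFIER",
]

HIGH = "HIGH"
MODERATE = "MODERATE"
LOW = "LOW"
MODIFIER = "MODIFIER"

_STOPS = {"TAA", "TAG", "TGA"}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _translate(seq: str) -> str:
    """Translate an in-frame nucleotide string; trailing partial codon dropped."""
    usable = len(seq) - len(seq) % 3
    return str(Seq(seq[:usable]).translate())


def _aa3(aa: str) -> str:
    return seq3(aa)  # '*' -> 'Ter'


@dataclass(frozen=True)
class GeneModel:
    """One gene = one transcript: exon and CDS intervals plus the CDS sequence.

    Intervals are 1-based inclusive genomic coordinates, non-overlapping and
    sorted in genomic order regardless of strand; ``cds_sequence`` is in
    transcript orientation (starts with ATG, ends with a stop codon, length
    divisible by 3, no internal stop).
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_intervals: tuple[tuple[int, int], ...]
    cds_sequence: str

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        for name, ivs in (("exons", self.exons), ("cds_intervals", self.cds_intervals)):
            if not ivs:
                raise ValueError(f"{self.gene_id}: empty {name}")
            prev_end = 0
            for start, end in ivs:
                if start < 1 or end < start:
                    raise ValueError(f"{self.gene_id}: bad interval {start}-{end}")
                if start <= prev_end:
                    raise ValueError(f"{self.gene_id}: {name} overlap or unsorted")
                prev_end = end
        for cs, ce in self.cds_intervals:
            if not any(es <= cs and ce <= ee for es, ee in self.exons):
                raise ValueError(f"{self.gene_id}: CDS interval outside exons")
        cds_len = sum(e - s + 1 for s, e in self.cds_intervals)
        seq = self.cds_sequence
        if len(seq) != cds_len:
            raise ValueError(
                f"{self.gene_id}: CDS sequence length {len(seq)} != intervals {cds_len}"
            )
        if len(seq) % 3 != 0:
            raise ValueError(f"{self.gene_id}: CDS length not divisible by 3")
        if not set(seq) <= set("ACGT"):
            raise ValueError(f"{self.gene_id}: CDS sequence has non-ACGT characters")
        if not seq.startswith("ATG"):
            raise ValueError(f"{self.gene_id}: CDS does not start with ATG")
        if seq[-3:] not in _STOPS:
            raise ValueError(f"{self.gene_id}: CDS does not end with a stop codon")
        protein = _translate(seq)
        if "*" in protein[:-1]:
            raise ValueError(f"{self.gene_id}: internal stop codon in CDS")

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def cds_length(self) -> int:
        return len(self.cds_sequence)

    @property
    def protein_length(self) -> int:
        """Residues excluding the stop."""
        return len(self.cds_sequence) // 3 - 1

    def contains(self, pos: int) -> bool:
        s, e = self.span
        return s <= pos <= e

    def in_exon(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)

    def genomic_to_cds(self, pos: int) -> int | None:
        """1-based CDS (transcript) coordinate of a genomic position, or None."""
        offset = 0
        if self.strand == "+":
            for s, e in self.cds_intervals:
                if s <= pos <= e:
                    return offset + (pos - s + 1)
                offset += e - s + 1
        else:
            for s, e in reversed(self.cds_intervals):
                if s <= pos <= e:
                    return offset + (e - pos + 1)
                offset += e - s + 1
        return None

    def cds_to_genomic(self, cds_pos: int) -> int:
        if not 1 <= cds_pos <= self.cds_length:
            raise ValueError(f"CDS position {cds_pos} outside 1..{self.cds_length}")
        remaining = cds_pos
        if self.strand == "+":
            for s, e in self.cds_intervals:
                length = e - s + 1
                if remaining <= length:
                    return s + remaining - 1
                remaining -= length
        else:
            for s, e in reversed(self.cds_intervals):
                length = e - s + 1
                if remaining <= length:
                    return e - remaining + 1
                remaining -= length
        raise AssertionError("unreachable")


@dataclass(frozen=True)
class ImpactCall:
    category: str
    reason: str
    gene_id: str | None = None


@dataclass(frozen=True)
class ProteinConsequence:
    """HGVS-like naming of a coding edit plus truncation bookkeeping.

    ``truncated_length`` is the number of residues retained before the first
    (premature) stop; it is ``None`` when the edit does not truncate — either
    because it is in-frame and stop-preserving, or because the shifted frame
    reaches the end of the CDS without any stop (``protein_notation`` then
    carries ``Ter?``).
    """

    cdna_notation: str
    protein_notation: str
    truncated_length: int | None
    full_length: int
    retained_fraction: float | None

    @property
    def is_frameshift(self) -> bool:
        return "fs" in self.protein_notation


def normalize_insertion_3prime(cds: str, pos: int, inserted: str) -> tuple[int, str]:
    """Shift an insertion (after CDS position ``pos``) to its most-3' equivalent
    placement, the standard HGVS normalization for repeats."""
    k = len(inserted)
    while pos + k <= len(cds) and cds[pos : pos + k] == inserted:
        pos += k
    return pos, inserted


def frameshift_consequence(
    gene: GeneModel,
    cds_position: tuple[int, int],
    seq: str | None = None,
    kind: str = "ins",
) -> ProteinConsequence:
    """Name a coding insertion or deletion and compute its truncation effect.

    ``cds_position`` is the 1-based CDS coordinate pair: for ``kind='ins'`` the
    flanking pair (p, p+1) with ``seq`` the inserted bases (transcript
    orientation); for ``kind='del'`` the deleted range (a, b) inclusive.

    The edit is applied to the CDS, translation restarts from the original
    ATG, and for frame-disrupting edits the first changed residue P and the
    first in-frame stop thereafter define ``p.(RefAAPosNewAAfsTerN)`` with the
    changed residue counting as 1 and the stop as N.
    """
    cds = gene.cds_sequence
    L = len(cds)
    if kind == "ins":
        if seq is None or not seq or not set(seq) <= set("ACGT"):
            raise ValueError("insertion requires a non-empty ACGT sequence")
        p, p2 = cds_position
        if p2 != p + 1:
            raise ValueError(f"insertion point must be a (p, p+1) pair, got {cds_position}")
        if not 1 <= p <= L - 1:
            raise ValueError(f"insertion point {p} outside CDS (1..{L - 1})")
        p, seq = normalize_insertion_3prime(cds, p, seq)
        edited = cds[:p] + seq + cds[p:]
        cdna = f"c.{p}_{p + 1}ins{seq}"
        diff = len(seq)
    elif kind == "del":
        a, b = cds_position
        if not (1 <= a <= b <= L):
            raise ValueError(f"deleted range {a}_{b} outside CDS (1..{L})")
        if seq is not None and cds[a - 1 : b] != seq:
            raise ValueError(f"deleted sequence mismatch at c.{a}_{b}")
        edited = cds[: a - 1] + cds[b:]
        cdna = f"c.{a}del" if a == b else f"c.{a}_{b}del"
        diff = -(b - a + 1)
    else:
        raise ValueError(f"kind must be 'ins' or 'del', got {kind!r}")

    orig_prot = _translate(cds)  # ends with '*'
    edited_prot = _translate(edited)
    full_length = gene.protein_length
    stop0 = edited_prot.find("*")

    if diff % 3 == 0:
        return _inframe_consequence(
            gene, cds, edited, cdna, orig_prot, edited_prot, stop0, kind, cds_position, seq
        )

    # frameshift path
    n = min(len(orig_prot), len(edited_prot))
    f0 = next((i for i in range(n) if orig_prot[i] != edited_prot[i]), n)
    P = f0 + 1
    ref_aa = orig_prot[f0] if f0 < len(orig_prot) else "*"
    new_aa = edited_prot[f0] if f0 < len(edited_prot) else None
    if stop0 == -1 or new_aa is None:
        label = _aa3(new_aa) if new_aa is not None else "?"
        return ProteinConsequence(
            cdna, f"p.({_aa3(ref_aa)}{P}{label}fsTer?)", None, full_length, None
        )
    if new_aa == "*":
        # the first changed residue is itself the stop: plain nonsense naming
        truncated = P - 1
        return ProteinConsequence(
            cdna, f"p.({_aa3(ref_aa)}{P}Ter)", truncated, full_length,
            truncated / full_length,
        )
    ter_pos = stop0 + 1
    N = ter_pos - P + 1
    truncated = ter_pos - 1
    return ProteinConsequence(
        cdna,
        f"p.({_aa3(ref_aa)}{P}{_aa3(new_aa)}fsTer{N})",
        truncated,
        full_length,
        truncated / full_length,
    )


def _inframe_consequence(
    gene: GeneModel,
    cds: str,
    edited: str,
    cdna: str,
    orig_prot: str,
    edited_prot: str,
    stop0: int,
    kind: str,
    cds_position: tuple[int, int],
    seq: str | None,
) -> ProteinConsequence:
    """Name an in-frame edit.  Never emits 'fs'."""
    full_length = gene.protein_length
    expected_len = len(edited) // 3 - 1  # residues if no premature stop
    premature = 0 <= stop0 < expected_len
    truncated = stop0 if premature else None
    retained = truncated / full_length if truncated is not None else None

    if kind == "ins" and seq is not None:
        p = cds_position[0]
        p, seq = normalize_insertion_3prime(cds, p, seq)
        if p % 3 == 0 and p >= 3:
            r = p // 3
            ins_aas = _translate(seq)
            left = orig_prot[r - 1]
            right = orig_prot[r] if r < len(orig_prot) else "*"
            notation = (
                f"p.({_aa3(left)}{r}_{_aa3(right)}{r + 1}"
                f"ins{''.join(_aa3(a) for a in ins_aas)})"
            )
            return ProteinConsequence(cdna, notation, truncated, full_length, retained)

    # generic in-frame: trim common prefix/suffix and describe as delins
    i = 0
    while i < min(len(orig_prot), len(edited_prot)) and orig_prot[i] == edited_prot[i]:
        i += 1
    j_o, j_e = len(orig_prot), len(edited_prot)
    while j_o > i and j_e > i and orig_prot[j_o - 1] == edited_prot[j_e - 1]:
        j_o -= 1
        j_e -= 1
    if i >= j_o and i >= j_e:
        return ProteinConsequence(cdna, "p.(=)", truncated, full_length, retained)
    first = orig_prot[i] if i < len(orig_prot) else "*"
    new_run = edited_prot[i:j_e] or ""
    if j_o - i <= 1:
        head = f"{_aa3(first)}{i + 1}"
    else:
        last = orig_prot[j_o - 1]
        head = f"{_aa3(first)}{i + 1}_{_aa3(last)}{j_o}"
    if new_run:
        notation = f"p.({head}delins{''.join(_aa3(a) for a in new_run)})"
    else:
        notation = f"p.({head}del)"
    return ProteinConsequence(cdna, notation, truncated, full_length, retained)


class TruncationResult(NamedTuple):
    truncated_length: int
    percent_retained: float
    percent_retained_rounded: int


_FS_RE = re.compile(r"^(?:p\.)?\(?([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2})fsTer(\d+)\)?$")


def truncation_fraction(protein_notation: str, full_length: int) -> TruncationResult:
    """Truncation arithmetic from an fsTer protein notation.

    For ``p.(RefAA Pos NewAA fsTer N)`` the truncated protein keeps
    ``(Pos - 1) + (N - 1)`` residues (everything before the first changed
    residue, plus the novel run up to but excluding the stop), and the
    retained percentage is ``100 * truncated / full_length``.
    """
    m = _FS_RE.match(protein_notation.strip())
    if m is None:
        raise ValueError(
            f"{protein_notation!r} is not an fsTer notation; "
            "in-frame events carry no truncation arithmetic — "
            "see frameshift_consequence for in-frame handling"
        )
    pos = int(m.group(2))
    n = int(m.group(4))
    truncated = (pos - 1) + (n - 1)
    percent = 100.0 * truncated / full_length
    return TruncationResult(truncated, percent, round(percent))


class StopFraction(NamedTuple):
    truncated_length: int
    retained_fraction: float
    removed_fraction: float
    removed_nearest_third: Fraction


def premature_stop_fraction(stop_residue: int, full_length: int) -> StopFraction:
    """Retained/removed protein fractions for a premature stop at a given residue.

    A stop at residue ``k`` leaves ``k - 1`` residues of a ``full_length``
    protein; the removed fraction is also reported rounded to the nearest
    third (the granularity in which such losses are conventionally quoted).
    """
    if not 1 <= stop_residue <= full_length:
        raise ValueError("stop residue must lie within the protein")
    truncated = stop_residue - 1
    retained = truncated / full_length
    removed = 1.0 - retained
    return StopFraction(truncated, retained, removed, Fraction(round(removed * 3), 3))


def _find_gene(variant: Variant, genes: Iterable[GeneModel]) -> GeneModel | None:
    end = variant.pos + len(variant.ref) - 1
    for gene in genes:
        if gene.chrom != variant.chrom:
            continue
        s, e = gene.span
        if variant.pos <= e and end >= s:
            return gene
    return None


def _transcript_base(gene: GeneModel, base: str) -> str:
    return base if gene.strand == "+" else base.translate(_COMPLEMENT)


def _snv_call(gene: GeneModel, c: int, ref: str, alt: str) -> tuple[ImpactCall, str, str]:
    """Impact + c./p. notation of an SNV at CDS position c (genomic alleles)."""
    tref = _transcript_base(gene, ref)
    talt = _transcript_base(gene, alt)
    cds = gene.cds_sequence
    codon_i = (c - 1) // 3
    off = (c - 1) % 3
    codon = cds[3 * codon_i : 3 * codon_i + 3]
    alt_codon = codon[:off] + talt + codon[off + 1 :]
    aa_ref = _translate(codon)
    aa_alt = _translate(alt_codon)
    cdna = f"c.{c}{tref}>{talt}"
    pos_aa = codon_i + 1
    if aa_ref == aa_alt:
        return ImpactCall(LOW, "synonymous", gene.gene_id), cdna, "p.(=)"
    if codon_i == 0:
        return ImpactCall(HIGH, "start_lost", gene.gene_id), cdna, "p.(Met1?)"
    if aa_alt == "*":
        call = ImpactCall(HIGH, "stop_gain", gene.gene_id)
        return call, cdna, f"p.({_aa3(aa_ref)}{pos_aa}Ter)"
    if aa_ref == "*":
        call = ImpactCall(HIGH, "stop_lost", gene.gene_id)
        return call, cdna, f"p.(Ter{pos_aa}{_aa3(aa_alt)}ext*?)"
    call = ImpactCall(MODERATE, "missense", gene.gene_id)
    return call, cdna, f"p.({_aa3(aa_ref)}{pos_aa}{_aa3(aa_alt)})"


def _noncoding_call(gene: GeneModel, positions: Sequence[int]) -> ImpactCall:
    if any(gene.in_exon(p) for p in positions):
        return ImpactCall(LOW, "noncoding", gene.gene_id)
    return ImpactCall(MODIFIER, "intronic", gene.gene_id)


@dataclass(frozen=True)
class Annotation:
    impact: ImpactCall
    gene_id: str | None
    cdna_notation: str | None
    protein_notation: str | None
    consequence: ProteinConsequence | None

    def msq(self) -> str:
        """The MSQ INFO payload: gene|impact|reason|cdna|protein."""
        return "|".join(
            [
                self.gene_id or ".",
                self.impact.category,
                self.impact.reason,
                self.cdna_notation or ".",
                self.protein_notation or ".",
            ]
        )


def annotate_variant(variant: Variant, genes: Sequence[GeneModel]) -> Annotation:
    """Full annotation: impact category/reason plus c./p. notation when coding."""
    gene = _find_gene(variant, genes)
    if gene is None:
        return Annotation(ImpactCall(MODIFIER, "intergenic"), None, None, None, None)
    ref, alt = variant.ref, variant.alts[0]
    pos = variant.pos

    if len(ref) == 1 and len(alt) == 1:  # SNV
        c = gene.genomic_to_cds(pos)
        if c is None:
            call = _noncoding_call(gene, [pos])
            return Annotation(call, gene.gene_id, None, None, None)
        call, cdna, prot = _snv_call(gene, c, ref, alt)
        return Annotation(call, gene.gene_id, cdna, prot, None)

    if len(ref) == 1 and len(alt) > 1 and alt[0] == ref:  # insertion
        inserted_genomic = alt[1:]
        c_left = gene.genomic_to_cds(pos)
        c_right = gene.genomic_to_cds(pos + 1)
        if c_left is None or c_right is None:
            call = _noncoding_call(gene, [pos, pos + 1])
            return Annotation(call, gene.gene_id, None, None, None)
        if gene.strand == "+":
            p = c_left
            tseq = inserted_genomic
        else:
            p = c_right
            tseq = _revcomp(inserted_genomic)
        p_norm, _ = normalize_insertion_3prime(gene.cds_sequence, p, tseq)
        cons = frameshift_consequence(gene, (p, p + 1), tseq, kind="ins")
        if p_norm < 3:
            call = ImpactCall(HIGH, "start_lost", gene.gene_id)
            return Annotation(call, gene.gene_id, cons.cdna_notation, "p.(Met1?)", None)
        if len(tseq) % 3 != 0:
            call = ImpactCall(HIGH, "frameshift", gene.gene_id)
        else:
            call = ImpactCall(MODERATE, "inframe_indel", gene.gene_id)
        return Annotation(
            call, gene.gene_id, cons.cdna_notation, cons.protein_notation, cons
        )

    if len(alt) == 1 and len(ref) > 1 and ref[0] == alt:  # deletion
        deleted_positions = list(range(pos + 1, pos + len(ref)))
        cds_positions = [
            c for p in deleted_positions if (c := gene.genomic_to_cds(p)) is not None
        ]
        if not cds_positions:
            call = _noncoding_call(gene, deleted_positions)
            return Annotation(call, gene.gene_id, None, None, None)
        del_len = len(cds_positions)
        if min(cds_positions) <= 3:
            call = ImpactCall(HIGH, "start_lost", gene.gene_id)
            return Annotation(call, gene.gene_id, None, "p.(Met1?)", None)
        cons = None
        if del_len == len(deleted_positions):  # fully coding: name it
            a, b = min(cds_positions), max(cds_positions)
            cons = frameshift_consequence(gene, (a, b), kind="del")
        if del_len % 3 != 0:
            call = ImpactCall(HIGH, "frameshift", gene.gene_id)
        else:
            call = ImpactCall(MODERATE, "inframe_indel", gene.gene_id)
        return Annotation(
            call,
            gene.gene_id,
            cons.cdna_notation if cons else None,
            cons.protein_notation if cons else None,
            cons,
        )

    # complex substitution (MNV / delins): classify by net length change
    span = range(pos, pos + len(ref))
    cds_positions = [c for p in span if (c := gene.genomic_to_cds(p)) is not None]
    if not cds_positions:
        call = _noncoding_call(gene, list(span))
        return Annotation(call, gene.gene_id, None, None, None)
    diff = abs(len(alt) - len(ref))
    if diff == 0:
        call = ImpactCall(MODERATE, "missense", gene.gene_id)
    elif diff % 3 != 0:
        call = ImpactCall(HIGH, "frameshift", gene.gene_id)
    else:
        call = ImpactCall(MODERATE, "inframe_indel", gene.gene_id)
    return Annotation(call, gene.gene_id, None, None, None)


def classify_impact(variant: Variant, genes: Sequence[GeneModel]) -> ImpactCall:
    """Impact category of a variant against a set of single-transcript genes.

    A deterministic pure function of (variant, gene models); chromosome
    mismatch simply means no overlap (MODIFIER), not an error.
    """
    return annotate_variant(variant, genes).impact


def _parse_intervals(text: str) -> tuple[tuple[int, int], ...]:
    out = []
    for part in text.split(";"):
        start, end = part.split("-")
        out.append((int(start), int(end)))
    return tuple(out)


def format_intervals(intervals: Iterable[tuple[int, int]]) -> str:
    return ";".join(f"{s}-{e}" for s, e in intervals)


def load_gene_models(genes_tsv: str | Path, cds_fasta: str | Path) -> list[GeneModel]:
    """Read gene models from the 6-column TSV + companion CDS FASTA.

    Columns: gene_id, chrom, strand, exons, cds_intervals, cds_fasta_id;
    interval lists are semicolon-joined ``start-end`` pairs (1-based inclusive).
    """
    cds_seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(cds_fasta), "fasta")}
    genes: list[GeneModel] = []
    with open(genes_tsv) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("gene_id\t"):
                continue
            gene_id, chrom, strand, exons, cds, fasta_id = line.split("\t")
            if fasta_id not in cds_seqs:
                raise ValueError(f"CDS FASTA is missing sequence {fasta_id!r}")
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    chrom=chrom,
                    strand=strand,
                    exons=_parse_intervals(exons),
                    cds_intervals=_parse_intervals(cds),
                    cds_sequence=cds_seqs[fasta_id],
                )
            )
    genes.sort(key=lambda g: (g.chrom, g.span[0]))
    return genes


def load_gene_models_gff(gff_path: str | Path, cds_fasta: str | Path) -> list[GeneModel]:
    """Read a minimal GFF3 subset (gene/exon/CDS features) plus a CDS FASTA
    keyed by gene ID."""
    import gffutils

    db = gffutils.create_db(
        str(gff_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    cds_seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(cds_fasta), "fasta")}
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        gene_id = gene.id
        exons = tuple(
            sorted((f.start, f.end) for f in db.children(gene, featuretype="exon"))
        )
        cds = tuple(
            sorted((f.start, f.end) for f in db.children(gene, featuretype="CDS"))
        )
        if gene_id not in cds_seqs:
            raise ValueError(f"CDS FASTA is missing sequence {gene_id!r}")
        genes.append(
            GeneModel(
                gene_id=gene_id,
                chrom=gene.seqid,
                strand=gene.strand,
                exons=exons,
                cds_intervals=cds,
                cds_sequence=cds_seqs[gene_id],
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.span[0]))
    return genes
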