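"""Data model and I/O for multi-sample pedigree variants.

The unit flowing through the filter cascade is a :class:`Variant`: one
genomic site with a single alternate allele and one :class:`GenotypeCall`
per genotyped pedigree member.  Multiallelic VCF records are split into one
``Variant`` per alternate allele at read time, with genotype states computed
per allele (carrying any *other* alternate allele counts as non-carrier for
the allele under consideration).

Coordinates are 1-based inclusive throughout, matching VCF.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

from cyvcf2 import VCF

__all__ = [
    "ConfigurationError",
    "VcfParseError",
    "GenotypeState",
    "GenotypeCall",
    "SiteKey",
    "Variant",
    "PedigreeSpec",
    "read_pedigree_vcf",
    "write_pedigree_vcf",
    "genotype_counts",
]

_VALID_BASES = frozenset("ACGTN")


class ConfigurationError(ValueError):
    """Inconsistent run configuration (e.g. pedigree sample absent from VCF)."""


class VcfParseError(ValueError):
    """Malformed VCF content (bad genotype, unexpected ploidy, unsorted records)."""


class GenotypeState(str, Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"


@dataclass(frozen=True)
class GenotypeCall:
    """A diploid genotype state plus the per-sample read depth (DP).

    ``depth=None`` means DP was absent from the record — deliberately distinct
    from an explicit depth of 0.
    """

    state: GenotypeState
    depth: int | None = None

    def __post_init__(self) -> None:
        if self.depth is not None and self.depth < 0:
            raise ValueError(f"negative depth {self.depth}")


@dataclass(frozen=True, order=True)
class SiteKey:
    """Site identity by (chrom, pos) only — the unit of catalog subtraction."""

    chrom: str
    pos: int


@dataclass
class Variant:
    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    calls: dict[str, GenotypeCall]
    site_depth: int | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        for allele in (self.ref, *self.alts):
            if not allele or not set(allele) <= _VALID_BASES:
                raise ValueError(f"invalid allele {allele!r} at {self.chrom}:{self.pos}")
        if not self.alts:
            raise ValueError("variant needs at least one alt allele")
        if self.site_depth is not None and self.site_depth < 0:
            raise ValueError("negative site depth")

    @property
    def site_key(self) -> SiteKey:
        return SiteKey(self.chrom, self.pos)

    @property
    def sort_key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alts[0])

    @property
    def allele_key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alts[0])

    def call(self, sample_id: str) -> GenotypeCall:
        return self.calls[sample_id]


@dataclass(frozen=True)
class PedigreeSpec:
    """Sample roles for a nuclear family: dam, optional sire, offspring by status.

    The sire may be present in the pedigree but ungenotyped (the study design
    this package emulates sequenced the dam and five offspring only).
    """

    dam_id: str
    affected_ids: tuple[str, ...]
    unaffected_ids: tuple[str, ...]
    sire_id: str | None = None
    sire_genotyped: bool = False

    def __post_init__(self) -> None:
        ids = [self.dam_id, *self.affected_ids, *self.unaffected_ids]
        if self.sire_id is not None:
            ids.append(self.sire_id)
        if len(set(ids)) != len(ids):
            raise ConfigurationError("pedigree sample ids must be unique")
        if not self.affected_ids:
            raise ConfigurationError("pedigree needs at least one affected sample")
        if self.sire_genotyped and self.sire_id is None:
            raise ConfigurationError("sire marked genotyped but no sire_id given")

    @property
    def genotyped_samples(self) -> tuple[str, ...]:
        """Samples expected to carry genotype calls, in canonical output order."""
        parents = [self.dam_id]
        if self.sire_id is not None and self.sire_genotyped:
            parents.append(self.sire_id)
        return tuple(parents) + self.affected_ids + self.unaffected_ids

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PedigreeSpec":
        """Read the 4-column pedigree TSV: sample_id, role, status, genotyped."""
        dam = sire = None
        sire_genotyped = False
        affected: list[str] = []
        unaffected: list[str] = []
        with open(path, newline="") as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#") or row[0] == "sample_id":
                    continue
                if len(row) != 4:
                    raise ConfigurationError(f"pedigree TSV row needs 4 columns: {row}")
                sample, role, status, genotyped = (c.strip() for c in row)
                if role == "dam":
                    dam = sample
                elif role == "sire":
                    sire = sample
                    sire_genotyped = genotyped == "yes"
                elif role == "offspring":
                    if genotyped != "yes":
                        raise ConfigurationError(
                            f"ungenotyped offspring {sample!r} is not supported"
                        )
                    if status == "affected":
                        affected.append(sample)
                    elif status == "unaffected":
                        unaffected.append(sample)
                    else:
                        raise ConfigurationError(
                            f"offspring {sample!r} needs status affected/unaffected"
                        )
                else:
                    raise ConfigurationError(f"unknown pedigree role {role!r}")
        if dam is None:
            raise ConfigurationError("pedigree TSV has no dam row")
        return cls(
            dam_id=dam,
            affected_ids=tuple(affected),
            unaffected_ids=tuple(unaffected),
            sire_id=sire,
            sire_genotyped=sire_genotyped,
        )

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["sample_id", "role", "status", "genotyped"])
            w.writerow([self.dam_id, "dam", "unaffected", "yes"])
            if self.sire_id is not None:
                w.writerow(
                    [self.sire_id, "sire", "unaffected",
                     "yes" if self.sire_genotyped else "no"]
                )
            for s in self.affected_ids:
                w.writerow([s, "offspring", "affected", "yes"])
            for s in self.unaffected_ids:
                w.writerow([s, "offspring", "unaffected", "yes"])


_GT_STRINGS = {
    GenotypeState.HOM_REF: "0/0",
    GenotypeState.HET: "0/1",
    GenotypeState.HOM_ALT: "1/1",
    GenotypeState.MISSING: "./.",
}


def _state_for_alt(a: int, b: int, alt_index: int) -> GenotypeState:
    """Genotype state with respect to one alternate allele of a (possibly
    multiallelic) record.  Any partially missing call is treated as missing."""
    if a < 0 or b < 0:
        return GenotypeState.MISSING
    n = (a == alt_index) + (b == alt_index)
    if n == 2:
        return GenotypeState.HOM_ALT
    if n == 1:
        return GenotypeState.HET
    return GenotypeState.HOM_REF


def read_pedigree_vcf(path: str | Path, pedigree: PedigreeSpec) -> list[Variant]:
    """Read a multi-sample VCF into the per-alt-allele ``Variant`` model.

    Records must be grouped by chromosome and position-sorted within each
    chromosome.  Phased separators are accepted and treated as unphased;
    ploidy other than 2 is a parse error (autosomal recessive model).
    """
    vcf = VCF(str(path))
    header_samples = list(vcf.samples)
    for sample in pedigree.genotyped_samples:
        if sample not in header_samples:
            raise ConfigurationError(
                f"pedigree sample {sample!r} not found in VCF header"
            )
    indices = {s: header_samples.index(s) for s in pedigree.genotyped_samples}

    variants: list[Variant] = []
    seen_chroms: set[str] = set()
    cur_chrom: str | None = None
    last_pos = 0
    for recno, rec in enumerate(vcf, start=1):
        chrom, pos = rec.CHROM, rec.POS
        if chrom != cur_chrom:
            if chrom in seen_chroms:
                raise VcfParseError(
                    f"record {recno}: chromosome {chrom} not grouped (unsorted VCF)"
                )
            seen_chroms.add(chrom)
            cur_chrom = chrom
            last_pos = 0
        if pos < last_pos:
            raise VcfParseError(f"record {recno}: unsorted position {chrom}:{pos}")
        last_pos = pos

        genotypes = rec.genotypes
        for sample, i in indices.items():
            if len(genotypes[i]) != 3:  # [allele_a, allele_b, phased]
                raise VcfParseError(
                    f"record {recno} ({chrom}:{pos}): sample {sample!r} is not "
                    f"diploid"
                )
        dp = rec.format("DP")
        info_dp = rec.INFO.get("DP")
        site_depth = int(info_dp) if info_dp is not None else None

        for alt_index, alt in enumerate(rec.ALT, start=1):
            calls: dict[str, GenotypeCall] = {}
            for sample, i in indices.items():
                a, b = genotypes[i][0], genotypes[i][1]
                depth: int | None = None
                if dp is not None:
                    d = int(dp[i][0]) if dp.ndim > 1 else int(dp[i])
                    depth = d if d >= 0 else None
                calls[sample] = GenotypeCall(_state_for_alt(a, b, alt_index), depth)
            try:
                variants.append(
                    Variant(chrom, pos, rec.REF.upper(), (alt.upper(),), calls,
                            site_depth=site_depth)
                )
            except ValueError as exc:
                raise VcfParseError(f"record {recno} ({chrom}:{pos}): {exc}") from exc
    vcf.close()
    return variants


def write_pedigree_vcf(
    variants: Sequence[Variant],
    pedigree: PedigreeSpec,
    path: str | Path,
    info_for: Callable[[Variant], str | None] | None = None,
) -> None:
    """Write a VCF 4.2 with GT and DP for the genotyped pedigree samples.

    Input must already be sorted by (chrom, pos) — unsorted input is an error,
    never silently re-sorted.  ``info_for``, when given, supplies an extra
    per-variant INFO string (used for the ``MSQ`` annotation field).
    """
    chrom_order: list[str] = []
    cur: str | None = None
    last_pos = 0
    for v in variants:
        if len(v.alts) != 1:
            raise ValueError(
                "writer expects split (single-alt) variants; "
                f"got {len(v.alts)} alts at {v.chrom}:{v.pos}"
            )
        if v.chrom != cur:
            if v.chrom in chrom_order:
                raise ValueError(f"unsorted variants: chromosome {v.chrom} repeats")
            chrom_order.append(v.chrom)
            cur = v.chrom
            last_pos = 0
        if v.pos < last_pos:
            raise ValueError(f"unsorted variants at {v.chrom}:{v.pos}")
        last_pos = v.pos

    samples = pedigree.genotyped_samples
    lines = ["##fileformat=VCFv4.2", "##source=mendelsieve"]
    lines += [f"##contig=<ID={c}>" for c in chrom_order]
    lines.append(
        '##INFO=<ID=DP,Number=1,Type=Integer,'
        'Description="Combined depth across samples">'
    )
    if info_for is not None:
        lines.append(
            '##INFO=<ID=MSQ,Number=1,Type=String,Description='
            '"mendelsieve annotation: gene|impact|reason|cdna|protein">'
        )
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )
    for v in variants:
        info_parts = []
        if v.site_depth is not None:
            info_parts.append(f"DP={v.site_depth}")
        if info_for is not None:
            extra = info_for(v)
            if extra:
                info_parts.append(extra)
        info = ";".join(info_parts) if info_parts else "."
        cols = [v.chrom, str(v.pos), ".", v.ref, v.alts[0], ".", "PASS", info, "GT:DP"]
        for s in samples:
            call = v.calls[s]
            d = "." if call.depth is None else str(call.depth)
            cols.append(f"{_GT_STRINGS[call.state]}:{d}")
        lines.append("\t".join(cols))
    Path(path).write_text("\n".join(lines) + "\n")


def genotype_counts(
    variant: Variant, pedigree: PedigreeSpec
) -> dict[str, dict[str, int]]:
    """Tally genotype states per pedigree role.

    Returns a mapping role -> {hom_ref, het, hom_alt, missing} counts; per
    role the counts sum to the role's cardinality.
    """
    roles: dict[str, tuple[str, ...]] = {
        "dam": (pedigree.dam_id,),
        "affected": pedigree.affected_ids,
        "unaffected": pedigree.unaffected_ids,
    }
    if pedigree.sire_id is not None and pedigree.sire_genotyped:
        roles["sire"] = (pedigree.sire_id,)
    out: dict[str, dict[str, int]] = {}
    for role, sample_ids in roles.items():
        counts = {s.value: 0 for s in GenotypeState}
        for sample in sample_ids:
            counts[variant.calls[sample].state.value] += 1
        out[role] = counts
    return out
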