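"""The recessive-candidate filter cascade with a funnel report.

Stages, in fixed narrative order (segregation sub-filters commute, but the
order is pinned so funnel reports are comparable across runs):

1. ``catalog_subtraction`` — drop every site already present in a background
   variant catalog, leaving variants private to the family.  Matching is
   site-level by (chrom, pos), mirroring ``vcftools --diff-site`` semantics;
   an allele-aware mode is available behind a flag.
2. ``quality`` — drop sites with low depth or too many missing genotypes.
3. ``affected_hom_alt`` — affected offspring must all be homozygous for the
   alternate allele.
4. ``carrier_parent_het`` — genotyped parents must be heterozygous carriers
   (the obligate-carrier expectation under autosomal recessive inheritance);
   ungenotyped parents impose no constraint.
5. ``unaffected_not_hom_alt`` — no unaffected offspring may be homozygous
   for the alternate allele.
6. ``impact_triage`` — retain only variants whose predicted coding impact
   is in the retained set (default MODERATE or HIGH).

``affected_only`` mode runs stages 1, 2, 3 and 6 only, emulating the design
where just the affected individuals were sequenced.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .effect_annotation import GeneModel, classify_impact
from .variant_model import (
    ConfigurationError,
    GenotypeState,
    PedigreeSpec,
    SiteKey,
    Variant,
)

__all__ = [
    "CatalogIndex",
    "QualityPolicy",
    "FunnelReport",
    "subtract_catalog",
    "apply_quality_filter",
    "filter_affected_hom_alt",
    "filter_carrier_parent",
    "filter_unaffected_not_hom_alt",
    "run_cascade",
    "site_depth_statistic",
    "FULL_FAMILY_STAGES",
    "AFFECTED_ONLY_STAGES",
]

STAGE_INPUT = "input"
STAGE_CATALOG = "catalog_subtraction"
STAGE_QUALITY = "quality"
STAGE_AFFECTED = "affected_hom_alt"
STAGE_CARRIER = "carrier_parent_het"
STAGE_UNAFFECTED = "unaffected_not_hom_alt"
STAGE_IMPACT = "impact_triage"

FULL_FAMILY_STAGES = (
    STAGE_CATALOG,
    STAGE_QUALITY,
    STAGE_AFFECTED,
    STAGE_CARRIER,
    STAGE_UNAFFECTED,
    STAGE_IMPACT,
)
AFFECTED_ONLY_STAGES = (STAGE_CATALOG, STAGE_QUALITY, STAGE_AFFECTED, STAGE_IMPACT)


class CatalogIndex:
    """Site (and optionally allele) membership index of a background catalog.

    Membership is deterministic and order-independent; the default test is by
    (chrom, pos) only.
    """

    def __init__(
        self,
        sites: Iterable[tuple[str, int]],
        alleles: Iterable[tuple[str, int, str, str]] | None = None,
    ) -> None:
        self._sites = frozenset((str(c), int(p)) for c, p in sites)
        self._alleles = (
            frozenset((str(c), int(p), r, a) for c, p, r, a in alleles)
            if alleles is not None
            else None
        )

    def __len__(self) -> int:
        return len(self._sites)

    def __contains__(self, key: SiteKey | tuple[str, int]) -> bool:
        if isinstance(key, SiteKey):
            return (key.chrom, key.pos) in self._sites
        return (key[0], int(key[1])) in self._sites

    def contains_site(self, chrom: str, pos: int) -> bool:
        return (chrom, pos) in self._sites

    def contains_allele(self, chrom: str, pos: int, ref: str, alt: str) -> bool:
        if self._alleles is None:
            raise ConfigurationError(
                "catalog was built without allele information; "
                "allele-aware matching unavailable"
            )
        return (chrom, pos, ref, alt) in self._alleles

    @property
    def has_alleles(self) -> bool:
        return self._alleles is not None

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CatalogIndex":
        """2-column TSV (chrom, pos), optionally gzip-compressed."""
        opener = gzip.open if str(path).endswith(".gz") else open
        sites = []
        with opener(path, "rt") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                chrom, pos = line.split("\t")[:2]
                sites.append((chrom, int(pos)))
        return cls(sites)

    @classmethod
    def from_vcf(cls, path: str | Path) -> "CatalogIndex":
        from cyvcf2 import VCF

        sites = []
        alleles = []
        vcf = VCF(str(path))
        for rec in vcf:
            sites.append((rec.CHROM, rec.POS))
            for alt in rec.ALT:
                alleles.append((rec.CHROM, rec.POS, rec.REF.upper(), alt.upper()))
        vcf.close()
        return cls(sites, alleles)

    @classmethod
    def from_path(cls, path: str | Path) -> "CatalogIndex":
        name = str(path)
        if name.endswith((".vcf", ".vcf.gz", ".bcf")):
            return cls.from_vcf(path)
        return cls.from_tsv(path)


@dataclass(frozen=True)
class QualityPolicy:
    """Depth and missingness thresholds for site-level quality filtering.

    Defaults mirror the study conditions this package emulates: sites with a
    depth statistic below 20 reads, any missing affected genotype, or more
    than two missing genotypes across the pedigree are removed.
    """

    min_depth: int = 20
    max_missing_pedigree: int = 2
    max_missing_affected: int = 0

    def __post_init__(self) -> None:
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")
        if self.max_missing_pedigree < 0 or self.max_missing_affected < 0:
            raise ValueError("missingness limits must be >= 0")


@dataclass(frozen=True)
class FunnelReport:
    """Ordered (stage, surviving count) pairs; the first entry is the input.

    Counts are validated non-increasing along the stage order on construction.
    """

    stages: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if not self.stages or self.stages[0][0] != STAGE_INPUT:
            raise ValueError("funnel must start with the input count")
        counts = [c for _, c in self.stages]
        if any(c < 0 for c in counts):
            raise ValueError("negative funnel count")
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise ValueError(f"funnel counts must be non-increasing: {counts}")

    @property
    def input_count(self) -> int:
        return self.stages[0][1]

    @property
    def final_count(self) -> int:
        return self.stages[-1][1]

    def count(self, stage: str) -> int:
        for name, c in self.stages:
            if name == stage:
                return c
        raise KeyError(stage)

    def to_tsv(self, path: str | Path) -> None:
        lines = ["stage\tcount"] + [f"{name}\t{c}" for name, c in self.stages]
        Path(path).write_text("\n".join(lines) + "\n")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {"stages": [{"stage": n, "count": c} for n, c in self.stages]}, indent=2
        )
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


def subtract_catalog(
    variants: Sequence[Variant],
    catalog: CatalogIndex,
    allele_aware: bool = False,
) -> list[Variant]:
    """Keep exactly the variants absent from the catalog, order preserved.

    Default matching is site-level by (chrom, pos); ``allele_aware=True``
    additionally requires the catalog to hold the same ref/alt pair for a
    variant to be considered known.
    """
    if allele_aware:
        return [
            v
            for v in variants
            if not catalog.contains_allele(v.chrom, v.pos, v.ref, v.alts[0])
        ]
    return [v for v in variants if not catalog.contains_site(v.chrom, v.pos)]


def site_depth_statistic(variant: Variant, pedigree: PedigreeSpec) -> float | None:
    """Site-level depth: mean per-sample DP across genotyped pedigree samples,
    falling back to the record's INFO DP when no per-sample depth is present.
    ``None`` means no depth information of any kind."""
    depths = [
        c.depth
        for s in pedigree.genotyped_samples
        if (c := variant.calls[s]).depth is not None
    ]
    if depths:
        return sum(depths) / len(depths)
    if variant.site_depth is not None:
        return float(variant.site_depth)
    return None


def _missing_counts(variant: Variant, pedigree: PedigreeSpec) -> tuple[int, int]:
    missing_affected = sum(
        variant.calls[s].state is GenotypeState.MISSING for s in pedigree.affected_ids
    )
    missing_total = sum(
        variant.calls[s].state is GenotypeState.MISSING
        for s in pedigree.genotyped_samples
    )
    return missing_affected, missing_total


def apply_quality_filter(
    variants: Sequence[Variant],
    pedigree: PedigreeSpec,
    policy: QualityPolicy,
) -> list[Variant]:
    """Remove sites failing depth (< min_depth, strict) or missingness limits.

    A site with no depth information of any kind fails whenever the policy
    requires depth (min_depth > 0): absent read counts are not invented.
    """
    out = []
    for v in variants:
        stat = site_depth_statistic(v, pedigree)
        if stat is None:
            if policy.min_depth > 0:
                continue
        elif stat < policy.min_depth:
            continue
        missing_affected, missing_total = _missing_counts(v, pedigree)
        if missing_affected > policy.max_missing_affected:
            continue
        if missing_total > policy.max_missing_pedigree:
            continue
        out.append(v)
    return out


def filter_affected_hom_alt(
    variants: Sequence[Variant], pedigree: PedigreeSpec
) -> list[Variant]:
    """Survivors are hom-alt in every affected sample."""
    return [
        v
        for v in variants
        if all(
            v.calls[s].state is GenotypeState.HOM_ALT for s in pedigree.affected_ids
        )
    ]


def filter_carrier_parent(
    variants: Sequence[Variant], pedigree: PedigreeSpec
) -> list[Variant]:
    """Survivors are het in every genotyped parent (obligate carriers).

    The dam must be genotyped for this filter; a genotyped sire, when present,
    must also be het.  A missing parental genotype is not het and fails.
    """
    parents = [pedigree.dam_id]
    if pedigree.sire_id is not None and pedigree.sire_genotyped:
        parents.append(pedigree.sire_id)
    for v in variants:
        for p in parents:
            if p not in v.calls:
                raise ConfigurationError(f"parent {p!r} has no genotype calls")
        break
    return [
        v
        for v in variants
        if all(v.calls[p].state is GenotypeState.HET for p in parents)
    ]


def filter_unaffected_not_hom_alt(
    variants: Sequence[Variant], pedigree: PedigreeSpec
) -> list[Variant]:
    """Survivors have no unaffected sample hom-alt; het and hom-ref both pass."""
    return [
        v
        for v in variants
        if not any(
            v.calls[s].state is GenotypeState.HOM_ALT for s in pedigree.unaffected_ids
        )
    ]


def _check_no_duplicates(variants: Sequence[Variant]) -> None:
    seen: set[tuple[str, int, str, str]] = set()
    for v in variants:
        key = v.allele_key
        if key in seen:
            raise ValueError(
                f"duplicate variant record {key[0]}:{key[1]} {key[2]}>{key[3]}; "
                "exact duplicates are an input error"
            )
        seen.add(key)


def run_cascade(
    variants: Sequence[Variant],
    catalog: CatalogIndex,
    pedigree: PedigreeSpec,
    policy: QualityPolicy,
    mode: str = "full_family",
    genes: Sequence[GeneModel] = (),
    retain: Sequence[str] = ("MODERATE", "HIGH"),
    allele_aware: bool = False,
) -> tuple[list[Variant], FunnelReport]:
    """Run the full filtering paradigm and return (survivors, funnel report).

    ``mode='full_family'`` applies every stage; ``mode='affected_only'``
    skips the parental-carrier and unaffected-exclusion stages, using only
    the information the affected individuals alone would provide.
    """
    if mode not in {"full_family", "affected_only"}:
        raise ValueError(f"unknown mode {mode!r}")
    _check_no_duplicates(variants)

    current = list(variants)
    stages: list[tuple[str, int]] = [(STAGE_INPUT, len(current))]

    current = subtract_catalog(current, catalog, allele_aware=allele_aware)
    stages.append((STAGE_CATALOG, len(current)))

    current = apply_quality_filter(current, pedigree, policy)
    stages.append((STAGE_QUALITY, len(current)))

    current = filter_affected_hom_alt(current, pedigree)
    stages.append((STAGE_AFFECTED, len(current)))

    if mode == "full_family":
        current = filter_carrier_parent(current, pedigree)
        stages.append((STAGE_CARRIER, len(current)))
        current = filter_unaffected_not_hom_alt(current, pedigree)
        stages.append((STAGE_UNAFFECTED, len(current)))

    retain_set = set(retain)
    current = [v for v in current if classify_impact(v, genes).category in retain_set]
    stages.append((STAGE_IMPACT, len(current)))

    return current, FunnelReport(tuple(stages))
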