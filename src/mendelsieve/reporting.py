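"""End-to-end orchestration: load inputs, run the cascade, write reports.

Outputs are deliberately timestamp-free so re-running a configuration on the
same inputs produces byte-identical files; timestamps live only in logs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict, field, replace
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .effect_annotation import (
    GeneModel,
    annotate_variant,
    load_gene_models,
    load_gene_models_gff,
)
from .filter_cascade import (
    CatalogIndex,
    FunnelReport,
    QualityPolicy,
    run_cascade,
)
from .variant_model import (
    ConfigurationError,
    PedigreeSpec,
    Variant,
    read_pedigree_vcf,
    write_pedigree_vcf,
)

__all__ = ["RunConfig", "AnalysisResult", "run_full_analysis",
           "EXIT_OK", "EXIT_NO_CANDIDATES"]

logger = logging.getLogger("mendelsieve")

EXIT_OK = 0
EXIT_NO_CANDIDATES = 3


@dataclass(frozen=True)
class RunConfig:
    """Fully serializable configuration of one cascade run.

    The effective configuration is echoed into the output directory
    (``config.yaml``) for provenance.
    """

    vcf: str
    catalog: str
    genes: str
    cds_fasta: str
    pedigree: str
    out_dir: str
    mode: str = "full_family"
    min_depth: int = 20
    max_missing_pedigree: int = 2
    max_missing_affected: int = 0
    retain: tuple[str, ...] = ("MODERATE", "HIGH")
    allele_aware: bool = False
    genes_format: str = "tsv"  # tsv | gff3
    log_level: str = "INFO"
    seed: int | None = None  # no sampling in the core cascade; kept for provenance

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "retain" in data:
            data["retain"] = tuple(data["retain"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["retain"] = list(self.retain)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @property
    def policy(self) -> QualityPolicy:
        return QualityPolicy(
            min_depth=self.min_depth,
            max_missing_pedigree=self.max_missing_pedigree,
            max_missing_affected=self.max_missing_affected,
        )


@dataclass(frozen=True)
class AnalysisResult:
    funnel: FunnelReport
    candidates: pd.DataFrame
    survivors: tuple[Variant, ...]
    status: int


def _genotype_pattern(variant: Variant, pedigree: PedigreeSpec) -> str:
    parts = [f"dam={variant.calls[pedigree.dam_id].state.value}"]
    if pedigree.sire_id is not None and pedigree.sire_genotyped:
        parts.append(f"sire={variant.calls[pedigree.sire_id].state.value}")
    parts.append(
        "affected="
        + ",".join(variant.calls[s].state.value for s in pedigree.affected_ids)
    )
    parts.append(
        "unaffected="
        + ",".join(variant.calls[s].state.value for s in pedigree.unaffected_ids)
    )
    return "|".join(parts)


def build_candidate_report(
    survivors: Sequence[Variant],
    pedigree: PedigreeSpec,
    genes: Sequence[GeneModel],
) -> pd.DataFrame:
    """One row per surviving variant: site, alleles, genotype pattern, impact,
    gene, c./p. notation, retained fraction for frameshifts, and a headline
    flag for HIGH coding candidates."""
    rows = []
    for v in survivors:
        ann = annotate_variant(v, genes)
        retained = (
            ann.consequence.retained_fraction
            if ann.consequence is not None and ann.impact.reason == "frameshift"
            else None
        )
        rows.append(
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alts[0],
                "genotype_pattern": _genotype_pattern(v, pedigree),
                "impact": ann.impact.category,
                "reason": ann.impact.reason,
                "gene": ann.gene_id or ".",
                "cdna": ann.cdna_notation or ".",
                "protein": ann.protein_notation or ".",
                "retained_fraction": retained,
                "headline": ann.impact.category == "HIGH"
                and ann.impact.reason
                in {"frameshift", "stop_gain", "start_lost", "stop_lost"},
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "ref", "alt", "genotype_pattern", "impact", "reason",
            "gene", "cdna", "protein", "retained_fraction", "headline",
        ],
    )


def run_full_analysis(config: RunConfig) -> AnalysisResult:
    """Execute read -> subtract -> quality -> segregation -> impact -> report.

    Writes funnel.tsv/funnel.json, candidates.tsv, annotated.vcf and the
    effective config.yaml into ``config.out_dir``.  Returns exit status 0
    with at least one survivor, 3 (``no candidates``) with zero — distinct
    from failure.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    pedigree = PedigreeSpec.from_tsv(config.pedigree)
    loader = load_gene_models_gff if config.genes_format == "gff3" else load_gene_models
    genes = loader(config.genes, config.cds_fasta)
    catalog = CatalogIndex.from_path(config.catalog)
    variants = read_pedigree_vcf(config.vcf, pedigree)
    logger.info("loaded %d variants, %d catalog sites, %d genes",
                len(variants), len(catalog), len(genes))

    gene_chroms = {g.chrom for g in genes}
    variant_chroms = {v.chrom for v in variants}
    if variants and gene_chroms and not (gene_chroms & variant_chroms):
        logger.warning(
            "no chromosome overlap between variants (%s) and gene models (%s)",
            sorted(variant_chroms), sorted(gene_chroms),
        )

    survivors, funnel = run_cascade(
        variants,
        catalog,
        pedigree,
        config.policy,
        mode=config.mode,
        genes=genes,
        retain=config.retain,
        allele_aware=config.allele_aware,
    )
    for stage, count in funnel.stages:
        logger.info("stage %-24s %d variants", stage, count)

    candidates = build_candidate_report(survivors, pedigree, genes)

    funnel.to_tsv(out_dir / "funnel.tsv")
    funnel.to_json(out_dir / "funnel.json")
    candidates.to_csv(out_dir / "candidates.tsv", sep="\t", index=False)
    write_pedigree_vcf(
        survivors,
        pedigree,
        out_dir / "annotated.vcf",
        info_for=lambda v: f"MSQ={annotate_variant(v, genes).msq()}",
    )
    config.to_yaml(out_dir / "config.yaml")

    status = EXIT_OK if survivors else EXIT_NO_CANDIDATES
    if status == EXIT_NO_CANDIDATES:
        logger.info("no candidates survived the cascade")
    return AnalysisResult(funnel, candidates, tuple(survivors), status)
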