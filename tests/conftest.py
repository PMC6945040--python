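"""Shared fixtures: toy gene models and small synthetic family bundles."""

from __future__ import annotations

import pytest

from mendelsieve.effect_annotation import GeneModel
from mendelsieve.synthetic_data import (
    SimConfig,
    generate_genome_and_genes,
    simulate_family,
    write_fixture_bundle,
)
from mendelsieve.variant_model import GenotypeCall, GenotypeState, PedigreeSpec, Variant


@pytest.fixture(scope="session")
def toy_gene() -> GeneModel:
    """Single-exon plus-strand gene with CDS ATG AAA GGT AAA TGA (M-K-G-K-stop)."""
    return GeneModel(
        gene_id="TOY",
        chrom="chrT",
        strand="+",
        exons=((11, 25),),
        cds_intervals=((11, 25),),
        cds_sequence="ATGAAAGGTAAATGA",
    )


@pytest.fixture(scope="session")
def pedigree() -> PedigreeSpec:
    return PedigreeSpec(
        dam_id="DAM",
        affected_ids=("AFF1", "AFF2"),
        unaffected_ids=("UNAFF1", "UNAFF2", "UNAFF3"),
        sire_id="SIRE",
        sire_genotyped=False,
    )


def make_variant(
    pedigree: PedigreeSpec,
    states: dict[str, GenotypeState],
    chrom: str = "chr1",
    pos: int = 100,
    ref: str = "A",
    alt: str = "T",
    depth: int = 30,
) -> Variant:
    calls = {
        s: GenotypeCall(states.get(s, GenotypeState.HOM_REF), depth)
        for s in pedigree.genotyped_samples
    }
    return Variant(chrom, pos, ref, (alt,), calls)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(seed=11, n_genes=8, n_background_variants=1500)


@pytest.fixture(scope="session")
def small_genome(small_config):
    return generate_genome_and_genes(small_config)


@pytest.fixture(scope="session")
def small_family(small_config, small_genome):
    genes, reference = small_genome
    return simulate_family(small_config, genes, reference)


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory, small_config):
    out = tmp_path_factory.mktemp("bundle")
    write_fixture_bundle(small_config, out)
    return out
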