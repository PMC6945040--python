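"""Fully synthetic inputs with the statistical structure the cascade assumes.

The generator emulates the study design this package re-implements: a
nuclear family (sire x dam -> affected and unaffected offspring, sire
ungenotyped by default) segregating a single recessive 1-bp coding
insertion, against a background of biallelic SNVs whose founder allele
frequencies follow a Beta distribution and which are mostly already present
in a population variant catalog.  Everything is reproducible: a fixed
draw order on substreams keyed by the seed makes identical configs produce
byte-identical fixture bundles.

Draw order (per substream):
  genome substream  — per gene: codon count, UTR lengths, exon count, exon
    size weights, intron lengths, gene gap, strand, CDS codons; then per
    chromosome: background sequence.
  family substream  — planted gene/position/base; decoy genes/positions/
    bases/genotypes; background positions, allele frequencies, founder
    alleles, transmissions, depths, missingness, catalog membership, extra
    catalog sites.

Besides the causal plant, three deterministic decoy indels exercise the
cascade: an in-frame 3-bp insertion that fails the unaffected-exclusion
stage, a frameshift insertion already present in the catalog, and a
frameshift insertion whose dam is hom-alt (fails the carrier stage but
survives affected-only filtering).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .effect_annotation import (
    GeneModel,
    format_intervals,
    frameshift_consequence,
)
from .expression_qc import CtRecord
from .filter_cascade import CatalogIndex
from .variant_model import (
    ConfigurationError,
    GenotypeCall,
    GenotypeState,
    PedigreeSpec,
    Variant,
    write_pedigree_vcf,
)

__all__ = [
    "SimConfig",
    "Reference",
    "TruthRecord",
    "FamilyData",
    "generate_genome_and_genes",
    "simulate_family",
    "write_fixture_bundle",
    "simulate_ct_table",
]

_BASES = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")
_NON_STOP_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
)
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic family dataset.

    Defaults are the conditions the analysis is exercised under: 12,000
    background SNVs of which ~99% are already cataloged (variant catalogs
    dwarf any single family's private variation), mean sequencing depth 30
    reads (Poisson per sample-site), 2% genotype missingness, founder
    alt-allele frequencies Beta(0.5, 2), two affected and three unaffected
    offspring with the sire ungenotyped.
    """

    seed: int = 17
    n_genes: int = 18
    n_background_variants: int = 12000
    catalog_membership_prob: float = 0.99
    allele_freq_beta: tuple[float, float] = (0.5, 2.0)
    mean_depth: float = 30.0
    missing_rate: float = 0.02
    n_affected: int = 2
    n_unaffected: int = 3
    sire_genotyped: bool = False
    n_chromosomes: int = 3
    n_catalog_extra_sites: int = 2000
    planted_min_depth: int = 20
    hard_mode: bool = False

    def __post_init__(self) -> None:
        for name in ("catalog_membership_prob", "missing_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        for name in ("n_genes", "n_background_variants", "n_affected",
                     "n_unaffected", "n_chromosomes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_affected < 1:
            raise ValueError("need at least one affected offspring")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")


@dataclass(frozen=True)
class Reference:
    """Synthetic reference: chromosome name -> sequence."""

    sequences: dict[str, str]

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def base(self, chrom: str, pos: int) -> str:
        return self.sequences[chrom][pos - 1]


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth about the planted causal insertion."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene_id: str
    cds_insertion_point: int
    inserted_base: str
    expected_genotypes: dict[str, str]
    expected_impact_category: str
    expected_impact_reason: str
    expected_cdna: str
    expected_protein: str
    expected_truncated_length: int | None
    expected_full_length: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthRecord":
        return cls(**json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class FamilyData:
    """Output of one family simulation.

    ``founder_genotypes`` maps (chrom, pos) -> (sire alt-allele count, dam
    alt-allele count) for every site, including the sire even when he is not
    written to the VCF — it exists so Mendelian consistency is checkable.
    """

    variants: tuple[Variant, ...]
    pedigree: PedigreeSpec
    catalog: CatalogIndex
    truth: TruthRecord
    founder_genotypes: dict[tuple[str, int], tuple[int, int]]


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream])


def _split_sizes(rng: np.random.Generator, total: int, parts: int, minimum: int) -> list[int]:
    """Random composition of `total` into `parts` sizes, each >= minimum."""
    if parts * minimum > total:
        raise ValueError("exonic span too small for requested exon count")
    free = total - parts * minimum
    weights = rng.dirichlet(np.ones(parts))
    extra = np.floor(weights * free).astype(int)
    extra[0] += free - extra.sum()
    return [minimum + int(e) for e in extra]


def generate_genome_and_genes(config: SimConfig) -> tuple[list[GeneModel], Reference]:
    """Build n_genes gene models on small synthetic chromosomes, mixed strands.

    CDS invariants hold by construction (ATG start, single terminal stop,
    length divisible by 3) and chromosome sequence is made consistent with
    each CDS, so genomic slicing reproduces the annotated coding sequence.
    """
    rng = _rng(config.seed, 101)
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    cursors = {c: 0 for c in chroms}
    gene_plans: list[dict] = []

    for i in range(config.n_genes):
        chrom = chroms[i % len(chroms)]
        n_codons = int(rng.integers(120, 481))
        cds_len = 3 * n_codons
        utr5 = int(rng.integers(20, 101))
        utr3 = int(rng.integers(20, 151))
        exonic = utr5 + cds_len + utr3
        n_exons = int(rng.integers(2, 6))
        exon_sizes = _split_sizes(rng, exonic, n_exons, 30)
        intron_sizes = [int(x) for x in rng.integers(200, 2001, n_exons - 1)]
        gap = int(rng.integers(8000, 25001))
        strand = "+" if rng.random() < 0.5 else "-"

        start = cursors[chrom] + gap
        exons = []
        pos = start
        for k, size in enumerate(exon_sizes):
            exons.append((pos, pos + size - 1))
            pos += size
            if k < n_exons - 1:
                pos += intron_sizes[k]
        cursors[chrom] = exons[-1][1]

        codons = rng.choice(len(_NON_STOP_CODONS), size=n_codons - 2)
        cds_seq = (
            "ATG"
            + "".join(_NON_STOP_CODONS[c] for c in codons)
            + _STOPS[int(rng.integers(0, 3))]
        )

        # transcript-ordered genomic positions of the exonic span
        tpos: list[int] = []
        if strand == "+":
            for s, e in exons:
                tpos.extend(range(s, e + 1))
        else:
            for s, e in reversed(exons):
                tpos.extend(range(e, s - 1, -1))
        cds_genomic = tpos[utr5 : utr5 + cds_len]

        gene_plans.append(
            dict(
                gene_id=f"GENE{i + 1:03d}",
                chrom=chrom,
                strand=strand,
                exons=tuple(exons),
                cds_genomic=cds_genomic,
                cds_seq=cds_seq,
            )
        )

    # chromosome sequences, then overwrite CDS positions for consistency
    sequences: dict[str, np.ndarray] = {}
    for chrom in chroms:
        length = cursors[chrom] + 10000
        sequences[chrom] = rng.choice(_BASES, size=length)
    for plan in gene_plans:
        arr = sequences[plan["chrom"]]
        seq = plan["cds_seq"]
        if plan["strand"] == "-":
            seq = seq.translate(_COMPLEMENT)  # complement only; order follows tpos
        idx = np.asarray(plan["cds_genomic"]) - 1
        arr[idx] = np.array(list(seq))

    genes = []
    for plan in gene_plans:
        cds_sorted = sorted(plan["cds_genomic"])
        intervals = []
        run_start = prev = cds_sorted[0]
        for p in cds_sorted[1:]:
            if p != prev + 1:
                intervals.append((run_start, prev))
                run_start = p
            prev = p
        intervals.append((run_start, prev))
        genes.append(
            GeneModel(
                gene_id=plan["gene_id"],
                chrom=plan["chrom"],
                strand=plan["strand"],
                exons=plan["exons"],
                cds_intervals=tuple(intervals),
                cds_sequence=plan["cds_seq"],
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.span[0]))
    reference = Reference({c: "".join(sequences[c]) for c in chroms})
    return genes, reference


_STATE_BY_COUNT = {
    0: GenotypeState.HOM_REF,
    1: GenotypeState.HET,
    2: GenotypeState.HOM_ALT,
}


def _pick_cds_insertion_site(
    rng: np.random.Generator, gene: GeneModel
) -> tuple[int, int]:
    """CDS insertion point p (insert between p and p+1, both past the start
    codon) whose flanks are genomically adjacent, plus the left genomic pos."""
    L = gene.cds_length
    while True:
        p = int(rng.integers(4, L - 3))
        g1 = gene.cds_to_genomic(p)
        g2 = gene.cds_to_genomic(p + 1)
        if abs(g1 - g2) == 1:
            return p, min(g1, g2)


def _insertion_variant_alleles(
    gene: GeneModel, reference: Reference, genomic_left: int, transcript_seq: str
) -> tuple[str, str]:
    ref = reference.base(gene.chrom, genomic_left)
    if gene.strand == "+":
        genomic_insert = transcript_seq
    else:
        genomic_insert = transcript_seq.translate(_COMPLEMENT)[::-1]
    return ref, ref + genomic_insert


def _sample_names(config: SimConfig) -> PedigreeSpec:
    return PedigreeSpec(
        dam_id="DAM",
        affected_ids=tuple(f"AFF{i + 1}" for i in range(config.n_affected)),
        unaffected_ids=tuple(f"UNAFF{i + 1}" for i in range(config.n_unaffected)),
        sire_id="SIRE",
        sire_genotyped=config.sire_genotyped,
    )


def _depth_draw(rng: np.random.Generator, config: SimConfig, n: int) -> list[int]:
    return [int(d) for d in rng.poisson(config.mean_depth, n)]


def _special_calls(
    rng: np.random.Generator,
    config: SimConfig,
    pedigree: PedigreeSpec,
    states: dict[str, GenotypeState],
    protected: bool,
) -> dict[str, GenotypeCall]:
    """Calls for a planted/decoy site.  Protected sites (the causal plant,
    unless hard_mode) are exempt from missingness and depth dropout so truth
    checks stay deterministic."""
    samples = pedigree.genotyped_samples
    depths = _depth_draw(rng, config, len(samples))
    miss = rng.random(len(samples))
    calls = {}
    for i, s in enumerate(samples):
        state = states[s]
        depth = depths[i]
        if protected and not config.hard_mode:
            depth = max(depth, config.planted_min_depth)
        elif miss[i] < config.missing_rate:
            state = GenotypeState.MISSING
        calls[s] = GenotypeCall(state, depth)
    return calls


def simulate_family(
    config: SimConfig, genes: Sequence[GeneModel], reference: Reference
) -> FamilyData:
    """Simulate the family genotype matrix with one planted causal insertion.

    Background SNVs: founder genotypes drawn from the allele-frequency
    distribution, offspring by random Mendelian transmission, Poisson depths,
    genotypes masked missing at ``missing_rate``.  The planted 1-bp coding
    insertion has sire and dam het, all affected hom-alt, unaffected drawn
    from het x het transmission conditioned on not hom-alt, and is always
    fully called with depth >= ``planted_min_depth`` (unless ``hard_mode``).
    """
    if not genes:
        raise ConfigurationError("zero genes: nowhere to plant the causal variant")
    rng = _rng(config.seed, 202)
    pedigree = _sample_names(config)
    samples = pedigree.genotyped_samples
    n_off = config.n_affected + config.n_unaffected

    # --- plan the causal plant -------------------------------------------
    gene_order = rng.permutation(len(genes))
    plant_gene = genes[int(gene_order[0])]
    p_ins, g_left = _pick_cds_insertion_site(rng, plant_gene)
    base = str(rng.choice(_BASES))
    ref, alt = _insertion_variant_alleles(plant_gene, reference, g_left, base)
    cons = frameshift_consequence(plant_gene, (p_ins, p_ins + 1), base, kind="ins")

    plant_states: dict[str, GenotypeState] = {pedigree.dam_id: GenotypeState.HET}
    if pedigree.sire_id:
        plant_states[pedigree.sire_id] = GenotypeState.HET
    for s in pedigree.affected_ids:
        plant_states[s] = GenotypeState.HOM_ALT
    for s in pedigree.unaffected_ids:
        # het x het transmission conditioned on not hom-alt: 1/3 hom-ref, 2/3 het
        plant_states[s] = (
            GenotypeState.HOM_REF if rng.random() < 1.0 / 3.0 else GenotypeState.HET
        )
    plant_calls = _special_calls(rng, config, pedigree, plant_states, protected=True)
    truth = TruthRecord(
        chrom=plant_gene.chrom,
        pos=g_left,
        ref=ref,
        alt=alt,
        gene_id=plant_gene.gene_id,
        cds_insertion_point=p_ins,
        inserted_base=base,
        expected_genotypes={s: plant_states[s].value for s in samples},
        expected_impact_category="HIGH",
        expected_impact_reason="frameshift",
        expected_cdna=cons.cdna_notation,
        expected_protein=cons.protein_notation,
        expected_truncated_length=cons.truncated_length,
        expected_full_length=cons.full_length,
    )

    # --- decoy indels ------------------------------------------------------
    special: list[tuple[Variant, bool]] = []  # (variant, in_catalog)
    founder_special: dict[tuple[str, int], tuple[int, int]] = {}
    plant_variant = Variant(truth.chrom, truth.pos, ref, (alt,), plant_calls)
    special.append((plant_variant, False))
    founder_special[(truth.chrom, truth.pos)] = (1, 1)

    def offspring_states(aff: GenotypeState, unaff: list[GenotypeState]) -> dict:
        states = {s: aff for s in pedigree.affected_ids}
        for s, st in zip(pedigree.unaffected_ids, unaff):
            states[s] = st
        return states

    if len(genes) >= 4:
        decoy_genes = [genes[int(i)] for i in gene_order[1:4]]

        # (a) in-frame 3-bp insertion; fails unaffected-exclusion
        g = decoy_genes[0]
        p, gl = _pick_cds_insertion_site(rng, g)
        codon = _NON_STOP_CODONS[int(rng.integers(0, len(_NON_STOP_CODONS)))]
        d_ref, d_alt = _insertion_variant_alleles(g, reference, gl, codon)
        unaff = [GenotypeState.HOM_ALT] + [
            GenotypeState.HET if i % 2 == 0 else GenotypeState.HOM_REF
            for i in range(config.n_unaffected - 1)
        ]
        states = {
            pedigree.dam_id: GenotypeState.HET,
            pedigree.sire_id: GenotypeState.HET,
            **offspring_states(GenotypeState.HOM_ALT, unaff),
        }
        calls = _special_calls(rng, config, pedigree, states, protected=False)
        special.append((Variant(g.chrom, gl, d_ref, (d_alt,), calls), False))
        founder_special[(g.chrom, gl)] = (1, 1)

        # (b) frameshift insertion already in the catalog; removed at subtraction
        g = decoy_genes[1]
        p, gl = _pick_cds_insertion_site(rng, g)
        b = str(rng.choice(_BASES))
        d_ref, d_alt = _insertion_variant_alleles(g, reference, gl, b)
        unaff = [
            GenotypeState.HOM_REF if rng.random() < 1.0 / 3.0 else GenotypeState.HET
            for _ in range(config.n_unaffected)
        ]
        states = {
            pedigree.dam_id: GenotypeState.HET,
            pedigree.sire_id: GenotypeState.HET,
            **offspring_states(GenotypeState.HOM_ALT, unaff),
        }
        calls = _special_calls(rng, config, pedigree, states, protected=False)
        special.append((Variant(g.chrom, gl, d_ref, (d_alt,), calls), True))
        founder_special[(g.chrom, gl)] = (1, 1)

        # (c) frameshift insertion, dam hom-alt; fails carrier stage but
        # passes affected-only filtering
        g = decoy_genes[2]
        p, gl = _pick_cds_insertion_site(rng, g)
        b = str(rng.choice(_BASES))
        d_ref, d_alt = _insertion_variant_alleles(g, reference, gl, b)
        # dam hom-alt always transmits the allele: unaffected must be het+
        states = {
            pedigree.dam_id: GenotypeState.HOM_ALT,
            pedigree.sire_id: GenotypeState.HET,
            **offspring_states(
                GenotypeState.HOM_ALT,
                [GenotypeState.HET] * config.n_unaffected,
            ),
        }
        calls = _special_calls(rng, config, pedigree, states, protected=False)
        special.append((Variant(g.chrom, gl, d_ref, (d_alt,), calls), False))
        founder_special[(g.chrom, gl)] = (1, 2)

    taken = {(v.chrom, v.pos) for v, _ in special}

    # --- background biallelic SNVs ----------------------------------------
    chroms = sorted(reference.sequences)
    lengths = np.array([len(reference.sequences[c]) for c in chroms], dtype=float)
    n_bg = config.n_background_variants
    per_chrom = rng.multinomial(n_bg, lengths / lengths.sum())
    bg_sites: list[tuple[str, int]] = []
    for chrom, k in zip(chroms, per_chrom):
        length = len(reference.sequences[chrom])
        positions = set()
        while len(positions) < k:
            draw = rng.integers(1, length + 1, size=k - len(positions))
            for pos in draw:
                pos = int(pos)
                if (chrom, pos) not in taken:
                    positions.add(pos)
        bg_sites.extend((chrom, pos) for pos in sorted(positions))
        taken.update((chrom, pos) for pos in positions)

    n_bg = len(bg_sites)
    a, b_par = config.allele_freq_beta
    af = rng.beta(a, b_par, n_bg)
    sire_alleles = rng.random((n_bg, 2)) < af[:, None]
    dam_alleles = rng.random((n_bg, 2)) < af[:, None]
    pick_s = rng.integers(0, 2, (n_bg, n_off))
    pick_d = rng.integers(0, 2, (n_bg, n_off))
    off_gt = (
        np.take_along_axis(sire_alleles, pick_s, axis=1).astype(int)
        + np.take_along_axis(dam_alleles, pick_d, axis=1).astype(int)
    )
    sire_gt = sire_alleles.sum(axis=1).astype(int)
    dam_gt = dam_alleles.sum(axis=1).astype(int)
    n_genotyped = len(samples)
    depths = rng.poisson(config.mean_depth, (n_bg, n_genotyped))
    missing = rng.random((n_bg, n_genotyped)) < config.missing_rate
    in_catalog = rng.random(n_bg) < config.catalog_membership_prob

    alt_choice = rng.integers(0, 3, n_bg)  # offset into the non-ref bases

    offspring_ids = pedigree.affected_ids + pedigree.unaffected_ids
    variants: list[Variant] = []
    founder_genotypes: dict[tuple[str, int], tuple[int, int]] = dict(founder_special)
    catalog_sites: list[tuple[str, int]] = []

    for i, (chrom, pos) in enumerate(bg_sites):
        ref_base = reference.base(chrom, pos)
        others = [x for x in "ACGT" if x != ref_base]
        alt_base = others[alt_choice[i]]
        counts = {pedigree.dam_id: int(dam_gt[i])}
        if config.sire_genotyped:
            counts[pedigree.sire_id] = int(sire_gt[i])
        for j, s in enumerate(offspring_ids):
            counts[s] = int(off_gt[i, j])
        calls = {}
        for j, s in enumerate(samples):
            state = _STATE_BY_COUNT[counts[s]]
            if missing[i, j]:
                state = GenotypeState.MISSING
            calls[s] = GenotypeCall(state, int(depths[i, j]))
        variants.append(Variant(chrom, pos, ref_base, (alt_base,), calls))
        founder_genotypes[(chrom, pos)] = (int(sire_gt[i]), int(dam_gt[i]))
        if in_catalog[i]:
            catalog_sites.append((chrom, pos))

    for v, cataloged in special:
        variants.append(v)
        if cataloged:
            catalog_sites.append((v.chrom, v.pos))

    # catalog-only sites absent from the family data
    extra = 0
    while extra < config.n_catalog_extra_sites:
        ci = int(rng.integers(0, len(chroms)))
        chrom = chroms[ci]
        pos = int(rng.integers(1, len(reference.sequences[chrom]) + 1))
        if (chrom, pos) in taken:
            continue
        catalog_sites.append((chrom, pos))
        taken.add((chrom, pos))
        extra += 1

    variants.sort(key=lambda v: v.sort_key)
    return FamilyData(
        variants=tuple(variants),
        pedigree=pedigree,
        catalog=CatalogIndex(catalog_sites),
        truth=truth,
        founder_genotypes=founder_genotypes,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_fixture_bundle(config: SimConfig, out_dir: str | Path) -> dict[str, str]:
    """Generate and write the full fixture bundle; returns {filename: sha256}.

    Files: pedigree.vcf, catalog.tsv, genes.tsv, cds.fasta, pedigree.tsv,
    truth.json, manifest.json.  Regeneration with the same config reproduces
    every checksum.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genes, reference = generate_genome_and_genes(config)
    fam = simulate_family(config, genes, reference)

    write_pedigree_vcf(list(fam.variants), fam.pedigree, out / "pedigree.vcf")

    sites = sorted(
        {(c, p) for c, p in _catalog_sites(fam.catalog)}
    )
    with open(out / "catalog.tsv", "w") as fh:
        fh.write("".join(f"{c}\t{p}\n" for c, p in sites))

    with open(out / "genes.tsv", "w") as fh:
        fh.write("gene_id\tchrom\tstrand\texons\tcds_intervals\tcds_fasta_id\n")
        for g in genes:
            fh.write(
                f"{g.gene_id}\t{g.chrom}\t{g.strand}\t"
                f"{format_intervals(g.exons)}\t{format_intervals(g.cds_intervals)}\t"
                f"{g.gene_id}\n"
            )
    records = [
        SeqRecord(Seq(g.cds_sequence), id=g.gene_id, description="") for g in genes
    ]
    SeqIO.write(records, str(out / "cds.fasta"), "fasta")

    fam.pedigree.to_tsv(out / "pedigree.tsv")
    fam.truth.to_json(out / "truth.json")

    names = ["pedigree.vcf", "catalog.tsv", "genes.tsv", "cds.fasta",
             "pedigree.tsv", "truth.json"]
    manifest = {name: _sha256(out / name) for name in names}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _catalog_sites(catalog: CatalogIndex) -> set[tuple[str, int]]:
    return set(catalog._sites)  # noqa: SLF001 — bundled writer, same package


def simulate_ct_table(
    seed: int,
    n_coated: int = 5,
    n_hairless: int = 2,
    target: str = "SGK3",
    housekeeping: Sequence[str] = ("GAPDH", "HPTR1", "RPS19"),
    n_replicates: int = 2,
    delta_means: dict[str, float] | None = None,
    noise_sd: float = 0.25,
) -> tuple[list[CtRecord], dict[str, float]]:
    """Synthetic qPCR Ct table with known per-phenotype ΔCt group means.

    Each sample gets a random baseline Ct offset (cancelled by ΔCt), each
    assay a housekeeping level near 20 cycles, and the target assay sits
    ``delta_means[phenotype]`` cycles above the mean housekeeping level
    (defaults emulate near-identical expression between groups).  Returns
    the records plus the generating means for truth checks.
    """
    rng = _rng(seed, 303)
    if delta_means is None:
        delta_means = {"coated": 5.0, "hairless": 5.2}
    records: list[CtRecord] = []
    samples = [("coated", f"C{i + 1}") for i in range(n_coated)] + [
        ("hairless", f"H{i + 1}") for i in range(n_hairless)
    ]
    for phenotype, sample in samples:
        offset = float(rng.normal(0.0, 1.0))  # per-sample loading/input shift
        hk_levels = {h: 20.0 + float(rng.normal(0.0, 0.5)) for h in housekeeping}
        target_level = (
            sum(hk_levels.values()) / len(hk_levels) + delta_means[phenotype]
        )
        for assay, level in [*hk_levels.items(), (target, target_level)]:
            for rep in range(1, n_replicates + 1):
                ct = level + offset + float(rng.normal(0.0, noise_sd))
                records.append(CtRecord(sample, phenotype, assay, ct, rep))
    return records, dict(delta_means)
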