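# Methods

## The inheritance model and the cascade

The package assumes a fully penetrant autosomal-recessive trait segregating
in a nuclear family on diploid autosomes. Under that model the causal
variant must be homozygous for the alternate allele in every affected
offspring, heterozygous in each (unaffected) parent, and not homozygous-alt
in any unaffected offspring. Because the trait is rare, the causal allele is
also expected to be absent from population-scale variant catalogs, which
motivates subtracting cataloged sites first.

Stages run in a fixed order — catalog subtraction, quality, affected
hom-alt, carrier-parent het, unaffected not-hom-alt, impact triage — even
though the three segregation filters commute (a property the tests assert).
Fixing the order keeps funnel reports comparable across runs and mirrors
how such cascades are conventionally reported.

Catalog matching is site-level by `(chrom, pos)`, the semantics of
`vcftools --gzdiff --diff-site`; an allele-aware mode exists behind a flag
but is off by default, since site-level matching is the conservative choice
for declaring a variant "known". Exact duplicate `(chrom, pos, ref, alt)`
records are treated as an input error, never silently deduplicated.

Multiallelic records are split into one working variant per alternate
allele at read time, with genotype states computed per allele (any other
alternate allele counts as non-carrier). The recessive-segregation logic is
defined per allele, so this is the natural unit. Phased genotype separators
are accepted and treated as unphased; ploidy other than 2 is a parse error.
Partially missing diploid calls (e.g. `./1`) are treated as missing.

### Quality filtering

"Depth" at a site is the mean per-sample DP across genotyped pedigree
members, falling back to the record-level INFO DP when per-sample depth is
absent; sites with a statistic below `min_depth` (default 20 reads, strict
`<`) are removed. The mean was chosen over a per-sample minimum because it
is robust to single-sample dropout; the statistic is a policy knob, not a
hard-coded rule. A site carrying no depth information at all fails whenever
the policy requires depth — read counts are never invented, and absent DP
is recorded as absent rather than zero.

Missingness limits default to: any missing affected genotype disqualifies
(`max_missing_affected = 0` — an uncalled affected sample cannot support
the hom-alt requirement), and more than two missing genotypes among the
genotyped family disqualify (`max_missing_pedigree = 2`).

### Parents

The sire may be ungenotyped (the motivating study design sequenced the dam
and offspring only); ungenotyped parents impose no constraint. When a sire
*is* genotyped the carrier filter requires him het as well — the obligate-
carrier expectation — which extends the dam-only rule symmetrically.

### Impact triage

The coding-effect classifier is a deliberate simplification of a full
annotator, using one transcript model per gene: intergenic and intronic →
MODIFIER; exonic non-CDS → LOW (noncoding); CDS SNVs → synonymous LOW,
missense MODERATE, stop gain/stop loss/start loss HIGH; CDS indels → HIGH
frameshift when the length change is not a multiple of 3, MODERATE
in-frame otherwise. Splice sites, UTR regulation and multi-isoform
resolution are out of scope. Triage retains MODERATE∪HIGH by default and
flags HIGH coding variants as headline candidates, matching the two-tier
retention convention of such studies. Minus-strand genes are handled by
mapping variants into transcript orientation (reverse complement) before
any CDS arithmetic.

## Frameshift consequence prediction

An insertion or deletion within the CDS is applied to the coding sequence,
which is re-translated from the original ATG. Insertions are first
normalized to their most-3' equivalent placement (the HGVS repeat rule).
For frame-disrupting edits, the first residue differing from the reference
protein (P) and the first in-frame stop thereafter define
`p.(RefAA P NewAA fsTer N)` with the changed residue counting as 1 and the
stop as N; the truncated protein therefore retains `P + N − 2` residues,
and `truncation_fraction` inverts this arithmetic from the notation alone.
Degenerate cases: a shifted frame that reaches the CDS end without a stop
is reported as `fsTer?` with undefined truncated length; an edit whose
first changed residue is itself a stop is named as plain nonsense
(`p.(RefAA P Ter)`); in-frame edits never carry `fs` and are named as
ins/del/delins at the protein level. Edits disrupting the start codon are
classified start-lost and named `p.(Met1?)`.

The fsTer counting convention was fixed against the two known SGK3
hairlessness alleles: p.(Glu47GlyfsTer3) of a 490-residue protein retains
47 + 3 − 2 = 48 residues (9.8%, printed as 10%). For the American Hairless
Terrier allele p.Val96GlyfsTer50 the same arithmetic places the stop at
residue 145, whereas the describing literature reports residue 157 and a
loss of two-thirds of the protein; the package follows standard HGVS
arithmetic and exposes `premature_stop_fraction` so the reported-stop
version of the calculation (157 of 490 → 0.682 removed ≈ 2/3) can be
reproduced explicitly from its stated inputs.

## ΔCt expression comparison

ΔCt = Ct(target) − Ct(reference); higher ΔCt means lower relative
expression. Technical replicates are combined by arithmetic mean of Ct
before subtraction (standard practice; subtraction and averaging commute,
which the tests verify). Two reference modes: `per_gene` (default; one ΔCt
per housekeeping gene per sample, matching plots that show
per-housekeeping points) and `mean` (one ΔCt per sample against the mean
housekeeping Ct). No ΔΔCt/fold-change is computed and no hypothesis test is
ever run — with two samples in the hairless group only descriptive
summaries are defensible, and the summary attaches an explicit notice
whenever a phenotype group has fewer than three samples. Samples missing
target or housekeeping measurements are listed in a skipped-samples report
rather than silently dropped. Assay names are opaque labels.

## The synthetic-data generator

The generator produces the statistical structure the cascade assumes, not
realistic genomes. Defaults, chosen once as the study conditions:

| parameter | default | rationale |
|---|---|---|
| background SNVs | 12,000 | large enough that catalog subtraction and segregation filtering operate at realistic selectivity while a bundle simulates in ~1 s |
| catalog membership | 0.99 | population catalogs dwarf a single family's private variation; ~1% private mirrors the ratio seen when a family's variants are compared against a multi-million-site catalog |
| founder allele frequency | Beta(0.5, 2) | right-skewed spectrum: most background alleles rare, a few common |
| mean depth | 30 reads, Poisson per sample-site | typical modern short-read WGS coverage |
| genotype missingness | 0.02 | a few percent of calls drop out in joint-called family data |
| family | dam + 2 affected + 3 unaffected, sire ungenotyped | the motivating study design |
| genes | 18 on 3 chromosomes, 2–5 exons, 120–480 codons, mixed strands, UTRs and introns | enough coding territory to exercise every impact class while keeping the coding fraction of the genome small |

Founder genotypes are drawn per site from the allele frequency; offspring
genotypes follow random Mendelian transmission (one allele from each
parent). The planted causal 1-bp insertion sits at a CDS position whose
flanks are genomically adjacent (so the genomic and transcript edits
coincide), with sire and dam het, affected hom-alt, and unaffected drawn
from het×het transmission conditioned on not-hom-alt — the observed-family
distribution rather than arbitrary forced genotypes. The planted site is
exempt from missingness and depth dropout so truth checks are
deterministic; a `hard_mode` flag removes the exemption for robustness
testing. Three deterministic decoy indels exercise specific stages: an
in-frame 3-bp insertion failing the unaffected-exclusion stage, a
frameshift insertion already present in the catalog, and a frameshift
insertion with a hom-alt dam that survives affected-only filtering but not
the carrier stage.

All sampling runs on `numpy` substreams keyed by the seed with a fixed draw
order, so identical configurations yield byte-identical fixture bundles
(verified by checksum). What the generator does **not** emulate: linkage
disequilibrium and haplotype structure, read-level errors (no FASTQ/BAM),
indel backgrounds beyond the planted decoys, population history, and
genotyping error correlated with depth. Passing tests therefore demonstrate
the correctness of the filtering logic under the recessive model, not
robustness to every artifact of real joint-called WGS data.

`simulate_family` takes the gene models *and* the generated reference
(background SNV ref alleles are read from the chromosome sequences) and
returns a `FamilyData` bundle that keeps the catalog and the founder
genotypes attached — the latter so Mendelian consistency is checkable for
every site including the unwritten sire.

## Problem sizes and numerical choices

The acceptance script and test suite run: 20 independently seeded families
of 12,000 background variants each for planted-variant recovery; 50,000
random genotype configurations for the segregation pass rate (closed form
8/729, simulation required within 3 binomial SE); 1,000+ random
CDS/insertion pairs against a naive translate-the-edited-CDS oracle; and
exact enumeration of all 3^6 called-genotype configurations. These sizes
give comfortable statistical resolution while the full suite completes in
well under a minute of compute per heavy test.

Ties and determinism: variants are totally ordered by
`(chrom, pos, ref, alt)`; funnel counts are validated non-increasing on
construction; reports contain no timestamps, so re-running a configuration
reproduces outputs byte-for-byte.

## Known limitations

- Single inheritance model: no compound heterozygotes, dominant or X-linked
  modes.
- One transcript per gene; no splice-site or regulatory annotation.
- Site-level catalog matching can over-subtract at multiallelic sites where
  the family carries a novel allele at a cataloged position (the
  allele-aware flag addresses this at the cost of fidelity to the
  `--diff-site` convention).
- The depth statistic interpretation (mean per-sample vs per-site) is a
  judgment call; both the statistic's fallback and its threshold are
  configurable.
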