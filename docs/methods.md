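# Methods

## Model of the screen

`emscreen` analyses an EMS forward-genetic screen as a set-filtering
problem over single-nucleotide variants (SNVs). The observable unit is a
biallelic SNV keyed by `(chrom, pos, ref, alt)`; multi-allelic VCF rows are
split into one record per alternate allele at import, and indels/symbolic
alleles are dropped (and counted), because EMS induces point mutations
almost exclusively. Each record carries the site quality QUAL and, per
sample, a genotype (hom_ref / het / hom_alt / missing) with its Phred
genotype quality GQ (capped at 99). Phred semantics are the standard
`p_err = 10^(−q/10)`.

Mutant strains in one lethal complementation group are sequenced as
heterozygotes over the background chromosome, so the causative lesion is
expected to be: heterozygous, a strong coding change (nonsynonymous,
nonsense or splice-site), absent from the background strain, a G>A / C>T
transition (guanine alkylation; 70–100% of EMS mutations), at an
evolutionarily conserved base, and private to its strain within the cohort.
Each of these expectations is one filter. All filters are pure predicates
given their fixed side inputs (background variant set, cohort matrix), so
they commute: the final set is order-independent and only the intermediate
counts of the cascade report depend on the narrative order used
(class → zygosity → background → EMS → conservation → cohort → region,
after an initial quality step).

Candidates are genes with at least one qualifying variant in each of *k*
strains (*k* defaults to all mutants). With the uniqueness filter active,
supporting variants are automatically distinct across strains — the
non-complementation signature.

## Effect annotation

Gene models are single CDS chains (one transcript per gene; the first mRNA
of each GFF3 gene). Coding positions are translated on the coding strand
with the standard genetic code; a substitution creating a stop codon is
*nonsense*, preserving the amino acid *synonymous*, otherwise
*nonsynonymous*. Intronic positions within 2 bases of an internal CDS exon
junction are *splice_site* (the donor/acceptor dinucleotides); the window
is internal-only because CDS-only models have no intron beyond the
terminal exon edges. Positions inside a gene span but not in CDS are
*intronic*; outside every span, *intergenic*. A variant overlapping several
genes gets one annotation per gene and counts toward each.

Conservation is a per-base score in [0, 1] (PhastCons-like), looked up at
exactly the variant base from a fixed-step WIG or 3-column table. The
filter keeps scores strictly greater than 0.5; a missing score fails the
filter by default (configurable), keeping the candidate funnel
conservative.

## Cohort matrix and backfilling

For every variant seen anywhere in the cohort, every sample is assigned
exactly one status: `alt` (carries the allele), `ref` (positive evidence of
reference: an explicit non-carrier call at the site, a call for a different
allele at the same position, or — when per-sample coverage intervals are
supplied — adequate depth, 8× by default), else `missing`. Absence of
evidence is never evidence of reference; frequency fractions are computed
over non-missing samples only, and uniqueness counts carriers among all
*other* samples. Background subtraction is site+allele keyed and triggers
on any background carrier call regardless of quality: the background genome
is typically sequenced at lower depth, and demanding high-quality
background calls would under-subtract shared natural variation.

## The simulator

The generator emulates the measured genome statistics of a real fly screen
at desk scale. Defaults (chosen once as the study conditions):

| parameter | default | rationale |
|---|---|---|
| arms | 3L: 2 Mb, 2R: 1 Mb | desk-scale stand-ins for fly chromosome arms |
| gene_count | 220 | ~73 genes/Mb, the fly's genome-wide gene density |
| mean CDS length | 1,200 bp | ~400 codons, typical fly protein |
| exons per gene | 3–5 | typical compact fly gene structure |
| background_density | 10,000 /Mbp | within the ~8,100–11,000 /Mbp measured on the large arms |
| ems_rate | 0.6 /kb/strain | the screen's observed per-kb mutation rate |
| transition_fraction | 0.8 | inside the 70–100% literature range for EMS |
| n_mutants / n_unrelated | 3 / 8 | one complementation group + unrelated cohort |
| het fraction (background) | 0.5 | mixed het/hom natural variation |
| call quality | ~90% pass GQ≥75, QUAL≥100 | "most calls pass" at ~40× depth |

Sequences are uniform random; genes are placed without overlap, each CDS
beginning with ATG, ending with one stop and free of internal stops, so
every CDS translates cleanly. Conservation is drawn in (0.55, 0.99) inside
CDS and (0.01, 0.45) outside. Mutant strains inherit the *full* background
variant set (they are heterozygotes over the background chromosome), so
background subtraction does real work; their calls are re-drawn to emulate
independent sequencing. Induced mutations are heterozygous, Poisson in
number; a `transition_fraction` share are G>A / C>T at G/C bases, the rest
uniform over the non-EMS substitutions. Unrelated genomes get their own
background draw plus their own EMS load. One causative stop-gain site per
mutant strain is planted in the single gene on the causative arm offering
the most stop-gain opportunities; sites are distinct across strains, forced
to be EMS transitions at conserved CDS bases, excluded from every other
sample's position draws, and asserted at generation time to satisfy every
default filter. Every induced mutation is logged to a truth table whose
function class is computed by simulator-side code independent of the
annotator, so the two can cross-check each other in tests. All randomness
flows from one seed; identical configurations yield byte-identical output
directories.

### What the simulator does not emulate

No read-level errors, alignment artifacts, coverage holes, repetitive
regions, or shared systematic false positives. Real screens contain large
numbers of *recurrent* non-causative variants (residual heterozygosity,
caller artifacts, mutational hotspots) that appear across unrelated
genomes, which is why cohort-uniqueness filtering is so powerful on real
data (removing ~90% of surviving candidates); in the simulator every
induced mutation is private, so the uniqueness filter mostly certifies
rather than prunes. Passing tests therefore demonstrate the correctness of
the filtering algebra and the recoverability of the planted gene, not the
real-data magnitude of each filter step.

### Chance co-candidates at desk scale

At 0.6 induced mutations/kb, a gene with a 1.2 kb CDS receives on average
~0.7 coding hits per strain; after the class/EMS/conservation filters the
probability that a given gene qualifies in one strain is ≈ 0.3. On a 3 Mb
genome with ~150 genes on the mapped arm, the expected number of
*non-causative* genes qualifying in all three strains is ≈ 150 × 0.3³ ≈ 4
— and the pipeline indeed returns a handful of chance co-candidates
alongside the planted gene at default scale. This is a property of the
compressed genome: the per-gene hit rate is that of the real screen, but
the gene count is ~60× smaller, so the candidate intersection cannot be
driven as close to zero as on a 180 Mb genome (where the same arithmetic
gives ≈ 13,601 × 0.01³ ≈ 0.01). The planted gene is guaranteed to be
*among* the candidates — by construction it can never be filtered out —
and it is distinguishable in the output as the gene carrying a nonsense
lesion in every strain. Scaling the arms up (and the gene count with them)
restores the clean single-gene intersection at proportional runtime cost.

## Numerical and degenerate-input choices

- Thresholds are inclusive (GQ ≥ 75, QUAL ≥ 100); conservation is strictly
  `> 0.5`.
- QUAL is stored by htslib as float32; values are renormalized to 7
  significant digits at read time so write→read round-trips are exact.
- A strain with zero variants yields all-zero cascade rows, not an error;
  an unknown region arm yields an empty result with a warning.
- Missing genotypes carry no GQ/depth and never count as carriers.
- Records failing the quality filter for lack of a GQ are logged, not
  raised; unannotated records reaching a class/conservation filter raise,
  since that is a pipeline wiring bug.
- Test and example configurations use a 0.3 Mb genome (same densities and
  rates, one tenth the sequence) so the suite runs in seconds; calibration
  checks that need ≥1,000 induced mutations use the full 3 Mb defaults.

## Known limitations

One transcript per gene (no isoforms, no UTRs — UTR positions classify as
intronic/intergenic); no indel/SV/CNV support; no hemizygosity model for
sex chromosomes; no protein-impact scores beyond the class enum; the
coverage-interval backfill is optional input, not computed from BAMs
(the toolkit consumes VCFs only).
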