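# emscreen

Gene identification for EMS mutagenesis screens in *Drosophila* (or any
organism with a reference, gene models and per-sample variant calls).

## The problem

A forward genetic screen with ethyl methanesulfonate (EMS) yields mutant
strains whose phenotype-causing lesion is a random point mutation hidden
among hundreds of thousands of natural variants. When several recessive
mutants fail to complement each other, they form a complementation group:
each strain carries a *different* lesion in the *same* gene. Whole-genome
sequencing of the background strain plus the mutants turns gene mapping into
a filtering problem, and `emscreen` implements that filtering pipeline
offline:

1. **Quality** — keep calls with genotype quality GQ ≥ 75 and site quality
   QUAL ≥ 100 (both Phred-scaled; `phred_to_prob(q) = 10^(−q/10)`).
2. **Class** — keep heterozygous nonsynonymous / nonsense / splice-site
   coding SNVs (mutants are sequenced as heterozygotes over the background
   chromosome).
3. **Background subtraction** — drop every variant carried by the
   unmutagenized parental strain.
4. **EMS signature** — keep G>A / C>T transitions, the guanine-alkylation
   spectrum of EMS (70–100% of induced mutations).
5. **Conservation** — keep variants at bases with PhastCons-style
   conservation strictly > 0.5.
6. **Cohort uniqueness** — a backfilled variant × sample matrix over
   background, mutants and unrelated cohort genomes gives honest frequency
   counts ("alt" / positively-known "ref" / "missing"); keep variants seen
   in no other sample.
7. **Region** — optionally restrict to the mapped chromosome arm.

Surviving variants are collapsed to genes, and candidate genes are those
qualifying in at least *k* of the mutant strains (default: all of them).
Every filter is an independent predicate, so the final candidate set does
not depend on filter order.

A full synthetic-screen simulator (`emscreen.simulator`) generates
reference FASTA, GFF3 gene models, a fixed-step WIG conservation track,
per-sample VCFs and a truth table of every induced mutation, emulating the
measured statistics of a real fly screen: ~10,000 natural variants per Mbp,
~0.6 induced mutations per kb per strain (~80% G/C→A/T), and one planted
causative nonsense mutation per mutant strain, all in one gene.

## Worked example

```sh
emscreen simulate --seed 11 -o screen/ \
    --arms "3L:200000,2R:100000" --gene-count 24 \
    --background-density 3000 --n-unrelated 4
emscreen analyze -m screen/manifest.yaml -o results/
```

`simulate` reports the planted gene; `analyze` prints the per-strain
cascade and the candidates:

```
wrote screen for 8 samples to screen
causative gene: gene0005
```

```
mut1: input=1079, quality=972, coding_class=81, zygosity=46, background=14, ems_transition=12, conservation=11, cohort_unique=10, region=9
mut2: input=1079, quality=954, coding_class=82, zygosity=47, background=18, ems_transition=13, conservation=13, cohort_unique=13, region=8
mut3: input=1072, quality=958, coding_class=77, zygosity=43, background=16, ems_transition=11, conservation=10, cohort_unique=10, region=6
candidate genes (k=3): gene0005, gene0013
```

Reading the cascade for `mut1`: of 1,079 raw SNVs, 972 pass the quality
thresholds, 81 are coding/splice, 46 of those heterozygous, 14 are not in
the background strain, 10 are EMS-signature transitions at conserved bases
unseen in any other cohort genome, and 9 lie on the mapped arm 3L. Two
genes have qualifying variants in all three strains; `candidates.tsv`
distinguishes them immediately — the planted gene carries a nonsense
lesion in every strain (`Q2*`, `W257*`, `W520*`), while the chance
co-candidate has only missense changes:

```
gene	n_strains	strains	n_variants	variants
gene0005	3	mut1,mut2,mut3	5	mut1:3L:45196:C>T;mut1:3L:45780:C>T;...
gene0013	3	mut1,mut2,mut3	3	mut1:3L:144189:G>A;mut2:3L:145348:C>T;...
```

`results/` contains `candidates.tsv` (gene table), `cascade_report.tsv`
and a readable `.txt` rendering (gene counts per cumulative filter row ×
required-strain-count column), `metrics.tsv` (per-sample SNV counts at each
analysis tier with a mutant totals row), and per-strain `*_candidates.bed`
UCSC custom tracks of the surviving variants.

At full scale (the default 3 Mb genome, 220 genes, 0.6 EMS mutations/kb)
the same two commands take ~30 s; note that at that mutation density a
3 Mb genome also accumulates a handful of *chance* genes hit in all three
strains — see `docs/methods.md` for why this is a property of the
simulation scale, not of the filters.

## Layout

```
src/emscreen/
  variant_model.py     SNV records, VCF read/write, Phred, TSV/BED export
  effect_annotator.py  codon classification, splice windows, conservation
  filter_engine.py     the filters and the cascade
  cohort_store.py      backfilled variant x sample matrix, uniqueness
  screen_analysis.py   gene collapse, strain intersection, reports
  simulator.py         synthetic screens with truth tables
  cli.py               `emscreen simulate` / `emscreen analyze`
```
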