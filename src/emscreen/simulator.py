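"""Synthetic EMS screens: reference, gene models, conservation, strains.

The generator emulates the genome statistics of a fly EMS screen at desk
scale: a few megabases of random sequence carrying non-overlapping
protein-coding genes, natural background variation at ~10,000 variants per
Mbp, and per-strain EMS mutagenesis at ~0.6 mutations per kb of which ~80%
are G>A / C>T transitions.  Each mutant strain additionally carries one
planted causative nonsense mutation, at a distinct position per strain, all
in the same gene -- a complementation group by construction.  Every emitted
mutation is recorded in a truth table that downstream tests use as an
oracle.

All randomness flows from a single integer seed; identical configurations
produce byte-identical output directories.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .effect_annotator import (
    CODON_TO_AA,
    COMPLEMENT,
    SPLICE_WINDOW,
    GeneModel,
)
from .screen_analysis import ScreenManifest
from .variant_model import (
    GenotypeCall,
    VariantRecord,
    VariantSite,
    Zygosity,
    write_vcf,
)

logger = logging.getLogger(__name__)

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = ("TAA", "TAG", "TGA")


class SimulationConfigError(ValueError):
    """The configuration cannot produce a valid screen."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic screen.

    Defaults: a 2 Mb arm "3L" plus a 1 Mb arm "2R"; 220 genes (~73 per Mb,
    the fly's gene density) with a mean CDS of 1,200 bp in 3-5 exons;
    background variation at 10,000 variants/Mbp; EMS mutations at 0.6 per kb
    per strain, 80% of them G>A / C>T; three mutant strains and eight
    unrelated cohort genomes; the causative gene on arm 3L.
    """

    arms: tuple[tuple[str, int], ...] = (("3L", 2_000_000), ("2R", 1_000_000))
    gene_count: int = 220
    mean_cds_length: int = 1200
    background_density: float = 10_000.0   # variants per Mbp
    ems_rate: float = 0.6                  # induced mutations per kb
    transition_fraction: float = 0.8
    n_mutants: int = 3
    n_unrelated: int = 8
    causative_arm: str = "3L"
    het_fraction_background: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.arms or any(length <= 0 for _, length in self.arms):
            raise SimulationConfigError("all arm lengths must be > 0")
        if not (0.0 <= self.transition_fraction <= 1.0):
            raise SimulationConfigError(
                f"transition_fraction must be in [0, 1], got {self.transition_fraction}")
        if self.ems_rate <= 0:
            raise SimulationConfigError(f"ems_rate must be > 0, got {self.ems_rate}")
        if self.background_density < 0:
            raise SimulationConfigError("background_density must be >= 0")
        if self.n_mutants < 1:
            raise SimulationConfigError("need at least one mutant strain")
        if self.causative_arm not in {name for name, _ in self.arms}:
            raise SimulationConfigError(
                f"causative_arm {self.causative_arm!r} is not a configured arm")
        if self.gene_count < 1 or self.mean_cds_length < 90:
            raise SimulationConfigError("need >= 1 gene and mean CDS >= 90 bp")

    @property
    def genome_bp(self) -> int:
        return sum(length for _, length in self.arms)

    @property
    def genome_kb(self) -> float:
        return self.genome_bp / 1000.0

    @property
    def mutant_names(self) -> list[str]:
        return [f"mut{i + 1}" for i in range(self.n_mutants)]

    @property
    def unrelated_names(self) -> list[str]:
        return [f"unr{j + 1}" for j in range(self.n_unrelated)]


@dataclass(frozen=True)
class TruthRow:
    """One induced mutation as the simulator intended it."""

    strain: str
    chrom: str
    pos: int
    ref: str
    alt: str
    function_class: str
    is_causative: bool


@dataclass
class TruthTable:
    rows: list[TruthRow] = field(default_factory=list)

    def for_strain(self, strain: str) -> list[TruthRow]:
        return [r for r in self.rows if r.strain == strain]

    def causative_rows(self) -> list[TruthRow]:
        return [r for r in self.rows if r.is_causative]

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("strain\tchrom\tpos\tref\talt\tfunction_class\tis_causative\n")
            for r in self.rows:
                fh.write(f"{r.strain}\t{r.chrom}\t{r.pos}\t{r.ref}\t{r.alt}\t"
                         f"{r.function_class}\t{int(r.is_causative)}\n")
        return path

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TruthTable":
        df = pd.read_csv(path, sep="\t")
        return cls([TruthRow(r.strain, r.chrom, int(r.pos), r.ref, r.alt,
                             r.function_class, bool(r.is_causative))
                    for r in df.itertuples(index=False)])


@dataclass
class SimGene:
    """A generated gene plus the construction-time facts the simulator uses
    to classify its own mutations independently of the annotator."""

    model: GeneModel
    cds_seq: str                 # translation order, starts ATG, ends with a stop
    cds_positions: np.ndarray    # genomic positions in translation order
    _pos2idx: dict[int, int] | None = None

    def cds_index_of(self, pos: int) -> int | None:
        if self._pos2idx is None:
            self._pos2idx = {int(p): i for i, p in enumerate(self.cds_positions)}
        return self._pos2idx.get(pos)


@dataclass
class SimReference:
    """Generated reference sequences, gene models and conservation scores."""

    config: SimulationConfig
    sequences: dict[str, str]
    genes: list[SimGene]
    conservation: dict[str, np.ndarray]

    _gc_positions: dict[str, np.ndarray] | None = None
    _gene_spans: dict[str, tuple[np.ndarray, np.ndarray, list[SimGene]]] | None = None

    @property
    def gene_models(self) -> list[GeneModel]:
        return [g.model for g in self.genes]

    def base(self, chrom: str, pos: int) -> str:
        return self.sequences[chrom][pos - 1]

    def gc_positions(self, chrom: str) -> np.ndarray:
        """1-based positions of G or C bases on an arm (cached)."""
        if self._gc_positions is None:
            self._gc_positions = {}
        if chrom not in self._gc_positions:
            arr = np.frombuffer(self.sequences[chrom].encode("ascii"), dtype=np.uint8)
            self._gc_positions[chrom] = np.flatnonzero((arr == ord("G")) | (arr == ord("C"))) + 1
        return self._gc_positions[chrom]

    def gene_at(self, chrom: str, pos: int) -> SimGene | None:
        if self._gene_spans is None:
            self._gene_spans = {}
            for name, _ in self.config.arms:
                genes = sorted((g for g in self.genes if g.model.chrom == name),
                               key=lambda g: g.model.span[0])
                starts = np.array([g.model.span[0] for g in genes], dtype=int)
                ends = np.array([g.model.span[1] for g in genes], dtype=int)
                self._gene_spans[name] = (starts, ends, genes)
        starts, ends, genes = self._gene_spans[chrom]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos <= ends[i]:
            return genes[i]
        return None

    # -- writers ------------------------------------------------------------

    def write_fasta(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            for name, _ in self.config.arms:
                fh.write(f">{name}\n")
                seq = self.sequences[name]
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        return path

    def write_gff3(self, path: str | Path) -> Path:
        path = Path(path)
        lines = ["##gff-version 3"]
        for g in sorted(self.genes, key=lambda g: (g.model.chrom, g.model.span[0])):
            m = g.model
            start, end = m.span
            gid = m.gene_id
            lines.append(f"{m.chrom}\temscreen_sim\tgene\t{start}\t{end}\t.\t{m.strand}\t.\tID={gid}")
            lines.append(f"{m.chrom}\temscreen_sim\tmRNA\t{start}\t{end}\t.\t{m.strand}\t.\t"
                         f"ID={gid}.t1;Parent={gid}")
            exons = m.cds_exons if m.strand == "+" else tuple(reversed(m.cds_exons))
            cum = 0
            phased = []
            for s, e in exons:  # translation order for phase computation
                phased.append((s, e, (3 - cum % 3) % 3))
                cum += e - s + 1
            for s, e, phase in sorted(phased):
                lines.append(f"{m.chrom}\temscreen_sim\tCDS\t{s}\t{e}\t.\t{m.strand}\t{phase}\t"
                             f"ID={gid}.cds;Parent={gid}.t1")
        path.write_text("\n".join(lines) + "\n")
        return path

    def write_wig(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            for name, _ in self.config.arms:
                fh.write(f"fixedStep chrom={name} start=1 step=1\n")
                pd.Series(np.round(self.conservation[name], 3)).to_csv(
                    fh, index=False, header=False, float_format="%.3f")
        return path


# ---------------------------------------------------------------------------
# reference generation


_SENSE_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                 if a + b + c not in _STOPS]


def _make_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random sense codons + one stop; no internal stop codons."""
    idx = rng.integers(0, len(_SENSE_CODONS), size=n_codons - 2)
    body = "".join(_SENSE_CODONS[i] for i in idx)
    return "ATG" + body + _STOPS[rng.integers(0, 3)]


def generate_reference(config: SimulationConfig, rng: np.random.Generator | None = None) -> SimReference:
    """Generate random arm sequences, non-overlapping genes with 3-5 CDS
    exons, and a conservation track high (> 0.5) inside CDS and low outside."""
    if rng is None:
        rng = np.random.default_rng(config.seed)

    raw = {name: rng.integers(0, 4, size=length, dtype=np.uint8)
           for name, length in config.arms}

    # apportion genes to arms by length
    total = config.genome_bp
    counts = {}
    assigned = 0
    arm_names = [name for name, _ in config.arms]
    for name, length in config.arms:
        counts[name] = int(round(config.gene_count * length / total))
        assigned += counts[name]
    counts[arm_names[0]] += config.gene_count - assigned

    genes: list[SimGene] = []
    gene_no = 0
    for name, length in config.arms:
        n_genes = counts[name]
        if n_genes == 0:
            continue
        plans = []
        for _ in range(n_genes):
            n_codons = max(40, int(round(rng.normal(config.mean_cds_length / 3,
                                                    config.mean_cds_length / 9))))
            n_exons = int(rng.integers(3, 6))
            cds_len = 3 * n_codons
            # split CDS into n_exons chunks of >= 9 bp
            cuts = np.sort(rng.choice(np.arange(9, cds_len - 8), size=n_exons - 1,
                                      replace=False)) if n_exons > 1 else np.array([], dtype=int)
            chunk_lens = np.diff(np.concatenate(([0], cuts, [cds_len])))
            introns = rng.integers(60, 401, size=n_exons - 1)
            strand = "+" if rng.random() < 0.5 else "-"
            span = cds_len + int(introns.sum())
            plans.append((n_codons, chunk_lens, introns, strand, span))
        span_total = sum(p[4] for p in plans)
        free = length - span_total - 2 * (n_genes + 1)
        if free < 0:
            raise SimulationConfigError(
                f"arm {name}: cannot place {n_genes} genes without overlap; "
                "use fewer or shorter genes")
        gaps = rng.random(n_genes + 1)
        gaps = np.floor(gaps / gaps.sum() * free).astype(int) + 2
        cursor = 0
        for (n_codons, chunk_lens, introns, strand, span), gap in zip(plans, gaps):
            cursor += int(gap)
            start0 = cursor  # 0-based span start
            cds = _make_cds(rng, n_codons)
            # genic sequence in transcription order: exon chunks with introns between
            parts = []
            off = 0
            exon_offsets = []
            for i, cl in enumerate(chunk_lens):
                exon_offsets.append((len("".join(parts)), int(cl)))
                parts.append(cds[off : off + cl])
                off += cl
                if i < len(introns):
                    ilen = int(introns[i])
                    ibytes = rng.integers(0, 4, size=ilen, dtype=np.uint8)
                    parts.append(_BASE_BYTES[ibytes].tobytes().decode("ascii"))
            gseq = "".join(parts)
            assert len(gseq) == span
            if strand == "-":
                inserted = "".join(COMPLEMENT[b] for b in reversed(gseq))
            else:
                inserted = gseq
            arr = np.frombuffer(inserted.encode("ascii"), dtype=np.uint8)
            base_codes = np.zeros(256, dtype=np.uint8)
            for i, b in enumerate(b"ACGT"):
                base_codes[b] = i
            raw[name][start0 : start0 + span] = base_codes[arr]

            exon_intervals = []
            for o, ln in exon_offsets:
                if strand == "+":
                    s = start0 + o + 1
                else:
                    s = start0 + span - o - ln + 1
                exon_intervals.append((s, s + ln - 1))
            exon_intervals.sort()
            gene_no += 1
            model = GeneModel(f"gene{gene_no:04d}", name, strand, tuple(exon_intervals))
            cds_positions = model.cds_positions()
            genes.append(SimGene(model, cds, cds_positions))
            cursor += span

    sequences = {name: _BASE_BYTES[arr].tobytes().decode("ascii") for name, arr in raw.items()}

    conservation = {}
    for name, length in config.arms:
        scores = rng.uniform(0.01, 0.45, size=length)
        conservation[name] = scores
    for g in genes:
        arr = conservation[g.model.chrom]
        idx = g.cds_positions - 1
        arr[idx] = rng.uniform(0.55, 0.99, size=len(idx))

    ref = SimReference(config, sequences, genes, conservation)
    for g in genes:  # construction invariant: reference spells every CDS
        spelled = "".join(ref.base(g.model.chrom, int(p)) for p in g.cds_positions[:3])
        coding = spelled if g.model.strand == "+" else "".join(
            COMPLEMENT[b] for b in spelled)
        assert coding == "ATG", f"{g.model.gene_id}: CDS start {coding!r}"
    return ref


# ---------------------------------------------------------------------------
# variant generation


def _draw_quality(rng: np.random.Generator, n: int):
    """GQ/QUAL/depth draws such that ~90% of calls pass GQ>=75, QUAL>=100."""
    good = rng.random(n) < 0.9
    gq = np.where(good, rng.integers(75, 100, size=n), rng.integers(5, 75, size=n))
    qual = np.round(np.where(good, rng.uniform(100, 1500, size=n),
                             rng.uniform(10, 100, size=n)), 1)
    depth = rng.poisson(40, size=n) + 1
    return gq, qual, depth


def _sample_positions(
    rng: np.random.Generator,
    pool: np.ndarray,
    n: int,
    taken: set[tuple[str, int]],
    chrom: str,
) -> list[int]:
    """Sample n distinct positions from pool avoiding (chrom, pos) in taken."""
    if n == 0:
        return []
    if n > len(pool):
        raise SimulationConfigError(f"cannot place {n} variants on arm {chrom}")
    chosen: list[int] = []
    need = n
    while need > 0:
        draw = rng.choice(pool, size=min(len(pool), int(need * 1.2) + 8), replace=False)
        for p in draw:
            p = int(p)
            if (chrom, p) not in taken:
                taken.add((chrom, p))
                chosen.append(p)
                if len(chosen) == n:
                    break
        need = n - len(chosen)
    return chosen


def _records_from_arrays(sample, chroms, positions, refs, alts, zygs, gqs, quals, depths):
    records = []
    for chrom, pos, ref, alt, z, gq, qual, dp in zip(
            chroms, positions, refs, alts, zygs, gqs, quals, depths):
        call = GenotypeCall(sample, z, gq=int(gq), depth=int(dp))
        records.append(VariantRecord(VariantSite(chrom, int(pos), ref, alt),
                                     float(qual), {sample: call}))
    return records


def generate_background(
    config: SimulationConfig,
    reference: SimReference,
    rng: np.random.Generator | None = None,
    sample_name: str = "background",
    exclude: frozenset[tuple[str, int]] | set | None = None,
) -> list[VariantRecord]:
    """Natural variation for one unmutagenized genome: Poisson(density x Mbp)
    SNVs per arm at uniform positions, random alternate alleles, a het/hom
    genotype mixture, and qualities such that most calls pass the default
    thresholds.  Positions in ``exclude`` are never used."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    taken: set[tuple[str, int]] = set(exclude or ())
    records: list[VariantRecord] = []
    for name, length in config.arms:
        n = int(rng.poisson(config.background_density * length / 1e6))
        pool = np.arange(1, length + 1)
        positions = sorted(_sample_positions(rng, pool, n, taken, name))
        seq = reference.sequences[name]
        refs = [seq[p - 1] for p in positions]
        alt_choice = rng.integers(0, 3, size=n)
        alts = []
        for r, c in zip(refs, alt_choice):
            others = [b for b in "ACGT" if b != r]
            alts.append(others[c])
        zygs = [Zygosity.HET if h else Zygosity.HOM_ALT
                for h in rng.random(n) < config.het_fraction_background]
        gq, qual, depth = _draw_quality(rng, n)
        records.extend(_records_from_arrays(sample_name, [name] * n, positions,
                                            refs, alts, zygs, gq, qual, depth))
    records.sort(key=lambda r: (r.site.chrom, r.site.pos))
    return records


@dataclass(frozen=True)
class CausativePlan:
    """The planted lesion set: one stop-gain site per mutant strain, all in
    one gene on the causative arm."""

    gene_id: str
    sites: tuple[tuple[str, int, str, str], ...]  # (chrom, pos, ref, alt) per strain


def _stop_gain_candidates(gene: SimGene) -> list[tuple[int, str, str]]:
    """(genomic pos, genomic ref, genomic alt) for every single G>A / C>T
    coding-strand substitution that turns a sense codon into a stop.  The
    complement of an EMS transition is itself an EMS transition, so the
    genomic change is guaranteed to be G>A or C>T."""
    out = []
    cds = gene.cds_seq
    strand = gene.model.strand
    for i in range(0, len(cds) - 3, 3):  # skip the terminal stop codon
        codon = cds[i : i + 3]
        if codon in _STOPS:
            continue
        for j, base in enumerate(codon):
            for ref_c, alt_c in (("C", "T"), ("G", "A")):
                if base != ref_c:
                    continue
                new = codon[:j] + alt_c + codon[j + 1 :]
                if new in _STOPS:
                    pos = int(gene.cds_positions[i + j])
                    if strand == "+":
                        out.append((pos, ref_c, alt_c))
                    else:
                        out.append((pos, COMPLEMENT[ref_c], COMPLEMENT[alt_c]))
    out.sort()
    return out


def plan_causative_sites(config: SimulationConfig, reference: SimReference) -> CausativePlan:
    """Pick the causative gene (the gene on the causative arm with the most
    stop-gain opportunities) and one distinct stop-gain site per strain,
    spread across the gene."""
    arm_genes = [g for g in reference.genes if g.model.chrom == config.causative_arm]
    if not arm_genes:
        raise SimulationConfigError(f"no genes on causative arm {config.causative_arm}")
    best, best_sites = None, []
    for g in arm_genes:
        sites = _stop_gain_candidates(g)
        if len(sites) > len(best_sites):
            best, best_sites = g, sites
    if best is None or len(best_sites) < config.n_mutants:
        raise SimulationConfigError(
            "no gene offers enough distinct stop-gain sites; regenerate with "
            "longer genes or fewer mutants")
    picks = np.linspace(0, len(best_sites) - 1, config.n_mutants).astype(int)
    chrom = best.model.chrom
    sites = tuple((chrom, best_sites[i][0], best_sites[i][1], best_sites[i][2])
                  for i in picks)
    return CausativePlan(best.model.gene_id, sites)


def _classify_sim(reference: SimReference, chrom: str, pos: int, alt: str) -> str:
    """The simulator's own classification of an induced mutation, computed
    from its construction-time gene records (independent of the annotator)."""
    gene = reference.gene_at(chrom, pos)
    if gene is None:
        return "intergenic"
    idx = gene.cds_index_of(pos)
    if idx is None:
        near_edge = any(
            s - SPLICE_WINDOW <= pos < s or e < pos <= e + SPLICE_WINDOW
            for s, e in gene.model.cds_exons
        )
        span_start, span_end = gene.model.span
        if near_edge and span_start < pos < span_end:
            return "splice_site"
        return "intronic"
    coding_alt = alt if gene.model.strand == "+" else COMPLEMENT[alt]
    ci, within = divmod(idx, 3)
    codon = gene.cds_seq[ci * 3 : ci * 3 + 3]
    new = codon[:within] + coding_alt + codon[within + 1 :]
    aa_ref, aa_alt = CODON_TO_AA[codon], CODON_TO_AA[new]
    if aa_alt == "*" and aa_ref != "*":
        return "nonsense"
    if aa_alt == aa_ref:
        return "synonymous"
    return "nonsynonymous"


def mutagenize(
    config: SimulationConfig,
    reference: SimReference,
    background_records: Sequence[VariantRecord],
    strain_index: int,
    rng: np.random.Generator | None = None,
    causative: tuple[str, int, str, str] | None = None,
    exclude: Iterable[tuple[str, int]] = (),
    sample_name: str | None = None,
) -> tuple[list[VariantRecord], list[TruthRow]]:
    """One mutagenized strain: the full background variant set (the strain is
    heterozygous over the background chromosome) plus Poisson(rate x kb) new
    heterozygous EMS mutations, plus the planted causative nonsense lesion
    when ``causative`` is given.

    Each induced mutation is a G>A / C>T transition with probability
    ``transition_fraction`` (placed at a G/C base); otherwise a uniformly
    chosen non-transition substitution at a random base.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1000 + strain_index)
    if sample_name is None:
        sample_name = f"mut{strain_index + 1}"

    taken: set[tuple[str, int]] = {(r.site.chrom, r.site.pos) for r in background_records}
    taken.update(exclude)

    # background chromosome carried over; calls re-drawn (independent sequencing)
    n_bg = len(background_records)
    gq, qual, depth = _draw_quality(rng, n_bg)
    records: list[VariantRecord] = []
    for r, g, q, d in zip(background_records, gq, qual, depth):
        call = GenotypeCall(sample_name, r.call_for().zygosity, gq=int(g), depth=int(d))
        records.append(VariantRecord(r.site, float(q), {sample_name: call}))

    n_induced = int(rng.poisson(config.ems_rate * config.genome_kb))
    n_trans = int(rng.binomial(n_induced, config.transition_fraction)) if n_induced else 0
    arm_names = [name for name, _ in config.arms]

    truth: list[TruthRow] = []
    induced: list[tuple[str, int, str, str]] = []

    # transitions: G>A or C>T at G/C sites, apportioned to arms by G/C content
    gc_pools = {name: reference.gc_positions(name) for name in arm_names}
    weights = np.array([len(gc_pools[name]) for name in arm_names], dtype=float)
    alloc = rng.multinomial(n_trans, weights / weights.sum())
    for name, n_arm in zip(arm_names, alloc):
        for p in _sample_positions(rng, gc_pools[name], int(n_arm), taken, name):
            ref = reference.base(name, p)
            alt = "A" if ref == "G" else "T"
            induced.append((name, p, ref, alt))

    # non-transitions: any base, any substitution that is not G>A / C>T
    n_other = n_induced - n_trans
    lengths = np.array([length for _, length in config.arms], dtype=float)
    alloc = rng.multinomial(n_other, lengths / lengths.sum())
    non_ems = {"G": ("C", "T"), "C": ("A", "G"),
               "A": ("C", "G", "T"), "T": ("A", "C", "G")}
    for name, n_arm in zip(arm_names, alloc):
        pool = np.arange(1, dict(config.arms)[name] + 1)
        for p in _sample_positions(rng, pool, int(n_arm), taken, name):
            ref = reference.base(name, p)
            choices = non_ems[ref]
            alt = choices[int(rng.integers(0, len(choices)))]
            induced.append((name, p, ref, alt))

    induced.sort()
    gq, qual, depth = _draw_quality(rng, len(induced))
    for (name, p, ref, alt), g, q, d in zip(induced, gq, qual, depth):
        call = GenotypeCall(sample_name, Zygosity.HET, gq=int(g), depth=int(d))
        records.append(VariantRecord(VariantSite(name, p, ref, alt), float(q),
                                     {sample_name: call}))
        truth.append(TruthRow(sample_name, name, p, ref, alt,
                              _classify_sim(reference, name, p, alt), False))

    if causative is not None:
        chrom, pos, ref, alt = causative
        assert reference.base(chrom, pos) == ref, "causative site disagrees with reference"
        assert (ref, alt) in (("G", "A"), ("C", "T")), "causative must be an EMS transition"
        assert _classify_sim(reference, chrom, pos, alt) == "nonsense"
        assert float(reference.conservation[chrom][pos - 1]) > 0.5
        assert (chrom, pos) not in {(r.site.chrom, r.site.pos) for r in background_records}
        call = GenotypeCall(sample_name, Zygosity.HET, gq=99, depth=45)
        records.append(VariantRecord(VariantSite(chrom, pos, ref, alt), 999.0,
                                     {sample_name: call}))
        truth.append(TruthRow(sample_name, chrom, pos, ref, alt, "nonsense", True))

    records.sort(key=lambda r: (r.site.chrom, r.site.pos))
    return records, truth


@dataclass
class SimulatedScreen:
    """A complete in-memory screen plus, when written, its file layout."""

    config: SimulationConfig
    reference: SimReference
    manifest: ScreenManifest
    records: dict[str, list[VariantRecord]]
    truth: TruthTable
    causative_gene: str
    outdir: Path | None = None


def simulate_screen(config: SimulationConfig) -> SimulatedScreen:
    """Generate a full screen in memory: background + mutants (sharing the
    background chromosome and each carrying one planted causative lesion) +
    independent unrelated genomes with their own EMS mutations."""
    rng = np.random.default_rng(config.seed)
    reference = generate_reference(config, rng)
    plan = plan_causative_sites(config, reference)
    causative_positions = {(c, p) for c, p, _, _ in plan.sites}

    background = generate_background(config, reference, rng,
                                     sample_name="background",
                                     exclude=causative_positions)
    records: dict[str, list[VariantRecord]] = {"background": background}
    truth = TruthTable()
    for i, name in enumerate(config.mutant_names):
        recs, rows = mutagenize(config, reference, background, i, rng,
                                causative=plan.sites[i],
                                exclude=causative_positions,
                                sample_name=name)
        records[name] = recs
        truth.rows.extend(rows)
    for name in config.unrelated_names:
        own_bg = generate_background(config, reference, rng, sample_name=name,
                                     exclude=causative_positions)
        recs, rows = mutagenize(config, reference, own_bg, 0, rng,
                                causative=None, exclude=causative_positions,
                                sample_name=name)
        records[name] = recs
        truth.rows.extend(rows)

    manifest = ScreenManifest(
        background="background",
        mutants=config.mutant_names,
        unrelated=config.unrelated_names,
        region=config.causative_arm,
    )
    return SimulatedScreen(config, reference, manifest, records, truth, plan.gene_id)


def generate_screen(config: SimulationConfig, outdir: str | Path) -> SimulatedScreen:
    """Simulate a screen and write the full fixture directory: reference
    FASTA, GFF3 gene models, fixed-step WIG conservation, one VCF per sample,
    the screen manifest and the truth table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    screen = simulate_screen(config)
    screen.outdir = outdir

    ref = screen.reference
    ref.write_fasta(outdir / "reference.fa")
    ref.write_gff3(outdir / "genes.gff3")
    ref.write_wig(outdir / "conservation.wig")

    vcf_dir = outdir / "vcf"
    vcf_dir.mkdir(exist_ok=True)
    contig_lengths = dict(config.arms)
    vcf_paths: dict[str, Path] = {}
    for name in screen.manifest.samples:
        p = vcf_dir / f"{name}.vcf"
        write_vcf(screen.records[name], p, contig_lengths=contig_lengths)
        vcf_paths[name] = p

    screen.truth.to_tsv(outdir / "truth_table.tsv")
    screen.manifest.vcf_paths = vcf_paths
    screen.manifest.reference_path = outdir / "reference.fa"
    screen.manifest.genes_path = outdir / "genes.gff3"
    screen.manifest.conservation_path = outdir / "conservation.wig"
    screen.manifest.to_yaml(outdir / "manifest.yaml")
    (outdir / "seed.txt").write_text(f"{config.seed}\n")
    return screen
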