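"""Functional-effect classification and conservation lookup for SNVs.

Each variant is classified against gene models (one CDS chain per gene) by
translating the affected codon on the coding strand with the standard genetic
code: a change producing a stop codon is *nonsense*, the same amino acid
*synonymous*, a different one *nonsynonymous*.  Intronic positions within two
bases of a CDS exon junction are *splice_site* (the donor/acceptor
dinucleotides); other intronic positions are *intronic* and positions outside
every gene span are *intergenic*.

Per-base conservation scores (PhastCons-style, in [0, 1]) are attached from a
fixed-step WIG or three-column tabular track; absence of a score at a base is
a value, not an error.
"""

from __future__ import annotations

import enum
import logging
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import numpy as np
from Bio.Data import CodonTable
from intervaltree import IntervalTree
from pyfaidx import Fasta

from .variant_model import VariantRecord, VariantSite

logger = logging.getLogger(__name__)

#: donor/acceptor window: intronic bases this close to a CDS exon edge are splice sites
SPLICE_WINDOW = 2

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
for _stop in _STANDARD.stop_codons:
    CODON_TO_AA[_stop] = "*"
STOP_CODONS = frozenset(_STANDARD.stop_codons)

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


class ReferenceMismatchError(ValueError):
    """The reference base at a site does not match the record's REF allele."""


class FunctionClass(enum.Enum):
    SYNONYMOUS = "synonymous"
    NONSYNONYMOUS = "nonsynonymous"
    NONSENSE = "nonsense"
    SPLICE_SITE = "splice_site"
    INTRONIC = "intronic"
    INTERGENIC = "intergenic"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: classes with a gene and a codon context
CODING_CLASSES = frozenset({FunctionClass.SYNONYMOUS, FunctionClass.NONSYNONYMOUS, FunctionClass.NONSENSE})
#: classes counted as "gene contains a coding variant" in gene-level summaries
GENIC_CLASSES = CODING_CLASSES | {FunctionClass.SPLICE_SITE}
#: the "strong coding variant" set used by the default filter cascade
NS_SS_CLASSES = frozenset({FunctionClass.NONSYNONYMOUS, FunctionClass.NONSENSE, FunctionClass.SPLICE_SITE})


@dataclass
class EffectAnnotation:
    """Functional class of a variant in one gene (or intergenic), plus the
    conservation score at the variant base once attached."""

    gene_id: str | None
    function_class: FunctionClass
    aa_change: str | None = None
    conservation: float | None = None

    def __post_init__(self) -> None:
        if self.function_class is FunctionClass.INTERGENIC and self.gene_id is not None:
            raise ValueError("intergenic annotations carry no gene")
        if self.conservation is not None and not (0.0 <= self.conservation <= 1.0):
            raise ValueError(f"conservation must be in [0,1], got {self.conservation}")


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene as a single CDS chain.

    ``cds_exons`` are 1-based inclusive genomic intervals in ascending
    genomic order; translation order follows ``strand``.  Total CDS length
    must be a multiple of three.
    """

    gene_id: str
    chrom: str
    strand: str
    cds_exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.cds_exons:
            raise ValueError(f"{self.gene_id}: gene must have at least one CDS exon")
        prev_end = 0
        for start, end in self.cds_exons:
            if start > end or start < 1:
                raise ValueError(f"{self.gene_id}: bad exon interval ({start}, {end})")
            if start <= prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or are unsorted")
            prev_end = end
        if self.cds_length % 3 != 0:
            raise ValueError(f"{self.gene_id}: CDS length {self.cds_length} not divisible by 3")

    @property
    def cds_length(self) -> int:
        return sum(end - start + 1 for start, end in self.cds_exons)

    @property
    def span(self) -> tuple[int, int]:
        return (self.cds_exons[0][0], self.cds_exons[-1][1])

    def cds_positions(self) -> np.ndarray:
        """Genomic positions of CDS bases in translation order."""
        parts = [np.arange(s, e + 1) for s, e in self.cds_exons]
        pos = np.concatenate(parts)
        return pos[::-1] if self.strand == "-" else pos

    def cds_index_of(self, pos: int) -> int | None:
        """Translation-order index of a genomic position, or None if intronic
        / outside the CDS."""
        offset = 0
        hit = None
        for start, end in self.cds_exons:
            if start <= pos <= end:
                hit = offset + (pos - start)
                break
            offset += end - start + 1
        if hit is None:
            return None
        return self.cds_length - 1 - hit if self.strand == "-" else hit

    def is_splice_site(self, pos: int) -> bool:
        """True for intronic positions within SPLICE_WINDOW of an internal
        CDS exon junction."""
        span_start, span_end = self.span
        if not (span_start < pos < span_end) or self.cds_index_of(pos) is not None:
            return False
        for start, end in self.cds_exons:
            if start - SPLICE_WINDOW <= pos < start or end < pos <= end + SPLICE_WINDOW:
                return True
        return False


class GeneIndex:
    """Interval index over gene spans for overlap queries."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes: list[GeneModel] = list(genes)
        self._trees: dict[str, IntervalTree] = {}
        self.by_id: dict[str, GeneModel] = {}
        for g in self.genes:
            if g.gene_id in self.by_id:
                raise ValueError(f"duplicate gene id {g.gene_id}")
            self.by_id[g.gene_id] = g
            start, end = g.span
            self._trees.setdefault(g.chrom, IntervalTree()).addi(start, end + 1, g)

    def overlapping(self, chrom: str, pos: int) -> list[GeneModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.at(pos)]
        hits.sort(key=lambda g: g.gene_id)
        return hits

    def __len__(self) -> int:
        return len(self.genes)


def load_gene_models(gff3_path: str | Path) -> GeneIndex:
    """Load gene models from a GFF3 file (gene/mRNA/CDS features).

    One transcript per gene is assumed: the CDS chain of the gene's first
    mRNA (or the CDS features directly attached to the gene).
    """
    db = gffutils.create_db(
        str(gff3_path), dbfn=":memory:", force=True,
        merge_strategy="create_unique", keep_order=True,
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        mrnas = list(db.children(gene, featuretype="mRNA", order_by="start"))
        parent = mrnas[0] if mrnas else gene
        cds = [(f.start, f.end) for f in db.children(parent, featuretype="CDS", order_by="start")]
        if not cds:
            logger.warning("gene %s has no CDS features; skipped", gene.id)
            continue
        genes.append(GeneModel(gene.id, gene.seqid, gene.strand, tuple(cds)))
    return GeneIndex(genes)


class ReferenceGenome:
    """Single-base access to a reference, from FASTA or in-memory sequences."""

    def __init__(self, sequences: dict[str, str] | None = None, fasta: Fasta | None = None):
        self._seqs = sequences
        self._fasta = fasta

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceGenome":
        return cls(fasta=Fasta(str(path), as_raw=True, sequence_always_upper=True))

    @classmethod
    def from_dict(cls, sequences: dict[str, str]) -> "ReferenceGenome":
        return cls(sequences={k: v.upper() for k, v in sequences.items()})

    def base(self, chrom: str, pos: int) -> str:
        if self._seqs is not None:
            return self._seqs[chrom][pos - 1]
        return str(self._fasta[chrom][pos - 1 : pos])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """1-based inclusive slice."""
        if self._seqs is not None:
            return self._seqs[chrom][start - 1 : end]
        return str(self._fasta[chrom][start - 1 : end])


class ConservationTrack:
    """Dense per-base conservation scores per chromosome arm (NaN = absent)."""

    def __init__(self, arrays: dict[str, np.ndarray]):
        self._arrays = {c: np.asarray(a, dtype=float) for c, a in arrays.items()}

    @classmethod
    def from_arrays(cls, arrays: dict[str, np.ndarray]) -> "ConservationTrack":
        return cls(arrays)

    @classmethod
    def from_wig(cls, path: str | Path) -> "ConservationTrack":
        """Parse a fixed-step WIG file (``fixedStep chrom=... start=... step=...``)."""
        import pandas as pd

        # one column of raw lines; declaration lines contain spaces, never tabs
        col = pd.read_csv(path, header=None, names=["v"], sep="\t",
                          dtype=str, skip_blank_lines=True)["v"]
        numeric = pd.to_numeric(col, errors="coerce").to_numpy()
        non_numeric = np.flatnonzero(np.isnan(numeric))
        header_idx = np.array(
            [i for i in non_numeric if str(col.iloc[i]).startswith("fixedStep")],
            dtype=int)
        if len(header_idx) == 0:
            raise ValueError(f"{path}: no fixedStep declaration found")
        blocks: dict[str, list[tuple[int, int, np.ndarray]]] = {}
        bounds = list(header_idx) + [len(col)]
        for b, (hi, nxt) in enumerate(zip(bounds[:-1], bounds[1:])):
            fields = dict(kv.split("=") for kv in col.iloc[hi].split()[1:])
            chrom = fields["chrom"]
            start = int(fields["start"])
            step = int(fields.get("step", 1))
            arr = numeric[hi + 1 : nxt]
            arr = arr[~np.isnan(arr)] if np.isnan(arr).any() else arr
            if len(arr):
                blocks.setdefault(chrom, []).append((start, step, arr))

        arrays: dict[str, np.ndarray] = {}
        for c, blist in blocks.items():
            size = max(s + (len(a) - 1) * st + 1 for s, st, a in blist)
            arr = np.full(size, np.nan)
            for s, st, a in blist:
                arr[s - 1 : s - 1 + len(a) * st : st] = a
            arrays[c] = arr
        return cls(arrays)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ConservationTrack":
        """Parse a headerless three-column (chrom, 1-based pos, score) table."""
        import pandas as pd

        df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "pos", "score"])
        arrays: dict[str, np.ndarray] = {}
        for c, sub in df.groupby("chrom"):
            arr = np.full(int(sub["pos"].max()), np.nan)
            arr[sub["pos"].to_numpy() - 1] = sub["score"].to_numpy()
            arrays[str(c)] = arr
        return cls(arrays)

    def get(self, chrom: str, pos: int) -> float | None:
        arr = self._arrays.get(chrom)
        if arr is None or not (1 <= pos <= len(arr)):
            return None
        v = arr[pos - 1]
        return None if np.isnan(v) else float(v)


def conservation_at(chrom: str, pos: int, track: ConservationTrack) -> float | None:
    """Score at exactly that base, or None where the track has no value."""
    return track.get(chrom, pos)


def is_ems_transition(ref: str, alt: str) -> bool:
    """True iff the substitution is the guanine-alkylation signature of EMS:
    G>A or C>T (the same event read from the two strands)."""
    ref, alt = ref.upper(), alt.upper()
    if ref not in COMPLEMENT or alt not in COMPLEMENT or ref == alt:
        raise ValueError(f"need two distinct single bases, got {ref!r}>{alt!r}")
    return (ref, alt) in (("G", "A"), ("C", "T"))


class _CdsCache:
    """Per-gene CDS sequence cache keyed by gene id."""

    def __init__(self, reference: ReferenceGenome):
        self.reference = reference
        self._seqs: dict[str, str] = {}

    def cds_seq(self, gene: GeneModel) -> str:
        seq = self._seqs.get(gene.gene_id)
        if seq is None:
            parts = [self.reference.fetch(gene.chrom, s, e) for s, e in gene.cds_exons]
            seq = "".join(parts).upper()
            if gene.strand == "-":
                seq = "".join(COMPLEMENT[b] for b in reversed(seq))
            self._seqs[gene.gene_id] = seq
        return seq


def classify_variant(
    site: VariantSite,
    models: GeneIndex,
    reference: ReferenceGenome,
    _cache: _CdsCache | None = None,
) -> list[EffectAnnotation]:
    """Classify one SNV against every overlapping gene.

    Returns one annotation per overlapping gene, or a single intergenic
    annotation when no gene span covers the position.  Raises
    :class:`ReferenceMismatchError` if the reference disagrees with REF.
    """
    ref_base = reference.base(site.chrom, site.pos).upper()
    if ref_base != site.ref:
        raise ReferenceMismatchError(
            f"reference has {ref_base} at {site.chrom}:{site.pos}, record says {site.ref}"
        )
    cache = _cache or _CdsCache(reference)
    genes = models.overlapping(site.chrom, site.pos)
    if not genes:
        return [EffectAnnotation(None, FunctionClass.INTERGENIC)]

    anns: list[EffectAnnotation] = []
    for gene in genes:
        idx = gene.cds_index_of(site.pos)
        if idx is None:
            cls = FunctionClass.SPLICE_SITE if gene.is_splice_site(site.pos) else FunctionClass.INTRONIC
            anns.append(EffectAnnotation(gene.gene_id, cls))
            continue
        cds = cache.cds_seq(gene)
        codon_i, within = divmod(idx, 3)
        codon = cds[codon_i * 3 : codon_i * 3 + 3]
        coding_alt = site.alt if gene.strand == "+" else COMPLEMENT[site.alt]
        alt_codon = codon[:within] + coding_alt + codon[within + 1 :]
        aa_ref = CODON_TO_AA.get(codon, "X")
        aa_alt = CODON_TO_AA.get(alt_codon, "X")
        if aa_alt == "*" and aa_ref != "*":
            cls = FunctionClass.NONSENSE
        elif aa_alt == aa_ref:
            cls = FunctionClass.SYNONYMOUS
        else:
            cls = FunctionClass.NONSYNONYMOUS
        anns.append(EffectAnnotation(gene.gene_id, cls, aa_change=f"{aa_ref}{codon_i + 1}{aa_alt}"))
    return anns


def annotate_all(
    records: Sequence[VariantRecord],
    models: GeneIndex,
    reference: ReferenceGenome,
    track: ConservationTrack | None = None,
) -> Sequence[VariantRecord]:
    """Attach effect annotations (and conservation scores) to every record.

    Record count and order are never changed; every record leaves with at
    least one annotation.
    """
    cache = _CdsCache(reference)
    for rec in records:
        anns = classify_variant(rec.site, models, reference, _cache=cache)
        if track is not None:
            score = track.get(rec.site.chrom, rec.site.pos)
            for a in anns:
                a.conservation = score
        rec.annotations = anns
    return records
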