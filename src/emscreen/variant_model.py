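"""Core variant types and file I/O for EMS-screen analysis.

The unit of analysis throughout the package is a biallelic single-nucleotide
variant (SNV) with per-sample genotype calls.  Multi-allelic VCF rows are
split into one record per alternate allele at read time; indels and symbolic
alleles are dropped (and counted), because EMS overwhelmingly induces point
mutations and the downstream filters are defined on single-base substitutions.

Coordinate conventions: VCF and GFF3 positions are 1-based inclusive and are
kept that way internally; BED output is 0-based half-open, converted at the
boundary.
"""

from __future__ import annotations

import enum
import logging
from collections.abc import Mapping, MutableMapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import cyvcf2
import pandas as pd

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")
_BASE_SET = frozenset(BASES)

#: maximum Phred-scaled genotype quality emitted by common callers
MAX_GQ = 99


class VcfFormatError(ValueError):
    """The file is not a usable VCF (e.g. no sample columns)."""


class VcfParseError(ValueError):
    """A header or body line could not be parsed."""


class VcfOrderError(ValueError):
    """Records handed to the writer are not coordinate sorted."""


class Zygosity(enum.Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: genotype states that carry the alternate allele
CARRIER_STATES = frozenset({Zygosity.HET, Zygosity.HOM_ALT})


@dataclass(frozen=True, order=True)
class VariantSite:
    """One biallelic SNV site; ``(chrom, pos, ref, alt)`` is the identity key
    for every cross-sample join in the package."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref not in _BASE_SET or self.alt not in _BASE_SET:
            raise ValueError(f"ref/alt must be single bases, got {self.ref!r}/{self.alt!r}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class GenotypeCall:
    """A per-sample genotype with its Phred-scaled confidence.

    ``gq`` is the genotype quality (0-99); ``depth`` the read depth, both
    optional.  A missing genotype ("./.") carries neither.
    """

    sample_id: str
    zygosity: Zygosity
    gq: int | None = None
    depth: int | None = None

    def __post_init__(self) -> None:
        if self.zygosity is Zygosity.MISSING and (self.gq is not None or self.depth is not None):
            raise ValueError("a missing genotype cannot carry GQ or depth")
        if self.gq is not None and not (0 <= self.gq <= MAX_GQ):
            raise ValueError(f"GQ must be in [0, {MAX_GQ}], got {self.gq}")
        if self.depth is not None and self.depth < 0:
            raise ValueError(f"depth must be >= 0, got {self.depth}")

    @property
    def is_carrier(self) -> bool:
        return self.zygosity in CARRIER_STATES


@dataclass
class VariantRecord:
    """An SNV site plus its site quality (QUAL), per-sample calls and any
    functional annotations attached by the annotator."""

    site: VariantSite
    qual: float
    calls: dict[str, GenotypeCall]
    annotations: list = field(default_factory=list, compare=False)
    flags: set = field(default_factory=set, compare=False)

    def __post_init__(self) -> None:
        if self.qual < 0:
            raise ValueError(f"QUAL must be >= 0, got {self.qual}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return self.site.key

    def call_for(self, sample: str | None = None) -> GenotypeCall:
        """Return the focal sample's call; with a single-sample record the
        sample name may be omitted."""
        if sample is None:
            if len(self.calls) != 1:
                raise KeyError("sample name required for multi-sample records")
            return next(iter(self.calls.values()))
        return self.calls[sample]


def phred_to_prob(q: float) -> float:
    """Convert a Phred-scaled score to an error probability, 10^(-q/10).

    A score of 10 corresponds to a 1-in-10 chance of error, 20 to 1-in-100,
    and so on (the standard Phred convention).
    """
    if q < 0:
        raise ValueError(f"Phred score must be >= 0, got {q}")
    return 10.0 ** (-q / 10.0)


# ---------------------------------------------------------------------------
# VCF reading


def read_vcf(
    path: str | Path,
    sample_role: str | None = None,
    skip_log: MutableMapping[str, int] | None = None,
) -> list[VariantRecord]:
    """Read a VCF into biallelic SNV records.

    Multi-allelic rows are split into one record per alternate allele (all
    sharing the row's QUAL); a sample carrying a different alternate allele is
    ``hom_ref`` with respect to the split allele.  Non-SNV alleles (indels,
    symbolic, spanning deletions) are dropped and counted in ``skip_log``
    under ``"non_snv"``; duplicate post-split keys under ``"duplicate"``.

    ``sample_role`` is an optional tag recorded on each record's ``flags``
    (e.g. ``role:background``) for provenance when mixing files.
    """
    path = Path(path)
    if skip_log is None:
        skip_log = {}
    skip_log.setdefault("non_snv", 0)
    skip_log.setdefault("duplicate", 0)

    try:
        vf = cyvcf2.VCF(str(path))
    except Exception as exc:
        raise VcfParseError(f"{path}: malformed VCF header: {exc}") from exc
    samples = list(vf.samples)
    if not samples:
        raise VcfFormatError(f"{path}: VCF has no sample columns")
    n_samples = len(samples)

    records: list[VariantRecord] = []
    seen: set[tuple[str, int, str, str]] = set()
    line_no = 0
    try:
        for rec in vf:
            line_no += 1
            ref = (rec.REF or "").upper()
            alts = rec.ALT or []
            parsed = None
            for i, alt in enumerate(alts):
                alt = (alt or "").upper()
                if len(ref) != 1 or len(alt) != 1 or ref not in _BASE_SET or alt not in _BASE_SET:
                    skip_log["non_snv"] += 1
                    continue
                key = (rec.CHROM, rec.POS, ref, alt)
                if key in seen:
                    skip_log["duplicate"] += 1
                    logger.warning("%s: duplicate record for %s:%d %s>%s dropped",
                                   path.name, rec.CHROM, rec.POS, ref, alt)
                    continue
                seen.add(key)
                if parsed is None:
                    gts = rec.genotypes
                    try:
                        gq_arr = rec.format("GQ")
                    except KeyError:  # tag absent from the header
                        gq_arr = None
                    try:
                        dp_arr = rec.format("DP")
                    except KeyError:
                        dp_arr = None
                    # htslib stores QUAL as float32; renormalize to the
                    # shortest 7-significant-digit value so round-trips hold
                    qual = 0.0 if rec.QUAL is None else float(f"{rec.QUAL:.7g}")
                    parsed = True
                allele = i + 1
                calls: dict[str, GenotypeCall] = {}
                for j in range(n_samples):
                    s = samples[j]
                    alleles = gts[j][:-1]  # last element is the phasing flag
                    if len(alleles) == 0 or any(a < 0 for a in alleles):
                        calls[s] = GenotypeCall(s, Zygosity.MISSING)
                        continue
                    n = sum(1 for a in alleles if a == allele)
                    zyg = (Zygosity.HOM_ALT if n >= 2
                           else Zygosity.HET if n == 1 else Zygosity.HOM_REF)
                    gq = None if gq_arr is None else int(gq_arr[j][0])
                    dp = None if dp_arr is None else int(dp_arr[j][0])
                    calls[s] = GenotypeCall(
                        s, zyg,
                        gq=None if gq is None or gq < 0 else min(gq, MAX_GQ),
                        depth=None if dp is None or dp < 0 else dp,
                    )
                vr = VariantRecord(
                    site=VariantSite(rec.CHROM, rec.POS, ref, alt),
                    qual=qual,
                    calls=calls,
                )
                if sample_role is not None:
                    vr.flags.add(f"role:{sample_role}")
                records.append(vr)
    except VcfFormatError:
        raise
    except Exception as exc:  # htslib raises assorted errors on bad bodies
        raise VcfParseError(
            f"{path}: malformed VCF body near data line {line_no + 1}: {exc}"
        ) from exc
    finally:
        vf.close()
    return records


# ---------------------------------------------------------------------------
# VCF writing


_GT_STRING = {
    Zygosity.HOM_REF: "0/0",
    Zygosity.HET: "0/1",
    Zygosity.HOM_ALT: "1/1",
    Zygosity.MISSING: "./.",
}


def _check_sorted(records: Sequence[VariantRecord]) -> None:
    prev: tuple[str, int] | None = None
    for r in records:
        cur = (r.site.chrom, r.site.pos)
        if prev is not None and cur < prev:
            raise VcfOrderError(
                f"records not coordinate sorted at {cur[0]}:{cur[1]} (after {prev[0]}:{prev[1]})"
            )
        prev = cur


def write_vcf(
    records: Sequence[VariantRecord],
    path: str | Path,
    contig_lengths: Mapping[str, int] | None = None,
) -> Path:
    """Write records to a VCF 4.2 file with GT/GQ/DP FORMAT fields.

    Records must be coordinate sorted and share one sample set;
    ``read_vcf(write_vcf(x)) == x`` for records produced by this package.
    """
    path = Path(path)
    _check_sorted(records)

    samples: list[str] = list(records[0].calls) if records else []
    contigs: list[str] = []
    for r in records:
        if r.site.chrom not in contigs:
            contigs.append(r.site.chrom)
        if list(r.calls) != samples:
            raise VcfFormatError("all records must share one ordered sample set")

    lines = ["##fileformat=VCFv4.2"]
    for c in contigs:
        if contig_lengths and c in contig_lengths:
            lines.append(f"##contig=<ID={c},length={contig_lengths[c]}>")
        else:
            lines.append(f"##contig=<ID={c}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality (Phred)">')
    lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header_cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
    if samples:
        header_cols += ["FORMAT", *samples]
    lines.append("\t".join(header_cols))

    for r in records:
        s = r.site
        fields = [s.chrom, str(s.pos), ".", s.ref, s.alt, repr(float(r.qual)), ".", "."]
        if samples:
            fields.append("GT:GQ:DP")
            for name in samples:
                call = r.calls[name]
                gq = "." if call.gq is None else str(call.gq)
                dp = "." if call.depth is None else str(call.depth)
                fields.append(f"{_GT_STRING[call.zygosity]}:{gq}:{dp}")
        lines.append("\t".join(fields))

    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# Tabular / BED export


#: fixed column order of the variant-mode tab-delimited export
TABLE_COLUMNS = [
    "chrom", "pos", "ref", "alt", "gene", "function_class", "aa_change",
    "zygosity", "gq", "qual", "conservation", "cohort_count",
]

GENE_TABLE_COLUMNS = ["gene", "n_strains", "strains", "n_variants", "variants"]


def _severity_rank(ann) -> int:
    order = ["nonsense", "splice_site", "nonsynonymous", "synonymous", "intronic", "intergenic"]
    name = getattr(ann.function_class, "value", str(ann.function_class))
    return order.index(name) if name in order else len(order)


def best_annotation(record: VariantRecord):
    """Most severe annotation on a record, or None if unannotated."""
    if not record.annotations:
        return None
    return min(record.annotations, key=_severity_rank)


def export_table(
    result: Sequence[VariantRecord] | Mapping[str, Mapping[str, Sequence[VariantRecord]]],
    path: str | Path,
    sample: str | None = None,
    cohort=None,
) -> Path:
    """Write a tab-delimited results table (Excel-friendly).

    In variant mode (``result`` is a sequence of records) one row is written
    per variant with the columns in :data:`TABLE_COLUMNS`; ``cohort``, when
    given, supplies the number of other cohort samples carrying the allele.
    In gene mode (``result`` maps gene -> strain -> supporting variants) one
    row is written per candidate gene.
    """
    path = Path(path)
    if isinstance(result, Mapping):
        rows = []
        for gene in sorted(result):
            per_strain = result[gene]
            variants = []
            n = 0
            for strain in per_strain:
                for rec in per_strain[strain]:
                    s = rec.site
                    variants.append(f"{strain}:{s.chrom}:{s.pos}:{s.ref}>{s.alt}")
                    n += 1
            rows.append({
                "gene": gene,
                "n_strains": len(per_strain),
                "strains": ",".join(per_strain),
                "n_variants": n,
                "variants": ";".join(variants),
            })
        df = pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS)
    else:
        rows = []
        for rec in result:
            ann = best_annotation(rec)
            call = rec.call_for(sample) if (sample is None or sample in rec.calls) else None
            count = ""
            if cohort is not None and sample is not None:
                try:
                    count = cohort.other_alt_count(rec.site, sample)
                except KeyError:
                    count = ""
            rows.append({
                "chrom": rec.site.chrom,
                "pos": rec.site.pos,
                "ref": rec.site.ref,
                "alt": rec.site.alt,
                "gene": "" if ann is None or ann.gene_id is None else ann.gene_id,
                "function_class": "" if ann is None else getattr(ann.function_class, "value", str(ann.function_class)),
                "aa_change": "" if ann is None or ann.aa_change is None else ann.aa_change,
                "zygosity": "" if call is None else call.zygosity.value,
                "gq": "" if call is None or call.gq is None else call.gq,
                "qual": rec.qual,
                "conservation": "" if ann is None or ann.conservation is None else ann.conservation,
                "cohort_count": count,
            })
        df = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
    return path


def export_bed_track(
    records: Sequence[VariantRecord],
    track_name: str,
    path: str | Path,
) -> Path:
    """Write variants as a UCSC-style custom track in BED format.

    A variant at 1-based position p becomes the half-open interval [p-1, p),
    so every interval has width exactly 1.
    """
    path = Path(path)
    _check_sorted(records)
    lines = [f'track name="{track_name}"']
    for r in records:
        s = r.site
        lines.append(f"{s.chrom}\t{s.pos - 1}\t{s.pos}\t{s.ref}>{s.alt}")
    path.write_text("\n".join(lines) + "\n")
    return path
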