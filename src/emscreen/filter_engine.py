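"""Step-wise variant filters and the screening cascade.

Every filter is a pure predicate over a record (given fixed side inputs such
as the background set or the cohort matrix), so each is idempotent, each
returns a subset of its input, and the *final* set after the full cascade is
independent of filter order; order only changes the intermediate counts that
the cascade report displays.

Defaults mirror a conservative EMS-screen analysis: genotype quality GQ >= 75
and site quality QUAL >= 100 (inclusive), heterozygous calls only (mutants
are sequenced as heterozygotes over the background chromosome),
nonsynonymous / nonsense / splice-site classes, G>A / C>T transitions only,
conservation strictly greater than 0.5, no other carrier in the cohort, and
subtraction of every variant carried by the background strain.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Sequence
from dataclasses import dataclass
from typing import NamedTuple

from .effect_annotator import (
    GENIC_CLASSES,
    NS_SS_CLASSES,
    FunctionClass,
    is_ems_transition,
)
from .variant_model import VariantRecord, Zygosity

logger = logging.getLogger(__name__)


class UnannotatedRecordError(ValueError):
    """A class/conservation filter was applied to unannotated records."""


@dataclass(frozen=True)
class FilterSpec:
    """Thresholds and switches for the full cascade."""

    min_gq: int = 75
    min_qual: float = 100.0
    zygosity: frozenset = frozenset({Zygosity.HET})
    classes: frozenset = NS_SS_CLASSES
    ems_only: bool = True
    min_conservation: float = 0.5
    conservation_missing_fails: bool = True
    region: str | tuple[str, int, int] | None = None
    max_cohort_count: int | None = 0
    subtract_background: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.min_gq <= 99):
            raise ValueError(f"min_gq must be in [0, 99], got {self.min_gq}")
        if self.min_qual < 0:
            raise ValueError(f"min_qual must be >= 0, got {self.min_qual}")
        if not (0.0 <= self.min_conservation <= 1.0):
            raise ValueError(f"min_conservation must be in [0, 1], got {self.min_conservation}")
        if self.max_cohort_count is not None and self.max_cohort_count < 0:
            raise ValueError("max_cohort_count must be >= 0 or None")


def _focal(record: VariantRecord, sample: str | None):
    if sample is None:
        return record.call_for()
    return record.calls.get(sample)


def filter_quality(
    records: Sequence[VariantRecord],
    min_gq: int = 75,
    min_qual: float = 100.0,
    sample: str | None = None,
) -> list[VariantRecord]:
    """Keep records with GQ >= min_gq (focal sample) and QUAL >= min_qual;
    both thresholds inclusive.  Calls lacking a GQ fail and are logged."""
    kept = []
    for r in records:
        call = _focal(r, sample)
        if call is None or call.zygosity is Zygosity.MISSING or call.gq is None:
            logger.debug("quality filter: no usable GQ at %s:%s", r.site.chrom, r.site.pos)
            continue
        if call.gq >= min_gq and r.qual >= min_qual:
            kept.append(r)
    return kept


def filter_zygosity(
    records: Sequence[VariantRecord],
    allowed: Iterable[Zygosity] = frozenset({Zygosity.HET}),
    sample: str | None = None,
) -> list[VariantRecord]:
    """Keep records whose focal genotype is in ``allowed``; missing genotypes
    are never kept."""
    allowed = frozenset(allowed) - {Zygosity.MISSING}
    kept = []
    for r in records:
        call = _focal(r, sample)
        if call is not None and call.zygosity in allowed:
            kept.append(r)
    return kept


def filter_class(
    records: Sequence[VariantRecord],
    classes: Iterable[FunctionClass] = NS_SS_CLASSES,
) -> list[VariantRecord]:
    """Keep records with at least one annotation in ``classes``."""
    classes = frozenset(classes)
    kept = []
    for r in records:
        if not r.annotations:
            raise UnannotatedRecordError(
                f"record {r.site.chrom}:{r.site.pos} has no annotations; run annotate_all first"
            )
        if any(a.function_class in classes for a in r.annotations):
            kept.append(r)
    return kept


def filter_ems(records: Sequence[VariantRecord]) -> list[VariantRecord]:
    """Keep only G>A / C>T transitions (the EMS mutational signature)."""
    return [r for r in records if is_ems_transition(r.site.ref, r.site.alt)]


def subtract_background(
    mutant_records: Sequence[VariantRecord],
    background_records: Sequence[VariantRecord],
) -> list[VariantRecord]:
    """Remove mutant variants carried by the background strain.

    Removal is keyed on (chrom, pos, ref, alt) and triggers on any carrier
    genotype in the background regardless of its quality.  A background
    record whose genotype is missing does NOT cause removal; the surviving
    mutant record is flagged ``background_missing``.
    """
    carrier_keys = set()
    missing_keys = set()
    for r in background_records:
        if any(c.is_carrier for c in r.calls.values()):
            carrier_keys.add(r.key)
        elif all(c.zygosity is Zygosity.MISSING for c in r.calls.values()):
            missing_keys.add(r.key)
    kept = []
    for r in mutant_records:
        if r.key in carrier_keys:
            continue
        if r.key in missing_keys:
            r.flags.add("background_missing")
        kept.append(r)
    return kept


def _record_conservation(r: VariantRecord) -> float | None:
    scores = [a.conservation for a in r.annotations if a.conservation is not None]
    return max(scores) if scores else None


def filter_conservation(
    records: Sequence[VariantRecord],
    min_conservation: float = 0.5,
    missing_fails: bool = True,
) -> list[VariantRecord]:
    """Keep records whose conservation score is strictly greater than
    ``min_conservation``; records with no score fail by default."""
    kept = []
    for r in records:
        if not r.annotations:
            raise UnannotatedRecordError(
                f"record {r.site.chrom}:{r.site.pos} has no annotations; run annotate_all first"
            )
        score = _record_conservation(r)
        if score is None:
            if not missing_fails:
                kept.append(r)
        elif score > min_conservation:
            kept.append(r)
    return kept


def filter_region(
    records: Sequence[VariantRecord],
    region: str | tuple[str, int, int],
) -> list[VariantRecord]:
    """Keep records on a chromosome arm, or inside a 1-based inclusive
    (arm, start, end) interval.  An arm matching no record yields an empty
    list with a warning, never an exception."""
    if isinstance(region, str):
        arm, start, end = region, None, None
    else:
        arm, start, end = region
    kept = [
        r for r in records
        if r.site.chrom == arm and (start is None or start <= r.site.pos <= end)
    ]
    if records and not kept and all(r.site.chrom != arm for r in records):
        logger.warning("region filter: no records on arm %r", arm)
    return kept


def filter_cohort_unique(
    records: Sequence[VariantRecord],
    cohort,
    sample: str,
    max_other_carriers: int = 0,
) -> list[VariantRecord]:
    """Keep records whose allele is carried by at most ``max_other_carriers``
    other samples in the cohort matrix.  Sites unknown to the matrix are kept
    (nothing else carries them)."""
    kept = []
    for r in records:
        try:
            others = cohort.other_alt_count(r.site, sample)
        except KeyError:
            others = 0
        if others <= max_other_carriers:
            kept.append(r)
    return kept


class CascadeStep(NamedTuple):
    label: str
    n_variants: int
    n_genes: int
    records: list


def count_genes(records: Sequence[VariantRecord], classes=GENIC_CLASSES) -> int:
    """Distinct genes having at least one annotation in ``classes``."""
    return len(gene_set(records, classes))


def gene_set(records: Sequence[VariantRecord], classes=GENIC_CLASSES) -> set[str]:
    genes: set[str] = set()
    for r in records:
        for a in r.annotations:
            if a.gene_id is not None and a.function_class in classes:
                genes.add(a.gene_id)
    return genes


def run_cascade(
    records: Sequence[VariantRecord],
    spec: FilterSpec,
    sample: str | None = None,
    background_records: Sequence[VariantRecord] | None = None,
    cohort=None,
) -> list[CascadeStep]:
    """Apply the full filter cascade to one strain, recording variant and
    distinct-gene counts after each step.

    Step order: quality, coding class, zygosity, background subtraction, EMS
    transition, conservation, cohort uniqueness, region.  Counts are
    non-increasing down the cascade because every step only removes records.
    """
    current = list(records)
    steps = [CascadeStep("input", len(current), count_genes(current), current)]

    def push(label: str, recs: list) -> None:
        nonlocal current
        current = recs
        steps.append(CascadeStep(label, len(recs), count_genes(recs), recs))

    push("quality", filter_quality(current, spec.min_gq, spec.min_qual, sample=sample))
    push("coding_class", filter_class(current, spec.classes))
    push("zygosity", filter_zygosity(current, spec.zygosity, sample=sample))
    if spec.subtract_background and background_records is not None:
        push("background", subtract_background(current, background_records))
    if spec.ems_only:
        push("ems_transition", filter_ems(current))
    push("conservation", filter_conservation(current, spec.min_conservation,
                                             spec.conservation_missing_fails))
    if cohort is not None and spec.max_cohort_count is not None and sample is not None:
        push("cohort_unique", filter_cohort_unique(current, cohort, sample,
                                                   spec.max_cohort_count))
    if spec.region is not None:
        push("region", filter_region(current, spec.region))
    return steps
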