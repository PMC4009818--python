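"""Cross-sample backfilled genotype matrix and frequency counts.

For every variant seen in any sample, the matrix records for *every* sample
whether it carries the alternate allele (``alt``), is positively known to be
reference (``ref``), or provides no evidence (``missing``) -- the
"backfilling" step that makes cohort frequency counts honest.  Reference
status requires positive evidence: an explicit non-carrier genotype call at
the site (including a call for a different alternate allele at the same
position), or, when per-sample coverage intervals are supplied, adequate
read depth there.  Absence of evidence is never evidence of reference.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping, Sequence
from pathlib import Path

import numpy as np
from intervaltree import IntervalTree

from .variant_model import VariantRecord, VariantSite, Zygosity

logger = logging.getLogger(__name__)

REF, ALT, MISSING = 0, 1, -1
_STATUS_NAME = {REF: "ref", ALT: "alt", MISSING: "missing"}


class DuplicateSampleError(ValueError):
    """Two samples share a name; statuses would be ambiguous."""


class CohortMatrix:
    """Complete (site x sample) status matrix with per-site alt counts."""

    def __init__(self, sites: list[VariantSite], samples: list[str], status: np.ndarray,
                 roles: Mapping[str, str] | None = None):
        if status.shape != (len(sites), len(samples)):
            raise ValueError("status matrix shape does not match sites x samples")
        self.sites = sites
        self.samples = samples
        self.roles = dict(roles or {})
        self._status = status
        self._site_index = {s.key: i for i, s in enumerate(sites)}
        self._sample_index = {s: j for j, s in enumerate(samples)}

    # -- lookups ------------------------------------------------------------

    def _row(self, site: VariantSite) -> int:
        try:
            return self._site_index[site.key]
        except KeyError:
            raise KeyError(f"site {site.chrom}:{site.pos} {site.ref}>{site.alt} not in matrix")

    def status(self, site: VariantSite, sample: str) -> str:
        return _STATUS_NAME[int(self._status[self._row(site), self._sample_index[sample]])]

    def alt_count(self, site: VariantSite) -> int:
        return int((self._status[self._row(site)] == ALT).sum())

    def alt_frequency(self, site: VariantSite) -> tuple[int, float | None]:
        """(carrier count, carrier fraction among non-missing samples);
        the fraction is None when every sample is missing at the site."""
        row = self._status[self._row(site)]
        n_alt = int((row == ALT).sum())
        n_known = int((row != MISSING).sum())
        return n_alt, (n_alt / n_known if n_known else None)

    def other_alt_count(self, site: VariantSite, sample: str) -> int:
        row = self._status[self._row(site)]
        j = self._sample_index[sample]
        return int((row == ALT).sum()) - int(row[j] == ALT)

    def is_unique_to(self, site: VariantSite, sample: str, max_other_carriers: int = 0) -> bool:
        """True iff at most ``max_other_carriers`` other samples carry the
        allele.  The queried sample must itself be a carrier."""
        row = self._status[self._row(site)]
        j = self._sample_index[sample]
        if row[j] != ALT:
            raise ValueError(f"sample {sample} does not carry the alt allele at "
                             f"{site.chrom}:{site.pos} {site.ref}>{site.alt}")
        return (int((row == ALT).sum()) - 1) <= max_other_carriers

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def total_alt_statuses(self) -> int:
        return int((self._status == ALT).sum())

    # -- persistence --------------------------------------------------------

    def to_tsv(self, path: str | Path) -> Path:
        """Persist as a sites x samples tab-delimited sidecar for inspection."""
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("chrom\tpos\tref\talt\talt_count\t" + "\t".join(self.samples) + "\n")
            for i, s in enumerate(self.sites):
                row = self._status[i]
                names = [_STATUS_NAME[int(v)] for v in row]
                fh.write(f"{s.chrom}\t{s.pos}\t{s.ref}\t{s.alt}\t{int((row == ALT).sum())}\t"
                         + "\t".join(names) + "\n")
        return path


def _coverage_trees(intervals) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in intervals:
        trees.setdefault(chrom, IntervalTree()).addi(start, end + 1)
    return trees


def build_matrix(
    per_sample_records: Mapping[str, Sequence[VariantRecord]] | Sequence[tuple[str, Sequence[VariantRecord]]],
    roles: Mapping[str, str] | None = None,
    coverage: Mapping[str, Sequence[tuple[str, int, int]]] | None = None,
) -> CohortMatrix:
    """Build the backfilled cohort matrix from per-sample record lists.

    ``coverage``, when given, maps a sample to 1-based inclusive intervals of
    confidently covered reference (already thresholded at the caller's
    minimum depth, 8x by default in the pipeline); sites inside them backfill
    as ``ref`` instead of ``missing``.
    """
    if isinstance(per_sample_records, Mapping):
        pairs = list(per_sample_records.items())
    else:
        pairs = list(per_sample_records)
    names = [n for n, _ in pairs]
    if len(set(names)) != len(names):
        raise DuplicateSampleError(f"duplicate sample names in {names}")
    if not names:
        raise ValueError("at least one sample is required")

    # union of sites, in sorted order for a stable matrix
    site_map: dict[tuple, VariantSite] = {}
    for _, records in pairs:
        for r in records:
            site_map.setdefault(r.key, r.site)
    sorted_keys = sorted(site_map)
    sites = [site_map[k] for k in sorted_keys]
    site_index = {k: i for i, k in enumerate(sorted_keys)}
    rows_at_pos: dict[tuple[str, int], list[int]] = {}
    for key, i in site_index.items():
        rows_at_pos.setdefault((key[0], key[1]), []).append(i)

    status = np.full((len(sites), len(names)), MISSING, dtype=np.int8)
    cov_trees = {s: _coverage_trees(iv) for s, iv in (coverage or {}).items()}

    for j, (name, records) in enumerate(pairs):
        explicit: set[int] = set()
        pos_nonmissing: list[tuple[str, int]] = []
        for r in records:
            call = r.calls.get(name)
            if call is None and len(r.calls) == 1:
                call = next(iter(r.calls.values()))
            if call is None:
                continue
            i = site_index[r.key]
            explicit.add(i)
            z = call.zygosity
            if z is Zygosity.HET or z is Zygosity.HOM_ALT:
                status[i, j] = ALT
            elif z is Zygosity.HOM_REF:
                status[i, j] = REF
            else:
                status[i, j] = MISSING
            if z is not Zygosity.MISSING:
                pos_nonmissing.append((r.site.chrom, r.site.pos))
        # backfill: a non-missing call at the same position is positive
        # evidence of reference for every other allele keyed there
        for cp in pos_nonmissing:
            for i in rows_at_pos[cp]:
                if i not in explicit:
                    status[i, j] = REF
        trees = cov_trees.get(name)
        if trees:
            for key, i in site_index.items():
                if status[i, j] == MISSING and i not in explicit:
                    chrom, pos = key[0], key[1]
                    if chrom in trees and trees[chrom].overlaps(pos):
                        status[i, j] = REF

    return CohortMatrix(sites, names, status, roles=roles)
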