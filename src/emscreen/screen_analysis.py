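"""Gene-level collapse, non-complementation intersection and screen reports.

Mutant strains in one complementation group are expected to carry *different*
lesions in the *same* gene.  After per-strain filtering, each strain's
surviving variants are collapsed to the genes they hit, and the candidate
genes are those qualifying in at least k strains (k defaulting to all
strains).  With the cohort-uniqueness filter active upstream, the supporting
variants are automatically distinct across strains.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .effect_annotator import GENIC_CLASSES, NS_SS_CLASSES
from .filter_engine import (
    CascadeStep,
    FilterSpec,
    filter_class,
    filter_cohort_unique,
    filter_quality,
    filter_region,
    run_cascade,
)
from .variant_model import VariantRecord

logger = logging.getLogger(__name__)


@dataclass
class ScreenManifest:
    """Samples of one screen and their roles.

    ``background`` is the unmutagenized parental strain, ``mutants`` the
    non-complementing strains of one complementation group, ``unrelated`` the
    cohort genomes from other projects used for frequency-based uniqueness.
    """

    background: str
    mutants: list[str]
    unrelated: list[str] = field(default_factory=list)
    region: str | None = None
    vcf_paths: dict[str, Path] = field(default_factory=dict)
    reference_path: Path | None = None
    genes_path: Path | None = None
    conservation_path: Path | None = None

    def __post_init__(self) -> None:
        names = [self.background, *self.mutants, *self.unrelated]
        if len(set(names)) != len(names):
            raise ValueError("sample names must be disjoint across roles")
        if not self.mutants:
            raise ValueError("at least one mutant strain is required")

    @property
    def samples(self) -> list[str]:
        return [self.background, *self.mutants, *self.unrelated]

    def role_of(self, sample: str) -> str:
        if sample == self.background:
            return "background"
        if sample in self.mutants:
            return "mutant"
        if sample in self.unrelated:
            return "unrelated"
        raise KeyError(sample)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScreenManifest":
        path = Path(path)
        data = yaml.safe_load(path.read_text())
        base = path.parent

        def resolve(p):
            return None if p is None else (base / p if not Path(p).is_absolute() else Path(p))

        return cls(
            background=data["background"],
            mutants=list(data["mutants"]),
            unrelated=list(data.get("unrelated", [])),
            region=data.get("region"),
            vcf_paths={k: resolve(v) for k, v in data.get("vcf", {}).items()},
            reference_path=resolve(data.get("reference")),
            genes_path=resolve(data.get("genes")),
            conservation_path=resolve(data.get("conservation")),
        )

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        base = path.parent

        def rel(p):
            if p is None:
                return None
            try:
                return str(Path(p).relative_to(base))
            except ValueError:
                return str(p)

        data = {
            "background": self.background,
            "mutants": list(self.mutants),
            "unrelated": list(self.unrelated),
            "region": self.region,
            "vcf": {k: rel(v) for k, v in self.vcf_paths.items()},
            "reference": rel(self.reference_path),
            "genes": rel(self.genes_path),
            "conservation": rel(self.conservation_path),
        }
        path.write_text(yaml.safe_dump(data, sort_keys=False))
        return path


def collapse_to_genes(
    records: Sequence[VariantRecord],
    classes=NS_SS_CLASSES,
) -> dict[str, list[VariantRecord]]:
    """Map gene id -> the strain's variants with a qualifying annotation in
    that gene.  A variant overlapping two genes contributes to both; a gene
    counts once regardless of how many variants hit it."""
    genes: dict[str, list[VariantRecord]] = {}
    for r in records:
        for a in r.annotations:
            if a.gene_id is not None and a.function_class in classes:
                bucket = genes.setdefault(a.gene_id, [])
                if r not in bucket:
                    bucket.append(r)
    return genes


def intersect_strains(
    per_strain_genes: Mapping[str, Mapping[str, Sequence]],
    k: int,
) -> dict[str, dict[str, list]]:
    """Genes qualifying in at least k strains, with each strain's supporting
    variants.  k must be between 1 and the number of strains."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > len(per_strain_genes):
        raise ValueError(f"k={k} exceeds the number of strains ({len(per_strain_genes)})")
    hits: dict[str, dict[str, list]] = {}
    for strain, gene_map in per_strain_genes.items():
        for gene, variants in gene_map.items():
            hits.setdefault(gene, {})[strain] = list(variants)
    return {g: per_strain for g, per_strain in hits.items() if len(per_strain) >= k}


@dataclass
class CascadeReport:
    """Gene counts per cumulative filter row x required-strain-count column,
    plus per-strain variant counts per row."""

    row_labels: list[str]
    strains: list[str]
    variant_counts: dict[str, list[int]]    # strain -> count per row
    gene_cells: list[list[int]]             # rows x k (k = 1..len(strains))
    gene_sets: list[dict[str, set[str]]] = field(default_factory=list, repr=False)
    final_records: dict[str, list] = field(default_factory=dict, repr=False)

    def to_frame(self) -> pd.DataFrame:
        cols = {f"genes_k{k}": [row[k - 1] for row in self.gene_cells]
                for k in range(1, len(self.strains) + 1)}
        for s in self.strains:
            cols[f"variants_{s}"] = self.variant_counts[s]
        return pd.DataFrame(cols, index=pd.Index(self.row_labels, name="filter_step"))

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t")
        return path

    def to_text(self) -> str:
        df = self.to_frame()
        lines = ["Cumulative filter cascade (cells: genes qualifying in >= k strains)", ""]
        lines.append(df.to_string())
        return "\n".join(lines) + "\n"


def build_cascade_report(
    manifest: ScreenManifest,
    per_strain_records: Mapping[str, Sequence[VariantRecord]],
    spec: FilterSpec,
    cohort,
    background_records: Sequence[VariantRecord] | None = None,
) -> CascadeReport:
    """Run the cascade for every mutant strain and tabulate gene counts.

    Cell (row, k) counts the genes qualifying in at least k strains after the
    cumulative filters of that row.  Counts are non-increasing down a column
    (filters only remove variants) and along a row (more strains required).
    """
    strains = list(manifest.mutants)
    per_strain_steps: dict[str, list[CascadeStep]] = {}
    for s in strains:
        per_strain_steps[s] = run_cascade(
            per_strain_records[s], spec, sample=s,
            background_records=background_records, cohort=cohort,
        )
    row_labels = [st.label for st in per_strain_steps[strains[0]]]

    from .filter_engine import gene_set  # local import to avoid cycle noise

    variant_counts = {s: [st.n_variants for st in per_strain_steps[s]] for s in strains}
    gene_cells: list[list[int]] = []
    gene_sets: list[dict[str, set[str]]] = []
    for i, label in enumerate(row_labels):
        classes = GENIC_CLASSES if label in ("input", "quality") else spec.classes
        sets = {s: gene_set(per_strain_steps[s][i].records, classes) for s in strains}
        gene_sets.append(sets)
        row = []
        for k in range(1, len(strains) + 1):
            count = 0
            all_genes = set().union(*sets.values()) if sets else set()
            for g in all_genes:
                if sum(1 for s in strains if g in sets[s]) >= k:
                    count += 1
            row.append(count)
        gene_cells.append(row)
    final = {s: per_strain_steps[s][-1].records for s in strains}
    return CascadeReport(row_labels, strains, variant_counts, gene_cells, gene_sets, final)


METRICS_COLUMNS = ["sample", "n_snvs", "n_high_quality", "n_ns_ss",
                   "n_ns_ss_region", "n_unique_ns_ss_region"]


def totals_and_mean(counts: Sequence[int]) -> tuple[int, float]:
    """Column total and per-strain mean for a metrics column."""
    counts = list(counts)
    return sum(counts), (sum(counts) / len(counts) if counts else 0.0)


def summarize_metrics(
    per_sample_records: Mapping[str, Sequence[VariantRecord]],
    manifest: ScreenManifest,
    spec: FilterSpec,
    cohort=None,
) -> pd.DataFrame:
    """Per-sample SNV counts at each analysis tier, with a totals row summing
    the mutant strains.

    Tiers: all SNVs; high-quality (GQ/QUAL thresholds); nonsynonymous /
    nonsense / splice-site coding SNVs; the same restricted to the mapped
    region; and those additionally unique within the cohort.  Samples must be
    annotated for the class tiers.
    """
    rows = []
    for sample in [manifest.background, *manifest.mutants]:
        records = list(per_sample_records.get(sample, []))
        hq = filter_quality(records, spec.min_gq, spec.min_qual, sample=sample)
        nsss = filter_class(hq, spec.classes) if hq else []
        on_region = filter_region(nsss, manifest.region) if manifest.region else nsss
        if cohort is not None:
            carriers = [r for r in on_region
                        if sample in r.calls and r.calls[sample].is_carrier]
            unique = filter_cohort_unique(carriers, cohort, sample,
                                          spec.max_cohort_count or 0)
        else:
            unique = []
        rows.append({
            "sample": sample,
            "n_snvs": len(records),
            "n_high_quality": len(hq),
            "n_ns_ss": len(nsss),
            "n_ns_ss_region": len(on_region),
            "n_unique_ns_ss_region": len(unique),
        })
    df = pd.DataFrame(rows, columns=METRICS_COLUMNS)
    mutant_rows = df[df["sample"].isin(manifest.mutants)]
    totals = {"sample": "total_mutants"}
    for col in METRICS_COLUMNS[1:]:
        totals[col] = int(mutant_rows[col].sum())
    return pd.concat([df, pd.DataFrame([totals])], ignore_index=True)
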