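"""Codon classification, splice windows, conservation lookup, EMS signature."""

from __future__ import annotations

import numpy as np
import pytest

from emscreen.effect_annotator import (
    ConservationTrack,
    FunctionClass,
    GeneIndex,
    GeneModel,
    ReferenceGenome,
    ReferenceMismatchError,
    annotate_all,
    classify_variant,
    conservation_at,
    is_ems_transition,
    load_gene_models,
)
from emscreen.variant_model import VariantSite
from conftest import make_record

# One-exon gene with CDS ATG CAG GGA TAA starting at position 11 (+ strand)
PLUS_SEQ = "T" * 10 + "ATGCAGGGATAA" + "T" * 10


def _complement(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


@pytest.fixture
def plus_gene():
    ref = ReferenceGenome.from_dict({"3L": PLUS_SEQ})
    index = GeneIndex([GeneModel("geneA", "3L", "+", ((11, 22),))])
    return ref, index


@pytest.fixture
def minus_gene():
    # same CDS planted on the minus strand: genome carries its reverse complement
    seq = "T" * 10 + _complement("ATGCAGGGATAA") + "T" * 10
    ref = ReferenceGenome.from_dict({"3L": seq})
    index = GeneIndex([GeneModel("geneA", "3L", "-", ((11, 22),))])
    return ref, index


class TestClassifyVariant:
    def test_stop_gain_is_nonsense(self, plus_gene):
        ref, index = plus_gene
        # codon 2 base 1: CAG -> TAG
        (ann,) = classify_variant(VariantSite("3L", 14, "C", "T"), index, ref)
        assert ann.function_class is FunctionClass.NONSENSE
        assert ann.aa_change == "Q2*"

    def test_degenerate_third_position_is_synonymous(self, plus_gene):
        ref, index = plus_gene
        # codon 3 base 3: GGA -> GGG (both glycine)
        (ann,) = classify_variant(VariantSite("3L", 19, "A", "G"), index, ref)
        assert ann.function_class is FunctionClass.SYNONYMOUS
        assert ann.aa_change == "G3G"

    def test_amino_acid_change_is_nonsynonymous(self, plus_gene):
        ref, index = plus_gene
        # codon 2 base 2: CAG -> CGG (Gln -> Arg)
        (ann,) = classify_variant(VariantSite("3L", 15, "A", "G"), index, ref)
        assert ann.function_class is FunctionClass.NONSYNONYMOUS
        assert ann.aa_change == "Q2R"

    def test_outside_any_gene_is_intergenic(self, plus_gene):
        ref, index = plus_gene
        (ann,) = classify_variant(VariantSite("3L", 3, "T", "A"), index, ref)
        assert ann.function_class is FunctionClass.INTERGENIC
        assert ann.gene_id is None

    def test_reference_mismatch_raises(self, plus_gene):
        ref, index = plus_gene
        with pytest.raises(ReferenceMismatchError, match="3L:14"):
            classify_variant(VariantSite("3L", 14, "G", "T"), index, ref)

    def test_minus_strand_gives_same_amino_acid_change(self, plus_gene, minus_gene):
        """Strand symmetry: the complemented construction yields the same
        protein-level change for the equivalent genomic substitution."""
        refp, idxp = plus_gene
        refm, idxm = minus_gene
        (plus_ann,) = classify_variant(VariantSite("3L", 14, "C", "T"), idxp, refp)
        # CDS index 3 maps to genomic position 11 + (22-11) - 3 = 19 on minus
        (minus_ann,) = classify_variant(VariantSite("3L", 19, "G", "A"), idxm, refm)
        assert minus_ann.function_class is plus_ann.function_class
        assert minus_ann.aa_change == plus_ann.aa_change


class TestSpliceWindow:
    @pytest.fixture
    def two_exon(self):
        # exon1 11-16 (ATGCAG), intron 17-46, exon2 47-52 (GGATAA)
        seq = "T" * 10 + "ATGCAG" + "C" * 30 + "GGATAA" + "T" * 10
        ref = ReferenceGenome.from_dict({"3L": seq})
        index = GeneIndex([GeneModel("geneB", "3L", "+", ((11, 16), (47, 52)))])
        return ref, index

    @pytest.mark.parametrize("pos,expected", [
        (17, FunctionClass.SPLICE_SITE),  # 1 bp past the donor
        (18, FunctionClass.SPLICE_SITE),  # 2 bp past the donor
        (19, FunctionClass.INTRONIC),     # 3 bp in: plain intron
        (45, FunctionClass.SPLICE_SITE),  # 2 bp before the acceptor
        (30, FunctionClass.INTRONIC),
    ])
    def test_two_base_window(self, two_exon, pos, expected):
        ref, index = two_exon
        (ann,) = classify_variant(VariantSite("3L", pos, "C", "T"), index, ref)
        assert ann.function_class is expected


class TestEmsTransition:
    @pytest.mark.parametrize("ref,alt,expected", [
        ("G", "A", True), ("C", "T", True),
        ("A", "G", False), ("T", "C", False),
        ("G", "T", False), ("C", "G", False),
    ])
    def test_signature(self, ref, alt, expected):
        assert is_ems_transition(ref, alt) is expected

    def test_identical_bases_rejected(self):
        with pytest.raises(ValueError):
            is_ems_transition("G", "G")


class TestConservation:
    def test_fixed_step_block_positions(self, tmp_path):
        p = tmp_path / "c.wig"
        p.write_text("fixedStep chrom=3L start=100 step=1\n0.1\n0.9\n")
        track = ConservationTrack.from_wig(p)
        assert conservation_at("3L", 100, track) == pytest.approx(0.1)
        assert conservation_at("3L", 101, track) == pytest.approx(0.9)
        assert conservation_at("3L", 99, track) is None
        assert conservation_at("2R", 100, track) is None

    def test_covered_value_is_identity(self):
        track = ConservationTrack.from_arrays({"3L": np.array([np.nan, 0.97])})
        assert track.get("3L", 2) == pytest.approx(0.97)
        assert track.get("3L", 1) is None

    def test_three_column_table(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("3L\t5\t0.42\n2R\t1\t0.8\n")
        track = ConservationTrack.from_tsv(p)
        assert track.get("3L", 5) == pytest.approx(0.42)
        assert track.get("3L", 4) is None
        assert track.get("2R", 1) == pytest.approx(0.8)


class TestAnnotateAll:
    def test_empty_input_stays_empty(self, plus_gene):
        ref, index = plus_gene
        assert annotate_all([], index, ref) == []

    def test_record_overlapping_two_genes_gets_two_annotations(self):
        seq = "T" * 10 + "ATGCAGGGATAA" + "T" * 10
        ref = ReferenceGenome.from_dict({"3L": seq})
        index = GeneIndex([
            GeneModel("geneA", "3L", "+", ((11, 22),)),
            GeneModel("geneB", "3L", "+", ((14, 19),)),  # nested frame
        ])
        rec = make_record(pos=15, ref="A", alt="G")
        annotate_all([rec], index, ref)
        assert sorted(a.gene_id for a in rec.annotations) == ["geneA", "geneB"]

    def test_count_order_and_conservation_attachment(self, plus_gene):
        ref, index = plus_gene
        track = ConservationTrack.from_arrays({"3L": np.full(40, 0.7)})
        recs = [make_record(pos=14, ref="C", alt="T"), make_record(pos=3, ref="T", alt="A")]
        out = annotate_all(recs, index, ref, track)
        assert list(out) == recs
        assert all(len(r.annotations) >= 1 for r in recs)
        assert recs[0].annotations[0].conservation == pytest.approx(0.7)


class TestAgainstSimulatorTruth:
    def test_annotator_matches_planted_classes(self, tiny_screen):
        """Every induced mutation is classified as the generator intended
        (the generator's classification is an independent code path)."""
        s = tiny_screen
        ref = ReferenceGenome.from_dict(s.reference.sequences)
        index = GeneIndex(s.reference.gene_models)
        by_sample = {}
        for row in s.truth.rows:
            by_sample.setdefault(row.strain, []).append(row)
        checked = 0
        for strain, rows in by_sample.items():
            truth_by_key = {(r.chrom, r.pos): r for r in rows}
            records = [r for r in s.records[strain]
                       if (r.site.chrom, r.site.pos) in truth_by_key]
            annotate_all(records, index, ref)
            for rec in records:
                intended = truth_by_key[(rec.site.chrom, rec.site.pos)].function_class
                got = {a.function_class.value for a in rec.annotations}
                assert intended in got, (rec.site, intended, got)
                checked += 1
        assert checked > 500

    def test_gff3_round_trip_reproduces_models(self, tiny_screen_dir):
        s = tiny_screen_dir
        index = load_gene_models(s.outdir / "genes.gff3")
        assert len(index) == len(s.reference.genes)
        for sim_gene in s.reference.genes:
            loaded = index.by_id[sim_gene.model.gene_id]
            assert loaded.cds_exons == sim_gene.model.cds_exons
            assert loaded.strand == sim_gene.model.strand
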