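"""Individual filters, their algebraic properties, and the cascade."""

from __future__ import annotations

import random

import pytest

from emscreen.cohort_store import build_matrix
from emscreen.effect_annotator import EffectAnnotation, FunctionClass
from emscreen.filter_engine import (
    FilterSpec,
    UnannotatedRecordError,
    filter_class,
    filter_cohort_unique,
    filter_conservation,
    filter_ems,
    filter_quality,
    filter_region,
    filter_zygosity,
    run_cascade,
    subtract_background,
)
from emscreen.variant_model import Zygosity
from conftest import make_record


def annotated(rec, cls=FunctionClass.NONSYNONYMOUS, gene="geneA", cons=None):
    gene_id = None if cls is FunctionClass.INTERGENIC else gene
    rec.annotations.append(EffectAnnotation(gene_id, cls, conservation=cons))
    return rec


class TestQuality:
    def test_inclusive_boundary_kept(self):
        assert filter_quality([make_record(gq=75, qual=100.0)]) != []

    def test_low_gq_removed_despite_high_qual(self):
        assert filter_quality([make_record(gq=74, qual=500.0)]) == []

    def test_enumerated_gq_ladder(self):
        recs = [make_record(pos=10 * (i + 1), gq=g, qual=200.0)
                for i, g in enumerate((99, 80, 75, 74, 10))]
        assert len(filter_quality(recs)) == 3

    def test_missing_gq_fails_not_raises(self):
        rec = make_record(gq=None)
        assert filter_quality([rec]) == []


class TestZygosity:
    def test_het_kept_hom_removed(self):
        het = make_record(zygosity=Zygosity.HET)
        hom = make_record(pos=200, zygosity=Zygosity.HOM_ALT)
        assert filter_zygosity([het, hom], {Zygosity.HET}) == [het]

    def test_missing_never_kept(self):
        rec = make_record(zygosity=Zygosity.MISSING, gq=None, qual=10.0, depth=None)
        assert filter_zygosity([rec], set(Zygosity)) == []


class TestClass:
    def test_synonymous_only_removed(self):
        rec = annotated(make_record(), FunctionClass.SYNONYMOUS)
        assert filter_class([rec]) == []

    def test_any_qualifying_annotation_keeps(self):
        rec = annotated(make_record(), FunctionClass.INTERGENIC)
        annotated(rec, FunctionClass.NONSENSE, gene="geneB")
        assert filter_class([rec]) == [rec]

    def test_unannotated_record_is_an_error(self):
        with pytest.raises(UnannotatedRecordError):
            filter_class([make_record()])


class TestEms:
    @pytest.mark.parametrize("ref,alt,kept", [
        ("G", "A", True), ("C", "T", True), ("T", "C", False), ("C", "G", False),
    ])
    def test_transition_rule(self, ref, alt, kept):
        rec = make_record(ref=ref, alt=alt)
        assert (filter_ems([rec]) == [rec]) is kept


class TestBackgroundSubtraction:
    def test_shared_variant_removed(self):
        mut = make_record(sample="mut1")
        bg = make_record(sample="background")
        assert subtract_background([mut], [bg]) == []

    def test_private_variant_kept(self):
        mut = make_record(sample="mut1")
        bg = make_record(pos=999, ref="C", alt="T", sample="background")
        assert subtract_background([mut], [bg]) == [mut]

    def test_background_missing_keeps_and_flags(self):
        mut = make_record(sample="mut1")
        bg = make_record(zygosity=Zygosity.MISSING, gq=None, depth=None,
                         sample="background", qual=5.0)
        kept = subtract_background([mut], [bg])
        assert kept == [mut]
        assert "background_missing" in kept[0].flags

    def test_empty_background_is_identity(self):
        muts = [make_record(pos=p) for p in (1, 2, 3)]
        assert subtract_background(muts, []) == muts

    def test_self_subtraction_empties_carriers(self):
        muts = [make_record(pos=p) for p in (1, 2, 3)]
        assert subtract_background(muts, muts) == []


class TestConservation:
    def test_strict_inequality_at_threshold(self):
        kept = annotated(make_record(), cons=0.51)
        removed = annotated(make_record(pos=200), cons=0.5)
        assert filter_conservation([kept, removed]) == [kept]

    def test_absent_score_fails_by_default_configurable(self):
        rec = annotated(make_record(), cons=None)
        assert filter_conservation([rec]) == []
        assert filter_conservation([rec], missing_fails=False) == [rec]

    def test_enumerated_score_ladder(self):
        recs = [annotated(make_record(pos=10 * (i + 1)), cons=i / 10)
                for i in range(10)]
        assert len(filter_conservation(recs, 0.5)) == 4  # 0.6, 0.7, 0.8, 0.9


class TestRegion:
    def test_arm_match(self):
        on = make_record(chrom="3L")
        off = make_record(chrom="2R")
        assert filter_region([on, off], "3L") == [on]

    def test_interval_bounds_inclusive(self):
        recs = [make_record(pos=p) for p in (50, 150, 151)]
        assert [r.site.pos for r in filter_region(recs, ("3L", 50, 150))] == [50, 150]

    def test_unknown_arm_warns_not_raises(self, caplog):
        with caplog.at_level("WARNING"):
            assert filter_region([make_record()], "nonexistent") == []
        assert any("no records" in m for m in caplog.messages)


def _random_records(rng, n=60, sample="s1"):
    recs = []
    positions = rng.sample(range(1, 100_000), n)
    for pos in positions:
        ref, alt = rng.sample("ACGT", 2)
        zyg = rng.choice([Zygosity.HET, Zygosity.HOM_ALT, Zygosity.HOM_REF])
        rec = make_record(chrom=rng.choice(["3L", "2R"]), pos=pos, ref=ref, alt=alt,
                          zygosity=zyg, gq=rng.randint(0, 99),
                          qual=float(rng.randint(0, 1000)), sample=sample)
        cls = rng.choice(list(FunctionClass))
        cons = rng.choice([None, round(rng.random(), 2)])
        annotated(rec, cls, cons=cons)
        recs.append(rec)
    return recs


def _predicates(background, cohort, sample):
    return {
        "quality": lambda rs: filter_quality(rs, 75, 100.0, sample=sample),
        "class": lambda rs: filter_class(rs),
        "zygosity": lambda rs: filter_zygosity(rs, {Zygosity.HET}, sample=sample),
        "background": lambda rs: subtract_background(rs, background),
        "ems": filter_ems,
        "conservation": lambda rs: filter_conservation(rs, 0.5),
        "cohort": lambda rs: filter_cohort_unique(rs, cohort, sample, 0),
        "region": lambda rs: filter_region(rs, "3L"),
    }


class TestFilterAlgebra:
    @pytest.mark.parametrize("seed", range(5))
    def test_every_filter_idempotent_and_subset(self, seed):
        rng = random.Random(seed)
        recs = _random_records(rng)
        background = _random_records(rng, n=30, sample="background")
        cohort = build_matrix({"s1": recs, "background": background})
        for name, f in _predicates(background, cohort, "s1").items():
            once = f(recs)
            assert set(r.key for r in once) <= set(r.key for r in recs), name
            assert f(once) == once, f"{name} is not idempotent"

    @pytest.mark.parametrize("seed", range(10))
    def test_final_set_is_order_independent(self, seed):
        rng = random.Random(1000 + seed)
        recs = _random_records(rng)
        background = _random_records(rng, n=30, sample="background")
        cohort = build_matrix({"s1": recs, "background": background})
        preds = _predicates(background, cohort, "s1")
        names = list(preds)
        baseline = None
        order = names[:]
        rng.shuffle(order)
        for ordering in (names, order, list(reversed(names))):
            out = recs
            for name in ordering:
                out = preds[name](out)
            keys = {r.key for r in out}
            if baseline is None:
                baseline = keys
            assert keys == baseline


class TestCascade:
    def test_empty_input_gives_all_zero_rows(self):
        steps = run_cascade([], FilterSpec(), sample="s1")
        assert all(st.n_variants == 0 and st.n_genes == 0 for st in steps)

    def test_counts_monotonically_non_increasing(self, tiny_screen):
        s = tiny_screen
        from emscreen.effect_annotator import (
            ConservationTrack, GeneIndex, ReferenceGenome, annotate_all)
        ref = ReferenceGenome.from_dict(s.reference.sequences)
        index = GeneIndex(s.reference.gene_models)
        track = ConservationTrack.from_arrays(s.reference.conservation)
        records = annotate_all(list(s.records["mut1"]), index, ref, track)
        cohort = build_matrix(s.records)
        steps = run_cascade(records, FilterSpec(region="3L"), sample="mut1",
                            background_records=s.records["background"], cohort=cohort)
        counts = [st.n_variants for st in steps]
        assert counts == sorted(counts, reverse=True)
        assert steps[-1].n_variants < steps[0].n_variants

    def test_planted_variant_survives_all_filters(self, tiny_screen):
        s = tiny_screen
        from emscreen.effect_annotator import (
            ConservationTrack, GeneIndex, ReferenceGenome, annotate_all)
        ref = ReferenceGenome.from_dict(s.reference.sequences)
        index = GeneIndex(s.reference.gene_models)
        track = ConservationTrack.from_arrays(s.reference.conservation)
        cohort = build_matrix(s.records)
        causative = {r.strain: (r.chrom, r.pos, r.ref, r.alt)
                     for r in s.truth.causative_rows()}
        for strain in s.manifest.mutants:
            records = annotate_all(list(s.records[strain]), index, ref, track)
            steps = run_cascade(records, FilterSpec(region="3L"), sample=strain,
                                background_records=s.records["background"],
                                cohort=cohort)
            final_keys = {r.key for r in steps[-1].records}
            assert causative[strain] in final_keys
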