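"""Homolog search and annotation-transfer semantics."""

import pytest

from grinmap.fixtures import ToyVariantSpec, make_variant_db
from grinmap.transfer import (
    PredictionStatus,
    annotate_database,
    find_homologs,
    predict,
)
from grinmap.variants import (
    AnnotationRecord,
    Functional,
    Pathogenicity,
    ProteinVariant,
    VariantDatabase,
)


def _entry_aa(identity_map, pos_a):
    return identity_map.lookup("GluN2A", pos_a, "GluN2B").aa_a


def _variant_pair(identity_map, pos_a, alt=None):
    """A homologous GluN2A/GluN2B variant pair on the identity-offset map."""
    e = identity_map.lookup("GluN2A", pos_a, "GluN2B")
    ref = e.aa_a
    alt = alt or ("A" if ref != "A" else "V")
    return (
        ProteinVariant("GluN2A", e.pos_a, ref, alt),
        ProteinVariant("GluN2B", e.pos_b, ref, alt),
    )


class TestFindHomologs:
    def test_same_change_at_equivalent_position_found(self, identity_map):
        v_a, v_b = _variant_pair(identity_map, 10)
        db = VariantDatabase()
        db.add(v_b, AnnotationRecord(Pathogenicity.PATHOGENIC))
        assert find_homologs(v_a, identity_map, db) == [v_b]

    def test_different_initial_residue_excluded(self, identity_map):
        v_a, v_b = _variant_pair(identity_map, 10)
        other_ref = "W" if v_b.ref != "W" else "Y"
        non_homolog = ProteinVariant("GluN2B", v_b.pos, other_ref, v_b.alt)
        db = VariantDatabase()
        db.add(non_homolog, AnnotationRecord(Pathogenicity.PATHOGENIC))
        assert find_homologs(v_a, identity_map, db) == []

    def test_different_final_residue_excluded(self, identity_map):
        v_a, v_b = _variant_pair(identity_map, 10)
        other_alt = "W" if v_b.alt != "W" and v_b.ref != "W" else "F"
        non_homolog = ProteinVariant("GluN2B", v_b.pos, v_b.ref, other_alt)
        db = VariantDatabase()
        db.add(non_homolog, AnnotationRecord(Pathogenicity.PATHOGENIC))
        assert find_homologs(v_a, identity_map, db) == []

    def test_unmapped_position_yields_nothing(self, identity_map):
        v = ProteinVariant("GluN2A", 4000, "A", "V")
        db = VariantDatabase()
        db.add(ProteinVariant("GluN2B", 4000, "A", "V"), AnnotationRecord())
        assert find_homologs(v, identity_map, db) == []

    def test_symmetry(self, identity_map):
        v_a, v_b = _variant_pair(identity_map, 25)
        db = VariantDatabase()
        db.add(v_a, AnnotationRecord())
        db.add(v_b, AnnotationRecord())
        assert v_b in find_homologs(v_a, identity_map, db)
        assert v_a in find_homologs(v_b, identity_map, db)


class TestPredict:
    def test_pathogenic_homolog_transfers(self, identity_map):
        v_a, v_b = _variant_pair(identity_map, 10)
        db = VariantDatabase()
        db.add(v_b, AnnotationRecord(Pathogenicity.PATHOGENIC, Functional.LOF))
        p = predict(v_a, identity_map, db)
        assert p.status == PredictionStatus.PREDICTED
        assert p.predicted_pathogenicity == Pathogenicity.PATHOGENIC
        assert p.predicted_functional == Functional.LOF

    def test_uncertain_homolog_never_transfers(self, identity_map):
        v_a, v_b = _variant_pair(identity_map, 10)
        db = VariantDatabase()
        db.add(v_b, AnnotationRecord(Pathogenicity.UNCERTAIN))
        p = predict(v_a, identity_map, db)
        assert p.status == PredictionStatus.HOMOLOG_UNANNOTATED
        assert p.predicted_pathogenicity is None
        assert p.predicted_pathogenicity != Pathogenicity.UNCERTAIN

    def test_no_homolog_status(self, identity_map):
        p = predict(ProteinVariant("GluN2A", 10, "A", "V"), identity_map, VariantDatabase())
        assert p.status == PredictionStatus.NO_HOMOLOG

    def test_disagreeing_homologs_yield_conflict(self, identity_map):
        # GluN1 and GluN2B both carry the change; they disagree
        e = identity_map.lookup("GluN2A", 10, "GluN2B")
        ref, alt = e.aa_a, "A" if e.aa_a != "A" else "V"
        from grinmap.equivalence import Equivalence, EquivalenceMap, STRUCTURAL

        trio = EquivalenceMap()
        trio.add("GluN2A", "GluN2B", Equivalence(10, 10, ref, ref, "LBD", STRUCTURAL))
        trio.add("GluN1", "GluN2A", Equivalence(10, 10, ref, ref, "LBD", STRUCTURAL))
        db = VariantDatabase()
        db.add(ProteinVariant("GluN2B", 10, ref, alt), AnnotationRecord(Pathogenicity.PATHOGENIC))
        db.add(ProteinVariant("GluN1", 10, ref, alt), AnnotationRecord(Pathogenicity.BENIGN))
        p = predict(ProteinVariant("GluN2A", 10, ref, alt), trio, db)
        assert p.status == PredictionStatus.CONFLICT
        assert p.predicted_pathogenicity is None

    def test_independent_dimensions(self, identity_map):
        v_a, v_b = _variant_pair(identity_map, 10)
        db = VariantDatabase()
        db.add(v_b, AnnotationRecord(Pathogenicity.UNANNOTATED, Functional.GOF))
        p = predict(v_a, identity_map, db)
        assert p.status == PredictionStatus.PREDICTED
        assert p.predicted_pathogenicity is None
        assert p.predicted_functional == Functional.GOF


class TestAnnotateDatabase:
    def test_saturated_fixture_predicts_everything(self, identity_map):
        # every unannotated variant has exactly one pathogenic homolog
        db = VariantDatabase()
        n = 20
        for k in range(n):
            v_a, v_b = _variant_pair(identity_map, 10 + k)
            db.add(v_b, AnnotationRecord(Pathogenicity.PATHOGENIC))
            db.add(v_a, AnnotationRecord())
        predictions, report = annotate_database(db, identity_map)
        predicted = [p for p in predictions if p.predicted_pathogenicity is not None]
        assert len(predicted) == n
        assert report.predicted_pathogenic == n
        assert report.baseline_pathogenic == n
        assert report.pathogenic_increase_percent == pytest.approx(100.0)

    def test_no_homologous_pairs_no_predictions(self, identity_map):
        db, _ = make_variant_db(
            ToyVariantSpec(n_groups=10, fraction_annotated=0.0, seed=3), identity_map
        )
        predictions, report = annotate_database(db, identity_map)
        assert all(p.predicted_pathogenicity is None for p in predictions)
        assert report.predicted_pathogenic == 0

    def test_vus_resolution_counted(self, identity_map):
        v_a, v_b = _variant_pair(identity_map, 12)
        db = VariantDatabase()
        db.add(v_b, AnnotationRecord(Pathogenicity.BENIGN))
        db.add(v_a, AnnotationRecord(Pathogenicity.UNCERTAIN))
        _, report = annotate_database(db, identity_map)
        assert report.vus_resolved == 1
        assert report.predicted_benign == 1
        assert report.vus_decrease_percent == pytest.approx(100.0)

    def test_idempotent_after_accepting_predictions(self, identity_map):
        db, _ = make_variant_db(
            ToyVariantSpec(n_groups=30, fraction_annotated=0.5, seed=4), identity_map
        )
        predictions, _ = annotate_database(db, identity_map)
        accepted = VariantDatabase()
        by_target = {p.target: p for p in predictions}
        for v, rec in db.items():
            p = by_target.get(v)
            new = AnnotationRecord(rec.pathogenicity, rec.functional, rec.source)
            if p is not None and p.predicted_pathogenicity is not None:
                new.pathogenicity = p.predicted_pathogenicity
            if p is not None and p.predicted_functional is not None:
                new.functional = p.predicted_functional
            accepted.add(v, new)
        second, report2 = annotate_database(accepted, identity_map)
        assert all(p.predicted_pathogenicity is None for p in second)
        assert all(p.predicted_functional is None for p in second)
        assert report2.predicted_pathogenic == 0

    def test_uncertain_never_in_predictions(self, identity_map):
        db, _ = make_variant_db(
            ToyVariantSpec(n_groups=40, fraction_annotated=0.7, seed=5), identity_map
        )
        predictions, _ = annotate_database(db, identity_map)
        for p in predictions:
            assert p.predicted_pathogenicity != Pathogenicity.UNCERTAIN
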