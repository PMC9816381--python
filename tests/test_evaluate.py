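"""Grouping of equivalent variants, concordance reports and the per-domain
identity/RMSD summary."""

import numpy as np
import pytest

from grinmap.evaluate import (
    ComparisonCategory,
    concordance,
    group_equivalent_variants,
    summarize_table1,
)
from grinmap.fixtures import ToyVariantSpec, make_variant_db, trio_domain_definitions
from grinmap.variants import (
    AnnotationRecord,
    Functional,
    Pathogenicity,
    ProteinVariant,
    VariantDatabase,
)


def _pair(identity_map, pos_a, alt=None, ref=None):
    e = identity_map.lookup("GluN2A", pos_a, "GluN2B")
    ref_a = ref or e.aa_a
    alt = alt or ("A" if ref_a != "A" else "V")
    return ProteinVariant("GluN2A", e.pos_a, ref_a, alt), ProteinVariant(
        "GluN2B", e.pos_b, e.aa_b, alt
    )


class TestGrouping:
    def test_homologous_pair_forms_one_group(self, identity_map):
        v_a, v_b = _pair(identity_map, 10)
        db = VariantDatabase()
        db.add(v_a, AnnotationRecord(Pathogenicity.PATHOGENIC))
        db.add(v_b, AnnotationRecord(Pathogenicity.PATHOGENIC))
        groups = group_equivalent_variants(db, identity_map, ComparisonCategory.HOMOLOGOUS)
        assert len(groups) == 1
        assert set(groups[0].members) == {v_a, v_b}

    def test_same_final_requires_distinct_refs(self, identity_map):
        e = identity_map.lookup("GluN2A", 10, "GluN2B")
        other_ref = "W" if e.aa_b != "W" else "Y"
        alt = "R" if e.aa_a != "R" and other_ref != "R" else "H"
        v_a = ProteinVariant("GluN2A", e.pos_a, e.aa_a, alt)
        v_b = ProteinVariant("GluN2B", e.pos_b, other_ref, alt)
        db = VariantDatabase()
        db.add(v_a, AnnotationRecord(Pathogenicity.PATHOGENIC))
        db.add(v_b, AnnotationRecord(Pathogenicity.PATHOGENIC))
        same_final = group_equivalent_variants(db, identity_map, ComparisonCategory.SAME_FINAL)
        assert len(same_final) == 1
        homologous = group_equivalent_variants(db, identity_map, ComparisonCategory.HOMOLOGOUS)
        assert homologous == []

    def test_same_initial_includes_same_subunit_alternates(self, identity_map):
        # Ala639Val vs Ala639Ser style: two alternates at one position plus a
        # cross-subunit partner
        e = identity_map.lookup("GluN2A", 15, "GluN2B")
        ref = e.aa_a
        alts = [a for a in "VSR" if a != ref][:2]
        v_a1 = ProteinVariant("GluN2A", e.pos_a, ref, alts[0])
        v_a2 = ProteinVariant("GluN2A", e.pos_a, ref, alts[1])
        v_b = ProteinVariant("GluN2B", e.pos_b, ref, alts[0])
        db = VariantDatabase()
        for v in (v_a1, v_a2, v_b):
            db.add(v, AnnotationRecord(Pathogenicity.PATHOGENIC))
        groups = group_equivalent_variants(db, identity_map, ComparisonCategory.SAME_INITIAL)
        assert len(groups) == 1
        assert set(groups[0].members) == {v_a1, v_a2, v_b}

    def test_unmapped_positions_form_no_groups(self, identity_map):
        db = VariantDatabase()
        db.add(ProteinVariant("GluN2A", 2000, "A", "V"), AnnotationRecord(Pathogenicity.BENIGN))
        db.add(ProteinVariant("GluN2B", 2000, "A", "V"), AnnotationRecord(Pathogenicity.BENIGN))
        for category in ComparisonCategory:
            assert group_equivalent_variants(db, identity_map, category) == []

    def test_categories_are_disjoint(self, identity_map):
        db, _ = make_variant_db(ToyVariantSpec(n_groups=30, seed=9), identity_map)
        seen = {}
        for category in ComparisonCategory:
            for g in group_equivalent_variants(db, identity_map, category):
                key = frozenset(g.members)
                assert key not in seen, f"group in both {seen.get(key)} and {category}"
                seen[key] = category


class TestConcordance:
    def test_all_agreeing_fixture_is_fully_concordant(self, identity_map):
        db, _ = make_variant_db(ToyVariantSpec(n_groups=25, concordance_p=1.0, seed=1), identity_map)
        groups = group_equivalent_variants(db, identity_map, ComparisonCategory.HOMOLOGOUS)
        rep = concordance(groups, db, "pathogenicity")
        assert rep.n_groups == 25
        assert rep.percent_coincident == pytest.approx(100.0)
        assert rep.discordant_groups == []

    def test_planted_partial_agreement_counts(self, identity_map):
        # 59 agreeing groups out of 72 -> 81.94%
        db, ledger = make_variant_db(
            ToyVariantSpec(n_groups=72, concordance_p=0.8, seed=23), identity_map
        )
        n_agree = sum(1 for row in ledger if row["agree"])
        groups = group_equivalent_variants(db, identity_map, ComparisonCategory.HOMOLOGOUS)
        rep = concordance(groups, db, "pathogenicity")
        assert rep.n_groups == 72
        assert rep.n_coincident == n_agree
        assert rep.percent_coincident == pytest.approx(100.0 * n_agree / 72)

    def test_discordant_group_listed(self, identity_map):
        v_a, v_b = _pair(identity_map, 30)
        db = VariantDatabase()
        db.add(v_a, AnnotationRecord(Pathogenicity.PATHOGENIC))
        db.add(v_b, AnnotationRecord(Pathogenicity.BENIGN))
        groups = group_equivalent_variants(db, identity_map, ComparisonCategory.HOMOLOGOUS)
        rep = concordance(groups, db, "pathogenicity")
        assert rep.n_groups == 1
        assert rep.n_coincident == 0
        assert rep.percent_coincident == pytest.approx(0.0)
        assert len(rep.discordant_groups) == 1

    def test_uncertain_members_dropped_from_denominator(self, identity_map):
        v_a, v_b = _pair(identity_map, 31)
        db = VariantDatabase()
        db.add(v_a, AnnotationRecord(Pathogenicity.UNCERTAIN))
        db.add(v_b, AnnotationRecord(Pathogenicity.PATHOGENIC))
        groups = group_equivalent_variants(db, identity_map, ComparisonCategory.HOMOLOGOUS)
        rep = concordance(groups, db, "pathogenicity")
        assert rep.n_groups == 0

    def test_complex_vs_lof_is_discordant(self, identity_map):
        v_a, v_b = _pair(identity_map, 32)
        db = VariantDatabase()
        db.add(v_a, AnnotationRecord(Pathogenicity.PATHOGENIC, Functional.COMPLEX))
        db.add(v_b, AnnotationRecord(Pathogenicity.PATHOGENIC, Functional.LOF))
        groups = group_equivalent_variants(db, identity_map, ComparisonCategory.HOMOLOGOUS)
        rep = concordance(groups, db, "functional")
        assert rep.n_coincident == 0

    def test_member_order_invariance(self, identity_map):
        db, _ = make_variant_db(ToyVariantSpec(n_groups=10, concordance_p=0.5, seed=2), identity_map)
        groups = group_equivalent_variants(db, identity_map, ComparisonCategory.HOMOLOGOUS)
        rep1 = concordance(groups, db, "pathogenicity")
        for g in groups:
            g.members.reverse()
        rep2 = concordance(groups, db, "pathogenicity")
        assert rep1.n_coincident == rep2.n_coincident

    def test_planted_rate_recovery(self, identity_map):
        """Concordance over 200 planted groups tracks the planted rate to
        within 3 percentage points (fixed seed)."""
        db, _ = make_variant_db(
            ToyVariantSpec(n_groups=200, concordance_p=0.8, seed=11), identity_map
        )
        groups = group_equivalent_variants(db, identity_map, ComparisonCategory.HOMOLOGOUS)
        rep = concordance(groups, db, "pathogenicity")
        assert rep.n_groups == 200
        assert abs(rep.percent_coincident - 80.0) <= 3.0


class TestSummarizeTable1:
    def test_identical_structures_give_full_identity_and_zero_rmsd(self):
        from grinmap.fixtures import make_trio_chains, make_trio_sequences

        seqs = make_trio_sequences(seed=3)
        chains = make_trio_chains(seqs, seed=3, noise_sigma=0.0)
        # compare one subunit against itself via a single-pair run
        doms = {d.subunit: {} for d in trio_domain_definitions()}
        for d in trio_domain_definitions():
            doms[d.subunit][d.domain] = d
        df = summarize_table1(
            {"GluN2A": chains["GluN2A"], "GluN2B": chains["GluN2A"]},
            {"GluN2A": doms["GluN2A"], "GluN2B": doms["GluN2A"]},
            pairs=[("GluN2A", "GluN2B")],
        )
        assert (df["identity_percent"] == 100.0).all()
        rmsds = df[["rmsd", "rmsd_ATD1", "rmsd_ATD2"]].to_numpy().ravel()
        rmsds = rmsds[~np.isnan(rmsds)]
        assert (rmsds < 1e-6).all()

    def test_demo_trio_summary_shape_and_gradient(self, demo_workspace):
        df = summarize_table1(demo_workspace.chains, demo_workspace.domains)
        assert len(df) == 9  # 3 pairs x 3 domains
        ab = df[df["pair"] == "GluN2A-GluN2B"].set_index("domain")
        # identity gradient ATD < LBD < TMD, as in the real subunits
        assert ab.loc["ATD", "identity_percent"] < ab.loc["LBD", "identity_percent"]
        assert ab.loc["LBD", "identity_percent"] < ab.loc["TMD", "identity_percent"]
        assert ab.loc["LBD", "n_columns"] == 317
        assert ab.loc["TMD", "n_columns"] == 140
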