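"""Concordance evaluation across equivalent positions, and the per-domain
identity/RMSD summary table.

Variants at equivalent positions are compared in three categories:
homologous (same initial and final residue), same-final (different initial,
same final) and same-initial (same initial, different finals).  A group is
coincident when all its confidently annotated members carry the same class.
The per-domain summary reproduces, for a set of loaded structures, the
identical-residue counts, identity percentages and superposition RMSDs for
each subunit pair and topological domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

import pandas as pd

from .alignment import derive_structural_alignment, global_align, identity_stats, merge_alignments
from .equivalence import EquivalenceMap, pair_key
from .structures import SUBUNITS, ChainModel, DomainDefinition, extract_domain
from .superposition import iterative_superpose
from .variants import Functional, Pathogenicity, ProteinVariant, VariantDatabase


class ComparisonCategory(str, Enum):
    HOMOLOGOUS = "homologous"        # same ref, same alt
    SAME_FINAL = "same_final"        # different refs, same alt
    SAME_INITIAL = "same_initial"    # same ref, different alts


@dataclass
class VariantGroup:
    category: ComparisonCategory
    members: list[ProteinVariant]

    @property
    def subunits(self) -> set[str]:
        return {v.subunit for v in self.members}


@dataclass
class ConcordanceReport:
    category: ComparisonCategory
    annotation_kind: str  # "pathogenicity" | "functional"
    n_groups: int
    n_variants: int
    n_coincident: int
    discordant_groups: list[VariantGroup] = field(default_factory=list)

    @property
    def percent_coincident(self) -> float:
        if self.n_groups == 0:
            return float("nan")
        return 100.0 * self.n_coincident / self.n_groups

    def to_dict(self) -> dict:
        return {
            "category": self.category.value,
            "annotation_kind": self.annotation_kind,
            "n_groups": self.n_groups,
            "n_variants": self.n_variants,
            "n_coincident": self.n_coincident,
            "percent_coincident": self.percent_coincident
            if self.n_groups > 0
            else None,
            "discordant_groups": [
                [str(v) for v in g.members] for g in self.discordant_groups
            ],
        }


def _position_classes(db: VariantDatabase, emap: EquivalenceMap) -> dict[tuple[str, int], frozenset]:
    """Union-find-free equivalence classes over the (subunit, pos) sites that
    carry variants, linked through the map."""
    sites = {(v.subunit, v.pos) for v in db}
    cls: dict[tuple[str, int], set] = {}
    for site in sites:
        linked = {site}
        for partner, pos, _ in emap.map_position(*site):
            if (partner, pos) in sites:
                linked.add((partner, pos))
        merged = set(linked)
        for s in linked:
            if s in cls:
                merged |= cls[s]
        frozen = merged
        for s in frozen:
            cls[s] = frozen
    return {s: frozenset(c) for s, c in cls.items()}


def group_equivalent_variants(
    db: VariantDatabase, emap: EquivalenceMap, category: ComparisonCategory
) -> list[VariantGroup]:
    """Groups of database variants at equivalent positions matching a
    category's ref/alt pattern.

    Every group spans at least two variants from at least two subunits.
    Within one equivalence class of positions: homologous groups share ref
    and alt; same-final groups share alt with at least two distinct refs;
    same-initial groups share ref with at least two distinct alts (additional
    same-subunit members at the same position are kept, as in the
    Ala639Val / Ala639Ser type of comparison)."""
    category = ComparisonCategory(category)
    classes = _position_classes(db, emap)
    variants_by_class: dict[frozenset, list[ProteinVariant]] = {}
    for v in db:
        key = classes.get((v.subunit, v.pos))
        if key is None or len(key) < 2:
            continue
        variants_by_class.setdefault(key, []).append(v)

    groups: list[VariantGroup] = []
    for members in variants_by_class.values():
        if category == ComparisonCategory.HOMOLOGOUS:
            keyfn = lambda v: (v.ref, v.alt)
        elif category == ComparisonCategory.SAME_FINAL:
            keyfn = lambda v: v.alt
        else:
            keyfn = lambda v: v.ref
        buckets: dict = {}
        for v in members:
            buckets.setdefault(keyfn(v), []).append(v)
        for bucket in buckets.values():
            if len(bucket) < 2 or len({v.subunit for v in bucket}) < 2:
                continue
            refs = {v.ref for v in bucket}
            alts = {v.alt for v in bucket}
            if category == ComparisonCategory.SAME_FINAL and len(refs) < 2:
                continue  # all-same-ref groups are homologous, not same-final
            if category == ComparisonCategory.SAME_INITIAL and len(alts) < 2:
                continue
            groups.append(
                VariantGroup(category, sorted(bucket, key=lambda v: (v.subunit, v.pos, v.alt)))
            )
    groups.sort(key=lambda g: (g.members[0].subunit, g.members[0].pos, g.members[0].alt))
    return groups


def concordance(
    groups: Iterable[VariantGroup],
    db: VariantDatabase,
    annotation_kind: str = "pathogenicity",
) -> ConcordanceReport:
    """Coincidence of annotations within variant groups.

    For pathogenicity, uncertain-significance members are discarded before
    comparison and a group left with fewer than two members drops out of the
    denominator; a group is coincident when all remaining members agree.
    Functional concordance compares annotated members only and treats
    'complex' as its own class (complex vs LoF is discordant)."""
    if annotation_kind not in ("pathogenicity", "functional"):
        raise ValueError(f"unknown annotation kind {annotation_kind!r}")
    groups = list(groups)
    category = groups[0].category if groups else ComparisonCategory.HOMOLOGOUS
    n_groups = n_variants = n_coincident = 0
    discordant: list[VariantGroup] = []
    for g in groups:
        values = []
        kept = []
        for v in g.members:
            rec = db.annotation(v)
            if annotation_kind == "pathogenicity":
                val = rec.pathogenicity
                if val in (Pathogenicity.UNCERTAIN, Pathogenicity.UNANNOTATED):
                    continue
            else:
                val = rec.functional
                if val == Functional.UNANNOTATED:
                    continue
            values.append(val)
            kept.append(v)
        if len(kept) < 2:
            continue
        n_groups += 1
        n_variants += len(kept)
        if len(set(values)) == 1:
            n_coincident += 1
        else:
            discordant.append(VariantGroup(g.category, kept))
    return ConcordanceReport(
        category, annotation_kind, n_groups, n_variants, n_coincident, discordant
    )


# ---------------------------------------------------------------------------
# Per-domain identity / RMSD summary


def summarize_table1(
    chains: Mapping[str, ChainModel],
    domains: Mapping[str, Mapping[str, DomainDefinition]],
    pairs: Iterable[tuple[str, str]] = (("GluN2A", "GluN1"), ("GluN2B", "GluN1"), ("GluN2A", "GluN2B")),
    cycles: int = 5,
    reject_cutoff: float = 2.0,
    pairing_cutoff: float = 4.0,
    denominator: str = "columns",
) -> pd.DataFrame:
    """Per-domain-pair identical residues, identity percent and RMSD.

    For each subunit pair and domain the two sub-chains are extracted,
    superposed (seeded by a global sequence alignment of the structured
    residues, then refined with iterative outlier rejection) and the
    structure-based alignment is read off to compute identity statistics.
    The ATD is superposed as its two sublobes; sublobe RMSDs are reported
    separately while ATD identity is pooled over both sublobes, mirroring the
    conventional presentation."""
    rows = []
    for sub_a, sub_b in pairs:
        for domain_label, parts in (("ATD", ("ATD1", "ATD2")), ("LBD", ("LBD",)), ("TMD", ("TMD",))):
            part_alignments = []
            part_rmsd = {}
            for part in parts:
                dom_a = domains[sub_a][part]
                dom_b = domains[sub_b][part]
                a = extract_domain(chains[sub_a], dom_a)
                b = extract_domain(chains[sub_b], dom_b)
                a_struct = ChainModel(a.subunit, a.structured_residues(), a.source)
                b_struct = ChainModel(b.subunit, b.structured_residues(), b.source)
                seed = global_align(
                    a_struct.sequence,
                    b_struct.sequence,
                    positions_a=a_struct.positions,
                    positions_b=b_struct.positions,
                    subunit_pair=(sub_a, sub_b),
                    domain=part,
                )
                sup = iterative_superpose(a_struct, b_struct, seed, cycles, reject_cutoff)
                moved = ChainModel(
                    a_struct.subunit,
                    [
                        type(r)(r.subunit, r.pos, r.aa, tuple(sup.apply(r.ca_array)))
                        for r in a_struct.residues
                    ],
                    a_struct.source,
                )
                aln = derive_structural_alignment(
                    moved, b_struct, pairing_cutoff, subunit_pair=(sub_a, sub_b), domain=part
                )
                part_alignments.append(aln)
                part_rmsd[part] = sup.rmsd
            pooled = merge_alignments(part_alignments[0], *part_alignments[1:])
            ident, pct = identity_stats(pooled, denominator=denominator)
            row = {
                "pair": f"{sub_a}-{sub_b}",
                "domain": domain_label,
                "identical_residues": ident,
                "n_columns": pooled.n_columns,
                "identity_percent": round(pct, 2),
            }
            if len(parts) == 2:
                row["rmsd_ATD1"] = round(part_rmsd["ATD1"], 3)
                row["rmsd_ATD2"] = round(part_rmsd["ATD2"], 3)
                row["rmsd"] = float("nan")
            else:
                row["rmsd"] = round(part_rmsd[parts[0]], 3)
            rows.append(row)
    return pd.DataFrame(rows)
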