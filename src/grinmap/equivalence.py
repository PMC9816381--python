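"""Cross-subunit residue equivalence maps.

Per-domain structural alignments and sequence fallbacks are assembled into a
partial bijection of canonical positions for each GluN subunit pair.  A
position query then returns the equivalent position(s) in the other
subunit(s), which is what lets a missense variant in one subunit be matched
with its homolog in another.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import groupby
from pathlib import Path
from typing import Iterable

from .alignment import SEQUENCE, STRUCTURAL, ResidueAlignment
from .structures import SUBUNITS, check_subunit

# Canonical ordering of a subunit pair key.
_ORDER = {s: i for i, s in enumerate(SUBUNITS)}


def pair_key(sub_a: str, sub_b: str) -> tuple[str, str]:
    check_subunit(sub_a)
    check_subunit(sub_b)
    if sub_a == sub_b:
        raise ValueError("a subunit pair needs two distinct subunits")
    return (sub_a, sub_b) if _ORDER[sub_a] < _ORDER[sub_b] else (sub_b, sub_a)


@dataclass(frozen=True)
class Equivalence:
    """One mapped position pair (subunits implied by the containing map)."""

    pos_a: int
    pos_b: int
    aa_a: str
    aa_b: str
    domain: str | None
    provenance: str


class EquivalenceMap:
    """Partial bijections of canonical positions across GluN subunit pairs."""

    def __init__(self):
        self._fwd: dict[tuple[str, str], dict[int, Equivalence]] = {}
        self._rev: dict[tuple[str, str], dict[int, Equivalence]] = {}

    # -- construction -------------------------------------------------------

    def add(self, sub_a: str, sub_b: str, entry: Equivalence, replace: bool = False) -> None:
        key = pair_key(sub_a, sub_b)
        if key != (sub_a, sub_b):  # normalise orientation
            entry = Equivalence(
                entry.pos_b, entry.pos_a, entry.aa_b, entry.aa_a, entry.domain, entry.provenance
            )
        fwd = self._fwd.setdefault(key, {})
        rev = self._rev.setdefault(key, {})
        old_f = fwd.get(entry.pos_a)
        old_r = rev.get(entry.pos_b)
        for old in (old_f, old_r):
            if old is not None and (old.pos_a, old.pos_b) != (entry.pos_a, entry.pos_b):
                if not replace:
                    raise ValueError(
                        f"conflicting equivalence for {key}: "
                        f"{entry.pos_a}<->{entry.pos_b} vs {old.pos_a}<->{old.pos_b}"
                    )
                fwd.pop(old.pos_a, None)
                rev.pop(old.pos_b, None)
        fwd[entry.pos_a] = entry
        rev[entry.pos_b] = entry

    def pairs(self, sub_a: str, sub_b: str) -> list[Equivalence]:
        key = pair_key(sub_a, sub_b)
        entries = sorted(self._fwd.get(key, {}).values(), key=lambda e: e.pos_a)
        if key == (sub_a, sub_b):
            return entries
        return [
            Equivalence(e.pos_b, e.pos_a, e.aa_b, e.aa_a, e.domain, e.provenance)
            for e in sorted(entries, key=lambda e: e.pos_b)
        ]

    def subunit_pairs(self) -> list[tuple[str, str]]:
        return sorted(self._fwd, key=lambda k: (_ORDER[k[0]], _ORDER[k[1]]))

    # -- queries -------------------------------------------------------------

    def lookup(self, subunit: str, pos: int, partner: str) -> Equivalence | None:
        key = pair_key(subunit, partner)
        if key == (subunit, partner):
            return self._fwd.get(key, {}).get(pos)
        e = self._rev.get(key, {}).get(pos)
        if e is None:
            return None
        return Equivalence(e.pos_b, e.pos_a, e.aa_b, e.aa_a, e.domain, e.provenance)

    def map_position(self, subunit: str, pos: int) -> set[tuple[str, int, str]]:
        """Equivalent positions of (subunit, pos) in the other subunits.

        Returns a set of (partner_subunit, partner_pos, provenance); empty
        when the position is unmapped (e.g. CTD beyond fallback coverage).
        """
        check_subunit(subunit)
        out = set()
        for partner in SUBUNITS:
            if partner == subunit:
                continue
            e = self.lookup(subunit, pos, partner)
            if e is not None:
                out.add((partner, e.pos_b, e.provenance))
        return out


def build_map(
    domain_alignments: Iterable[ResidueAlignment],
    sequence_fallbacks: Iterable[ResidueAlignment] = (),
    min_fallback_run: int = 5,
) -> EquivalenceMap:
    """Assemble an EquivalenceMap from structural alignments and fallbacks.

    Structural entries are installed first and take precedence; sequence
    fallback pairs fill only positions not already mapped, and only inside
    runs of at least ``min_fallback_run`` consecutive aligned columns (a
    guard against spurious single-residue matches in low-identity regions).
    Conflicting structural claims for the same position raise.
    """
    emap = EquivalenceMap()
    for aln in domain_alignments:
        sub_a, sub_b = aln.subunit_pair
        for p in aln.pairs:
            emap.add(
                sub_a,
                sub_b,
                Equivalence(p.pos_a, p.pos_b, p.aa_a, p.aa_b, aln.domain, STRUCTURAL),
            )
    for aln in sequence_fallbacks:
        sub_a, sub_b = aln.subunit_pair
        for run in _consecutive_runs(aln.pairs):
            if len(run) < min_fallback_run:
                continue
            for p in run:
                if (
                    emap.lookup(sub_a, p.pos_a, sub_b) is not None
                    or emap.lookup(sub_b, p.pos_b, sub_a) is not None
                ):
                    continue  # structural (or earlier fallback) wins
                emap.add(
                    sub_a,
                    sub_b,
                    Equivalence(p.pos_a, p.pos_b, p.aa_a, p.aa_b, aln.domain, SEQUENCE),
                )
    return emap


def _consecutive_runs(pairs):
    """Split aligned pairs into maximal gap-free runs (both sides +1 steps)."""
    runs = []
    current = []
    for p in pairs:
        if current and (
            p.pos_a != current[-1].pos_a + 1 or p.pos_b != current[-1].pos_b + 1
        ):
            runs.append(current)
            current = []
        current.append(p)
    if current:
        runs.append(current)
    return runs


def map_position(emap: EquivalenceMap, subunit: str, pos: int) -> set[tuple[str, int, str]]:
    """Module-level convenience wrapper for EquivalenceMap.map_position."""
    return emap.map_position(subunit, pos)


def check_three_way_consistency(emap: EquivalenceMap) -> list[dict]:
    """Positions where GluN1->GluN2A composed with GluN2A->GluN2B disagrees
    with the direct GluN1->GluN2B entry.  Inconsistencies are reported, never
    auto-repaired; an empty list means the trio map is fully consistent."""
    report = []
    for e in emap.pairs("GluN1", "GluN2A"):
        via = emap.lookup("GluN2A", e.pos_b, "GluN2B")
        direct = emap.lookup("GluN1", e.pos_a, "GluN2B")
        if via is None or direct is None:
            continue
        if via.pos_b != direct.pos_b:
            report.append(
                {
                    "GluN1": e.pos_a,
                    "GluN2A": e.pos_b,
                    "GluN2B_via_GluN2A": via.pos_b,
                    "GluN2B_direct": direct.pos_b,
                }
            )
    return report


# -- serialization -----------------------------------------------------------


def to_json(emap: EquivalenceMap, path: str | Path | None = None) -> str:
    entries = []
    for sub_a, sub_b in emap.subunit_pairs():
        for e in emap.pairs(sub_a, sub_b):
            entries.append(
                {
                    "subunit_a": sub_a,
                    "pos_a": e.pos_a,
                    "aa_a": e.aa_a,
                    "subunit_b": sub_b,
                    "pos_b": e.pos_b,
                    "aa_b": e.aa_b,
                    "domain": e.domain,
                    "provenance": e.provenance,
                }
            )
    text = json.dumps({"equivalences": entries}, indent=1)
    if path is not None:
        Path(path).write_text(text)
    return text


def from_json(source: str | Path) -> EquivalenceMap:
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and Path(source).exists()):
        text = Path(source).read_text()
    else:
        text = source
    obj = json.loads(text)
    emap = EquivalenceMap()
    for e in obj["equivalences"]:
        emap.add(
            e["subunit_a"],
            e["subunit_b"],
            Equivalence(
                int(e["pos_a"]), int(e["pos_b"]), e["aa_a"], e["aa_b"],
                e.get("domain"), e["provenance"],
            ),
        )
    return emap
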