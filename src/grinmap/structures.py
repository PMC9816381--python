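"""Structure input and residue bookkeeping for GluN subunit chains.

The NMDA receptor subunits handled here (GluN1, GluN2A, GluN2B) are read from
PDB/mmCIF files, carved into topological domains (amino-terminal domain with
its two sublobes, ligand-binding domain, transmembrane domain) and renumbered
onto canonical full-length coordinates — the 1-based positions of the UniProt
canonical human sequences, signal peptide included, which is the numbering
used by clinical HGVS p. variant names.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

from ._aa import AA3_TO_1, STANDARD_AA

SUBUNITS = ("GluN1", "GluN2A", "GluN2B")
GENE_TO_SUBUNIT = {"GRIN1": "GluN1", "GRIN2A": "GluN2A", "GRIN2B": "GluN2B"}
SUBUNIT_TO_GENE = {v: k for k, v in GENE_TO_SUBUNIT.items()}
DOMAINS = ("ATD1", "ATD2", "LBD", "TMD")

# Residues treated as a standard parent at parse time.
_MODIFIED_PARENT = {"MSE": "MET"}


def check_subunit(subunit: str) -> str:
    if subunit not in SUBUNITS:
        raise ValueError(f"unknown subunit {subunit!r}; expected one of {SUBUNITS}")
    return subunit


@dataclass(frozen=True)
class ResidueSite:
    """One residue position of a subunit chain.

    ``ca`` is the alpha-carbon coordinate in Å, or None for residues whose
    sequence is known (from the entity record) but that are structurally
    unresolved.
    """

    subunit: str
    pos: int
    aa: str  # 1-letter
    ca: tuple[float, float, float] | None = None

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"canonical position must be >= 1, got {self.pos}")
        if self.aa not in STANDARD_AA:
            raise ValueError(f"non-standard residue {self.aa!r} at position {self.pos}")

    @property
    def structured(self) -> bool:
        return self.ca is not None

    @property
    def ca_array(self) -> np.ndarray:
        if self.ca is None:
            raise ValueError(f"residue {self.pos} has no coordinates")
        return np.asarray(self.ca, dtype=float)


@dataclass
class ChainModel:
    """Ordered residues of one subunit chain, strictly increasing in position."""

    subunit: str
    residues: list[ResidueSite]
    source: str = ""

    def __post_init__(self):
        check_subunit(self.subunit)
        if not self.residues:
            raise ValueError("ChainModel must contain at least one residue")
        pos = [r.pos for r in self.residues]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("residue positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self):
        return iter(self.residues)

    @property
    def positions(self) -> list[int]:
        return [r.pos for r in self.residues]

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def structured_residues(self) -> list[ResidueSite]:
        return [r for r in self.residues if r.structured]

    def site(self, pos: int) -> ResidueSite:
        i = self._index().get(pos)
        if i is None:
            raise KeyError(f"{self.subunit} has no residue at position {pos}")
        return self.residues[i]

    def __contains__(self, pos: int) -> bool:
        return pos in self._index()

    def _index(self) -> dict[int, int]:
        idx = getattr(self, "_pos_index", None)
        if idx is None or len(idx) != len(self.residues):
            idx = {r.pos: i for i, r in enumerate(self.residues)}
            self._pos_index = idx
        return idx

    def coords(self, positions: Iterable[int]) -> np.ndarray:
        """Stack alpha-carbon coordinates for the given canonical positions."""
        return np.array([self.site(p).ca_array for p in positions], dtype=float)


@dataclass(frozen=True)
class DomainDefinition:
    """Canonical-position ranges of one topological domain of one subunit.

    Ranges are 1-based inclusive [start, end] intervals; the ligand-binding
    domain (S1 + S2) and the transmembrane domain (M1-M3 + M4) are
    discontinuous in sequence and therefore carry two intervals.
    """

    subunit: str
    domain: str
    ranges: tuple[tuple[int, int], ...]

    def __post_init__(self):
        check_subunit(self.subunit)
        if self.domain not in DOMAINS:
            raise ValueError(f"unknown domain {self.domain!r}; expected one of {DOMAINS}")
        last_end = 0
        for start, end in self.ranges:
            if start > end:
                raise ValueError(f"invalid interval [{start}, {end}]")
            if start <= last_end:
                raise ValueError("domain intervals must be sorted and non-overlapping")
            last_end = end

    def __contains__(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.ranges)

    @property
    def n_positions(self) -> int:
        return sum(e - s + 1 for s, e in self.ranges)


class NumberingMap:
    """Monotone partial map construct position -> canonical position.

    Deposited constructs (and the rat GluN2B structure) do not use human
    canonical numbering; this map rewrites them.  Built either from explicit
    offset segments or from a pairwise sequence alignment.
    """

    def __init__(self, pairs: Iterable[tuple[int, int]]):
        items = sorted(pairs)
        canon = [c for _, c in items]
        if any(b <= a for a, b in zip(canon, canon[1:])):
            raise ValueError("numbering map must be strictly increasing")
        self._map = dict(items)

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, construct_pos: int) -> bool:
        return construct_pos in self._map

    def __getitem__(self, construct_pos: int) -> int:
        return self._map[construct_pos]

    def get(self, construct_pos: int, default=None):
        return self._map.get(construct_pos, default)

    def items(self):
        return self._map.items()

    def inverse(self) -> "NumberingMap":
        return NumberingMap((c, k) for k, c in self._map.items())

    @classmethod
    def identity(cls, positions: Iterable[int]) -> "NumberingMap":
        return cls((p, p) for p in positions)

    @classmethod
    def from_offset(cls, start: int, end: int, offset: int) -> "NumberingMap":
        return cls((p, p + offset) for p in range(start, end + 1))

    @classmethod
    def from_alignment(cls, alignment) -> "NumberingMap":
        """Build from a ResidueAlignment (construct side = A, canonical = B)."""
        return cls((p.pos_a, p.pos_b) for p in alignment.pairs)

    def to_json_obj(self) -> list[list[int]]:
        return [[k, v] for k, v in sorted(self._map.items())]

    @classmethod
    def from_json_obj(cls, obj: Sequence[Sequence[int]]) -> "NumberingMap":
        return cls((int(a), int(b)) for a, b in obj)


# ---------------------------------------------------------------------------
# Structure reading


def read_structure(
    path: str | Path,
    format: str | None = None,
    subunit_of_chain: Mapping[str, str] | None = None,
    default_subunit: str | None = None,
) -> list[ChainModel]:
    """Read a PDB or mmCIF file into one ChainModel per polymer chain.

    Parameters
    ----------
    path : structure file (PDB or mmCIF; gzip accepted).
    format : "PDB" or "mmCIF"; inferred from the file name when omitted.
    subunit_of_chain : chain-name -> subunit assignment.  Chains without an
        assignment fall back to ``default_subunit`` and are skipped (with a
        warning) when that is None.

    Alternate locations keep the highest-occupancy conformer (first in file on
    ties); selenomethionine is read as methionine; other non-standard residues
    are dropped with a warning.  Residues present in the entity record
    (SEQRES) but missing from the coordinates are emitted as coordinate-absent
    sites when their author numbering can be inferred from flanking residues.
    """
    path = Path(path)
    try:
        if format is not None:
            formats = {"PDB": gemmi.CoorFormat.Pdb, "MMCIF": gemmi.CoorFormat.Mmcif}
            try:
                fmt = formats[format.upper()]
            except KeyError:
                raise ValueError(f"format must be PDB or mmCIF, got {format!r}") from None
            st = gemmi.read_structure(str(path), format=fmt)
        else:
            st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError, KeyError) as exc:
        raise ValueError(f"cannot parse structure file {path}: {exc}") from exc

    st.setup_entities()
    st.remove_alternative_conformations()  # keeps highest occupancy / first

    chains: list[ChainModel] = []
    model = st[0]
    for chain in model:
        polymer = chain.get_polymer()
        if len(polymer) == 0:
            continue
        name = chain.name
        if subunit_of_chain is not None and name in subunit_of_chain:
            subunit = subunit_of_chain[name]
        elif default_subunit is not None:
            subunit = default_subunit
        elif subunit_of_chain is not None:
            warnings.warn(f"chain {name}: no subunit assignment, skipped")
            continue
        else:
            raise ValueError(
                "read_structure needs subunit_of_chain and/or default_subunit "
                "to assign chains to GluN subunits"
            )
        check_subunit(subunit)

        sites: list[ResidueSite] = []
        resolved: dict[int, str] = {}
        for res in polymer:
            rname = _MODIFIED_PARENT.get(res.name, res.name)
            one = AA3_TO_1.get(rname.capitalize())
            if one is None:
                warnings.warn(
                    f"{path.name} chain {name}: dropping non-standard residue "
                    f"{res.name} {res.seqid.num}"
                )
                continue
            ca = res.find_atom("CA", "*")
            if ca is None:
                continue
            sites.append(
                ResidueSite(subunit, res.seqid.num, one, (ca.pos.x, ca.pos.y, ca.pos.z))
            )
            resolved[res.seqid.num] = one

        if not sites:
            warnings.warn(f"{path.name} chain {name}: no alpha carbons, chain skipped")
            continue

        entity = st.get_entity_of(polymer)
        sites.extend(
            _unresolved_sites(entity, subunit, resolved, {s.pos for s in sites})
        )
        sites.sort(key=lambda s: s.pos)
        chains.append(ChainModel(subunit, sites, source=f"{path.name}:{name}"))
    if not chains:
        raise ValueError(f"no usable polymer chains found in {path}")
    return chains


def _unresolved_sites(entity, subunit, resolved, taken) -> list[ResidueSite]:
    """Coordinate-absent sites for entity (SEQRES) residues missing from the
    coordinates.

    Depositions keep author numbering counting through unmodelled stretches,
    so one constant offset relates author numbering to the SEQRES index; the
    offset is inferred by requiring every resolved residue to match the
    entity sequence, and missing indices are then emitted as sites without
    coordinates.  Chains whose numbering admits no (or no unique) constant
    offset are left as-is.
    """
    sites: list[ResidueSite] = []
    if entity is None or not entity.full_sequence or not resolved:
        return sites
    full = []
    for item in entity.full_sequence:
        name = _MODIFIED_PARENT.get(gemmi.Entity.first_mon(item), gemmi.Entity.first_mon(item))
        full.append(AA3_TO_1.get(str(name).capitalize()))
    n = len(full)
    min_a, max_a = min(resolved), max(resolved)
    # SEQRES index i (1-based) = author position + delta
    deltas = [
        d
        for d in range(1 - min_a, n - max_a + 1)
        if all(full[a + d - 1] == aa for a, aa in resolved.items())
    ]
    if not deltas:
        return sites
    delta = min(deltas, key=abs)
    for i in range(1, n + 1):
        pos = i - delta
        one = full[i - 1]
        if one is None or pos < 1 or pos in taken:
            continue
        sites.append(ResidueSite(subunit, pos, one, None))
        taken.add(pos)
    return sites


def renumber(chain: ChainModel, mapping: NumberingMap, strict: bool = True) -> ChainModel:
    """Rewrite chain positions through a numbering map.

    With ``strict`` every residue must be mapped; otherwise unmapped residues
    are dropped.
    """
    unmapped = [r.pos for r in chain.residues if r.pos not in mapping]
    if unmapped and strict:
        raise ValueError(
            f"renumber: {len(unmapped)} unmapped positions in {chain.subunit} "
            f"(first few: {unmapped[:8]})"
        )
    residues = [
        replace(r, pos=mapping[r.pos]) for r in chain.residues if r.pos in mapping
    ]
    if not residues:
        raise ValueError("renumber: no residues left after dropping unmapped positions")
    return ChainModel(chain.subunit, residues, source=chain.source)


def extract_domain(chain: ChainModel, dom: DomainDefinition) -> ChainModel:
    """Return the sub-chain whose canonical positions fall in the domain ranges."""
    if dom.subunit != chain.subunit:
        raise ValueError(
            f"domain is defined for {dom.subunit} but chain is {chain.subunit}"
        )
    residues = [r for r in chain.residues if r.pos in dom]
    if not residues:
        raise ValueError(
            f"extract_domain: no {chain.subunit} residues in {dom.domain} ranges "
            f"{dom.ranges} — domain/structure mismatch?"
        )
    return ChainModel(chain.subunit, residues, source=f"{chain.source}[{dom.domain}]")


# ---------------------------------------------------------------------------
# Domain configuration IO


def load_domain_config(path: str | Path) -> dict[str, dict[str, DomainDefinition]]:
    """Load {subunit: {domain: DomainDefinition}} from a JSON config.

    Expected layout: {"domains": [{"subunit": ..., "domain": ...,
    "ranges": [[start, end], ...]}, ...]} with 1-based inclusive ranges.
    """
    with open(path) as fh:
        obj = json.load(fh)
    out: dict[str, dict[str, DomainDefinition]] = {}
    for entry in obj["domains"]:
        d = DomainDefinition(
            entry["subunit"],
            entry["domain"],
            tuple((int(s), int(e)) for s, e in entry["ranges"]),
        )
        out.setdefault(d.subunit, {})[d.domain] = d
    return out


def dump_domain_config(
    domains: Iterable[DomainDefinition], path: str | Path, note: str | None = None
) -> None:
    obj = {
        "domains": [
            {"subunit": d.subunit, "domain": d.domain, "ranges": [list(r) for r in d.ranges]}
            for d in domains
        ]
    }
    if note:
        obj["note"] = note
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1)


def default_domain_config() -> dict[str, dict[str, DomainDefinition]]:
    """The domain definitions shipped with the package (see data/domains.json)."""
    here = Path(__file__).parent / "data" / "domains.json"
    return load_domain_config(here)
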