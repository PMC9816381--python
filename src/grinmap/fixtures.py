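"""Deterministic synthetic fixtures: toy structure pairs with known
ground-truth correspondence, toy variant databases with planted annotation
structure, and a complete synthetic GluN1/GluN2A/GluN2B demo workspace.

Everything here is generated, never downloaded.  The demo trio emulates the
salient features of the real subunits that the algorithm depends on —
per-domain topology (ATD sublobes, split LBD and TMD, unsolved signal
peptide and CTD), a one-residue canonical-numbering offset between GluN2A
and GluN2B (and two between GluN1 and GluN2B), per-domain sequence-identity
gradients, and a deposited-construct numbering that differs from canonical —
while the coordinates themselves are idealised helices, not receptor
geometry.  All randomness flows from an explicit per-spec seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import gemmi
import numpy as np

from ._aa import AA1_TO_3
from .alignment import STRUCTURAL, AlignedPair, ResidueAlignment
from .equivalence import EquivalenceMap
from .structures import ChainModel, DomainDefinition, ResidueSite, dump_domain_config
from .variants import (
    AnnotationRecord,
    Functional,
    Pathogenicity,
    ProteinVariant,
    VariantDatabase,
    write_variant_table,
)

_AA = "ACDEFGHIKLMNPQRSTVWY"


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def helix_coords(
    n: int, twist_deg: float = 100.0, rise: float = 1.5, radius: float = 2.3
) -> np.ndarray:
    """Alpha-carbon trace of an ideal helix (default: 100° twist and 1.5 Å
    rise per residue)."""
    t = np.arange(n)
    ang = np.deg2rad(twist_deg) * t
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang), rise * t])


def zigzag_coords(n: int, step: float = 3.5, amplitude: float = 1.0) -> np.ndarray:
    t = np.arange(n)
    return np.column_stack([step * t, amplitude * (t % 2), np.zeros(n)])


@dataclass
class ToyStructureSpec:
    """Recipe for a toy chain pair with known correspondence.

    Chain B is a rigid transform of chain A plus Gaussian coordinate noise
    plus explicit per-residue displacements; the ground-truth residue
    correspondence (identity up to ``offset_b``) is returned alongside."""

    n_residues: int = 50
    topology: str = "ideal_helix"  # or "zigzag_sheet"
    noise_sigma: float = 0.0
    displaced_positions: tuple[tuple[int, tuple[float, float, float]], ...] = ()
    offset_b: int = 0  # canonical numbering of B = numbering of A + offset
    subunit_a: str = "GluN2A"
    subunit_b: str = "GluN2B"
    seed: int = 0

    def __post_init__(self):
        if self.n_residues < 4:
            raise ValueError("toy structures need at least 4 residues")
        if self.topology not in ("ideal_helix", "zigzag_sheet"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def make_structure_pair(
    spec: ToyStructureSpec,
) -> tuple[ChainModel, ChainModel, ResidueAlignment, dict]:
    """Build the toy pair; returns (chain_a, chain_b, ground_truth, transform).

    ``transform`` holds the rotation/translation applied to produce B, for
    tests that assert rotation recovery."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_residues
    coords = helix_coords(n) if spec.topology == "ideal_helix" else zigzag_coords(n)
    seq = "".join(rng.choice(list(_AA), size=n))
    R = _random_rotation(rng)
    t = rng.uniform(-20, 20, size=3)
    coords_b = coords @ R.T + t
    if spec.noise_sigma > 0:
        coords_b = coords_b + rng.normal(scale=spec.noise_sigma, size=coords_b.shape)
    for pos, offset in spec.displaced_positions:
        coords_b[pos - 1] = coords_b[pos - 1] + np.asarray(offset, dtype=float)

    chain_a = ChainModel(
        spec.subunit_a,
        [
            ResidueSite(spec.subunit_a, i + 1, seq[i], tuple(coords[i]))
            for i in range(n)
        ],
        source=f"toy:{spec.seed}:A",
    )
    chain_b = ChainModel(
        spec.subunit_b,
        [
            ResidueSite(spec.subunit_b, i + 1 + spec.offset_b, seq[i], tuple(coords_b[i]))
            for i in range(n)
        ],
        source=f"toy:{spec.seed}:B",
    )
    truth = ResidueAlignment(
        (spec.subunit_a, spec.subunit_b),
        [
            AlignedPair(i + 1, i + 1 + spec.offset_b, seq[i], seq[i], STRUCTURAL)
            for i in range(n)
        ],
        n_columns=n,
    )
    return chain_a, chain_b, truth, {"rotation": R, "translation": t}


def write_pdb(chains: Sequence[ChainModel], path: str | Path, name: str = "SYNTHETIC") -> None:
    """Write chains as a CA-only PDB file with SEQRES records.

    Residues without coordinates appear in SEQRES only, which is how real
    depositions represent unresolved stretches."""
    st = gemmi.Structure()
    st.name = name
    model = gemmi.Model("1")
    chain_ids = "ABCDEFGH"
    for idx, cm in enumerate(chains):
        chain = gemmi.Chain(chain_ids[idx])
        for site in cm.residues:
            if not site.structured:
                continue
            res = gemmi.Residue()
            res.name = AA1_TO_3[site.aa].upper()
            res.seqid = gemmi.SeqId(site.pos, " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            x, y, z = site.ca
            atom.pos = gemmi.Position(x, y, z)
            atom.occ = 1.0
            res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    # attach full sequences (SEQRES) per chain entity
    subchain_to_chain = {
        res.subchain: ch.name for ch in st[0] for res in ch
    }
    full_seq_of_chain = {
        chain_ids[idx]: [AA1_TO_3[s.aa].upper() for s in cm.residues]
        for idx, cm in enumerate(chains)
    }
    for ent in st.entities:
        for sub in ent.subchains:
            chain_name = subchain_to_chain.get(sub)
            if chain_name in full_seq_of_chain:
                ent.full_sequence = full_seq_of_chain[chain_name]
    st.assign_label_seq_id()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Toy variant databases


@dataclass
class ToyVariantSpec:
    """Recipe for a planted-annotation variant database over a built map.

    ``n_groups`` homologous pairs are planted at mapped identical-residue
    positions; each annotated pair agrees in class with probability
    ``concordance_p``.  Class draws follow ``pathogenic_frac`` (the rest
    benign) and uniform LoF/GoF for the functional dimension."""

    n_groups: int = 50
    fraction_annotated: float = 1.0
    concordance_p: float = 1.0
    pathogenic_frac: float = 0.6
    with_functional: bool = True
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.concordance_p <= 1.0):
            raise ValueError("concordance_p must be in [0, 1]")
        if not (0.0 <= self.fraction_annotated <= 1.0):
            raise ValueError("fraction_annotated must be in [0, 1]")


def make_variant_db(
    spec: ToyVariantSpec,
    emap: EquivalenceMap,
    subunit_pair: tuple[str, str] = ("GluN2A", "GluN2B"),
) -> tuple[VariantDatabase, list[dict]]:
    """Plant homologous variant pairs on an equivalence map.

    Returns the database plus a ledger: one entry per planted group recording
    positions, classes, the agreement flag and whether both members are
    annotated.  Ledger counts are the ground truth that concordance reports
    must reconcile with."""
    rng = np.random.default_rng(spec.seed)
    sub_a, sub_b = subunit_pair
    entries = [e for e in emap.pairs(sub_a, sub_b) if e.aa_a == e.aa_b]
    if len(entries) < spec.n_groups:
        raise ValueError(
            f"map offers {len(entries)} identical-residue pairs, "
            f"need {spec.n_groups} groups"
        )
    picked = rng.choice(len(entries), size=spec.n_groups, replace=False)
    # exact-count planting: the realized agreement rate equals the planted
    # rate (up to rounding); which groups disagree is randomized
    n_agree = int(round(spec.concordance_p * spec.n_groups))
    agree_flags = np.zeros(spec.n_groups, dtype=bool)
    agree_flags[rng.permutation(spec.n_groups)[:n_agree]] = True
    db = VariantDatabase()
    ledger: list[dict] = []
    for g, k in enumerate(sorted(picked)):
        e = entries[k]
        alt = rng.choice([a for a in _AA if a != e.aa_a])
        v_a = ProteinVariant(sub_a, e.pos_a, e.aa_a, alt)
        v_b = ProteinVariant(sub_b, e.pos_b, e.aa_b, alt)
        path_class = (
            Pathogenicity.PATHOGENIC
            if rng.random() < spec.pathogenic_frac
            else Pathogenicity.BENIGN
        )
        func_class = Functional.LOF if rng.random() < 0.5 else Functional.GOF
        agree = bool(agree_flags[g])
        path_b = path_class if agree else (
            Pathogenicity.BENIGN
            if path_class == Pathogenicity.PATHOGENIC
            else Pathogenicity.PATHOGENIC
        )
        func_b = func_class if agree else (
            Functional.GOF if func_class == Functional.LOF else Functional.LOF
        )
        annotated_a = bool(rng.random() < spec.fraction_annotated)
        annotated_b = bool(rng.random() < spec.fraction_annotated)
        rec_a = AnnotationRecord(
            path_class if annotated_a else Pathogenicity.UNANNOTATED,
            (func_class if spec.with_functional else Functional.UNANNOTATED)
            if annotated_a
            else Functional.UNANNOTATED,
            source="planted",
        )
        rec_b = AnnotationRecord(
            path_b if annotated_b else Pathogenicity.UNANNOTATED,
            (func_b if spec.with_functional else Functional.UNANNOTATED)
            if annotated_b
            else Functional.UNANNOTATED,
            source="planted",
        )
        db.add(v_a, rec_a)
        db.add(v_b, rec_b)
        ledger.append(
            {
                "variant_a": str(v_a),
                "variant_b": str(v_b),
                "pathogenicity_a": rec_a.pathogenicity.value,
                "pathogenicity_b": rec_b.pathogenicity.value,
                "functional_a": rec_a.functional.value,
                "functional_b": rec_b.functional.value,
                "agree": agree,
                "annotated_a": annotated_a,
                "annotated_b": annotated_b,
            }
        )
    return db, ledger


def make_concordance_benchmark() -> tuple[EquivalenceMap, VariantDatabase, dict]:
    """Synthetic concordance benchmark with a prescribed group structure.

    Builds a toy trio equivalence map plus a variant database laid out to a
    fixed census of comparison groups — everything about the individual
    variants (positions, residues) is fabricated; only the group/annotation
    structure is meaningful.  The census:

    * homologous: 33 groups (21 trios, 12 pairs, 87 variants); 9 members are
      uncertain, leaving 78 confidently annotated variants (28 benign, 50
      pathogenic) that agree within every group; 8 groups additionally carry
      coincident functional annotations.
    * same-final (different initial residues, same final): 13 groups, 27
      variants, 12 coincident — the discordant one is a benign GluN1
      Lys685Arg against a pathogenic GluN2B Pro687Arg.
    * same-initial (same initial residue, different finals): 72 groups, 210
      variants, 59 coincident in pathogenicity; 30 groups carry two
      functional annotations of which 23 agree.

    Returns (map, database, expected) where ``expected`` records the census
    for assertions.
    """
    from .equivalence import Equivalence

    emap = EquivalenceMap()
    db = VariantDatabase()
    next_pos = [10]

    def new_class(aa1="A", aa2a="A", aa2b="A", pos=None):
        p = pos if pos is not None else next_pos[0]
        if pos is None:
            next_pos[0] += 3
        emap.add("GluN1", "GluN2A", Equivalence(p, p + 1, aa1, aa2a, "LBD", STRUCTURAL))
        emap.add("GluN1", "GluN2B", Equivalence(p, p + 2, aa1, aa2b, "LBD", STRUCTURAL))
        emap.add("GluN2A", "GluN2B", Equivalence(p + 1, p + 2, aa2a, aa2b, "LBD", STRUCTURAL))
        return p

    P, B, U = Pathogenicity.PATHOGENIC, Pathogenicity.BENIGN, Pathogenicity.UNCERTAIN

    def member(subunit, cls_pos, ref, alt, path, func=Functional.UNANNOTATED):
        offset = {"GluN1": 0, "GluN2A": 1, "GluN2B": 2}[subunit]
        v = ProteinVariant(subunit, cls_pos + offset, ref, alt)
        db.add(v, AnnotationRecord(path, func, "benchmark"))
        return v

    # --- homologous groups -------------------------------------------------
    # post-filter composition: 12 trios (2 benign, 10 pathogenic) and 21
    # pairs (11 benign, 10 pathogenic); 9 pairs get a third, uncertain member
    trio_classes = [B] * 2 + [P] * 10
    pair_classes = [B] * 11 + [P] * 10
    func_cycle = [Functional.LOF, Functional.GOF]
    n_func_groups = 0
    for i, cls in enumerate(trio_classes + pair_classes):
        trio = i < len(trio_classes)
        p = new_class("G", "G", "G")
        func = func_cycle[i % 2] if n_func_groups < 8 else Functional.UNANNOTATED
        if func != Functional.UNANNOTATED:
            n_func_groups += 1
        member("GluN1", p, "G", "R", cls, func)
        member("GluN2A", p, "G", "R", cls, func)
        if trio:
            member("GluN2B", p, "G", "R", cls)
        elif i - len(trio_classes) < 9:  # originally a trio; third member VUS
            member("GluN2B", p, "G", "R", U)

    # --- same-final groups ---------------------------------------------------
    # 12 coincident (one of them a trio, for 27 variants total) + the
    # discordant GluN1 p.(Lys685Arg) / GluN2B p.(Pro687Arg) pair
    for j in range(12):
        p = new_class("S", "T", "N")
        cls = P if j % 2 else B
        member("GluN1", p, "S", "W", cls)
        member("GluN2B", p, "N", "W", cls)
        if j == 0:
            member("GluN2A", p, "T", "W", cls)
    p685 = new_class("K", "Q", "P", pos=685)
    member("GluN1", p685, "K", "R", B)
    member("GluN2B", p685, "P", "R", P)

    # --- same-initial groups -------------------------------------------------
    # 66 trios + 6 pairs = 210 variants; 59 coincident in pathogenicity;
    # the first 30 groups carry two functional annotations (23 agree)
    n_coincident = 0
    for k in range(72):
        trio = k < 66
        p = new_class("H", "H", "H")
        coincident = k >= 13  # 59 of 72
        cls = P if k % 2 else B
        other = B if cls == P else P
        funcs = [Functional.UNANNOTATED] * 3
        if k < 30:
            agree_func = k >= 7  # 23 of 30
            funcs[0] = Functional.LOF
            funcs[1] = Functional.LOF if agree_func else Functional.GOF
        member("GluN1", p, "H", "Y", cls, funcs[0])
        member("GluN2A", p, "H", "Q", cls if coincident else other, funcs[1])
        if trio:
            member("GluN2B", p, "H", "D", cls, funcs[2])
        if coincident:
            n_coincident += 1

    expected = {
        "homologous": {"n_groups": 33, "n_variants": 78, "n_coincident": 33},
        "homologous_functional": {"n_groups": 8, "n_coincident": 8},
        "same_final": {"n_groups": 13, "n_variants": 27, "n_coincident": 12},
        "same_initial": {"n_groups": 72, "n_variants": 210, "n_coincident": 59},
        "same_initial_functional": {"n_groups": 30, "n_coincident": 23},
    }
    return emap, db, expected


# ---------------------------------------------------------------------------
# Synthetic GluN trio demo workspace


# Architecture in GluN2A canonical coordinates; GluN1 = -1, GluN2B = +1.
_ARCH_2A = {
    "signal": (1, 19),
    "ATD1": ((20, 209),),
    "ATD2": ((210, 419),),
    "LBD": ((420, 551), (658, 842)),
    "TMD": ((552, 657), (843, 876)),
    "solved": (20, 876),
    "length": 1464,
}
_OFFSETS = {"GluN1": -1, "GluN2A": 0, "GluN2B": +1}
_LENGTHS = {"GluN1": 938, "GluN2A": 1464, "GluN2B": 1484}
# Per-domain substitution probabilities applied when deriving each partner
# from the master sequence (tuned so pairwise identities fall in the
# realistic ATD < LBD < TMD gradient).
_MUT_RATES = {
    "GluN2B": {"ATD": 0.45, "LBD": 0.16, "TMD": 0.068, "other": 0.45},
    "GluN1": {"ATD": 0.70, "LBD": 0.65, "TMD": 0.65, "other": 0.75},
}
# Anchor residues, GluN2B canonical numbering -> reference residue; the same
# residue is planted at the equivalent GluN2A (pos-1) and, where listed, the
# GluN1 member of the printed comparison pairs.
_ANCHORS_2B = {459: "G", 484: "G", 532: "T", 543: "G", 689: "G", 693: "R", 820: "G", 824: "M"}
_ANCHOR_PAIRS = [  # (GluN2B pos, ref, alt) for the demo variant table
    (459, "G", "R"),
    (484, "G", "D"),
    (532, "T", "A"),
    (543, "G", "R"),
    (689, "G", "S"),
    (693, "R", "G"),
    (820, "G", "A"),
    (820, "G", "E"),
    (824, "M", "V"),
]
_SAME_FINAL_ANCHOR = {"GluN1_pos": 685, "GluN1_ref": "K", "GluN2B_pos": 687, "GluN2B_ref": "P", "alt": "R"}


def _domain_of_2a(pos: int) -> str:
    for name in ("ATD1", "ATD2", "LBD", "TMD"):
        for s, e in _ARCH_2A[name]:
            if s <= pos <= e:
                return "ATD" if name.startswith("ATD") else name
    return "other"


def trio_domain_definitions() -> list[DomainDefinition]:
    out = []
    for subunit, off in _OFFSETS.items():
        for name in ("ATD1", "ATD2", "LBD", "TMD"):
            ranges = tuple((s + off, e + off) for s, e in _ARCH_2A[name])
            out.append(DomainDefinition(subunit, name, ranges))
    return out


def make_trio_sequences(seed: int) -> dict[str, str]:
    """Three canonical subunit sequences with planted offsets and anchors.

    GluN2A is the master; GluN2B inserts one residue after the signal peptide
    (canonical offset +1) and appends a longer CTD; GluN1 deletes one residue
    there (offset -1) and truncates the CTD.  Per-domain substitution rates
    produce the identity gradient; anchor residues from the printed variant
    positions are planted last on every subunit."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    L = _ARCH_2A["length"]
    master = rng.choice(list(_AA), size=L)
    # Shared per-site variability (rate heterogeneity among sites): a single
    # uniform draw per site decides which subunits diverge there, so a site
    # mutable in the less-diverged subunit is also mutable in the more-diverged
    # one.  This keeps cross-pair identities near the per-subunit levels, as
    # in real protein families, instead of collapsing to their product.
    site_u = rng.uniform(size=L)

    def mutate(arr, rates):
        arr = arr.copy()
        for i in range(len(arr)):
            dom = _domain_of_2a(i + 1)
            rate = rates["ATD"] if dom == "ATD" else rates.get(dom, rates["other"])
            if site_u[i] < rate:
                arr[i] = rng.choice([a for a in _AA if a != arr[i]])
        return arr

    seq_2a = master.copy()
    b_core = mutate(master, _MUT_RATES["GluN2B"])
    # GluN2B canonical p maps to GluN2A p-1: one residue inserted at GluN2B
    # position 20 (inside the extended signal peptide) shifts every position
    # from 21 on by +1.
    b_list = list(b_core)
    b_list.insert(19, "S")
    tail = rng.choice(list(_AA), size=_LENGTHS["GluN2B"] - len(b_list))
    seq_2b = np.array(b_list + list(tail))

    n1_core = mutate(master, _MUT_RATES["GluN1"])
    n1_list = list(n1_core)
    del n1_list[18]  # GluN1 position p maps to GluN2A p+1 from position 19 on
    seq_n1 = np.array(n1_list[: _LENGTHS["GluN1"]])

    seqs = {"GluN1": seq_n1, "GluN2A": seq_2a, "GluN2B": seq_2b}
    for pos_2b, aa in _ANCHORS_2B.items():
        seqs["GluN2B"][pos_2b - 1] = aa
        seqs["GluN2A"][pos_2b - 2] = aa  # GluN2A = GluN2B - 1
        seqs["GluN1"][pos_2b - 3] = aa   # GluN1 = GluN2B - 2
    sf = _SAME_FINAL_ANCHOR
    seqs["GluN1"][sf["GluN1_pos"] - 1] = sf["GluN1_ref"]
    seqs["GluN2B"][sf["GluN2B_pos"] - 1] = sf["GluN2B_ref"]
    seqs["GluN2A"][sf["GluN2B_pos"] - 2] = "Q"  # distinct initial residue at the trio site
    return {k: "".join(v) for k, v in seqs.items()}


def make_trio_chains(
    sequences: Mapping[str, str], seed: int, noise_sigma: float = 0.25
) -> dict[str, ChainModel]:
    """Chains over the solved region: shared master-frame helix coordinates
    plus per-chain Gaussian noise; signal peptide and CTD stay coordinate-
    absent.  Coordinates are in the master frame — workspace writing applies
    per-file rigid transforms."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    s0, s1 = _ARCH_2A["solved"]
    n = s1 - s0 + 1
    # An ideal helix carries a screw symmetry: shifting the register by k
    # residues is itself a rigid motion, so a mis-seeded superposition could
    # lock onto a shifted overlap.  A smooth deterministic meander (shared by
    # all chains) breaks that symmetry while keeping local geometry realistic.
    m = np.arange(n, dtype=float)
    meander = np.column_stack(
        [3.0 * np.sin(m / 7.3), 3.0 * np.cos(m / 11.1), 2.0 * np.sin(m / 17.9)]
    )
    master_xyz = helix_coords(n) + meander
    chains = {}
    for subunit, seq in sequences.items():
        off = _OFFSETS[subunit]
        sites = []
        for pos in range(1, len(seq) + 1):
            m = pos - off  # master (GluN2A) coordinate
            if s0 <= m <= s1:
                xyz = master_xyz[m - s0] + rng.normal(scale=noise_sigma, size=3)
                sites.append(ResidueSite(subunit, pos, seq[pos - 1], tuple(xyz)))
            else:
                sites.append(ResidueSite(subunit, pos, seq[pos - 1], None))
        chains[subunit] = ChainModel(subunit, sites, source=f"trio:{seed}:{subunit}")
    return chains


def make_trio_variant_table(
    sequences: Mapping[str, str], seed: int, n_extra_groups: int = 40, concordance_p: float = 1.0
) -> tuple[VariantDatabase, list[dict]]:
    """Demo variant table: the nine printed GluN2B pathogenic variants (their
    GluN2A homolog left unannotated, for the transfer demo), one same-final
    GluN1/GluN2B pair, and ``n_extra_groups`` random annotated homologous
    GluN2A/GluN2B pairs with planted agreement probability."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))
    db = VariantDatabase()
    ledger = []
    func_cycle = [Functional.LOF, Functional.GOF, Functional.LOF, Functional.COMPLEX]
    for i, (pos_b, ref, alt) in enumerate(_ANCHOR_PAIRS):
        v_b = ProteinVariant("GluN2B", pos_b, ref, alt)
        v_a = ProteinVariant("GluN2A", pos_b - 1, ref, alt)
        db.add(v_b, AnnotationRecord(Pathogenicity.PATHOGENIC, func_cycle[i % 4], "planted"))
        db.add(v_a, AnnotationRecord())  # the in-silico designed homolog: unannotated
        ledger.append({"kind": "anchor_pair", "GluN2B": str(v_b), "GluN2A": str(v_a)})
    sf = _SAME_FINAL_ANCHOR
    v1 = ProteinVariant("GluN1", sf["GluN1_pos"], sf["GluN1_ref"], sf["alt"])
    v2 = ProteinVariant("GluN2B", sf["GluN2B_pos"], sf["GluN2B_ref"], sf["alt"])
    db.add(v1, AnnotationRecord(Pathogenicity.BENIGN, Functional.UNANNOTATED, "planted"))
    db.add(v2, AnnotationRecord(Pathogenicity.PATHOGENIC, Functional.UNANNOTATED, "planted"))
    ledger.append({"kind": "same_final_pair", "GluN1": str(v1), "GluN2B": str(v2)})

    # extra homologous pairs at identical-residue positions inside the LBD/TMD
    seq_a, seq_b = sequences["GluN2A"], sequences["GluN2B"]
    candidates = []
    used = {pos for pos, *_ in _ANCHOR_PAIRS} | {sf["GluN2B_pos"]}
    for name in ("LBD", "TMD"):
        for s, e in _ARCH_2A[name]:
            for m in range(s, e + 1):
                pos_b = m + 1
                if pos_b in used:
                    continue
                if seq_a[m - 1] == seq_b[pos_b - 1]:
                    candidates.append(pos_b)
    picked = rng.choice(len(candidates), size=n_extra_groups, replace=False)
    planted_agree = np.zeros(n_extra_groups, dtype=bool)
    planted_agree[rng.permutation(n_extra_groups)[: int(round(concordance_p * n_extra_groups))]] = True
    n_agree = 0
    for g, k in enumerate(sorted(picked)):
        pos_b = candidates[k]
        ref = seq_b[pos_b - 1]
        alt = rng.choice([a for a in _AA if a != ref])
        path_class = Pathogenicity.PATHOGENIC if rng.random() < 0.6 else Pathogenicity.BENIGN
        func_class = Functional.LOF if rng.random() < 0.5 else Functional.GOF
        agree = bool(planted_agree[g])
        path_b, func_b = path_class, func_class
        if agree:
            path_a, func_a = path_class, func_class
        else:
            path_a = (
                Pathogenicity.BENIGN
                if path_class == Pathogenicity.PATHOGENIC
                else Pathogenicity.PATHOGENIC
            )
            func_a = Functional.GOF if func_class == Functional.LOF else Functional.LOF
        n_agree += agree
        v_b = ProteinVariant("GluN2B", pos_b, ref, alt)
        v_a = ProteinVariant("GluN2A", pos_b - 1, ref, alt)
        db.add(v_b, AnnotationRecord(path_b, func_b, "planted"))
        db.add(v_a, AnnotationRecord(path_a, func_a, "planted"))
        ledger.append(
            {
                "kind": "planted_group",
                "GluN2B": str(v_b),
                "GluN2A": str(v_a),
                "agree": agree,
            }
        )
    ledger.append(
        {
            "kind": "planted_summary",
            "n_planted_groups": int(n_extra_groups),
            "n_agreeing": int(n_agree),
        }
    )
    return db, ledger


def write_demo_workspace(directory: str | Path, seed: int = 0, n_extra_groups: int = 40,
                         concordance_p: float = 1.0, noise_sigma: float = 0.25) -> dict:
    """Write a complete, self-contained demo workspace.

    Files: two CA-only PDB structures (GluN1+GluN2A and GluN1+GluN2B hetero-
    dimers, each in its own random frame; the GluN2B chain uses deposited-
    construct numbering = canonical - 2), canonical sequences FASTA, domain
    config JSON, variant table TSV, workspace manifest and a ground-truth
    ledger.  Same seed, same bytes."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 404]))
    sequences = make_trio_sequences(seed)
    chains = make_trio_chains(sequences, seed, noise_sigma=noise_sigma)

    def transformed(cm: ChainModel, R: np.ndarray, t: np.ndarray) -> ChainModel:
        sites = []
        for s in cm.residues:
            if s.structured:
                xyz = R @ s.ca_array + t
                sites.append(ResidueSite(s.subunit, s.pos, s.aa, tuple(xyz)))
            else:
                sites.append(s)
        return ChainModel(cm.subunit, sites, cm.source)

    R1, t1 = _random_rotation(rng), rng.uniform(-30, 30, 3)
    R2, t2 = _random_rotation(rng), rng.uniform(-30, 30, 3)
    file1 = directory / "demo_glun1_glun2a.pdb"
    file2 = directory / "demo_glun1_glun2b.pdb"
    write_pdb([transformed(chains["GluN1"], R1, t1), transformed(chains["GluN2A"], R1, t1)], file1)

    # GluN2B chain in construct numbering (canonical - 2), mimicking a
    # deposited construct that starts two residues into the canonical frame.
    b = chains["GluN2B"]
    construct_sites = [
        ResidueSite(b.subunit, s.pos - 2, s.aa, s.ca) for s in b.residues if s.pos > 2
    ]
    b_construct = ChainModel(b.subunit, construct_sites, b.source + ":construct")
    write_pdb(
        [transformed(chains["GluN1"], R2, t2), transformed(b_construct, R2, t2)], file2
    )

    fasta = directory / "sequences.fasta"
    with open(fasta, "w") as fh:
        for subunit, seq in sequences.items():
            fh.write(f">{subunit} synthetic canonical\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")

    domains_path = directory / "domains.json"
    dump_domain_config(
        trio_domain_definitions(),
        domains_path,
        note="synthetic demo domain ranges (see fixtures module)",
    )

    db, ledger = make_trio_variant_table(
        sequences, seed, n_extra_groups=n_extra_groups, concordance_p=concordance_p
    )
    variants_path = directory / "variants.tsv"
    write_variant_table(db, variants_path)

    manifest = {
        "seed": seed,
        "structures": [
            {"path": file1.name, "chains": {"A": "GluN1", "B": "GluN2A"}, "numbering": "canonical"},
            {
                "path": file2.name,
                "chains": {"A": "GluN1", "B": "GluN2B"},
                "numbering": {"B": "construct"},
            },
        ],
        "sequences": fasta.name,
        "domains": domains_path.name,
        "variants": variants_path.name,
    }
    (directory / "workspace.json").write_text(json.dumps(manifest, indent=1))

    truth = {
        "seed": seed,
        "offsets_vs_GluN2A": _OFFSETS,
        "anchor_pairs_GluN2B_to_GluN2A": {str(p): p - 1 for p, *_ in _ANCHOR_PAIRS},
        "same_final_pair": _SAME_FINAL_ANCHOR,
        "ledger": ledger,
    }
    (directory / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    return manifest
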