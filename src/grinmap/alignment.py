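"""Pairwise residue alignments: global sequence alignment and the
structure-based alignment read off a superposition.

Two provenances feed the cross-subunit equivalence map.  Solved regions use
the structural route: after rigid superposition, residues are paired by
mutual-nearest-neighbour alpha-carbon distance and pruned to an
order-consistent (non-crossing) subset.  Unsolved regions (signal peptide,
carboxy-terminal domain, disordered loops) fall back to Needleman-Wunsch
global sequence alignment.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.spatial import cKDTree

from ._aa import STANDARD_AA

STRUCTURAL = "structural"
SEQUENCE = "sequence"


@dataclass(frozen=True)
class AlignedPair:
    pos_a: int
    pos_b: int
    aa_a: str
    aa_b: str
    provenance: str = SEQUENCE
    distance: float | None = None  # post-fit CA distance, structural pairs only

    @property
    def same_aa(self) -> bool:
        return self.aa_a == self.aa_b


@dataclass
class ResidueAlignment:
    """Order-consistent pairing of canonical positions of two subunits.

    ``n_columns`` counts aligned pairs plus gap columns, i.e. the length of
    the implied two-row alignment; for structural alignments it is the number
    of pairs plus unpaired residues of either chain within the aligned region.
    """

    subunit_pair: tuple[str, str]
    pairs: list[AlignedPair]
    n_columns: int
    domain: str | None = None

    def __post_init__(self):
        a = [p.pos_a for p in self.pairs]
        b = [p.pos_b for p in self.pairs]
        if any(y <= x for x, y in zip(a, a[1:])) or any(y <= x for x, y in zip(b, b[1:])):
            raise ValueError("alignment pairs must be strictly increasing on both sides")
        if self.n_columns < len(self.pairs):
            raise ValueError("n_columns cannot be smaller than the number of pairs")

    @property
    def identical_count(self) -> int:
        return sum(1 for p in self.pairs if p.same_aa)

    def identity_percent(self, denominator: str = "columns") -> float:
        return identity_stats(self, denominator)[1]

    def transpose(self) -> "ResidueAlignment":
        return ResidueAlignment(
            (self.subunit_pair[1], self.subunit_pair[0]),
            [
                AlignedPair(p.pos_b, p.pos_a, p.aa_b, p.aa_a, p.provenance, p.distance)
                for p in self.pairs
            ],
            self.n_columns,
            domain=self.domain,
        )


def _check_sequence(seq: str, label: str) -> None:
    for i, ch in enumerate(seq):
        if ch not in STANDARD_AA:
            raise ValueError(f"non-standard letter {ch!r} at position {i + 1} of {label}")
    if not seq:
        raise ValueError(f"empty sequence: {label}")


def global_align(
    seq_a: str,
    seq_b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    positions_a: Sequence[int] | None = None,
    positions_b: Sequence[int] | None = None,
    subunit_pair: tuple[str, str] = ("GluN1", "GluN2A"),
    domain: str | None = None,
) -> ResidueAlignment:
    """Needleman-Wunsch optimal global alignment with affine gap penalties.

    A gap of length L costs ``gap_open + (L - 1) * gap_extend``.  When the
    sequences are fragments of longer canonical proteins, ``positions_a`` /
    ``positions_b`` supply the canonical position of each letter (default
    1..len).  The first optimal alignment under the engine's deterministic
    traceback order is returned.
    """
    _check_sequence(seq_a, "sequence A")
    _check_sequence(seq_b, "sequence B")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    aln = aligner.align(seq_a, seq_b)[0]

    if positions_a is None:
        positions_a = list(range(1, len(seq_a) + 1))
    if positions_b is None:
        positions_b = list(range(1, len(seq_b) + 1))

    pairs: list[AlignedPair] = []
    aligned_a, aligned_b = aln.aligned
    n_in_pairs = 0
    for (a0, a1), (b0, b1) in zip(aligned_a, aligned_b):
        for i, j in zip(range(a0, a1), range(b0, b1)):
            pairs.append(
                AlignedPair(positions_a[i], positions_b[j], seq_a[i], seq_b[j], SEQUENCE)
            )
        n_in_pairs += a1 - a0
    n_columns = len(pairs) + (len(seq_a) - len(pairs)) + (len(seq_b) - len(pairs))
    out = ResidueAlignment(subunit_pair, pairs, n_columns, domain=domain)
    out.score = float(aln.score)
    return out


def derive_structural_alignment(
    chain_a,
    chain_b,
    pairing_cutoff: float = 4.0,
    subunit_pair: tuple[str, str] | None = None,
    domain: str | None = None,
) -> ResidueAlignment:
    """Read a residue alignment off a superposition.

    ``chain_b`` must already be transformed into ``chain_a``'s frame.
    Residues are paired when they are mutual nearest neighbours within
    ``pairing_cutoff`` Å; order consistency is then enforced by keeping the
    maximum-cardinality non-crossing subset (ties resolved toward smaller
    distances).
    """
    res_a = chain_a.structured_residues()
    res_b = chain_b.structured_residues()
    if not res_a or not res_b:
        raise ValueError("both chains need structured residues")
    A = np.array([r.ca_array for r in res_a])
    B = np.array([r.ca_array for r in res_b])
    tree_a = cKDTree(A)
    tree_b = cKDTree(B)
    d_ab, nn_ab = tree_b.query(A, k=1)
    d_ba, nn_ba = tree_a.query(B, k=1)

    cand = []
    for i, (j, dij) in enumerate(zip(nn_ab, d_ab)):
        if dij <= pairing_cutoff and nn_ba[j] == i:
            cand.append((i, int(j), float(dij)))
    if not cand:
        raise ValueError("no residue pairs within the pairing cutoff")

    kept = _max_noncrossing(cand)
    pairs = [
        AlignedPair(res_a[i].pos, res_b[j].pos, res_a[i].aa, res_b[j].aa, STRUCTURAL, d)
        for i, j, d in kept
    ]
    sub_pair = subunit_pair or (chain_a.subunit, chain_b.subunit)
    n_columns = len(pairs) + (len(res_a) - len(pairs)) + (len(res_b) - len(pairs))
    return ResidueAlignment(sub_pair, pairs, n_columns, domain=domain)


def _max_noncrossing(cand: list[tuple[int, int, float]]) -> list[tuple[int, int, float]]:
    """Longest strictly-increasing subsequence of (i, j) candidate pairs.

    Candidates are mutual nearest neighbours, so each i and each j occurs at
    most once; sorting by i and running patience LIS on j yields the
    maximum-cardinality non-crossing pairing.  Distance never changes the
    cardinality here (one candidate per i), it only orders the input scan.
    """
    cand = sorted(cand, key=lambda c: (c[0], c[2]))
    tails_j: list[int] = []
    tails_idx: list[int] = []
    prev = [-1] * len(cand)
    for k, (_, j, _) in enumerate(cand):
        p = bisect.bisect_left(tails_j, j)
        if p == len(tails_j):
            tails_j.append(j)
            tails_idx.append(k)
        else:
            tails_j[p] = j
            tails_idx[p] = k
        prev[k] = tails_idx[p - 1] if p > 0 else -1
    out = []
    k = tails_idx[-1]
    while k != -1:
        out.append(cand[k])
        k = prev[k]
    return out[::-1]


def identity_stats(
    aln: ResidueAlignment, denominator: str = "columns"
) -> tuple[int, float]:
    """Identical-residue count and identity percentage of an alignment.

    denominator: "columns" (aligned pairs + gap columns, the default),
    "pairs" (aligned pairs only).  Percentages are exact internally; display
    rounding is the caller's concern.
    """
    if not aln.pairs:
        raise ValueError("identity_stats: empty alignment")
    ident = aln.identical_count
    if denominator == "columns":
        den = aln.n_columns
    elif denominator == "pairs":
        den = len(aln.pairs)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return ident, 100.0 * ident / den


def merge_alignments(primary: ResidueAlignment, *others: ResidueAlignment) -> ResidueAlignment:
    """Concatenate alignments of disjoint position ranges of the same pair."""
    pairs = list(primary.pairs)
    n_columns = primary.n_columns
    for o in others:
        if o.subunit_pair != primary.subunit_pair:
            raise ValueError("cannot merge alignments of different subunit pairs")
        pairs.extend(o.pairs)
        n_columns += o.n_columns
    pairs.sort(key=lambda p: p.pos_a)
    return ResidueAlignment(primary.subunit_pair, pairs, n_columns, domain=primary.domain)
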