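"""Rigid-body superposition of paired alpha-carbon sets.

Implements the Kabsch least-squares fit with reflection correction, plus the
align-style iterative protocol: fit, reject pairs whose post-fit distance
exceeds a cutoff, refit, for a bounded number of cycles.  Per-domain RMSD
values between GluN subunits are produced this way.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class Superposition:
    """A rigid transform x -> rotation @ x + translation, with fit metadata.

    ``rmsd`` is computed over ``retained_pairs`` only; ``rmsd_all`` is the
    RMSD over the full seed pairing under the final transform (reported
    alongside because align-style tools differ in which one they print).
    """

    rotation: np.ndarray
    translation: np.ndarray
    retained_pairs: list[tuple[int, int]]
    rmsd: float
    cycles_run: int = 0
    rmsd_all: float | None = None

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-6):
            raise ValueError("rotation must be orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det = +1)")
        self.rotation = R
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation


def rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """Root-mean-square deviation of two equal-length coordinate sets, no fitting."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise ValueError(f"coordinate sets differ in shape: {P.shape} vs {Q.shape}")
    if P.ndim != 2 or P.shape[1] != 3 or len(P) < 1:
        raise ValueError("expected non-empty (n, 3) coordinate arrays")
    return float(np.sqrt(np.mean(np.sum((P - Q) ** 2, axis=1))))


def kabsch(P: np.ndarray, Q: np.ndarray, pair_ids=None) -> Superposition:
    """Least-squares-optimal proper rigid transform of P onto Q.

    Returns the Superposition minimising RMSD(R @ P + t, Q).  The reflection
    case of the SVD solution is corrected by flipping the smallest singular
    direction, so a proper rotation is always returned.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("kabsch expects two equal-shape (n, 3) arrays")
    n = len(P)
    if n < 3:
        raise ValueError(f"kabsch needs >= 3 point pairs, got {n}")
    Pc = P.mean(axis=0)
    Qc = Q.mean(axis=0)
    H = (P - Pc).T @ (Q - Qc)
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-9:  # rank < 2: points collinear or coincident
        raise ValueError("kabsch: degenerate (collinear) point geometry")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = Qc - R @ Pc
    if pair_ids is None:
        pair_ids = [(i, i) for i in range(n)]
    sup = Superposition(R, t, list(pair_ids), 0.0)
    sup.rmsd = rmsd(sup.apply(P), Q)
    return sup


def iterative_superpose(
    chain_a,
    chain_b,
    seed,
    cycles: int = 5,
    reject_cutoff: float = 2.0,
) -> Superposition:
    """Superpose chain_a onto chain_b over a seed residue pairing with
    iterative outlier rejection.

    ``seed`` is a ResidueAlignment whose pairs reference canonical positions
    of the two chains; only pairs structured in both chains enter the fit.
    Each cycle rejects pairs whose post-fit alpha-carbon distance exceeds
    ``reject_cutoff`` Å and refits; iteration stops early when nothing is
    rejected.  RMSD is non-increasing across cycles.
    """
    pairs = [
        (p.pos_a, p.pos_b)
        for p in seed.pairs
        if p.pos_a in chain_a
        and p.pos_b in chain_b
        and chain_a.site(p.pos_a).structured
        and chain_b.site(p.pos_b).structured
    ]
    if len(pairs) < 3:
        raise ValueError(f"iterative_superpose: seed provides {len(pairs)} structured pairs, need >= 3")
    all_pairs = list(pairs)
    P_all = chain_a.coords([a for a, _ in all_pairs])
    Q_all = chain_b.coords([b for _, b in all_pairs])

    retained = list(range(len(all_pairs)))
    sup = kabsch(P_all, Q_all, all_pairs)
    cycles_run = 0
    for _ in range(cycles):
        d = np.linalg.norm(sup.apply(P_all[retained]) - Q_all[retained], axis=1)
        keep = [idx for idx, di in zip(retained, d) if di <= reject_cutoff]
        if len(keep) == len(retained):
            break
        # Anneal: never drop more than the worst 30% in one cycle, so a rough
        # seed alignment refines instead of collapsing outright.
        floor = max(3, int(np.ceil(0.7 * len(retained))))
        if len(keep) < floor:
            order = np.argsort(d)
            keep = sorted(retained[i] for i in order[:floor])
        if len(keep) < 3:
            raise ValueError("superposition collapsed: fewer than 3 pairs retained")
        retained = keep
        sup = kabsch(P_all[retained], Q_all[retained], [all_pairs[i] for i in retained])
        cycles_run += 1
    final = Superposition(
        sup.rotation,
        sup.translation,
        [all_pairs[i] for i in retained],
        sup.rmsd,
        cycles_run=cycles_run,
    )
    final.rmsd_all = rmsd(final.apply(P_all), Q_all)
    return final
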