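"""Independent brute-force oracles used only by the tests.

These deliberately avoid the code paths they check: rotation fitting is done
by naive search over rotation space, and global alignment scoring by
exhaustive enumeration of all alignments.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Align import substitution_matrices
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def brute_force_min_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """Minimum RMSD over all proper rotations + translations, by coarse
    Euler-angle grid search refined with a local optimizer.

    For any fixed rotation the optimal translation aligns centroids, so the
    search is over rotations only, applied to centered coordinates."""
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)

    def cost(euler):
        R = Rotation.from_euler("zyx", euler).as_matrix()
        return np.sqrt(np.mean(np.sum((Pc @ R.T - Qc) ** 2, axis=1)))

    grid = np.deg2rad(np.arange(0, 360, 24))
    half = np.deg2rad(np.arange(-90, 91, 24))
    best = (np.inf, None)
    for a, b, c in itertools.product(grid, half, grid):
        v = cost((a, b, c))
        if v < best[0]:
            best = (v, (a, b, c))
    res = minimize(cost, best[1], method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
    return float(min(best[0], res.fun))


def enumerate_global_alignment_score(
    seq_a: str,
    seq_b: str,
    matrix_name: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> float:
    """Optimal global alignment score by exhaustive enumeration.

    A gap run of length L costs gap_open + (L - 1) * gap_extend.  Exponential
    in the lengths; use only for sequences up to ~8 residues."""
    matrix = substitution_matrices.load(matrix_name)
    best = [-np.inf]

    def step(i, j, score, state):
        if i == len(seq_a) and j == len(seq_b):
            best[0] = max(best[0], score)
            return
        if i < len(seq_a) and j < len(seq_b):
            step(i + 1, j + 1, score + matrix[seq_a[i], seq_b[j]], "M")
        if i < len(seq_a):
            cost = gap_extend if state == "A" else gap_open
            step(i + 1, j, score - cost, "A")
        if j < len(seq_b):
            cost = gap_extend if state == "B" else gap_open
            step(i, j + 1, score - cost, "B")

    step(0, 0, 0.0, "M")
    return float(best[0])
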