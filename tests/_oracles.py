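"""Independent oracles used by the test suite.

These implementations deliberately share no code with the package: the
alignment oracle enumerates every global alignment explicitly, and the
superposition oracle minimises RMSD numerically over rotation angles.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def enumerate_alignment_score(a: str, b: str, scheme) -> float:
    """Optimal global alignment score by exhaustive enumeration.

    Every sequence of moves (match/mismatch, gap-in-b, gap-in-a) consuming
    both strings is generated; each complete alignment is scored with affine
    gap runs (open + (L-1)*extend) and the scheme's terminal-gap policy: a
    gap run is terminal when the gapped sequence is at its start or already
    fully consumed.  Intended for combined length <= ~14.
    """
    la, lb = len(a), len(b)
    sub = scheme.substitution
    free_ends = scheme.terminal_gap_policy == "free"
    best = -np.inf

    def score(moves: list[str]) -> float:
        total = 0.0
        i = j = 0
        idx = 0
        n = len(moves)
        while idx < n:
            mv = moves[idx]
            if mv == "M":
                total += float(sub[a[i], b[j]])
                i += 1
                j += 1
                idx += 1
                continue
            # a run of identical gap moves
            run_start = idx
            while idx < n and moves[idx] == mv:
                idx += 1
            run_len = idx - run_start
            if mv == "D":  # gap in b, consumes a
                terminal = j == 0 or j == lb
                i += run_len
            else:  # "I": gap in a, consumes b
                terminal = i == 0 or i == la
                j += run_len
            if not (free_ends and terminal):
                total -= scheme.gap_open + (run_len - 1) * scheme.gap_extend
        return total

    moves: list[str] = []

    def recurse(i: int, j: int) -> None:
        nonlocal best
        if i == la and j == lb:
            best = max(best, score(moves))
            return
        if i < la and j < lb:
            moves.append("M")
            recurse(i + 1, j + 1)
            moves.pop()
        if i < la:
            moves.append("D")
            recurse(i + 1, j)
            moves.pop()
        if j < lb:
            moves.append("I")
            recurse(i, j + 1)
            moves.pop()

    recurse(0, 0)
    return float(best)


def numeric_superposition_rmsd(moving: np.ndarray, reference: np.ndarray) -> float:
    """Minimum RMSD over rigid transforms, by direct numerical optimisation.

    Parameterises rotation as a rotation vector; the optimal translation for
    any rotation aligns the centroids.  Multi-start to dodge local minima.
    """
    P = np.asarray(moving, float)
    Q = np.asarray(reference, float)
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    Pc, Qc = P - cp, Q - cq

    def rmsd_of(rotvec: np.ndarray) -> float:
        R = Rotation.from_rotvec(rotvec).as_matrix()
        d = Pc @ R.T - Qc
        return float(np.sqrt(np.mean(np.sum(d**2, axis=1))))

    rng = np.random.default_rng(0)
    best = np.inf
    starts = [np.zeros(3)] + [
        Rotation.random(random_state=int(s)).as_rotvec()
        for s in rng.integers(0, 2**31, size=24)
    ]
    for x0 in starts:
        res = minimize(rmsd_of, x0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000})
        best = min(best, float(res.fun))
    return best


def exact_binomial_interval(p: float, n: int, level: float = 0.99):
    """Exact (Clopper–Pearson-style) acceptance interval for a count at
    success probability ``p``: the central probability-``level`` range of
    Binomial(n, p), returned as (lo, hi) counts."""
    from scipy.stats import binom

    alpha = 1.0 - level
    lo = binom.ppf(alpha / 2, n, p)
    hi = binom.isf(alpha / 2, n, p)
    return int(lo), int(hi)
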