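"""Rigid superposition, TM-score, and heuristic pairwise structural alignment.

The aligner is a simplified TM-align-style procedure: gapless-threading
and secondary-structure seeds, then iterative {superpose -> distance
score matrix -> dynamic programming} refinement, maximizing the TM-score
normalized by the second structure's length.  Both normalizations are
reported.  It is fully deterministic for fixed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .structio import StructureModel

__all__ = [
    "RigidTransform",
    "ResidueMapping",
    "AlignmentResult",
    "kabsch",
    "tm_d0",
    "tm_score",
    "align_structures",
    "seq_identity_on_alignment",
    "alignment_tsv_row",
    "ALIGNMENT_TSV_HEADER",
]

GAP_OPEN = -0.6  # DP gap-open penalty; no extension penalty
MAX_ITER = 30
MAX_SEEDS = 40
N_REFINE = 4  # seeds carried into full iterative refinement


@dataclass
class RigidTransform:
    """Proper rigid motion ``x -> R x + t`` (no reflection)."""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    def is_proper(self, tol: float = 1e-8) -> bool:
        R = self.rotation
        return (np.allclose(R.T @ R, np.eye(3), atol=tol)
                and np.linalg.det(R) > 0)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass
class ResidueMapping:
    """Sequential residue correspondence: (i in A, j in B) pairs."""

    pairs: list[tuple[int, int]]

    def __post_init__(self) -> None:
        for (i0, j0), (i1, j1) in zip(self.pairs, self.pairs[1:]):
            if not (i1 > i0 and j1 > j0):
                raise ValueError("mapping must be strictly increasing "
                                 "in both coordinates")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def a_indices(self) -> np.ndarray:
        return np.array([i for i, _ in self.pairs], dtype=np.int64)

    @property
    def b_indices(self) -> np.ndarray:
        return np.array([j for _, j in self.pairs], dtype=np.int64)


@dataclass
class AlignmentResult:
    """Outcome of a pairwise structural alignment."""

    mapping: ResidueMapping
    transform: RigidTransform
    rmsd_aligned: float
    tm_norm_a: float
    tm_norm_b: float
    aligned_length: int
    seq_identity_aligned: float


@njit(cache=True)
def _kabsch_core(A, B):
    """Least-squares rotation/translation of A onto B; returns R, t, rmsd."""
    n = A.shape[0]
    ca = np.zeros(3)
    cb = np.zeros(3)
    for k in range(n):
        ca += A[k]
        cb += B[k]
    ca /= n
    cb /= n
    H = np.zeros((3, 3))
    for k in range(n):
        for p in range(3):
            for q in range(3):
                H[p, q] += (A[k, p] - ca[p]) * (B[k, q] - cb[q])
    U, _, Vt = np.linalg.svd(H)
    # R maps A-frame onto B-frame; correct reflection via determinant
    M = Vt.T @ U.T
    det = (M[0, 0] * (M[1, 1] * M[2, 2] - M[1, 2] * M[2, 1])
           - M[0, 1] * (M[1, 0] * M[2, 2] - M[1, 2] * M[2, 0])
           + M[0, 2] * (M[1, 0] * M[2, 1] - M[1, 1] * M[2, 0]))
    if det < 0:
        D = np.eye(3)
        D[2, 2] = -1.0
        R = Vt.T @ D @ U.T
    else:
        R = M
    t = cb - R @ ca
    ss = 0.0
    for k in range(n):
        d = R @ A[k] + t - B[k]
        ss += d[0] * d[0] + d[1] * d[1] + d[2] * d[2]
    rmsd = np.sqrt(ss / n)
    return R, t, rmsd


@njit(cache=True)
def _dp_traceback(S, gap_open):
    """Semi-global alignment over score matrix S (free end gaps).

    Affine gaps with zero extension cost: each gap run costs ``gap_open``
    once.  Traceback prefers the diagonal.  Returns (mi, mj, n_pairs).
    """
    n, m = S.shape
    NEG = -1e18
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in B (consume A)
    Y = np.full((n + 1, m + 1), NEG)  # gap in A (consume B)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = 0.0  # free leading end gaps
    for j in range(1, m + 1):
        Y[0, j] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best = M[i - 1, j - 1]
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
            M[i, j] = best + S[i - 1, j - 1]
            x = M[i - 1, j] + gap_open
            if X[i - 1, j] > x:
                x = X[i - 1, j]
            X[i, j] = x
            y = M[i, j - 1] + gap_open
            if Y[i, j - 1] > y:
                y = Y[i, j - 1]
            Y[i, j] = y
    # free trailing end gaps: no penalty for X/Y at the border
    mi = np.empty(min(n, m), dtype=np.int64)
    mj = np.empty(min(n, m), dtype=np.int64)
    i, j = n, m
    # state: 0=M, 1=X, 2=Y ; prefer diagonal on ties
    state = 0
    best = M[n, m]
    if X[n, m] >= best and X[n, m] > M[n, m]:
        state, best = 1, X[n, m]
    if Y[n, m] > best:
        state, best = 2, Y[n, m]
    k = 0
    while i > 0 and j > 0:
        if state == 0:
            k += 1
            mi[min(n, m) - k] = i - 1
            mj[min(n, m) - k] = j - 1
            prev = M[i - 1, j - 1]
            state = 0
            if X[i - 1, j - 1] > prev:
                prev, state = X[i - 1, j - 1], 1
            if Y[i - 1, j - 1] > prev:
                prev, state = Y[i - 1, j - 1], 2
            i -= 1
            j -= 1
        elif state == 1:
            # came from M (gap opened) or X (gap extended); prefer closing
            if M[i - 1, j] + gap_open >= X[i - 1, j]:
                state = 0
            i -= 1
        else:
            if M[i, j - 1] + gap_open >= Y[i, j - 1]:
                state = 0
            j -= 1
    npairs = k
    return mi[min(n, m) - k:], mj[min(n, m) - k:], npairs


@njit(cache=True)
def _tm_of_mapping(A, B, mi, mj, d0, l_norm):
    """TM-score after superposing the mapped C-alpha subsets."""
    npairs = mi.shape[0]
    if npairs < 3:
        return 0.0
    sub_a = np.empty((npairs, 3))
    sub_b = np.empty((npairs, 3))
    for k in range(npairs):
        sub_a[k] = A[mi[k]]
        sub_b[k] = B[mj[k]]
    R, t, _ = _kabsch_core(sub_a, sub_b)
    s = 0.0
    for k in range(npairs):
        d = R @ sub_a[k] + t - sub_b[k]
        d2 = d[0] * d[0] + d[1] * d[1] + d[2] * d[2]
        s += 1.0 / (1.0 + d2 / (d0 * d0))
    return s / l_norm


@njit(cache=True)
def _refine_mapping(A, B, mi, mj, d0, gap_open, max_iter):
    """Iterate superpose -> score matrix -> DP until the mapping repeats."""
    n = A.shape[0]
    m = B.shape[0]
    best_mi, best_mj = mi, mj
    best_tm = _tm_of_mapping(A, B, mi, mj, d0, m)
    prev_mi, prev_mj = mi, mj
    S = np.empty((n, m))
    for _ in range(max_iter):
        npairs = prev_mi.shape[0]
        if npairs < 3:
            break
        sub_a = np.empty((npairs, 3))
        sub_b = np.empty((npairs, 3))
        for k in range(npairs):
            sub_a[k] = A[prev_mi[k]]
            sub_b[k] = B[prev_mj[k]]
        R, t, _ = _kabsch_core(sub_a, sub_b)
        for i in range(n):
            p = R @ A[i] + t
            for j in range(m):
                dx = p[0] - B[j, 0]
                dy = p[1] - B[j, 1]
                dz = p[2] - B[j, 2]
                d2 = dx * dx + dy * dy + dz * dz
                S[i, j] = 1.0 / (1.0 + d2 / (d0 * d0))
        new_mi, new_mj, npairs2 = _dp_traceback(S, gap_open)
        if npairs2 < 3:
            break
        tm = _tm_of_mapping(A, B, new_mi, new_mj, d0, m)
        if tm > best_tm:
            best_tm = tm
            best_mi, best_mj = new_mi, new_mj
        if (npairs2 == prev_mi.shape[0]
                and np.all(new_mi == prev_mi) and np.all(new_mj == prev_mj)):
            break
        prev_mi, prev_mj = new_mi, new_mj
    return best_mi, best_mj, best_tm


def tm_d0(l_norm: int) -> float:
    """TM-score distance scale: ``max(0.5, 1.24 (L-15)^(1/3) - 1.8)``."""
    if l_norm < 1:
        raise ValueError("l_norm must be >= 1")
    return float(max(0.5, 1.24 * np.cbrt(l_norm - 15.0) - 1.8))


def kabsch(coords_a: np.ndarray, coords_b: np.ndarray) -> RigidTransform:
    """Least-squares proper rigid transform of ``coords_a`` onto ``coords_b``."""
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape:
        raise ValueError("coordinate sets must have equal shapes")
    if A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("expected (n, 3) coordinate arrays")
    if A.shape[0] < 3:
        raise ValueError("need at least 3 points")
    R, t, _ = _kabsch_core(A, B)
    return RigidTransform(rotation=R, translation=t)


def tm_score(mapping: ResidueMapping, a: StructureModel, b: StructureModel,
             transform: RigidTransform, l_norm: int) -> float:
    """TM-score of a fixed mapping under a fixed transform.

    ``(1/l_norm) * sum over pairs of 1 / (1 + (d_i/d0)^2)`` with the
    post-transform C-alpha distances ``d_i``.  Empty mapping scores 0.
    """
    if l_norm < 1:
        raise ValueError("l_norm must be >= 1")
    if len(mapping) == 0:
        return 0.0
    d0 = tm_d0(l_norm)
    pa = transform.apply(a.ca_coords[mapping.a_indices])
    pb = b.ca_coords[mapping.b_indices]
    d2 = np.sum((pa - pb) ** 2, axis=1)
    return float(np.sum(1.0 / (1.0 + d2 / d0 ** 2)) / l_norm)


def seq_identity_on_alignment(mapping: ResidueMapping, a: StructureModel,
                              b: StructureModel) -> float:
    """Fraction of mapped pairs with identical residue types."""
    if len(mapping) == 0:
        return 0.0
    sa, sb = a.sequence, b.sequence
    same = sum(1 for i, j in mapping.pairs if sa[i] == sb[j])
    return same / len(mapping)


def _gapless_offsets(n: int, m: int, step: int = 5,
                     max_seeds: int = MAX_SEEDS) -> list[int]:
    offsets = [o for o in range(-(m - 5), n - 5 + 1, step)]
    if 0 not in offsets:
        offsets.append(0)
    if len(offsets) > max_seeds:
        idx = np.linspace(0, len(offsets) - 1, max_seeds).round().astype(int)
        offsets = [offsets[i] for i in sorted(set(idx.tolist()))]
    return offsets


def _gapless_mapping(n: int, m: int, offset: int):
    lo = max(0, offset)
    hi = min(n, m + offset)
    mi = np.arange(lo, hi, dtype=np.int64)
    mj = mi - offset
    return mi, mj


def _sse_seed(a: StructureModel, b: StructureModel):
    """Seed mapping from aligning the two secondary-structure strings."""
    from .secstruct import assign_ss  # local import; no cycle at module load

    codes = {"H": 0, "E": 1, "C": 2}
    va = np.array([codes[c] for c in assign_ss(a)])
    vb = np.array([codes[c] for c in assign_ss(b)])
    same = va[:, None] == vb[None, :]
    S = np.where(same, np.where(va[:, None] == 2, 0.2, 1.0), -0.5)
    mi, mj, _ = _dp_traceback(np.ascontiguousarray(S), -1.0)
    return mi, mj


def align_structures(a: StructureModel, b: StructureModel) -> AlignmentResult:
    """Heuristic pairwise structural alignment maximizing TM (norm by B).

    Seeds from gapless threading at multiple offsets plus a
    secondary-structure-string alignment are scored cheaply; the best
    few are refined by iterative superposition / dynamic programming.
    """
    if len(a) < 5 or len(b) < 5:
        raise ValueError("structures must have at least 5 residues")
    A = np.ascontiguousarray(a.ca_coords)
    B = np.ascontiguousarray(b.ca_coords)
    n, m = len(a), len(b)
    d0 = tm_d0(m)

    seeds = []
    for off in _gapless_offsets(n, m):
        mi, mj = _gapless_mapping(n, m, off)
        if len(mi) >= 5:
            tm0 = _tm_of_mapping(A, B, mi, mj, d0, m)
            seeds.append((tm0, off, mi, mj))
    seeds.sort(key=lambda s: (-s[0], s[1]))
    candidates = [(mi, mj) for _, _, mi, mj in seeds[:N_REFINE]]
    try:
        sse_mi, sse_mj = _sse_seed(a, b)
        if len(sse_mi) >= 5:
            candidates.append((sse_mi, sse_mj))
    except ValueError:
        pass

    best = None
    for mi, mj in candidates:
        rmi, rmj, tm_b = _refine_mapping(A, B, mi, mj, d0, GAP_OPEN, MAX_ITER)
        if best is None or tm_b > best[0] + 1e-12:
            best = (tm_b, rmi, rmj)
    assert best is not None
    _, mi, mj = best

    mapping = ResidueMapping(pairs=list(zip(mi.tolist(), mj.tolist())))
    transform = kabsch(A[mi], B[mj])
    pa = transform.apply(A[mi])
    d2 = np.sum((pa - B[mj]) ** 2, axis=1)
    rmsd = float(np.sqrt(np.mean(d2)))
    tm_a = float(np.sum(1.0 / (1.0 + d2 / tm_d0(n) ** 2)) / n)
    tm_b = float(np.sum(1.0 / (1.0 + d2 / tm_d0(m) ** 2)) / m)
    return AlignmentResult(
        mapping=mapping,
        transform=transform,
        rmsd_aligned=rmsd,
        tm_norm_a=tm_a,
        tm_norm_b=tm_b,
        aligned_length=len(mapping),
        seq_identity_aligned=seq_identity_on_alignment(mapping, a, b),
    )


ALIGNMENT_TSV_HEADER = ("id_a\tid_b\tlen_a\tlen_b\taligned_length\trmsd"
                        "\ttm_norm_a\ttm_norm_b\tseq_identity")


def alignment_tsv_row(a: StructureModel, b: StructureModel,
                      res: AlignmentResult) -> str:
    return (f"{a.id}\t{b.id}\t{len(a)}\t{len(b)}\t{res.aligned_length}"
            f"\t{res.rmsd_aligned:.4f}\t{res.tm_norm_a:.4f}"
            f"\t{res.tm_norm_b:.4f}\t{res.seq_identity_aligned:.4f}")
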