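"""Rigid-body superposition and structural similarity metrics.

Implements the Kabsch least-squares fit (closed-form SVD solution for the
proper rotation minimizing squared error), RMSD over aligned residue
pairs, the length-dependent TM-score distance scale

    d0(L) = 1.24 * (L - 15)^(1/3) - 1.8   [Å, clamped below at 0.5],

the TM-score

    TM = (1/L_norm) * sum_i 1 / (1 + (d_i / d0)^2),

and a deterministic iterative search for the superposition maximizing the
TM-score of a fixed residue correspondence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Superposition",
    "AlignedPairSet",
    "kabsch",
    "rmsd",
    "d0",
    "tm_score",
    "tm_score_optimal",
    "D0_MIN",
    "TM_CUTOFF_SCHEDULE",
]

D0_MIN = 0.5  # Å floor keeping d0 positive for chains/parts of length <= 21
TM_CUTOFF_SCHEDULE = (8.0, 7.0, 6.0, 5.0, 4.5, 4.0, 3.5)  # Å, then d0
_MAX_REFINE_ITER = 20


@dataclass(frozen=True)
class Superposition:
    """Rigid transform x -> R @ x + t with R proper orthonormal."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation must be proper (det = +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Transform an (N, 3) coordinate array (or a single 3-vector)."""
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "Superposition":
        return cls(np.eye(3), np.zeros(3))


@dataclass(frozen=True)
class AlignedPairSet:
    """Residue correspondence with per-pair distances under a superposition."""

    pairs: tuple[tuple[int, int], ...]
    distances: np.ndarray  # (N_ali,), Å

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        if d.ndim != 1 or len(d) != len(self.pairs):
            raise ValueError("one distance per pair required")
        if np.any(d < 0):
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "pairs", tuple(self.pairs))
        object.__setattr__(self, "distances", d)

    @property
    def n_ali(self) -> int:
        return len(self.pairs)


def pair_distances(
    pairs: list[tuple[int, int]] | tuple[tuple[int, int], ...],
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    sup: Superposition,
) -> AlignedPairSet:
    """Build an :class:`AlignedPairSet` by transforming coords_a onto coords_b."""
    ia = np.fromiter((p[0] for p in pairs), dtype=int, count=len(pairs))
    ib = np.fromiter((p[1] for p in pairs), dtype=int, count=len(pairs))
    moved = sup.apply(np.asarray(coords_a)[ia])
    d = np.linalg.norm(moved - np.asarray(coords_b)[ib], axis=1)
    return AlignedPairSet(pairs=tuple(pairs), distances=d)


def kabsch(moving: np.ndarray, fixed: np.ndarray) -> Superposition:
    """Least-squares rigid fit of ``moving`` onto ``fixed``.

    Returns the proper rotation + translation minimizing the sum of squared
    distances; a reflection in the SVD solution is corrected by flipping
    the sign of the smallest singular vector.
    """
    P = np.asarray(moving, dtype=float)
    Q = np.asarray(fixed, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("moving and fixed must be equal-shape (N, 3) arrays")
    if len(P) < 3:
        raise ValueError("at least 3 points required for a rigid fit")
    cp = P.mean(axis=0)
    cq = Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    sign = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, sign if sign != 0 else 1.0])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    return Superposition(rotation=R, translation=t)


def rmsd(pairs: AlignedPairSet) -> float:
    """Root-mean-square deviation sqrt(mean(d_i^2)) over the aligned pairs."""
    if pairs.n_ali == 0:
        raise ValueError("RMSD of an empty pair set is undefined")
    return float(np.sqrt(np.mean(pairs.distances**2)))


def d0(L: int) -> float:
    """TM-score distance scale for normalization length L, clamped at 0.5 Å."""
    if L < 1:
        raise ValueError("L must be >= 1")
    if L <= 15:
        return D0_MIN
    return max(1.24 * (L - 15.0) ** (1.0 / 3.0) - 1.8, D0_MIN)


def tm_score(pairs: AlignedPairSet, L_norm: int, *, d0_len: int | None = None) -> float:
    """TM-score of a fixed correspondence under a fixed superposition.

    ``L_norm`` is the normalization length (default convention: the
    template, i.e. shorter-chain, length).  ``d0_len`` decouples the
    distance scale from the normalization length when a sub-part of the
    template is scored against the full-template d0.
    """
    if L_norm < 1:
        raise ValueError("L_norm must be >= 1")
    if pairs.n_ali == 0:
        return 0.0
    scale = d0(d0_len if d0_len is not None else L_norm)
    return float(np.sum(1.0 / (1.0 + (pairs.distances / scale) ** 2)) / L_norm)


def tm_score_optimal(
    pairs: list[tuple[int, int]] | tuple[tuple[int, int], ...],
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    L_norm: int,
    *,
    d0_len: int | None = None,
) -> tuple[float, Superposition]:
    """Maximize the TM-score of a fixed correspondence over superpositions.

    Deterministic iterative refinement: start from the Kabsch fit on all
    pairs, then for each distance cutoff descending from 8 Å to d0 re-fit
    on the subset of pairs closer than the cutoff (while >= 3 survive),
    iterating until the subset stabilizes; the superposition giving the
    highest TM-score over ALL pairs is kept.  The result is never worse
    than the plain all-pair Kabsch fit.
    """
    pairs = tuple(pairs)
    if len(pairs) < 3:
        raise ValueError("at least 3 aligned pairs required")
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    ia = np.array([p[0] for p in pairs])
    ib = np.array([p[1] for p in pairs])
    PA, PB = A[ia], B[ib]

    scale_len = d0_len if d0_len is not None else L_norm
    cutoffs = list(TM_CUTOFF_SCHEDULE) + [max(d0(scale_len), D0_MIN)]

    def score_of(sup: Superposition) -> tuple[float, np.ndarray]:
        d = np.linalg.norm(sup.apply(PA) - PB, axis=1)
        aps = AlignedPairSet(pairs=pairs, distances=d)
        return tm_score(aps, L_norm, d0_len=d0_len), d

    best_sup = kabsch(PA, PB)
    best_tm, dist = score_of(best_sup)

    for cutoff in cutoffs:
        sup = best_sup
        d = dist
        prev_mask: np.ndarray | None = None
        for _ in range(_MAX_REFINE_ITER):
            mask = d < cutoff
            if mask.sum() < 3:
                break
            if prev_mask is not None and np.array_equal(mask, prev_mask):
                break
            prev_mask = mask
            sup = kabsch(PA[mask], PB[mask])
            tm, d = score_of(sup)
            if tm > best_tm:
                best_tm, best_sup, dist = tm, sup, d
    return best_tm, best_sup
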