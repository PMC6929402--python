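"""Phase 2: fragment-based residue-level alignment maximizing the TM-score.

The shorter chain (the *template*) is threaded along the longer chain (the
*constant*): for every contiguous constant window of template length the
template is rigidly superposed onto the window (Kabsch on the gapless
identity correspondence), a distance-based scoring matrix

    M[i,j] = max( M[i-1,j] + g,
                  M[i,j-1] + g,
                  M[i-1,j-1] + 1 / (1 + d_ij^2 / d0(L_min)^2) )

(first row and column zero, g the user gap penalty, L_min the template
length) is filled, an alignment is recovered by dynamic-programming
traceback, runs of >= 10 consecutively aligned pairs seed one re-fit and
re-traceback, and the window with the highest TM-score wins.

The template is additionally split into 1, 2, 3, 5 and 8 equal contiguous
parts; each part is threaded independently (in template order, over
disjoint ordered constant regions), the parts' alignments are combined,
and the part count giving the highest combined TM-score is reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .geometry import (
    AlignedPairSet,
    Superposition,
    d0,
    kabsch,
    pair_distances,
    rmsd,
    tm_score,
    tm_score_optimal,
)
from .structure_io import Chain

__all__ = [
    "ScoringMatrixM",
    "Fragment",
    "PartScheme",
    "ResidueAlignment",
    "ThreadingResult",
    "DEFAULT_GAP_PENALTY",
    "PART_GROUPS",
    "MIN_FRAGMENT_LEN",
    "choose_template",
    "score_matrix",
    "dp_traceback_M",
    "collect_fragments",
    "refine_alignment",
    "gapless_threading",
    "split_parts",
    "align_pair",
    "align_pair_groups",
]

DEFAULT_GAP_PENALTY = 3e-6  # near-zero setting suited to remote homologs
ALT_GAP_PENALTY = 0.08      # setting suited to structurally analogous pairs
PART_GROUPS = (1, 2, 3, 5, 8)
MIN_FRAGMENT_LEN = 10
_MIN_PART_LEN = 3  # a rigid fit needs >= 3 points; smaller parts are skipped


def _coords(x: "Chain | np.ndarray") -> np.ndarray:
    if isinstance(x, Chain):
        return x.coords
    a = np.asarray(x, dtype=float)
    if a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("expected a Chain or an (N, 3) coordinate array")
    return a


@dataclass(frozen=True)
class ScoringMatrixM:
    """Filled phase-2 scoring matrix plus the per-cell match terms."""

    M: np.ndarray    # (L_part+1, W+1)
    g: float
    sim: np.ndarray  # (L_part, W) match terms 1/(1+d^2/d0^2)


@dataclass(frozen=True)
class Fragment:
    """Run of >= 10 aligned pairs consecutive in both chains."""

    pairs: tuple[tuple[int, int], ...]

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class PartScheme:
    """Equal split of the template into k contiguous parts (sizes differ <= 1)."""

    k: int
    boundaries: tuple[tuple[int, int], ...]  # half-open (start, end) ranges


@dataclass(frozen=True)
class ThreadingResult:
    """Winning window of a gapless threading scan."""

    pairs: tuple[tuple[int, int], ...]
    superposition: Superposition
    tm: float
    shift: int
    n_windows: int


@dataclass(frozen=True)
class ResidueAlignment:
    """Final residue-level alignment of a chain pair.

    ``pairs`` are (template_index, constant_index); ``template_is_first``
    records whether the template was the first argument of
    :func:`align_pair`.
    """

    pairs: tuple[tuple[int, int], ...]
    superposition: Superposition
    tm: float
    rmsd: float
    n_ali: int
    g_used: float
    parts_used: int
    template_is_first: bool = True


def choose_template(chain_a: Chain, chain_b: Chain) -> tuple[Chain, Chain]:
    """Pick the shorter chain as template, the other as constant.

    On equal lengths the first argument is the template.
    """
    if len(chain_b) < len(chain_a):
        return chain_b, chain_a
    return chain_a, chain_b


def score_matrix(
    template_coords: np.ndarray,
    window_coords: np.ndarray,
    sup: Superposition,
    g: float = DEFAULT_GAP_PENALTY,
    *,
    d0_len: int | None = None,
) -> ScoringMatrixM:
    """Fill the phase-2 scoring matrix for a template (part) vs a window.

    ``d0_len`` is the length entering d0 — the FULL template length, also
    when scoring a sub-part of it (defaults to the row count).
    """
    T = _coords(template_coords)
    W = _coords(window_coords)
    L, Wn = len(T), len(W)
    scale = d0(d0_len if d0_len is not None else L)
    moved = sup.apply(T)
    d2 = np.sum((moved[:, None, :] - W[None, :, :]) ** 2, axis=2)
    sim = 1.0 / (1.0 + d2 / scale**2)
    M = np.zeros((L + 1, Wn + 1))
    # antidiagonal sweep: every cell on diagonal s depends only on s-1, s-2
    for s in range(2, L + Wn + 1):
        lo, hi = max(1, s - Wn), min(L, s - 1)
        if lo > hi:
            continue
        i = np.arange(lo, hi + 1)
        j = s - i
        up = M[i - 1, j] + g
        left = M[i, j - 1] + g
        diag = M[i - 1, j - 1] + sim[i - 1, j - 1]
        M[i, j] = np.maximum(np.maximum(up, left), diag)
    return ScoringMatrixM(M=M, g=g, sim=sim)


def dp_traceback_M(mat: ScoringMatrixM) -> list[tuple[int, int]]:
    """Recover one optimal global path from a filled phase-2 matrix.

    Ties are broken diagonal > up > left for determinism.  Returns aligned
    (i, j) pairs, strictly increasing in both coordinates (gap moves emit
    nothing).
    """
    M, g, sim = mat.M, mat.g, mat.sim
    i, j = M.shape[0] - 1, M.shape[1] - 1
    pairs: list[tuple[int, int]] = []
    tol = 1e-12
    while i > 0 and j > 0:
        v = M[i, j]
        if abs(v - (M[i - 1, j - 1] + sim[i - 1, j - 1])) <= tol:
            pairs.append((i - 1, j - 1))
            i -= 1
            j -= 1
        elif abs(v - (M[i - 1, j] + g)) <= tol:
            i -= 1
        else:
            j -= 1
    pairs.reverse()
    return pairs


def collect_fragments(
    pairs: Sequence[tuple[int, int]], min_len: int = MIN_FRAGMENT_LEN
) -> list[Fragment]:
    """Maximal runs of pairs consecutive in BOTH chains, of length >= min_len."""
    fragments: list[Fragment] = []
    run: list[tuple[int, int]] = []
    for p in pairs:
        if run and (p[0] == run[-1][0] + 1 and p[1] == run[-1][1] + 1):
            run.append(p)
        else:
            if len(run) >= min_len:
                fragments.append(Fragment(pairs=tuple(run)))
            run = [p]
    if len(run) >= min_len:
        fragments.append(Fragment(pairs=tuple(run)))
    return fragments


def refine_alignment(
    fragments: Sequence[Fragment],
    template_coords: np.ndarray,
    window_coords: np.ndarray,
    g: float = DEFAULT_GAP_PENALTY,
    *,
    d0_len: int | None = None,
    fallback_pairs: Sequence[tuple[int, int]] = (),
) -> list[tuple[int, int]]:
    """Re-superpose on the union of fragment pairs and re-align.

    Kabsch on all fragment pairs gives a new superposition; a new scoring
    matrix over the same window is filled and traced back.  With no
    fragments (or fewer than 3 fragment pairs) the input alignment is
    returned unchanged.
    """
    frag_pairs = [p for f in fragments for p in f.pairs]
    if len(frag_pairs) < 3:
        return list(fallback_pairs)
    T = _coords(template_coords)
    W = _coords(window_coords)
    ia = np.array([p[0] for p in frag_pairs])
    ib = np.array([p[1] for p in frag_pairs])
    sup = kabsch(T[ia], W[ib])
    mat = score_matrix(T, W, sup, g, d0_len=d0_len)
    return dp_traceback_M(mat)


def gapless_threading(
    template: "Chain | np.ndarray",
    constant: "Chain | np.ndarray",
    g: float = DEFAULT_GAP_PENALTY,
    *,
    d0_len: int | None = None,
    L_norm: int | None = None,
    min_frag: int = MIN_FRAGMENT_LEN,
    shift_range: tuple[int, int] | None = None,
) -> ThreadingResult:
    """Slide the template over every contiguous constant window and keep the
    best-scoring one.

    For each of the L_c - L_t + 1 shifts (optionally restricted to
    ``shift_range``, half-open): Kabsch on the gapless identity
    correspondence, scoring-matrix fill, traceback, fragment collection and
    one re-superposition pass; the resulting alignment is scored by its
    TM-score (normalized by ``L_norm``, template length by default, with
    the d0 of ``d0_len``).  Ties go to the smaller shift.  Returned pair
    indices are template-local and constant-global.
    """
    T = _coords(template)
    C = _coords(constant)
    L_t, L_c = len(T), len(C)
    if L_t > L_c:
        raise ValueError(f"template length {L_t} exceeds constant length {L_c}")
    if L_t < _MIN_PART_LEN:
        raise ValueError(f"template must have >= {_MIN_PART_LEN} residues")
    lo, hi = (0, L_c - L_t + 1) if shift_range is None else shift_range
    lo = max(lo, 0)
    hi = min(hi, L_c - L_t + 1)
    if lo >= hi:
        raise ValueError(f"empty shift range [{lo}, {hi})")
    norm = L_norm if L_norm is not None else L_t
    scale_len = d0_len if d0_len is not None else L_t

    best: ThreadingResult | None = None
    identity = [(i, i) for i in range(L_t)]
    for s in range(lo, hi):
        window = C[s : s + L_t]
        sup0 = kabsch(T, window)
        mat = score_matrix(T, window, sup0, g, d0_len=scale_len)
        pairs_w = dp_traceback_M(mat)
        frags = collect_fragments(pairs_w, min_frag)
        pairs_r = refine_alignment(
            frags, T, window, g, d0_len=scale_len, fallback_pairs=pairs_w
        )
        if len(pairs_r) >= 3:
            tm, sup = tm_score_optimal(pairs_r, T, window, norm, d0_len=scale_len)
        else:
            pairs_r = identity
            tm, sup = tm_score_optimal(identity, T, window, norm, d0_len=scale_len)
        if best is None or tm > best.tm:
            best = ThreadingResult(
                pairs=tuple((i, j + s) for i, j in pairs_r),
                superposition=sup,
                tm=tm,
                shift=s,
                n_windows=hi - lo,
            )
    assert best is not None
    return best


def split_parts(template: "Chain | np.ndarray | int", k: int) -> PartScheme | None:
    """Split the template into k equal contiguous parts.

    Base size floor(L_t / k); the first L_t mod k parts get one extra
    residue.  Returns ``None`` (group skipped) when k exceeds the template
    length or any part would be too short for a rigid fit.
    """
    if k not in PART_GROUPS:
        raise ValueError(f"k must be one of {PART_GROUPS}, got {k}")
    L_t = template if isinstance(template, int) else len(_coords(template))
    if k > L_t:
        return None
    base, extra = divmod(L_t, k)
    if k > 1 and base < _MIN_PART_LEN:
        return None
    sizes = [base + 1] * extra + [base] * (k - extra)
    bounds = []
    start = 0
    for size in sizes:
        bounds.append((start, start + size))
        start += size
    return PartScheme(k=k, boundaries=tuple(bounds))


def _monotone_union(parts_pairs: list[list[tuple[int, int]]]) -> list[tuple[int, int]]:
    """Concatenate per-part pairs, dropping any pair that would break strict
    monotonicity (earlier parts win)."""
    out: list[tuple[int, int]] = []
    for part in parts_pairs:
        for p in part:
            if not out or (p[0] > out[-1][0] and p[1] > out[-1][1]):
                out.append(p)
    return out


def align_pair_groups(
    chain_a: Chain,
    chain_b: Chain,
    g: float = DEFAULT_GAP_PENALTY,
    *,
    parts: Sequence[int] = PART_GROUPS,
    min_frag: int = MIN_FRAGMENT_LEN,
) -> dict[int, ResidueAlignment]:
    """Run the full phase-2 procedure for every part group separately.

    Returns one :class:`ResidueAlignment` per feasible part count k.  Part
    p threads over constant shifts at or after the end of part p-1's
    winning window (and leaves room for the remaining parts), so the
    combined alignment stays sequential.  Each group is scored by one joint
    TM-score-optimal superposition over its combined pairs, normalized by
    the template length.
    """
    template, constant = choose_template(chain_a, chain_b)
    template_is_first = template is chain_a
    T, C = template.coords, constant.coords
    L_t, L_c = len(T), len(C)
    if L_t < 5:
        raise ValueError("chains must have at least 5 residues")

    results: dict[int, ResidueAlignment] = {}
    for k in parts:
        scheme = split_parts(L_t, k)
        if scheme is None:
            continue
        prev_end = 0
        per_part: list[list[tuple[int, int]]] = []
        sizes = [e - s for s, e in scheme.boundaries]
        feasible = True
        for idx, (start, end) in enumerate(scheme.boundaries):
            part_len = end - start
            remaining = sum(sizes[idx + 1 :])
            hi = L_c - part_len - remaining + 1  # leave room for later parts
            if prev_end >= hi:
                feasible = False
                break
            res = gapless_threading(
                T[start:end],
                C,
                g,
                d0_len=L_t,
                L_norm=part_len,
                min_frag=min_frag,
                shift_range=(prev_end, hi),
            )
            per_part.append([(start + i, j) for i, j in res.pairs])
            prev_end = res.shift + part_len
        if not feasible:
            continue
        combined = _monotone_union(per_part)
        if len(combined) < 3:
            continue
        tm, sup = tm_score_optimal(combined, T, C, L_t)
        aps = pair_distances(combined, T, C, sup)
        results[k] = ResidueAlignment(
            pairs=tuple(combined),
            superposition=sup,
            tm=tm,
            rmsd=rmsd(aps),
            n_ali=len(combined),
            g_used=g,
            parts_used=k,
            template_is_first=template_is_first,
        )
    if not results:
        raise ValueError("no feasible part group for these chains")
    return results


def align_pair(
    chain_a: Chain,
    chain_b: Chain,
    g: float = DEFAULT_GAP_PENALTY,
    *,
    parts: Sequence[int] = PART_GROUPS,
    min_frag: int = MIN_FRAGMENT_LEN,
) -> ResidueAlignment:
    """Full phase-2 alignment of two chains.

    Runs every part group and returns the alignment with the highest
    TM-score (ties to the smallest part count).
    """
    groups = align_pair_groups(chain_a, chain_b, g, parts=parts, min_frag=min_frag)
    best_k = min(groups, key=lambda k: (-groups[k].tm, k))
    return groups[best_k]
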