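"""Phase 1: longest-common-subsequence filtering of SSE strings.

Two chains whose 4-state secondary-structure strings share a long common
subsequence are plausible structural neighbours; the rest are discarded
before the expensive residue-level phase.  A pair passes when the LCS
length S[m,n] strictly exceeds min(m,n) × factor (factor 0.7 by default).

Two implementations of the LCS length are provided: the full dynamic
programming matrix (needed for traceback of the initial alignment) and a
bit-parallel scan used by the database search, which only needs the length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sse_assign import SSEString

__all__ = [
    "LcsMatrix",
    "InitialAlignment",
    "lcs_matrix",
    "lcs_length",
    "traceback",
    "passes_filter",
    "DEFAULT_FILTER_FACTOR",
]

DEFAULT_FILTER_FACTOR = 0.7


def _chars(s: "SSEString | str") -> str:
    return s.chars if isinstance(s, SSEString) else s


@dataclass(frozen=True)
class LcsMatrix:
    """(m+1)×(n+1) LCS dynamic-programming matrix.

    S[i,j] is the LCS length of the prefixes A[:i] and B[:j]; row 0 and
    column 0 are zero; S[m,n] is the LCS length of the full strings.
    """

    S: np.ndarray
    m: int
    n: int

    @property
    def lcs_length(self) -> int:
        return int(self.S[self.m, self.n])


@dataclass(frozen=True)
class InitialAlignment:
    """One optimal LCS path: matched index pairs, increasing in both coordinates."""

    pairs: tuple[tuple[int, int], ...]
    lcs_length: int


def lcs_matrix(A: "SSEString | str", B: "SSEString | str") -> LcsMatrix:
    """Fill the LCS DP matrix.

    S[i,j] = 0 on the borders; S[i-1,j-1]+1 on a character match;
    max(S[i-1,j], S[i,j-1]) otherwise.
    """
    a, b = _chars(A), _chars(B)
    m, n = len(a), len(b)
    S = np.zeros((m + 1, n + 1), dtype=np.int32)
    if m and n:
        av = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
        bv = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
        for i in range(1, m + 1):
            prev = S[i - 1]
            cur = S[i]
            match = av[i - 1] == bv
            run = 0
            for j in range(1, n + 1):
                if match[j - 1]:
                    run = prev[j - 1] + 1
                else:
                    run = max(prev[j], run)
                cur[j] = run
    return LcsMatrix(S=S, m=m, n=n)


def lcs_length(A: "SSEString | str", B: "SSEString | str") -> int:
    """LCS length via the bit-parallel column scan (no matrix, O(mn/w)).

    Equivalent to ``lcs_matrix(A, B).lcs_length`` but far faster on
    protein-scale strings; used by the database filter where the traceback
    path is not needed.
    """
    a, b = _chars(A), _chars(B)
    m = len(a)
    if m == 0 or len(b) == 0:
        return 0
    masks: dict[str, int] = {}
    for i, ch in enumerate(a):
        masks[ch] = masks.get(ch, 0) | (1 << i)
    full = (1 << m) - 1
    V = full
    for ch in b:
        U = V & masks.get(ch, 0)
        V = ((V + U) | (V & ~U & full)) & full
    # zero bits of V mark matched positions of A
    return m - bin(V).count("1")


def traceback(mat: LcsMatrix, A: "SSEString | str", B: "SSEString | str") -> InitialAlignment:
    """Recover one optimal LCS path from a filled matrix.

    Tie-break when max(S[i-1,j], S[i,j-1]) is ambiguous: take the matched
    diagonal when the characters agree, otherwise prefer the up-move
    (i-1, j) over the left-move — fixed so the path is deterministic.
    """
    a, b = _chars(A), _chars(B)
    if mat.m != len(a) or mat.n != len(b):
        raise ValueError("matrix dimensions do not match the strings")
    S = mat.S
    i, j = mat.m, mat.n
    pairs: list[tuple[int, int]] = []
    while i > 0 and j > 0:
        if a[i - 1] == b[j - 1]:
            pairs.append((i - 1, j - 1))
            i -= 1
            j -= 1
        elif S[i - 1, j] >= S[i, j - 1]:
            i -= 1
        else:
            j -= 1
    pairs.reverse()
    return InitialAlignment(pairs=tuple(pairs), lcs_length=mat.lcs_length)


def passes_filter(
    lcs_len: int, m: int, n: int, factor: float = DEFAULT_FILTER_FACTOR
) -> bool:
    """Phase-1 pass test: LCS length strictly greater than min(m,n) × factor."""
    if not (0.0 < factor <= 1.0):
        raise ValueError(f"factor must be in (0, 1], got {factor}")
    if m < 1 or n < 1:
        raise ValueError("string lengths must be >= 1")
    return lcs_len > min(m, n) * factor
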