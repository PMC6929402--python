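"""Per-residue 4-state secondary-structure strings.

The first alignment phase represents each chain as a string over the
alphabet ``{H, E, C, O}`` — α-helix, β-strand, coil, other — one character
per residue.  The string can come from a DSSP output file (preferred when
available) or from a purely Cα-geometric assigner so the tool has no
external-binary dependency.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .structure_io import Chain

__all__ = ["SSEString", "map_dssp_states", "assign_sse_from_ca", "read_dssp"]

FOUR_STATE_ALPHABET = "HECO"

# DSSP 8-state -> 4-state collapse.  3_10 (G) and π (I) helices fold into H
# to keep helix subtypes mutually matchable in the LCS phase; turns, bends
# and isolated β-bridges are treated as coil; unassigned states as other.
_DSSP_MAP = {
    "H": "H", "G": "H", "I": "H",
    "E": "E",
    "T": "C", "S": "C", "B": "C",
    " ": "O", "-": "O",
}

# Cα-distance signatures of ideal secondary structure, in Å.
HELIX_D13 = 5.3   # d(i, i+3) in an α-helix
HELIX_D14 = 6.4   # d(i, i+4) in an α-helix
STRAND_D13 = 6.7  # d(i, i+2) in a β-strand
SSE_TOL = 1.0     # acceptance window around each signature distance
_EXTENDED_D4 = 10.0  # d(i-2, i+2) above this means locally extended


@dataclass(frozen=True)
class SSEString:
    """4-state secondary-structure string aligned to a chain."""

    chars: str

    def __post_init__(self) -> None:
        bad = set(self.chars) - set(FOUR_STATE_ALPHABET)
        if bad:
            raise ValueError(f"invalid SSE characters: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.chars)

    def __str__(self) -> str:
        return self.chars


def map_dssp_states(dssp_states: str) -> SSEString:
    """Collapse a DSSP 8-state string to the 4-state alphabet.

    H, G, I → H;  E → E;  T, S, B → C;  blank/'-' → O.
    """
    out = []
    for ch in dssp_states:
        try:
            out.append(_DSSP_MAP[ch])
        except KeyError:
            raise ValueError(f"unknown DSSP state {ch!r}") from None
    return SSEString("".join(out))


def assign_sse_from_ca(
    chain: Chain,
    *,
    helix_d13: float = HELIX_D13,
    helix_d14: float = HELIX_D14,
    strand_d13: float = STRAND_D13,
    tol: float = SSE_TOL,
) -> SSEString:
    """Assign 4-state secondary structure from Cα geometry alone.

    A residue needs 4 neighbours on each side to be classified; termini get
    'O'.  Helix: d(i,i+3)≈5.3 Å and d(i,i+4)≈6.4 Å on 3 consecutive
    residues.  Strand: d(i,i+2)≈6.7 Å on 3 consecutive residues and the
    local trace is extended.  Everything else classified is coil.

    The assignment depends only on inter-Cα distances, hence is exactly
    invariant under rigid motion of the chain.
    """
    n = len(chain)
    xyz = chain.coords

    def d(i: int, j: int) -> float:
        return float(np.linalg.norm(xyz[i] - xyz[j]))

    chars = ["O"] * n
    for i in range(4, n - 4):
        # smooth over 3 consecutive windows ending at i; indices stay in
        # [i-2, i+4], inside the 4-neighbour margin
        helix = all(
            abs(d(o, o + 3) - helix_d13) <= tol and abs(d(o, o + 4) - helix_d14) <= tol
            for o in (i - 2, i - 1, i)
        )
        if helix:
            chars[i] = "H"
            continue
        strand = all(
            abs(d(o, o + 2) - strand_d13) <= tol for o in (i - 2, i - 1, i)
        ) and d(i - 2, i + 2) > _EXTENDED_D4
        chars[i] = "E" if strand else "C"
    return SSEString("".join(chars))


def read_dssp(path: str | Path, chain_id: str | None = None) -> str:
    """Extract the one-letter structure column for one chain from a classic
    ``.dssp`` file.

    Returns the raw 8-state string (blanks preserved); feed it through
    :func:`map_dssp_states` to get the 4-state representation.  Chain-break
    lines ('!' residues) are skipped.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    try:
        start = next(i for i, ln in enumerate(lines) if ln.lstrip().startswith("#  RESIDUE"))
    except StopIteration:
        raise ValueError(f"{path} does not look like DSSP output") from None
    states = []
    for ln in lines[start + 1:]:
        if len(ln) < 17:
            continue
        aa = ln[13]
        if aa == "!":
            continue  # chain break marker
        ch = ln[11]
        if chain_id is not None and ch != chain_id:
            continue
        states.append(ln[16])
    return "".join(states)
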