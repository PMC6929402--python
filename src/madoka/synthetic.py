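"""Synthetic Cα traces with known ground truth.

Generates idealized helix / strand / coil traces, optionally perturbed by
Gaussian coordinate noise and moved by a known rigid transform, plus decoy
chains with a template rigidly embedded at a known offset.  Every stage of
the alignment pipeline can thus be exercised against a planted answer
without downloading real structures.

Geometry of the ideal motifs:

* helix — rise 1.5 Å per residue, radius 2.3 Å, 100° twist per residue
  (consecutive Cα spacing ≈ 3.8 Å);
* strand — near-collinear zig-zag with 3.8 Å Cα spacing and ≈ 6.7 Å
  d(i, i+2);
* coil — self-avoiding random walk with 3.8 Å steps (non-bonded Cα pairs
  kept > 3.4 Å apart by rejection sampling).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import Superposition
from .structure_io import Chain, Residue
from .sse_assign import SSEString

__all__ = [
    "SyntheticSpec",
    "make_chain",
    "make_decoy_with_embedded_template",
    "make_two_part_decoy",
    "random_rotation",
]

CA_STEP = 3.8          # Å, consecutive Cα spacing
HELIX_RISE = 1.5       # Å per residue
HELIX_RADIUS = 2.3     # Å
HELIX_TWIST = 100.0    # degrees per residue
_COIL_MIN_SEP = 3.4    # Å, minimum non-bonded Cα separation
_MOTIFS = ("helix", "strand", "coil", "mixed")


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic chain; identical seeds give identical output."""

    n_res: int
    motif: str = "helix"
    noise_sigma: float = 0.0
    transform: Superposition | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_res < 1:
            raise ValueError("n_res must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.motif not in _MOTIFS:
            raise ValueError(f"motif must be one of {_MOTIFS}")


def random_rotation(rng: np.random.Generator) -> Superposition:
    """Uniform random proper rotation (QR of a Gaussian matrix) with a
    random translation in [-20, 20]^3 Å."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.uniform(-20.0, 20.0, size=3)
    return Superposition(rotation=Q, translation=t)


def _helix_coords(n: int) -> np.ndarray:
    i = np.arange(n)
    theta = np.deg2rad(HELIX_TWIST) * i
    return np.column_stack(
        [HELIX_RADIUS * np.cos(theta), HELIX_RADIUS * np.sin(theta), HELIX_RISE * i]
    )


def _strand_coords(n: int) -> np.ndarray:
    # zig-zag chosen so d(i,i+1) = 3.8 and d(i,i+2) = 6.7
    a = 6.7 / 2.0
    b = math.sqrt(CA_STEP**2 - a**2) / 2.0
    i = np.arange(n)
    return np.column_stack([a * i, b * np.where(i % 2 == 0, 1.0, -1.0), np.zeros(n)])


def _coil_coords(n: int, rng: np.random.Generator) -> np.ndarray:
    pts = [np.zeros(3)]
    while len(pts) < n:
        placed = False
        for _ in range(200):
            v = rng.normal(size=3)
            v *= CA_STEP / np.linalg.norm(v)
            cand = pts[-1] + v
            prior = np.array(pts[:-1]) if len(pts) > 1 else None
            if prior is None or np.min(np.linalg.norm(prior - cand, axis=1)) > _COIL_MIN_SEP:
                pts.append(cand)
                placed = True
                break
        if not placed:  # dead end: back up one step and retry
            if len(pts) > 1:
                pts.pop()
            else:
                pts = [np.zeros(3)]
    return np.array(pts)


def _append_segment(base: np.ndarray, seg: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Translate ``seg`` so its first residue sits one Cα step beyond the
    last residue of ``base``, in a random direction."""
    if len(base) == 0:
        return seg
    v = rng.normal(size=3)
    v *= CA_STEP / np.linalg.norm(v)
    return np.vstack([base, seg - seg[0] + base[-1] + v])


def _motif_segments(spec: SyntheticSpec, rng: np.random.Generator) -> tuple[np.ndarray, str]:
    n = spec.n_res
    if spec.motif == "helix":
        return _helix_coords(n), "H" * n
    if spec.motif == "strand":
        return _strand_coords(n), "E" * n
    if spec.motif == "coil":
        return _coil_coords(n, rng), "C" * n
    # mixed: helix / coil / strand thirds
    n1 = n // 3
    n2 = n // 3
    n3 = n - n1 - n2
    coords = np.empty((0, 3))
    labels = ""
    for size, motif in ((n1, "helix"), (n2, "coil"), (n3, "strand")):
        if size == 0:
            continue
        seg = {"helix": _helix_coords, "strand": _strand_coords}.get(motif)
        seg_coords = seg(size) if seg else _coil_coords(size, rng)
        coords = _append_segment(coords, seg_coords, rng)
        labels += {"helix": "H", "coil": "C", "strand": "E"}[motif] * size
    return coords, labels


def make_chain(spec: SyntheticSpec, *, structure_id: str | None = None) -> tuple[Chain, SSEString]:
    """Build a synthetic chain and its ground-truth 4-state SSE string."""
    rng = np.random.default_rng(spec.seed)
    coords, labels = _motif_segments(spec, rng)
    if spec.noise_sigma > 0:
        coords = coords + rng.normal(scale=spec.noise_sigma, size=coords.shape)
    if spec.transform is not None:
        coords = spec.transform.apply(coords)
    sid = structure_id or f"synth_{spec.motif}_{spec.seed}"
    chain = Chain(
        structure_id=sid,
        chain_id="A",
        residues=tuple(
            Residue(seq_index=i, resname="GLY", ca=coords[i], auth_seq_id=i + 1)
            for i in range(len(coords))
        ),
    )
    return chain, SSEString(labels)


def _embed(
    length: int,
    inserts: list[tuple[int, np.ndarray]],
    rng: np.random.Generator,
) -> Chain:
    """Coil chain of ``length`` residues with rigid segments planted at the
    given offsets (segments pre-transformed by the caller)."""
    inserts = sorted(inserts, key=lambda t: t[0])
    coords = np.empty((0, 3))
    cursor = 0
    for offset, seg in inserts:
        if offset < cursor:
            raise ValueError("overlapping or out-of-order embeddings")
        if offset + len(seg) > length:
            raise ValueError("embedding does not fit in the decoy length")
        if offset > cursor:
            flank = _coil_coords(offset - cursor, rng)
            coords = _append_segment(coords, flank, rng)
        # keep the segment rigid: translate whole block for continuity only
        if len(coords) > 0:
            v = rng.normal(size=3)
            v *= CA_STEP / np.linalg.norm(v)
            seg = seg - seg[0] + coords[-1] + v
        coords = np.vstack([coords, seg]) if len(coords) else seg.copy()
        cursor = offset + len(seg)
    if cursor < length:
        coords = _append_segment(coords, _coil_coords(length - cursor, rng), rng)
    chain = Chain(
        structure_id="decoy",
        chain_id="A",
        residues=tuple(
            Residue(seq_index=i, resname="GLY", ca=coords[i], auth_seq_id=i + 1)
            for i in range(len(coords))
        ),
    )
    return chain


def make_decoy_with_embedded_template(
    template: Chain,
    offset: int,
    total_length: int,
    *,
    seed: int = 0,
    transform: Superposition | None = None,
) -> Chain:
    """Decoy chain whose window [offset, offset + L_t) is a rigid copy of
    the template; the flanks are coil.

    The copy is moved as one rigid block (optionally pre-rotated by
    ``transform``), so threading the template over the decoy should win at
    shift ``offset`` with a perfect superposition.
    """
    L_t = len(template)
    if offset < 0 or offset + L_t > total_length:
        raise ValueError(
            f"offset {offset} with template length {L_t} does not fit in {total_length}"
        )
    rng = np.random.default_rng(seed)
    seg = template.coords
    if transform is not None:
        seg = transform.apply(seg)
    return _embed(total_length, [(offset, seg)], rng)


def make_two_part_decoy(
    template: Chain,
    offsets: tuple[int, int],
    total_length: int,
    *,
    seed: int = 0,
) -> Chain:
    """Decoy with the template's two halves planted at non-contiguous
    offsets, both under one common rigid motion, separated by coil.

    A single gapless window of template length cannot span both halves
    (the coil insertion pushes the second half out of reach), while a
    2-part split threads each half onto its own embedding; because the
    halves share one rigid placement, the combined alignment superposes
    jointly — so the 2-part group should score strictly above the unsplit
    threading.  Coil filler connects to the planted blocks only
    approximately (the blocks' absolute placement is what matters here).
    """
    rng = np.random.default_rng(seed)
    L_t = len(template)
    half = L_t // 2
    o1, o2 = offsets
    if o2 < o1 + half:
        raise ValueError("second offset overlaps the first embedding")
    if o2 + (L_t - half) > total_length:
        raise ValueError("second half does not fit in the decoy length")
    placed = random_rotation(rng).apply(template.coords)
    first, second = placed[:half], placed[half:]

    coords = np.zeros((total_length, 3))
    coords[o1 : o1 + half] = first
    coords[o2 : o2 + (L_t - half)] = second
    if o1 > 0:  # leading coil, re-anchored to end one step before the first block
        lead = _coil_coords(o1, rng)
        v = rng.normal(size=3)
        v *= CA_STEP / np.linalg.norm(v)
        coords[:o1] = lead - lead[-1] + first[0] + v
    if o2 > o1 + half:  # insertion coil wandering off the first block's end
        mid = _coil_coords(o2 - o1 - half, rng)
        v = rng.normal(size=3)
        v *= CA_STEP / np.linalg.norm(v)
        coords[o1 + half : o2] = mid - mid[0] + first[-1] + v
    tail_start = o2 + (L_t - half)
    if tail_start < total_length:
        tail = _coil_coords(total_length - tail_start, rng)
        v = rng.normal(size=3)
        v *= CA_STEP / np.linalg.norm(v)
        coords[tail_start:] = tail - tail[0] + second[-1] + v
    return Chain(
        structure_id="decoy2",
        chain_id="A",
        residues=tuple(
            Residue(seq_index=i, resname="GLY", ca=coords[i], auth_seq_id=i + 1)
            for i in range(total_length)
        ),
    )
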