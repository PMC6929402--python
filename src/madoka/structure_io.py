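"""PDB input/output restricted to per-chain Cα traces.

The alignment engine operates on the alpha-carbon trace of a single chain:
one 3-vector per residue, in file order.  Everything else in a PDB file
(side chains, heteroatoms, waters, anisotropic records) is ignored.  Only
the first MODEL of a multi-model (e.g. NMR) entry is read, since the
alignment is single-conformer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Residue",
    "Chain",
    "ChainNotFoundError",
    "EmptyChainError",
    "read_pdb_chain",
    "list_chains",
    "write_pdb_chain",
]


class ChainNotFoundError(KeyError):
    """Requested chain identifier does not occur in the file."""


class EmptyChainError(ValueError):
    """The chain exists but contains no Cα atoms."""


@dataclass(frozen=True)
class Residue:
    """One residue reduced to its Cα position.

    ``seq_index`` is a dense 0-based positional index within the chain (the
    algorithms are purely positional); the author-assigned residue number
    and insertion code are kept for reporting only.
    """

    seq_index: int
    resname: str
    ca: np.ndarray  # shape (3,), Å
    auth_seq_id: int = 0
    icode: str = ""

    def __post_init__(self) -> None:
        ca = np.asarray(self.ca, dtype=float)
        if ca.shape != (3,) or not np.all(np.isfinite(ca)):
            raise ValueError("Cα coordinates must be a finite 3-vector")
        object.__setattr__(self, "ca", ca)


@dataclass(frozen=True)
class Chain:
    """Ordered Cα trace of one protein chain."""

    structure_id: str
    chain_id: str
    residues: tuple[Residue, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", tuple(self.residues))
        if len(self.residues) < 1:
            raise EmptyChainError(
                f"chain {self.chain_id!r} of {self.structure_id!r} has no residues"
            )
        idx = [r.seq_index for r in self.residues]
        if idx != sorted(set(idx)):
            raise ValueError("seq_index must be strictly increasing and unique")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def coords(self) -> np.ndarray:
        """(L, 3) array of Cα coordinates in Å."""
        return np.array([r.ca for r in self.residues], dtype=float)

    @property
    def name(self) -> str:
        return f"{self.structure_id}_{self.chain_id}"


def _first_ca(res: gemmi.Residue) -> gemmi.Atom | None:
    # first-listed conformer wins when altlocs are present
    for atom in res:
        if atom.name == "CA":
            return atom
    return None


def read_pdb_chain(path: str | Path, chain_id: str | None = None) -> Chain:
    """Read the Cα trace of one chain from a PDB file.

    Parameters
    ----------
    path:
        PDB-format text file.
    chain_id:
        Chain identifier; ``None`` selects the first chain that has Cα atoms.

    Returns one :class:`Residue` per Cα-bearing ATOM residue, in file order,
    densely re-indexed from 0.  HETATM records and residues lacking a Cα are
    excluded; altloc duplicates collapse to the first-listed conformer.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    structure = gemmi.read_pdb(str(path))
    if len(structure) == 0:
        raise EmptyChainError(f"{path} contains no models")
    model = structure[0]  # first model only

    if chain_id is None:
        available = list_chains(path)
        if not available:
            raise EmptyChainError(f"{path} has no chain with Cα atoms")
        chain_id = available[0]

    gchain = None
    for ch in model:
        if ch.name == chain_id:
            gchain = ch
            break
    if gchain is None:
        raise ChainNotFoundError(
            f"chain {chain_id!r} not found in {path} "
            f"(present: {[c.name for c in model]})"
        )

    residues: list[Residue] = []
    skipped = 0
    for res in gchain:
        if res.het_flag != "A":
            continue
        atom = _first_ca(res)
        if atom is None:
            skipped += 1
            continue
        residues.append(
            Residue(
                seq_index=len(residues),
                resname=res.name,
                ca=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                auth_seq_id=res.seqid.num,
                icode=res.seqid.icode.strip(),
            )
        )
    if skipped:
        logger.info("%s chain %s: skipped %d residue(s) without Cα", path, chain_id, skipped)
    if not residues:
        raise EmptyChainError(f"chain {chain_id!r} in {path} has no Cα atoms")
    return Chain(structure_id=path.stem, chain_id=chain_id, residues=tuple(residues))


def list_chains(path: str | Path) -> list[str]:
    """Distinct chain ids having at least one Cα ATOM, in order of appearance."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    structure = gemmi.read_pdb(str(path))
    if len(structure) == 0:
        return []
    seen: list[str] = []
    for ch in structure[0]:
        if ch.name in seen:
            continue
        for res in ch:
            if res.het_flag == "A" and _first_ca(res) is not None:
                seen.append(ch.name)
                break
    return seen


_ATOM_FMT = (
    "ATOM  {serial:>5d}  CA  {resname:<3s} {chain:1s}{resseq:>4d}    "
    "{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
)


def _chain_to_pdb_lines(chain: Chain, serial0: int = 1) -> list[str]:
    lines = []
    for k, res in enumerate(chain.residues):
        lines.append(
            _ATOM_FMT.format(
                serial=serial0 + k,
                resname=(res.resname or "GLY")[:3],
                chain=chain.chain_id[:1] or "A",
                resseq=res.auth_seq_id if res.auth_seq_id else res.seq_index + 1,
                x=res.ca[0],
                y=res.ca[1],
                z=res.ca[2],
            )
        )
    return lines


def write_pdb_chain(chain: Chain, path: str | Path, *, extra_models: list[Chain] | None = None) -> None:
    """Write a minimal Cα-only PDB file (wwPDB v3.3 fixed-width columns).

    With ``extra_models``, each chain goes into its own MODEL record — used
    for superposed alignment output, where the constant structure stays in
    its original frame and the transformed template follows.
    """
    path = Path(path)
    chains = [chain] + list(extra_models or [])
    out: list[str] = []
    if len(chains) == 1:
        out.extend(_chain_to_pdb_lines(chain))
        out.append("TER")
    else:
        for num, ch in enumerate(chains, start=1):
            out.append(f"MODEL     {num:>4d}")
            out.extend(_chain_to_pdb_lines(ch))
            out.append("TER")
            out.append("ENDMDL")
    out.append("END")
    path.write_text("\n".join(out) + "\n")
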