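import itertools

import numpy as np
import pytest

from madoka.structure_io import Chain, Residue
from madoka.synthetic import SyntheticSpec, make_chain


def brute_force_lcs(a: str, b: str) -> int:
    """Exhaustive LCS oracle: enumerate every subsequence of the shorter
    string and test it against the longer one. Only viable for tiny inputs."""
    if len(a) > len(b):
        a, b = b, a

    def is_subseq(s: str, t: str) -> bool:
        it = iter(t)
        return all(c in it for c in s)

    best = 0
    for r in range(len(a), 0, -1):
        for idx in itertools.combinations(range(len(a)), r):
            if is_subseq("".join(a[i] for i in idx), b):
                return r
    return best


def brute_force_best_path(sim, g: float) -> float:
    """Independent oracle for the phase-2 DP: enumerate every monotone
    lattice path from (0,0) to (L,W) move by move, scoring diagonal moves
    by the match term and gap moves by g, with the running score reset to 0
    on the zero border."""
    L, W = sim.shape
    best = [-np.inf]

    def walk(i: int, j: int, v: float) -> None:
        if i == 0 or j == 0:
            v = 0.0
        if i == L and j == W:
            best[0] = max(best[0], v)
            return
        if i < L and j < W:
            walk(i + 1, j + 1, v + sim[i, j])
        if i < L:
            walk(i + 1, j, v + g)
        if j < W:
            walk(i, j + 1, v + g)

    walk(0, 0, 0.0)
    return best[0]


def chain_from_coords(coords, structure_id="test", chain_id="A") -> Chain:
    coords = np.asarray(coords, dtype=float)
    return Chain(
        structure_id=structure_id,
        chain_id=chain_id,
        residues=tuple(
            Residue(seq_index=i, resname="GLY", ca=coords[i], auth_seq_id=i + 1)
            for i in range(len(coords))
        ),
    )


@pytest.fixture
def helix_chain():
    chain, _ = make_chain(SyntheticSpec(n_res=20, motif="helix", seed=1))
    return chain


@pytest.fixture
def mixed_chain():
    chain, _ = make_chain(SyntheticSpec(n_res=40, motif="mixed", seed=7))
    return chain


TWO_CHAIN_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  CA  GLY A   2      12.513   7.500  -2.900  1.00  0.00           C
ATOM      4  CA  SER A   3       9.700   9.100  -1.500  1.00  0.00           C
TER
ATOM      5  CA  LEU B  10       1.000   2.000   3.000  1.00  0.00           C
ATOM      6  CA  VAL B  11       4.800   2.100   3.100  1.00  0.00           C
TER
HETATM    7 CA    CA A 101      0.000   0.000   0.000  1.00  0.00          CA
HETATM    8  O   HOH B 102      5.000   5.000   5.000  1.00  0.00           O
END
"""


@pytest.fixture
def two_chain_pdb(tmp_path):
    path = tmp_path / "two_chain.pdb"
    path.write_text(TWO_CHAIN_PDB)
    return path
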