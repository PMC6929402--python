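# Methods

This note documents the models, parameters and design choices behind the
package, what the synthetic fixtures do and do not emulate, and the known
limitations.

## Structure representation

All algorithms operate on the ordered Cα trace of a single chain. The PDB
reader keeps one residue per Cα-bearing ATOM record, in file order, with a
dense 0-based positional index; author numbering and insertion codes are
retained for reporting only. HETATM records, residues without a Cα, and
all models after the first of a multi-model entry are dropped. When
altloc conformers are present the first-listed one is used — at Cα
resolution the conformers differ by fractions of an Ångström, well below
the distance scales the scoring uses.

## Secondary-structure strings (phase 1)

Each residue is classed as H (α-helix, including 3₁₀ and π when mapping
from DSSP — folding the helix subtypes together keeps them mutually
matchable in the string comparison), E (β-strand), C (coil: turns, bends
and isolated β-bridges) or O (other/unassigned). When no DSSP file is
supplied, a purely geometric assigner classifies each residue from
inter-Cα distances, which makes the assignment exactly invariant under
rigid motion:

* helix signature: d(i,i+3) ≈ 5.3 Å and d(i,i+4) ≈ 6.4 Å;
* strand signature: d(i,i+2) ≈ 6.7 Å with a locally extended trace
  (d(i−2,i+2) > 10 Å);
* each signature must hold over 3 consecutive windows anchored at
  (i−2, i−1, i), a smoothing that suppresses single-residue flickers; the
  windows are anchored backward so every probed index stays within the
  4-neighbour margin that classification requires.

Tolerance is ±1.0 Å on each signature distance. Residues closer than 4
positions to either terminus are labelled O, so chains shorter than 9
residues come out all-O. These constants are exposed as keyword arguments;
they were chosen from the geometry of ideal motifs and are not fitted.

The LCS filter threshold is `min(m,n) × 0.7`, compared strictly
(`S[m,n] > threshold`), with the factor kept as a float. The database
driver computes LCS lengths with a bit-parallel scan (word-packed column
updates, algebraically equivalent to the DP matrix and cross-checked
against it and against exhaustive enumeration in the tests); the full
matrix implementation is used whenever the traceback path itself is
needed. Traceback ties (when `S[i-1,j] = S[i,j-1]`) resolve to the
up-move, making the recovered path deterministic.

## Superposition and scores (phase 2)

The Kabsch fit is the closed-form SVD solution with the usual
determinant-sign correction to exclude reflections; it requires ≥ 3
non-collinear points. RMSD is the root mean square of the per-pair
distances. The TM-score distance scale d0(L) = 1.24·∛(L−15) − 1.8 Å is
clamped below at 0.5 Å so the score stays well-defined for fragments and
parts of length ≤ 21, following the convention long used with this score.
TM-scores are normalized by the template (shorter-chain) length, the same
length that enters d0 — one consistent convention throughout.

The maximization over superpositions is a deterministic iterative
refinement: starting from the Kabsch fit on all aligned pairs, the fit is
repeated on the subset of pairs closer than a cutoff descending through
8, 7, 6, 5, 4.5, 4, 3.5 Å and finally d0, iterating at each cutoff until
the subset stabilizes (or 20 iterations), keeping the superposition with
the highest TM-score over all pairs. The result is never worse than the
plain all-pair fit. On random decoy pairs this refinement reliably finds
optima that thousands of random-rotation restarts with greedy descent do
not reach (the TM landscape at d0 of ~1–2 Å is extremely spiky), so the
test suite checks dominance over a randomized search rather than
agreement with it.

## Alignment engine

Per constant window: Kabsch on the gapless identity correspondence →
scoring-matrix fill → global traceback (ties diagonal > up > left) →
collection of runs of ≥ 10 pairs consecutive in both chains → one
re-superposition on the union of those runs and one re-alignment. A
single refinement pass is used; iterating to convergence changed nothing
on the fixtures and costs a full matrix fill per round.

The gap term g is *added* on gap moves exactly as the scoring matrix
definition is printed, default 3×10⁻⁶ (a setting suited to remote
homologs; 0.08 suits structurally analogous pairs better). Negating the
penalty for experimentation is just `--gap-penalty -0.08`; no separate
sign flag is provided. The matrix is filled by an antidiagonal
vectorized sweep (cells on diagonal s depend only on diagonals s−1, s−2),
verified cell-for-cell against the naive nested-loop recurrence.

Multi-part splitting: the template is divided into k ∈ {1, 2, 3, 5, 8}
contiguous parts, base size ⌊L_t/k⌋ with the remainder distributed to the
leading parts. Groups with k > L_t, or whose parts would be shorter than
the 3 residues a rigid fit needs, are skipped. Parts thread in template
order over disjoint, ordered constant regions: part p's windows start at
or after part p−1's winning window end, and the upper shift bound leaves
room for the remaining parts, which guarantees every part gets a
feasible window. The per-part alignments are concatenated (any pair that
would break strict monotonicity is dropped, earlier parts winning — with
the disjoint-window constraint this is a no-op in practice) and the group
is scored by ONE joint TM-score-optimal superposition over the combined
pairs, normalized by the full template length. The highest-scoring group
wins; ties go to the smaller k.

Scoring a group with a single joint superposition has a consequence worth
stating: splitting helps when the template's pieces occur in the constant
*non-contiguously but under a compatible rigid placement* (domains
separated by an insertion). If the pieces sit in mutually incompatible
orientations, no single rigid transform can reward both, and the split
gains nothing — a flexible/hinge alignment is out of scope.

## Search driver

One query against a database directory: phase 1 on every entry, phase 2
only on survivors; results ranked by TM-score descending then identifier
ascending (a total order, so ties are stable). Each pair is a pure
function of its inputs, evaluated with joblib when there are more than 8
tasks and more than one worker; because tasks share no state and the
ranking is a total order, reports are byte-identical for any worker
count. The all-vs-all mode evaluates each unordered pair once
(n(n−1)/2 pairs) and reports summary means over the pairs that completed
phase 2.

## Synthetic fixtures

The generator produces idealized Cα geometry with planted ground truth:

* helix: rise 1.5 Å/residue, radius 2.3 Å, 100°/residue twist
  (consecutive Cα ≈ 3.8 Å);
* strand: planar zig-zag with 3.8 Å steps and d(i,i+2) = 6.7 Å;
* coil: self-avoiding random walk, 3.8 Å steps, non-bonded pairs kept
  > 3.4 Å apart by rejection with backtracking;
* mixed: helix/coil/strand thirds joined end to end;
* decoys: a rigid copy of a template planted at a known offset inside
  coil flanks, and a two-part variant with the template's halves planted
  non-contiguously under one common rigid placement, separated by more
  coil than a single gapless window can span — the fixture on which
  splitting provably beats unsplit threading.

Gaussian coordinate noise and a known rigid transform can be applied on
top; everything is deterministic per seed. These fixtures emulate the
*geometry* the algorithms consume, not real proteins: there is no
Ramachandran statistics, no side-chain packing, no compact globular fold,
and coil decoys are far less self-similar than real structure databases.
Passing tests therefore demonstrate algorithmic correctness (planted
answers recovered, oracles matched, invariants held), not benchmark-level
accuracy on curated structure sets, which would require the original
experimental structures.

Problem sizes used throughout the tests and the acceptance script —
templates of 20–40 residues, constants up to 100, databases of 10–200
synthetic entries — were chosen as the smallest sizes at which every
behaviour of interest (filtering, threading, splitting, parallelism) is
exercised with non-trivial window counts.

## Numerical choices and degenerate inputs

* Traceback comparisons use a 10⁻¹² absolute tolerance; matrix cells are
  recomputed with the same floating-point operations that filled them, so
  the comparison is exact in practice and the tolerance only guards
  against pathological compiler reassociation.
* Rotation matrices are validated to 10⁻⁸ (orthonormality, det = +1).
* Empty pair sets: TM-score 0; RMSD raises (undefined).
* Chains shorter than 5 residues are rejected by the pair aligner;
  templates shorter than 3 cannot be rigidly fitted anywhere.
* d0 clamp at 0.5 Å as above.

## Known limitations

* Alignments are strictly sequential; circular permutations,
  non-sequential topologies and hinge motions are not handled.
* The geometric SSE assigner is a deliberate Cα-only classifier; it
  agrees with hydrogen-bond-based assignment on ideal geometry but will
  differ on distorted real structures, shifting phase-1 pass rates.
* The gap term must be chosen by the user per dataset character (remote
  homologs vs analogous folds); no automatic selection is attempted.
* mmCIF input is not parsed; convert to PDB first.
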