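import numpy as np
import pytest

from conftest import brute_force_best_path, chain_from_coords
from madoka.accurate_align import (
    DEFAULT_GAP_PENALTY,
    ScoringMatrixM,
    align_pair,
    align_pair_groups,
    choose_template,
    collect_fragments,
    dp_traceback_M,
    gapless_threading,
    refine_alignment,
    score_matrix,
    split_parts,
)
from madoka.geometry import Superposition, d0, kabsch
from madoka.synthetic import (
    SyntheticSpec,
    make_chain,
    make_decoy_with_embedded_template,
    make_two_part_decoy,
    random_rotation,
)


class TestChooseTemplate:
    def test_shorter_first_argument_wins(self):
        a = chain_from_coords(np.random.default_rng(0).normal(size=(9, 3)))
        b = chain_from_coords(np.random.default_rng(1).normal(size=(30, 3)))
        assert choose_template(a, b) == (a, b)
        assert choose_template(b, a) == (a, b)

    def test_equal_lengths_tie_breaks_to_first(self):
        a = chain_from_coords(np.random.default_rng(2).normal(size=(9, 3)))
        b = chain_from_coords(np.random.default_rng(3).normal(size=(9, 3)))
        assert choose_template(a, b)[0] is a


class TestScoreMatrix:
    def test_border_rows_and_columns_zero(self):
        rng = np.random.default_rng(4)
        T = rng.normal(size=(5, 3))
        mat = score_matrix(T, T, Superposition.identity(), DEFAULT_GAP_PENALTY)
        assert np.all(mat.M[0, :] == 0) and np.all(mat.M[:, 0] == 0)

    def test_perfectly_superposed_diagonal_accumulates_ones(self):
        rng = np.random.default_rng(5)
        T = rng.normal(size=(6, 3)) * 5
        mat = score_matrix(T, T, Superposition.identity(), DEFAULT_GAP_PENALTY)
        for i in range(1, 7):
            assert mat.M[i, i] == pytest.approx(i * 1.0, abs=1e-9)

    def test_single_residue_at_d0_scores_half(self):
        T = np.array([[0.0, 0.0, 0.0]])
        W = np.array([[d0(1), 0.0, 0.0]])
        mat = score_matrix(T, W, Superposition.identity(), DEFAULT_GAP_PENALTY, d0_len=1)
        assert mat.M[1, 1] == pytest.approx(0.5, abs=1e-12)

    def test_matches_naive_fill(self):
        """Antidiagonal vectorized fill equals the direct nested-loop recurrence."""
        rng = np.random.default_rng(6)
        T = rng.normal(size=(7, 3)) * 4
        W = rng.normal(size=(9, 3)) * 4
        sup = kabsch(T, W[:7])
        for g in (DEFAULT_GAP_PENALTY, 0.08, -0.5):
            mat = score_matrix(T, W, sup, g)
            M = np.zeros((8, 10))
            for i in range(1, 8):
                for j in range(1, 10):
                    M[i, j] = max(
                        M[i - 1, j] + g,
                        M[i, j - 1] + g,
                        M[i - 1, j - 1] + mat.sim[i - 1, j - 1],
                    )
            assert np.allclose(mat.M, M, atol=0)


class TestTraceback:
    def test_single_cell_match(self):
        sim = np.array([[1.0]])
        M = np.array([[0.0, 0.0], [0.0, 1.0]])
        assert dp_traceback_M(ScoringMatrixM(M=M, g=DEFAULT_GAP_PENALTY, sim=sim)) == [(0, 0)]

    def test_identical_windows_full_diagonal(self):
        rng = np.random.default_rng(7)
        T = rng.normal(size=(5, 3)) * 5
        mat = score_matrix(T, T, Superposition.identity(), DEFAULT_GAP_PENALTY)
        assert dp_traceback_M(mat) == [(i, i) for i in range(5)]

    def test_pairs_strictly_monotone(self):
        rng = np.random.default_rng(8)
        T = rng.normal(size=(6, 3)) * 4
        W = rng.normal(size=(8, 3)) * 4
        mat = score_matrix(T, W, kabsch(T, W[:6]), 0.08)
        pairs = dp_traceback_M(mat)
        for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
            assert i2 > i1 and j2 > j1

    @pytest.mark.parametrize("g", [DEFAULT_GAP_PENALTY, 0.08, -1.0])
    def test_dp_score_matches_exhaustive_path_enumeration(self, g):
        rng = np.random.default_rng(9)
        for _ in range(5):
            T = rng.normal(size=(5, 3)) * 6
            W = rng.normal(size=(6, 3)) * 6
            mat = score_matrix(T, W, kabsch(T, W[:5]), g)
            assert mat.M[-1, -1] == pytest.approx(
                brute_force_best_path(mat.sim, g), abs=1e-9
            )


class TestCollectFragments:
    def _diag(self, start_i, start_j, n):
        return [(start_i + k, start_j + k) for k in range(n)]

    def test_single_long_run(self):
        frags = collect_fragments(self._diag(0, 0, 12))
        assert len(frags) == 1 and len(frags[0]) == 12

    def test_nine_pairs_below_minimum(self):
        assert collect_fragments(self._diag(0, 0, 9)) == []

    def test_two_runs_split_by_gap(self):
        pairs = self._diag(0, 0, 10) + self._diag(11, 12, 15)
        frags = collect_fragments(pairs)
        assert [len(f) for f in frags] == [10, 15]

    def test_gap_in_one_coordinate_breaks_run(self):
        pairs = self._diag(0, 0, 10) + self._diag(10, 11, 10)  # j jumps by 2
        frags = collect_fragments(pairs)
        assert [len(f) for f in frags] == [10, 10]


class TestRefineAlignment:
    def test_no_fragments_returns_input(self):
        rng = np.random.default_rng(10)
        T = rng.normal(size=(8, 3))
        fallback = [(0, 0), (3, 4)]
        assert refine_alignment([], T, T, fallback_pairs=fallback) == fallback

    def test_perfect_alignment_is_fixed_point(self):
        rng = np.random.default_rng(11)
        T = rng.normal(size=(15, 3)) * 5
        pairs = [(i, i) for i in range(15)]
        frags = collect_fragments(pairs)
        assert refine_alignment(frags, T, T) == pairs

    def test_refit_recovers_from_skewed_tail(self):
        """A displaced tail skews the initial full-length fit; re-fitting on
        the clean fragment restores the true superposition."""
        rng = np.random.default_rng(12)
        T = make_chain(SyntheticSpec(n_res=30, motif="helix", seed=12))[0].coords
        W = T.copy()
        W[20:] += rng.normal(scale=15.0, size=(10, 3))  # wreck the tail
        sup0 = kabsch(T, W)
        mat0 = score_matrix(T, W, sup0, DEFAULT_GAP_PENALTY)
        pairs0 = dp_traceback_M(mat0)
        frags = collect_fragments(pairs0)
        refined = refine_alignment(frags, T, W, fallback_pairs=pairs0)
        assert refined  # the clean head still aligns
        # the fragment-seeded fit excludes the tail, so the clean head
        # superposes better than under the tail-skewed full-length fit
        frag_pairs = [p for f in frags for p in f.pairs if p[0] < 20]
        ia = np.array([p[0] for p in frag_pairs])
        ib = np.array([p[1] for p in frag_pairs])
        sup1 = kabsch(T[ia], W[ib])
        d_head0 = np.linalg.norm(sup0.apply(T[:20]) - W[:20], axis=1)
        d_head1 = np.linalg.norm(sup1.apply(T[:20]) - W[:20], axis=1)
        assert np.mean(d_head1) <= np.mean(d_head0)


class TestGaplessThreading:
    def test_number_of_windows(self):
        rng = np.random.default_rng(13)
        T = rng.normal(size=(4, 3)) * 4
        C = rng.normal(size=(10, 3)) * 4
        assert gapless_threading(T, C).n_windows == 7

    def test_exact_subwindow_recovered(self):
        chain, _ = make_chain(SyntheticSpec(n_res=10, motif="mixed", seed=14))
        C = make_chain(SyntheticSpec(n_res=30, motif="coil", seed=15))[0].coords.copy()
        C[3:13] = chain.coords
        res = gapless_threading(chain.coords, C)
        assert res.shift == 3
        assert res.tm == pytest.approx(1.0, abs=1e-6)

    def test_equal_lengths_single_window(self):
        rng = np.random.default_rng(16)
        T = rng.normal(size=(12, 3)) * 4
        res = gapless_threading(T, T)
        assert res.n_windows == 1 and res.shift == 0
        assert res.tm == pytest.approx(1.0)

    def test_template_longer_than_constant_rejected(self):
        rng = np.random.default_rng(17)
        with pytest.raises(ValueError):
            gapless_threading(rng.normal(size=(10, 3)), rng.normal(size=(5, 3)))


class TestSplitParts:
    def test_divisible_case(self):
        scheme = split_parts(40, 5)
        assert [e - s for s, e in scheme.boundaries] == [8] * 5

    def test_remainder_goes_to_leading_parts(self):
        scheme = split_parts(41, 5)
        assert [e - s for s, e in scheme.boundaries] == [9, 8, 8, 8, 8]

    def test_parts_tile_the_template(self):
        for L, k in [(40, 5), (41, 5), (23, 3), (100, 8)]:
            scheme = split_parts(L, k)
            flat = [i for s, e in scheme.boundaries for i in range(s, e)]
            assert flat == list(range(L))

    def test_oversized_k_skipped(self):
        assert split_parts(7, 8) is None

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            split_parts(40, 4)


class TestAlignPair:
    def test_self_alignment_is_perfect(self, mixed_chain):
        aln = align_pair(mixed_chain, mixed_chain)
        assert aln.tm == pytest.approx(1.0)
        assert aln.n_ali == len(mixed_chain)
        assert aln.rmsd == pytest.approx(0.0, abs=1e-9)
        assert aln.parts_used == 1

    def test_exact_substructure_recovery(self, mixed_chain):
        offset = 17
        decoy = make_decoy_with_embedded_template(mixed_chain, offset, 100, seed=5)
        aln = align_pair(mixed_chain, decoy)
        assert aln.tm >= 0.95
        # most aligned pairs should sit on the planted diagonal j = i + offset
        on_diag = sum(1 for i, j in aln.pairs if j - i == offset)
        assert on_diag >= 0.9 * len(mixed_chain)

    def test_pairs_strictly_monotone(self, mixed_chain):
        decoy = make_decoy_with_embedded_template(mixed_chain, 10, 90, seed=6)
        aln = align_pair(mixed_chain, decoy)
        for (i1, j1), (i2, j2) in zip(aln.pairs, aln.pairs[1:]):
            assert i2 > i1 and j2 > j1

    def test_symmetric_quality(self, mixed_chain):
        decoy = make_decoy_with_embedded_template(mixed_chain, 12, 80, seed=8)
        tm_ab = align_pair(mixed_chain, decoy).tm
        tm_ba = align_pair(decoy, mixed_chain).tm
        assert tm_ab == pytest.approx(tm_ba, abs=1e-9)

    def test_multipart_beats_single_on_split_embedding(self, mixed_chain):
        decoy = make_two_part_decoy(mixed_chain, (5, 55), 100, seed=3)
        groups = align_pair_groups(mixed_chain, decoy)
        best_multi = max(v.tm for k, v in groups.items() if k > 1)
        assert best_multi > groups[1].tm
        aln = align_pair(mixed_chain, decoy)
        assert aln.tm == pytest.approx(max(v.tm for v in groups.values()))

    def test_too_short_chains_rejected(self):
        short = chain_from_coords(np.random.default_rng(18).normal(size=(4, 3)))
        with pytest.raises(ValueError):
            align_pair(short, short)
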