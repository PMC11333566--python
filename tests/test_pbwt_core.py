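import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import naive_block_index, naive_pbwt, naive_rank0
from phaseprep.pbwt_core import (
    CompactPBWT,
    build_backward_pbwt,
    build_index,
    build_pbwt,
    invert_pbwt,
    permutations,
    rank0,
    rank1,
    read_pbwt,
    write_pbwt,
)


def random_matrix(rng, max_n=64, max_m=32):
    n = int(rng.integers(1, max_n + 1))
    m = int(rng.integers(1, max_m + 1))
    return rng.integers(0, 2, (m, n)).astype(np.uint8)


class TestBuildPbwt:
    def test_hand_traced_three_by_four(self):
        rows = np.array([[0, 1, 0, 1], [1, 1, 0, 0], [0, 1, 1, 0]], dtype=np.uint8)
        p = build_pbwt(rows)
        assert p.pbwt_rows.tolist() == [[0, 1, 0, 1], [1, 0, 1, 0], [1, 0, 0, 1]]
        assert p.cnt0.tolist() == [2, 2, 2]
        assert p.final_permutation.tolist() == [3, 0, 2, 1]

    def test_all_zero_matrix_keeps_identity_permutation(self):
        rows = np.zeros((5, 7), dtype=np.uint8)
        p = build_pbwt(rows)
        assert np.all(p.pbwt_rows == 0)
        assert p.cnt0.tolist() == [7] * 5
        assert p.final_permutation.tolist() == list(range(7))

    def test_first_site_emitted_in_input_order(self):
        p = build_pbwt(np.array([[0, 1, 1, 0]], dtype=np.uint8))
        assert p.pbwt_rows[0].tolist() == [0, 1, 1, 0]
        assert p.cnt0.tolist() == [2]

    def test_ragged_input_rejected(self):
        with pytest.raises(ValueError):
            build_pbwt(np.array([[0, 1], [1]], dtype=object))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_reversed_prefix_sort_oracle(self, seed):
        rng = np.random.default_rng(seed)
        rows = random_matrix(rng)
        p = build_pbwt(rows)
        exp_rows, exp_cnt0, exp_final = naive_pbwt(rows)
        assert p.pbwt_rows.tolist() == exp_rows
        assert p.cnt0.tolist() == exp_cnt0
        assert p.final_permutation.tolist() == exp_final

    def test_permutation_is_bijective_after_every_site(self, rng):
        rows = random_matrix(rng)
        perms = permutations(build_pbwt(rows))
        for a in perms:
            assert sorted(a.tolist()) == list(range(rows.shape[1]))

    def test_sorted_reversed_prefixes_at_every_site(self, rng):
        # the defining PBWT property: reversed prefixes are sorted in permuted order
        rows = random_matrix(rng, max_n=32, max_m=16)
        perms = permutations(build_pbwt(rows))
        for m in range(rows.shape[0] + 1):
            keys = [tuple(rows[s, h] for s in range(m - 1, -1, -1)) for h in perms[m]]
            assert keys == sorted(keys)


class TestBackwardPbwt:
    def test_single_site_equals_forward(self):
        rows = np.array([[0, 1, 1, 0]], dtype=np.uint8)
        fwd, bwd = build_pbwt(rows), build_backward_pbwt(rows)
        assert np.array_equal(fwd.pbwt_rows, bwd.pbwt_rows)
        assert bwd.direction == "backward"

    def test_palindromic_sites_give_equal_rows(self, rng):
        half = rng.integers(0, 2, (4, 9)).astype(np.uint8)
        rows = np.vstack([half, half[::-1]])
        fwd, bwd = build_pbwt(rows), build_backward_pbwt(rows)
        assert np.array_equal(fwd.pbwt_rows, bwd.pbwt_rows)

    def test_definitional_equivalence_with_reversed_forward(self, rng):
        rows = rng.integers(0, 2, (20, 30)).astype(np.uint8)
        bwd = build_backward_pbwt(rows)
        fwd_rev = build_pbwt(rows[::-1])
        assert np.array_equal(bwd.pbwt_rows, fwd_rev.pbwt_rows)
        assert np.array_equal(bwd.cnt0, fwd_rev.cnt0)


class TestIndexAndRank:
    def test_all_zero_block(self):
        p = build_pbwt(np.zeros((1, 32), dtype=np.uint8))
        assert p.index.tolist() == [[32]]

    def test_all_one_block(self):
        p = build_pbwt(np.ones((1, 32), dtype=np.uint8))
        assert p.index.tolist() == [[0]]

    def test_partial_final_block_excludes_padding(self):
        # 20 ones then 20 zeros: block 0 holds 12 zeros, row total is 20
        row = np.array([1] * 20 + [0] * 20, dtype=np.uint8)
        p = build_pbwt(row[None, :])
        assert p.index.tolist() == [naive_block_index(row.tolist())]
        assert p.index.tolist() == [[12, 20]]

    @pytest.mark.parametrize("n", [1, 5, 31, 32, 33, 63, 64, 65, 100])
    def test_rank_matches_naive_scan_everywhere(self, n, rng):
        rows = rng.integers(0, 2, (3, n)).astype(np.uint8)
        p = build_pbwt(rows)
        for m in range(3):
            row = p.pbwt_rows[m].tolist()
            for i in range(n + 1):
                assert rank0(p, m, i) == naive_rank0(row, i)
                assert rank1(p, m, i) == i - naive_rank0(row, i)
            assert rank0(p, m, 0) == 0
            assert rank0(p, m, n) == p.cnt0[m]

    def test_index_nondecreasing_and_ends_at_cnt0(self, rng):
        rows = rng.integers(0, 2, (6, 77)).astype(np.uint8)
        p = build_pbwt(rows)
        for m in range(6):
            idx = p.index[m].tolist()
            assert idx == sorted(idx)
            assert idx[-1] == p.cnt0[m]

    def test_out_of_range_position_rejected(self):
        p = build_pbwt(np.zeros((1, 4), dtype=np.uint8))
        with pytest.raises(ValueError):
            rank0(p, 0, 5)


class TestInvertibility:
    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_roundtrip_from_rows_and_cnt0_alone(self, seed):
        rng = np.random.default_rng(seed)
        rows = random_matrix(rng, max_n=48, max_m=24)
        p = build_pbwt(rows)
        stripped = CompactPBWT(pbwt_rows=p.pbwt_rows, cnt0=p.cnt0)
        assert np.array_equal(invert_pbwt(stripped), rows)

    def test_backward_roundtrip_restores_site_order(self, rng):
        rows = random_matrix(rng)
        assert np.array_equal(invert_pbwt(build_backward_pbwt(rows)), rows)


class TestSerialization:
    @pytest.mark.parametrize("n", [1, 31, 32, 40, 64, 70])
    def test_container_roundtrip(self, n, tmp_path, rng):
        rows = rng.integers(0, 2, (5, n)).astype(np.uint8)
        p = build_pbwt(rows)
        path = tmp_path / "x.pbwt"
        write_pbwt(p, path)
        back = read_pbwt(path)
        assert np.array_equal(back.pbwt_rows, p.pbwt_rows)
        assert np.array_equal(back.cnt0, p.cnt0)
        assert np.array_equal(back.index, p.index)
        assert back.direction == "forward"
        assert np.array_equal(invert_pbwt(back), rows)

    def test_direction_flag_preserved(self, tmp_path, rng):
        rows = rng.integers(0, 2, (4, 10)).astype(np.uint8)
        path = tmp_path / "b.pbwt"
        write_pbwt(build_backward_pbwt(rows), path)
        assert read_pbwt(path).direction == "backward"

    def test_bad_magic_rejected(self, tmp_path):
        path = tmp_path / "junk.pbwt"
        path.write_bytes(b"NOPE" + bytes(10))
        with pytest.raises(ValueError, match="not a phaseprep PBWT"):
            read_pbwt(path)
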