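import numpy as np
import pytest

from conftest import make_panel, make_target, random_target
from oracles import naive_condensed, naive_inconsistency
from phaseprep.preliminaries import (
    RowKind,
    build_condensed,
    compact_row,
    inconsistency_bit,
    inconsistency_row,
    score_haplotypes,
    select_kbest,
)


class TestInconsistencyBit:
    @pytest.mark.parametrize(
        "is0, is2, hap, expected",
        [
            (1, 0, 1, 1),  # hom-ref genotype contradicted by an alt allele
            (1, 0, 0, 0),
            (0, 1, 0, 1),  # hom-alt genotype contradicted by a ref allele
            (0, 1, 1, 0),
            (0, 0, 0, 0),  # het/missing sites never contribute
            (0, 0, 1, 0),
        ],
    )
    def test_truth_table(self, is0, is2, hap, expected):
        assert inconsistency_bit(is0, is2, hap) == expected

    def test_conflicting_genotype_rejected(self):
        with pytest.raises(ValueError):
            inconsistency_bit(1, 1, 0)
        with pytest.raises(ValueError):
            inconsistency_row(1, 1, np.zeros(4, dtype=np.uint8))

    def test_row_form_matches_scalar(self, rng):
        haps = rng.integers(0, 2, 40).astype(np.uint8)
        for is0, is2 in ((1, 0), (0, 1), (0, 0)):
            row = inconsistency_row(is0, is2, haps)
            assert row.tolist() == [naive_inconsistency(is0, is2, int(h)) for h in haps]


class TestScoreHaplotypes:
    def test_all_missing_target_scores_zero(self, rng):
        panel = make_panel(rng.integers(0, 2, (10, 8)))
        scores = score_haplotypes(panel, make_target("." * 10))
        assert scores.tolist() == [0] * 8

    def test_haplotype_matching_hom_pattern_scores_zero(self):
        # hap 0 equals the target's homozygous pattern exactly
        panel = make_panel(np.array([[0, 1], [1, 0], [0, 1]]))
        scores = score_haplotypes(panel, make_target("020"))
        assert scores[0] == 0 and scores[1] == 3

    def test_three_site_worked_example(self):
        # is0=101, is2=000; hap bits per site 1,1,0: only site 0 contradicts
        panel = make_panel(np.array([[1], [1], [0]]))
        assert score_haplotypes(panel, make_target("0h0")).tolist() == [1]

    def test_agrees_with_per_site_loop(self, rng):
        panel = make_panel(rng.integers(0, 2, (25, 12)))
        target = random_target(25, rng)
        scores = score_haplotypes(panel, target)
        for h in range(12):
            expected = sum(
                naive_inconsistency(int(target.is0[m]), int(target.is2[m]), int(panel.rows[m, h]))
                for m in range(25)
            )
            assert scores[h] == expected


class TestSelectKBest:
    def test_lowest_scores_win_with_index_tie_break(self):
        sel = select_kbest(np.array([2, 1, 2, 1, 2]), 3)
        assert sel.selected_indices.tolist() == [0, 1, 3]
        assert sel.k_effective == 3

    def test_k_saturates_at_panel_size(self):
        sel = select_kbest(np.array([5, 0, 3]), 10)
        assert sel.k_effective == 3 and sel.mask.tolist() == [1, 1, 1]

    def test_all_equal_scores_take_lowest_indices(self):
        sel = select_kbest(np.zeros(6, dtype=int), 2)
        assert sel.selected_indices.tolist() == [0, 1]

    def test_selected_never_score_worse_than_unselected(self, rng):
        scores = rng.integers(0, 20, 50)
        sel = select_kbest(scores, 17)
        worst_in = scores[sel.mask.astype(bool)].max()
        best_out = scores[~sel.mask.astype(bool)].min()
        assert worst_in <= best_out

    def test_k_below_one_rejected(self):
        with pytest.raises(ValueError):
            select_kbest(np.array([1, 2]), 0)


class TestCompactRow:
    def test_all_ones_mask_is_identity(self, rng):
        row = rng.integers(0, 2, 20).astype(np.uint8)
        assert np.array_equal(compact_row(row, np.ones(20, dtype=np.uint8)), row)

    def test_positions_follow_set_mask_bits(self):
        row = np.array([1, 0, 0, 1, 0, 0], dtype=np.uint8)
        mask = np.array([1, 0, 0, 1, 0, 1], dtype=np.uint8)
        assert compact_row(row, mask).tolist() == [1, 1, 0]

    def test_matches_naive_filter(self, rng):
        row = rng.integers(0, 2, 64).astype(np.uint8)
        mask = rng.integers(0, 2, 64).astype(np.uint8)
        expected = [int(b) for b, m in zip(row, mask) if m]
        assert compact_row(row, mask).tolist() == expected


class TestBuildCondensed:
    def run(self, rows, classes, mask=None):
        panel = make_panel(rows)
        target = make_target(classes)
        n = panel.n_haps
        scores = score_haplotypes(panel, target)
        sel = select_kbest(scores, n)
        if mask is not None:
            sel.mask = np.asarray(mask, dtype=np.uint8)
        return panel, target, sel, build_condensed(panel, target, sel)

    def test_worked_two_haplotype_example(self):
        # haps A=(0,1,1,0,0), B=(1,0,0,1,1) over genotypes hom0,het,hom2,het,hom0
        rows = np.array([[0, 1], [1, 0], [1, 0], [0, 1], [0, 1]])
        *_, cond = self.run(rows, "0h2h0")
        assert cond.rows.tolist() == [[0, 1], [1, 0], [0, 1], [0, 1], [0, 1]]
        assert cond.row_kind == [
            RowKind.SEGMENT,
            RowKind.CALLSITE,
            RowKind.SEGMENT,
            RowKind.CALLSITE,
            RowKind.SEGMENT,
        ]
        assert cond.call_site_index == [1, 3]

    def test_zero_call_sites_collapse_to_one_segment(self, rng):
        rows = rng.integers(0, 2, (8, 4))
        *_, cond = self.run(rows, "02020202")
        assert cond.rows.shape[0] == 1
        assert cond.n_call_sites == 0

    def test_leading_call_site_gives_empty_first_segment(self, rng):
        rows = rng.integers(0, 2, (3, 4))
        *_, cond = self.run(rows, "h00")
        assert cond.row_kind[0] == RowKind.SEGMENT
        assert cond.rows[0].tolist() == [0, 0, 0, 0]

    def test_adjacent_call_sites_give_explicit_empty_segment(self, rng):
        rows = rng.integers(0, 2, (4, 5))
        *_, cond = self.run(rows, "0hh0")
        assert cond.rows.shape[0] == 5
        assert cond.rows[2].tolist() == [0] * 5  # segment between the two call sites

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_naive_per_site_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 40))
        m = int(rng.integers(1, 50))
        rows = rng.integers(0, 2, (m, n))
        classes = "".join(rng.choice(list("02h."), m, p=[0.3, 0.3, 0.25, 0.15]))
        k = int(rng.integers(1, n + 1))
        panel = make_panel(rows)
        target = make_target(classes)
        sel = select_kbest(score_haplotypes(panel, target), k)
        cond = build_condensed(panel, target, sel)
        exp_rows, exp_kinds = naive_condensed(rows, target.is0, target.is2, target.call, sel.mask)
        assert cond.rows.tolist() == exp_rows
        assert [k.name[0] for k in cond.row_kind] == exp_kinds
        assert cond.rows.shape[0] == 2 * cond.n_call_sites + 1

    def test_segment_or_is_monotone_in_sites(self, rng):
        # extending the site range never clears a segment bit
        rows = rng.integers(0, 2, (30, 10))
        panel = make_panel(rows)
        prev = np.zeros(10, dtype=np.uint8)
        sel = select_kbest(np.zeros(10, dtype=int), 10)
        for m in range(1, 31):
            sub_panel = make_panel(rows[:m])
            target = make_target("0" * m)
            cond = build_condensed(sub_panel, target, sel)
            seg = cond.rows[0]
            assert np.all(seg >= prev)
            prev = seg

    def test_score_zero_haplotype_has_clean_segments(self, rng):
        rows = rng.integers(0, 2, (20, 8))
        classes = "".join(rng.choice(list("02h"), 20))
        panel = make_panel(rows)
        target = make_target(classes)
        scores = score_haplotypes(panel, target)
        sel = select_kbest(scores, 8)
        cond = build_condensed(panel, target, sel)
        for j, h in enumerate(sel.selected_indices):
            if scores[h] == 0:
                for row, kind in zip(cond.rows, cond.row_kind):
                    if kind == RowKind.SEGMENT:
                        assert row[j] == 0
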