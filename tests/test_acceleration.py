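"""Acceleration LRT, batch LRT, BH calling, and deletion calling."""

import numpy as np
import pytest

import convreg as cv
from convreg.acceleration import (AccelerationResult, acceleration_lrt,
                                  batch_acceleration_lrt, batch_fit_scale,
                                  call_accelerated_regions, call_deletions,
                                  fit_conserved_scale, stack_cr_columns)
from convreg.conservation import ConservedRegion
from convreg.phylo import MISSING


def alignment_with_events(tree, jc, seed, accelerated=None, deleted=None):
    layout = cv.demo_layout(n_conserved=6, conserved_len=150, neutral_len=600,
                            rho=0.3, accelerated=accelerated, deleted=deleted)
    aln, truth = cv.simulate_alignment(tree, jc, layout, seed=seed)
    crs = [ConservedRegion(r.chrom, r.start, r.end, 1.0)
           for _, r in truth.iterrows() if r.seg_class != "neutral"]
    return aln, truth, crs


class TestConservedScaleFit:
    def test_recovers_planted_scale(self, tree, jc):
        hits = 0
        for seed in range(10):
            cols = cv.simulate_columns(tree, jc, 500, scale=0.3, rng=seed)
            rho = fit_conserved_scale(cols, tree, jc)
            hits += 0.2 <= rho <= 0.4
        assert hits >= 9

    def test_neutral_data_pushes_to_upper_boundary(self, tree, jc):
        cols = cv.simulate_columns(tree, jc, 2000, scale=1.0, rng=3)
        assert fit_conserved_scale(cols, tree, jc) > 0.9

    def test_all_missing_raises(self, tree, jc):
        with pytest.raises(ValueError):
            fit_conserved_scale(np.full((12, 30), MISSING, dtype=np.int8),
                                tree, jc)

    def test_batch_fit_agrees_with_scalar_fit(self, tree, jc):
        cols = np.stack([cv.simulate_columns(tree, jc, 200, scale=s, rng=i)
                         for i, s in enumerate((0.2, 0.5, 0.9))])
        batch = batch_fit_scale(cols, tree, jc)
        for i in range(3):
            scalar = fit_conserved_scale(cols[i], tree, jc)
            assert abs(batch[i] - scalar) < 1e-3


class TestAccelerationLrt:
    def test_planted_acceleration_is_significant(self, tree, jc):
        aln, truth, crs = alignment_with_events(
            tree, jc, seed=31, accelerated={1: (8.0, ("hib_A",))})
        acc_row = truth[truth.seg_class == "accelerated"].iloc[0]
        cr = next(c for c in crs if c.start == acc_row.start)
        res = acceleration_lrt(cr, aln, tree, jc, "hib_A")
        assert res.testable and res.p_value < 1e-3 and res.r_hat > 2

    def test_conserved_region_is_not_significant(self, tree, jc):
        aln, truth, crs = alignment_with_events(tree, jc, seed=32)
        res = acceleration_lrt(crs[0], aln, tree, jc, "hib_A")
        assert res.p_value > 0.01

    def test_boundary_case_reports_unit_rate_and_p_one(self, tree, jc):
        # strongly conserved data in the foreground lineage too: r stays at 1
        aln, truth, crs = alignment_with_events(tree, jc, seed=33)
        boundary = [acceleration_lrt(c, aln, tree, jc, "hib_B") for c in crs]
        at_boundary = [r for r in boundary if r.lrt == 0.0]
        assert at_boundary, "expected at least one CR on the r=1 boundary"
        for r in at_boundary:
            assert r.r_hat == 1.0 and r.p_value == 1.0

    def test_p_value_is_half_chi2_tail(self, tree, jc):
        from scipy.stats import chi2
        aln, truth, crs = alignment_with_events(
            tree, jc, seed=34, accelerated={0: (4.0, ("hib_C",))})
        res = acceleration_lrt(crs[0], aln, tree, jc, "hib_C")
        assert res.lrt > 0
        assert res.p_value == pytest.approx(0.5 * chi2.sf(res.lrt, 1))

    def test_mostly_gapped_lineage_is_untestable(self, tree, jc):
        aln, truth, crs = alignment_with_events(
            tree, jc, seed=35, deleted={2: ("hib_D",)})
        del_row = truth[truth.seg_class == "deleted"].iloc[0]
        cr = next(c for c in crs if c.start == del_row.start)
        res = acceleration_lrt(cr, aln, tree, jc, "hib_D")
        assert not res.testable and np.isnan(res.p_value)

    def test_unknown_lineage_raises(self, tree, jc):
        aln, _, crs = alignment_with_events(tree, jc, seed=36)
        with pytest.raises(ValueError):
            acceleration_lrt(crs[0], aln, tree, jc, "outgroup_X")

    def test_batch_lrt_agrees_with_scalar_lrt(self, tree, jc):
        aln, truth, crs = alignment_with_events(
            tree, jc, seed=37, accelerated={1: (6.0, ("hib_A",))})
        cols = stack_cr_columns(crs, aln, tree)
        batch = batch_acceleration_lrt(cols, tree, jc, "hib_A",
                                       rounds=3, iters=35)
        for i, cr in enumerate(crs):
            scalar = acceleration_lrt(cr, aln, tree, jc, "hib_A")
            assert abs(batch["lrt"][i] - scalar.lrt) < 0.05
            assert abs(batch["rho_hat"][i] - scalar.rho_hat) < 5e-3

    def test_padding_with_missing_columns_changes_nothing(self, tree, jc):
        cols = cv.simulate_columns(tree, jc, 60, scale=0.3, rng=8)
        batch = np.stack([cols])
        padded = np.concatenate(
            [batch, np.full((1, tree.n_leaves, 40), MISSING, dtype=np.int8)],
            axis=2)
        r1 = batch_acceleration_lrt(batch, tree, jc, "hib_A")
        r2 = batch_acceleration_lrt(padded, tree, jc, "hib_A")
        assert abs(r1["lrt"][0] - r2["lrt"][0]) < 1e-6

    def test_duplicating_columns_doubles_the_statistic(self, tree, jc):
        cols = cv.simulate_columns(tree, jc, 80, scale=0.3,
                                   branch_scales={"hib_A": 6.0}, rng=12)
        single = np.stack([cols])
        doubled = np.stack([np.concatenate([cols, cols], axis=1)])
        l1 = batch_acceleration_lrt(single, tree, jc, "hib_A",
                                    rounds=3, iters=35)["lrt"][0]
        l2 = batch_acceleration_lrt(doubled, tree, jc, "hib_A",
                                    rounds=3, iters=35)["lrt"][0]
        assert l2 == pytest.approx(2 * l1, rel=0.02)


class TestBenjaminiHochbergCalling:
    @staticmethod
    def _result(cr_id, lineage, p):
        return AccelerationResult(cr_id, lineage, 0.3, 2.0, 0.0, 1.0, 1.0, p)

    def test_hand_worked_bh_example(self):
        # p = (0.001, 0.01, 0.02, 0.5): BH at 0.05 rejects the first three
        ps = [0.001, 0.01, 0.02, 0.5]
        res = {"hib_A": [self._result(f"cr{i}", "hib_A", p)
                         for i, p in enumerate(ps)]}
        sig = call_accelerated_regions(res, target_fdr=0.05)
        assert {r.cr_id for r in sig["hib_A"]} == {"cr0", "cr1", "cr2"}
        qs = {r.cr_id: r.q_value for r in res["hib_A"]}
        assert qs["cr0"] == pytest.approx(0.004)
        assert qs["cr3"] == pytest.approx(0.5)

    def test_untestable_results_excluded_from_correction(self):
        res = {"hib_A": [self._result("cr0", "hib_A", 0.04),
                         AccelerationResult("cr1", "hib_A", np.nan, np.nan,
                                            np.nan, np.nan, np.nan, np.nan,
                                            testable=False)]}
        sig = call_accelerated_regions(res, target_fdr=0.05)
        assert {r.cr_id for r in sig["hib_A"]} == {"cr0"}

    def test_correction_is_per_lineage(self):
        res = {"hib_A": [self._result("cr0", "hib_A", 0.01)],
               "hib_B": [self._result(f"cr{i}", "hib_B", p)
                         for i, p in enumerate([0.01] + [0.9] * 99)]}
        sig = call_accelerated_regions(res, target_fdr=0.05)
        assert len(sig["hib_A"]) == 1      # 0.01 alone survives
        assert len(sig["hib_B"]) == 0      # 0.01 * 100 / 1 = 1 > 0.05


class TestDeletionCalling:
    def test_planted_deletion_called_with_aligned_flanks(self, tree, jc):
        aln, truth, crs = alignment_with_events(
            tree, jc, seed=41, deleted={3: ("hib_B",)})
        calls = call_deletions(crs, aln, "hib_B")
        called = [c for c in calls if c.call]
        del_row = truth[truth.seg_class == "deleted"].iloc[0]
        assert len(called) == 1
        assert called[0].cr_id == \
            f"{del_row.chrom}:{del_row.start}-{del_row.end}"
        assert called[0].gap_fraction == 1.0
        assert called[0].left_flank_aligned == 1.0

    def test_aligned_regions_are_not_called(self, tree, jc):
        aln, _, crs = alignment_with_events(tree, jc, seed=42)
        for lineage in ("hib_A", "ctrl_C"):
            assert not any(c.call for c in call_deletions(crs, aln, lineage))

    def test_gap_fraction_below_threshold_is_not_called(self, tree, jc):
        aln, truth, crs = alignment_with_events(
            tree, jc, seed=43, deleted={1: ("hib_C",)})
        del_row = truth[truth.seg_class == "deleted"].iloc[0]
        cr = next(c for c in crs if c.start == del_row.start)
        # half-deleted region: rebuild a CR covering the deletion plus an
        # equally long aligned stretch -> gap fraction ~0.5 < 0.8
        wide = ConservedRegion(cr.chrom, cr.start - cr.length, cr.end, 1.0)
        calls = call_deletions([wide], aln, "hib_C")
        assert calls[0].gap_fraction == pytest.approx(0.5, abs=0.05)
        assert not calls[0].call

    def test_unaligned_flanks_block_the_call(self, tree, jc):
        # lineage missing everywhere: gap fraction 1 but flanks unaligned too
        aln, truth, crs = alignment_with_events(tree, jc, seed=44)
        stripped_blocks = []
        for b in aln.blocks:
            rows = {sp: (np.full_like(r, MISSING) if sp == "hib_D" else r)
                    for sp, r in b.rows.items()}
            stripped_blocks.append(type(b)(b.chrom, b.ref_start, rows,
                                           b.src_sizes, b.starts))
        stripped = cv.MultipleAlignment(aln.reference, stripped_blocks)
        calls = call_deletions(crs, stripped, "hib_D")
        assert all(c.gap_fraction == 1.0 for c in calls)
        assert not any(c.call for c in calls)

    def test_truncated_flank_is_flagged(self, tree, jc):
        aln, truth, crs = alignment_with_events(tree, jc, seed=45)
        lo, _ = aln.reference_extent("chrSim")
        edge_cr = ConservedRegion("chrSim", lo + 10, lo + 60, 1.0)
        call = call_deletions([edge_cr], aln, "hib_A")[0]
        assert call.flank_truncated

    def test_invalid_thresholds_raise(self, tree, jc):
        aln, _, crs = alignment_with_events(tree, jc, seed=46)
        with pytest.raises(ValueError):
            call_deletions(crs, aln, "hib_A", gap_threshold=0.0)
        with pytest.raises(ValueError):
            call_deletions(crs, aln, "no_such_lineage")
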