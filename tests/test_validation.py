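"""DSC, landmark-distance criterion and the cohort statistics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spectreg.image import LandmarkSet
from spectreg.preprocess import BoneMask
from spectreg.validation import (
    compare_dsc_by_resolution,
    compare_dsc_prepost,
    dice,
    landmark_error,
)


def _mask(arr):
    return BoneMask(np.asarray(arr, dtype=bool), (1, 1, 1), (0, 0, 0))


class TestDice:
    def test_self_overlap_is_one(self, rng):
        m = _mask(rng.random((6, 6, 6)) > 0.5)
        assert dice(m, m).dsc == 1.0

    def test_disjoint_masks_are_zero(self):
        a = np.zeros((4, 4, 4), dtype=bool)
        b = np.zeros((4, 4, 4), dtype=bool)
        a[0], b[2] = True, True
        assert dice(_mask(a), _mask(b)).dsc == 0.0

    def test_hand_counted_overlap(self):
        """|A|=4, |B|=6, overlap 3 -> 2*3/10 = 0.6 on a constructed 3^3 pair."""
        a = np.zeros((3, 3, 3), dtype=bool)
        b = np.zeros((3, 3, 3), dtype=bool)
        a.ravel()[[0, 1, 2, 3]] = True
        b.ravel()[[1, 2, 3, 10, 11, 12]] = True
        res = dice(_mask(a), _mask(b))
        assert res.size_a == 4 and res.size_b == 6 and res.overlap == 3
        assert res.dsc == 0.6

    def test_both_empty_defined_as_zero(self):
        z = _mask(np.zeros((3, 3, 3)))
        assert dice(z, z).dsc == 0.0

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_symmetry(self, seed):
        r = np.random.default_rng(seed)
        a = _mask(r.random((5, 5, 5)) > 0.4)
        b = _mask(r.random((5, 5, 5)) > 0.6)
        assert dice(a, b).dsc == dice(b, a).dsc

    def test_growing_overlap_at_fixed_sizes_never_decreases_dsc(self):
        a = np.zeros((4, 4, 4), dtype=bool)
        b = np.zeros((4, 4, 4), dtype=bool)
        a.ravel()[:8] = True
        b.ravel()[4:12] = True  # overlap 4
        base = dice(_mask(a), _mask(b)).dsc
        b2 = np.zeros((4, 4, 4), dtype=bool)
        b2.ravel()[3:11] = True  # overlap 5, same sizes
        assert dice(_mask(a), _mask(b2)).dsc >= base

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            dice(_mask(np.zeros((3, 3, 3))), _mask(np.zeros((4, 3, 3))))


class TestLandmarkError:
    SPACING = (0.98, 0.98, 3.0)

    def _lms(self, offsets):
        names = ["FKC", "FME", "FLE", "FTP"]
        base = {n: np.array([10.0 * i, 5.0 * i, 20.0 * i]) for i, n in enumerate(names)}
        ref = LandmarkSet(base)
        mapped = LandmarkSet({n: base[n] + np.asarray(offsets) for n in names})
        return ref, mapped

    def test_identical_sets_pass_with_zero_differences(self):
        ref, mapped = self._lms((0, 0, 0))
        err = landmark_error(ref, mapped, self.SPACING)
        assert np.all(err.voxel_differences == 0) and err.passed

    def test_two_voxel_in_plane_boundary_still_passes(self):
        # 1.96 mm / 0.98 mm = exactly 2 voxels: boundary of the (2,2,0) rule
        ref, mapped = self._lms((1.96, 0, 0))
        err = landmark_error(ref, mapped, self.SPACING)
        assert np.all(err.voxel_differences[:, 0] == 2) and err.passed

    def test_one_slice_out_of_plane_fails(self):
        # 3 mm at 3 mm slices = 1 voxel in z; the threshold there is 0
        ref, mapped = self._lms((0, 0, 3.0))
        err = landmark_error(ref, mapped, self.SPACING)
        assert np.all(err.voxel_differences[:, 2] == 1) and not err.passed

    def test_rounding_is_half_away_from_zero(self):
        ref, mapped = self._lms((0.49 * 0.98, 0.51 * 0.98, 0))
        err = landmark_error(ref, mapped, self.SPACING)
        assert np.all(err.voxel_differences[:, 0] == 0)
        assert np.all(err.voxel_differences[:, 1] == 1)

    def test_common_translation_leaves_zero_differences(self, rng):
        ref, _ = self._lms((0, 0, 0))
        shift = rng.normal(size=3) * 30
        moved_ref = ref.map(lambda p: p + shift)
        moved_mapped = ref.map(lambda p: p + shift)
        err = landmark_error(moved_ref, moved_mapped, self.SPACING)
        assert np.all(err.voxel_differences == 0)

    def test_name_mismatch_rejected(self):
        ref, _ = self._lms((0, 0, 0))
        with pytest.raises(ValueError, match="missing"):
            landmark_error(ref, LandmarkSet({"FKC": (0, 0, 0)}), self.SPACING)


class TestWilcoxonPrePost:
    def test_all_tied_pairs_report_no_difference(self):
        rep = compare_dsc_prepost([0.8, 0.82, 0.85, 0.9, 0.7], [0.8, 0.82, 0.85, 0.9, 0.7])
        assert rep.p_value == 1.0 and not rep.significant

    def test_six_uniform_improvements_match_exact_enumeration(self):
        """All 6 signs positive: one-sided p = 1/64, two-sided 2/64."""
        pre = [0.70, 0.72, 0.74, 0.76, 0.78, 0.80]
        post = [p + d for p, d in zip(pre, [0.10, 0.11, 0.12, 0.13, 0.14, 0.15])]
        rep = compare_dsc_prepost(pre, post)
        assert np.isclose(rep.p_value, 2 / 64)
        assert rep.significant

    def test_exact_null_distribution_for_n6(self):
        """Brute-force enumeration of all 2^6 sign patterns reproduces scipy."""
        diffs = np.array([0.10, 0.11, 0.12, 0.13, 0.14, 0.15])
        ranks = np.argsort(np.argsort(np.abs(diffs))) + 1
        observed_w = ranks.sum()  # all positive
        count = 0
        total = 0
        for signs in itertools.product([1, -1], repeat=6):
            w_plus = sum(r for r, s in zip(ranks, signs) if s > 0)
            total += 1
            w_minus = ranks.sum() - w_plus
            if min(w_plus, w_minus) <= min(observed_w, ranks.sum() - observed_w):
                count += 1
        assert np.isclose(count / total, 2 / 64)

    def test_detects_genuine_improvement_in_simulated_cohort(self, rng):
        pre = rng.uniform(0.65, 0.8, size=10)
        post = pre + rng.uniform(0.05, 0.15, size=10)
        rep = compare_dsc_prepost(pre, post)
        assert rep.significant and rep.p_value < 0.05

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            compare_dsc_prepost([0.8, 0.9], [0.8])

    def test_normality_precheck_reported(self, rng):
        pre = rng.uniform(0.6, 0.8, size=12)
        post = pre + rng.normal(0.1, 0.01, size=12)
        rep = compare_dsc_prepost(pre, post)
        assert rep.normality_p is not None and 0 <= rep.normality_p <= 1


class TestMannWhitneyByResolution:
    def test_identical_groups_not_significant(self):
        g = [0.85, 0.86, 0.9, 0.88]
        rep = compare_dsc_by_resolution(g, list(g))
        assert rep.p_value > 0.9 and not rep.significant

    def test_fully_separated_4v4_matches_exact_enumeration(self):
        """U = 0 (or 16): exact two-sided p = 2 / C(8,4) = 2/70."""
        rep = compare_dsc_by_resolution(
            [0.90, 0.91, 0.92, 0.93], [0.70, 0.71, 0.72, 0.73]
        )
        assert np.isclose(rep.p_value, 2 / 70)
        assert rep.significant

    def test_shift_below_within_group_spread_keeps_ranks(self):
        """Adding a constant smaller than the gaps leaves the exact p unchanged."""
        a = [0.90, 0.92, 0.94, 0.96]
        b = [0.70, 0.72, 0.74, 0.76]
        p1 = compare_dsc_by_resolution(a, b).p_value
        p2 = compare_dsc_by_resolution([x + 0.005 for x in a], b).p_value
        assert p1 == p2

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            compare_dsc_by_resolution([], [0.8])
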