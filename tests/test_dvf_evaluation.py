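"""DVF comparison, error statistics, landmark propagation and masked reports."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import dirqa


def _field(vectors, tag="SOT->EOT", spacing=(1, 1, 1)):
    return dirqa.VectorField(vectors, spacing=spacing, direction_tag=tag)


def _pair(gt_vec, test_vec, mask=None):
    return dirqa.DVFComparison(
        gt_field=_field(gt_vec, "SOT->EOT"),
        test_field=_field(test_vec, "dEOT->EOT"),
        mask=mask,
    )


class TestErrorMap:
    def test_identical_fields_zero_error(self, rng):
        v = rng.normal(0, 5, size=(6, 7, 8, 3))
        np.testing.assert_array_equal(dirqa.dvf_error_map(_pair(v, v.copy())), 0.0)

    def test_constant_offset_345(self):
        gt = np.zeros((4, 4, 4, 3))
        test = np.zeros((4, 4, 4, 3)) + [1.0, 2.0, 2.0]
        np.testing.assert_allclose(dirqa.dvf_error_map(_pair(gt, test)), 3.0)

    def test_matches_elementwise_loop(self, rng):
        gt = rng.normal(0, 3, size=(8, 8, 8, 3))
        test = rng.normal(0, 3, size=(8, 8, 8, 3))
        err = dirqa.dvf_error_map(_pair(gt, test))
        for z in range(8):
            for y in range(8):
                for x in range(8):
                    d = test[z, y, x] - gt[z, y, x]
                    expected = (d[0] ** 2 + d[1] ** 2 + d[2] ** 2) ** 0.5
                    assert err[z, y, x] == pytest.approx(expected, abs=1e-12)

    def test_common_field_cancels(self, rng):
        """Adding the same field to both test and gt leaves the error map unchanged."""
        gt = rng.normal(0, 3, size=(6, 6, 6, 3))
        test = rng.normal(0, 3, size=(6, 6, 6, 3))
        extra = rng.normal(0, 10, size=(6, 6, 6, 3))
        np.testing.assert_allclose(
            dirqa.dvf_error_map(_pair(gt, test)),
            dirqa.dvf_error_map(_pair(gt + extra, test + extra)),
            atol=1e-9,
        )

    def test_direction_tag_mismatch_refused(self, rng):
        v = rng.normal(size=(4, 4, 4, 3))
        with pytest.raises(ValueError, match="direction-tag"):
            dirqa.DVFComparison(
                gt_field=_field(v, "SOT->EOT"), test_field=_field(v, "dEOT->SOT")
            )

    def test_grid_mismatch_refused(self, rng):
        with pytest.raises(ValueError, match="grid"):
            dirqa.DVFComparison(
                gt_field=_field(np.zeros((4, 4, 4, 3))),
                test_field=_field(np.zeros((4, 4, 5, 3)), "dEOT->EOT"),
            )


class TestErrorStatistics:
    def test_hand_arithmetic(self):
        s = dirqa.error_statistics(np.array([1.0, 1.0, 4.0]))
        assert (s.mean, s.median, s.max) == (2.0, 1.0, 4.0)
        assert s.frac_lt_2mm == pytest.approx(200.0 / 3.0)

    def test_all_zero(self):
        s = dirqa.error_statistics(np.zeros((4, 4, 4)))
        assert s.mean == 0.0 and s.frac_lt_2mm == 100.0 and s.n == 64

    def test_median_conventions(self):
        err = np.array([1.0, 2.0, 3.0, 10.0])
        assert dirqa.error_statistics(err, median_convention="lower").median == 2.0
        assert dirqa.error_statistics(err, median_convention="midpoint").median == 2.5

    def test_halfnormal_sample_matches_closed_forms(self, rng):
        """10⁵ half-normal errors: mean and median within 1 % of theory."""
        sigma = 1.7
        err = np.abs(rng.normal(0, sigma, size=100_000))
        s = dirqa.error_statistics(err, median_convention="midpoint")
        dist = sps.halfnorm(scale=sigma)
        assert s.mean == pytest.approx(dist.mean(), rel=0.01)
        assert s.median == pytest.approx(dist.median(), rel=0.01)
        assert s.frac_lt_2mm == pytest.approx(100 * dist.cdf(2.0), rel=0.01)

    def test_empty_selection_rejected(self):
        mask = dirqa.StructureMask(np.zeros((4, 4, 4), dtype=int))
        with pytest.raises(ValueError, match="empty"):
            dirqa.error_statistics(np.ones((4, 4, 4)), mask=mask)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_permutation_invariance(self, seed):
        r = np.random.default_rng(seed)
        err = r.exponential(1.5, size=101)
        a = dirqa.error_statistics(err)
        b = dirqa.error_statistics(r.permutation(err))
        assert (a.median, a.max, a.frac_lt_2mm) == (b.median, b.max, b.frac_lt_2mm)
        assert a.mean == pytest.approx(b.mean, rel=1e-12)  # summation order

    def test_fraction_monotone_in_threshold(self, rng):
        err = rng.exponential(1.5, size=500)
        fracs = [dirqa.error_statistics(err, threshold=t).frac_lt_2mm
                 for t in np.linspace(0.1, 5.0, 20)]
        assert np.all(np.diff(fracs) >= 0)


class TestPropagateLandmarks:
    def test_zero_field_identity(self, rng):
        fld = _field(np.zeros((8, 8, 8, 3)))
        pts = dirqa.LandmarkSet(rng.uniform(0, 7, size=(20, 3)))
        out = dirqa.propagate_landmarks(pts, fld)
        np.testing.assert_array_equal(out.points, pts.points)

    def test_constant_field_shifts(self, rng):
        v = np.zeros((8, 8, 8, 3)) + [5.0, 0.0, 0.0]
        pts = dirqa.LandmarkSet(rng.uniform(0, 7, size=(20, 3)))
        out = dirqa.propagate_landmarks(pts, _field(v))
        np.testing.assert_allclose(out.points, pts.points + [5.0, 0.0, 0.0])

    def test_affine_field_exact(self, rng):
        """Trilinear interpolation reproduces a sampled affine map exactly."""
        spec = dirqa.SyntheticDeformationSpec(
            shape=(12, 16, 16), spacing=(1.5, 1.5, 2.0),
            components=[{"type": "affine",
                         "matrix": [[0.02, 0.01, 0.0], [0.0, 0.03, 0.005],
                                    [0.01, 0.0, 0.02]],
                         "translation": [1.0, 2.0, 3.0]}],
        )
        fld = dirqa.generate_dvf(spec)
        pts = rng.uniform([1, 1, 1], [20, 20, 20], size=(50, 3))
        out = dirqa.propagate_landmarks(dirqa.LandmarkSet(pts), fld)
        expected = pts + dirqa.evaluate_deformation(spec, pts)
        assert np.abs(out.points - expected).max() < 1e-9

    def test_out_of_grid_point_rejected(self):
        fld = _field(np.zeros((8, 8, 8, 3)))
        with pytest.raises(ValueError, match="outside"):
            dirqa.propagate_landmarks(dirqa.LandmarkSet([[20.0, 0.0, 0.0]]), fld)

    def test_negated_constant_field_inverts(self, rng):
        v = np.zeros((8, 8, 8, 3)) + [1.0, -2.0, 0.5]
        pts = dirqa.LandmarkSet(rng.uniform(2, 5, size=(10, 3)))
        fwd = dirqa.propagate_landmarks(pts, _field(v))
        back = dirqa.propagate_landmarks(fwd, _field(-v))
        np.testing.assert_allclose(back.points, pts.points, atol=1e-12)


class TestLandmarkTre:
    def test_identical_sets(self, rng):
        pts = dirqa.LandmarkSet(rng.uniform(0, 10, size=(12, 3)))
        s = dirqa.landmark_tre(pts, dirqa.LandmarkSet(pts.points.copy()))
        assert s.mean == 0.0 and s.frac_lt_2mm == 100.0

    def test_exact_2mm_offset_is_not_below_threshold(self):
        """The percentage uses a strict <, so an error of exactly 2 mm fails."""
        a = dirqa.LandmarkSet([[0.0, 0.0, 0.0]])
        b = dirqa.LandmarkSet([[2.0, 0.0, 0.0]])
        assert dirqa.landmark_tre(a, b).frac_lt_2mm == 0.0

    def test_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="count"):
            dirqa.landmark_tre(dirqa.LandmarkSet([[0, 0, 0]]),
                               dirqa.LandmarkSet([[0, 0, 0], [1, 1, 1]]))

    def test_enumerated_distances(self):
        """Distances 0.1·k for k=0..99: statistics match hand computation."""
        ref = np.zeros((100, 3))
        moved = np.zeros((100, 3))
        moved[:, 0] = 0.1 * np.arange(100)
        s = dirqa.landmark_tre(dirqa.LandmarkSet(moved), dirqa.LandmarkSet(ref))
        d = 0.1 * np.arange(100)
        assert s.mean == pytest.approx(d.mean())
        assert s.median == d[49]  # lower central order statistic
        assert s.max == pytest.approx(9.9)
        assert s.frac_lt_2mm == pytest.approx(20.0)  # k = 0..19


class TestPerStructureReport:
    def _cmp_with_error(self, shape=(6, 6, 6)):
        gt = np.zeros(shape + (3,))
        test = np.zeros(shape + (3,))
        test[:3, ..., 0] = 1.0  # 1 mm error in the lower half
        test[3:, ..., 0] = 3.0  # 3 mm error in the upper half
        return _pair(gt, test)

    def test_disjoint_masks_report_their_errors(self):
        cmp = self._cmp_with_error()
        lower = np.zeros((6, 6, 6), dtype=int)
        lower[:3] = 1
        upper = 1 - lower
        rep = dirqa.per_structure_report(
            cmp, [dirqa.StructureMask(lower, "lower"), dirqa.StructureMask(upper, "upper")]
        )
        assert list(rep["structure"]) == ["lower", "upper", "(whole grid)"]
        assert rep.loc[0, "mean_mm"] == pytest.approx(1.0)
        assert rep.loc[1, "mean_mm"] == pytest.approx(3.0)

    def test_full_mask_equals_whole_grid(self):
        cmp = self._cmp_with_error()
        rep = dirqa.per_structure_report(
            cmp, [dirqa.StructureMask(np.ones((6, 6, 6), dtype=int), "all")]
        )
        all_row = rep.iloc[0].drop("structure")
        grid_row = rep.iloc[1].drop("structure")
        pd.testing.assert_series_equal(all_row, grid_row, check_names=False)

    def test_random_masks_match_loop_oracle(self, rng):
        gt = rng.normal(0, 2, size=(8, 8, 8, 3))
        test = rng.normal(0, 2, size=(8, 8, 8, 3))
        cmp = _pair(gt, test)
        mask = dirqa.StructureMask((rng.random((8, 8, 8)) < 0.4).astype(int), "m")
        rep = dirqa.per_structure_report(cmp, [mask])
        sel = []
        for z in range(8):
            for y in range(8):
                for x in range(8):
                    if mask.voxels[z, y, x]:
                        sel.append(np.linalg.norm(test[z, y, x] - gt[z, y, x]))
        sel = np.array(sel)
        assert rep.loc[0, "mean_mm"] == pytest.approx(sel.mean())
        assert rep.loc[0, "max_mm"] == pytest.approx(sel.max())
        assert rep.loc[0, "n"] == len(sel)

    def test_empty_mask_rejected(self):
        cmp = self._cmp_with_error()
        with pytest.raises(ValueError, match="empty"):
            dirqa.per_structure_report(
                cmp, [dirqa.StructureMask(np.zeros((6, 6, 6), dtype=int), "void")]
            )
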