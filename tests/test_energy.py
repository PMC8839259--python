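import numpy as np
import pytest

from bandstraight.energy import (
    ConstraintError,
    EnergyParams,
    column_correlation_matrix,
    external_energy,
    internal_energy,
    mean_column_correlation,
    total_energy,
)
from bandstraight.lane import DimensionError, LaneImage
from bandstraight.warp import DeformationField, apply_deformation

from conftest import make_band_lane


class TestColumnCorrelation:
    def test_duplicate_columns_correlate_fully(self, rng):
        col = rng.uniform(size=20)
        lane = LaneImage(np.stack([col, col], axis=1))
        r = column_correlation_matrix(lane, min_overlap=2)
        assert r[0, 1] == pytest.approx(1.0)

    def test_negated_column_anticorrelates(self, rng):
        col = rng.uniform(size=20)
        lane = LaneImage(np.stack([col, -col], axis=1))
        r = column_correlation_matrix(lane, min_overlap=2)
        assert r[0, 1] == pytest.approx(-1.0)

    def test_masked_rows_excluded_from_pairing(self, rng):
        """Columns equal on shared rows correlate fully even if one column
        disagrees under its own mask."""
        col = rng.uniform(size=30)
        other = col.copy()
        other[5:10] = 99.0  # differs only where masked
        missing = np.zeros((30, 2), bool)
        missing[5:10, 1] = True
        lane = LaneImage(np.stack([col, other], axis=1), missing)
        r = column_correlation_matrix(lane, min_overlap=2)
        assert r[0, 1] == pytest.approx(1.0)

    def test_low_overlap_flagged_invalid(self, rng):
        missing = np.zeros((30, 2), bool)
        missing[:25, 1] = True  # only 5 shared rows
        lane = LaneImage(rng.uniform(size=(30, 2)), missing)
        r = column_correlation_matrix(lane, min_overlap=10)
        assert np.isnan(r[0, 1])

    def test_zero_variance_flagged_invalid(self, rng):
        lane = LaneImage(
            np.stack([np.full(10, 3.0), rng.uniform(size=10)], axis=1)
        )
        r = column_correlation_matrix(lane, min_overlap=2)
        assert np.isnan(r[0, 1])

    def test_diagonal_excluded(self, rng):
        lane = LaneImage(rng.uniform(size=(10, 3)))
        r = column_correlation_matrix(lane, min_overlap=2)
        assert np.isnan(np.diag(r)).all()

    def test_single_column_raises(self):
        with pytest.raises(DimensionError):
            column_correlation_matrix(LaneImage(np.zeros((5, 1))))

    def test_masked_disk_leaves_other_pairs_untouched(self, rng):
        """Masking a disk changes no correlation outside its column pairs."""
        img = rng.uniform(0, 100, (40, 10))
        lane = LaneImage(img)
        r0 = column_correlation_matrix(lane, min_overlap=2)
        missing = np.zeros((40, 10), bool)
        ys, xs = np.mgrid[0:40, 0:10]
        missing[(ys - 20) ** 2 + (xs - 2) ** 2 <= 4] = True  # touches cols 0-4
        r1 = column_correlation_matrix(LaneImage(img, missing), min_overlap=2)
        touched = np.unique(np.where(missing)[1])
        keep = np.ones(10, bool)
        keep[touched] = False
        np.testing.assert_allclose(
            r1[np.ix_(keep, keep)], r0[np.ix_(keep, keep)], equal_nan=True
        )


class TestExternalEnergy:
    def test_straight_bands_give_zero(self):
        lane = make_band_lane(60, 12)
        assert external_energy(lane, EnergyParams(min_overlap=2)) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_independent_noise_near_one(self, rng):
        lane = LaneImage(rng.normal(size=(400, 20)))
        e = external_energy(lane, EnergyParams(min_overlap=2))
        assert e > 0.9

    def test_f_endpoints_and_monotonicity(self):
        params = EnergyParams(p=2.0)
        assert params.f(0.0) == 1.0
        assert params.f(1.0) == 0.0
        vals = [params.f(c) for c in np.linspace(0, 1, 11)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_no_valid_pair_warns_and_returns_one(self):
        lane = LaneImage(np.full((10, 3), 7.0))  # zero variance everywhere
        with pytest.warns(RuntimeWarning):
            assert external_energy(lane, EnergyParams(min_overlap=2)) == 1.0

    def test_negative_correlations_clamped(self, rng):
        col = rng.uniform(size=30)
        lane = LaneImage(np.stack([col, -col], axis=1))
        assert mean_column_correlation(lane, EnergyParams(min_overlap=2)) == 0.0


class TestInternalEnergy:
    def test_zero_and_constant_fields_cost_nothing(self):
        assert internal_energy(DeformationField.zero((5, 5))) == 0.0
        assert internal_energy(DeformationField(np.full((5, 5), 3.0))) == 0.0

    def test_linear_ramp_finite_difference_value(self):
        """DY = x on a 4x4 field with wx=1, wy=0: 4 rows x 3 unit diffs."""
        dy = np.tile(np.arange(4.0), (4, 1))
        assert internal_energy(dy := DeformationField(dy),
                               EnergyParams(wx=1.0, wy=0.0)) == 12.0

    def test_matches_loop_oracle_on_random_fields(self, rng):
        f = DeformationField(rng.normal(size=(6, 5)))
        params = EnergyParams(wx=0.7, wy=1.3)
        expected = 0.0
        for y in range(6):
            for x in range(4):
                expected += 0.7 * abs(f.dy[y, x + 1] - f.dy[y, x])
        for y in range(5):
            for x in range(5):
                expected += 1.3 * abs(f.dy[y + 1, x] - f.dy[y, x])
        assert internal_energy(f, params) == pytest.approx(expected)


class TestTotalEnergy:
    def test_zero_field_reduces_to_external(self):
        lane = make_band_lane(60, 12, tilt=0.2)
        params = EnergyParams(min_overlap=2)
        assert total_energy(lane, DeformationField.zero(lane.shape), params) == (
            pytest.approx(external_energy(lane, params))
        )

    def test_decomposes_into_terms(self, rng):
        lane = make_band_lane(60, 12, tilt=0.2)
        dy = rng.normal(size=(60, 12)) * 0.5
        dy -= dy.mean(axis=1, keepdims=True)
        f = DeformationField(dy)
        params = EnergyParams(min_overlap=2)
        assert total_energy(lane, f, params) == pytest.approx(
            external_energy(apply_deformation(lane, f), params)
            + internal_energy(f, params)
        )

    def test_ground_truth_inverse_beats_zero_field(self):
        """Undoing a known tilt lowers the energy on a banded lane."""
        width, tilt = 20, 0.4
        lane = make_band_lane(80, width, positions=(25, 55), amplitude=40.0,
                              tilt=tilt)
        xs = np.arange(width, dtype=float)
        correction = -tilt * (xs - (width - 1) / 2)
        f = DeformationField(np.tile(correction, (80, 1)))
        # per-pixel weight normalisation, as the optimiser applies it
        params = EnergyParams(min_overlap=2).scaled(1.0 / (80 * width))
        assert total_energy(lane, f, params) < total_energy(
            lane, DeformationField.zero(lane.shape), params
        )

    def test_constraint_violation_rejected(self):
        lane = make_band_lane(20, 6)
        f = DeformationField(np.full((20, 6), 0.5))  # row means = 0.5
        with pytest.raises(ConstraintError):
            total_energy(lane, f)
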