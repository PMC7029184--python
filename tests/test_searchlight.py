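"""Searchlight geometry, scaling, SVR behavior and LORO accuracy."""

import dataclasses

import numpy as np
import pytest

from _svr_oracle import loro_accuracy_qp, svr_predict_qp
from paramwm.searchlight import (
    FISHER_Z_CAP,
    AccuracyMap,
    DecoderConfig,
    delay_average,
    loro_accuracy,
    run_searchlight,
    sphere_offsets,
    svr_fit_predict,
    zscale_patterns,
)

RUNS = np.repeat(np.arange(4), 4)
TARGETS = np.tile([7.0, 9.0, 11.0, 13.0], 4)


class TestSphereOffsets:
    @pytest.mark.parametrize("radius,expected", [(0, 1), (1, 7), (4, 257)])
    def test_lattice_counts(self, radius, expected):
        # oracle: triple loop over the bounding cube
        count = 0
        r = int(radius)
        for x in range(-r, r + 1):
            for y in range(-r, r + 1):
                for z in range(-r, r + 1):
                    count += x * x + y * y + z * z <= radius**2
        offsets = sphere_offsets(radius)
        assert len(offsets) == expected == count

    def test_center_included_and_symmetric(self):
        offs = sphere_offsets(2)
        assert [0, 0, 0] in offs.tolist()
        assert {tuple(-o) for o in offs} == {tuple(o) for o in offs}

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            sphere_offsets(-1)


class TestZScale:
    def test_train_columns_standardized(self, rng):
        train = rng.standard_normal((12, 9))
        test = rng.standard_normal((4, 9))
        trz, tez, flag = zscale_patterns(train, test)
        np.testing.assert_allclose(trz.mean(0), 0.0, atol=1e-12)
        np.testing.assert_allclose(trz.std(0), 1.0, atol=1e-12)
        assert not flag

    def test_constant_voxel_zeroed_and_flagged(self, rng):
        train = rng.standard_normal((12, 3))
        train[:, 1] = 5.0
        test = rng.standard_normal((4, 3))
        trz, tez, flag = zscale_patterns(train, test)
        assert flag
        assert np.all(trz[:, 1] == 0) and np.all(tez[:, 1] == 0)

    def test_idempotent_on_scaled_train(self, rng):
        train = rng.standard_normal((12, 5))
        trz, _, _ = zscale_patterns(train, train[:2])
        trz2, _, _ = zscale_patterns(trz, trz[:2])
        np.testing.assert_allclose(trz, trz2, atol=1e-12)


class TestSvr:
    def test_prediction_interpolates_on_clean_line(self):
        # 1-D y = x: with large C the fit tracks the line within the
        # epsilon-insensitive band; cross-checked against the QP dual
        X = np.array([[7.0], [9.0], [11.0], [13.0]])
        y = np.array([7.0, 9.0, 11.0, 13.0])
        cfg = DecoderConfig(svr_c=100.0, svr_epsilon=0.1)
        pred = svr_fit_predict(X, y, np.array([[10.0]]), cfg)
        assert abs(pred[0] - 10.0) <= 0.1 + 1e-6
        qp = svr_predict_qp(X, y, np.array([[10.0]]), C=100.0, eps=0.1)
        np.testing.assert_allclose(pred, qp, atol=1e-6)

    def test_duplicating_training_set_preserves_predictions(self, rng):
        # holds when no dual variable is clamped at the box bound C, so use
        # a large C on near-linear data (with active bounds the duplicated
        # problem has twice the capacity and may differ)
        X = rng.standard_normal((12, 6))
        y = X[:, 0] + 0.05 * rng.standard_normal(12)
        T = rng.standard_normal((4, 6))
        cfg = DecoderConfig(svr_c=1000.0)
        p1 = svr_fit_predict(X, y, T, cfg)
        p2 = svr_fit_predict(np.vstack([X, X]), np.concatenate([y, y]), T, cfg)
        np.testing.assert_allclose(p1, p2, atol=1e-5)

    def test_target_shift_absorbed_by_bias(self, rng):
        # oracle: re-solving the dual with shifted targets moves only b
        X = rng.standard_normal((12, 6))
        y = TARGETS[:12]
        T = rng.standard_normal((4, 6))
        p1 = svr_fit_predict(X, y, T)
        p2 = svr_fit_predict(X, y + 100.0, T)
        np.testing.assert_allclose(p2 - p1, 100.0, atol=1e-6)
        qp1 = svr_predict_qp(X, y, T)
        qp2 = svr_predict_qp(X, y + 100.0, T)
        np.testing.assert_allclose(qp2 - qp1, 100.0, atol=1e-6)

    def test_single_target_value_rejected(self, rng):
        with pytest.raises(ValueError, match="distinct"):
            svr_fit_predict(rng.standard_normal((4, 3)), np.ones(4),
                            rng.standard_normal((2, 3)))

    def test_identical_training_vectors_fall_back_to_mean(self, rng):
        X = np.ones((12, 3))
        with pytest.warns(UserWarning, match="degenerate"):
            pred = svr_fit_predict(X, TARGETS[:12], rng.standard_normal((2, 3)))
        np.testing.assert_allclose(pred, 10.0)


class TestLoroAccuracy:
    def test_perfect_patterns_reach_cap(self):
        # patterns that are exactly the targets in one voxel: every fold
        # predicts a monotone transform of the truth, so |r| = 1 (capped)
        patterns = np.column_stack([TARGETS, TARGETS]).astype(float)
        acc = loro_accuracy(patterns, RUNS, TARGETS)
        assert acc == pytest.approx(FISHER_Z_CAP)

    def test_shuffled_labels_are_at_chance(self):
        # oracle: under independence the Fisher-z null has mean 0
        rng = np.random.default_rng(31)
        vals = []
        for _ in range(800):
            patterns = rng.standard_normal((16, 20))
            targets = rng.permutation(TARGETS)
            vals.append(loro_accuracy(patterns, RUNS, targets))
        mean = np.mean(vals)
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(mean) < 2 * se + 1e-3

    def test_four_folds_averaged(self, rng):
        # accuracy is the mean of the four per-run-held-out fold scores:
        # check by recomputing with an independent QP solver fold by fold
        patterns = rng.standard_normal((16, 8))
        a = loro_accuracy(patterns, RUNS, TARGETS)
        b = loro_accuracy_qp(patterns, RUNS, TARGETS)
        assert a == pytest.approx(b, abs=1e-6)

    def test_misaligned_inputs_rejected(self, rng):
        with pytest.raises(ValueError):
            loro_accuracy(rng.standard_normal((15, 4)), RUNS, TARGETS)


class TestRunSearchlight:
    def test_planted_voxel_code_peaks_at_plant(self, rng):
        # a tiny 3D problem with the code planted at one location
        shape = (7, 7, 5)
        mask = np.ones(shape, dtype=bool)
        betas = rng.standard_normal((4, 4, 1, *shape))
        betas[:, :, 0, 3, 3, 2] += 5.0 * np.tile([-1.5, -0.5, 0.5, 1.5], (4, 1))
        from paramwm.firstlevel import BetaMaps

        bm = BetaMaps(betas, (7, 9, 11, 13), 1)
        cfg = DecoderConfig(radius_vox=1, min_sphere_voxels=1, delay_bins=(1,))
        acc = run_searchlight(bm, mask, cfg, time_bins=(1,))
        peak = np.unravel_index(np.nanargmax(acc.maps[1]), shape)
        # information spreads at most one searchlight radius from the plant
        assert np.linalg.norm(np.subtract(peak, (3, 3, 2))) <= 1
        # far-away searchlights that never see the planted voxel stay low
        far = acc.maps[1][:2, :2, :]
        assert np.nanmax(far) < acc.maps[1][3, 3, 2]

    def test_deterministic_and_masked(self, rng):
        shape = (6, 6, 4)
        mask = np.zeros(shape, dtype=bool)
        mask[1:5, 1:5, 1:3] = True
        betas = rng.standard_normal((4, 4, 2, *shape))
        from paramwm.firstlevel import BetaMaps

        bm = BetaMaps(betas, (7, 9, 11, 13), 2)
        cfg = DecoderConfig(radius_vox=1, min_sphere_voxels=1)
        a1 = run_searchlight(bm, mask, cfg, time_bins=(1, 2))
        a2 = run_searchlight(bm, mask, cfg, time_bins=(1, 2))
        np.testing.assert_array_equal(a1.maps[1], a2.maps[1])
        assert np.all(np.isnan(a1.maps[1][~mask]))
        assert np.all(np.isfinite(a1.maps[1][mask]))

    def test_min_sphere_voxels_skips_centers(self, rng):
        shape = (5, 5, 3)
        mask = np.zeros(shape, dtype=bool)
        mask[2, 2, 1] = True  # an isolated voxel: sphere of size 1
        mask[0, 0, 0] = True
        betas = rng.standard_normal((4, 4, 1, *shape))
        from paramwm.firstlevel import BetaMaps

        bm = BetaMaps(betas, (7, 9, 11, 13), 1)
        cfg = DecoderConfig(radius_vox=1, min_sphere_voxels=2)
        acc = run_searchlight(bm, mask, cfg, time_bins=(1,))
        assert np.all(np.isnan(acc.maps[1]))

    def test_empty_mask_rejected(self, rng):
        from paramwm.firstlevel import BetaMaps

        bm = BetaMaps(rng.standard_normal((4, 4, 1, 4, 4, 4)), (7, 9, 11, 13), 1)
        with pytest.raises(ValueError, match="empty"):
            run_searchlight(bm, np.zeros((4, 4, 4), bool))


class TestDelayAverage:
    def test_identical_maps_pass_through(self, rng):
        m = rng.standard_normal((4, 4, 2))
        acc = {b: m for b in range(1, 11)}
        np.testing.assert_allclose(delay_average(acc), m)

    def test_six_delay_bins_averaged_linearly(self, rng):
        maps_a = {b: rng.standard_normal((3, 3, 2)) for b in range(1, 11)}
        maps_b = {b: rng.standard_normal((3, 3, 2)) for b in range(1, 11)}
        maps_sum = {b: maps_a[b] + maps_b[b] for b in range(1, 11)}
        np.testing.assert_allclose(
            delay_average(maps_sum), delay_average(maps_a) + delay_average(maps_b)
        )
        np.testing.assert_allclose(
            delay_average(maps_a),
            np.mean([maps_a[b] for b in (3, 4, 5, 6, 7, 8)], axis=0),
        )

    def test_missing_bin_rejected(self, rng):
        maps = {b: rng.standard_normal((2, 2, 2)) for b in (3, 4, 5)}
        with pytest.raises(ValueError, match="missing"):
            delay_average(maps)
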