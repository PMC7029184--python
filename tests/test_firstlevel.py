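"""FIR and parametric first-level models: designs, nuisance, OLS recovery."""

import numpy as np
import pandas as pd
import pytest

from paramwm import firstlevel, stimgen
from paramwm.firstlevel import (
    FIR_N_BINS,
    build_fir_design,
    build_parametric_model,
    dct_highpass,
    double_gamma_hrf,
    extract_nuisance_pcs,
    fit_fir_betas,
    fit_glm_run,
)


def _single_trial_events(onset, cued=9, uncued=13):
    rows = []
    for event_type, rel in stimgen.EVENT_ONSETS_S.items():
        rows.append(
            {
                "onset": onset + rel,
                "duration": 1.0,
                "event_type": event_type,
                "cued_numerosity": cued,
                "uncued_numerosity": uncued,
                "cue": 1,
                "match_position": 1,
                "foil_numerosity": 12,
            }
        )
    return pd.DataFrame(rows)


class TestHrf:
    def test_peak_and_undershoot_shape(self):
        h = double_gamma_hrf(2.0, oversampling=16)
        dt = 2.0 / 16
        t_peak = np.argmax(h) * dt
        assert 4.5 < t_peak < 6.5
        undershoot = h[int(12 / dt) : int(24 / dt)]
        assert undershoot.min() < 0

    def test_sustained_boxcar_plateaus_near_one(self):
        reg = firstlevel.hrf_convolve(
            np.array([10.0]), np.array([30.0]), np.array([1.0]), 40, 2.0
        )
        assert abs(reg[int(30 / 2)] - 1.0) < 0.2


class TestFirDesign:
    def test_single_trial_indicator_positions(self):
        events = _single_trial_events(onset=20.0, cued=9)
        design = build_fir_design(events, n_volumes=30, tr_s=2.0)
        assert design.matrix.shape[1] == 40
        for b in range(1, FIR_N_BINS + 1):
            col = design.matrix[:, design.task_columns[(9, b)]]
            expected = np.zeros(30)
            expected[10 + b - 1] = 1.0
            np.testing.assert_array_equal(col, expected)
        # all other condition columns stay empty
        for cond in (7, 11, 13):
            for b in range(1, FIR_N_BINS + 1):
                assert design.matrix[:, design.task_columns[(cond, b)]].sum() == 0

    def test_column_sums_equal_trial_counts(self, example_run):
        events = stimgen.events_table(example_run)
        n_vol = int(events.onset.max() / 2) + FIR_N_BINS + 2
        design = build_fir_design(events, n_vol, 2.0)
        counts = (
            events[events.event_type == "sample1"]
            .groupby("cued_numerosity")
            .size()
            .to_dict()
        )
        for (cond, b), j in design.task_columns.items():
            assert design.matrix[:, j].sum() == counts[cond]

    def test_uncued_label_source_swaps_conditions(self):
        events = _single_trial_events(onset=0.0, cued=9, uncued=13)
        design = build_fir_design(events, 20, 2.0, label_source="uncued")
        assert design.matrix[:, design.task_columns[(13, 1)]].sum() == 1
        assert design.matrix[:, design.task_columns[(9, 1)]].sum() == 0

    def test_misaligned_onset_rejected(self):
        events = _single_trial_events(onset=1.0)
        with pytest.raises(ValueError, match="TR-aligned"):
            build_fir_design(events, 30, 2.0)

    def test_trial_past_run_end_rejected(self):
        events = _single_trial_events(onset=20.0)
        with pytest.raises(ValueError, match="past the run end"):
            build_fir_design(events, 15, 2.0)


class TestDctHighpass:
    def test_basis_count_at_standard_cutoff(self):
        # 128 volumes at TR 2 (256 s) with a 128 s cutoff: 4 cosines
        basis = dct_highpass(128, 2.0, 128.0)
        assert basis.shape == (128, 4)

    def test_orthonormal_columns(self):
        basis = dct_highpass(100, 2.0, 100.0)
        gram = basis.T @ basis
        np.testing.assert_allclose(gram, np.eye(basis.shape[1]), atol=1e-10)

    def test_infinite_cutoff_empty(self):
        assert dct_highpass(64, 2.0, np.inf).shape == (64, 0)


class TestNuisancePcs:
    def test_rank_one_recovery(self, rng):
        t = np.sin(np.linspace(0, 6 * np.pi, 120))
        loadings = rng.standard_normal(30)
        data = np.outer(loadings, t) + 1e-6 * rng.standard_normal((30, 120))
        vol = data.reshape(5, 6, 1, 120)
        mask = np.ones((5, 6, 1), dtype=bool)
        pcs = extract_nuisance_pcs(vol, mask, k=3)
        r = np.corrcoef(pcs[:, 0], t)[0, 1]
        assert abs(r) > 0.999

    def test_explained_variance_ordering(self, rng):
        vol = rng.standard_normal((4, 4, 3, 60))
        mask = np.ones((4, 4, 3), dtype=bool)
        pcs = extract_nuisance_pcs(vol, mask, k=5)
        X = vol[mask].T - vol[mask].T.mean(0)
        ev = [np.var(X @ X.T @ pcs[:, i]) for i in range(5)]
        assert all(a >= b - 1e-9 for a, b in zip(ev, ev[1:]))

    def test_empty_mask_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            extract_nuisance_pcs(rng.standard_normal((2, 2, 2, 10)),
                                 np.zeros((2, 2, 2), bool), k=2)

    def test_k_zero(self, rng):
        out = extract_nuisance_pcs(rng.standard_normal((2, 2, 2, 10)),
                                   np.ones((2, 2, 2), bool), k=0)
        assert out.shape == (10, 0)


class TestGlmFit:
    @staticmethod
    def _four_trial_events():
        return pd.concat(
            [
                _single_trial_events(onset, cued=cond)
                for onset, cond in zip((0.0, 24.0, 48.0, 72.0), (7, 9, 11, 13))
            ],
            ignore_index=True,
        )

    def test_noiseless_recovery_is_exact(self, rng):
        events = self._four_trial_events()
        design = build_fir_design(events, 48, 2.0)
        true_beta = rng.standard_normal(40)
        Y = design.matrix @ true_beta  # single voxel
        vol = np.tile(Y, (2, 2, 1, 1)).reshape(2, 2, 1, 48)
        betas = fit_glm_run(vol, design)
        for ci, cond in enumerate((7, 9, 11, 13)):
            got = np.array([betas[ci, b - 1, 0, 0, 0] for b in range(1, 11)])
            want = np.array(
                [true_beta[design.task_columns[(cond, b)]] for b in range(1, 11)]
            )
            np.testing.assert_allclose(got, want, atol=1e-8)

    def test_nuisance_regression_leaves_task_betas_unchanged(self, rng):
        # projection algebra on a 10-voxel toy: adding any multiple of an
        # included nuisance column to the data must not move task betas
        events = self._four_trial_events()
        design = build_fir_design(events, 48, 2.0)
        nuis = rng.standard_normal(48)
        design_n = design.append(nuis[:, None], ["nuisance"])
        base = rng.standard_normal((10, 48))
        vol0 = base.reshape(10, 1, 1, 48)
        vol1 = (base + 3.7 * nuis).reshape(10, 1, 1, 48)
        b0 = fit_glm_run(vol0, design_n)
        b1 = fit_glm_run(vol1, design_n)
        np.testing.assert_allclose(b0, b1, atol=1e-8)

    def test_rank_deficiency_names_columns(self):
        events = _single_trial_events(onset=4.0, cued=7)
        design = build_fir_design(events, 25, 2.0)
        dup = design.matrix[:, [design.task_columns[(7, 1)]]]
        design_bad = design.append(dup, ["duplicate"])
        with pytest.raises(ValueError, match="rank deficient"):
            fit_glm_run(np.zeros((2, 2, 1, 25)), design_bad)

    def test_beta_count_contract(self, small_betamaps):
        # 4 runs x 4 conditions x 10 bins = 160 beta volumes per subject
        assert small_betamaps.data.shape[:3] == (4, 4, 10)
        assert small_betamaps.conditions == (7, 9, 11, 13)
        n_maps = np.prod(small_betamaps.data.shape[:3])
        assert n_maps == 160
        mask = small_betamaps.mask
        assert np.all(np.isfinite(small_betamaps.data[..., mask]))


class TestParametricModel:
    def test_ten_task_regressors(self, example_run):
        events = stimgen.events_table(example_run)
        n_vol = int(events.onset.max() / 2) + 12
        model = build_parametric_model(events, n_vol, 2.0)
        assert model.design.matrix.shape[1] == 10
        assert not model.degenerate

    def test_modulators_mean_centered(self, example_run):
        events = stimgen.events_table(example_run)
        trials = events[events.event_type == "sample1"]
        centered = trials.cued_numerosity - trials.cued_numerosity.mean()
        assert abs(centered.mean()) < 1e-12

    def test_contrast_selects_wm_modulator(self, example_run):
        events = stimgen.events_table(example_run)
        n_vol = int(events.onset.max() / 2) + 12
        model = build_parametric_model(events, n_vol, 2.0)
        j = model.design.labels.index("wm_delay_x_numerosity")
        assert model.contrast[j] == 1.0 and model.contrast.sum() == 1.0

    def test_single_numerosity_degenerate_flagged(self):
        events = pd.concat(
            [_single_trial_events(0.0, cued=9), _single_trial_events(24.0, cued=9)],
            ignore_index=True,
        )
        with pytest.warns(UserWarning, match="modulator is zero"):
            model = build_parametric_model(events, 25, 2.0)
        assert model.degenerate
        j = model.design.labels.index("wm_delay_x_numerosity")
        np.testing.assert_allclose(model.design.matrix[:, j], 0.0, atol=1e-12)
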