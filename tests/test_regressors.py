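"""Parametric modulators, HRF, design matrices and synthetic-BOLD recovery."""

import numpy as np
import pandas as pd
import pytest

from fbl_rlddm.regressors import (
    build_design,
    canonical_hrf,
    extract_modulators,
    fit_glm,
    read_bids_events,
    simulate_bold,
    write_bids_events,
)


@pytest.fixture(scope="module")
def subject_log(small_cohort):
    log, _ = small_cohort
    return log[(log["subject"] == 1) & (log["block"] == 1)].copy()


@pytest.fixture(scope="module")
def events(subject_log):
    return extract_modulators(subject_log)


@pytest.fixture(scope="module")
def design(events):
    return build_design(events, n_volumes=460, tr_s=1.0)


class TestExtractModulators:
    def test_modulators_mean_centered(self, events):
        for cond in ("stimulus", "feedback"):
            vals = events.loc[events["condition"] == cond, "modulator"]
            assert abs(vals.mean()) < 1e-12

    def test_onsets_nondecreasing(self, events):
        assert (np.diff(events["onset_s"]) >= 0).all()

    def test_missing_trials_routed_to_nuisance(self, subject_log):
        log = subject_log.copy()
        n_missing = int(log["missing"].sum())
        ev = extract_modulators(log)
        missed = ev[ev["condition"].str.startswith("missed")]
        assert len(missed) == 2 * n_missing
        no_miss = log[~log["missing"]].copy()
        ev2 = extract_modulators(no_miss)
        assert not ev2["condition"].str.startswith("missed").any()

    def test_hand_traced_three_trial_log(self):
        """AS/PE per event follow the delta rule traced by hand.

        Trial 1 (match pair, correct): AS mean pre = 0, PE = +1, AS -> 0.5.
        Trial 2 (same sound, foil pair, wrong): AS mean = 0.25, PE = -0, i.e.
        f=0 minus AS_foil=0 -> 0; AS unchanged.
        Trial 3 (match pair again, correct): AS mean = 0.25, PE = 1-0.5 = 0.5.
        """
        from fbl_rlddm.rlddm import SubjectParams, sequence_loglik

        log = pd.DataFrame({
            "task": "A", "block": 1, "trial": [1, 2, 3],
            "sound_id": ["s1", "s1", "s1"],
            "symbol_id": ["m1", "f1", "m1"],
            "is_match": [True, False, True],
            "correct": [1.0, 0.0, 1.0],
            "rt_s": [1.0, 1.2, 0.9],
            "missing": [False] * 3,
            "stim_onset_s": [0.0, 6.0, 12.0],
        })
        params = SubjectParams(a=1.5, tau=0.3, v_mod=2.0,
                               eta_pos=0.5, eta_neg=0.5)
        _, series = sequence_loglik(params, log)
        log["as_cor"], log["as_inc"] = series["as_cor"], series["as_inc"]
        log["pe"] = series["pe"]
        ev = extract_modulators(log)
        stim = ev[ev["condition"] == "stimulus"]["modulator"].to_numpy()
        fb = ev[ev["condition"] == "feedback"]["modulator"].to_numpy()
        raw_as = np.array([0.0, 0.25, 0.25])
        raw_pe = np.array([1.0, 0.0, 0.5])
        np.testing.assert_allclose(stim, raw_as - raw_as.mean(), atol=1e-12)
        np.testing.assert_allclose(fb, raw_pe - raw_pe.mean(), atol=1e-12)

    def test_presented_pair_modulator_mode(self, subject_log):
        ev = extract_modulators(subject_log, stimulus_modulator="presented")
        assert len(ev) == len(extract_modulators(subject_log))

    def test_requires_derived_columns(self, subject_log):
        with pytest.raises(ValueError, match="derived"):
            extract_modulators(subject_log.drop(columns=["pe"]))


class TestCanonicalHrf:
    def test_unit_sum(self):
        h = canonical_hrf(1.0, decimate=False)
        assert h.sum() == pytest.approx(1.0)

    def test_peak_near_six_seconds(self):
        h = canonical_hrf(1.0, microtime_s=0.1, decimate=False)
        assert np.argmax(h) * 0.1 == pytest.approx(6.0, abs=0.2)

    def test_undershoot_present(self):
        h = canonical_hrf(1.0, decimate=False)
        assert h.min() < 0.0
        assert np.argmin(h) * 0.1 > 10.0


class TestBuildDesign:
    def test_shape_and_columns(self, design, events):
        assert design.matrix.shape == (460, len(design.columns))
        assert design.columns[-1] == "intercept"
        assert {"stimulus", "stimulus_x_as", "feedback",
                "feedback_x_pe"} <= set(design.columns)
        has_missed = events["condition"].str.startswith("missed").any()
        assert ("missed" in design.columns) == has_missed

    def test_zero_events_gives_intercept_only_signal(self):
        ev = pd.DataFrame(columns=["onset_s", "duration_s", "condition",
                                   "modulator", "response_time_s"])
        dm = build_design(ev, n_volumes=100, tr_s=1.0)
        body = dm.matrix[:, :-1]
        assert np.allclose(body, 0.0)
        assert np.allclose(dm.matrix[:, -1], 1.0)

    def test_single_event_reproduces_hrf(self):
        ev = pd.DataFrame({"onset_s": [0.0], "duration_s": [0.0],
                           "condition": ["stimulus"], "modulator": [0.0],
                           "response_time_s": [1.0]})
        dm = build_design(ev, n_volumes=40, tr_s=1.0, microtime_s=0.1)
        hrf = canonical_hrf(1.0, microtime_s=0.1, decimate=True)
        col = dm.matrix[:, dm.columns.index("stimulus")]
        np.testing.assert_allclose(col[:hrf.size], hrf, atol=1e-12)

    def test_fft_and_direct_convolution_agree(self, events):
        a = build_design(events, 460, 1.0, use_fft=True).matrix
        b = build_design(events, 460, 1.0, use_fft=False).matrix
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_events_beyond_scan_truncated_with_warning(self, events):
        with pytest.warns(UserWarning, match="truncated"):
            dm = build_design(events, n_volumes=100, tr_s=1.0)
        assert dm.matrix.shape[0] == 100

    def test_modulated_column_near_orthogonal_to_unmodulated(self, design):
        m = design.to_frame()
        for base, mod in (("stimulus", "stimulus_x_as"),
                          ("feedback", "feedback_x_pe")):
            r = np.corrcoef(m[base], m[mod])[0, 1]
            assert abs(r) < 0.3


class TestGlm:
    BETAS = {"stimulus": 1.0, "stimulus_x_as": 0.5, "feedback": 0.8,
             "feedback_x_pe": 0.7, "missed": 0.2, "intercept": 10.0}

    def test_noiseless_recovery_is_exact(self, design):
        bold = simulate_bold(design, self.BETAS, noise_sd=0.0, rng_seed=0)
        betas, _ = fit_glm(design, bold)
        for name, val in self.BETAS.items():
            if name in design.columns:
                assert betas.loc[name, "voxel0"] == pytest.approx(val, abs=1e-8)

    def test_noisy_recovery_within_sampling_theory(self, design):
        """Mean recovered AS beta over 500 voxels within 3 SE of truth."""
        bold = simulate_bold(design, self.BETAS, noise_sd=1.0, rng_seed=1,
                             n_voxels=500)
        betas, _ = fit_glm(design, bold)
        est = betas.loc["stimulus_x_as"].to_numpy()
        se_mean = est.std(ddof=1) / np.sqrt(est.size)
        assert abs(est.mean() - 0.5) < 3 * se_mean

    def test_null_modulator_t_stats_in_null_range(self, design):
        betas = dict(self.BETAS, feedback_x_pe=0.0)
        bold = simulate_bold(design, betas, noise_sd=1.0, rng_seed=2,
                             n_voxels=500)
        _, tstats = fit_glm(design, bold)
        t_pe = tstats.loc["feedback_x_pe"].to_numpy()
        assert (np.abs(t_pe) < 3).mean() >= 0.99

    def test_rank_deficient_design_raises(self, design):
        from fbl_rlddm.regressors import DesignMatrix

        mat = np.column_stack([design.matrix, design.matrix[:, 0]])
        dup = DesignMatrix(mat, design.columns + ["dup"], design.tr_s)
        with pytest.raises(ValueError, match="rank deficient"):
            fit_glm(dup, np.zeros(mat.shape[0]))


class TestBidsEvents:
    def test_roundtrip(self, events, tmp_path):
        path = tmp_path / "sub-01_task-A_events.tsv"
        write_bids_events(events, path)
        back = read_bids_events(path)
        assert len(back) == len(events)
        np.testing.assert_allclose(back["onset_s"], events["onset_s"].round(3))
        assert (back["condition"] == events["condition"]).all()

    def test_bids_column_order_and_precision(self, events, tmp_path):
        path = tmp_path / "events.tsv"
        write_bids_events(events, path)
        header = path.read_text().splitlines()[0].split("\t")
        assert header == ["onset", "duration", "trial_type",
                          "response_time", "modulator"]
        first = path.read_text().splitlines()[1].split("\t")
        assert len(first[0].split(".")[-1]) <= 3
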