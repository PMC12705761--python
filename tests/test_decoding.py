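"""Sliding-window decoder, permutation nulls, LOO probabilities, rivalry."""

import numpy as np
import pandas as pd
import pytest

import percept
from percept.decoding import (
    DecoderSpec,
    best_bin,
    decode_features_auc,
    feature_matrix,
    make_classifier,
    significance_runs,
    sliding_window_auc,
    window_probability_test,
)
from percept.session import RateMatrix
from percept.synth import UnitProfile, make_profiles


def _znorm(values):
    return RateMatrix(np.asarray(values, dtype=float), "znorm", 10, -300)


@pytest.fixture(scope="module")
def fs_decoding():
    profiles = make_profiles(16, 1, classes=("face", "place"), noise_fraction=0.5)
    b = percept.simulate_flash_suppression(profiles, 2, n_trials_per_condition=25)
    net = percept.net_rate(b)
    z = percept.z_normalize(net, b.units["array"].to_numpy())
    return b, z


class TestSlidingWindowAuc:
    def test_separable_data_saturates_and_baseline_at_chance(self, fs_decoding):
        b, z = fs_decoding
        lab = b.trials["phase1_class"].to_numpy()
        spec = DecoderSpec(step_ms=100)
        starts = np.array([-300.0, -200.0, 300.0, 500.0])
        tr = sliding_window_auc(z, lab, spec, seed=0, starts=starts)
        assert tr.auc_mean[0] < 0.65 and tr.auc_mean[1] < 0.65
        assert tr.auc_mean[2] > 0.85 and tr.auc_mean[3] > 0.85

    def test_label_shuffle_restores_chance(self, fs_decoding):
        b, z = fs_decoding
        rng = np.random.default_rng(3)
        lab = rng.permutation(b.trials["phase1_class"].to_numpy())
        tr = sliding_window_auc(
            z, lab, DecoderSpec(), seed=0, starts=np.array([300.0])
        )
        assert abs(tr.auc_mean[0] - 0.5) < 0.12

    def test_auc_monotone_in_class_separation(self):
        rng = np.random.default_rng(4)
        aucs = []
        for sep in (0.5, 1.0, 2.0):
            X = np.vstack(
                [rng.normal(0, 1, (40, 8)), rng.normal(sep / np.sqrt(8), 1, (40, 8))]
            )
            y = np.array(["a"] * 40 + ["b"] * 40)
            auc, _, _ = decode_features_auc(X, y, DecoderSpec(), seed=0)
            aucs.append(auc)
        assert aucs[0] < aucs[1] < aucs[2]

    def test_macro_auc_multiclass(self):
        rng = np.random.default_rng(5)
        mus = {"a": [3, 0, 0], "b": [0, 3, 0], "c": [0, 0, 3]}
        X = np.vstack([rng.normal(mus[c], 1.0, (30, 3)) for c in "abc"])
        y = np.repeat(list("abc"), 30)
        auc, _, _ = decode_features_auc(X, y, DecoderSpec(), seed=0)
        assert auc > 0.9

    def test_lasso_zeroes_noise_units(self, fs_decoding):
        b, z = fs_decoding
        lab = b.trials["phase1_class"].to_numpy()
        X = feature_matrix(z, 300.0, 100.0)
        m = make_classifier(DecoderSpec(), 0)
        m.fit(X, lab)
        coef = m.coef_.ravel()
        # first half of the profiles are pure-noise units
        n_noise = 8
        assert (coef[:n_noise] == 0).mean() > 0.5


class TestPermutationNull:
    def test_null_pvalues_and_run_rule(self, fs_decoding):
        b, z = fs_decoding
        lab = b.trials["phase1_class"].to_numpy()
        spec = DecoderSpec(n_repetitions=5)
        starts = np.array([-250.0, 300.0])
        tr = sliding_window_auc(z, lab, spec, seed=0, starts=starts)
        tr = percept.permutation_null(
            z, lab, tr, spec, seed=1, n_shuffle=60, min_run=1
        )
        assert tr.p_values[0] > 0.05  # baseline window at chance
        assert tr.p_values[1] < 0.05  # response window above the null
        assert tr.null_auc.shape == (60, 2)
        assert abs(tr.null_auc.mean() - 0.5) < 0.05

    def test_significance_run_mask(self):
        p = np.array([0.01, 0.2, 0.01, 0.01, 0.01, 0.2, 0.01, 0.01])
        mask = significance_runs(p, 0.05, min_run=3)
        assert mask.tolist() == [False, False, True, True, True, False, False, False]


class TestBestBinLoo:
    def test_probabilities_bounded_and_ordered(self, fs_decoding):
        b, z = fs_decoding
        lab = b.trials["phase1_class"].to_numpy()
        traj = percept.best_bin_loo_probability(
            z, lab, np.arange(len(lab)), DecoderSpec(step_ms=50), seed=0
        )
        assert traj.probabilities.min() >= 0.0 and traj.probabilities.max() <= 1.0
        cond = b.trials["condition"].to_numpy()
        w2 = (traj.window_centers >= 1100) & (traj.window_centers <= 1400)
        mean_p = {
            c: traj.probabilities[cond == c][:, w2].mean()
            for c in ("CON_P", "FS_PF", "RA_PF", "CON_F")
        }
        # newly perceived face raises face probability above continued place,
        # but (percept gain < 1) below real alternation
        assert mean_p["CON_P"] < mean_p["FS_PF"] < mean_p["RA_PF"]
        assert mean_p["CON_F"] > mean_p["CON_P"]

    def test_con_f_high_probability_throughout(self, fs_decoding):
        b, z = fs_decoding
        lab = b.trials["phase1_class"].to_numpy()
        traj = percept.best_bin_loo_probability(
            z, lab, np.arange(len(lab)), DecoderSpec(step_ms=50), seed=0
        )
        cond = b.trials["condition"].to_numpy()
        resp = (traj.window_centers > 200) & (traj.window_centers < 1400)
        con_f = traj.probabilities[cond == "CON_F"][:, resp].mean()
        con_p = traj.probabilities[cond == "CON_P"][:, resp].mean()
        assert con_f > con_p + 0.1

    def test_too_few_trials_is_error(self, fs_decoding):
        _, z = fs_decoding
        with pytest.raises(ValueError):
            percept.best_bin_loo_probability(
                z, np.array(["face", "place"]), np.array([0, 1]), seed=0
            )


class TestWindowProbabilityTest:
    def _traj(self, rng, diff=0.0):
        from percept.decoding import ProbabilityTrajectory

        probs = np.clip(rng.normal(0.5, 0.1, (40, 20)), 0, 1)
        probs[:20] += diff
        return ProbabilityTrajectory(
            np.arange(20) * 10.0 + 50.0, probs, np.arange(40), 0.0, 0.5
        )

    def test_exchangeable_groups_null(self):
        rng = np.random.default_rng(0)
        ps = [
            window_probability_test(
                self._traj(np.random.default_rng(k)),
                np.arange(20),
                np.arange(20, 40),
                (100, 200),
                n_perm=400,
                seed=k,
            )["p_value"]
            for k in range(20)
        ]
        assert (np.array(ps) < 0.05).mean() <= 0.2

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(1)
        res = window_probability_test(
            self._traj(rng, diff=0.15),
            np.arange(20),
            np.arange(20, 40),
            (100, 200),
            n_perm=400,
            seed=0,
        )
        assert res["p_value"] < 0.05

    def test_missing_group_is_error(self):
        rng = np.random.default_rng(2)
        with pytest.raises(KeyError):
            window_probability_test(
                self._traj(rng), np.array([99]), np.arange(5), (100, 200)
            )


class TestCrossTemporal:
    def test_diagonal_matches_sliding_auc(self, fs_decoding):
        b, z = fs_decoding
        lab = b.trials["phase1_class"].to_numpy()
        starts = np.array([-250.0, 300.0, 600.0])
        spec = DecoderSpec(n_repetitions=5)
        mat, centers = percept.cross_temporal_generalization(
            z, lab, spec, seed=0, starts=starts
        )
        tr = sliding_window_auc(z, lab, spec, seed=0, starts=starts)
        assert np.allclose(np.diag(mat), tr.auc_mean, atol=0.1)
        # stationary sustained code generalizes across response windows
        assert mat[1, 2] > 0.75 and mat[2, 1] > 0.75


class TestRivalry:
    @pytest.fixture(scope="class")
    def rivalry_setup(self):
        profiles = [
            UnitProfile(
                baseline=5.0,
                latency=90.0,
                amplitudes={"face": 40.0, "place": 5.0},
                sustain=0.8,
                array=2,
            )
            for _ in range(6)
        ] + [
            UnitProfile(
                baseline=5.0,
                latency=90.0,
                amplitudes={"face": 5.0, "place": 40.0},
                sustain=0.8,
                array=2,
            )
            for _ in range(6)
        ]
        b = percept.simulate_rivalry(profiles, 9, n_trials_per_condition=10)
        net = percept.net_rate(b)
        z = percept.z_normalize(net, b.units["array"].to_numpy())
        traj = percept.rivalry_probability(z, b.trials, DecoderSpec(step_ms=50), seed=0)
        return b, z, traj

    def test_divergence_precedes_button_press(self, rivalry_setup):
        b, _, traj = rivalry_setup
        div = percept.press_locked_divergence(traj, b.trials)
        assert div["lead_ms"] is not None
        assert 1100.0 <= div["lead_ms"] <= 1900.0

    def test_density_median_centered(self, rivalry_setup):
        b, _, traj = rivalry_setup
        dens = percept.rivalry_probability_density(traj, b.trials)
        pooled = np.concatenate([dens["face_dom_sample"], dens["place_dom_sample"]])
        assert abs(np.median(pooled)) < 1e-9
        assert dens["face_dom"].shape == dens["grid"].shape

    def test_dominant_eye_stimulus_scores_higher(self):
        profiles = make_profiles(10, 3, classes=("face", "place"))
        from percept.synth import ParadigmSpec

        spec = ParadigmSpec(eye_bias=0.9)
        b = percept.simulate_rivalry(profiles, 14, n_trials_per_condition=10, spec=spec)
        net = percept.net_rate(b)
        z = percept.z_normalize(net, b.units["array"].to_numpy())
        traj = percept.rivalry_probability(z, b.trials, DecoderSpec(step_ms=100), seed=0)
        cond = b.trials["condition"].to_numpy()[traj.trial_idx]
        post = traj.window_centers > 0
        face_dom = traj.probabilities[cond == "RIVAL_FACE_DOM"][:, post].mean()
        place_dom = traj.probabilities[cond == "RIVAL_PLACE_DOM"][:, post].mean()
        assert face_dom > place_dom
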