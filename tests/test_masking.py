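"""Delay grouping, bimodality test, signal loss, divergence, prestimulus AUC."""

import numpy as np
import pandas as pd
import pytest

import percept
from percept.masking import (
    FIVE_GROUPS,
    THREE_GROUPS,
    group_delays,
    silverman_bimodality,
)
from percept.session import RateMatrix
from percept.synth import ParadigmSpec, UnitProfile


def _znorm(values):
    return RateMatrix(np.asarray(values, dtype=float), "znorm", 10, -300)


class TestGroupDelays:
    def test_printed_partitions(self):
        trials = pd.DataFrame({"mask_delay": [16, 50, 83, 116, 150, 183]})
        five = group_delays(trials, "five")
        assert five.mapping[83] == 2  # group [83, 100]
        assert five.mapping[150] == 4
        three = group_delays(trials, "three")
        assert three.mapping[16] == 0  # group [16, 32, 50, 66]
        assert three.mapping[116] == 1

    def test_200ms_assigned_to_last_group(self):
        trials = pd.DataFrame({"mask_delay": [200, 16]})
        assert group_delays(trials, "five").mapping[200] == len(FIVE_GROUPS) - 1
        assert group_delays(trials, "three").mapping[200] == len(THREE_GROUPS) - 1

    def test_unknown_delay_rejected(self):
        with pytest.raises(ValueError):
            group_delays(pd.DataFrame({"mask_delay": [75]}), "five")


class TestSilvermanBimodality:
    @staticmethod
    def _traces(n, peaks, rng, amp=3.0, noise=1.0, bins=70):
        centers = -300 + (np.arange(bins) + 0.5) * 10
        out = np.zeros((n, bins))
        for pt in peaks:
            out += amp * np.exp(-0.5 * ((centers - pt) / 30.0) ** 2)
        return out + rng.normal(0, noise, out.shape)

    def test_single_bump_yields_high_p(self):
        rng = np.random.default_rng(0)
        res = silverman_bimodality(
            self._traces(30, [150], rng), -300, 10, reference_max=3.0, seed=1
        )
        assert res.p_value >= 0.95

    def test_two_bumps_yield_low_p(self):
        rng = np.random.default_rng(1)
        res = silverman_bimodality(
            self._traces(30, [120, 280], rng), -300, 10, reference_max=3.0, seed=1
        )
        assert res.p_value <= 0.05
        assert res.peak_count_hist[2] > 900

    def test_two_traces_is_error(self):
        with pytest.raises(ValueError, match="3 traces"):
            silverman_bimodality(np.zeros((2, 70)), -300, 10, 1.0)

    def test_invariant_to_trace_order_and_scaling(self):
        rng = np.random.default_rng(2)
        tr = self._traces(24, [150], rng)
        r1 = silverman_bimodality(tr, -300, 10, reference_max=3.0, seed=5)
        r2 = silverman_bimodality(tr[::-1].copy(), -300, 10, reference_max=3.0, seed=5)
        r3 = silverman_bimodality(3.0 * tr, -300, 10, reference_max=9.0, seed=5)
        # same seed: same random triples by position; scaling is relative
        assert r1.p_value == r3.p_value
        assert abs(r1.p_value - r2.p_value) < 0.1

    def test_no_peaks_gives_undefined_with_diagnostic(self):
        rng = np.random.default_rng(3)
        flat = rng.normal(0, 0.05, (9, 70))
        res = silverman_bimodality(flat, -300, 10, reference_max=5.0, seed=0)
        assert res.p_value is None and "no peaks" in res.diagnostic


class TestSelectiveUnits:
    def test_preferred_class_found_and_null_calibrated(self, masking_bundle, windows):
        net = percept.net_rate(masking_bundle)
        arrays = masking_bundle.units["array"].to_numpy()
        z = percept.z_normalize(net, arrays, windows)
        sel = percept.select_masking_selective_units(
            z,
            masking_bundle.trials,
            lambda u: windows.dprime_window(int(arrays[u])),
            seed=0,
        )
        assert len(sel) >= 6  # most units are class-preferring by design
        truth = masking_bundle.truth["profiles"]
        for u, (pref, p) in sel.items():
            amps = truth[u]["amplitudes"]
            assert pref == max(amps, key=amps.get)

    def test_exchangeable_classes_rarely_selected(self):
        prof = [
            UnitProfile(baseline=8.0, latency=100.0, amplitudes={c: 20.0 for c in "abcd"})
            for _ in range(12)
        ]
        spec = ParadigmSpec(masking_delays=(150, 166, 183))
        b = percept.simulate_masking(prof, 5, classes=tuple("abcd"), n_trials=160, spec=spec)
        net = percept.net_rate(b)
        z = percept.z_normalize(net, b.units["array"].to_numpy())
        sel = percept.select_masking_selective_units(
            z, b.trials, lambda u: (130, 280), seed=1
        )
        assert len(sel) <= 2


class TestSignalLoss:
    def test_plug_in_formula(self):
        # construct z-rates with known window activities 1.0 and 0.6
        vals = np.zeros((1, 20, 70))
        perceived = np.array([True] * 10 + [False] * 10)
        vals[0, :10, 40:55] = 1.0
        vals[0, 10:, 40:55] = 0.6
        z = _znorm(vals)
        trials = pd.DataFrame({"perceived": perceived})
        res = percept.signal_loss(z, [0], trials, (100, 250))
        assert res.loss_percent == pytest.approx(40.0)

    def test_equal_arms_zero_loss(self):
        vals = np.zeros((1, 20, 70))
        vals[0, :, 40:55] = 1.0
        z = _znorm(vals)
        trials = pd.DataFrame({"perceived": [True] * 10 + [False] * 10})
        assert percept.signal_loss(z, [0], trials, (100, 250)).loss_percent == 0.0

    def test_nonpositive_perceived_activity_flagged(self):
        vals = np.zeros((1, 10, 70))
        z = _znorm(vals)
        trials = pd.DataFrame({"perceived": [True] * 5 + [False] * 5})
        res = percept.signal_loss(z, [0], trials, (100, 250))
        assert res.flagged and res.loss_percent is None

    @pytest.mark.parametrize("loss", [0.15, 0.27, 0.45])
    def test_programmed_loss_recovered(self, loss):
        ests = []
        for seed in range(4):
            prof = [
                UnitProfile(
                    baseline=5.0,
                    latency=80.0,
                    amplitudes={"face": 50.0},
                    sustain=0.6,
                    mondrian_amp=0.0,
                    array=2,
                )
                for _ in range(10)
            ]
            spec = ParadigmSpec(masking_loss=loss, masking_delays=(83,))
            b = percept.simulate_masking(prof, seed, classes=("face",), n_trials=160, spec=spec)
            net = percept.net_rate(b)
            z = percept.z_normalize(net, b.units["array"].to_numpy())
            ests.append(
                percept.signal_loss(z, list(range(10)), b.trials, (80, 230)).loss_percent
            )
        assert abs(np.mean(ests) - 100 * loss) < 3.0


class TestDivergenceLatency:
    def test_no_modulation_undefined(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(0, 1, (4, 60, 70))
        z = _znorm(vals)
        trials = pd.DataFrame({"perceived": [True] * 30 + [False] * 30})
        res = percept.divergence_latency(z, np.arange(4), trials, seed=0)
        assert res.latency_ms is None

    def test_modulation_onset_recovered(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(0, 1, (4, 60, 70))
        onset_bin = 30 + 9  # 90 ms
        vals[:, :30, onset_bin:] += 1.5
        z = _znorm(vals)
        trials = pd.DataFrame({"perceived": [True] * 30 + [False] * 30})
        res = percept.divergence_latency(z, np.arange(4), trials, seed=0)
        assert res.latency_ms == pytest.approx(95.0, abs=10.0)

    def test_single_bin_modulation_rejected(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(0, 0.3, (4, 60, 70))
        vals[:, :30, 45] += 3.0
        z = _znorm(vals)
        trials = pd.DataFrame({"perceived": [True] * 30 + [False] * 30})
        assert percept.divergence_latency(z, np.arange(4), trials, seed=0).latency_ms is None


class TestPerceivedContrast:
    def test_empty_arm_is_error(self):
        z = _znorm(np.zeros((1, 6, 70)))
        trials = pd.DataFrame({"perceived": [True] * 6})
        with pytest.raises(ValueError):
            percept.perceived_vs_nonperceived_rate_test(z, [0], trials, (100, 250))

    def test_generated_loss_detected(self):
        prof = [
            UnitProfile(baseline=5.0, latency=80.0, amplitudes={"face": 50.0}, sustain=0.6, array=2)
            for _ in range(8)
        ]
        spec = ParadigmSpec(masking_loss=0.4, masking_delays=(83,))
        b = percept.simulate_masking(prof, 3, classes=("face",), n_trials=120, spec=spec)
        net = percept.net_rate(b)
        z = percept.z_normalize(net, b.units["array"].to_numpy())
        rep = percept.perceived_vs_nonperceived_rate_test(z, list(range(8)), b.trials, (80, 230))
        assert rep["p_value"] < 0.01
        assert rep["mean_perceived"] > rep["mean_nonperceived"]


class TestPrestimulusDecoder:
    def test_shifted_baseline_is_decodable(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(0, 1, (10, 60, 70))
        perceived = np.array([True] * 30 + [False] * 30)
        vals[:, :30, :30] += 2.0  # +2 SD baseline shift on perceived trials
        z = _znorm(vals)
        trials = pd.DataFrame({"perceived": perceived})
        auc = percept.prestimulus_awareness_decoder(z, trials, seed=0)
        assert auc > 0.9

    def test_single_trial_arm_is_error(self):
        z = _znorm(np.zeros((2, 5, 70)))
        trials = pd.DataFrame({"perceived": [True] * 4 + [False]})
        with pytest.raises(ValueError):
            percept.prestimulus_awareness_decoder(z, trials, seed=0)
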