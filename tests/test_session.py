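"""Binning, baseline subtraction, z-normalization, responsiveness screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import percept
from percept.session import RateMatrix, ResponseWindowConfig, SessionBundle


def _rate(values, kind="net", t_start=-300):
    return RateMatrix(np.asarray(values, dtype=float), kind, 10, t_start)


class TestBinSpikes:
    def test_boundary_convention_half_open(self):
        counts, _ = percept.bin_spikes([[[5.0, 9.0, 10.0]]], 0, 100)
        assert counts[0, 0, 0] == 2  # [0, 10) gets 5 and 9
        assert counts[0, 0, 1] == 1  # [10, 20) gets 10

    def test_no_events_all_zero(self):
        counts, qc = percept.bin_spikes([[[]]], -300, 700)
        assert counts.sum() == 0 and qc["n_events"] == 0

    def test_conservation_of_uniform_events(self):
        rng = np.random.default_rng(0)
        ev = rng.uniform(0, 1000, 1000)
        counts, qc = percept.bin_spikes([[ev]], 0, 1000)
        assert counts.sum() == 1000 == qc["n_events"]
        assert qc["n_dropped"] == 0

    def test_out_of_grid_events_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="dropped"):
            counts, qc = percept.bin_spikes([[[-400.0, 50.0, 900.0]]], -300, 700)
        assert qc["n_dropped"] == 2 and counts.sum() == 1

    @given(shift=st.integers(min_value=1, max_value=5))
    @settings(max_examples=10, deadline=None)
    def test_shifting_events_shifts_counts_one_bin(self, shift):
        ev = np.array([3.0, 47.0, 151.0, 222.0])
        c0, _ = percept.bin_spikes([[ev]], 0, 400)
        c1, _ = percept.bin_spikes([[ev + 10 * shift]], 0, 400)
        assert np.array_equal(c0[0, 0, : 40 - shift], c1[0, 0, shift:])

    def test_bad_grid_rejected(self):
        with pytest.raises(ValueError, match="divide"):
            percept.bin_spikes([[[1.0]]], 0, 105)


class TestNetRate:
    def test_constant_rate_gives_zero_net(self):
        units = pd.DataFrame({"id": ["u0"], "array": [2], "kind": ["SUA"]})
        trials = pd.DataFrame({"paradigm": ["localizer"], "condition": ["x"]})
        spikes = np.full((1, 1, 60), 1)  # 100 sp/s everywhere
        b = SessionBundle(units, trials, spikes)
        net = percept.net_rate(b)
        assert np.allclose(net.values, 0.0)

    def test_baseline_and_response_levels(self):
        units = pd.DataFrame({"id": ["u0"], "array": [2], "kind": ["SUA"]})
        trials = pd.DataFrame({"paradigm": ["localizer"], "condition": ["x"]})
        spikes = np.zeros((1, 1, 60), dtype=int)
        spikes[0, 0, :30] = 1  # baseline 100 sp/s
        spikes[0, 0, 30:] = 4  # response 400 sp/s
        b = SessionBundle(units, trials, spikes)
        net = percept.net_rate(b)
        assert np.allclose(net.values[0, 0, 30:], 300.0)

    def test_baseline_mean_exactly_zero_per_trial(self, localizer_bundle):
        net = percept.net_rate(localizer_bundle)
        base = net.window_bins(-300, 0)
        assert np.abs(net.values[:, :, base].mean(axis=2)).max() < 1e-10

    def test_missing_baseline_is_hard_error(self):
        units = pd.DataFrame({"id": ["u0"], "array": [2], "kind": ["SUA"]})
        trials = pd.DataFrame({"paradigm": ["localizer"], "condition": ["x"]})
        with pytest.raises(ValueError):
            SessionBundle(units, trials, np.zeros((1, 1, 10), dtype=int), t_start=-100)


class TestZNormalize:
    def test_hand_computed_window_zscores(self):
        # single trial, three window bins {0, 2, 4}: population SD 1.633
        vals = np.zeros((1, 1, 33))
        vals[0, 0, 30:33] = [0.0, 2.0, 4.0]
        net = _rate(vals)
        win = ResponseWindowConfig(dprime_windows={2: (0, 30)})
        z = percept.z_normalize(net, [2], win)
        expected = np.array([-1.0, 0.0, 1.0]) * (2.0 / np.std([0, 2, 4]))
        assert np.allclose(z.values[0, 0, 30:33], expected, atol=1e-12)
        assert np.allclose(z.values[0, 0, 30:33], [-1.2247, 0.0, 1.2247], atol=1e-3)

    def test_constant_input_flagged_degenerate(self):
        vals = np.full((1, 2, 40), 7.0)
        net = _rate(vals)
        win = ResponseWindowConfig(dprime_windows={2: (0, 100)})
        z = percept.z_normalize(net, [2], win)
        assert 0 in z.degenerate_units
        assert np.allclose(z.values, 0.0)

    def test_window_mean_zero_across_all_conditions(self, localizer_rates, windows):
        _, z = localizer_rates
        for u in range(z.values.shape[0]):
            lo, hi = windows.dprime_window(3)
            idx = z.window_bins(lo, hi)
            assert abs(z.values[u][:, idx].mean()) < 1e-10

    def test_requires_net_rates(self, localizer_bundle):
        with pytest.raises(ValueError, match="net"):
            percept.z_normalize(localizer_bundle.raw_rate(), [2] * 4)


class TestScreenResponsive:
    def test_pure_noise_units_rarely_fire(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(0, 1, (30, 40, 70))
        vals -= vals[:, :, :30].mean(axis=2, keepdims=True)
        net = _rate(vals)
        trials = pd.DataFrame({"condition": ["a"] * 20 + ["b"] * 20})
        responsive, _ = percept.screen_responsive(net, trials)
        # 8 tests per unit at alpha 0.005: expected family rate ~4%
        assert len(responsive) <= 4

    def test_strong_sustained_response_detected(self, localizer_rates):
        net, _ = localizer_rates
        trials_df = pd.DataFrame(
            {"condition": ["nonscrambled"] * 40 + ["scrambled"] * 40}
        )
        # use actual bundle trials instead
        responsive, prov = percept.screen_responsive(
            net, trials_df.iloc[: net.values.shape[1]]
        )
        assert responsive == set(range(net.values.shape[0]))
        assert all(len(prov[u]) >= 1 for u in responsive)

    def test_single_condition_responder_found(self):
        rng = np.random.default_rng(9)
        vals = rng.normal(0, 1, (1, 100, 70))
        cond = np.array(["c%d" % (i % 10) for i in range(100)])
        vals[0, cond == "c3", 40:66] += 8.0  # only one of 10 conditions responds
        vals -= vals[:, :, :30].mean(axis=2, keepdims=True)
        net = _rate(vals)
        responsive, prov = percept.screen_responsive(net, pd.DataFrame({"condition": cond}))
        assert responsive == {0}
        assert any(c == "c3" for c, _, _ in prov[0])

    def test_small_condition_skipped_with_warning(self):
        vals = np.zeros((1, 3, 70))
        net = _rate(vals)
        trials = pd.DataFrame({"condition": ["a", "a", "b"]})
        with pytest.warns(UserWarning, match="<2 trials"):
            percept.screen_responsive(net, trials)


class TestBundleIO:
    def test_roundtrip_with_truth_sidecar(self, tmp_path, masking_bundle):
        p = str(tmp_path / "b.h5")
        percept.save_bundle(masking_bundle, p)
        loaded = percept.load_bundle(p)
        assert np.array_equal(loaded.spikes, masking_bundle.spikes)
        assert list(loaded.trials.columns) == list(masking_bundle.trials.columns)
        assert loaded.truth is not None
        assert (tmp_path / "b.truth.json").exists()

    def test_validate_bundle_passes_and_flags(self, masking_bundle):
        rep = percept.validate_bundle(masking_bundle)
        assert rep["ok"]
        bad = masking_bundle.trials.copy()
        bad.loc[0, "mask_delay"] = 77
        broken = SessionBundle(
            masking_bundle.units, bad, masking_bundle.spikes
        )
        rep2 = percept.validate_bundle(broken)
        assert not rep2["ok"] and any("delay" in v for v in rep2["violations"])
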