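"""Synthetic session generator for the awareness paradigms.

Emulates the phenomenology the analyses are built for, with known ground
truth so every downstream estimator can be validated by parameter
recovery:

* inhomogeneous-Poisson spiking with convex-onset transients that plateau
  at a unit-specific sustain fraction,
* per-array response latencies in the 65-255 ms range and class-selective
  amplitudes,
* backward masking under the interruption model (the target's selective
  drive is cut when the Mondrian arrives) with a logistic psychometric
  P(perceived | delay) and a percept-loss factor applied only after
  stimulus onset,
* flash suppression with a graded percept gain g < 1 (perceptual shifts
  drive weaker responses than real alternation) and a suppression
  residual r for the physically present but unseen stimulus,
* binocular rivalry with gamma-distributed dominance durations, an
  eye-dominance bias on the first percept, and firing-rate switches that
  precede the recorded button press by a programmed lead time,
* b-CFS breakage latencies (lognormal per eye, censored at 10 s),
* LFP as 1/f background plus stimulus-gated 60-120 Hz gamma.

Identical seeds reproduce identical bundles bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .session import (
    BIN_WIDTH_MS,
    MASKING_DELAYS,
    SessionBundle,
)

CATEGORY_CLASSES = ("face", "body", "object", "fruit")


@dataclass
class UnitProfile:
    """Ground-truth firing model of one unit.

    Instantaneous rate is ``baseline + sum of stimulus drives``; each drive
    is ``A_c * kernel(t - onset - latency)`` where the kernel rises
    convexly to peak 1 at ``tau_rise``, settles onto the sustain fraction
    ``s`` while the stimulus is on, and decays with ``tau_decay`` after
    offset or interruption.
    """

    baseline: float = 5.0  # sp/s
    latency: float = 100.0  # ms
    amplitudes: Mapping[str, float] = field(default_factory=dict)  # sp/s
    sustain: float = 0.5  # fraction of A maintained while stimulus on
    percept_gain: float = 0.6  # g: FS/percept-driven response vs real alternation
    suppression_residual: float = 0.1  # r: suppressed-but-present stimulus
    mondrian_amp: float = 0.0  # response to the masking Mondrian, sp/s
    array: int = 2
    tau_rise: float = 30.0  # ms
    tau_decay: float = 60.0  # ms

    def amp(self, cls: str) -> float:
        return float(self.amplitudes.get(cls, 0.0))


@dataclass
class ParadigmSpec:
    """Timing and behavioural parameters of the simulated paradigms."""

    masking_delays: Sequence[int] = MASKING_DELAYS
    target_duration: float = 16.0  # ms
    mask_duration: float = 250.0  # ms
    psychometric_d50: float = 83.0  # delay of 50% perceived, ms
    psychometric_slope: float = 25.0  # ms
    masking_loss: float = 0.4  # fractional response loss when not perceived
    localizer_duration: float = 300.0  # ms
    fs_phase1: float = 1000.0  # ms
    fs_phase2: float = 400.0  # ms
    rivalry_duration_s: float = 10.0
    dominance_mean_ms: float = 2000.0
    dominance_gamma_shape: float = 3.0
    percept_lead_ms: float = 1500.0  # rate change precedes button press
    motor_jitter_sd_ms: float = 150.0
    eye_bias: float = 0.75  # P(first percept = dominant-eye stimulus)
    bcfs_median_s: tuple[float, float] = (5.0, 3.0)  # (left, right)
    bcfs_sigma: float = 0.4
    bcfs_censor_s: float = 10.0


# ---------------------------------------------------------------------------
# rate construction

# Convex onset profile of the transient (fractions of peak at fractions of
# the rise time). Cortical visual onsets are expansive: the rate roughly
# triples across successive 10 ms bins before saturating, which is also
# what run-based latency criteria are designed around.
_RISE_T = np.array([0.0, 5.0, 15.0, 25.0, 30.0]) / 30.0
_RISE_V = np.array([0.0, 0.15, 0.35, 0.8, 1.0])


def _rise(tau: np.ndarray, tau_rise: float) -> np.ndarray:
    """Convex onset: fraction of peak reached at time tau into the rise."""
    return np.interp(np.asarray(tau, dtype=float) / tau_rise, _RISE_T, _RISE_V)


def _drive(
    t: np.ndarray,
    onset: float,
    off: float,
    profile: UnitProfile,
    fresh: bool = True,
    truncate_at: float | None = None,
) -> np.ndarray:
    """Unit-amplitude envelope of one stimulus epoch at times ``t`` (ms).

    ``fresh`` epochs rise to the transient peak, settle onto the sustained
    plateau while the stimulus is on, and decay after offset; continuation
    epochs (a stimulus already on screen, e.g. the suppressed-stimulus
    residual) carry only the sustained plateau. A transient always
    completes its rise even if the stimulus is briefer than the rise time
    (a response outlasts a 16 ms flash). ``truncate_at`` cuts the drive
    (interruption) with the decay time constant.
    """
    tau = t - onset - profile.latency
    on_dur = off - onset
    tr = profile.tau_rise
    s = profile.sustain
    t_off_eff = max(on_dur, tr)  # the transient completes even for a flash
    if fresh:
        settle = s + (1.0 - s) * np.exp(-(tau - tr) / (2.0 * tr))
        level_off = (
            1.0
            if on_dur <= tr
            else s + (1.0 - s) * np.exp(-(on_dur - tr) / (2.0 * tr))
        )
        env = np.where(
            tau <= tr,
            _rise(np.clip(tau, 0.0, None), tr),
            np.where(
                tau <= t_off_eff,
                settle,
                level_off * np.exp(-(tau - t_off_eff) / profile.tau_decay),
            ),
        )
        env = np.where(tau > 0, env, 0.0)
    else:
        env = np.where(
            tau <= on_dur,
            np.where(tau > 0, s, 0.0),
            s * np.exp(-(tau - on_dur) / profile.tau_decay),
        )
    if truncate_at is not None:
        # interruption reaches cortex one response latency after the event
        cut = t - (truncate_at + profile.latency)
        after = cut > 0
        if np.any(after):
            at = np.interp(truncate_at + profile.latency, t, env) if t.size > 1 else 0.0
            env = np.where(after, at * np.exp(-cut / profile.tau_decay), env)
    return env


def _poisson_counts(
    rate: np.ndarray, rng: np.random.Generator, bin_width: float = BIN_WIDTH_MS
) -> np.ndarray:
    lam = np.clip(rate, 0.0, None) * (bin_width / 1000.0)
    return rng.poisson(lam)


def _grid(t_start: float, t_stop: float) -> np.ndarray:
    n = int(round((t_stop - t_start) / BIN_WIDTH_MS))
    return t_start + (np.arange(n) + 0.5) * BIN_WIDTH_MS  # bin centers


def make_profiles(
    n_units: int,
    seed: int,
    classes: Sequence[str] = CATEGORY_CLASSES,
    arrays: Sequence[int] = (2, 3, 4, 5),
    amp_range: tuple[float, float] = (20.0, 50.0),
    selectivity: float = 0.75,
    sustain_range: tuple[float, float] = (0.3, 0.8),
    percept_gain: float = 0.6,
    suppression_residual: float = 0.1,
    mondrian_frac: float = 0.5,
    noise_fraction: float = 0.0,
) -> list[UnitProfile]:
    """Draw a heterogeneous population of unit profiles.

    Each unit prefers one class (amplitude from ``amp_range``) and responds
    to the others at ``(1 - selectivity)`` of that amplitude. A
    ``noise_fraction`` of units is purely baseline-driven (zero amplitude
    to every class) — useful for testing decoder sparsity.
    """
    rng = np.random.default_rng(seed)
    array_latency = {1: 65.0, 2: 85.0, 3: 135.0, 4: 255.0, 5: 135.0}
    profiles = []
    n_noise = int(round(noise_fraction * n_units))
    for u in range(n_units):
        arr = int(rng.choice(arrays))
        pref = str(rng.choice(classes))
        a_pref = rng.uniform(*amp_range)
        amps = {
            c: a_pref if c == pref else a_pref * (1.0 - selectivity)
            for c in classes
        }
        if u < n_noise:
            amps = {c: 0.0 for c in classes}
        profiles.append(
            UnitProfile(
                baseline=rng.uniform(2.0, 10.0),
                latency=array_latency[arr] + rng.normal(0.0, 5.0),
                amplitudes=amps,
                sustain=rng.uniform(*sustain_range),
                percept_gain=percept_gain,
                suppression_residual=suppression_residual,
                mondrian_amp=(
                    rng.uniform(10.0, 30.0) if rng.random() < mondrian_frac else 0.0
                ),
                array=arr,
            )
        )
    return profiles


def _units_frame(profiles: Sequence[UnitProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [f"u{i:03d}" for i in range(len(profiles))],
            "array": [p.array for p in profiles],
            "kind": ["SUA"] * len(profiles),
        }
    )


def _truth(profiles, spec, extra=None) -> dict:
    d = {
        "profiles": [
            {**asdict(p), "amplitudes": dict(p.amplitudes)} for p in profiles
        ],
        "spec": {
            k: (list(v) if isinstance(v, (tuple, list)) else v)
            for k, v in asdict(spec).items()
        },
    }
    if extra:
        d.update(extra)
    return d


# ---------------------------------------------------------------------------
# paradigms

def simulate_localizer(
    profiles: Sequence[UnitProfile],
    seed: int,
    classes: Sequence[str] = ("scrambled", "nonscrambled"),
    n_trials_per_class: int = 30,
    spec: ParadigmSpec | None = None,
    t_stop: float = 600.0,
) -> SessionBundle:
    """Passive viewing of images presented for 300 ms."""
    if not profiles:
        raise ValueError("need at least one unit profile")
    spec = spec or ParadigmSpec()
    rng = np.random.default_rng(seed)
    t = _grid(-300.0, t_stop)
    conds = [c for c in classes for _ in range(n_trials_per_class)]
    rng.shuffle(conds)
    spikes = np.empty((len(profiles), len(conds), t.size), dtype=np.int64)
    for i, p in enumerate(profiles):
        for j, c in enumerate(conds):
            rate = p.baseline + p.amp(c) * _drive(
                t, 0.0, spec.localizer_duration, p
            )
            spikes[i, j] = _poisson_counts(rate, rng)
    trials = pd.DataFrame(
        {"paradigm": "localizer", "condition": conds, "stimulus_class": conds}
    )
    return SessionBundle(
        _units_frame(profiles), trials, spikes, truth=_truth(profiles, spec)
    )


def simulate_masking(
    profiles: Sequence[UnitProfile],
    seed: int,
    classes: Sequence[str] = CATEGORY_CLASSES,
    n_trials: int = 288,
    spec: ParadigmSpec | None = None,
    t_stop: float = 700.0,
) -> SessionBundle:
    """Backward masking: 16 ms target, variable delay, 250 ms Mondrian.

    Perceived labels are Bernoulli draws from a logistic psychometric in
    delay. On nonperceived trials the target's class-selective drive is
    scaled by ``1 - masking_loss`` — only after stimulus onset, so the
    fixation baseline is identically distributed across the two arms.
    Under the interruption model the target drive is cut at mask arrival.
    """
    spec = spec or ParadigmSpec()
    rng = np.random.default_rng(seed)
    delays = np.array(spec.masking_delays)
    t = _grid(-300.0, t_stop)
    delay_per_trial = rng.choice(delays, size=n_trials)
    class_per_trial = rng.choice(list(classes), size=n_trials)
    p_perc = 1.0 / (
        1.0 + np.exp(-(delay_per_trial - spec.psychometric_d50) / spec.psychometric_slope)
    )
    perceived = rng.random(n_trials) < p_perc
    spikes = np.empty((len(profiles), n_trials, t.size), dtype=np.int64)
    for i, p in enumerate(profiles):
        for j in range(n_trials):
            d = float(delay_per_trial[j])
            scale = 1.0 if perceived[j] else (1.0 - spec.masking_loss)
            target = p.amp(str(class_per_trial[j])) * scale * _drive(
                t, 0.0, spec.target_duration, p, truncate_at=d
            )
            mask = p.mondrian_amp * _drive(t, d, d + spec.mask_duration, p)
            spikes[i, j] = _poisson_counts(p.baseline + target + mask, rng)
    trials = pd.DataFrame(
        {
            "paradigm": "masking",
            "condition": class_per_trial,
            "stimulus_class": class_per_trial,
            "mask_delay": delay_per_trial,
            "perceived": perceived,
        }
    )
    return SessionBundle(
        _units_frame(profiles), trials, spikes, truth=_truth(profiles, spec)
    )


_FS_CONDITIONS = ("FS_FP", "FS_PF", "RA_FP", "RA_PF", "CON_F", "CON_P")


def _fs_epochs(cond: str, p: UnitProfile, spec: ParadigmSpec):
    """(class, amplitude scale, on, off, fresh, truncate) epochs per condition."""
    t1, t2 = spec.fs_phase1, spec.fs_phase1 + spec.fs_phase2
    g, r = p.percept_gain, p.suppression_residual
    if cond == "CON_F":
        return [("face", 1.0, 0.0, t2, True, None)]
    if cond == "CON_P":
        return [("place", 1.0, 0.0, t2, True, None)]
    if cond == "RA_FP":
        return [("face", 1.0, 0.0, t1, True, t1), ("place", 1.0, t1, t2, True, None)]
    if cond == "RA_PF":
        return [("place", 1.0, 0.0, t1, True, t1), ("face", 1.0, t1, t2, True, None)]
    if cond == "FS_FP":
        # face physically continues but is suppressed: a fraction r of its
        # drive survives (continues uninterrupted), the rest is cut at the
        # suppression onset; the newly perceived place drives at gain g.
        return [
            ("face", 1.0 - r, 0.0, t1, True, t1),
            ("face", r, 0.0, t2, True, None),
            ("place", g, t1, t2, True, None),
        ]
    if cond == "FS_PF":
        return [
            ("place", 1.0 - r, 0.0, t1, True, t1),
            ("place", r, 0.0, t2, True, None),
            ("face", g, t1, t2, True, None),
        ]
    raise ValueError(f"unknown flash-suppression condition {cond!r}")


def simulate_flash_suppression(
    profiles: Sequence[UnitProfile],
    seed: int,
    n_trials_per_condition: int = 30,
    spec: ParadigmSpec | None = None,
) -> SessionBundle:
    """Flash suppression: 1000 ms monocular phase 1, 400 ms dichoptic phase 2.

    Phase-2 drives follow the percept: real alternation (RA) at full
    amplitude, flash suppression (FS) at ``percept_gain`` for the newly
    perceived stimulus plus ``suppression_residual`` for the suppressed
    one, continuation (CON) unchanged.
    """
    spec = spec or ParadigmSpec()
    rng = np.random.default_rng(seed)
    t = _grid(-300.0, spec.fs_phase1 + spec.fs_phase2)
    conds = [c for c in _FS_CONDITIONS for _ in range(n_trials_per_condition)]
    rng.shuffle(conds)
    spikes = np.empty((len(profiles), len(conds), t.size), dtype=np.int64)
    for i, p in enumerate(profiles):
        env_cache: dict[str, np.ndarray] = {}
        for cond in _FS_CONDITIONS:
            rate = np.full(t.size, p.baseline)
            for cls, scale, on, off, fresh, trunc in _fs_epochs(cond, p, spec):
                rate = rate + p.amp(cls) * scale * _drive(
                    t, on, off, p, fresh=fresh, truncate_at=trunc
                )
            env_cache[cond] = rate
        for j, cond in enumerate(conds):
            spikes[i, j] = _poisson_counts(env_cache[cond], rng)
    phase1 = {
        "FS_FP": "face", "RA_FP": "face", "CON_F": "face",
        "FS_PF": "place", "RA_PF": "place", "CON_P": "place",
    }
    phase2 = {  # the percept after the phase-2 event
        "FS_FP": "place", "RA_FP": "place", "CON_F": "face",
        "FS_PF": "face", "RA_PF": "face", "CON_P": "place",
    }
    trials = pd.DataFrame(
        {
            "paradigm": "flash_suppression",
            "condition": conds,
            "stimulus_class": [phase1[c] for c in conds],
            "phase1_class": [phase1[c] for c in conds],
            "phase2_percept": [phase2[c] for c in conds],
        }
    )
    return SessionBundle(
        _units_frame(profiles), trials, spikes, truth=_truth(profiles, spec)
    )


_RIVALRY_CONDITIONS = (
    "FACE_BINOC",
    "PLACE_BINOC",
    "ALTERNATE_1HZ",
    "RIVAL_FACE_DOM",
    "RIVAL_PLACE_DOM",
)


def _percept_path(
    cond: str, dur_ms: float, spec: ParadigmSpec, rng: np.random.Generator
) -> list[tuple[float, str]]:
    """(switch time, percept) list; first entry at t=0."""
    if cond == "FACE_BINOC":
        return [(0.0, "face")]
    if cond == "PLACE_BINOC":
        return [(0.0, "place")]
    if cond == "ALTERNATE_1HZ":
        k = int(np.ceil(dur_ms / 1000.0))
        start = "face" if rng.random() < 0.5 else "place"
        other = "place" if start == "face" else "face"
        return [(1000.0 * i, start if i % 2 == 0 else other) for i in range(k)]
    dom = "face" if cond == "RIVAL_FACE_DOM" else "place"
    nondom = "place" if dom == "face" else "face"
    first = dom if rng.random() < spec.eye_bias else nondom
    path = [(0.0, first)]
    t = 0.0
    cur = first
    shape = spec.dominance_gamma_shape
    scale = spec.dominance_mean_ms / shape
    while True:
        t += rng.gamma(shape, scale)
        if t >= dur_ms:
            break
        cur = "place" if cur == "face" else "face"
        path.append((t, cur))
    return path


def simulate_rivalry(
    profiles: Sequence[UnitProfile],
    seed: int,
    n_trials_per_condition: int = 12,
    spec: ParadigmSpec | None = None,
) -> SessionBundle:
    """Binocular rivalry plus the non-rivalrous control conditions.

    On rivalrous trials a hidden percept path alternates with
    gamma-distributed dominance durations; the first percept matches the
    dominant-eye stimulus with probability ``eye_bias``. Unit rates follow
    the percept from each hidden switch; the button press is recorded
    ``percept_lead_ms`` later plus Gaussian motor jitter, so neural
    divergence precedes the report by the programmed lead.
    """
    spec = spec or ParadigmSpec()
    rng = np.random.default_rng(seed)
    dur = spec.rivalry_duration_s * 1000.0
    if dur < 2 * spec.dominance_mean_ms:
        raise ValueError("trial duration must allow >= 2 dominance epochs")
    t = _grid(-300.0, dur)
    conds = [c for c in _RIVALRY_CONDITIONS for _ in range(n_trials_per_condition)]
    rng.shuffle(conds)
    n_trials = len(conds)
    paths = [_percept_path(c, dur, spec, rng) for c in conds]
    reports: list[list] = []
    for cond, path in zip(conds, paths):
        ev = []
        if cond in ("RIVAL_FACE_DOM", "RIVAL_PLACE_DOM"):
            for st, percept in path:
                press = st + spec.percept_lead_ms + rng.normal(
                    0.0, spec.motor_jitter_sd_ms
                )
                if 0.0 <= press < dur:
                    ev.append([round(press, 1), percept])
        reports.append(ev)
    spikes = np.empty((len(profiles), n_trials, t.size), dtype=np.int64)
    for i, p in enumerate(profiles):
        for j, path in enumerate(paths):
            rate = np.full(t.size, p.baseline)
            for k, (st, percept) in enumerate(path):
                off = path[k + 1][0] if k + 1 < len(path) else dur
                rate = rate + p.amp(percept) * _drive(
                    t, st, off, p, fresh=True, truncate_at=off if off < dur else None
                )
            spikes[i, j] = _poisson_counts(rate, rng)
    # the display schedule is known metadata for non-rivalrous conditions
    # (used as decoder training labels); hidden for rivalrous trials
    display = [
        json.dumps([[round(s, 1), c] for s, c in path])
        if cond in ("FACE_BINOC", "PLACE_BINOC", "ALTERNATE_1HZ")
        else ""
        for cond, path in zip(conds, paths)
    ]
    trials = pd.DataFrame(
        {
            "paradigm": "rivalry",
            "condition": conds,
            "first_percept": [p[0][1] for p in paths],
            "reports": [json.dumps(r) for r in reports],
            "display_path": display,
        }
    )
    truth = _truth(
        profiles,
        spec,
        {"percept_paths": [[[round(s, 1), c] for s, c in p] for p in paths]},
    )
    return SessionBundle(_units_frame(profiles), trials, spikes, truth=truth)


def simulate_bcfs(
    seed: int,
    n_trials_per_eye: int = 40,
    spec: ParadigmSpec | None = None,
) -> SessionBundle:
    """b-CFS eye-dominance session (behaviour only, no spiking units).

    Breakage latencies are lognormal per eye with the spec's medians;
    trials exceeding the 10 s contrast ramp are censored at 10 s.
    """
    spec = spec or ParadigmSpec()
    rng = np.random.default_rng(seed)
    rows = []
    for eye, median in zip(("left", "right"), spec.bcfs_median_s):
        lat = rng.lognormal(np.log(median), spec.bcfs_sigma, n_trials_per_eye)
        for x in lat:
            censored = x >= spec.bcfs_censor_s
            rows.append(
                {
                    "paradigm": "bcfs",
                    "condition": f"arrow_{eye}",
                    "arrow_eye": eye,
                    "breakage_latency_s": min(float(x), spec.bcfs_censor_s),
                    "censored": censored,
                }
            )
    rng.shuffle(rows)
    trials = pd.DataFrame(rows)
    spikes = np.zeros((0, len(trials), 30), dtype=np.int64)
    units = pd.DataFrame({"id": [], "array": [], "kind": []})
    return SessionBundle(
        units, trials, spikes, truth=_truth([], spec)
    )


def simulate_lfp(
    seed: int,
    n_channels: int = 4,
    n_trials: int = 30,
    t_start: float = -300.0,
    t_stop: float = 1400.0,
    fs: float = 1000.0,
    gamma_gain: float = 1.0,
    gamma_band: tuple[float, float] = (60.0, 120.0),
    stim_duration: float = 1000.0,
    envelope: np.ndarray | None = None,
) -> tuple[np.ndarray, float, float, dict]:
    """1/f background plus stimulus-gated gamma-band oscillation.

    The gamma component is narrowband noise (60-120 Hz) whose amplitude
    envelope rises at stimulus onset and stays up for ``stim_duration``
    (sustained drive), unless an explicit ``envelope`` (per sample, in
    [0, 1]) is given.

    Returns ``(traces, fs, t_start, truth)`` with traces shaped
    (channels, trials, samples).
    """
    from scipy import signal as sps

    rng = np.random.default_rng(seed)
    n = int(round((t_stop - t_start) * fs / 1000.0))
    tt = t_start + np.arange(n) * 1000.0 / fs
    if envelope is None:
        ramp = 30.0  # ms rise/fall
        envelope = np.clip((tt - 0.0) / ramp, 0.0, 1.0) * np.clip(
            (stim_duration - tt) / ramp + 1.0, 0.0, 1.0
        )
        envelope = np.where((tt > 0) & (tt < stim_duration + ramp), envelope, 0.0)
    sos = sps.butter(4, gamma_band, btype="bandpass", fs=fs, output="sos")
    traces = np.empty((n_channels, n_trials, n), dtype=float)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.where(freqs > 0, 1.0 / np.sqrt(np.maximum(freqs, 1.0)), 0.0)
    for c in range(n_channels):
        for j in range(n_trials):
            white = rng.standard_normal(n)
            pink = np.fft.irfft(np.fft.rfft(white) * shaping, n)
            pink *= 20.0 / max(pink.std(), 1e-12)
            gamma = sps.sosfiltfilt(sos, rng.standard_normal(n))
            gamma *= 10.0 / max(gamma.std(), 1e-12)
            traces[c, j] = pink + gamma_gain * envelope * gamma
    truth = {
        "gamma_gain": gamma_gain,
        "gamma_band": list(gamma_band),
        "stim_duration": stim_duration,
        "envelope": envelope.tolist(),
    }
    return traces, fs, t_start, truth
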