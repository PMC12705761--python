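"""Session data model: binned spike counts, trial metadata, rate normalization.

All analyses in this package operate on a :class:`SessionBundle` — spike
counts per (unit, trial, 10 ms bin) on a common grid with stimulus onset at
t = 0 ms and a 300 ms pre-stimulus fixation baseline — plus a per-trial
metadata table and optional LFP traces.

Rates come in three kinds:

``raw``
    spikes/s straight from the counts.
``net``
    raw minus the per-trial mean rate over the 300 ms baseline, so the
    baseline mean of every trial is exactly zero.
``znorm``
    net rates standardized per unit by the mean and standard deviation of
    the net rate over all trials within that unit's response window, so the
    window mean across all trials/conditions is exactly zero per unit.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

BIN_WIDTH_MS = 10
BASELINE_MS = 300

#: Per-array response windows (ms after onset) used for d-prime and most
#: window-mean statistics; spans the fastest selectivity latency + 150 ms.
ARRAY_DPRIME_WINDOWS: dict[int, tuple[int, int]] = {
    1: (100, 250),
    2: (130, 280),
    3: (130, 280),
    4: (200, 350),
    5: (140, 290),
}

#: Per-array windows (response latency + 150 ms) used for the signal-loss
#: metric, which deliberately starts earlier than selectivity.
ARRAY_SIGNAL_LOSS_WINDOWS: dict[int, tuple[int, int]] = {
    1: (60, 210),
    2: (80, 230),
    3: (130, 280),
    4: (200, 350),
    5: (130, 280),
}

#: The four 100 ms screens used for visual-responsiveness testing.
SCREEN_WINDOWS: tuple[tuple[int, int], ...] = (
    (100, 200),
    (150, 250),
    (200, 300),
    (250, 350),
)

MASKING_DELAYS = (16, 32, 50, 66, 83, 100, 116, 132, 150, 166, 183, 200)

CONDITION_VOCABULARY = {
    "masking_category": ("face", "body", "object", "fruit"),
    "masking_scrambled": ("scrambled", "nonscrambled"),
    "flash_suppression": ("FS_FP", "FS_PF", "RA_FP", "RA_PF", "CON_F", "CON_P"),
    "rivalry": (
        "FACE_BINOC",
        "PLACE_BINOC",
        "ALTERNATE_1HZ",
        "RIVAL_FACE_DOM",
        "RIVAL_PLACE_DOM",
    ),
}


@dataclass
class ResponseWindowConfig:
    """Per-array analysis windows in ms after stimulus onset."""

    dprime_windows: dict[int, tuple[int, int]] = field(
        default_factory=lambda: dict(ARRAY_DPRIME_WINDOWS)
    )
    signal_loss_windows: dict[int, tuple[int, int]] = field(
        default_factory=lambda: dict(ARRAY_SIGNAL_LOSS_WINDOWS)
    )
    screen_windows: tuple[tuple[int, int], ...] = SCREEN_WINDOWS

    def dprime_window(self, array: int) -> tuple[int, int]:
        return self.dprime_windows[array]

    def signal_loss_window(self, array: int) -> tuple[int, int]:
        return self.signal_loss_windows[array]


@dataclass
class SessionBundle:
    """One recording session: units x trials x 10 ms bins plus metadata.

    Parameters
    ----------
    units
        DataFrame with columns ``id``, ``array`` (int), ``kind``
        (``"SUA"`` or ``"MUA"``).
    trials
        Per-trial metadata. Always has ``paradigm`` and ``condition``;
        paradigm-specific columns include ``mask_delay``, ``perceived``,
        ``dominant_eye_stimulus``, ``arrow_eye``, ``breakage_latency_s``,
        ``censored`` and (rivalry) JSON-encoded ``reports``.
    spikes
        Integer counts, shape (n_units, n_trials, n_bins).
    t_start
        Time of the left edge of bin 0 in ms (default -300).
    lfp
        Optional traces, shape (n_channels, n_trials, n_samples).
    """

    units: pd.DataFrame
    trials: pd.DataFrame
    spikes: np.ndarray
    bin_width: int = BIN_WIDTH_MS
    t_start: int = -BASELINE_MS
    lfp: np.ndarray | None = None
    lfp_fs: float | None = None
    lfp_t_start: float | None = None
    truth: dict | None = None

    def __post_init__(self) -> None:
        self.spikes = np.asarray(self.spikes)
        if self.spikes.ndim != 3:
            raise ValueError("spikes must be (units, trials, bins)")
        if len(self.units) != self.spikes.shape[0]:
            raise ValueError("unit table does not match spike tensor")
        if len(self.trials) != self.spikes.shape[1]:
            raise ValueError("trial table does not match spike tensor")
        if self.t_start > -BASELINE_MS:
            raise ValueError("grid must cover the 300 ms fixation baseline")
        if np.any(self.spikes < 0):
            raise ValueError("spike counts must be non-negative")

    @property
    def n_units(self) -> int:
        return self.spikes.shape[0]

    @property
    def n_trials(self) -> int:
        return self.spikes.shape[1]

    @property
    def n_bins(self) -> int:
        return self.spikes.shape[2]

    @property
    def bin_starts(self) -> np.ndarray:
        """Left edges of the bins in ms relative to stimulus onset."""
        return self.t_start + np.arange(self.n_bins) * self.bin_width

    @property
    def bin_centers(self) -> np.ndarray:
        return self.bin_starts + self.bin_width / 2.0

    @property
    def onset_bin(self) -> int:
        return int(-self.t_start // self.bin_width)

    def raw_rate(self) -> "RateMatrix":
        """Counts converted to spikes/s."""
        values = self.spikes * (1000.0 / self.bin_width)
        return RateMatrix(values, "raw", self.bin_width, self.t_start)


@dataclass
class RateMatrix:
    """Firing rates (spikes/s) per (unit, trial, bin) on the session grid."""

    values: np.ndarray
    kind: str  # raw | net | znorm
    bin_width: int = BIN_WIDTH_MS
    t_start: int = -BASELINE_MS
    degenerate_units: frozenset = frozenset()

    @property
    def n_bins(self) -> int:
        return self.values.shape[2]

    @property
    def bin_starts(self) -> np.ndarray:
        return self.t_start + np.arange(self.n_bins) * self.bin_width

    @property
    def bin_centers(self) -> np.ndarray:
        return self.bin_starts + self.bin_width / 2.0

    def window_bins(self, start_ms: float, end_ms: float) -> np.ndarray:
        """Indices of bins whose full [t, t+width) extent lies in [start, end)."""
        starts = self.bin_starts
        mask = (starts >= start_ms) & (starts + self.bin_width <= end_ms)
        return np.flatnonzero(mask)

    def window_mean(self, start_ms: float, end_ms: float) -> np.ndarray:
        """Per (unit, trial) mean rate over a window; shape (units, trials)."""
        idx = self.window_bins(start_ms, end_ms)
        if idx.size == 0:
            raise ValueError(f"window [{start_ms}, {end_ms}) contains no bins")
        return self.values[:, :, idx].mean(axis=2)


def bin_spikes(
    event_times: Sequence[Sequence[Sequence[float]]],
    t_start: float,
    t_stop: float,
    bin_width: int = BIN_WIDTH_MS,
) -> tuple[np.ndarray, dict]:
    """Bin spike event times (ms, onset at 0) into half-open 10 ms bins.

    ``event_times[u][t]`` holds the event times for unit ``u`` in trial
    ``t``. Bin ``b`` counts events with ``t_start + b*w <= x < t_start +
    (b+1)*w``. Events outside the grid are dropped with a warning and
    reported in the QC dict.

    Returns
    -------
    counts : (units, trials, bins) int array
    qc : dict with ``n_events``, ``n_dropped``
    """
    extent = t_stop - t_start
    if extent <= 0 or abs(extent / bin_width - round(extent / bin_width)) > 1e-9:
        raise ValueError("bin width must divide the grid extent")
    n_bins = int(round(extent / bin_width))
    n_units = len(event_times)
    n_trials = len(event_times[0]) if n_units else 0
    edges = t_start + np.arange(n_bins + 1) * float(bin_width)
    counts = np.zeros((n_units, n_trials, n_bins), dtype=np.int64)
    n_total = 0
    n_dropped = 0
    for u in range(n_units):
        for t in range(n_trials):
            ev = np.asarray(event_times[u][t], dtype=float)
            n_total += ev.size
            inside = (ev >= t_start) & (ev < t_stop)
            n_dropped += int(ev.size - inside.sum())
            ev = ev[inside]
            if ev.size:
                # half-open left-closed bins
                idx = np.floor((ev - t_start) / bin_width).astype(int)
                np.add.at(counts[u, t], idx, 1)
    if n_dropped:
        warnings.warn(f"bin_spikes: dropped {n_dropped} events outside the grid")
    return counts, {"n_events": n_total, "n_dropped": n_dropped}


def net_rate(session: SessionBundle) -> RateMatrix:
    """Baseline-subtracted firing rates.

    The mean rate over the 300 ms fixation interval [-300, 0) is removed
    from the entire trial, separately per unit and trial, so the baseline
    mean of every net trace is exactly zero.
    """
    raw = session.raw_rate()
    base_idx = raw.window_bins(-BASELINE_MS, 0)
    if base_idx.size != BASELINE_MS // session.bin_width:
        raise ValueError("baseline interval [-300, 0) not fully present")
    baseline = raw.values[:, :, base_idx].mean(axis=2, keepdims=True)
    return RateMatrix(raw.values - baseline, "net", raw.bin_width, raw.t_start)


def z_normalize(
    net: RateMatrix,
    arrays: Sequence[int],
    windows: ResponseWindowConfig | None = None,
) -> RateMatrix:
    """Z-score net rates per unit using response-window statistics.

    For each unit, the mean and standard deviation of the net rate are
    taken over every 10 ms bin inside the unit's array-specific response
    window, pooled across all trials and conditions; the whole trace is
    then standardized with them. This guarantees a mean z-score of zero
    over the response window across all conditions per unit.

    Units with zero window variance are flagged degenerate (z set to 0)
    and should be excluded from z-based analyses.
    """
    if net.kind != "net":
        raise ValueError("z_normalize expects net rates")
    windows = windows or ResponseWindowConfig()
    arrays = np.asarray(arrays)
    if arrays.shape[0] != net.values.shape[0]:
        raise ValueError("one array label per unit required")
    out = np.empty_like(net.values, dtype=float)
    degenerate = set()
    for u in range(net.values.shape[0]):
        lo, hi = windows.dprime_window(int(arrays[u]))
        idx = net.window_bins(lo, hi)
        pooled = net.values[u][:, idx]
        r_mean = pooled.mean()
        r_std = pooled.std()  # population (n-denominator) SD
        if r_std == 0:
            degenerate.add(u)
            logger.warning("unit %d degenerate: zero response-window variance", u)
            out[u] = 0.0
        else:
            out[u] = (net.values[u] - r_mean) / r_std
    return RateMatrix(
        out, "znorm", net.bin_width, net.t_start, frozenset(degenerate)
    )


def screen_responsive(
    net: RateMatrix,
    trials: pd.DataFrame,
    alpha: float = 0.005,
    condition_col: str = "condition",
    windows: Iterable[tuple[int, int]] = SCREEN_WINDOWS,
) -> tuple[set[int], dict[int, list[tuple[str, tuple[int, int], float]]]]:
    """Visual-responsiveness screen.

    A unit is responsive if, for any condition and any of the four 100 ms
    screens after onset, a two-sided one-sample t-test of the per-trial
    window-mean net rate against 0 (baseline is already subtracted) gives
    p < ``alpha``. Testing per condition ensures a site with a strong
    preference for a single category is not washed out by a pooled test.

    Returns the responsive unit indices and, per unit, the
    (condition, window, p) triples that fired.
    """
    if net.kind != "net":
        raise ValueError("screen_responsive expects net rates")
    responsive: set[int] = set()
    provenance: dict[int, list] = {}
    conditions = trials[condition_col].unique()
    for cond in conditions:
        tr_idx = np.flatnonzero((trials[condition_col] == cond).to_numpy())
        if tr_idx.size < 2:
            warnings.warn(f"condition {cond!r} has <2 trials; skipped in screen")
            continue
        for lo, hi in windows:
            means = net.window_mean(lo, hi)[:, tr_idx]
            with np.errstate(invalid="ignore", divide="ignore"):
                tstat, pval = stats.ttest_1samp(means, 0.0, axis=1)
            hit = np.flatnonzero(np.nan_to_num(pval, nan=1.0) < alpha)
            for u in hit:
                responsive.add(int(u))
                provenance.setdefault(int(u), []).append(
                    (str(cond), (lo, hi), float(pval[u]))
                )
    return responsive, provenance


# ---------------------------------------------------------------------------
# Disk I/O: HDF5 bundle with the trial table embedded as TSV text; an
# optional ground-truth sidecar (JSON) is written next to the bundle.

def save_bundle(session: SessionBundle, path: str) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("spikes", data=session.spikes, compression="gzip")
        f.attrs["bin_width"] = session.bin_width
        f.attrs["t_start"] = session.t_start
        f.create_dataset(
            "units_tsv", data=session.units.to_csv(sep="\t", index=False)
        )
        f.create_dataset(
            "trials_tsv", data=session.trials.to_csv(sep="\t", index=False)
        )
        if session.lfp is not None:
            f.create_dataset("lfp", data=session.lfp, compression="gzip")
            f.attrs["lfp_fs"] = session.lfp_fs
            f.attrs["lfp_t_start"] = session.lfp_t_start
    if session.truth is not None:
        with open(_truth_path(path), "w") as fh:
            json.dump(session.truth, fh, indent=1, default=_json_default)


def load_bundle(path: str) -> SessionBundle:
    import io

    with h5py.File(path, "r") as f:
        spikes = f["spikes"][()]
        units = pd.read_csv(io.StringIO(f["units_tsv"][()].decode()), sep="\t")
        trials = pd.read_csv(io.StringIO(f["trials_tsv"][()].decode()), sep="\t")
        kw: dict = {
            "bin_width": int(f.attrs["bin_width"]),
            "t_start": int(f.attrs["t_start"]),
        }
        if "lfp" in f:
            kw["lfp"] = f["lfp"][()]
            kw["lfp_fs"] = float(f.attrs["lfp_fs"])
            kw["lfp_t_start"] = float(f.attrs["lfp_t_start"])
    truth = None
    try:
        with open(_truth_path(path)) as fh:
            truth = json.load(fh)
    except FileNotFoundError:
        pass
    return SessionBundle(units, trials, spikes, truth=truth, **kw)


def _truth_path(path: str) -> str:
    base = path[:-3] if path.endswith(".h5") else path
    return base + ".truth.json"


def _json_default(obj):
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
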