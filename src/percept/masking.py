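"""Backward-masking analyses.

Covers the delay-group partitions used for decoding, selection of
class-selective units from long-delay trials, the bootstrap KDE
bimodality test on target/mask response peaks, perceived-vs-nonperceived
rate contrasts, the signal-loss metric, the divergence latency of
awareness-related modulation, and the prestimulus-state decoder.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from .decoding import DecoderSpec, decode_features_auc
from .session import RateMatrix

logger = logging.getLogger(__name__)

FIVE_GROUPS = ((16, 32), (50, 66), (83, 100), (116, 132), (150, 166, 183))
THREE_GROUPS = ((16, 32, 50, 66), (83, 100, 116, 132), (150, 166, 183))


@dataclass
class DelayGrouping:
    scheme: str
    mapping: dict  # delay -> group index (0-based)
    counts: dict  # group index -> n trials


@dataclass
class BimodalityResult:
    peak_times_ms: np.ndarray  # pooled detected peak times
    peak_count_hist: np.ndarray  # bootstrap histogram, index = #KDE peaks
    p_value: float | None  # fraction of bootstraps with exactly one peak
    n_traces_in: int
    n_traces_averaged: int
    per_trace_peaks: list = field(default_factory=list)
    diagnostic: str | None = None


@dataclass
class SignalLossResult:
    loss_percent: float | None
    activity_perceived: float
    activity_nonperceived: float
    window: tuple[float, float]
    t_stat: float
    p_value: float
    flagged: bool = False


def group_delays(
    trials: pd.DataFrame, scheme: str = "five", delay_col: str = "mask_delay"
) -> DelayGrouping:
    """Partition masking delays into the fixed five- or three-group scheme.

    200 ms trials (a presented delay that the printed partitions omit) are
    assigned to the last group and logged.
    """
    groups = FIVE_GROUPS if scheme == "five" else THREE_GROUPS
    mapping = {d: g for g, ds in enumerate(groups) for d in ds}
    mapping[200] = len(groups) - 1
    delays = trials[delay_col].to_numpy()
    if np.any(delays == 200):
        logger.info("assigning %d trials at 200 ms delay to the last group",
                    int((delays == 200).sum()))
    unknown = set(np.unique(delays)) - set(mapping)
    if unknown:
        raise ValueError(f"delays {sorted(unknown)} not in the grouping scheme")
    counts: dict[int, int] = {}
    for d in delays:
        counts[mapping[int(d)]] = counts.get(mapping[int(d)], 0) + 1
    return DelayGrouping(scheme, mapping, counts)


def select_masking_selective_units(
    znorm: RateMatrix,
    trials: pd.DataFrame,
    window_for_unit,
    alpha: float = 0.01,
    n_perm: int = 1000,
    seed: int = 0,
    long_delay_ms: float = 150.0,
    class_col: str = "stimulus_class",
) -> dict[int, tuple[str, float]]:
    """Class-selective units from long-delay trials (mask can't interfere).

    A unit is selective for its preferred class if the mean
    response-window rate to that class exceeds the pooled other classes on
    delay >= 150 ms trials, with a one-sided permutation p < alpha.
    ``window_for_unit(u)`` returns the unit's response window.

    Returns {unit: (preferred class, p)} for selective units.
    """
    rng = np.random.default_rng(seed)
    long_idx = np.flatnonzero(trials["mask_delay"].to_numpy() >= long_delay_ms)
    classes = trials[class_col].to_numpy()
    out: dict[int, tuple[str, float]] = {}
    for u in range(znorm.values.shape[0]):
        if u in znorm.degenerate_units:
            continue
        lo, hi = window_for_unit(u)
        means = znorm.window_mean(lo, hi)[u][long_idx]
        labs = classes[long_idx]
        uniq, counts = np.unique(labs, return_counts=True)
        usable = uniq[counts >= 2]
        if len(usable) < 2:
            continue
        cls_means = {c: means[labs == c].mean() for c in usable}
        pref = max(cls_means, key=cls_means.get)
        is_pref = labs == pref
        obs = means[is_pref].mean() - means[~is_pref].mean()
        n1 = int(is_pref.sum())
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(means)
            if perm[:n1].mean() - perm[n1:].mean() >= obs:
                count += 1
        p = (1 + count) / (1 + n_perm)
        if p < alpha:
            out[u] = (str(pref), float(p))
    return out


# ---------------------------------------------------------------------------
# bootstrap KDE bimodality ("are target and mask responses two peaks?")

def _moving_average(x: np.ndarray, k: int = 5) -> np.ndarray:
    """Centered moving average with edge windows shrunk (no padding)."""
    n = x.shape[-1]
    c = np.concatenate([np.zeros(x.shape[:-1] + (1,)), np.cumsum(x, axis=-1)], axis=-1)
    half = k // 2
    lo = np.clip(np.arange(n) - half, 0, n)
    hi = np.clip(np.arange(n) + half + 1, 0, n)
    return (c[..., hi] - c[..., lo]) / (hi - lo)


def _trace_peaks(
    trace: np.ndarray,
    times: np.ndarray,
    height_threshold: float,
    min_sep_ms: float = 30.0,
    max_peaks: int = 2,
) -> np.ndarray:
    """Up to two largest peaks above threshold with the separation rule."""
    step = times[1] - times[0]
    idx, props = sps.find_peaks(
        trace, height=height_threshold, distance=max(int(round(min_sep_ms / step)), 1)
    )
    if idx.size == 0:
        return np.empty(0)
    order = np.argsort(props["peak_heights"])[::-1][:max_peaks]
    return np.sort(times[idx[order]])


def _kde_peak_counts(
    samples: np.ndarray,
    grid: np.ndarray,
    bandwidth_ms: float,
    height_frac: float = 0.3,
    valley_ms: float = 30.0,
) -> np.ndarray:
    """Number of recognized KDE peaks for each bootstrap sample (row).

    The tallest density mode always counts; an additional mode counts if
    its height exceeds ``height_frac`` of the tallest and the nearest
    valleys (local minima of the density, with the support boundary
    counting as a valley) are at least ``valley_ms`` away on both sides.
    """
    n_boot, n = samples.shape
    out = np.empty(n_boot, dtype=int)
    step = grid[1] - grid[0]
    chunk = max(1, int(2e7 // (n * grid.size)))
    dens = np.empty((n_boot, grid.size))
    for s in range(0, n_boot, chunk):
        block = samples[s : s + chunk]
        d = grid[None, None, :] - block[:, :, None]
        dens[s : s + chunk] = np.exp(-0.5 * (d / bandwidth_ms) ** 2).mean(axis=1)
    for b in range(n_boot):
        y = dens[b]
        interior = np.flatnonzero((y[1:-1] > y[:-2]) & (y[1:-1] >= y[2:])) + 1
        if interior.size == 0:
            out[b] = 1
            continue
        mins = np.flatnonzero((y[1:-1] < y[:-2]) & (y[1:-1] <= y[2:])) + 1
        valleys = np.concatenate([[0], mins, [grid.size - 1]])
        heights = y[interior]
        order = np.argsort(heights)[::-1]
        top = heights[order[0]]
        count = 1
        for k in order[1:]:
            pk = interior[k]
            if y[pk] <= height_frac * top:
                continue
            left = valleys[valleys < pk]
            right = valleys[valleys > pk]
            if left.size == 0 or right.size == 0:
                continue
            dl = (pk - left.max()) * step
            dr = (right.min() - pk) * step
            if dl >= valley_ms and dr >= valley_ms:
                count += 1
        out[b] = count
    return out


def silverman_bimodality(
    traces: np.ndarray,
    t_start: float,
    bin_width: float,
    reference_max: float,
    seed: int = 0,
    n_boot: int = 1000,
    bandwidth_bins: float = 2.0,
    smooth_ms: float = 50.0,
    min_sep_ms: float = 30.0,
    height_frac: float = 0.3,
) -> BimodalityResult:
    """Bootstrap KDE test for bimodal (target + mask) response traces.

    Pipeline: shuffle the per-trial z-traces into random non-overlapping
    triples and average (remainder dropped) -> 50 ms moving-average smooth
    -> detect up to 2 post-onset peaks per averaged trace (>= 30 ms apart,
    height above 30% of ``reference_max``, the highest average rate across
    all delays for the tested class) -> pool the peak times -> 1000
    bootstrap resamples with replacement -> Gaussian KDE (bandwidth 2
    bins = 20 ms) -> count recognized KDE peaks. p is the fraction of
    bootstrap samples with exactly one peak, so small p indicates a
    reliably bimodal (two-peak) response.
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    n_in = traces.shape[0]
    if n_in < 3:
        raise ValueError("bimodality test needs at least 3 traces")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_in)
    n_groups = n_in // 3
    if n_in % 3:
        logger.info("dropping %d leftover traces after triple grouping", n_in % 3)
    grouped = traces[order[: n_groups * 3]].reshape(n_groups, 3, -1).mean(axis=1)
    k = max(int(round(smooth_ms / bin_width)), 1)
    smoothed = _moving_average(grouped, k)
    times = t_start + (np.arange(traces.shape[1]) + 0.5) * bin_width
    post = times > 0
    peak_lists = [
        _trace_peaks(
            tr[post], times[post], height_frac * reference_max, min_sep_ms
        )
        for tr in smoothed
    ]
    pooled = np.concatenate(peak_lists) if peak_lists else np.empty(0)
    if pooled.size == 0:
        return BimodalityResult(
            pooled,
            np.zeros(0, dtype=int),
            None,
            n_in,
            n_groups,
            peak_lists,
            diagnostic="no peaks detected in any averaged trace; "
            "test undefined (weak responses inflate type-I error)",
        )
    boots = rng.choice(pooled, size=(n_boot, pooled.size), replace=True)
    grid = np.arange(times[post][0], times[-1] + 1.0, 1.0)
    counts = _kde_peak_counts(
        boots, grid, bandwidth_bins * bin_width, height_frac, min_sep_ms
    )
    hist = np.bincount(counts)
    p = float((counts == 1).mean())
    return BimodalityResult(pooled, hist, p, n_in, n_groups, peak_lists)


# ---------------------------------------------------------------------------
# perception contrasts

def perceived_vs_nonperceived_rate_test(
    znorm: RateMatrix,
    unit_idx: np.ndarray,
    trials: pd.DataFrame,
    window: tuple[float, float],
    trial_idx: np.ndarray | None = None,
) -> dict:
    """One-sided t-test: response-window rate, perceived > nonperceived.

    The per-trial statistic is the mean z-rate over the given units within
    the window.
    """
    if trial_idx is None:
        trial_idx = np.arange(len(trials))
    perceived = trials["perceived"].to_numpy()[trial_idx]
    if perceived.all() or (~perceived).all():
        raise ValueError("need both perceived and nonperceived trials")
    means = znorm.window_mean(*window)[np.asarray(unit_idx)][:, trial_idx].mean(axis=0)
    t, p = stats.ttest_ind(
        means[perceived], means[~perceived], alternative="greater"
    )
    return {
        "t": float(t),
        "p_value": float(p),
        "mean_perceived": float(means[perceived].mean()),
        "mean_nonperceived": float(means[~perceived].mean()),
        "n_perceived": int(perceived.sum()),
        "n_nonperceived": int((~perceived).sum()),
    }


def signal_loss(
    znorm: RateMatrix,
    unit_idx: np.ndarray,
    trials: pd.DataFrame,
    window: tuple[float, float],
    trial_idx: np.ndarray | None = None,
) -> SignalLossResult:
    """Percent response reduction for nonperceived vs perceived stimuli.

    loss = (1 - Activity_nonperceived / Activity_perceived) * 100, where
    each activity is the mean z-rate in the 150 ms window after response
    latency, baseline-corrected by that arm's mean baseline z-rate.
    Undefined (flagged) when the perceived-arm activity is <= 0.
    """
    if trial_idx is None:
        trial_idx = np.arange(len(trials))
    unit_idx = np.asarray(unit_idx)
    perceived = trials["perceived"].to_numpy()[trial_idx]
    win = znorm.window_mean(*window)[unit_idx][:, trial_idx]
    base = znorm.window_mean(znorm.t_start, 0.0)[unit_idx][:, trial_idx]
    per_trial = win.mean(axis=0)
    a_p = float(win[:, perceived].mean() - base[:, perceived].mean())
    a_np = float(win[:, ~perceived].mean() - base[:, ~perceived].mean())
    t, p = stats.ttest_ind(per_trial[perceived], per_trial[~perceived])
    if a_p <= 0:
        return SignalLossResult(None, a_p, a_np, window, float(t), float(p), True)
    return SignalLossResult(
        (1.0 - a_np / a_p) * 100.0, a_p, a_np, window, float(t), float(p)
    )


def divergence_latency(
    znorm: RateMatrix,
    unit_idx: np.ndarray,
    trials: pd.DataFrame,
    alpha: float = 0.05,
    n_perm: int = 1000,
    run: int = 3,
    seed: int = 0,
    trial_idx: np.ndarray | None = None,
):
    """Latency at which perceived trials pull away from nonperceived.

    Per-bin one-sided permutation test (perceived > nonperceived) on the
    unit-averaged z-rate; the latency is the midpoint of the first bin of
    the earliest run of ``run`` consecutive significant bins after onset.
    """
    from .tuning import LatencyResult, _first_run

    if trial_idx is None:
        trial_idx = np.arange(len(trials))
    perceived = trials["perceived"].to_numpy()[trial_idx]
    data = znorm.values[np.asarray(unit_idx)][:, trial_idx].mean(axis=0)  # (T, bins)
    n1 = int(perceived.sum())
    obs = data[perceived].mean(axis=0) - data[~perceived].mean(axis=0)
    rng = np.random.default_rng(seed)
    n_t = data.shape[0]
    count = np.zeros(data.shape[1])
    for _ in range(n_perm):
        perm = rng.permutation(n_t)
        diff = data[perm[:n1]].mean(axis=0) - data[perm[n1:]].mean(axis=0)
        count += diff >= obs
    p = (1 + count) / (1 + n_perm)
    onset = int(-znorm.t_start // znorm.bin_width)
    flags = np.zeros(data.shape[1], dtype=bool)
    flags[onset:] = p[onset:] < alpha
    start = _first_run(flags[onset:], run)
    latency = None if start is None else float(znorm.bin_centers[onset + start])
    return LatencyResult(latency, flags, znorm.bin_centers)


def prestimulus_awareness_decoder(
    znorm: RateMatrix,
    trials: pd.DataFrame,
    spec: DecoderSpec | None = None,
    seed: int = 0,
    unit_idx: np.ndarray | None = None,
    trial_idx: np.ndarray | None = None,
) -> float:
    """Mean AUC of a decoder predicting perception from baseline activity.

    Features are the 30 pre-stimulus 10 ms z-rate bins of every unit; an
    AUC of 0.5 means the prestimulus state carries no information about
    whether the upcoming target will be perceived.
    """
    spec = spec or DecoderSpec()
    if trial_idx is None:
        trial_idx = np.arange(len(trials))
    if unit_idx is None:
        unit_idx = np.array(
            [u for u in range(znorm.values.shape[0]) if u not in znorm.degenerate_units]
        )
    perceived = trials["perceived"].to_numpy()[trial_idx]
    if perceived.sum() < 2 or (~perceived).sum() < 2:
        raise ValueError("need >= 2 trials per perception arm")
    base_bins = znorm.window_bins(znorm.t_start, 0.0)
    X = (
        znorm.values[np.asarray(unit_idx)][:, trial_idx][:, :, base_bins]
        .transpose(1, 0, 2)
        .reshape(len(trial_idx), -1)
    )
    y = np.where(perceived, "perceived", "nonperceived")
    mean_auc, _, _ = decode_features_auc(X, y, spec, seed=seed)
    return float(mean_auc)
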