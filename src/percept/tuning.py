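"""Response latency, selectivity latency, d-prime, and category selectivity.

These are the per-unit/per-array tuning characterizations: when a site
starts responding, when it starts discriminating, how strongly it
separates two stimulus groups (d'), and which of face/body/object it
prefers (ANOVA + Tukey HSD rule set).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .session import RateMatrix


@dataclass
class LatencyResult:
    """Latency in ms (midpoint of the first bin of the qualifying run), or
    None if no run of 3 consecutive qualifying bins exists. ``criterion``
    holds the per-bin pass/fail flags for audit."""

    latency_ms: float | None
    criterion: np.ndarray
    bin_centers: np.ndarray


@dataclass
class DPrimeResult:
    dprime: float
    mu1: float
    mu2: float
    var1: float
    var2: float
    window: tuple[float, float]
    p_value: float | None = None


@dataclass
class CategorySelectivity:
    anova_p: float
    tukey_p: dict
    label: str  # face | body | object | face+body | none
    group_means: dict


def _first_run(flags: np.ndarray, run: int = 3) -> int | None:
    """Index of the first element of the earliest run of ``run`` True flags."""
    count = 0
    for i, f in enumerate(flags):
        count = count + 1 if f else 0
        if count == run:
            return i - run + 1
    return None


def response_latency(
    net: RateMatrix,
    unit: int,
    trial_idx: np.ndarray | None = None,
    sd_floor: float = 0.1,
    run: int = 3,
    guard_bins: int = 1,
) -> LatencyResult:
    """Response latency of one unit from its trial-averaged net trace.

    The latency is the first of ``run`` (default 3) consecutive 10 ms bins
    in which the average net rate (i) increased vs the previous bin and
    (ii) exceeded 2 SD of the baseline rate. An anticipation guard — a
    rise of more than 50% relative to the previous bin and more than
    5 sp/s in absolute terms — must additionally hold on the first
    ``guard_bins`` bins of the run: a slow anticipatory ramp never clears
    it, while any genuine saturating response does (near its peak no
    response keeps growing 50% per bin, so demanding the guard on every
    run bin would reject real onsets). Baseline SD is taken over the
    baseline bins of the same trial-averaged trace the criterion is
    applied to, floored at ``sd_floor`` sp/s against silent baselines.
    """
    values = net.values[unit]
    if trial_idx is not None:
        values = values[trial_idx]
    trace = values.mean(axis=0)
    base_idx = net.window_bins(net.t_start, 0)
    sd = max(float(trace[base_idx].std()), sd_floor)
    onset = int(-net.t_start // net.bin_width)
    n = trace.size
    core = np.zeros(n, dtype=bool)
    guard = np.zeros(n, dtype=bool)
    for b in range(max(onset, 1), n):
        prev = trace[b - 1]
        core[b] = (trace[b] > prev) and (trace[b] > 2.0 * sd)
        # when prev <= 0, any increase is >50% relative
        guard[b] = (trace[b] > 1.5 * prev) and (trace[b] - prev > 5.0)
    latency = None
    flags = core.copy()
    for b in range(onset, n - run + 1):
        if core[b : b + run].all() and guard[b : b + guard_bins].all():
            latency = float(net.bin_centers[b])
            break
    return LatencyResult(latency, flags, net.bin_centers)


def selectivity_latency(
    net: RateMatrix,
    unit: int,
    group1_trials: np.ndarray,
    group2_trials: np.ndarray,
    alpha: float = 0.05,
    run: int = 3,
    equal_var: bool = True,
) -> LatencyResult:
    """First of 3 consecutive bins with mu_group1 > mu_group2 (one-sided t).

    Uses the pooled-variance two-sample t by default (Welch via
    ``equal_var=False``); evaluated per 10 ms bin across trials, post
    stimulus onset.
    """
    if len(group1_trials) < 2 or len(group2_trials) < 2:
        raise ValueError("each group needs >= 2 trials")
    x1 = net.values[unit][group1_trials]  # (n1, bins)
    x2 = net.values[unit][group2_trials]
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(
            x1, x2, axis=0, equal_var=equal_var, alternative="greater"
        )
    p = np.nan_to_num(p, nan=1.0)
    onset = int(-net.t_start // net.bin_width)
    flags = np.zeros(net.n_bins, dtype=bool)
    flags[onset:] = p[onset:] < alpha
    start = _first_run(flags[onset:], run)
    latency = None if start is None else float(net.bin_centers[onset + start])
    return LatencyResult(latency, flags, net.bin_centers)


def dprime_values(x1: np.ndarray, x2: np.ndarray, ddof: int = 1) -> float:
    """d' between two samples of per-trial window means."""
    mu1, mu2 = float(np.mean(x1)), float(np.mean(x2))
    v1 = float(np.var(x1, ddof=ddof)) if len(x1) > ddof else 0.0
    v2 = float(np.var(x2, ddof=ddof)) if len(x2) > ddof else 0.0
    denom = np.sqrt((v1 + v2) / 2.0)
    if denom == 0.0:
        return 0.0 if mu1 == mu2 else float(np.sign(mu1 - mu2) * np.inf)
    return (mu1 - mu2) / denom


def dprime(
    net: RateMatrix,
    unit: int,
    group1_trials: np.ndarray,
    group2_trials: np.ndarray,
    window: tuple[float, float],
    n_perm: int = 1000,
    seed: int | None = 0,
) -> DPrimeResult:
    """d' on response-window mean net rates, with a permutation p-value.

    d' = (mu1 - mu2) / sqrt((var1 + var2) / 2); positive d' means group 1
    responded more. Significance comes from 1000 random relabelings of
    the pooled trials, one-sided toward the observed sign, with +1
    smoothing: p = (1 + #{null at least as extreme}) / (1 + n_perm).
    """
    if len(group1_trials) < 2 or len(group2_trials) < 2:
        raise ValueError("each group needs >= 2 trials")
    means = net.window_mean(*window)[unit]
    x1, x2 = means[group1_trials], means[group2_trials]
    obs = dprime_values(x1, x2)
    p = None
    if n_perm and np.isfinite(obs):
        rng = np.random.default_rng(seed)
        pooled = np.concatenate([x1, x2])
        n1 = len(x1)
        perms = rng.permuted(np.tile(pooled, (n_perm, 1)), axis=1)
        a, b = perms[:, :n1], perms[:, n1:]
        denom = np.sqrt((a.var(axis=1, ddof=1) + b.var(axis=1, ddof=1)) / 2.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            d0 = (a.mean(axis=1) - b.mean(axis=1)) / denom
        d0 = np.nan_to_num(d0, nan=0.0)
        count = int((d0 >= obs).sum() if obs >= 0 else (d0 <= obs).sum())
        p = (1 + count) / (1 + n_perm)
    return DPrimeResult(
        obs,
        float(np.mean(x1)),
        float(np.mean(x2)),
        float(np.var(x1, ddof=1)),
        float(np.var(x2, ddof=1)),
        window,
        p,
    )


def categorize_unit(
    net: RateMatrix,
    unit: int,
    labels: np.ndarray,
    window: tuple[float, float],
    alpha: float = 0.05,
) -> CategorySelectivity:
    """Face/body/object selectivity from ANOVA + Tukey HSD on window means.

    ``labels`` holds per-trial class names with the object-like categories
    already pooled into ``"object"``. A unit is face-selective if its face
    response exceeds both object and body at Tukey p < alpha (body
    symmetric); object-selective if object exceeds both; face-and-body
    selective if both exceed object at p < alpha while face vs body is not
    significant; ``none`` if the ANOVA is not significant or no rule
    fires.
    """
    labels = np.asarray(labels)
    required = ("face", "body", "object")
    groups = {}
    means = net.window_mean(*window)[unit]
    for c in required:
        idx = np.flatnonzero(labels == c)
        if idx.size < 2:
            raise ValueError(f"category {c!r} missing or has <2 trials")
        groups[c] = means[idx]
    _, anova_p = stats.f_oneway(*groups.values())
    mu = {c: float(np.mean(v)) for c, v in groups.items()}
    res = stats.tukey_hsd(groups["face"], groups["body"], groups["object"])
    tk = {
        ("face", "body"): float(res.pvalue[0, 1]),
        ("face", "object"): float(res.pvalue[0, 2]),
        ("body", "object"): float(res.pvalue[1, 2]),
    }
    label = "none"
    if anova_p < alpha:
        fo = mu["face"] > mu["object"] and tk[("face", "object")] < alpha
        bo = mu["body"] > mu["object"] and tk[("body", "object")] < alpha
        fb = mu["face"] > mu["body"] and tk[("face", "body")] < alpha
        bf = mu["body"] > mu["face"] and tk[("face", "body")] < alpha
        of = mu["object"] > mu["face"] and tk[("face", "object")] < alpha
        ob = mu["object"] > mu["body"] and tk[("body", "object")] < alpha
        if fo and fb:
            label = "face"
        elif bo and bf:
            label = "body"
        elif of and ob:
            label = "object"
        elif fo and bo and tk[("face", "body")] >= alpha:
            label = "face+body"
    return CategorySelectivity(float(anova_p), tk, label, mu)
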