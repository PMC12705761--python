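"""Flash-suppression responder taxonomy and b-CFS eye dominance.

Conditions (phase 1 -> phase 2, 1000 ms + 400 ms): FS_FP / FS_PF (flash
suppression, face-to-place / place-to-face percept shift), RA_FP / RA_PF
(real alternation), CON_F / CON_P (continuation). Units are classified as
face/place selective, sustained, inhibitory, and — through the quoted
eligibility gates — as percept-following or not evaluable. Phase-2
statistics use the array's response window re-referenced to the phase-2
onset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .decoding import significance_runs
from .session import RateMatrix

PHASE1_MS = 1000.0

FACE_PHASE1 = ("FS_FP", "RA_FP", "CON_F")
PLACE_PHASE1 = ("FS_PF", "RA_PF", "CON_P")


@dataclass
class ResponderClassification:
    selectivity: str  # face | place | none
    selectivity_p: float
    sustained: bool
    sustained_p: float
    inhibitory: bool | None
    inhibitory_p: float | None
    percept_following_selective: str  # yes | no | not-evaluable
    percept_following_sustained: str  # yes | no | not-evaluable
    mu_800_1000: float
    mu_fixation: float


@dataclass
class EyeDominanceResult:
    mean_latency_s: dict
    n_censored: dict
    dominant_eye: str  # left | right | none
    t_stat: float | None
    p_value: float | None


def phase2_window(window: tuple[float, float], onset: float = PHASE1_MS):
    """Re-reference an after-onset response window to the phase-2 onset."""
    return (onset + window[0], onset + window[1])


def _cond_idx(trials: pd.DataFrame, *conds: str) -> np.ndarray:
    return np.flatnonzero(trials["condition"].isin(conds).to_numpy())


def _perm_p(
    x1: np.ndarray,
    x2: np.ndarray,
    rng: np.random.Generator,
    n_perm: int = 1000,
    alternative: str = "greater",
) -> float:
    """Permutation p for mean(x1) - mean(x2) with +1 smoothing."""
    obs = x1.mean() - x2.mean()
    pooled = np.concatenate([x1, x2])
    n1 = len(x1)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        d = perm[:n1].mean() - perm[n1:].mean()
        if alternative == "greater":
            count += d >= obs
        elif alternative == "less":
            count += d <= obs
        else:
            count += abs(d) >= abs(obs)
    return (1 + count) / (1 + n_perm)


def classify_selective(
    net: RateMatrix,
    unit: int,
    trials: pd.DataFrame,
    window: tuple[float, float],
    alpha: float = 0.05,
) -> tuple[str, float]:
    """Face/place selectivity from phase-1 monocular presentations.

    Two-sided independent t-test on response-window mean net rates, face
    vs place trials; returns ("face"|"place"|"none", p).
    """
    f = _cond_idx(trials, *FACE_PHASE1)
    p_ = _cond_idx(trials, *PLACE_PHASE1)
    if len(f) < 2 or len(p_) < 2:
        raise ValueError("need >= 2 face and >= 2 place phase-1 trials")
    means = net.window_mean(*window)[unit]
    t, p = stats.ttest_ind(means[f], means[p_])
    if p < alpha:
        return ("face" if means[f].mean() > means[p_].mean() else "place", float(p))
    return ("none", float(p))


def classify_sustained(
    rates: RateMatrix,
    unit: int,
    trials: pd.DataFrame,
    preferred: str = "face",
    alpha: float = 0.05,
) -> tuple[bool, float, float, float]:
    """Sustained responder: late phase-1 activity above fixation.

    Tests the mean net rate (or gamma activity) in the last 200 ms of
    phase 1 ([800, 1000) ms) of continued preferred-stimulus trials
    against the fixation level. On net rates the fixation mean is 0 by
    construction, so the paired test reduces to a one-sided one-sample t
    of the per-trial [800, 1000) mean against the per-trial fixation mean.

    Returns (flag, p, mu_800_1000, mu_fixation).
    """
    conds = FACE_PHASE1 if preferred == "face" else PLACE_PHASE1
    idx = _cond_idx(trials, *conds)
    if len(idx) < 2:
        raise ValueError("need >= 2 preferred phase-1 trials")
    late = rates.window_mean(800.0, 1000.0)[unit][idx]
    fix = rates.window_mean(rates.t_start, 0.0)[unit][idx]
    t, p = stats.ttest_rel(late, fix, alternative="greater")
    return (
        bool(p < alpha),
        float(p),
        float(late.mean()),
        float(fix.mean()),
    )


def classify_inhibitory(
    net: RateMatrix,
    unit: int,
    trials: pd.DataFrame,
    window: tuple[float, float],
    alpha: float = 0.05,
    preferred: str = "face",
) -> tuple[bool, float]:
    """Inhibitory responder: RA preferred-to-nonpreferred below continuation.

    One-sided independent t on phase-2 response-window means,
    RA F->P < CON F (labels swapped for place-preferring units).
    """
    ra = "RA_FP" if preferred == "face" else "RA_PF"
    con = "CON_F" if preferred == "face" else "CON_P"
    i_ra = _cond_idx(trials, ra)
    i_con = _cond_idx(trials, con)
    if len(i_ra) < 2 or len(i_con) < 2:
        raise ValueError(f"need >= 2 trials of {ra} and {con}")
    means = net.window_mean(*phase2_window(window))[unit]
    t, p = stats.ttest_ind(means[i_ra], means[i_con], alternative="less")
    return bool(p < alpha), float(p)


def identify_percept_following(
    net: RateMatrix,
    unit: int,
    trials: pd.DataFrame,
    window: tuple[float, float],
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> ResponderClassification:
    """Full responder taxonomy and percept-following status of one unit.

    Path 1 (selective units): eligible if the unit is face/place selective
    and shows significant phase-2 activity vs baseline after real
    alternation from the nonpreferred to the preferred image; it follows
    perception if its response after flash suppression from nonpreferred
    to preferred exceeds continued nonpreferred presentation (one-sided
    permutation test).

    Path 2 (sustained or inhibitory units): follows perception if phase-2
    response-window rates after both FS and RA shifts away from the
    preferred stimulus are lower than during its continued presentation.

    Units failing a path's gates are "not-evaluable" on that path.
    """
    rng = np.random.default_rng(seed)
    sel, sel_p = classify_selective(net, unit, trials, window, alpha)
    preferred = sel if sel != "none" else "face"
    sus, sus_p, mu_late, mu_fix = classify_sustained(
        net, unit, trials, preferred, alpha
    )
    try:
        inh, inh_p = classify_inhibitory(net, unit, trials, window, alpha, preferred)
    except ValueError:
        inh, inh_p = None, None

    w2 = phase2_window(window)
    means2 = net.window_mean(*w2)[unit]
    if preferred == "face":
        fs_np, ra_np, con_np, fs_pn, ra_pn, con_p = (
            "FS_PF", "RA_PF", "CON_P", "FS_FP", "RA_FP", "CON_F",
        )
    else:
        fs_np, ra_np, con_np, fs_pn, ra_pn, con_p = (
            "FS_FP", "RA_FP", "CON_F", "FS_PF", "RA_PF", "CON_P",
        )

    # path 1: selective units
    path1 = "not-evaluable"
    if sel != "none":
        i_ra = _cond_idx(trials, ra_np)
        gate_t, gate_p = stats.ttest_1samp(
            means2[i_ra], 0.0, alternative="greater"
        )
        if gate_p < alpha:
            x_fs = means2[_cond_idx(trials, fs_np)]
            x_con = means2[_cond_idx(trials, con_np)]
            p1 = _perm_p(x_fs, x_con, rng, n_perm, "greater")
            path1 = "yes" if p1 < alpha else "no"

    # path 2: sustained or inhibitory units
    path2 = "not-evaluable"
    if sus or (inh is True):
        x_con = means2[_cond_idx(trials, con_p)]
        p_fs = _perm_p(means2[_cond_idx(trials, fs_pn)], x_con, rng, n_perm, "less")
        p_ra = _perm_p(means2[_cond_idx(trials, ra_pn)], x_con, rng, n_perm, "less")
        path2 = "yes" if (p_fs < alpha and p_ra < alpha) else "no"

    return ResponderClassification(
        sel, sel_p, sus, sus_p, inh, inh_p, path1, path2, mu_late, mu_fix
    )


def fs_contrast_traces(
    znorm: RateMatrix,
    unit_idx: np.ndarray,
    trials: pd.DataFrame,
    alpha: float = 0.05,
    n_perm: int = 1000,
    min_run: int = 5,
    seed: int = 0,
    pairs: tuple = (
        ("FS_PF", "RA_PF"),
        ("FS_PF", "CON_P"),
        ("FS_FP", "RA_FP"),
        ("FS_FP", "CON_F"),
    ),
) -> dict:
    """Per-bin two-sided permutation contrasts of population z-traces.

    For each condition pair, trials' unit-averaged z-traces are compared
    bin-by-bin with a two-sided permutation test; windows of >= 5
    consecutive significant bins are flagged as significant runs.
    """
    rng = np.random.default_rng(seed)
    data = znorm.values[np.asarray(unit_idx)].mean(axis=0)  # (trials, bins)
    out = {}
    for a, b in pairs:
        ia, ib = _cond_idx(trials, a), _cond_idx(trials, b)
        if len(ia) < 2 or len(ib) < 2:
            raise ValueError(f"need >= 2 trials of {a} and {b}")
        xa, xb = data[ia], data[ib]
        obs = xa.mean(axis=0) - xb.mean(axis=0)
        pooled = np.vstack([xa, xb])
        n1 = len(ia)
        count = np.zeros(obs.size)
        for _ in range(n_perm):
            perm = rng.permutation(len(pooled))
            d = pooled[perm[:n1]].mean(axis=0) - pooled[perm[n1:]].mean(axis=0)
            count += np.abs(d) >= np.abs(obs)
        p = (1 + count) / (1 + n_perm)
        out[(a, b)] = {
            "diff": obs,
            "p_values": p,
            "significant": significance_runs(p, alpha, min_run),
        }
    return out


def eye_dominance(trials: pd.DataFrame, alpha: float = 0.05) -> EyeDominanceResult:
    """Dominant eye from b-CFS breakage latencies.

    The dominant eye is the one with the shorter mean suppression-breakage
    latency, accepted only if the two-sided t-test is significant.
    Censored trials (no breakage within the 10 s ramp) enter at the censor
    time.
    """
    lat = {}
    cens = {}
    for eye in ("left", "right"):
        sub = trials[trials["arrow_eye"] == eye]
        lat[eye] = sub["breakage_latency_s"].to_numpy()
        cens[eye] = int(sub["censored"].sum()) if "censored" in sub else 0
        if len(sub) and cens[eye] == len(sub):
            warnings.warn(f"all {eye}-eye trials censored; dominance undefined")
            return EyeDominanceResult(
                {e: float(np.mean(lat[e])) if len(lat.get(e, [])) else np.nan
                 for e in lat},
                cens,
                "none",
                None,
                None,
            )
    if len(lat["left"]) < 2 or len(lat["right"]) < 2:
        raise ValueError("need >= 2 trials per eye")
    t, p = stats.ttest_ind(lat["left"], lat["right"])
    dom = "none"
    if p < alpha:
        dom = "left" if lat["left"].mean() < lat["right"].mean() else "right"
    return EyeDominanceResult(
        {e: float(v.mean()) for e, v in lat.items()},
        cens,
        dom,
        float(t),
        float(p),
    )
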