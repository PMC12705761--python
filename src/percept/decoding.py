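"""Sliding-window population decoding with L1-regularized logistic models.

The decoding protocol: z-normalized per-unit rates are averaged in 100 ms
windows stepped by 10 ms; per window an L1 (LASSO) logistic classifier
with C = 0.1 and class weights inversely proportional to class frequency
is trained on a stratified 80% of trials and scored by AUC on the held-out
20%, averaged over 10 repetitions. Multiclass problems use one-vs-rest
with macro-averaged AUC. Chance is assessed from a 250-shuffle null per
window, with significance runs of at least 5 consecutive windows.

For flash suppression and rivalry the "best bin" (highest face-vs-place
AUC) trains leave-one-out probability decoders that emit a face
probability for every window of the held-out trial; rivalrous trials are
scored by an ensemble of 10 randomly chosen LOO decoders trained on
non-rivalrous data only. Window times are reported as interval midpoints.

Small-C L1 keeps the models sparse: units carrying no class information
get coefficients that are exactly zero.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedShuffleSplit, cross_val_score
from sklearn.multiclass import OneVsRestClassifier

from .session import RateMatrix


@dataclass
class DecoderSpec:
    C: float = 0.1
    window_ms: float = 100.0
    step_ms: float = 10.0
    n_repetitions: int = 10
    test_size: float = 0.2
    n_folds: int = 10
    inner_cv: bool = False  # 10-fold CV inside the 80% as a sanity metric only
    positive_class: str = "face"


@dataclass
class DecodeTrace:
    window_centers: np.ndarray
    auc_mean: np.ndarray
    auc_se: np.ndarray
    auc_per_rep: np.ndarray  # (n_repetitions, n_windows)
    null_auc: np.ndarray | None = None  # (n_shuffle, n_windows)
    p_values: np.ndarray | None = None
    significant: np.ndarray | None = None  # run-filtered mask
    inner_cv_auc: np.ndarray | None = None


@dataclass
class ProbabilityTrajectory:
    window_centers: np.ndarray
    probabilities: np.ndarray  # (n_trials, n_windows), face probability
    trial_idx: np.ndarray
    best_window_start: float
    baseline_probability: float

    @property
    def baseline_subtracted(self) -> np.ndarray:
        return self.probabilities - self.baseline_probability


def make_classifier(spec: DecoderSpec, seed: int | None = None) -> LogisticRegression:
    # liblinear penalizes the intercept; a large intercept_scaling makes it
    # effectively unpenalized while keeping the fast solver.
    return LogisticRegression(
        l1_ratio=1.0,  # pure L1 (LASSO)
        C=spec.C,
        solver="liblinear",
        class_weight="balanced",
        intercept_scaling=100.0,
        max_iter=2000,
        random_state=seed,
    )


def fit_model(X, y, spec: DecoderSpec, seed: int | None = None):
    """Fit the L1 logistic model; multiclass problems use explicit
    one-vs-rest, reducing each class to a standard binary task."""
    model = make_classifier(spec, seed)
    if len(np.unique(y)) > 2:
        model = OneVsRestClassifier(model)
    model.fit(X, y)
    return model


def feature_matrix(
    znorm: RateMatrix,
    start_ms: float,
    window_ms: float,
    unit_idx: np.ndarray | None = None,
) -> np.ndarray:
    """Per-trial feature vector: per-unit mean z-rate in [start, start+window).

    Degenerate units (zero response-window variance) are excluded unless
    an explicit ``unit_idx`` is given.
    """
    if unit_idx is None:
        unit_idx = np.array(
            [u for u in range(znorm.values.shape[0]) if u not in znorm.degenerate_units]
        )
    means = znorm.window_mean(start_ms, start_ms + window_ms)  # (units, trials)
    return means[unit_idx].T


def window_starts(
    znorm: RateMatrix, spec: DecoderSpec, t_min: float | None = None,
    t_max: float | None = None,
) -> np.ndarray:
    """Left edges of all sliding windows that fit on the grid."""
    t0 = znorm.t_start if t_min is None else t_min
    t1 = (znorm.t_start + znorm.n_bins * znorm.bin_width) if t_max is None else t_max
    return np.arange(t0, t1 - spec.window_ms + 1e-9, spec.step_ms)


def _auc(model, X_test, y_test, classes) -> float:
    proba = model.predict_proba(X_test)
    if len(classes) == 2:
        pos = list(model.classes_).index(classes[1])
        return roc_auc_score((y_test == classes[1]).astype(int), proba[:, pos])
    return roc_auc_score(
        y_test, proba, multi_class="ovr", average="macro", labels=list(model.classes_)
    )


def _ordered_classes(y: np.ndarray, spec: DecoderSpec) -> list:
    classes = sorted(np.unique(y).tolist())
    if len(classes) == 2 and spec.positive_class in classes:
        classes = [c for c in classes if c != spec.positive_class] + [
            spec.positive_class
        ]
    return classes


def decode_features_auc(
    X: np.ndarray,
    y: np.ndarray,
    spec: DecoderSpec,
    seed: int,
) -> tuple[float, np.ndarray, float | None]:
    """Mean held-out AUC for one feature matrix over the spec's repetitions.

    Each repetition draws a fresh stratified 80/20 split; the model is fit
    on the 80% and scored on the 20%. Features are not re-normalized per
    split (normalization is global, from the z-scoring step). Returns
    (mean AUC, per-repetition AUCs, inner-CV AUC or None).
    """
    y = np.asarray(y)
    classes = _ordered_classes(y, spec)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    counts = pd.Series(y).value_counts()
    if counts.min() < 10:
        warnings.warn("fewer than 10 trials in some class; AUC will be noisy")
    splitter = StratifiedShuffleSplit(
        n_splits=spec.n_repetitions, test_size=spec.test_size, random_state=seed
    )
    aucs = np.empty(spec.n_repetitions)
    inner = []
    for r, (tr, te) in enumerate(splitter.split(X, y)):
        model = fit_model(X[tr], y[tr], spec, seed=seed + r)
        aucs[r] = _auc(model, X[te], y[te], classes)
        if spec.inner_cv:
            sc = cross_val_score(
                make_classifier(spec, seed=seed + r),
                X[tr],
                y[tr],
                cv=min(spec.n_folds, int(counts.min())),
                scoring="roc_auc_ovr" if len(classes) > 2 else "roc_auc",
            )
            inner.append(sc.mean())
    return float(aucs.mean()), aucs, (float(np.mean(inner)) if inner else None)


def sliding_window_auc(
    znorm: RateMatrix,
    labels: np.ndarray,
    spec: DecoderSpec | None = None,
    seed: int = 0,
    trial_idx: np.ndarray | None = None,
    unit_idx: np.ndarray | None = None,
    starts: np.ndarray | None = None,
) -> DecodeTrace:
    """AUC trajectory of the sliding-window decoder."""
    spec = spec or DecoderSpec()
    labels = np.asarray(labels)
    if trial_idx is None:
        trial_idx = np.arange(znorm.values.shape[1])
    if starts is None:
        starts = window_starts(znorm, spec)
    n_w = len(starts)
    auc_rep = np.empty((spec.n_repetitions, n_w))
    inner = np.full(n_w, np.nan)
    for w, s in enumerate(starts):
        X = feature_matrix(znorm, s, spec.window_ms, unit_idx)[trial_idx]
        mean_auc, reps, icv = decode_features_auc(
            X, labels[trial_idx], spec, seed=seed + 1000 * w
        )
        auc_rep[:, w] = reps
        if icv is not None:
            inner[w] = icv
    return DecodeTrace(
        window_centers=starts + spec.window_ms / 2.0,
        auc_mean=auc_rep.mean(axis=0),
        auc_se=auc_rep.std(axis=0, ddof=1) / np.sqrt(spec.n_repetitions),
        auc_per_rep=auc_rep,
        inner_cv_auc=inner if spec.inner_cv else None,
    )


def significance_runs(p: np.ndarray, alpha: float, min_run: int = 5) -> np.ndarray:
    """Mask of windows belonging to a run of >= min_run consecutive p < alpha."""
    sig = np.asarray(p) < alpha
    out = np.zeros_like(sig)
    i = 0
    n = len(sig)
    while i < n:
        if sig[i]:
            j = i
            while j < n and sig[j]:
                j += 1
            if j - i >= min_run:
                out[i:j] = True
            i = j
        else:
            i += 1
    return out


def permutation_null(
    znorm: RateMatrix,
    labels: np.ndarray,
    trace: DecodeTrace,
    spec: DecoderSpec | None = None,
    seed: int = 0,
    n_shuffle: int = 250,
    alpha: float = 0.05,
    min_run: int = 5,
    trial_idx: np.ndarray | None = None,
    unit_idx: np.ndarray | None = None,
) -> DecodeTrace:
    """Attach a label-shuffle null and per-window p-values to a trace.

    The null distribution per window comes from ``n_shuffle`` decoding
    runs with the trial labels randomly permuted (one split each). The
    observed mean AUC is compared one-sidedly against the empirical null
    with +1 smoothing; windows in runs of >= ``min_run`` consecutive
    significant windows are flagged.
    """
    spec = spec or DecoderSpec()
    labels = np.asarray(labels)
    if trial_idx is None:
        trial_idx = np.arange(znorm.values.shape[1])
    rng = np.random.default_rng(seed)
    starts = trace.window_centers - spec.window_ms / 2.0
    one_rep = DecoderSpec(**{**spec.__dict__, "n_repetitions": 1})
    null = np.empty((n_shuffle, len(starts)))
    feats = [
        feature_matrix(znorm, s, spec.window_ms, unit_idx)[trial_idx] for s in starts
    ]
    y = labels[trial_idx]
    for k in range(n_shuffle):
        y_perm = rng.permutation(y)
        sub_seed = int(rng.integers(2**31 - 1))
        for w, X in enumerate(feats):
            null[k, w], _, _ = decode_features_auc(X, y_perm, one_rep, seed=sub_seed)
    p = (1 + (null >= trace.auc_mean[None, :]).sum(axis=0)) / (1 + n_shuffle)
    trace.null_auc = null
    trace.p_values = p
    trace.significant = significance_runs(p, alpha, min_run)
    return trace


# ---------------------------------------------------------------------------
# best-bin / LOO probability decoding (flash suppression, rivalry)

def best_bin(
    znorm: RateMatrix,
    labels: np.ndarray,
    spec: DecoderSpec | None = None,
    seed: int = 0,
    trial_idx: np.ndarray | None = None,
    unit_idx: np.ndarray | None = None,
    t_min: float = 0.0,
    t_max: float | None = None,
) -> tuple[float, DecodeTrace]:
    """Window start with the highest face-vs-place AUC after onset."""
    spec = spec or DecoderSpec()
    starts = window_starts(znorm, spec, t_min=t_min, t_max=t_max)
    trace = sliding_window_auc(
        znorm, labels, spec, seed, trial_idx, unit_idx, starts
    )
    best = int(np.argmax(trace.auc_mean))
    tied = np.flatnonzero(trace.auc_mean >= trace.auc_mean[best] - 1e-9)
    if tied.size > 1:
        # several windows saturate the AUC; prefer the one with the widest
        # feature-space margin between the classes
        if trial_idx is None:
            trial_idx = np.arange(znorm.values.shape[1])
        y = np.asarray(labels)[trial_idx]
        classes = np.unique(y)
        margins = []
        for w in tied:
            X = feature_matrix(znorm, starts[w], spec.window_ms, unit_idx)[trial_idx]
            mu = [X[y == c].mean(axis=0) for c in classes[:2]]
            sd = X.std(axis=0).mean() + 1e-12
            margins.append(float(np.linalg.norm(mu[0] - mu[1]) / sd))
        best = int(tied[int(np.argmax(margins))])
    return float(starts[best]), trace


def best_bin_loo_probability(
    znorm: RateMatrix,
    labels: np.ndarray,
    trial_idx: np.ndarray,
    spec: DecoderSpec | None = None,
    seed: int = 0,
    unit_idx: np.ndarray | None = None,
    best_start: float | None = None,
    return_models: bool = False,
):
    """Leave-one-out face-probability trajectories from best-bin training.

    For each held-out trial the classifier is fit on the best-bin features
    of all other trials and then emits the face probability for every
    sliding window of the held-out trial. Because training uses one bin
    but testing spans all bins, the baseline face probability is not
    guaranteed to center on 0.5; it is measured over the pre-stimulus
    windows and stored for baseline subtraction.
    """
    spec = spec or DecoderSpec()
    labels = np.asarray(labels)
    trial_idx = np.asarray(trial_idx)
    if len(trial_idx) < 3:
        raise ValueError("LOO probability decoding needs >= 3 trials")
    if best_start is None:
        best_start, _ = best_bin(
            znorm, labels, spec, seed, trial_idx, unit_idx
        )
    Xbest = feature_matrix(znorm, best_start, spec.window_ms, unit_idx)[trial_idx]
    y = labels[trial_idx]
    starts = window_starts(znorm, spec)
    feats_all = np.stack(
        [
            feature_matrix(znorm, s, spec.window_ms, unit_idx)[trial_idx]
            for s in starts
        ],
        axis=1,
    )  # (trials, windows, units)
    n = len(trial_idx)
    probs = np.empty((n, len(starts)))
    models = []
    for i in range(n):
        keep = np.arange(n) != i
        model = make_classifier(spec, seed=seed)
        model.fit(Xbest[keep], y[keep])
        pos = list(model.classes_).index(spec.positive_class)
        probs[i] = model.predict_proba(feats_all[i])[:, pos]
        if return_models:
            models.append(model)
    centers = starts + spec.window_ms / 2.0
    base_w = centers + spec.window_ms / 2.0 <= 0  # windows fully pre-stimulus
    baseline = float(probs[:, base_w].mean()) if base_w.any() else 0.5
    traj = ProbabilityTrajectory(centers, probs, trial_idx, best_start, baseline)
    return (traj, models) if return_models else traj


# ---------------------------------------------------------------------------
# rivalry

def _alternation_epochs(trials: pd.DataFrame, idx: np.ndarray) -> list[tuple[int, float, str]]:
    """(trial index, epoch onset ms, class) for 1 Hz alternation trials."""
    out = []
    for i in idx:
        path = json.loads(trials.iloc[i]["display_path"])
        for onset, cls in path:
            out.append((int(i), float(onset), str(cls)))
    return out


def rivalry_probability(
    znorm: RateMatrix,
    trials: pd.DataFrame,
    spec: DecoderSpec | None = None,
    seed: int = 0,
    unit_idx: np.ndarray | None = None,
    n_ensemble: int = 10,
    step_ms: float | None = None,
) -> ProbabilityTrajectory:
    """Face-probability trajectories for rivalrous trials.

    The classifier is trained exclusively on non-rivalrous data: binocular
    face/place trials plus every 1 Hz alternation epoch as an additional
    labeled sample (each epoch contributes the best-bin window re-anchored
    to the epoch onset). From the LOO ensemble of trained decoders,
    ``n_ensemble`` are drawn at random and their face probabilities for
    every window of every rivalrous trial are averaged.
    """
    spec = spec or DecoderSpec()
    if step_ms is not None:
        spec = DecoderSpec(**{**spec.__dict__, "step_ms": step_ms})
    cond = trials["condition"].to_numpy()
    binoc = np.flatnonzero(np.isin(cond, ["FACE_BINOC", "PLACE_BINOC"]))
    alt = np.flatnonzero(cond == "ALTERNATE_1HZ")
    rival = np.flatnonzero(np.isin(cond, ["RIVAL_FACE_DOM", "RIVAL_PLACE_DOM"]))
    if binoc.size < 4 or rival.size == 0:
        raise ValueError("need binocular training trials and rivalrous test trials")
    binoc_labels = np.where(cond[binoc] == "FACE_BINOC", "face", "place")

    bb, _ = best_bin(
        znorm,
        trials["condition"].map({"FACE_BINOC": "face", "PLACE_BINOC": "place"}).to_numpy(),
        spec,
        seed,
        binoc,
        unit_idx,
        t_min=0.0,
        t_max=1000.0,
    )
    # training samples: binocular trials at the best bin + alternation epochs
    Xs, ys = [], []
    for i, lab in zip(binoc, binoc_labels):
        Xs.append(feature_matrix(znorm, bb, spec.window_ms, unit_idx)[i])
        ys.append(lab)
    t_end = znorm.t_start + znorm.n_bins * znorm.bin_width
    for i, onset, cls in _alternation_epochs(trials, alt):
        s = onset + bb
        if s + spec.window_ms <= t_end:
            Xs.append(feature_matrix(znorm, s, spec.window_ms, unit_idx)[i])
            ys.append(cls)
    X = np.asarray(Xs)
    y = np.asarray(ys)
    n = len(y)
    rng = np.random.default_rng(seed)
    models = []
    for i in range(n):  # LOO ensemble on the non-rivalrous training set
        keep = np.arange(n) != i
        m = make_classifier(spec, seed=seed)
        m.fit(X[keep], y[keep])
        models.append(m)
    chosen = rng.choice(n, size=min(n_ensemble, n), replace=False)
    starts = window_starts(znorm, spec)
    feats = np.stack(
        [feature_matrix(znorm, s, spec.window_ms, unit_idx)[rival] for s in starts],
        axis=1,
    )  # (rival trials, windows, units)
    probs = np.zeros((len(rival), len(starts)))
    for k in chosen:
        m = models[k]
        pos = list(m.classes_).index(spec.positive_class)
        for j in range(len(rival)):
            probs[j] += m.predict_proba(feats[j])[:, pos]
    probs /= len(chosen)
    centers = starts + spec.window_ms / 2.0
    base_w = centers + spec.window_ms / 2.0 <= 0
    baseline = float(probs[:, base_w].mean()) if base_w.any() else 0.5
    return ProbabilityTrajectory(centers, probs, rival, bb, baseline)


def rivalry_probability_density(
    traj: ProbabilityTrajectory,
    trials: pd.DataFrame,
    grid: np.ndarray | None = None,
) -> dict:
    """Median-centered probability densities for Face-Dom vs Place-Dom.

    Probabilities from all non-overlapping 150 ms bins of all rivalrous
    trials are pooled after subtracting the array-wise median, then a
    Gaussian KDE is evaluated per dominance condition.
    """
    cond = trials["condition"].to_numpy()[traj.trial_idx]
    pooled = traj.probabilities
    med = float(np.median(pooled))
    centered = pooled - med
    if grid is None:
        grid = np.linspace(-0.7, 0.7, 281)
    out = {"grid": grid, "median": med}
    for name, label in (("face_dom", "RIVAL_FACE_DOM"), ("place_dom", "RIVAL_PLACE_DOM")):
        sample = centered[cond == label].ravel()
        out[name] = (
            stats.gaussian_kde(sample)(grid) if sample.size > 1 else np.zeros_like(grid)
        )
        out[name + "_sample"] = sample
    return out


def window_probability_test(
    traj: ProbabilityTrajectory,
    group1: np.ndarray,
    group2: np.ndarray,
    response_window: tuple[float, float],
    n_perm: int = 10000,
    seed: int = 0,
) -> dict:
    """One-sided permutation test of per-trial probabilities between groups.

    Uses the window whose center is nearest the response-window center
    (the 150 ms bin "spanning" the response window); tests mean(group1) >
    mean(group2) by label permutation.
    """
    center = (response_window[0] + response_window[1]) / 2.0
    w = int(np.argmin(np.abs(traj.window_centers - center)))
    # positions within the trajectory's trial set
    pos = {t: i for i, t in enumerate(traj.trial_idx)}
    x1 = traj.probabilities[[pos[t] for t in group1], w]
    x2 = traj.probabilities[[pos[t] for t in group2], w]
    obs = x1.mean() - x2.mean()
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([x1, x2])
    n1 = len(x1)
    null = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(pooled)
        null[k] = perm[:n1].mean() - perm[n1:].mean()
    p = (1 + (null >= obs).sum()) / (1 + n_perm)
    return {
        "window_center": float(traj.window_centers[w]),
        "observed_diff": float(obs),
        "p_value": float(p),
    }


def press_locked_divergence(
    traj: ProbabilityTrajectory,
    trials: pd.DataFrame,
    pre_ms: float = 3000.0,
    post_ms: float = 200.0,
    alpha: float = 0.05,
    min_run: int = 3,
) -> dict:
    """Compare face probability around button presses by reported percept.

    Trajectory segments are aligned to each press; face-report and
    place-report groups are compared per lag with a one-sided t-test
    (face > place). The divergence onset is the start of the significant
    run containing the latest significant lag; its negative is the lead
    time by which the decoder anticipates the report.
    """
    lags = np.arange(-pre_ms, post_ms + 1e-9, traj.window_centers[1] - traj.window_centers[0])
    seg_face, seg_place = [], []
    for row_i, t in enumerate(traj.trial_idx):
        reports = json.loads(trials.iloc[int(t)]["reports"])
        for press, percept in reports:
            if press - pre_ms < traj.window_centers[0]:
                continue
            seg = np.interp(
                press + lags, traj.window_centers, traj.probabilities[row_i]
            )
            (seg_face if percept == "face" else seg_place).append(seg)
    seg_face = np.asarray(seg_face)
    seg_place = np.asarray(seg_place)
    if len(seg_face) < 2 or len(seg_place) < 2:
        raise ValueError("need >= 2 press-locked segments per percept")
    _, p = stats.ttest_ind(seg_face, seg_place, axis=0, alternative="greater")
    p = np.nan_to_num(p, nan=1.0)
    sig = p < alpha
    lead = None
    runs = significance_runs(p, alpha, min_run)
    if runs.any():
        last = int(np.flatnonzero(runs)[-1])
        start = last
        while start > 0 and runs[start - 1]:
            start -= 1
        lead = -float(lags[start])
    return {
        "lags_ms": lags,
        "face_mean": seg_face.mean(axis=0),
        "place_mean": seg_place.mean(axis=0),
        "p_values": p,
        "lead_ms": lead,
        "n_face": len(seg_face),
        "n_place": len(seg_place),
    }


def cross_temporal_generalization(
    znorm: RateMatrix,
    labels: np.ndarray,
    spec: DecoderSpec | None = None,
    seed: int = 0,
    trial_idx: np.ndarray | None = None,
    unit_idx: np.ndarray | None = None,
    starts: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """AUC matrix (train window x test window) under the same split rules."""
    spec = spec or DecoderSpec()
    labels = np.asarray(labels)
    if trial_idx is None:
        trial_idx = np.arange(znorm.values.shape[1])
    if starts is None:
        starts = window_starts(znorm, spec)
    y = labels[trial_idx]
    classes = _ordered_classes(y, spec)
    feats = [
        feature_matrix(znorm, s, spec.window_ms, unit_idx)[trial_idx] for s in starts
    ]
    splitter = StratifiedShuffleSplit(
        n_splits=spec.n_repetitions, test_size=spec.test_size, random_state=seed
    )
    n_w = len(starts)
    acc = np.zeros((n_w, n_w))
    for r, (tr, te) in enumerate(splitter.split(feats[0], y)):
        for i in range(n_w):
            model = fit_model(feats[i][tr], y[tr], spec, seed=seed + r)
            for j in range(n_w):
                acc[i, j] += _auc(model, feats[j][te], y[te], classes)
    acc /= spec.n_repetitions
    return acc, starts + spec.window_ms / 2.0
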