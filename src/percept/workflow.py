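"""End-to-end orchestration: config, QC validation, per-paradigm pipelines.

`run_pipeline` drives screening -> tuning -> paradigm-specific analysis ->
decoding on a (typically synthetic) session bundle and returns a nested
report dict; `save_report` writes it as JSON with a provenance block
(seed, config hash, package version). `validate_bundle` checks the
structural invariants every analysis relies on.
"""

from __future__ import annotations

import hashlib
import json
import time
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import synth
from .decoding import DecoderSpec
from .masking import (
    divergence_latency,
    group_delays,
    prestimulus_awareness_decoder,
    select_masking_selective_units,
    signal_loss,
)
from .session import (
    CONDITION_VOCABULARY,
    MASKING_DELAYS,
    ResponseWindowConfig,
    SessionBundle,
    net_rate,
    screen_responsive,
    z_normalize,
)
from .suppression import eye_dominance, identify_percept_following
from .tuning import dprime, response_latency

DEFAULT_CONFIG: dict[str, Any] = {
    "paradigm": "localizer",
    "seed": 0,
    "n_units": 20,
    "alpha_screen": 0.005,
    "decoder": {},
    "synth": {},
}


def load_config(path: str) -> dict:
    with open(path) as f:
        cfg = yaml.safe_load(f)
    merged = {**DEFAULT_CONFIG, **cfg}
    return merged


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def validate_bundle(bundle: SessionBundle) -> dict:
    """Structural QC: grid, baseline, vocabularies, count integrality."""
    violations = []
    if bundle.t_start > -300:
        violations.append("baseline interval [-300, 0) not covered")
    if not np.issubdtype(bundle.spikes.dtype, np.integer):
        violations.append("spike counts are not integers")
    if np.any(bundle.spikes < 0):
        violations.append("negative spike counts")
    paradigms = set(bundle.trials.get("paradigm", pd.Series(dtype=str)).unique())
    known = {"localizer", "category", "bcfs", "masking", "flash_suppression", "rivalry"}
    if not paradigms <= known:
        violations.append(f"unknown paradigms: {sorted(paradigms - known)}")
    if "mask_delay" in bundle.trials.columns:
        bad = set(bundle.trials["mask_delay"].dropna().astype(int)) - set(
            MASKING_DELAYS
        )
        if bad:
            violations.append(f"mask delays outside the presented set: {sorted(bad)}")
    for p, vocab in (
        ("flash_suppression", CONDITION_VOCABULARY["flash_suppression"]),
        ("rivalry", CONDITION_VOCABULARY["rivalry"]),
    ):
        sub = bundle.trials[bundle.trials.get("paradigm") == p]
        if len(sub):
            bad = set(sub["condition"]) - set(vocab)
            if bad:
                violations.append(f"{p} conditions outside vocabulary: {sorted(bad)}")
    if bundle.lfp is not None and bundle.lfp.shape[1] != bundle.n_trials:
        violations.append("LFP/spike trial-count mismatch")
    return {"ok": not violations, "violations": violations}


def _prepare(bundle: SessionBundle, windows: ResponseWindowConfig):
    net = net_rate(bundle)
    arrays = bundle.units["array"].to_numpy()
    znorm = z_normalize(net, arrays, windows)
    return net, znorm, arrays


def run_pipeline(config: dict) -> dict:
    """Generate (or load) a bundle and run the paradigm's analysis chain."""
    cfg = {**DEFAULT_CONFIG, **config}
    paradigm = cfg["paradigm"]
    seed = int(cfg["seed"])
    windows = ResponseWindowConfig()
    spec = DecoderSpec(**cfg.get("decoder", {}))
    t0 = time.time()
    report: dict[str, Any] = {
        "provenance": {
            "paradigm": paradigm,
            "seed": seed,
            "config_hash": config_hash(cfg),
        }
    }

    if "bundle_path" in cfg:
        from .session import load_bundle

        bundle = load_bundle(cfg["bundle_path"])
    elif paradigm == "bcfs":
        bundle = synth.simulate_bcfs(seed, **cfg.get("synth", {}))
    else:
        profiles = synth.make_profiles(
            cfg["n_units"],
            seed,
            classes=(
                ("face", "place")
                if paradigm in ("flash_suppression", "rivalry")
                else synth.CATEGORY_CLASSES
            ),
        )
        sim = {
            "localizer": synth.simulate_localizer,
            "masking": synth.simulate_masking,
            "flash_suppression": synth.simulate_flash_suppression,
            "rivalry": synth.simulate_rivalry,
        }[paradigm]
        bundle = sim(profiles, seed + 1, **cfg.get("synth", {}))

    report["qc"] = validate_bundle(bundle)
    if paradigm == "bcfs":
        ed = eye_dominance(bundle.trials)
        report["eye_dominance"] = {
            "dominant_eye": ed.dominant_eye,
            "mean_latency_s": ed.mean_latency_s,
            "p_value": ed.p_value,
        }
        report["provenance"]["runtime_s"] = round(time.time() - t0, 2)
        return report

    net, znorm, arrays = _prepare(bundle, windows)
    responsive, _ = screen_responsive(net, bundle.trials, cfg["alpha_screen"])
    report["screening"] = {"n_responsive": len(responsive), "n_units": bundle.n_units}
    resp = sorted(responsive - set(znorm.degenerate_units))

    if paradigm == "localizer":
        lat = [response_latency(net, u).latency_ms for u in resp]
        report["tuning"] = {
            "latencies_ms": lat,
            "n_with_latency": sum(l is not None for l in lat),
        }
        classes = sorted(bundle.trials["condition"].unique())
        if len(classes) == 2:
            g1 = np.flatnonzero(bundle.trials["condition"] == classes[1])
            g2 = np.flatnonzero(bundle.trials["condition"] == classes[0])
            ds = [
                dprime(
                    net, u, g1, g2, windows.dprime_window(int(arrays[u])), n_perm=0
                ).dprime
                for u in resp
            ]
            report["tuning"]["dprime_mean"] = float(np.mean(ds)) if ds else None
    elif paradigm == "masking":
        report["delay_groups"] = group_delays(bundle.trials, "five").counts
        sel = select_masking_selective_units(
            znorm,
            bundle.trials,
            lambda u: windows.dprime_window(int(arrays[u])),
            seed=seed,
        )
        report["n_selective"] = len(sel)
        if resp:
            arr = int(arrays[resp[0]])
            sl = signal_loss(
                znorm, resp, bundle.trials, windows.signal_loss_window(arr)
            )
            report["signal_loss_percent"] = sl.loss_percent
            dl = divergence_latency(znorm, resp, bundle.trials, seed=seed)
            report["divergence_latency_ms"] = dl.latency_ms
        report["prestimulus_auc"] = prestimulus_awareness_decoder(
            znorm, bundle.trials, spec, seed=seed
        )
    elif paradigm == "flash_suppression":
        classif = {}
        for u in resp:
            win = windows.dprime_window(int(arrays[u]))
            c = identify_percept_following(
                net, u, bundle.trials, win, seed=seed + u
            )
            classif[u] = {
                "selectivity": c.selectivity,
                "sustained": c.sustained,
                "inhibitory": c.inhibitory,
                "path1": c.percept_following_selective,
                "path2": c.percept_following_sustained,
            }
        report["classification"] = classif
        report["n_percept_following"] = sum(
            1
            for c in classif.values()
            if "yes" in (c["path1"], c["path2"])
        )
    elif paradigm == "rivalry":
        from .decoding import press_locked_divergence, rivalry_probability

        traj = rivalry_probability(znorm, bundle.trials, spec, seed=seed)
        div = press_locked_divergence(traj, bundle.trials)
        report["rivalry"] = {
            "baseline_probability": traj.baseline_probability,
            "lead_ms": div["lead_ms"],
            "n_press_face": div["n_face"],
            "n_press_place": div["n_place"],
        }

    report["provenance"]["runtime_s"] = round(time.time() - t0, 2)
    return report


def save_report(report: dict, path: str) -> None:
    def default(o):
        if isinstance(o, np.generic):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    with open(path, "w") as f:
        json.dump(report, f, indent=1, default=default)
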