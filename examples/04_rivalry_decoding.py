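"""Binocular-rivalry decoding from non-rivalrous training data.

Trains LOO decoders on binocular and 1 Hz-alternation epochs only, scores
the rivalrous trials, and shows that the decoded face probability
diverges ahead of the button press by the programmed perceptual lead.
"""

import percept
from percept.decoding import DecoderSpec
from percept.synth import UnitProfile

profiles = [
    UnitProfile(baseline=5.0, latency=90.0, amplitudes={"face": 40.0, "place": 5.0},
                sustain=0.8, array=2)
    for _ in range(6)
] + [
    UnitProfile(baseline=5.0, latency=90.0, amplitudes={"face": 5.0, "place": 40.0},
                sustain=0.8, array=2)
    for _ in range(6)
]
bundle = percept.simulate_rivalry(profiles, seed=9, n_trials_per_condition=10)
net = percept.net_rate(bundle)
znorm = percept.z_normalize(net, bundle.units["array"].to_numpy())

traj = percept.rivalry_probability(znorm, bundle.trials, DecoderSpec(step_ms=50), seed=0)
print(f"decoder baseline face probability: {traj.baseline_probability:.2f} "
      "(not forced to 0.50 by the best-bin LOO scheme)")

div = percept.press_locked_divergence(traj, bundle.trials)
print(
    f"face-report vs place-report trajectories diverge {div['lead_ms']:.0f} ms "
    f"before the button press ({div['n_face']} face and {div['n_place']} place "
    "press-locked segments)"
)
print("the generator switches firing to the new percept 1500 ms before each press,")
print("so the decoder reads out the upcoming percept well ahead of the report.")

dens = percept.rivalry_probability_density(traj, bundle.trials)
fd = dens["face_dom_sample"].mean()
pd_ = dens["place_dom_sample"].mean()
print(
    f"\nmedian-centered probability mean, face-dominant-eye trials: {fd:+.3f}; "
    f"place-dominant-eye trials: {pd_:+.3f}"
)
print("a positive gap means the dominant-eye stimulus wins more viewing time.")
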