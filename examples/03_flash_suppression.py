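"""Flash-suppression responder taxonomy and percept probability decoding.

Classifies units as face/place selective, sustained, inhibitory, and
percept-following, then decodes the face probability per trial with the
best-bin leave-one-out decoder to show that perceptual shifts through
flash suppression drive weaker responses than real alternation.
"""

import numpy as np

import percept
from percept.decoding import DecoderSpec
from percept.synth import UnitProfile

profiles = [
    UnitProfile(
        baseline=5.0,
        latency=90.0,
        amplitudes={"face": 45.0, "place": 8.0},
        sustain=0.7,
        percept_gain=0.6,
        suppression_residual=0.1,
        array=2,
    )
    for _ in range(8)
]
bundle = percept.simulate_flash_suppression(profiles, seed=2, n_trials_per_condition=30)
net = percept.net_rate(bundle)
znorm = percept.z_normalize(net, bundle.units["array"].to_numpy())

print("unit  selective  sustained  inhibitory  follows-percept")
for u in range(bundle.n_units):
    c = percept.identify_percept_following(net, u, bundle.trials, (130, 280), seed=u)
    follows = "yes" in (c.percept_following_selective, c.percept_following_sustained)
    print(
        f"{u:4d}  {c.selectivity:>9}  {str(c.sustained):>9}"
        f"  {str(c.inhibitory):>10}  {follows}"
    )

labels = bundle.trials["phase1_class"].to_numpy()
traj = percept.best_bin_loo_probability(
    znorm, labels, np.arange(len(labels)), DecoderSpec(step_ms=50), seed=0
)
cond = bundle.trials["condition"].to_numpy()
w2 = (traj.window_centers >= 1100) & (traj.window_centers <= 1400)
print(f"\nbest decoding bin starts at {traj.best_window_start:.0f} ms after onset")
print("mean decoded face probability in phase 2 (1100-1400 ms):")
for c in ("CON_P", "FS_PF", "RA_PF", "CON_F"):
    print(f"  {c:6s}: {traj.probabilities[cond == c][:, w2].mean():.2f}")
print(
    "The newly perceived face (FS P->F) lifts the face probability above "
    "continued place viewing but below real alternation: the perceptual "
    "shift drives a real but weaker response (percept gain < 1)."
)
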