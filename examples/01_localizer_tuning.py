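"""Tuning characterization of a simulated localizer session.

Generates units viewing scrambled vs non-scrambled images for 300 ms,
screens for visual responsiveness, and reports response latency,
selectivity latency, and the d-prime discriminability index per unit.
"""

import numpy as np

import percept
from percept.synth import UnitProfile

profiles = [
    UnitProfile(
        baseline=4.0,
        latency=L,
        amplitudes={"nonscrambled": 80.0, "scrambled": 20.0},
        sustain=0.6,
        array=3,
    )
    for L in (85.0, 135.0, 135.0, 255.0)
]
bundle = percept.simulate_localizer(profiles, seed=1, n_trials_per_class=50)
net = percept.net_rate(bundle)
arrays = bundle.units["array"].to_numpy()

responsive, _ = percept.screen_responsive(net, bundle.trials)
print(f"visually responsive units: {sorted(responsive)} of {bundle.n_units}")

g1 = np.flatnonzero(bundle.trials["condition"] == "nonscrambled")
g2 = np.flatnonzero(bundle.trials["condition"] == "scrambled")
print("\nunit  true-L  resp-latency  select-latency  d'     perm-p")
for u in sorted(responsive):
    rl = percept.response_latency(net, u).latency_ms
    sl = percept.selectivity_latency(net, u, g1, g2).latency_ms
    d = percept.dprime(net, u, g1, g2, (130, 280), seed=u)
    print(
        f"{u:4d}  {profiles[u].latency:6.0f}  {str(rl):>12}  {str(sl):>14}"
        f"  {d.dprime:5.2f}  {d.p_value:.3f}"
    )

print(
    "\nLatencies are bin midpoints from the 3-consecutive-bin run criterion; "
    "positive d' means stronger responses to non-scrambled images, with "
    "significance from 1000 label permutations."
)
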