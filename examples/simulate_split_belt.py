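"""Simulate one split-belt condition in the hemisected model.

Builds the right-hemisected circuit (right supraspinal drives removed),
runs 50 s of left-slow/right-fast locomotion (betaL = 0.4, betaR = 1.0)
and prints per-side cycle, stance and swing durations and the duty factor.
A duty factor below 50% on the right side means the ipsilesional hindlimb
spends more time in swing than in stance -- the model's headline split-belt
prediction.
"""

from hemigait import ModelConfig, build_network, integrate
from hemigait.phases import analyze_result

config = ModelConfig()
network = build_network("hemisected", config.circuit)
result = integrate(network, (0.4, 1.0), config)

print("hemisected model, betaL = 0.4 (contralesional), betaR = 1.0 (ipsilesional)")
for side in ("left", "right"):
    s = analyze_result(result, side, config)
    print(
        f"  {side:5s}: cycle {s['cycle_mean']:.3f} s, "
        f"stance {s['stance_mean']:.3f} s, swing {s['swing_mean']:.3f} s, "
        f"duty {100 * s['duty_mean']:.1f}% over {s['n_cycles']} cycles"
    )
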