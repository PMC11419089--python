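"""Tied-belt speed sweeps before and after hemisection.

Runs the intact and right-hemisected models across treadmill speeds
0.4-1.0 m/s (equal belts) and prints the right-hindlimb phase durations.
After hemisection the ipsilesional stance shortens and swing lengthens --
the loss of presynaptic inhibition lets the speed-dependent hip-flexor
stretch feedback trigger the stance-to-swing transition earlier.
"""

from hemigait import ModelConfig, run_sweep

config = ModelConfig()
for condition in ("intact", "hemisected"):
    sweep = run_sweep(condition, "tied", config, grid_step=0.2)
    right = sweep[sweep["side"] == "right"]
    print(f"{condition} (right hindlimb):")
    for _, row in right.iterrows():
        print(
            f"  belt {row.betaL:.1f} m/s: cycle {row.cycle_mean:.2f} s, "
            f"stance {row.stance_mean:.2f} s, swing {row.swing_mean:.2f} s"
        )
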