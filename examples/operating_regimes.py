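"""Operating regime of a single rhythm generator versus supraspinal drive.

An isolated rhythm generator (no commissural input, no feedback) is probed
at increasing drive: at low drive it is a non-oscillatory state machine
(feedback must trigger each flexion), at moderate drive intrinsic
persistent-sodium bursting of the flexor half-center paces the rhythm, and
at high drive the oscillation requires the mutual inhibition of the two
half-centers.
"""

from hemigait import ModelConfig
from hemigait.phases import classify_regime

config = ModelConfig()
for alpha in (0.0, 0.2, 0.35, 0.5, 0.7):
    print(f"alpha = {alpha:.2f}: {classify_regime(alpha, config)}")
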