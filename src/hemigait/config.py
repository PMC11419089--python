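"""Bundled model configuration (weights, gains, protocol and solver settings).

One JSON-serialisable object carries everything needed to reproduce a
simulation: circuit weights, feedback gains, the speed-to-drive mapping and
integrator settings.  Round-trips through JSON exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

from .network import CircuitParams
from .feedback import FeedbackGains, THETA_SW, HYSTERESIS

__all__ = ["ModelConfig"]


@dataclass(frozen=True)
class ModelConfig:
    """Full configuration of the model and its simulation protocol."""

    circuit: CircuitParams = field(default_factory=CircuitParams)
    gains: FeedbackGains = field(default_factory=FeedbackGains)
    # speed-to-drive mapping: alpha = max(0, a0 + a1 * beta); gamma constant
    a0: float = -0.017
    a1: float = 0.717
    gamma: float = 0.5
    # integrator / protocol settings
    duration_ms: float = 50_000.0
    transient_ms: float = 10_000.0
    dt_ms: float = 0.1
    record_every_ms: float = 1.0
    theta_sw: float = THETA_SW
    hysteresis: float = HYSTERESIS

    def to_json(self) -> str:
        doc = asdict(self)
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        doc = json.loads(text)
        doc["circuit"] = CircuitParams(**doc["circuit"])
        doc["gains"] = FeedbackGains(**doc["gains"])
        return cls(**doc)
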