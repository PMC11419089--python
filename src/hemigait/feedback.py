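"""Limb-state bookkeeping and stance-phase sensory feedback.

Two feedback signals are generated per hindlimb, both active only during
the ipsilateral stance (extensor) phase:

* **SF-E1** models length-dependent feedback from hip-flexor muscle
  spindles.  During stance the hip extends in proportion to belt
  displacement, so SF-E1 rises as a ramp whose slope is the belt-speed
  parameter beta; it promotes the stance-to-swing transition by exciting
  the ipsilateral flexor half-center (and inhibiting the contralateral
  one).
* **SF-E2** models force-dependent group Ib feedback from extensor
  muscles, taken proportional to the ipsilateral extensor half-center
  output (the available load proxy); it reinforces extension and weight
  support.

Supraspinal drive presynaptically inhibits all ipsilateral feedback: the
transmitted fraction is ``max(0, 1 - kPSI * alpha)``, so a hemisected side
(alpha = 0) receives its feedback at full gain.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = [
    "LimbState",
    "FeedbackGains",
    "FeedbackSignal",
    "THETA_SW",
    "HYSTERESIS",
    "update_limb",
    "compute_feedback",
    "presynaptic_gain",
]

#: flexor-output threshold separating swing (above) from stance (below)
THETA_SW = 0.1
#: hysteresis half-band around THETA_SW preventing chatter at burst edges
HYSTERESIS = 0.05


@dataclass(frozen=True)
class FeedbackGains:
    """Feedback gains and presynaptic-inhibition coefficient.

    Calibration parameters: with alpha = 0 the feedback alone must sustain
    state-machine stepping, while at alpha >= 0.35 presynaptic inhibition
    must render the feedback influence small.
    """

    kE1: float = 0.65   # SF-E1 units per unit stance progress
    kE2: float = 1.0    # SF-E2 units per unit extensor output
    kPSI: float = 3.5   # presynaptic-inhibition slope per unit drive


@dataclass(frozen=True)
class LimbState:
    """Phase and stance-progress coordinate of one hindlimb.

    ``s`` is the dimensionless belt displacement accumulated since stance
    onset (time in seconds times beta); it resets to 0 at each stance onset
    and is frozen during swing.
    """

    side: str                   # "left" | "right"
    phase: str = "stance"       # "stance" | "swing"
    s: float = 0.0
    t_phase_onset: float = 0.0  # ms

    def __post_init__(self) -> None:
        if self.phase not in ("stance", "swing"):
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.s < 0:
            raise ValueError("stance progress s must be >= 0")


@dataclass(frozen=True)
class FeedbackSignal:
    """Current values of the four feedback channels, pre-synaptically scaled."""

    sfE1_L: float = 0.0
    sfE1_R: float = 0.0
    sfE2_L: float = 0.0
    sfE2_R: float = 0.0

    def as_dict(self) -> dict[str, float]:
        return {
            "SF-E1-L": self.sfE1_L,
            "SF-E1-R": self.sfE1_R,
            "SF-E2-L": self.sfE2_L,
            "SF-E2-R": self.sfE2_R,
        }


def update_limb(
    limb: LimbState,
    beta: float,
    flexor_out: float,
    dt: float,
    t: float = 0.0,
    theta_sw: float = THETA_SW,
    hysteresis: float = HYSTERESIS,
) -> LimbState:
    """Advance the limb state by one time step ``dt`` (ms).

    The limb is in swing while the ipsilateral flexor output exceeds the
    phase threshold (with hysteresis: swing entered above
    ``theta_sw + hysteresis``, left below ``theta_sw - hysteresis``).
    During stance the progress coordinate integrates ``ds/dt = beta``
    (time in seconds); on the swing-to-stance transition ``s`` resets to 0;
    during swing ``s`` is frozen.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if beta < 0:
        raise ValueError("belt-speed parameter beta must be >= 0")
    if limb.phase == "stance":
        s = limb.s + beta * dt * 1e-3
        if flexor_out > theta_sw + hysteresis:
            return replace(limb, phase="swing", s=s, t_phase_onset=t + dt)
        return replace(limb, s=s)
    # swing: s frozen
    if flexor_out < theta_sw - hysteresis:
        return replace(limb, phase="stance", s=0.0, t_phase_onset=t + dt)
    return limb


def compute_feedback(
    limb: LimbState,
    beta: float,
    extensor_out: float,
    gains: FeedbackGains,
) -> tuple[float, float]:
    """Raw (un-scaled) feedback pair ``(sfE1, sfE2)`` for one limb.

    During stance ``sfE1 = kE1 * s`` (a ramp rising at rate ``kE1 * beta``
    per second) and ``sfE2 = kE2 * extensor_out``; during swing both are 0.
    """
    if limb.phase == "swing":
        return 0.0, 0.0
    return gains.kE1 * limb.s, gains.kE2 * max(0.0, extensor_out)


def presynaptic_gain(alpha: float, kPSI: float) -> float:
    """Transmitted fraction of ipsilateral feedback under drive ``alpha``.

    ``max(0, 1 - kPSI * alpha)``: monotone nonincreasing in alpha, 1 at
    alpha = 0 (hemisected side: feedback at full gain), 0 once
    ``kPSI * alpha >= 1``.
    """
    if alpha < 0 or kPSI < 0:
        raise ValueError("alpha and kPSI must be >= 0")
    return max(0.0, 1.0 - kPSI * alpha)
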