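"""Synthetic cat step-cycle datasets with the study's repeated-measures design.

The experimental recordings behind the hemisection study (cats walking on a
tied-belt or split-belt treadmill before and 7-8 weeks after a right
thoracic lateral hemisection) are not deposited; this module generates
datasets with the same design -- cat x state x speed x cycle, speeds
0.4-1.0 m/s in 0.1 m/s steps (fast belt 0.5-1.0 in the split protocols),
5 cats in the tied-belt protocol and 6 in the split-belt protocols -- so
the statistical stage can be exercised and calibrated.

Per-cycle stance and swing durations are drawn around speed-dependent
baseline curves (hyperbolic in speed, the standard shape for cat cycle
duration) with a cat-level multiplicative random effect shared across
states and additive cycle-to-cycle residuals.  Hemisection effects are
applied to the per-side means either as multiplicative shifts of stance
and swing or as a cycle-preserving transfer of duration from stance to
swing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SideEffect",
    "EffectConfig",
    "generate_cat_dataset",
    "predicted_effect_config",
    "null_effect_config",
    "TIED_SPEEDS",
    "SPLIT_SPEEDS",
]

TIED_SPEEDS = tuple(np.round(np.arange(0.4, 1.01, 0.1), 10))
SPLIT_SPEEDS = tuple(np.round(np.arange(0.5, 1.01, 0.1), 10))
_SLOW_BELT = 0.4

STATES = ("intact", "hemisected")


@dataclass(frozen=True)
class SideEffect:
    """Hemisection effect on one side's mean durations.

    ``stance_mult``/``swing_mult`` scale the phase means; ``transfer``
    moves that fraction of the cycle duration from stance to swing,
    leaving the cycle mean exactly unchanged.
    """

    stance_mult: float = 1.0
    swing_mult: float = 1.0
    transfer: float = 0.0

    def apply(self, stance: float, swing: float) -> tuple[float, float]:
        cycle = stance + swing
        return (
            self.stance_mult * stance - self.transfer * cycle,
            self.swing_mult * swing + self.transfer * cycle,
        )


@dataclass(frozen=True)
class EffectConfig:
    """Design and noise parameters of one synthetic protocol dataset."""

    protocol: str = "tied"        # tied | lsrf | lfrs
    # baseline curves: cycle T0(v) = c0 + c1/v, stance S0(v) = d0 + d1/v
    c0: float = 0.31667
    c1: float = 0.23333
    d0: float = 0.06833
    d1: float = 0.20667
    effects: dict = field(
        default_factory=lambda: {"left": SideEffect(), "right": SideEffect()}
    )
    cat_rel_sd: float = 0.05      # SD of the per-cat multiplicative intercept
    resid_sd: float = 0.02        # s, per-cycle additive residual per phase
    n_cats: int | None = None     # default: 5 (tied), 6 (split)
    n_cycles: int = 15
    min_duration: float = 0.1     # s, truncation floor for each phase

    def __post_init__(self) -> None:
        if self.protocol not in ("tied", "lsrf", "lfrs"):
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if self.cat_rel_sd < 0 or self.resid_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.n_cats is not None and self.n_cats < 2:
            raise ValueError("need n_cats >= 2 for a repeated-measures design")
        for side in ("left", "right"):
            if side not in self.effects:
                raise ValueError(f"missing effect specification for side {side!r}")
        for speed in self.speeds:
            for side in ("left", "right"):
                s0, w0 = self.baseline(side, speed)
                s1, w1 = self.effects[side].apply(s0, w0)
                for val, name in ((s1, "stance"), (w1, "swing")):
                    if val <= self.min_duration:
                        raise ValueError(
                            f"effect configuration implies {name} <= "
                            f"{self.min_duration} s on the {side} side at "
                            f"{speed} m/s"
                        )

    @property
    def speeds(self) -> tuple[float, ...]:
        return TIED_SPEEDS if self.protocol == "tied" else SPLIT_SPEEDS

    @property
    def default_n_cats(self) -> int:
        if self.n_cats is not None:
            return self.n_cats
        return 5 if self.protocol == "tied" else 6

    def belt_speed(self, side: str, sweep_speed: float) -> float:
        """The belt speed under the given side at one sweep point."""
        if self.protocol == "tied":
            return sweep_speed
        if self.protocol == "lsrf":
            return _SLOW_BELT if side == "left" else sweep_speed
        return sweep_speed if side == "left" else _SLOW_BELT

    def baseline(self, side: str, sweep_speed: float) -> tuple[float, float]:
        """Intact mean (stance, swing) for one side at one sweep point."""
        v = self.belt_speed(side, sweep_speed)
        cycle = self.c0 + self.c1 / v
        stance = self.d0 + self.d1 / v
        return stance, cycle - stance


def null_effect_config(protocol: str = "tied", **kw) -> EffectConfig:
    """No hemisection effect anywhere (basis for type-I-error calibration)."""
    return EffectConfig(protocol=protocol, **kw)


def predicted_effect_config(protocol: str) -> EffectConfig:
    """Effects encoding the qualitative hemisection directions that the
    circuit model predicts for each protocol.

    tied: on the ipsilesional (right) side duration is transferred from
    stance to swing (shorter stance, longer swing, unchanged cycle), the
    contralesional side is unchanged.  Left slow/right fast: contralesional
    stance (and hence cycle) lengthens; ipsilesional stance shortens and
    swing lengthens enough to lengthen the cycle.  Left fast/right slow:
    only a small ipsilesional stance-to-swing transfer.
    """
    if protocol == "tied":
        effects = {"left": SideEffect(), "right": SideEffect(transfer=0.10)}
    elif protocol == "lsrf":
        effects = {
            "left": SideEffect(stance_mult=1.15),
            "right": SideEffect(stance_mult=0.85, swing_mult=1.35),
        }
    elif protocol == "lfrs":
        effects = {"left": SideEffect(), "right": SideEffect(transfer=0.08)}
    else:
        raise ValueError(f"unknown protocol {protocol!r}")
    return EffectConfig(protocol=protocol, effects=effects)


def generate_cat_dataset(config: EffectConfig, seed: int = 0) -> pd.DataFrame:
    """Draw one synthetic repeated-measures dataset.

    Columns: cat, state, protocol, speed (sweep axis, m/s), betaL, betaR,
    side, cycle_index, cycle_s, stance_s, swing_s.  Deterministic under a
    fixed seed; stance + swing = cycle exactly per row.
    """
    rng = np.random.default_rng(seed)
    n_cats = config.default_n_cats
    nc = config.n_cycles
    cat_intercepts = 1.0 + rng.normal(0.0, config.cat_rel_sd, size=n_cats)

    cats, states, speeds, sides = [], [], [], []
    stance_parts, swing_parts = [], []
    for cat in range(n_cats):
        for state in STATES:
            for speed in config.speeds:
                for side in ("left", "right"):
                    s0, w0 = config.baseline(side, speed)
                    if state == "hemisected":
                        s0, w0 = config.effects[side].apply(s0, w0)
                    stance_parts.append(np.maximum(
                        config.min_duration,
                        s0 * cat_intercepts[cat] + rng.normal(0, config.resid_sd, nc),
                    ))
                    swing_parts.append(np.maximum(
                        config.min_duration,
                        w0 * cat_intercepts[cat] + rng.normal(0, config.resid_sd, nc),
                    ))
                    cats.append(f"cat{cat:02d}")
                    states.append(state)
                    speeds.append(speed)
                    sides.append(side)
    n_blocks = len(cats)
    stance = np.concatenate(stance_parts)
    swing = np.concatenate(swing_parts)
    speed_col = np.repeat(speeds, nc)
    if config.protocol == "tied":
        betaL, betaR = speed_col, speed_col
    elif config.protocol == "lsrf":
        betaL, betaR = np.full(n_blocks * nc, _SLOW_BELT), speed_col
    else:
        betaL, betaR = speed_col, np.full(n_blocks * nc, _SLOW_BELT)
    return pd.DataFrame({
        "cat": np.repeat(cats, nc),
        "state": np.repeat(states, nc),
        "protocol": config.protocol,
        "speed": speed_col,
        "betaL": betaL,
        "betaR": betaR,
        "side": np.repeat(sides, nc),
        "cycle_index": np.tile(np.arange(nc), n_blocks),
        "cycle_s": stance + swing,
        "stance_s": stance,
        "swing_s": swing,
    })
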