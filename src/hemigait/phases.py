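"""Phase-duration analysis of simulated locomotor traces.

Phase is defined on the flexor half-center output (flexion = swing,
extension = stance): swing onset is the upward crossing of the phase
threshold plus hysteresis, stance onset the downward crossing of the
threshold minus hysteresis.  Crossing times are refined by linear
interpolation between samples, cycle = stance onset to next stance onset,
stance = stance onset to swing onset, swing = cycle - stance (exact by
construction).  The module also locates the stance/swing crossing speed on
sweep summaries and classifies the operating regime of a single rhythm
generator (state-machine / flexor-driven / classical half-center).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ModelConfig
from .feedback import THETA_SW, HYSTERESIS
from .network import build_network

__all__ = [
    "PhaseEvent",
    "detect_phase_events",
    "tabulate_cycles",
    "cycle_stats",
    "analyze_result",
    "is_rhythmic",
    "find_crossing_speed",
    "classify_regime",
    "REGIMES",
]

REGIMES = ("state-machine", "flexor-driven", "half-center")

SWING_ONSET = "swing-onset"
STANCE_ONSET = "stance-onset"


@dataclass(frozen=True)
class PhaseEvent:
    t_ms: float
    kind: str  # SWING_ONSET | STANCE_ONSET


def detect_phase_events(
    trace: np.ndarray,
    t_ms: np.ndarray,
    theta_sw: float = THETA_SW,
    hysteresis: float = HYSTERESIS,
) -> list[PhaseEvent]:
    """Hysteretic threshold crossings of a flexor output trace.

    Swing onsets are upward crossings of ``theta_sw + hysteresis`` while in
    stance; stance onsets are downward crossings of ``theta_sw -
    hysteresis`` while in swing.  Crossing times are linearly interpolated
    between samples.  Events strictly alternate by construction.  A trace
    with no crossings yields an empty list (non-rhythmic), not an error.
    """
    trace = np.asarray(trace, dtype=float)
    t_ms = np.asarray(t_ms, dtype=float)
    if trace.shape != t_ms.shape:
        raise ValueError("trace and time grid must have equal length")
    if not np.all(np.isfinite(trace)):
        raise ValueError("trace contains non-finite samples")
    hi = theta_sw + hysteresis
    lo = theta_sw - hysteresis
    events: list[PhaseEvent] = []
    in_swing = trace[0] > theta_sw
    for i in range(1, len(trace)):
        a, b = trace[i - 1], trace[i]
        if not in_swing and a <= hi < b:
            frac = (hi - a) / (b - a)
            events.append(PhaseEvent(t_ms[i - 1] + frac * (t_ms[i] - t_ms[i - 1]), SWING_ONSET))
            in_swing = True
        elif in_swing and a >= lo > b:
            frac = (a - lo) / (a - b)
            events.append(PhaseEvent(t_ms[i - 1] + frac * (t_ms[i] - t_ms[i - 1]), STANCE_ONSET))
            in_swing = False
    return events


def tabulate_cycles(events: list[PhaseEvent], side: str = "") -> pd.DataFrame:
    """Per-cycle durations from an alternating event list.

    A cycle runs from one stance onset to the next; stance from its stance
    onset to the following swing onset; swing = cycle - stance exactly.
    Partial cycles at either end are discarded.  Fewer than two complete
    cycles yields an empty table.
    """
    kinds = [e.kind for e in events]
    for prev, cur in zip(kinds, kinds[1:]):
        if prev == cur:
            raise ValueError("phase events must strictly alternate")
    stance_idx = [i for i, e in enumerate(events) if e.kind == STANCE_ONSET]
    rows = []
    cycle_no = 0
    for i0, i1 in zip(stance_idx, stance_idx[1:]):
        # swing onset between the two stance onsets (guaranteed by alternation)
        t_st = events[i0].t_ms
        t_sw = events[i0 + 1].t_ms
        t_next = events[i1].t_ms
        cycle = (t_next - t_st) / 1e3
        stance = (t_sw - t_st) / 1e3
        rows.append({
            "side": side,
            "cycle_index": cycle_no,
            "cycle_s": cycle,
            "stance_s": stance,
            "swing_s": cycle - stance,
            "duty": stance / cycle,
        })
        cycle_no += 1
    if len(rows) < 2:
        rows = []
    return pd.DataFrame(
        rows, columns=["side", "cycle_index", "cycle_s", "stance_s", "swing_s", "duty"]
    )


def is_rhythmic(events: list[PhaseEvent], max_period_cv: float = 0.05) -> bool:
    """Oscillation test: at least 3 threshold crossings and relative SD of
    the period (swing onset to swing onset) below ``max_period_cv``."""
    if len(events) < 3:
        return False
    onsets = np.array([e.t_ms for e in events if e.kind == SWING_ONSET])
    if len(onsets) < 3:
        return False
    periods = np.diff(onsets)
    return float(np.std(periods) / np.mean(periods)) < max_period_cv


def cycle_stats(table: pd.DataFrame) -> dict[str, float]:
    """Mean/SD summary of a step-cycle table."""
    if table.empty:
        return {
            "n_cycles": 0,
            "cycle_mean": np.nan, "cycle_sd": np.nan,
            "stance_mean": np.nan, "stance_sd": np.nan,
            "swing_mean": np.nan, "swing_sd": np.nan,
            "duty_mean": np.nan,
        }
    return {
        "n_cycles": int(len(table)),
        "cycle_mean": float(table["cycle_s"].mean()),
        "cycle_sd": float(table["cycle_s"].std(ddof=1)),
        "stance_mean": float(table["stance_s"].mean()),
        "stance_sd": float(table["stance_s"].std(ddof=1)),
        "swing_mean": float(table["swing_s"].mean()),
        "swing_sd": float(table["swing_s"].std(ddof=1)),
        "duty_mean": float(table["duty"].mean()),
    }


def analyze_result(res, side: str, config: ModelConfig | None = None) -> dict:
    """Cycle statistics of one simulation, one side, after transient discard."""
    config = config or ModelConfig()
    pop = "RG-F-L" if side == "left" else "RG-F-R"
    keep = res.t >= res.transient_ms
    events = detect_phase_events(
        res.trace(pop)[keep], res.t[keep], config.theta_sw, config.hysteresis
    )
    table = tabulate_cycles(events, side=side)
    stats = cycle_stats(table)
    stats["rhythmic"] = is_rhythmic(events)
    return stats


def events_and_table(res, side: str, config: ModelConfig | None = None):
    """(events, step-cycle table) for one side of a simulation result."""
    config = config or ModelConfig()
    pop = "RG-F-L" if side == "left" else "RG-F-R"
    keep = res.t >= res.transient_ms
    events = detect_phase_events(
        res.trace(pop)[keep], res.t[keep], config.theta_sw, config.hysteresis
    )
    return events, tabulate_cycles(events, side=side)


def find_crossing_speed(
    sweep: pd.DataFrame, side: str, beta_col: str | None = None
) -> float | None:
    """Belt speed at which stance and swing durations first intersect.

    Linear interpolation of the first sign change of (stance - swing) along
    the sweep axis; ``None`` when the difference never changes sign.  The
    sweep axis defaults to whichever of betaR/betaL varies.
    """
    rows = sweep[sweep["side"] == side]
    if len(rows) < 2:
        raise ValueError("sweep must contain at least 2 points for the side")
    if beta_col is None:
        beta_col = "betaR" if rows["betaR"].nunique() > 1 else "betaL"
    rows = rows.sort_values(beta_col)
    beta = rows[beta_col].to_numpy(dtype=float)
    diff = (rows["stance_mean"] - rows["swing_mean"]).to_numpy(dtype=float)
    if not np.all(np.isfinite(diff)):
        raise ValueError("non-finite durations in sweep")
    for i in range(1, len(diff)):
        if diff[i] == 0.0:
            return float(beta[i])
        if diff[i - 1] * diff[i] < 0:
            frac = diff[i - 1] / (diff[i - 1] - diff[i])
            return float(beta[i - 1] + frac * (beta[i] - beta[i - 1]))
    if diff[0] == 0.0:
        return float(beta[0])
    return None


def _zero_connections(network, predicate):
    """Copy of ``network`` with weights of matching connections set to 0."""
    from dataclasses import replace
    from .network import NetworkSpec

    conns = [replace(c, weight=0.0) if predicate(c) else c for c in network.connections]
    return NetworkSpec(
        populations=network.populations,
        connections=conns,
        condition=network.condition,
        params=network.params,
    )


def classify_regime(
    alpha: float,
    config: ModelConfig | None = None,
    feedback_enabled: bool = False,
    side: str = "left",
    duration_ms: float = 30_000.0,
) -> str:
    """Operating regime of a single, isolated rhythm generator at drive
    ``alpha``.

    The RG is isolated by zeroing all commissural connections.  Decision
    procedure: (1) simulate at drive ``alpha``; if the flexor half-center
    is non-oscillatory the RG is in the *state-machine* regime (an external
    input such as sensory feedback is required to switch extension to
    flexion -- pass ``feedback_enabled=False``, the default, to probe the
    intrinsic regime).  (2) If oscillatory, re-simulate with the
    extensor-to-flexor inhibition (InE -> RG-F) silenced: if the flexor
    still bursts rhythmically the rhythm is *flexor-driven*, otherwise it
    requires mutual inhibition and the RG is in the classical
    *half-center* regime.
    """
    from .engine import integrate, DriveMap

    config = config or ModelConfig()
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    network = build_network("intact", config.circuit)
    isolated = _zero_connections(network, lambda c: c.crossed)
    drives = DriveMap(alphaL=alpha, alphaR=alpha, gammaL=config.gamma, gammaR=config.gamma)
    pop = "RG-F-L" if side == "left" else "RG-F-R"

    def _probe(net) -> bool:
        res = integrate(
            net, (0.4, 0.4), config,
            duration_ms=duration_ms, drives=drives,
            feedback_enabled=feedback_enabled,
        )
        keep = res.t >= config.transient_ms
        events = detect_phase_events(
            res.trace(pop)[keep], res.t[keep], config.theta_sw, config.hysteresis
        )
        return is_rhythmic(events)

    if not _probe(isolated):
        return "state-machine"
    no_ine = _zero_connections(
        isolated, lambda c: c.source.startswith("InE") and c.target.startswith("RG-F")
    )
    if _probe(no_ine):
        return "flexor-driven"
    return "half-center"
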