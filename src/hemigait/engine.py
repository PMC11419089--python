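"""Closed-loop simulation of the bilateral circuit over belt protocols.

The engine maps belt speeds to supraspinal drives, assembles the weight
matrices of a :class:`~hemigait.network.NetworkSpec` and integrates the
full system (populations + limb/feedback state machines) with a fixed-step
4th-order Runge-Kutta scheme, then extracts step-cycle tables per sweep
point.

Belt-speed parameters beta are dimensionless and numerically equal to the
treadmill speed in m/s (0.4-1.0), so sweep axes compare directly with the
experimental speed axes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernel
from .config import ModelConfig
from .feedback import presynaptic_gain
from .network import (
    NetworkSpec,
    build_network,
    DRIVE_SOURCES,
    FEEDBACK_SOURCES,
    h_inf,
)

__all__ = [
    "BeltProtocol",
    "DriveMap",
    "SimResult",
    "PROTOCOL_LABELS",
    "make_protocol",
    "drive_from_speed",
    "integrate",
    "run_sweep",
]

PROTOCOL_LABELS = ("tied", "lsrf", "lfrs")
_SLOW_BELT = 0.4


@dataclass(frozen=True)
class BeltProtocol:
    """A belt-speed protocol: label plus the ordered sweep grid."""

    label: str
    sweep: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if self.label not in PROTOCOL_LABELS:
            raise ValueError(
                f"unknown protocol {self.label!r}; expected one of {PROTOCOL_LABELS}"
            )
        for bL, bR in self.sweep:
            if self.label == "tied" and bL != bR:
                raise ValueError("tied protocol requires betaL == betaR")
            if self.label == "lsrf" and bL != _SLOW_BELT:
                raise ValueError("left-slow/right-fast requires betaL = 0.4")
            if self.label == "lfrs" and bR != _SLOW_BELT:
                raise ValueError("left-fast/right-slow requires betaR = 0.4")


def make_protocol(label: str, step: float = 0.05) -> BeltProtocol:
    """Build the standard sweep grid for a protocol.

    tied: betaL = betaR = 0.4..1.0; lsrf: betaL = 0.4, betaR = 0.5..1.0;
    lfrs: betaR = 0.4, betaL = 0.5..1.0.  ``step`` = 0.1 mirrors the
    experimental grid, 0.05 gives smoother simulation curves.
    """
    if label == "tied":
        lo, hi = 0.4, 1.0
        grid = np.round(np.arange(lo, hi + step / 2, step), 10)
        sweep = tuple((float(b), float(b)) for b in grid)
    elif label == "lsrf":
        grid = np.round(np.arange(0.5, 1.0 + step / 2, step), 10)
        sweep = tuple((_SLOW_BELT, float(b)) for b in grid)
    elif label == "lfrs":
        grid = np.round(np.arange(0.5, 1.0 + step / 2, step), 10)
        sweep = tuple((float(b), _SLOW_BELT) for b in grid)
    else:
        raise ValueError(f"unknown protocol {label!r}")
    return BeltProtocol(label=label, sweep=sweep)


@dataclass(frozen=True)
class DriveMap:
    """Supraspinal drive values for one simulation point."""

    alphaL: float
    alphaR: float
    gammaL: float
    gammaR: float

    def as_dict(self) -> dict[str, float]:
        return {
            "drive-alpha-L": self.alphaL,
            "drive-alpha-R": self.alphaR,
            "drive-gamma-L": self.gammaL,
            "drive-gamma-R": self.gammaR,
        }


def drive_from_speed(
    beta: float,
    side: str,
    condition: str,
    a0: float = 0.0,
    a1: float = 1.0,
) -> float:
    """Ipsilateral alpha drive compensating for belt speed.

    ``alpha = max(0, a0 + a1 * beta)`` on the intact side; a hemisected
    right side (and both sides of a transected cord) receives zero
    regardless of the mapping.
    """
    if beta < 0:
        raise ValueError("belt-speed parameter beta must be >= 0")
    if condition == "transected":
        return 0.0
    if condition == "hemisected" and side == "right":
        return 0.0
    return max(0.0, a0 + a1 * beta)


def make_drive_map(
    betaL: float, betaR: float, condition: str, config: ModelConfig
) -> DriveMap:
    """Drives for one protocol point under ``condition``."""
    gamma = config.gamma
    if condition == "transected":
        gL = gR = 0.0
    elif condition == "hemisected":
        gL, gR = gamma, 0.0
    else:
        gL = gR = gamma
    return DriveMap(
        alphaL=drive_from_speed(betaL, "left", condition, config.a0, config.a1),
        alphaR=drive_from_speed(betaR, "right", condition, config.a0, config.a1),
        gammaL=gL,
        gammaR=gR,
    )


@dataclass
class SimResult:
    """Recorded trajectory of one simulation point."""

    t: np.ndarray                  # ms, decimated grid
    out: np.ndarray                # (n_rec, n_pop) normalised outputs
    pop_ids: list[str]
    s: np.ndarray                  # (n_rec, 2) stance progress [L, R]
    limb_swing: np.ndarray         # (n_rec, 2) int8, 1 = swing
    betaL: float
    betaR: float
    condition: str
    drives: DriveMap
    dt_ms: float
    transient_ms: float
    final_V: np.ndarray = field(repr=False, default=None)
    final_h: np.ndarray = field(repr=False, default=None)

    def trace(self, pop_id: str) -> np.ndarray:
        return self.out[:, self.pop_ids.index(pop_id)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.out, columns=self.pop_ids)
        df.insert(0, "t_ms", self.t)
        return df


def _matrices(network: NetworkSpec):
    """Weight matrices and external-input maps from a network spec."""
    ids = network.population_ids
    index = {pid: i for i, pid in enumerate(ids)}
    n = len(ids)
    WE = np.zeros((n, n))
    WI = np.zeros((n, n))
    drive_w: dict[str, np.ndarray] = {src: np.zeros(n) for src in DRIVE_SOURCES}
    fbE = np.zeros((n, 4))
    fbI = np.zeros((n, 4))
    fb_col = {src: k for k, src in enumerate(FEEDBACK_SOURCES)}
    for c in network.connections:
        ti = index[c.target]
        if c.source in index:
            if c.sign == "excitatory":
                WE[ti, index[c.source]] += c.weight
            else:
                WI[ti, index[c.source]] += c.weight
        elif c.source in drive_w:
            drive_w[c.source][ti] += c.weight
        else:
            k = fb_col[c.source]
            if c.sign == "excitatory":
                fbE[ti, k] += c.weight
            else:
                fbI[ti, k] += c.weight
    return index, WE, WI, drive_w, fbE, fbI


def _param_arrays(network: NetworkSpec):
    pops = network.populations
    get = lambda attr: np.array([getattr(p, attr) for p in pops], dtype=float)
    return dict(
        is_burster=np.array([p.kind == "burster" for p in pops]),
        C=get("C"), gNaP=get("gNaP"), gL=get("gL"), ENa=get("ENa"),
        EL=get("EL"), Vm_half=get("Vm_half"), km=get("km"),
        Vh_half=get("Vh_half"), kh=get("kh"), tau0=get("tau0"),
        Vtau=get("Vtau"), ktau=get("ktau"),
        Vout_min=get("Vout_min"), Vout_max=get("Vout_max"),
    )


def default_initial_state(network: NetworkSpec) -> tuple[np.ndarray, np.ndarray]:
    """Antisymmetric seed selecting the alternating-gait branch: the left
    flexor half-center starts depolarised (left limb in swing), everything
    else at the leak potential."""
    n = len(network.populations)
    V = np.array([p.EL for p in network.populations], dtype=float)
    h = np.ones(n)
    for i, p in enumerate(network.populations):
        if p.kind == "burster":
            h[i] = h_inf(V[i], p)
    iFL = network.population_ids.index("RG-F-L")
    V[iFL] = -30.0
    h[iFL] = 0.6
    return V, h


def integrate(
    network: NetworkSpec,
    point: tuple[float, float],
    config: ModelConfig | None = None,
    *,
    duration_ms: float | None = None,
    dt_ms: float | None = None,
    drives: DriveMap | None = None,
    feedback_enabled: bool = True,
    initial: tuple[np.ndarray, np.ndarray] | None = None,
    initial_phases: tuple[bool, bool] = (True, False),
) -> SimResult:
    """Integrate the closed-loop system at one protocol point.

    ``point`` is (betaL, betaR).  Drives default to the condition-dependent
    speed mapping; pass ``drives`` to override (e.g. probing rhythmicity at
    a fixed bilateral alpha).  ``feedback_enabled=False`` disconnects both
    SF-E1 and SF-E2 on both sides.  Deterministic given the initial state.
    ``initial_phases`` gives the starting (left, right) swing flags matched
    to the antisymmetric default seed.
    """
    config = config or ModelConfig()
    betaL, betaR = point
    if betaL < 0 or betaR < 0:
        raise ValueError("belt-speed parameters must be >= 0")
    duration = config.duration_ms if duration_ms is None else duration_ms
    dt = config.dt_ms if dt_ms is None else dt_ms
    if dt > 1.0:
        raise ValueError("dt must be <= 1 ms")
    if drives is None:
        drives = make_drive_map(betaL, betaR, network.condition, config)

    index, WE, WI, drive_w, fbE, fbI = _matrices(network)
    pa = _param_arrays(network)
    driveE = sum(drive_w[src] * val for src, val in drives.as_dict().items())
    if not feedback_enabled:
        fbE = np.zeros_like(fbE)
        fbI = np.zeros_like(fbI)

    psiL = presynaptic_gain(drives.alphaL, config.gains.kPSI)
    psiR = presynaptic_gain(drives.alphaR, config.gains.kPSI)

    if initial is None:
        V0, h0 = default_initial_state(network)
    else:
        V0, h0 = initial
    V = np.ascontiguousarray(V0, dtype=float).copy()
    h = np.ascontiguousarray(h0, dtype=float).copy()

    n_steps = int(round(duration / dt))
    rec_every = max(1, int(round(config.record_every_ms / dt)))
    theta_lo = config.theta_sw - config.hysteresis
    theta_hi = config.theta_sw + config.hysteresis
    swingL, swingR = initial_phases

    (status, bad_i, bad_t, out_rec, s_rec, phase_rec, Vf, hf) = _kernel.simulate_kernel(
        WE, WI, np.ascontiguousarray(driveE), fbE, fbI,
        psiL, psiR, float(betaL), float(betaR),
        config.gains.kE1, config.gains.kE2,
        pa["is_burster"], pa["C"], pa["gNaP"], pa["gL"], pa["ENa"], pa["EL"],
        network.populations[0].EsynE, network.populations[0].EsynI,
        pa["Vm_half"], pa["km"], pa["Vh_half"], pa["kh"],
        pa["tau0"], pa["Vtau"], pa["ktau"],
        pa["Vout_min"], pa["Vout_max"],
        index["RG-F-L"], index["RG-F-R"], index["RG-E-L"], index["RG-E-R"],
        theta_lo, theta_hi,
        float(dt), n_steps, rec_every,
        V, h, swingL, swingR, 0.0, 0.0,
    )
    if status != _kernel.OK:
        raise FloatingPointError(
            f"non-finite state in population {network.population_ids[bad_i]!r} "
            f"at t = {bad_t:.1f} ms (betaL={betaL}, betaR={betaR}, "
            f"condition={network.condition})"
        )
    t = np.arange(out_rec.shape[0]) * rec_every * dt
    return SimResult(
        t=t, out=out_rec, pop_ids=list(network.population_ids),
        s=s_rec, limb_swing=phase_rec,
        betaL=betaL, betaR=betaR, condition=network.condition,
        drives=drives, dt_ms=dt, transient_ms=config.transient_ms,
        final_V=Vf, final_h=hf,
    )


def run_sweep(
    condition: str,
    protocol: str | BeltProtocol,
    config: ModelConfig | None = None,
    *,
    grid_step: float = 0.05,
    duration_ms: float | None = None,
) -> pd.DataFrame:
    """Run a full speed sweep and tabulate per-side cycle statistics.

    Returns one row per (sweep point, side) with mean/SD of cycle, stance
    and swing durations (s), duty factor, the number of retained cycles and
    a ``rhythmic`` flag.  Non-rhythmic points are flagged, never dropped.
    """
    from .phases import analyze_result  # local import to avoid a cycle

    config = config or ModelConfig()
    if isinstance(protocol, str):
        protocol = make_protocol(protocol, step=grid_step)
    network = build_network(condition, config.circuit)
    rows = []
    for betaL, betaR in protocol.sweep:
        res = integrate(network, (betaL, betaR), config, duration_ms=duration_ms)
        for side in ("left", "right"):
            stats = analyze_result(res, side, config)
            rows.append({
                "condition": condition,
                "protocol": protocol.label,
                "betaL": betaL,
                "betaR": betaR,
                "side": side,
                **stats,
            })
    return pd.DataFrame(rows)
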