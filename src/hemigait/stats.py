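"""Two-factor repeated-measures ANOVA and the simulation/data agreement report.

The study design is fully within-subject: every cat is measured in both
states (intact, hemisected) at every speed.  For each dependent variable
(cycle, stance or swing duration) and side, per-cycle values are first
averaged within cat x state x speed, then the classical univariate
partition is applied:

    SS_total = SS_subject + SS_state + SS_speed + SS_state:speed
               + SS_state:subject + SS_speed:subject + SS_state:speed:subject

with each effect tested against its own effect-by-subject interaction,
F = MS_effect / MS_{effect x subject}.  No sphericity correction is applied
by default (the state factor has two levels; speed F-tests assume
sphericity); a Greenhouse-Geisser correction is available behind a flag.

The agreement report compares the sign of the simulated hemisection effect
(grid mean of hemisected minus intact, per side and variable) with the sign
of the data-estimated state effect, zeroing signs that fall inside a small
relative dead-band or (for the data) fail the P < 0.05 criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaEffect",
    "AnovaResult",
    "rm_anova",
    "anova_table",
    "compare_sim_experiment",
    "AgreementReport",
    "DVS",
]

DVS = ("cycle", "stance", "swing")
_DV_COL = {"cycle": "cycle_s", "stance": "stance_s", "swing": "swing_s"}
_SWEEP_COL = {"cycle": "cycle_mean", "stance": "stance_mean", "swing": "swing_mean"}

ALPHA_LEVEL = 0.05
DEADBAND = 0.02


@dataclass(frozen=True)
class AnovaEffect:
    """One tested effect: F statistic, degrees of freedom and p-value."""

    F: float
    df1: int
    df2: int
    p: float
    gg_eps: float = 1.0   # Greenhouse-Geisser epsilon if correction applied


@dataclass(frozen=True)
class AnovaResult:
    """RM-ANOVA of one dependent variable on one side."""

    dv: str
    side: str
    state: AnovaEffect
    speed: AnovaEffect
    interaction: AnovaEffect
    n_subjects: int
    state_means: dict   # marginal mean of the dv per state
    cell_means: pd.DataFrame   # cat x state x speed averaged table


def _cell_means(dataset: pd.DataFrame, dv: str, side: str) -> pd.DataFrame:
    col = _DV_COL[dv]
    sub = dataset[dataset["side"] == side]
    if sub.empty:
        raise ValueError(f"no rows for side {side!r}")
    cells = (
        sub.groupby(["cat", "state", "speed"], observed=True)[col]
        .mean()
        .reset_index()
        .rename(columns={col: "y"})
    )
    counts = cells.pivot_table(index="cat", columns=["state", "speed"],
                               values="y", aggfunc="size")
    full = cells.pivot_table(index="cat", columns=["state", "speed"], values="y")
    if full.isna().any().any() or (counts != 1).any().any():
        missing = [str(c) for c in full.columns[full.isna().any()]]
        raise ValueError(f"unbalanced design; offending cells: {missing}")
    return cells


def _gg_epsilon(wide: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from an (n_subjects, k_levels) matrix."""
    k = wide.shape[1]
    S = np.cov(wide, rowvar=False, ddof=1)
    mean_diag = np.trace(S) / k
    mean_all = S.mean()
    num = (k * (mean_diag - mean_all)) ** 2
    den = (k - 1) * (np.sum(S**2) - 2 * k * np.sum(S.mean(axis=1) ** 2)
                     + k**2 * mean_all**2)
    if den <= 0:
        return 1.0
    return float(min(1.0, max(num / den, 1.0 / (k - 1))))


def _effect(ss: float, df1: int, ss_err: float, df2: int, eps: float = 1.0) -> AnovaEffect:
    if ss <= 0 or df1 == 0:
        return AnovaEffect(F=0.0, df1=df1, df2=df2, p=1.0, gg_eps=eps)
    if ss_err <= 0:
        return AnovaEffect(F=float("inf"), df1=df1, df2=df2, p=0.0, gg_eps=eps)
    F = (ss / df1) / (ss_err / df2)
    p = float(sps.f.sf(F, df1 * eps, df2 * eps))
    return AnovaEffect(F=float(F), df1=df1, df2=df2, p=p, gg_eps=eps)


def rm_anova(
    dataset: pd.DataFrame,
    dv: str = "cycle",
    side: str = "right",
    gg_correction: bool = False,
) -> AnovaResult:
    """Classical two-factor (state x speed) within-subject ANOVA.

    Cycles are averaged within cat x state x speed first; the design must
    then be balanced (every cat measured in every state x speed cell) with
    at least two cats.
    """
    if dv not in DVS:
        raise ValueError(f"unknown dependent variable {dv!r}; expected one of {DVS}")
    cells = _cell_means(dataset, dv, side)
    cats = sorted(cells["cat"].unique())
    states = sorted(cells["state"].unique())
    speeds = sorted(cells["speed"].unique())
    n, a, b = len(cats), len(states), len(speeds)
    if n < 2:
        raise ValueError("need at least 2 subjects for a repeated-measures ANOVA")
    if a != 2:
        raise ValueError("state factor must have exactly 2 levels")

    Y = (
        cells.set_index(["cat", "state", "speed"])["y"]
        .unstack(["state", "speed"])
        .reindex(index=cats)
        .to_numpy()
        .reshape(n, a, b)
    )
    M = Y.mean()
    m_c = Y.mean(axis=(1, 2))
    m_i = Y.mean(axis=(0, 2))
    m_j = Y.mean(axis=(0, 1))
    m_ci = Y.mean(axis=2)
    m_cj = Y.mean(axis=1)
    m_ij = Y.mean(axis=0)

    ss_state = b * n * np.sum((m_i - M) ** 2)
    ss_speed = a * n * np.sum((m_j - M) ** 2)
    ss_int = n * np.sum((m_ij - m_i[:, None] - m_j[None, :] + M) ** 2)
    ss_state_subj = b * np.sum((m_ci - m_c[:, None] - m_i[None, :] + M) ** 2)
    ss_speed_subj = a * np.sum((m_cj - m_c[:, None] - m_j[None, :] + M) ** 2)
    resid = (
        Y
        - m_ci[:, :, None]
        - m_cj[:, None, :]
        - m_ij[None, :, :]
        + m_c[:, None, None]
        + m_i[None, :, None]
        + m_j[None, None, :]
        - M
    )
    ss_int_subj = np.sum(resid**2)

    eps_state = eps_speed = eps_int = 1.0
    if gg_correction:
        # epsilon from the covariance of the within-factor contrasts
        eps_speed = _gg_epsilon(Y.mean(axis=1))
        eps_int = _gg_epsilon((Y[:, 0, :] - Y[:, 1, :]))

    state = _effect(ss_state, a - 1, ss_state_subj, (a - 1) * (n - 1), eps_state)
    speed = _effect(ss_speed, b - 1, ss_speed_subj, (b - 1) * (n - 1), eps_speed)
    inter = _effect(ss_int, (a - 1) * (b - 1), ss_int_subj,
                    (a - 1) * (b - 1) * (n - 1), eps_int)
    state_means = {s: float(m_i[k]) for k, s in enumerate(states)}
    return AnovaResult(
        dv=dv, side=side, state=state, speed=speed, interaction=inter,
        n_subjects=n, state_means=state_means, cell_means=cells,
    )


def anova_table(dataset: pd.DataFrame, gg_correction: bool = False) -> pd.DataFrame:
    """RM-ANOVA of every dependent variable on both sides, as one table."""
    rows = []
    for side in ("left", "right"):
        for dv in DVS:
            r = rm_anova(dataset, dv, side, gg_correction)
            for name, eff in (("state", r.state), ("speed", r.speed),
                              ("state x speed", r.interaction)):
                rows.append({
                    "side": side, "dv": dv, "effect": name,
                    "F": eff.F, "df1": eff.df1, "df2": eff.df2, "p": eff.p,
                })
    return pd.DataFrame(rows)


@dataclass
class AgreementReport:
    """Sign-level comparison of simulated and data-estimated hemisection
    effects, one row per (protocol, side, variable)."""

    table: pd.DataFrame

    @property
    def all_match(self) -> bool:
        return bool(self.table["match"].all())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"AgreementReport(match {int(self.table['match'].sum())}/{len(self.table)})"


def _sign(delta_rel: float, deadband: float) -> int:
    if abs(delta_rel) < deadband:
        return 0
    return 1 if delta_rel > 0 else -1


def compare_sim_experiment(
    sim_intact: pd.DataFrame,
    sim_hemi: pd.DataFrame,
    dataset: pd.DataFrame,
    deadband: float = DEADBAND,
    alpha_level: float = ALPHA_LEVEL,
) -> AgreementReport:
    """Qualitative agreement between simulated and synthetic-data effects.

    ``sim_intact``/``sim_hemi`` are sweep summaries from
    :func:`hemigait.engine.run_sweep` for the same protocol; ``dataset`` is
    a synthetic step-cycle table for that protocol.  For each (side,
    variable): the simulated effect sign is the sign of the grid-mean of
    (hemisected - intact) relative to the intact mean; the data effect
    sign is the sign of the state marginal-mean difference, zeroed when the
    RM-ANOVA state effect has p >= ``alpha_level``.  Both signs are zeroed
    inside the same relative dead-band, so that a formally significant but
    negligibly small data effect is not scored as a direction.
    """
    protos = set(sim_intact["protocol"]) | set(sim_hemi["protocol"])
    if len(protos) != 1:
        raise ValueError("sweep summaries must cover exactly one protocol")
    protocol = protos.pop()
    axis = "betaL" if protocol == "lfrs" else "betaR"
    grid_sim = set(np.round(sim_intact[axis], 10)) & set(np.round(sim_hemi[axis], 10))
    grid_data = set(np.round(dataset["speed"], 10))
    common = sorted(grid_sim & grid_data)
    if not common:
        raise ValueError("simulation and dataset speed grids are disjoint")

    rows = []
    for side in ("left", "right"):
        for dv in DVS:
            col = _SWEEP_COL[dv]
            si = sim_intact[(sim_intact["side"] == side)
                            & sim_intact[axis].round(10).isin(common)]
            sh = sim_hemi[(sim_hemi["side"] == side)
                          & sim_hemi[axis].round(10).isin(common)]
            vi = si.sort_values(axis)[col].to_numpy(dtype=float)
            vh = sh.sort_values(axis)[col].to_numpy(dtype=float)
            sim_rel = float((vh - vi).mean() / vi.mean())
            res = rm_anova(dataset[dataset["speed"].round(10).isin(common)], dv, side)
            data_rel = float(
                (res.state_means["hemisected"] - res.state_means["intact"])
                / res.state_means["intact"]
            )
            data_sign = 0 if res.state.p >= alpha_level else _sign(data_rel, deadband)
            rows.append({
                "protocol": protocol, "side": side, "variable": dv,
                "sim_delta_rel": sim_rel, "sim_sign": _sign(sim_rel, deadband),
                "data_delta_rel": data_rel, "data_p": res.state.p,
                "data_sign": data_sign,
            })
    table = pd.DataFrame(rows)
    table["match"] = table["sim_sign"] == table["data_sign"]
    return AgreementReport(table=table)
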