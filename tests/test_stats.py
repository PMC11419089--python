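"""Repeated-measures ANOVA against independent oracles; agreement report."""

import numpy as np
import pandas as pd
import pytest

from hemigait.stats import compare_sim_experiment, rm_anova
from hemigait.synth import generate_cat_dataset, null_effect_config, predicted_effect_config


def oracle_rm_anova(Y):
    """Textbook two-way within-subject ANOVA by explicit loops.

    Y has shape (subjects, a levels of factor A, b levels of factor B).
    Returns (F_A, F_B, F_AB).  Written independently of the package's
    vectorised partition.
    """
    n, a, b = Y.shape
    M = Y.mean()
    ss_A = ss_B = ss_AB = ss_As = ss_Bs = ss_ABs = 0.0
    mA = [Y[:, i, :].mean() for i in range(a)]
    mB = [Y[:, :, j].mean() for j in range(b)]
    mS = [Y[c].mean() for c in range(n)]
    for i in range(a):
        ss_A += b * n * (mA[i] - M) ** 2
    for j in range(b):
        ss_B += a * n * (mB[j] - M) ** 2
    for i in range(a):
        for j in range(b):
            ss_AB += n * (Y[:, i, j].mean() - mA[i] - mB[j] + M) ** 2
    for c in range(n):
        for i in range(a):
            ss_As += b * (Y[c, i, :].mean() - mS[c] - mA[i] + M) ** 2
        for j in range(b):
            ss_Bs += a * (Y[c, :, j].mean() - mS[c] - mB[j] + M) ** 2
    for c in range(n):
        for i in range(a):
            for j in range(b):
                ss_ABs += (
                    Y[c, i, j]
                    - Y[c, i, :].mean() - Y[c, :, j].mean() - Y[:, i, j].mean()
                    + mS[c] + mA[i] + mB[j] - M
                ) ** 2
    F_A = (ss_A / (a - 1)) / (ss_As / ((a - 1) * (n - 1)))
    F_B = (ss_B / (b - 1)) / (ss_Bs / ((b - 1) * (n - 1)))
    F_AB = (ss_AB / ((a - 1) * (b - 1))) / (ss_ABs / ((a - 1) * (b - 1) * (n - 1)))
    return F_A, F_B, F_AB


def table_from_cells(Y, speeds=None):
    """Wrap an (n_cats, 2 states, b speeds) array as a step-cycle table."""
    n, a, b = Y.shape
    speeds = speeds if speeds is not None else np.round(0.4 + 0.1 * np.arange(b), 10)
    rows = []
    for c in range(n):
        for i, state in enumerate(("intact", "hemisected")):
            for j, v in enumerate(speeds):
                rows.append({
                    "cat": f"cat{c}", "state": state, "speed": v, "side": "right",
                    "cycle_index": 0, "cycle_s": Y[c, i, j],
                    "stance_s": 0.6 * Y[c, i, j], "swing_s": 0.4 * Y[c, i, j],
                })
    return pd.DataFrame(rows)


class TestRmAnovaOracles:
    def test_identical_states_give_null_state_effect(self):
        rng = np.random.default_rng(0)
        half = rng.uniform(0.5, 1.0, size=(4, 1, 5))
        Y = np.concatenate([half, half], axis=1)
        res = rm_anova(table_from_cells(Y), dv="cycle", side="right")
        assert res.state.F == 0.0
        assert res.state.p == 1.0

    def test_two_by_two_toy_table_matches_hand_worked_oracle(self):
        Y = np.array([
            [[0.9, 0.7], [1.0, 0.8]],
            [[0.8, 0.6], [0.9, 0.75]],
        ])
        F_A, F_B, F_AB = oracle_rm_anova(Y)
        res = rm_anova(table_from_cells(Y), dv="cycle", side="right")
        assert res.state.F == pytest.approx(F_A, rel=1e-10)
        assert res.speed.F == pytest.approx(F_B, rel=1e-10)
        assert res.interaction.F == pytest.approx(F_AB, rel=1e-10)
        assert (res.state.df1, res.state.df2) == (1, 1)
        assert (res.speed.df1, res.speed.df2) == (1, 1)

    @pytest.mark.parametrize("seed", range(6))
    def test_random_balanced_designs_match_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, b = int(rng.integers(3, 7)), int(rng.integers(2, 8))
        Y = rng.uniform(0.3, 1.2, size=(n, 2, b))
        F_A, F_B, F_AB = oracle_rm_anova(Y)
        res = rm_anova(table_from_cells(Y), dv="cycle", side="right")
        assert res.state.F == pytest.approx(F_A, rel=1e-8)
        assert res.speed.F == pytest.approx(F_B, rel=1e-8)
        assert res.interaction.F == pytest.approx(F_AB, rel=1e-8)

    def test_matches_statsmodels_general_purpose_oracle(self):
        from statsmodels.stats.anova import AnovaRM

        rng = np.random.default_rng(42)
        Y = rng.uniform(0.3, 1.2, size=(5, 2, 4))
        df = table_from_cells(Y)
        res = rm_anova(df, dv="cycle", side="right")
        cells = df.rename(columns={"cycle_s": "y"})
        fit = AnovaRM(cells, depvar="y", subject="cat",
                      within=["state", "speed"]).fit()
        tab = fit.anova_table
        assert res.state.F == pytest.approx(tab.loc["state", "F Value"], rel=1e-8)
        assert res.speed.F == pytest.approx(tab.loc["speed", "F Value"], rel=1e-8)
        assert res.interaction.F == pytest.approx(
            tab.loc["state:speed", "F Value"], rel=1e-8)
        assert res.state.p == pytest.approx(tab.loc["state", "Pr > F"], abs=1e-10)

    def test_cycle_averaging_happens_before_anova(self):
        # duplicating every row (two identical cycles per cell) must not
        # change the statistics
        rng = np.random.default_rng(1)
        Y = rng.uniform(0.4, 1.0, size=(4, 2, 3))
        df = table_from_cells(Y)
        doubled = pd.concat([df, df.assign(cycle_index=1)], ignore_index=True)
        a = rm_anova(df, "cycle", "right")
        b = rm_anova(doubled, "cycle", "right")
        assert a.state.F == pytest.approx(b.state.F)
        assert a.speed.F == pytest.approx(b.speed.F)


class TestRmAnovaValidation:
    def test_unbalanced_design_rejected_with_cells_named(self):
        rng = np.random.default_rng(2)
        Y = rng.uniform(0.4, 1.0, size=(3, 2, 4))
        df = table_from_cells(Y)
        broken = df[~((df.cat == "cat0") & (df.state == "intact") & (df.speed == 0.4))]
        with pytest.raises(ValueError, match="unbalanced"):
            rm_anova(broken, "cycle", "right")

    def test_single_subject_rejected(self):
        Y = np.random.default_rng(3).uniform(0.4, 1.0, size=(1, 2, 4))
        with pytest.raises(ValueError, match="2 subjects"):
            rm_anova(table_from_cells(Y), "cycle", "right")

    def test_permuting_state_labels_destroys_effect(self):
        cfg = predicted_effect_config("tied")
        df = generate_cat_dataset(cfg, seed=4)
        base = rm_anova(df, "swing", "right").state.F
        rng = np.random.default_rng(5)
        permuted_F = []
        for _ in range(10):
            shuffled = df.copy()
            for cat in shuffled["cat"].unique():
                mask = shuffled["cat"] == cat
                if rng.random() < 0.5:
                    shuffled.loc[mask, "state"] = shuffled.loc[mask, "state"].map(
                        {"intact": "hemisected", "hemisected": "intact"})
            permuted_F.append(rm_anova(shuffled, "swing", "right").state.F)
        assert np.mean(permuted_F) < base / 5


class TestAgreementReport:
    @staticmethod
    def _sweep(protocol, side_vals, betas):
        rows = []
        for side, (cyc, st) in side_vals.items():
            for b in betas:
                bl, br = (0.4, b) if protocol in ("tied", "lsrf") else (b, 0.4)
                if protocol == "tied":
                    bl = br = b
                rows.append({
                    "condition": "x", "protocol": protocol, "betaL": bl, "betaR": br,
                    "side": side, "cycle_mean": cyc, "stance_mean": st,
                    "swing_mean": cyc - st, "n_cycles": 30, "rhythmic": True,
                })
        return pd.DataFrame(rows)

    def test_constructed_match_and_mismatch(self):
        betas = np.round(np.arange(0.4, 1.01, 0.1), 10)
        intact = self._sweep("tied", {"left": (0.9, 0.6), "right": (0.9, 0.6)}, betas)
        # simulated hemisection: right swing up / stance down, cycle fixed
        hemi = self._sweep("tied", {"left": (0.9, 0.6), "right": (0.9, 0.5)}, betas)
        data = generate_cat_dataset(predicted_effect_config("tied"), seed=7)
        report = compare_sim_experiment(intact, hemi, data)
        t = report.table.set_index(["side", "variable"])
        assert t.loc[("right", "swing"), "sim_sign"] == 1
        assert t.loc[("right", "stance"), "sim_sign"] == -1
        assert t.loc[("right", "cycle"), "sim_sign"] == 0
        assert t.loc[("right", "swing"), "match"]
        assert t.loc[("right", "stance"), "match"]

    def test_zero_effect_data_vs_nonzero_sim_is_recorded_mismatch(self):
        betas = np.round(np.arange(0.4, 1.01, 0.1), 10)
        intact = self._sweep("tied", {"left": (0.9, 0.6), "right": (0.9, 0.6)}, betas)
        hemi = self._sweep("tied", {"left": (0.9, 0.6), "right": (0.9, 0.45)}, betas)
        data = generate_cat_dataset(null_effect_config("tied"), seed=8)
        report = compare_sim_experiment(intact, hemi, data)
        t = report.table.set_index(["side", "variable"])
        assert not t.loc[("right", "stance"), "match"]
        assert not report.all_match

    def test_disjoint_grids_rejected(self):
        betas = np.array([1.4, 1.5])
        intact = self._sweep("tied", {"left": (0.9, 0.6), "right": (0.9, 0.6)}, betas)
        hemi = intact.copy()
        data = generate_cat_dataset(null_effect_config("tied", n_cats=2), seed=0)
        with pytest.raises(ValueError, match="disjoint"):
            compare_sim_experiment(intact, hemi, data)
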