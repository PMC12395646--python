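"""Mixed 2x2x2 ANOVA against a brute-force balanced split-plot oracle."""

import itertools

import numpy as np
import pandas as pd
import pytest

from swaykit import medication_regroup, mixed_anova
from swaykit.anova import MixedSwayAnova
from swaykit.io import CONDITION_CODES
from swaykit.simulate import null_metric_table


def _long_table(y, groups, weight=None, race=None):
    """y: dict (pid, code) -> value."""
    rows = []
    pids = sorted({p for p, _ in y})
    for pid in pids:
        for code in CONDITION_CODES:
            rows.append(
                {
                    "participant_id": pid,
                    "group": groups[pid],
                    "weight_kg": (weight or {}).get(pid, 70.0),
                    "race": (race or {}).get(pid, "White"),
                    "medicated": False,
                    "condition": code,
                    "metric": "m",
                    "value": y[(pid, code)],
                    "transformed": False,
                }
            )
    return pd.DataFrame(rows)


def _balanced_data(n_per_group=4, seed=0, effects=None):
    """Balanced 2 groups x n x 2 x 2 cells with optional planted effects."""
    rng = np.random.default_rng(seed)
    effects = effects or {}
    y, groups = {}, {}
    for g, glab in enumerate(["A", "B"]):
        for s in range(n_per_group):
            pid = f"{glab}{s}"
            groups[pid] = glab
            subj = rng.normal(0, 1)
            for code in CONDITION_CODES:
                eye = 1 if code[1] == "C" else 0
                base = 1 if code[2] == "C" else 0
                val = (
                    subj
                    + rng.normal(0, 0.5)
                    + effects.get("group", 0) * g
                    + effects.get("eye", 0) * eye
                    + effects.get("group:eye", 0) * g * eye
                )
                y[(pid, code)] = val
    return y, groups


def split_plot_oracle(y, groups):
    """Brute-force balanced split-plot F values via cell-mean decomposition.

    Independent of the package's stratified-OLS path: every sum of squares
    is computed by inclusion-exclusion over marginal means of the balanced
    4-way layout (group x subject-in-group x eye x base), and the three-way
    within error is obtained by subtraction from the total.
    """
    glabels = sorted(set(groups.values()))
    subj = {g: sorted(p for p in groups if groups[p] == g) for g in glabels}
    n = len(subj[glabels[0]])
    assert all(len(s) == n for s in subj.values()), "oracle needs balance"
    G = len(glabels)
    Y = np.empty((G, n, 2, 2))
    for gi, g in enumerate(glabels):
        for si, pid in enumerate(subj[g]):
            for code in CONDITION_CODES:
                e = 1 if code[1] == "C" else 0
                b = 1 if code[2] == "C" else 0
                Y[gi, si, e, b] = y[(pid, code)]
    M = Y.mean()
    A = Y.mean(axis=(1, 2, 3))          # group means
    S = Y.mean(axis=(2, 3))             # subject means
    C = Y.mean(axis=(0, 1, 3))          # eye means
    D = Y.mean(axis=(0, 1, 2))          # base means
    AC = Y.mean(axis=(1, 3))
    AD = Y.mean(axis=(1, 2))
    CD = Y.mean(axis=(0, 1))
    ACD = Y.mean(axis=1)
    CS = Y.mean(axis=3)                 # (g, s, e)
    DS = Y.mean(axis=2)                 # (g, s, b)

    ss = {}
    ss["group"] = 4 * n * np.sum((A - M) ** 2)
    ss["subj"] = 4 * np.sum((S - A[:, None]) ** 2)
    ss["eye"] = 2 * G * n * np.sum((C - M) ** 2)
    ss["group:eye"] = 2 * n * np.sum(
        (AC - A[:, None] - C[None, :] + M) ** 2
    )
    ss["err_eye"] = 2 * np.sum(
        (CS - S[:, :, None] - AC[:, None, :] + A[:, None, None]) ** 2
    )
    ss["base"] = 2 * G * n * np.sum((D - M) ** 2)
    ss["group:base"] = 2 * n * np.sum(
        (AD - A[:, None] - D[None, :] + M) ** 2
    )
    ss["err_base"] = 2 * np.sum(
        (DS - S[:, :, None] - AD[:, None, :] + A[:, None, None]) ** 2
    )
    ss["eye:base"] = G * n * np.sum(
        (CD - C[:, None] - D[None, :] + M) ** 2
    )
    ss["group:eye:base"] = n * np.sum(
        (
            ACD
            - AC[:, :, None]
            - AD[:, None, :]
            - CD[None, :, :]
            + A[:, None, None]
            + C[None, :, None]
            + D[None, None, :]
            - M
        )
        ** 2
    )
    ss_total = np.sum((Y - M) ** 2)
    ss["err_eye:base"] = ss_total - sum(
        ss[k] for k in ss if not k.startswith("err_eye:base")
    )

    df_err = G * (n - 1)
    out = {}
    out["group"] = (ss["group"] / (G - 1)) / (ss["subj"] / df_err)
    out["eye"] = ss["eye"] / (ss["err_eye"] / df_err)
    out["group:eye"] = (ss["group:eye"] / (G - 1)) / (ss["err_eye"] / df_err)
    out["base"] = ss["base"] / (ss["err_base"] / df_err)
    out["group:base"] = (ss["group:base"] / (G - 1)) / (ss["err_base"] / df_err)
    out["eye:base"] = ss["eye:base"] / (ss["err_eye:base"] / df_err)
    out["group:eye:base"] = (ss["group:eye:base"] / (G - 1)) / (
        ss["err_eye:base"] / df_err
    )
    return out


def test_matches_brute_force_oracle_on_balanced_design():
    y, groups = _balanced_data(
        n_per_group=4, seed=1, effects={"group": 0.8, "eye": 0.5, "group:eye": 0.7}
    )
    table = _long_table(y, groups)
    res = mixed_anova(table, "m", covariates=())
    oracle = split_plot_oracle(y, groups)
    for effect, want in oracle.items():
        got = res.effect(effect)
        assert got["F"] == pytest.approx(want, abs=1e-10), effect
        assert got["df2"] == 2 * (4 - 1)


def test_between_stratum_matches_statsmodels_type3():
    """Group/covariate F on participant means equals statsmodels typ-3."""
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    rng = np.random.default_rng(2)
    y, groups, weight, race = {}, {}, {}, {}
    for g, glab in enumerate(["A", "B"]):
        for s in range(6 + 3 * g):  # unbalanced groups on purpose
            pid = f"{glab}{s}"
            groups[pid] = glab
            weight[pid] = rng.normal(75, 10)
            race[pid] = "White" if rng.random() < 0.6 else "non-White"
            for code in CONDITION_CODES:
                y[(pid, code)] = (
                    rng.normal(0, 1) + 0.5 * g + 0.02 * weight[pid]
                )
    table = _long_table(y, groups, weight, race)
    res = mixed_anova(table, "m", covariates=("weight_kg", "race"))

    means = (
        table.groupby("participant_id")
        .agg(m=("value", "mean"), group=("group", "first"),
             weight_kg=("weight_kg", "first"), race=("race", "first"))
        .reset_index()
    )
    fit = smf.ols(
        "m ~ C(group, Sum) + weight_kg + C(race, Sum)", data=means
    ).fit()
    ref = anova_lm(fit, typ=3)
    assert res.effect("group")["F"] == pytest.approx(
        ref.loc["C(group, Sum)", "F"], rel=1e-8
    )
    assert res.effect("weight_kg")["F"] == pytest.approx(
        ref.loc["weight_kg", "F"], rel=1e-8
    )
    assert res.effect("race")["F"] == pytest.approx(
        ref.loc["C(race, Sum)", "F"], rel=1e-8
    )


def test_location_shift_leaves_f_unchanged():
    y, groups = _balanced_data(n_per_group=5, seed=3, effects={"eye": 0.6})
    t1 = _long_table(y, groups)
    t2 = t1.copy()
    t2["value"] += 123.4
    r1 = mixed_anova(t1, "m", covariates=())
    r2 = mixed_anova(t2, "m", covariates=())
    np.testing.assert_allclose(r1.anova_table["F"], r2.anova_table["F"], atol=1e-8)


def test_constant_data_flagged_degenerate():
    y, groups = _balanced_data(n_per_group=3, seed=0)
    y = {k: 5.0 for k in y}
    res = mixed_anova(_long_table(y, groups), "m", covariates=())
    assert res.anova_table["degenerate"].all()
    assert (res.anova_table["F"] == 0).all()


def test_identical_groups_give_zero_group_contrast():
    rng = np.random.default_rng(4)
    vals = {code: rng.normal(0, 1, 5) for code in CONDITION_CODES}
    y, groups = {}, {}
    for glab in ["A", "B"]:  # the two groups carry identical data
        for s in range(5):
            pid = f"{glab}{s}"
            groups[pid] = glab
            for code in CONDITION_CODES:
                y[(pid, code)] = vals[code][s]
    res = mixed_anova(_long_table(y, groups), "m", covariates=())
    con = res.contrasts(by="group")
    assert con["estimate"].iloc[0] == pytest.approx(0.0, abs=1e-12)
    assert res.effect("group")["F"] == pytest.approx(0.0, abs=1e-12)


def test_bonferroni_doubles_raw_p_capped_at_one():
    y, groups = _balanced_data(n_per_group=6, seed=5, effects={"group:eye": 0.4})
    res = mixed_anova(_long_table(y, groups), "m", covariates=())
    con = res.contrasts(by="eye")
    assert len(con) == 2
    np.testing.assert_allclose(
        con["p_adj"], np.minimum(1.0, 2 * con["p_raw"]), atol=0
    )


def test_within_group_eye_contrast_estimates_cell_difference():
    """The eye contrast equals each group's mean closed-minus-open difference."""
    y, groups = _balanced_data(n_per_group=6, seed=6, effects={"eye": 1.0})
    table = _long_table(y, groups)
    res = mixed_anova(table, "m", covariates=())
    con = res.contrasts(by="eye").set_index("group")
    wide = table.pivot_table(index="participant_id", columns="condition", values="value")
    diff = (wide[["ECOB", "ECCB"]].mean(axis=1) - wide[["EOOB", "EOCB"]].mean(axis=1))
    for glab in ["A", "B"]:
        pids = [p for p, g in groups.items() if g == glab]
        assert con.loc[glab, "estimate"] == pytest.approx(diff[pids].mean())


def test_three_level_group_supported():
    """After a medication regroup the same engine runs with 3 levels."""
    table = null_metric_table((12, 12), seed=7)
    table.loc[table["group"] == "ASC", "medicated"] = (
        table.loc[table["group"] == "ASC", "participant_id"].str[-1].astype(int) % 2 == 0
    )
    re3 = medication_regroup(table)
    assert set(re3["group"]) == {"ASC-medicated", "ASC-unmedicated", "NC"}
    res = mixed_anova(re3, "metric", covariates=())
    assert res.effect("group")["df1"] == 2


def test_medication_regroup_contracts():
    table = null_metric_table((6, 6), seed=8)
    table["medicated"] = table["group"] == "ASC"
    re3 = medication_regroup(table)
    # counts: every ASC participant medicated here
    assert (re3[re3["group_original"] == "ASC"]["group"] == "ASC-medicated").all()
    # round trip
    assert (re3["group_original"] == table["group"]).all()
    nc_only = table[table["group"] == "NC"].copy()
    with pytest.raises(ValueError, match="single level"):
        medication_regroup(nc_only)
    bad = table.drop(columns=["medicated"])
    with pytest.raises(ValueError, match="medicated"):
        medication_regroup(bad)


def test_incomplete_participant_dropped_with_log(caplog):
    y, groups = _balanced_data(n_per_group=4, seed=9)
    table = _long_table(y, groups)
    table = table[~((table.participant_id == "A0") & (table.condition == "ECCB"))]
    res = mixed_anova(table, "m", covariates=())
    assert res.model.n == 7
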