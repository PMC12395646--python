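"""Mixed-design ANOVA for the sway battery.

Each metric is analysed with a 2 (Group, between) x 2 (Eye, within) x 2
(Base, within) mixed ANOVA with participant-level covariates (weight,
race), using the classical split-plot decomposition: the four condition
cells per participant are reduced to orthogonal within-subject contrast
scores (mean, eye, base, eye x base), and each stratum is analysed by OLS
with sum-to-zero coding and Type-III tests. The participant-mean stratum
carries Group and the covariates; each within-contrast stratum carries
that factor's main effect (the intercept) and its Group interaction,
tested against the matching participant x factor error term. For 2-level
within factors this is exactly the univariate repeated-measures analysis
(sphericity is not an issue with a single contrast per factor).

The model object follows the statsmodels convention: build a
:class:`MixedSwayAnova` from the long metrics table, ``fit()`` it, and
read the F table, adjusted means and Bonferroni follow-ups off the
returned :class:`MixedAnovaResults`.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CONDITION_CODES, Condition

logger = logging.getLogger("swaykit")

__all__ = [
    "MixedSwayAnova",
    "MixedAnovaResults",
    "mixed_anova",
    "followup_contrasts",
    "medication_regroup",
    "significance_code",
]

#: Table-style effect order for the 2x2x2 design
EFFECT_ORDER = (
    "group",
    "eye",
    "group:eye",
    "base",
    "group:base",
    "eye:base",
    "group:eye:base",
)


def significance_code(p: float) -> str:
    """Conventional significance flags: trend dagger below 0.10, then stars."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.10:
        return "†"
    return ""


def _sum_to_zero(values: pd.Series) -> tuple[np.ndarray, list[str], list]:
    """Sum-to-zero (deviation) coding for a categorical column.

    Levels are sorted; the last level is the reference carrying -1 in
    every column. Returns (n x (k-1) matrix, column names, levels).
    """
    levels = sorted(pd.unique(values))
    k = len(levels)
    if k < 2:
        raise ValueError(f"categorical needs >= 2 levels, got {levels}")
    codes = pd.Categorical(values, categories=levels).codes
    X = np.zeros((len(values), k - 1))
    for j in range(k - 1):
        X[codes == j, j] = 1.0
        X[codes == k - 1, j] = -1.0
    names = [f"[{levels[j]}]" for j in range(k - 1)]
    return X, names, levels


def _ols_sse(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


@dataclass
class _Stratum:
    """One error stratum: response vector + named term blocks."""

    name: str
    y: np.ndarray
    terms: dict[str, np.ndarray]  # term -> design block (n, q)
    tested: list[str]  # terms reported from this stratum (design order)

    def type3(self) -> list[dict]:
        X_full = np.column_stack([self.terms[t] for t in self.terms])
        n, p = X_full.shape
        df_err = n - np.linalg.matrix_rank(X_full)
        sse_full = _ols_sse(X_full, self.y)
        scale = max(float(self.y @ self.y), 1.0)
        if sse_full <= 1e-12 * scale:  # error variance is numerically zero
            sse_full = 0.0
        mse = sse_full / df_err if df_err > 0 else np.nan
        rows = []
        for term in self.tested:
            blocks = [self.terms[t] for t in self.terms if t != term]
            X_red = np.column_stack(blocks) if blocks else np.zeros((n, 0))
            sse_red = self.y @ self.y if X_red.shape[1] == 0 else _ols_sse(X_red, self.y)
            q = self.terms[term].shape[1]
            ss = max(sse_red - sse_full, 0.0)
            if ss <= 1e-12 * scale:
                ss = 0.0
            if df_err <= 0 or mse == 0:
                F, p_val = (0.0, 1.0) if ss <= 1e-300 else (np.inf, 0.0)
                degenerate = True
            else:
                F = (ss / q) / mse
                p_val = float(stats.f.sf(F, q, df_err))
                degenerate = False
            rows.append(
                {
                    "effect": term,
                    "stratum": self.name,
                    "ss": ss,
                    "df1": q,
                    "df2": df_err,
                    "F": float(F),
                    "p": p_val,
                    "degenerate": degenerate,
                }
            )
        return rows


class MixedSwayAnova:
    """Mixed 2x2x2 ANOVA model for one sway metric.

    Parameters
    ----------
    table : DataFrame
        Long metrics table (one row per participant x condition with a
        ``value`` column), already normality-screened if desired.
    metric : str
        Which metric to analyse (rows with other metrics are ignored).
    covariates : sequence of str
        Participant-level covariate columns; numeric columns enter
        centred, non-numeric ones with sum-to-zero coding.
    covariates_in_within : bool
        Carry the covariates into the within-contrast strata as well
        (covariate x factor interactions absorbed into the error model).
        Off by default: covariates are participant-constant.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        metric: str,
        covariates: tuple[str, ...] = ("weight_kg", "race"),
        *,
        group_col: str = "group",
        covariates_in_within: bool = False,
    ):
        self.metric = metric
        self.covariates = tuple(covariates)
        self.group_col = group_col
        self.covariates_in_within = covariates_in_within

        sub = table[table["metric"] == metric] if "metric" in table.columns else table
        if sub.empty:
            raise ValueError(f"no rows for metric {metric!r}")
        wide = sub.pivot_table(
            index="participant_id", columns="condition", values="value", sort=False
        )
        complete = wide.dropna()
        dropped = set(wide.index) - set(complete.index)
        for pid in sorted(dropped):
            logger.warning(
                "%s: participant %s missing conditions, dropped from ANOVA", metric, pid
            )
        missing_codes = [c for c in CONDITION_CODES if c not in complete.columns]
        if missing_codes:
            raise ValueError(f"conditions absent from table: {missing_codes}")
        complete = complete[list(CONDITION_CODES)]

        meta_cols = [group_col, *covariates]
        meta = (
            sub[["participant_id", *meta_cols]]
            .drop_duplicates("participant_id")
            .set_index("participant_id")
            .loc[complete.index]
        )
        self.data = complete
        self.meta = meta
        self.n = len(complete)
        if self.n < 3:
            raise ValueError("need at least 3 complete participants")

        # orthogonal within-subject contrast scores per participant
        eye_closed = [c for c in CONDITION_CODES if Condition.from_code(c).eye == "closed"]
        eye_open = [c for c in CONDITION_CODES if Condition.from_code(c).eye == "open"]
        base_closed = [c for c in CONDITION_CODES if Condition.from_code(c).base == "closed"]
        base_open = [c for c in CONDITION_CODES if Condition.from_code(c).base == "open"]
        cells = complete
        self.scores = pd.DataFrame(
            {
                "mean": cells.mean(axis=1),
                # closed minus open mean differences
                "eye": cells[eye_closed].mean(axis=1) - cells[eye_open].mean(axis=1),
                "base": cells[base_closed].mean(axis=1) - cells[base_open].mean(axis=1),
                "eye:base": (
                    cells["ECCB"] - cells["ECOB"] - cells["EOCB"] + cells["EOOB"]
                ),
            }
        )

    # -- design helpers -------------------------------------------------
    def _group_block(self) -> tuple[np.ndarray, list]:
        X, _, levels = _sum_to_zero(self.meta[self.group_col])
        return X, levels

    def _covariate_blocks(self) -> dict[str, np.ndarray]:
        blocks: dict[str, np.ndarray] = {}
        for cov in self.covariates:
            col = self.meta[cov]
            if pd.api.types.is_numeric_dtype(col) and not pd.api.types.is_bool_dtype(col):
                x = col.to_numpy(float)
                blocks[cov] = (x - x.mean())[:, None]
            else:
                if col.nunique() < 2:
                    logger.warning(
                        "%s: covariate %r has a single level, dropped",
                        self.metric, cov,
                    )
                    continue
                X, _, _ = _sum_to_zero(col.astype(str))
                blocks[cov] = X
        return blocks

    def fit(self) -> "MixedAnovaResults":
        """Estimate every stratum and assemble the F table."""
        n = self.n
        ones = np.ones((n, 1))
        G, group_levels = self._group_block()
        covs = self._covariate_blocks()

        strata = []
        between_terms = {"(intercept)": ones, "group": G, **covs}
        strata.append(
            _Stratum(
                name="between",
                y=self.scores["mean"].to_numpy(float),
                terms=between_terms,
                tested=["group", *covs.keys()],
            )
        )
        for factor in ("eye", "base", "eye:base"):
            terms = {"(intercept)": ones, "group": G}
            if self.covariates_in_within:
                terms.update(covs)
            strata.append(
                _Stratum(
                    name=f"within[{factor}]",
                    y=self.scores[factor].to_numpy(float),
                    terms=terms,
                    tested=["(intercept)", "group"],
                )
            )

        rows = []
        for stratum in strata:
            for row in stratum.type3():
                effect = row["effect"]
                if stratum.name.startswith("within"):
                    factor = stratum.name[7:-1]
                    row["effect"] = factor if effect == "(intercept)" else f"group:{factor}"
                rows.append(row)
        table = pd.DataFrame(rows)
        order = {e: i for i, e in enumerate(EFFECT_ORDER)}
        table["_o"] = table["effect"].map(lambda e: order.get(e, len(order)))
        table = table.sort_values(["_o", "effect"]).drop(columns="_o").reset_index(drop=True)
        table["sig"] = table["p"].map(significance_code)
        return MixedAnovaResults(model=self, anova_table=table, group_levels=group_levels)


@dataclass
class MixedAnovaResults:
    """Fitted mixed ANOVA: F table plus follow-up machinery."""

    model: MixedSwayAnova
    anova_table: pd.DataFrame
    group_levels: list

    def effect(self, name: str) -> pd.Series:
        row = self.anova_table[self.anova_table["effect"] == name]
        if row.empty:
            raise KeyError(f"no effect {name!r}")
        return row.iloc[0]

    def summary(self) -> str:
        m = self.model
        lines = [
            f"Mixed ANOVA for {m.metric}",
            f"  {len(self.group_levels)} groups {self.group_levels}, "
            f"n = {m.n} complete participants, covariates {list(m.covariates)}",
            "",
            self.anova_table[["effect", "F", "df1", "df2", "p", "sig"]]
            .to_string(index=False, float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)

    # -- follow-up contrasts --------------------------------------------
    def contrasts(self, by: str = "eye", adjust: str = "bonferroni") -> pd.DataFrame:
        """Bonferroni-adjusted follow-up contrasts.

        ``by="eye"`` (or ``"base"``): the within-group closed-minus-open
        adjusted mean difference for that factor, one contrast per group
        (the family). ``by="group"``: pairwise differences of the
        covariate-adjusted group means of the participant averages.
        Adjusted p is ``min(1, raw * family size)``.
        """
        if by in ("eye", "base"):
            out = self._within_group_contrasts(by)
        elif by == "group":
            out = self._group_contrasts()
        else:
            raise ValueError(f"no contrast family {by!r}; use 'eye', 'base' or 'group'")
        k = len(out)
        if adjust == "bonferroni":
            out["p_adj"] = np.minimum(1.0, out["p_raw"] * k)
        elif adjust in (None, "none"):
            out["p_adj"] = out["p_raw"]
        else:
            raise ValueError(f"unknown adjustment {adjust!r}")
        out["sig"] = out["p_adj"].map(significance_code)
        return out

    def _stratum_fit(self, response: str, with_covs: bool):
        m = self.model
        y = m.scores[response].to_numpy(float)
        G, levels = m._group_block()
        terms = {"(intercept)": np.ones((m.n, 1)), "group": G}
        if with_covs:
            terms.update(m._covariate_blocks())
        X = np.column_stack(list(terms.values()))
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        df = m.n - np.linalg.matrix_rank(X)
        mse = float((y - X @ beta) @ (y - X @ beta)) / df
        XtX_inv = np.linalg.pinv(X.T @ X)
        return X, beta, XtX_inv, mse, df, levels

    def _group_rows(self, levels) -> dict:
        """Sum-to-zero row vectors mapping group level -> effect coding."""
        k = len(levels)
        rows = {}
        for j, lvl in enumerate(levels):
            r = np.zeros(k - 1)
            if j < k - 1:
                r[j] = 1.0
            else:
                r[:] = -1.0
            rows[lvl] = r
        return rows

    def _within_group_contrasts(self, factor: str) -> pd.DataFrame:
        m = self.model
        X, beta, XtX_inv, mse, df, levels = self._stratum_fit(
            factor, m.covariates_in_within
        )
        grows = self._group_rows(levels)
        pad = X.shape[1] - 1 - (len(levels) - 1)  # covariate columns, at their means
        recs = []
        for lvl in levels:
            c = np.concatenate([[1.0], grows[lvl], np.zeros(pad)])
            est = float(c @ beta)
            se = float(np.sqrt(mse * c @ XtX_inv @ c))
            tval = est / se if se > 0 else np.inf
            p = float(2 * stats.t.sf(abs(tval), df))
            ci = stats.t.ppf(0.975, df) * se
            recs.append(
                {
                    "contrast": f"{factor}: closed - open",
                    "group": lvl,
                    "estimate": est,
                    "se": se,
                    "df": df,
                    "t": tval,
                    "ci_low": est - ci,
                    "ci_high": est + ci,
                    "p_raw": p,
                }
            )
        return pd.DataFrame(recs)

    def _group_contrasts(self) -> pd.DataFrame:
        X, beta, XtX_inv, mse, df, levels = self._stratum_fit("mean", True)
        grows = self._group_rows(levels)
        pad = X.shape[1] - 1 - (len(levels) - 1)
        recs = []
        means = {}
        for lvl in levels:
            c = np.concatenate([[1.0], grows[lvl], np.zeros(pad)])
            means[lvl] = (c, float(c @ beta))
        for a, b in itertools.combinations(levels, 2):
            c = means[a][0] - means[b][0]
            est = float(c @ beta)
            se = float(np.sqrt(mse * c @ XtX_inv @ c))
            tval = est / se if se > 0 else np.inf
            p = float(2 * stats.t.sf(abs(tval), df))
            ci = stats.t.ppf(0.975, df) * se
            recs.append(
                {
                    "contrast": f"group: {a} - {b}",
                    "group": f"{a} vs {b}",
                    "estimate": est,
                    "se": se,
                    "df": df,
                    "t": tval,
                    "ci_low": est - ci,
                    "ci_high": est + ci,
                    "p_raw": p,
                }
            )
        return pd.DataFrame(recs)

    def adjusted_means(self) -> pd.DataFrame:
        """Covariate-adjusted group means of the participant averages."""
        _, beta, _, mse, df, levels = self._stratum_fit("mean", True)
        grows = self._group_rows(levels)
        pad = len(beta) - 1 - (len(levels) - 1)
        recs = []
        for lvl in levels:
            c = np.concatenate([[1.0], grows[lvl], np.zeros(pad)])
            recs.append({"group": lvl, "adjusted_mean": float(c @ beta)})
        return pd.DataFrame(recs)


def mixed_anova(
    table: pd.DataFrame,
    metric: str,
    covariates: tuple[str, ...] = ("weight_kg", "race"),
    **kwargs,
) -> MixedAnovaResults:
    """Fit the mixed 2x2x2 ANOVA for one metric (functional front door)."""
    return MixedSwayAnova(table, metric, covariates, **kwargs).fit()


def followup_contrasts(results: MixedAnovaResults, by: str = "eye") -> pd.DataFrame:
    """Bonferroni follow-up contrasts for a fitted mixed ANOVA."""
    return results.contrasts(by=by)


def medication_regroup(
    table: pd.DataFrame,
    *,
    clinical_group: str = "ASC",
    control_group: str = "NC",
) -> pd.DataFrame:
    """Recode the two-level grouping into three medication-aware levels.

    Rows of the clinical group become ``{clinical_group}-medicated`` /
    ``{clinical_group}-unmedicated`` from the boolean ``medicated``
    column; control rows keep their label. The original labels are kept
    in ``group_original`` so the recode round-trips.
    """
    if "medicated" not in table.columns:
        raise ValueError("table has no 'medicated' column")
    clin = table["group"] == clinical_group
    missing = table.loc[clin, "medicated"].isna()
    if missing.any():
        pids = sorted(table.loc[clin & missing.to_numpy(), "participant_id"].unique())
        raise ValueError(f"missing medication flags for participants: {pids}")
    out = table.copy()
    out["group_original"] = out["group"]
    med = out["medicated"].astype(bool)
    out.loc[clin & med, "group"] = f"{clinical_group}-medicated"
    out.loc[clin & ~med, "group"] = f"{clinical_group}-unmedicated"
    if out["group"].nunique() < 2:
        raise ValueError(
            f"regrouping produced a single level {out['group'].unique()}; "
            "need at least two groups"
        )
    return out
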