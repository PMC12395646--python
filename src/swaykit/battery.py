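"""The six-metric sway battery and the normality screen.

For every trial the battery computes sway area (95% ellipse), sway path,
and the RMS of the rambling and trembling components in ML and AP — six
metrics per condition, 24 variables per participant across the four
sensory conditions. Before inferential analysis each metric x condition
variable is screened for normality (Lilliefors-corrected KS by default)
and log-transformed when it violates, at the whole-variable level.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, asdict
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .decomposition import decompose_trial
from .geometry import confidence_ellipse, sway_path
from .io import CONDITION_CODES, ForcePlateTrial, ParticipantRecord
from .preprocess import PreprocessSettings, preprocess

logger = logging.getLogger("swaykit")

__all__ = [
    "METRICS",
    "SwayMetricSet",
    "compute_metric_set",
    "metrics_table",
    "normality_screen",
]

#: canonical metric order used throughout the package
METRICS = (
    "sway_area",
    "sway_path",
    "rms_rambling_ml",
    "rms_rambling_ap",
    "rms_trembling_ml",
    "rms_trembling_ap",
)


@dataclass(frozen=True)
class SwayMetricSet:
    """The six per-trial sway metrics (area in unit^2, the rest in unit)."""

    sway_area: float
    sway_path: float
    rms_rambling_ml: float
    rms_rambling_ap: float
    rms_trembling_ml: float
    rms_trembling_ap: float

    def __post_init__(self):
        for name, value in asdict(self).items():
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"metric {name} must be finite and >= 0, got {value}")

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def compute_metric_set(
    trial: ForcePlateTrial,
    settings: PreprocessSettings | None = None,
    *,
    coverage: float = 0.95,
    demean_rms: bool = True,
) -> SwayMetricSet:
    """Preprocess a trial and compute all six sway metrics.

    Deterministic given the trial and settings: decimate + low-pass, fit
    the coverage ellipse and path on (ML, AP), then decompose each axis
    against its own shear-force channel and take component RMS.
    """
    clean = preprocess(trial, settings)
    ellipse = confidence_ellipse(clean.cop_ml, clean.cop_ap, coverage)
    path = sway_path(clean.cop_ml, clean.cop_ap)
    decomp = decompose_trial(clean)
    return SwayMetricSet(
        sway_area=ellipse.area,
        sway_path=path,
        rms_rambling_ml=decomp["ML"].rms_rambling(demean_rms),
        rms_rambling_ap=decomp["AP"].rms_rambling(demean_rms),
        rms_trembling_ml=decomp["ML"].rms_trembling(demean_rms),
        rms_trembling_ap=decomp["AP"].rms_trembling(demean_rms),
    )


def metrics_table(
    cohort: Iterable[ParticipantRecord],
    settings: PreprocessSettings | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Long-format metrics table for a whole cohort.

    One row per participant x condition x metric with the participant
    metadata repeated; a complete participant contributes exactly 24 rows
    (6 metrics x 4 conditions). Columns: participant_id, group, weight_kg,
    race, medicated, condition, metric, value, transformed.
    """
    rows = []
    for rec in cohort:
        for code in CONDITION_CODES:
            try:
                mset = compute_metric_set(rec.trials[code], settings, **kwargs)
            except Exception as exc:
                raise type(exc)(
                    f"participant {rec.participant_id}, condition {code}: {exc}"
                ) from exc
            for metric, value in mset.as_dict().items():
                rows.append(
                    {
                        "participant_id": rec.participant_id,
                        "group": rec.group,
                        "weight_kg": rec.weight_kg,
                        "race": rec.race,
                        "medicated": rec.medicated,
                        "condition": code,
                        "metric": metric,
                        "value": value,
                        "transformed": False,
                    }
                )
    return pd.DataFrame(rows)


def _ks_pvalue(values: np.ndarray, method: str) -> float:
    if method == "lilliefors":
        from statsmodels.stats.diagnostic import lilliefors

        _, p = lilliefors(values, dist="norm", pvalmethod="table")
        return float(p)
    if method == "ks":
        # naive KS against a normal with estimated mean/sd (anticonservative)
        _, p = stats.kstest(values, "norm", args=(values.mean(), values.std(ddof=1)))
        return float(p)
    raise ValueError(f"unknown normality method {method!r}")


def normality_screen(
    table: pd.DataFrame,
    alpha: float = 0.05,
    *,
    method: str = "lilliefors",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Screen each metric x condition variable and log-transform violators.

    The unit of screening is the whole variable (all participants' values
    of one metric in one condition, 24 variables in the full design). A
    variable whose KS p-value falls below ``alpha`` is replaced by its
    natural log with ``transformed=True`` — unless it contains
    non-positive values, in which case the transform is skipped with a
    warning. Returns ``(screened_table, report)`` where the report lists
    the per-variable decision.

    ``method`` is ``"lilliefors"`` (KS with estimated parameters and
    Monte-Carlo/table critical values, the default) or ``"ks"`` (naive KS
    with estimated parameters, anticonservative).
    """
    out = table.copy()
    report_rows = []
    for (metric, condition), grp in table.groupby(["metric", "condition"], sort=False):
        values = grp["value"].to_numpy(float)
        p = _ks_pvalue(values, method)
        violates = p < alpha
        action = "none"
        if violates:
            if np.any(values <= 0):
                warnings.warn(
                    f"{metric}/{condition}: non-normal but contains non-positive "
                    "values; log transform skipped",
                    stacklevel=2,
                )
                action = "skipped (non-positive values)"
            else:
                out.loc[grp.index, "value"] = np.log(values)
                out.loc[grp.index, "transformed"] = True
                action = "log"
        report_rows.append(
            {
                "metric": metric,
                "condition": condition,
                "method": method,
                "p_value": p,
                "violates_normality": violates,
                "action": action,
            }
        )
    report = pd.DataFrame(report_rows)
    n_logged = int((report["action"] == "log").sum())
    logger.info("normality screen: %d of %d variables log-transformed", n_logged, len(report))
    return out, report


def to_wide(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long table to participants x (metric, condition) columns.

    Column labels are ``{metric}@{condition}``; the participant metadata
    is carried in columns group/weight_kg/race/medicated. This is the
    input layout of the MFA.
    """
    wide = table.pivot_table(
        index="participant_id",
        columns=["metric", "condition"],
        values="value",
        sort=False,
    )
    wide.columns = [f"{m}@{c}" for m, c in wide.columns]
    meta = (
        table[["participant_id", "group", "weight_kg", "race", "medicated"]]
        .drop_duplicates("participant_id")
        .set_index("participant_id")
    )
    return meta.join(wide)
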