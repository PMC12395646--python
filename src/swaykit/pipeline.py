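"""End-to-end study pipeline: cohort -> metrics -> ANOVA -> MFA -> report.

``run_pipeline`` either simulates a synthetic cohort or ingests trial
files via a manifest, computes the six-metric battery per trial, screens
for normality, fits the mixed 2x2x2 ANOVA per metric with covariates,
fits the combined and per-group MFA, and writes a plain-text report
bundle (TSV tables plus a YAML run manifest recording every setting and
decision). Deterministic under the config seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .anova import MixedSwayAnova, medication_regroup
from .battery import METRICS, metrics_table, normality_screen, to_wide
from .io import read_cohort, write_cohort
from .mfa import (
    MFA,
    dimension_group_test,
    group_variance_share,
    interpret_loadings,
)
from .preprocess import PreprocessSettings
from .simulate import CohortSpec, generate_cohort

logger = logging.getLogger("swaykit")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything a pipeline run depends on, in one serialisable object."""

    mode: str = "simulate"  # "simulate" | "analyze"
    manifest: str | None = None  # analyze mode: cohort manifest path
    out_dir: str = "swaykit_out"
    seed: int = 0
    preprocess: PreprocessSettings = field(default_factory=PreprocessSettings)
    cohort: CohortSpec | None = None  # simulate mode; default spec if None
    screen_alpha: float = 0.05
    screen_method: str = "lilliefors"
    covariates: tuple[str, ...] = ("weight_kg", "race")
    mfa_n_dims: int | None = None  # None -> Horn's parallel analysis
    mfa_rotate: bool = True
    horn_quantile: float = 0.95
    horn_iter: int = 500
    substantial_threshold: float = 0.40
    crossload_threshold: float = 0.32
    medication_split: bool = False
    write_trials: bool = False  # simulate mode: also dump trial CSVs

    def __post_init__(self):
        if self.mode not in ("simulate", "analyze"):
            raise ValueError(f"mode must be 'simulate' or 'analyze', got {self.mode!r}")
        if self.mode == "analyze" and not self.manifest:
            raise ValueError("analyze mode needs a manifest path")
        for thr in (self.substantial_threshold, self.crossload_threshold):
            if not 0 < thr < 1:
                raise ValueError("loading thresholds must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "preprocess" in raw:
            raw["preprocess"] = PreprocessSettings(**raw["preprocess"])
        if "cohort" in raw and raw["cohort"] is not None:
            raw["cohort"] = CohortSpec(**raw["cohort"])
        if "covariates" in raw:
            raw["covariates"] = tuple(raw["covariates"])
        return cls(**raw)


@dataclass
class PipelineResult:
    """In-memory handles on everything the pipeline wrote."""

    config: PipelineConfig
    metrics: pd.DataFrame
    screened: pd.DataFrame
    normality_report: pd.DataFrame
    anova_tables: dict[str, pd.DataFrame]
    contrasts: dict[str, pd.DataFrame]
    mfa_results: "object"
    group_shares: pd.DataFrame
    dimension_tests: dict[str, dict]
    out_dir: Path


def _write(df: pd.DataFrame, path: Path, **kwargs) -> None:
    df.to_csv(path, sep="\t", index=kwargs.pop("index", False), **kwargs)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full study pipeline and write the report bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    decisions: list[str] = []

    # ---- cohort -------------------------------------------------------
    if config.mode == "simulate":
        spec = config.cohort or CohortSpec(seed=config.seed)
        if spec.seed != config.seed:
            spec = spec.replace(seed=config.seed)
        cohort, truth = generate_cohort(spec)
        decisions.append(
            f"simulated cohort: {len(cohort)} participants "
            f"({spec.n_per_group[0]} {spec.group_labels[0]} + "
            f"{spec.n_per_group[1]} {spec.group_labels[1]}), seed {spec.seed}"
        )
        _write(truth, out / "truth_table.tsv")
        if config.write_trials:
            write_cohort(cohort, out / "trials")
            decisions.append("trial CSVs + manifest written to trials/")
    else:
        cohort = read_cohort(config.manifest)
        decisions.append(f"read {len(cohort)} complete participants from {config.manifest}")

    # ---- metric battery ----------------------------------------------
    metrics = metrics_table(cohort, config.preprocess)
    _write(metrics, out / "metrics.tsv")
    decisions.append(
        f"preprocessing: decimate to {config.preprocess.target_fs} Hz, "
        f"Butterworth order {config.preprocess.order} low-pass "
        f"{config.preprocess.cutoff} Hz, zero_phase={config.preprocess.zero_phase}"
    )

    screened, report = normality_screen(
        metrics, config.screen_alpha, method=config.screen_method
    )
    _write(report, out / "normality_report.tsv")
    n_logged = int((report["action"] == "log").sum())
    decisions.append(
        f"normality screen ({config.screen_method}, alpha={config.screen_alpha}): "
        f"{n_logged}/{len(report)} variables log-transformed"
    )

    # ---- mixed ANOVAs -------------------------------------------------
    if config.medication_split:
        screened = medication_regroup(screened)
        decisions.append("group recoded to three medication-aware levels")
    anova_tables: dict[str, pd.DataFrame] = {}
    contrasts: dict[str, pd.DataFrame] = {}
    anova_rows = []
    for metric in METRICS:
        res = MixedSwayAnova(screened, metric, config.covariates).fit()
        anova_tables[metric] = res.anova_table
        tbl = res.anova_table.copy()
        tbl.insert(0, "metric", metric)
        anova_rows.append(tbl)
        for effect, by in (("group:eye", "eye"), ("group:base", "base")):
            if res.effect(effect)["p"] < 0.05:
                con = res.contrasts(by=by)
                con.insert(0, "metric", metric)
                contrasts[f"{metric}:{by}"] = con
    anova_all = pd.concat(anova_rows, ignore_index=True)
    _write(anova_all, out / "anova_results.tsv")
    if contrasts:
        _write(pd.concat(contrasts.values(), ignore_index=True), out / "contrasts.tsv")
        decisions.append(
            "Bonferroni follow-up contrasts run for significant interactions: "
            + ", ".join(contrasts)
        )

    # ---- MFA ----------------------------------------------------------
    wide = to_wide(screened)
    feature_cols = [c for c in wide.columns if "@" in c]
    mfa_model = MFA(
        wide[feature_cols],
        n_dims=config.mfa_n_dims,
        rotate=config.mfa_rotate,
        horn_iter=config.horn_iter,
        horn_quantile=config.horn_quantile,
        seed=config.seed,
    )
    mfa_res = mfa_model.fit()
    decisions.append(
        f"MFA: Horn retains {mfa_res.diagnostics.horn_retained} dims; "
        f"{mfa_res.n_retained} interpreted; KMO overall "
        f"{mfa_res.diagnostics.kmo_overall:.3f}"
    )
    _write(mfa_res.loadings_table(), out / "mfa_loadings.tsv")

    groups = wide["group"]
    shares = group_variance_share(
        wide[feature_cols], groups, n_dims=max(mfa_res.n_retained, 2),
        horn_iter=config.horn_iter, seed=config.seed,
    )
    summary_rows = [
        {
            "item": f"eigenvalue_{dim}",
            "value": float(ev),
            "pct_variance": float(mfa_res.variance_explained[dim]),
        }
        for dim, ev in zip(mfa_res.variance_explained.index[:6], mfa_res.eigenvalues[:6])
    ]
    _write(pd.DataFrame(summary_rows), out / "mfa_summary.tsv")
    _write(shares, out / "mfa_group_shares.tsv")

    dim_tests = {}
    for dim in mfa_res.scores.columns[: mfa_res.n_retained]:
        dim_tests[dim] = dimension_group_test(mfa_res.scores[dim], groups)
    _write(
        pd.DataFrame([{"dim": d, **v} for d, v in dim_tests.items()]),
        out / "dimension_group_tests.tsv",
    )

    if mfa_res.rotated_loadings is not None:
        classification = interpret_loadings(
            mfa_res.rotated_loadings,
            config.substantial_threshold,
            config.crossload_threshold,
        )
        _write(classification.reset_index(), out / "loading_classification.tsv")
        biplot = mfa_res.rotated_loadings.copy()
        biplot["contrib_dim1"] = mfa_res.contrib.iloc[:, 0]
        if biplot.shape[1] > 2:
            biplot["contrib_dim2"] = mfa_res.contrib.iloc[:, 1]
        _write(biplot.reset_index(names="variable"), out / "biplot_data.tsv")

    # ---- run manifest -------------------------------------------------
    manifest = {
        "swaykit_version": __version__,
        "config": _config_dict(config),
        "decisions": decisions,
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    (out / "run_manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    logger.info("pipeline complete: %s", out)

    return PipelineResult(
        config=config,
        metrics=metrics,
        screened=screened,
        normality_report=report,
        anova_tables=anova_tables,
        contrasts=contrasts,
        mfa_results=mfa_res,
        group_shares=shares,
        dimension_tests=dim_tests,
        out_dir=out,
    )


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    for key, value in list(d.items()):
        if isinstance(value, tuple):
            d[key] = list(value)
    for sub in ("preprocess", "cohort"):
        if isinstance(d.get(sub), dict):
            d[sub] = {
                k: (list(v) if isinstance(v, tuple) else v) for k, v in d[sub].items()
            }
    return _plain(d)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
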