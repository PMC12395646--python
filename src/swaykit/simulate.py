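"""Synthetic force-plate cohorts with known ground truth.

Real quiet-standing recordings were not available, so the test bed for
the whole pipeline is a generator that plants exactly the structure the
analysis assumes:

* a slow *rambling* reference r(t) — band-limited Gaussian noise in the
  CNS band (0–0.5 Hz by default);
* a fast *trembling* oscillation tau(t) around it — band-limited noise in
  the PNS band (1.5–8 Hz by default);
* CoP = r + tau exactly, per axis;
* a horizontal shear force f = -k (CoP - r) + noise, a restoring spring
  toward the reference, so the force crosses zero exactly where the CoP
  crosses its reference and the true instant equilibrium points are known;
* 2 x 2 sensory conditions (eyes open/closed x base open/closed) and two
  groups with multiplicative amplitude effects, plus per-participant
  latent slow/fast amplitude factors shared across axes and conditions —
  which is what gives the battery its two-factor correlation structure.

Everything is deterministic given the spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .io import CONDITION_CODES, Condition, ForcePlateTrial, ParticipantRecord

__all__ = ["CohortSpec", "TrialTruth", "generate_trial", "generate_cohort",
           "null_metric_table"]

AXES = ("ML", "AP")
COMPONENTS = ("slow", "fast")


def _per_group(value, group: str) -> float:
    """Multiplier entries may be scalars or {group: scalar} maps."""
    if isinstance(value, Mapping):
        return float(value[group])
    return float(value)


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters of the synthetic cohort.

    Defaults mirror the design the pipeline targets: 49 clinical (ASC)
    and 94 control (NC) participants, four conditions of 120 s recorded
    at 200 Hz, CNS-band rambling below 0.5 Hz and PNS-band trembling
    above 1.5 Hz. Amplitudes are in mm; the spring constant converts mm
    of trembling excursion into newtons of restoring shear force.

    Condition and group effects are multiplicative on component RMS:
    eyes-closed inflates the slow component (more in controls), closed
    base inflates both, and the clinical group carries a larger fast
    component with greater between-participant dispersion — the planted
    analogues of the sway effects the pipeline is meant to detect.
    """

    n_per_group: tuple[int, int] = (49, 94)
    group_labels: tuple[str, str] = ("ASC", "NC")
    fs: float = 200.0
    duration: float = 120.0
    rambling_band: tuple[float, float] = (0.0, 0.5)
    trembling_band: tuple[float, float] = (1.5, 8.0)
    #: baseline component RMS per axis, mm
    rambling_rms: Mapping[str, float] = field(
        default_factory=lambda: {"ML": 4.0, "AP": 6.0}
    )
    trembling_rms: Mapping[str, float] = field(
        default_factory=lambda: {"ML": 0.8, "AP": 1.0}
    )
    #: restoring-force scale, N per mm of trembling excursion
    spring_constant: float = 0.7
    force_noise_sd: float = 0.0
    #: amplitude multipliers: factor level -> component -> scalar or per-group map
    condition_multipliers: Mapping[str, Mapping] = field(
        default_factory=lambda: {
            "eye_closed": {"slow": {"ASC": 1.2, "NC": 1.4}, "fast": 1.1},
            "base_closed": {"slow": 1.25, "fast": 1.3},
        }
    )
    group_multipliers: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "ASC": {"slow": 1.0, "fast": 1.3},
            "NC": {"slow": 1.0, "fast": 1.0},
        }
    )
    #: sd of the log-normal participant latent amplitude factors; the
    #: clinical group's larger fast dispersion is what gives its fast
    #: dimension the larger variance share in the per-group MFA
    latent_sd: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "ASC": {"slow": 0.15, "fast": 0.65},
            "NC": {"slow": 0.15, "fast": 0.30},
        }
    )
    #: sd of the per-trial, per-axis log-normal amplitude jitter
    trial_jitter_sd: float = 0.18
    #: covariate models per group
    weight_model: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"ASC": (79.55, 26.67), "NC": (69.42, 17.36)}
    )
    race_white_prob: Mapping[str, float] = field(
        default_factory=lambda: {"ASC": 0.898, "NC": 0.608}
    )
    medicated_prob: Mapping[str, float] = field(
        default_factory=lambda: {"ASC": 28 / 49, "NC": 0.0}
    )
    seed: int = 0

    def __post_init__(self):
        if self.rambling_band[1] > self.trembling_band[0]:
            raise ValueError("rambling band must end before the trembling band starts")
        if self.trembling_band[1] >= self.fs / 2:
            raise ValueError("trembling band exceeds the Nyquist frequency")
        if min(self.n_per_group) < 2:
            raise ValueError("need at least 2 participants per group")
        for m in (self.rambling_rms, self.trembling_rms):
            if any(v < 0 for v in m.values()):
                raise ValueError("component RMS targets must be >= 0")

    @classmethod
    def null(cls, n_per_group: tuple[int, int] = (49, 94), seed: int = 0, **kwargs) -> "CohortSpec":
        """A no-effect spec: all multipliers 1, identical latent dispersion.

        Group labels remain, but group and condition have no influence on
        the generated amplitudes — the null for calibration studies.
        """
        return cls(
            n_per_group=n_per_group,
            condition_multipliers={
                "eye_closed": {"slow": 1.0, "fast": 1.0},
                "base_closed": {"slow": 1.0, "fast": 1.0},
            },
            group_multipliers={
                "ASC": {"slow": 1.0, "fast": 1.0},
                "NC": {"slow": 1.0, "fast": 1.0},
            },
            latent_sd={
                "ASC": {"slow": 0.15, "fast": 0.30},
                "NC": {"slow": 0.15, "fast": 0.30},
            },
            seed=seed,
            **kwargs,
        )

    def replace(self, **changes) -> "CohortSpec":
        return replace(self, **changes)

    def component_rms(
        self, group: str, condition: Condition, axis: str, component: str
    ) -> float:
        """Planted RMS (before latent factors) for one component of one axis."""
        base = (self.rambling_rms if component == "slow" else self.trembling_rms)[axis]
        mult = self.group_multipliers[group][component]
        if condition.eye == "closed":
            mult *= _per_group(self.condition_multipliers["eye_closed"][component], group)
        if condition.base == "closed":
            mult *= _per_group(self.condition_multipliers["base_closed"][component], group)
        return base * mult


@dataclass
class TrialTruth:
    """Ground-truth components behind one generated trial."""

    participant_id: str
    condition: str
    true_rambling: dict[str, np.ndarray]
    true_trembling: dict[str, np.ndarray]
    true_rambling_rms: dict[str, float]
    true_trembling_rms: dict[str, float]
    multipliers: dict[str, float]


def band_limited_noise(
    n: int, fs: float, band: tuple[float, float], rms: float, rng: np.random.Generator
) -> np.ndarray:
    """Zero-mean Gaussian noise with all spectral power inside ``band``.

    White Gaussian noise is masked in the rFFT domain to the open-closed
    interval (band[0], band[1]] (DC always excluded) and rescaled to the
    requested RMS. With ``rms == 0`` the zero signal is returned.
    """
    if rms == 0:
        return np.zeros(n)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec = np.fft.rfft(rng.standard_normal(n))
    mask = (freqs > band[0]) & (freqs <= band[1]) & (freqs > 0)
    if not mask.any():
        raise ValueError(f"band {band} contains no FFT bins at n={n}, fs={fs}")
    spec[~mask] = 0.0
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def generate_trial(
    spec: CohortSpec,
    group: str,
    condition: Condition | str,
    participant_seed: int,
    *,
    participant_id: str = "sim",
    latent: Mapping[str, float] | None = None,
) -> tuple[ForcePlateTrial, TrialTruth]:
    """Generate one synthetic trial plus its ground truth.

    ``latent`` maps component -> participant amplitude factor (default 1).
    Deterministic under ``(spec.seed, participant_seed, condition)``.
    """
    condition = condition if isinstance(condition, Condition) else Condition.from_code(condition)
    latent = dict(latent or {})
    n = int(round(spec.duration * spec.fs))
    cidx = CONDITION_CODES.index(condition.code)
    rng = np.random.default_rng([spec.seed, participant_seed & 0x7FFFFFFF, cidx])
    t = np.arange(n) / spec.fs

    rambling, trembling, cop, force = {}, {}, {}, {}
    r_rms, t_rms, mults = {}, {}, {}
    for axis in AXES:
        jitter_slow = float(np.exp(rng.normal(0.0, spec.trial_jitter_sd)))
        jitter_fast = float(np.exp(rng.normal(0.0, spec.trial_jitter_sd)))
        amp_slow = (
            spec.component_rms(group, condition, axis, "slow")
            * latent.get("slow", 1.0) * jitter_slow
        )
        amp_fast = (
            spec.component_rms(group, condition, axis, "fast")
            * latent.get("fast", 1.0) * jitter_fast
        )
        r = band_limited_noise(n, spec.fs, spec.rambling_band, amp_slow, rng)
        tau = band_limited_noise(n, spec.fs, spec.trembling_band, amp_fast, rng)
        f = -spec.spring_constant * tau
        if spec.force_noise_sd > 0:
            f = f + rng.normal(0.0, spec.force_noise_sd, n)
        rambling[axis], trembling[axis] = r, tau
        cop[axis], force[axis] = r + tau, f
        r_rms[axis], t_rms[axis] = amp_slow, amp_fast
        mults[f"slow_{axis}"], mults[f"fast_{axis}"] = amp_slow, amp_fast

    trial = ForcePlateTrial(
        participant_id=participant_id,
        condition=condition,
        t=t,
        cop_ml=cop["ML"],
        cop_ap=cop["AP"],
        f_ml=force["ML"],
        f_ap=force["AP"],
        fs=spec.fs,
        unit="mm",
    )
    truth = TrialTruth(
        participant_id=participant_id,
        condition=condition.code,
        true_rambling=rambling,
        true_trembling=trembling,
        true_rambling_rms=r_rms,
        true_trembling_rms=t_rms,
        multipliers=mults,
    )
    return trial, truth


def generate_cohort(
    spec: CohortSpec, *, keep_truth_signals: bool = False
) -> tuple[list[ParticipantRecord], pd.DataFrame]:
    """Generate the full two-group cohort.

    Returns the participant records (one trial per condition each) and a
    truth table with one row per participant x condition x axis holding
    the planted component RMS values and the participant latent factors.
    Trial-level truth signals are dropped unless ``keep_truth_signals``
    (they are large); the planted RMS columns are what recovery tests
    need at cohort scale.
    """
    records: list[ParticipantRecord] = []
    truth_rows = []
    meta_rng = np.random.default_rng([spec.seed, 999_983])
    pidx = 0
    for group, n_group in zip(spec.group_labels, spec.n_per_group):
        for i in range(n_group):
            pid = f"{group}{i + 1:03d}"
            latent = {
                comp: float(np.exp(meta_rng.normal(0.0, spec.latent_sd[group][comp])))
                for comp in COMPONENTS
            }
            mean_w, sd_w = spec.weight_model[group]
            weight = float(np.clip(meta_rng.normal(mean_w, sd_w), 40.0, 180.0))
            race = "White" if meta_rng.random() < spec.race_white_prob[group] else "non-White"
            medicated = bool(meta_rng.random() < spec.medicated_prob[group])
            trials = {}
            for code in CONDITION_CODES:
                trial, truth = generate_trial(
                    spec, group, code, pidx, participant_id=pid, latent=latent
                )
                trials[code] = trial
                for axis in AXES:
                    truth_rows.append(
                        {
                            "participant_id": pid,
                            "group": group,
                            "condition": code,
                            "axis": axis,
                            "latent_slow": latent["slow"],
                            "latent_fast": latent["fast"],
                            "true_rambling_rms": truth.true_rambling_rms[axis],
                            "true_trembling_rms": truth.true_trembling_rms[axis],
                            **(
                                {
                                    "true_rambling": truth.true_rambling[axis],
                                    "true_trembling": truth.true_trembling[axis],
                                }
                                if keep_truth_signals
                                else {}
                            ),
                        }
                    )
            records.append(
                ParticipantRecord(
                    participant_id=pid,
                    group=group,
                    weight_kg=weight,
                    race=race,
                    medicated=medicated,
                    trials=trials,
                )
            )
            pidx += 1
    return records, pd.DataFrame(truth_rows)


def null_metric_table(
    n_per_group: tuple[int, int] = (10, 10),
    seed: int = 0,
    *,
    group_labels: tuple[str, str] = ("ASC", "NC"),
    participant_sd: float = 1.0,
    noise_sd: float = 1.0,
    metric: str = "metric",
) -> pd.DataFrame:
    """An exchangeable-null long metrics table for calibration studies.

    Values are participant random intercepts plus iid cell noise —
    compound symmetry with no group, condition or covariate effects, so
    every mixed-ANOVA F test is exact and its type-I error should sit at
    the nominal level. Covariates are drawn independently of everything.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for group, n_group in zip(group_labels, n_per_group):
        for i in range(n_group):
            pid = f"{group}{i + 1:03d}"
            intercept = rng.normal(0.0, participant_sd)
            weight = rng.normal(75.0, 15.0)
            race = "White" if rng.random() < 0.7 else "non-White"
            for code in CONDITION_CODES:
                rows.append(
                    {
                        "participant_id": pid,
                        "group": group,
                        "weight_kg": weight,
                        "race": race,
                        "medicated": False,
                        "condition": code,
                        "metric": metric,
                        "value": intercept + rng.normal(0.0, noise_sd),
                        "transformed": False,
                    }
                )
    return pd.DataFrame(rows)
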