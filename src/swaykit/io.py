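"""Force-plate trial I/O and the core trial data model.

A trial is one quiet-standing recording for one participant under one
sensory condition: the centre-of-pressure (CoP) trajectory in the
medio-lateral (ML) and anterior-posterior (AP) axes plus the two
horizontal shear-force channels used by the rambling-trembling
decomposition. Trials are stored as plain delimited text with
``#``-prefixed metadata comments, so any force-plate export can be
massaged into the format with a column-name mapping.
"""

from __future__ import annotations

import io as _io
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("swaykit")

__all__ = [
    "Condition",
    "ForcePlateTrial",
    "ParticipantRecord",
    "TrialFormatError",
    "TrialValidationError",
    "ManifestError",
    "read_trial",
    "write_trial",
    "read_cohort",
    "write_cohort",
    "DEFAULT_COLUMNS",
]

#: canonical channel names, in file order
DEFAULT_COLUMNS = ("time", "cop_ml", "cop_ap", "f_ml", "f_ap")

#: the four sensory conditions: eyes open/closed x base of support open/closed
CONDITION_CODES = ("EOOB", "EOCB", "ECOB", "ECCB")


class TrialFormatError(ValueError):
    """File does not follow the trial format (missing column, bad header)."""


class TrialValidationError(ValueError):
    """Channel data violate a trial invariant (non-finite, irregular fs)."""


class ManifestError(ValueError):
    """Cohort manifest is inconsistent (duplicates, unknown codes)."""


@dataclass(frozen=True)
class Condition:
    """One cell of the 2 (eye) x 2 (base of support) sensory design."""

    eye: str  # "open" | "closed"
    base: str  # "open" | "closed"

    def __post_init__(self):
        for name, value in (("eye", self.eye), ("base", self.base)):
            if value not in ("open", "closed"):
                raise ValueError(f"{name} must be 'open' or 'closed', got {value!r}")

    @property
    def code(self) -> str:
        """Four-letter code, e.g. eyes-closed / open-base -> ``ECOB``."""
        return f"E{self.eye[0].upper()}{self.base[0].upper()}B"

    @classmethod
    def from_code(cls, code: str) -> "Condition":
        code = code.strip().upper()
        if len(code) != 4 or code[0] != "E" or code[3] != "B":
            raise ValueError(f"not a condition code: {code!r}")
        mapping = {"O": "open", "C": "closed"}
        try:
            return cls(eye=mapping[code[1]], base=mapping[code[2]])
        except KeyError:
            raise ValueError(f"not a condition code: {code!r}") from None

    @classmethod
    def all(cls) -> tuple["Condition", ...]:
        return tuple(cls.from_code(c) for c in CONDITION_CODES)


@dataclass
class ForcePlateTrial:
    """One condition's CoP + horizontal-force time series for one participant.

    Parameters
    ----------
    t : array
        Time stamps in seconds, strictly increasing with spacing ``1/fs``.
    cop_ml, cop_ap : array
        Centre-of-pressure position along the medio-lateral and
        anterior-posterior axes, in ``unit`` (default mm).
    f_ml, f_ap : array
        Horizontal shear force along each axis, in newtons. Zero crossings
        of these channels mark the instant equilibrium points.
    fs : float
        Sampling rate in Hz.
    """

    participant_id: str
    condition: Condition
    t: np.ndarray
    cop_ml: np.ndarray
    cop_ap: np.ndarray
    f_ml: np.ndarray
    f_ap: np.ndarray
    fs: float
    unit: str = "mm"
    meta: dict = field(default_factory=dict)

    #: relative tolerance on sample spacing vs 1/fs
    _spacing_rtol = 1e-3

    def __post_init__(self):
        arrays = {}
        for name in ("t", "cop_ml", "cop_ap", "f_ml", "f_ap"):
            arrays[name] = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arrays[name])
        n = len(self.t)
        if n < 2:
            raise TrialValidationError("trial needs at least 2 samples")
        for name, arr in arrays.items():
            if arr.ndim != 1 or len(arr) != n:
                raise TrialValidationError(
                    f"channel {name!r} has length {len(arr)}, expected {n}"
                )
            bad = np.flatnonzero(~np.isfinite(arr))
            if bad.size:
                raise TrialValidationError(
                    f"non-finite value in channel {name!r} at row {bad[0]}"
                )
        if not self.fs > 0:
            raise TrialValidationError(f"fs must be positive, got {self.fs}")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise TrialValidationError("time vector must be strictly increasing")
        expected = 1.0 / self.fs
        if np.any(np.abs(dt - expected) > self._spacing_rtol * expected):
            raise TrialValidationError(
                f"irregular sampling: spacing deviates from 1/fs = {expected:g} s"
            )

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        """Trial duration in seconds (last minus first time stamp)."""
        return float(self.t[-1] - self.t[0])

    def channels(self) -> dict[str, np.ndarray]:
        return {
            "cop_ml": self.cop_ml,
            "cop_ap": self.cop_ap,
            "f_ml": self.f_ml,
            "f_ap": self.f_ap,
        }

    def with_channels(self, *, fs: float | None = None, t=None, **channels) -> "ForcePlateTrial":
        """Copy of the trial with some channels (and optionally fs/t) replaced."""
        kwargs = dict(channels)
        if fs is not None:
            kwargs["fs"] = fs
        if t is not None:
            kwargs["t"] = t
        return replace(self, **kwargs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.t,
                "cop_ml": self.cop_ml,
                "cop_ap": self.cop_ap,
                "f_ml": self.f_ml,
                "f_ap": self.f_ap,
            }
        )


@dataclass
class ParticipantRecord:
    """A participant's metadata plus one trial per sensory condition."""

    participant_id: str
    group: str
    weight_kg: float
    race: str
    medicated: bool
    trials: dict[str, ForcePlateTrial]  # condition code -> trial

    def __post_init__(self):
        if not self.weight_kg > 0:
            raise TrialValidationError(
                f"participant {self.participant_id}: weight must be positive"
            )
        codes = sorted(self.trials)
        if codes != sorted(CONDITION_CODES):
            raise TrialValidationError(
                f"participant {self.participant_id}: expected one trial per "
                f"condition {CONDITION_CODES}, got {codes}"
            )

    def trial(self, code: str) -> ForcePlateTrial:
        return self.trials[code.upper()]


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_trial(
    path,
    *,
    participant_id: str | None = None,
    condition: str | Condition | None = None,
    column_map: Mapping[str, str] | None = None,
    unit: str | None = None,
    fs: float | None = None,
) -> ForcePlateTrial:
    """Read a single trial from a delimited text file.

    The file holds a header row naming the five channels and optional
    ``# key = value`` comment lines before it (recognised keys: ``fs``,
    ``unit``, ``participant_id``, ``condition``). ``column_map`` maps
    canonical names (``time``, ``cop_ml``, ...) to the file's own column
    names for vendor exports. Explicit keyword arguments override file
    metadata; ``fs`` is inferred from the time column when absent.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    lines = path.read_text().splitlines()
    data_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
        else:
            data_start = i
            break
    else:
        raise TrialFormatError(f"{path}: no data rows")

    text = "\n".join(lines[data_start:])
    delim = _sniff_delimiter(lines[data_start])
    df = pd.read_csv(_io.StringIO(text), sep=delim)

    colmap = dict(zip(DEFAULT_COLUMNS, DEFAULT_COLUMNS))
    if column_map:
        colmap.update(column_map)
    for canonical, actual in colmap.items():
        if actual not in df.columns:
            raise TrialFormatError(
                f"{path}: missing column {actual!r} (for channel {canonical!r})"
            )

    t = df[colmap["time"]].to_numpy(float)
    if fs is None:
        fs = float(meta["fs"]) if "fs" in meta else None
    if fs is None:
        dt = np.diff(t)
        if len(dt) == 0:
            raise TrialFormatError(f"{path}: cannot infer fs from a single row")
        fs = 1.0 / float(np.median(dt))

    return ForcePlateTrial(
        participant_id=participant_id or meta.get("participant_id", path.stem),
        condition=_coerce_condition(condition or meta.get("condition", "EOOB")),
        t=t,
        cop_ml=df[colmap["cop_ml"]].to_numpy(float),
        cop_ap=df[colmap["cop_ap"]].to_numpy(float),
        f_ml=df[colmap["f_ml"]].to_numpy(float),
        f_ap=df[colmap["f_ap"]].to_numpy(float),
        fs=float(fs),
        unit=unit or meta.get("unit", "mm"),
        meta=meta,
    )


def _coerce_condition(cond) -> Condition:
    if isinstance(cond, Condition):
        return cond
    return Condition.from_code(str(cond))


def write_trial(trial: ForcePlateTrial, path, *, sep: str = ",", float_fmt: str = "%.10g") -> None:
    """Write a trial in the format :func:`read_trial` reads back."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# fs = {trial.fs:.10g}\n")
        fh.write(f"# unit = {trial.unit}\n")
        fh.write(f"# participant_id = {trial.participant_id}\n")
        fh.write(f"# condition = {trial.condition.code}\n")
        trial.to_frame().to_csv(fh, sep=sep, index=False, float_format=float_fmt)


MANIFEST_COLUMNS = (
    "participant_id",
    "condition",
    "file",
    "group",
    "weight_kg",
    "race",
    "medicated",
)


def read_cohort(
    manifest_path,
    *,
    strict: bool = True,
    column_map: Mapping[str, str] | None = None,
) -> list[ParticipantRecord]:
    """Read a whole cohort from a manifest CSV.

    The manifest maps (participant_id, condition) to a trial file, with
    participant-level metadata repeated on each row. Participants missing
    any of the four conditions are excluded with a logged reason when
    ``strict`` (default), otherwise they raise.
    """
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ManifestError(f"manifest missing columns: {missing}")
    if manifest.empty:
        warnings.warn("empty cohort manifest", stacklevel=2)
        return []

    dup = manifest.duplicated(subset=["participant_id", "condition"])
    if dup.any():
        pairs = manifest.loc[dup, ["participant_id", "condition"]].to_records(index=False)
        raise ManifestError(f"duplicate (participant, condition) pairs: {list(pairs)}")

    records: list[ParticipantRecord] = []
    for pid, rows in manifest.groupby("participant_id", sort=False):
        codes = set(rows["condition"].str.upper())
        if codes != set(CONDITION_CODES):
            msg = (
                f"participant {pid!r} has conditions {sorted(codes)}, "
                f"expected all of {CONDITION_CODES}"
            )
            if strict:
                logger.warning("excluding %s", msg)
                continue
            raise ManifestError(msg)
        first = rows.iloc[0]
        trials = {}
        for _, row in rows.iterrows():
            trial_path = Path(row["file"])
            if not trial_path.is_absolute():
                trial_path = manifest_path.parent / trial_path
            code = str(row["condition"]).upper()
            trials[code] = read_trial(
                trial_path,
                participant_id=str(pid),
                condition=code,
                column_map=column_map,
            )
        records.append(
            ParticipantRecord(
                participant_id=str(pid),
                group=str(first["group"]),
                weight_kg=float(first["weight_kg"]),
                race=str(first["race"]),
                medicated=bool(first["medicated"]),
                trials=trials,
            )
        )
    return records


def write_cohort(records: Sequence[ParticipantRecord], out_dir, *, sep: str = ",") -> Path:
    """Write trial files plus a manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        for code, trial in sorted(rec.trials.items()):
            fname = f"{rec.participant_id}_{code}.csv"
            write_trial(trial, out_dir / fname, sep=sep)
            rows.append(
                {
                    "participant_id": rec.participant_id,
                    "condition": code,
                    "file": fname,
                    "group": rec.group,
                    "weight_kg": rec.weight_kg,
                    "race": rec.race,
                    "medicated": rec.medicated,
                }
            )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(manifest, index=False)
    return manifest
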