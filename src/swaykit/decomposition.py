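"""Rambling-trembling decomposition of a CoP axis.

The CoP trajectory is split into a slow *rambling* component — the
migrating reference point the CNS steers, estimated as a cubic spline
through the CoP values at the instant equilibrium points (IEPs, where the
horizontal shear force is zero and the body is momentarily aligned over
its support) — and a fast *trembling* residual around it, attributed to
peripheral, proprioception-driven corrections. Each axis (ML, AP) is
decomposed independently against its own force channel, and both
components are summarised by their RMS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .io import ForcePlateTrial

__all__ = ["Decomposition", "find_ieps", "decompose_axis", "decompose_trial", "rms"]

#: force below this fraction of its max absolute value counts as "identically zero"
_ZERO_FORCE_ATOL = 1e-12


@dataclass
class Decomposition:
    """Rambling/trembling split of one CoP axis.

    ``rambling + trembling`` reconstructs the input CoP exactly at every
    sample; ``iep_times``/``iep_values`` are the spline knots (equilibrium
    instants and the CoP there, linearly interpolated between samples).
    """

    axis: str  # "ML" | "AP"
    t: np.ndarray
    cop: np.ndarray
    rambling: np.ndarray
    trembling: np.ndarray
    iep_times: np.ndarray
    iep_values: np.ndarray
    degenerate: bool = False
    spline_fallback: bool = False

    @property
    def n_iep(self) -> int:
        return len(self.iep_times)

    def rms_rambling(self, demean: bool = True) -> float:
        return rms(self.rambling, demean=demean)

    def rms_trembling(self, demean: bool = True) -> float:
        return rms(self.trembling, demean=demean)

    def to_frame(self):
        import pandas as pd

        idx = np.searchsorted(self.t, self.iep_times)
        idx = np.clip(idx, 0, len(self.t) - 1)
        is_iep = np.zeros(len(self.t), dtype=bool)
        is_iep[idx] = True
        return pd.DataFrame(
            {
                "t": self.t,
                "cop": self.cop,
                "rambling": self.rambling,
                "trembling": self.trembling,
                "is_iep": is_iep,
            }
        )


def find_ieps(force, t) -> tuple[np.ndarray, np.ndarray]:
    """Locate instant equilibrium points: zeros of the horizontal force.

    Every sign change between consecutive samples yields one IEP at the
    linearly interpolated zero instant; samples that are exactly zero are
    IEPs themselves, with runs of consecutive zeros collapsed to their
    midpoint. Returns ``(iep_times, iep_indices)`` where the index points
    at the sample at (or just before) each crossing. Times are strictly
    increasing; the result may be empty.
    """
    f = np.asarray(force, dtype=float)
    t = np.asarray(t, dtype=float)
    if f.ndim != 1 or len(f) != len(t):
        raise ValueError("force and t must be 1-D and equal length")
    if len(f) < 2:
        raise ValueError("need at least 2 samples")
    if not np.all(np.isfinite(f)):
        raise ValueError("force must be finite")

    times: list[float] = []
    indices: list[int] = []

    zero = f == 0.0
    # exact zeros: collapse runs to their midpoint instant
    if zero.any():
        starts = np.flatnonzero(zero & ~np.roll(zero, 1))
        if zero[0]:
            starts = np.unique(np.concatenate([[0], starts]))
        for s in starts:
            e = s
            while e + 1 < len(f) and zero[e + 1]:
                e += 1
            times.append(0.5 * (t[s] + t[e]))
            indices.append(int(s))

    # sign changes between strictly nonzero neighbours
    s = np.sign(f)
    change = np.flatnonzero((s[:-1] * s[1:]) < 0)
    for i in change:
        # linear interpolation of the zero instant
        tau = t[i] + (t[i + 1] - t[i]) * (0.0 - f[i]) / (f[i + 1] - f[i])
        times.append(float(tau))
        indices.append(int(i))

    if not times:
        return np.array([]), np.array([], dtype=int)
    order = np.argsort(times)
    out_t = np.asarray(times)[order]
    out_i = np.asarray(indices, dtype=int)[order]
    # a near-zero sample between opposite signs produces two crossings at
    # float-coincident instants; keep one so times are strictly increasing
    eps = 1e-9 * max(float(t[-1] - t[0]) / max(len(t) - 1, 1), 1e-300)
    keep = np.concatenate([[True], np.diff(out_t) > eps])
    return out_t[keep], out_i[keep]


def decompose_axis(cop, force, t, *, axis: str = "ML") -> Decomposition:
    """Split one CoP axis into rambling and trembling.

    The CoP is sampled at each IEP instant by linear interpolation between
    the bracketing samples; a natural cubic spline through those knots
    (anchored additionally at the trial's first and last CoP samples, so
    no extrapolation occurs) evaluated on the full time grid is the
    rambling trajectory, and ``trembling = cop - rambling``.

    Degenerate inputs: a force channel that is identically zero yields
    ``rambling = cop`` and zero trembling with ``degenerate=True``; fewer
    than 4 spline knots falls back to linear interpolation with a warning.
    """
    cop = np.asarray(cop, dtype=float)
    force = np.asarray(force, dtype=float)
    t = np.asarray(t, dtype=float)
    if not (len(cop) == len(force) == len(t)):
        raise ValueError("cop, force and t must have equal length")

    fscale = np.max(np.abs(force)) if len(force) else 0.0
    if fscale <= _ZERO_FORCE_ATOL:
        return Decomposition(
            axis=axis,
            t=t,
            cop=cop,
            rambling=cop.copy(),
            trembling=np.zeros_like(cop),
            iep_times=np.array([]),
            iep_values=np.array([]),
            degenerate=True,
        )

    iep_times, _ = find_ieps(force, t)
    iep_values = np.interp(iep_times, t, cop)

    # anchor the spline at the trial boundaries so it is defined everywhere
    knot_t = iep_times
    knot_v = iep_values
    eps = 1e-9 * max(t[-1] - t[0], 1.0)
    if len(knot_t) == 0 or knot_t[0] > t[0] + eps:
        knot_t = np.concatenate([[t[0]], knot_t])
        knot_v = np.concatenate([[cop[0]], knot_v])
    if knot_t[-1] < t[-1] - eps:
        knot_t = np.concatenate([knot_t, [t[-1]]])
        knot_v = np.concatenate([knot_v, [cop[-1]]])
    # guard against coincident knots from interpolation round-off
    keep = np.concatenate([[True], np.diff(knot_t) > eps])
    knot_t, knot_v = knot_t[keep], knot_v[keep]

    fallback = False
    if len(knot_t) < 4:
        warnings.warn(
            f"only {len(knot_t)} equilibrium knots; falling back to linear "
            "interpolation for the rambling trajectory",
            stacklevel=2,
        )
        rambling = np.interp(t, knot_t, knot_v)
        fallback = True
    else:
        spline = CubicSpline(knot_t, knot_v, bc_type="natural")
        rambling = spline(t)

    return Decomposition(
        axis=axis,
        t=t,
        cop=cop,
        rambling=rambling,
        trembling=cop - rambling,
        iep_times=iep_times,
        iep_values=iep_values,
        spline_fallback=fallback,
    )


def decompose_trial(trial: ForcePlateTrial) -> dict[str, Decomposition]:
    """Decompose both axes of a trial; returns ``{"ML": ..., "AP": ...}``."""
    return {
        "ML": decompose_axis(trial.cop_ml, trial.f_ml, trial.t, axis="ML"),
        "AP": decompose_axis(trial.cop_ap, trial.f_ap, trial.t, axis="AP"),
    }


def rms(series, demean: bool = True) -> float:
    """Root mean square, optionally about the series mean."""
    v = np.asarray(series, dtype=float)
    if v.size == 0:
        raise ValueError("rms of an empty series")
    if demean:
        v = v - v.mean()
    return float(np.sqrt(np.mean(v**2)))
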