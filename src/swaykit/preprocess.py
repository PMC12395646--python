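"""Signal conditioning for force-plate trials.

The conventional posturography recipe applied here is plain decimation of
the 200 Hz recording to 50 Hz (keeping every k-th sample, MATLAB
``downsample`` style, i.e. no anti-alias prefilter unless asked for)
followed by a 4th-order Butterworth low-pass at 20 Hz. Zero-phase
(forward-backward) filtering is the default so the geometric metrics see
no phase lag; note this doubles the effective filter order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .io import ForcePlateTrial

__all__ = ["PreprocessSettings", "downsample", "lowpass", "preprocess"]


class ParameterError(ValueError):
    """A preprocessing setting is inconsistent with the trial."""


@dataclass(frozen=True)
class PreprocessSettings:
    """Settings for the decimate-then-filter conditioning stage.

    Attributes
    ----------
    target_fs : float
        Output sampling rate in Hz (default 50).
    cutoff : float
        Low-pass cutoff in Hz (default 20); must stay below the
        post-decimation Nyquist frequency.
    order : int
        Butterworth order (default 4).
    zero_phase : bool
        Run the filter forward and backward (filtfilt). Default True.
    antialias : bool
        Apply an anti-alias low-pass before decimation. Default False,
        replicating plain sample-dropping decimation.
    apply_to_force : bool
        Filter the shear-force channels with the same settings so the
        equilibrium-point timing stays aligned with the CoP. Default True.
    """

    target_fs: float = 50.0
    cutoff: float = 20.0
    order: int = 4
    zero_phase: bool = True
    antialias: bool = False
    apply_to_force: bool = True

    def __post_init__(self):
        if self.order < 1:
            raise ParameterError("filter order must be >= 1")
        if not self.cutoff < self.target_fs / 2:
            raise ParameterError(
                f"cutoff {self.cutoff} Hz must be below Nyquist "
                f"{self.target_fs / 2} Hz of the target rate"
            )


def downsample(trial: ForcePlateTrial, settings: PreprocessSettings) -> ForcePlateTrial:
    """Decimate a trial to ``settings.target_fs`` by keeping every k-th sample.

    The decimation factor ``k = fs / target_fs`` must be a positive
    integer; the first sample is always retained. With
    ``settings.antialias`` an 8th-order Chebyshev-I low-pass at 0.8x the
    new Nyquist is applied first (scipy.signal.decimate's default); by
    default samples are dropped verbatim.
    """
    ratio = trial.fs / settings.target_fs
    k = int(round(ratio))
    if abs(ratio - k) > 1e-9 or k < 1:
        raise ParameterError(
            f"fs {trial.fs} Hz is not an integer multiple of target "
            f"{settings.target_fs} Hz; resample the trial first"
        )
    if k == 1:
        return trial
    channels = trial.channels()
    if settings.antialias:
        out = {
            name: sps.decimate(arr, k, ftype="iir", zero_phase=True)
            for name, arr in channels.items()
        }
    else:
        out = {name: arr[::k].copy() for name, arr in channels.items()}
    return trial.with_channels(t=trial.t[::k].copy(), fs=settings.target_fs, **out)


def _butter_sos(cutoff: float, fs: float, order: int):
    return sps.butter(order, cutoff, btype="low", fs=fs, output="sos")


def lowpass(trial: ForcePlateTrial, settings: PreprocessSettings) -> ForcePlateTrial:
    """Butterworth low-pass each selected channel of a trial.

    DC gain is exactly 1, so a constant signal passes unchanged. With
    ``zero_phase`` the filter runs forward and backward (squaring the
    magnitude response); otherwise a single causal pass is used.
    """
    nyq = trial.fs / 2
    if not settings.cutoff < nyq:
        raise ParameterError(
            f"cutoff {settings.cutoff} Hz must be below Nyquist {nyq} Hz"
        )
    sos = _butter_sos(settings.cutoff, trial.fs, settings.order)
    names = ["cop_ml", "cop_ap"]
    if settings.apply_to_force:
        names += ["f_ml", "f_ap"]
    out = {}
    for name in names:
        x = getattr(trial, name)
        if settings.zero_phase:
            out[name] = sps.sosfiltfilt(sos, x)
        else:
            out[name] = sps.sosfilt(sos, x)
    return trial.with_channels(**out)


def butterworth_gain(
    f: np.ndarray | float,
    cutoff: float,
    order: int,
    passes: int = 1,
    fs: float | None = None,
):
    """Closed-form Butterworth magnitude response |H(f)| for ``passes`` passes.

    With ``fs=None`` this is the analog prototype
    |H|^2 = 1 / (1 + (f/fc)^(2*order)). With ``fs`` given it is the exact
    response of the bilinear-transform digital filter (scipy's), whose
    frequency axis is warped as tan(pi f / fs) — the two agree only well
    below Nyquist. Forward-backward filtering squares the magnitude
    (passes=2).
    """
    f = np.asarray(f, dtype=float)
    if fs is None:
        ratio = f / cutoff
    else:
        ratio = np.tan(np.pi * f / fs) / np.tan(np.pi * cutoff / fs)
    single = 1.0 / np.sqrt(1.0 + ratio ** (2 * order))
    return single**passes


def preprocess(trial: ForcePlateTrial, settings: PreprocessSettings | None = None) -> ForcePlateTrial:
    """Decimate then low-pass, in that order."""
    settings = settings or PreprocessSettings()
    return lowpass(downsample(trial, settings), settings)
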