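"""Geometric sway metrics: path length and 95% confidence-ellipse area.

Sway path is the total length travelled by the CoP,

    path = sum_n sqrt((x_n - x_{n-1})^2 + (y_n - y_{n-1})^2),

and sway area is the area of the prediction ellipse enclosing a stated
fraction of the CoP point cloud, built from the eigenvalues of the 2x2
sample covariance of (ML, AP):

    area = pi * c * sqrt(lambda_1 * lambda_2),

with c the chi-square(2) quantile at the chosen coverage (5.9915 at 95%)
in the large-sample form, or the small-sample F-corrected constant
2 (n-1) / (n-2) * F_{2, n-2}(coverage) on request.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["EllipseFit", "sway_path", "confidence_ellipse"]


def _as_xy(cop_ml, cop_ap, min_len: int):
    x = np.asarray(cop_ml, dtype=float)
    y = np.asarray(cop_ap, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or len(x) != len(y):
        raise ValueError("cop_ml and cop_ap must be 1-D and equal length")
    if len(x) < min_len:
        raise ValueError(f"need at least {min_len} samples, got {len(x)}")
    return x, y


def sway_path(cop_ml, cop_ap) -> float:
    """Total length of the CoP trajectory (sum of sample-to-sample steps).

    Zero iff the trajectory is constant. Note the value depends on the
    sampling rate of the input; report it alongside fs.
    """
    x, y = _as_xy(cop_ml, cop_ap, min_len=2)
    return float(np.sum(np.hypot(np.diff(x), np.diff(y))))


@dataclass(frozen=True)
class EllipseFit:
    """A fitted coverage ellipse for a 2-D CoP point cloud.

    ``eigenvalues`` are those of the sample covariance (ddof=1), sorted
    descending; ``orientation`` is the angle of the major axis in radians
    measured from the ML axis; ``scale_constant`` is the coverage-to-
    squared-radius multiplier actually used, so
    ``area == pi * scale_constant * sqrt(l1 * l2)``.
    """

    center: tuple[float, float]
    eigenvalues: tuple[float, float]
    orientation: float
    coverage: float
    scale_constant: float
    area: float
    degenerate: bool = False

    @property
    def semi_axes(self) -> tuple[float, float]:
        l1, l2 = self.eigenvalues
        s = self.scale_constant
        return (float(np.sqrt(s * l1)), float(np.sqrt(s * l2)))

    def contains(self, cop_ml, cop_ap) -> np.ndarray:
        """Boolean mask of points inside (or on) the ellipse."""
        x = np.asarray(cop_ml, float) - self.center[0]
        y = np.asarray(cop_ap, float) - self.center[1]
        c, s = np.cos(self.orientation), np.sin(self.orientation)
        u = c * x + s * y
        v = -s * x + c * y
        a, b = self.semi_axes
        if a == 0 or b == 0:
            return np.zeros_like(u, dtype=bool)
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def confidence_ellipse(
    cop_ml,
    cop_ap,
    coverage: float = 0.95,
    *,
    small_sample: bool = False,
) -> EllipseFit:
    """Fit the coverage ellipse of a CoP point cloud.

    The 2x2 sample covariance (denominator n-1) is eigendecomposed; the
    ellipse axes follow the eigenvectors with squared semi-axes
    ``scale_constant * eigenvalue``. The default constant is the
    chi-square(2) quantile at ``coverage``; ``small_sample`` switches to
    the F-based prediction-ellipse constant, which matters only at small
    n. Rank-deficient clouds (all points collinear or identical) return
    area 0 with ``degenerate=True``.
    """
    if not 0.0 < coverage < 1.0:
        raise ValueError(f"coverage must be in (0, 1), got {coverage}")
    x, y = _as_xy(cop_ml, cop_ap, min_len=3)
    n = len(x)
    center = (float(np.mean(x)), float(np.mean(y)))
    cov = np.cov(x, y, ddof=1)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    evals = np.maximum(evals[::-1], 0.0)  # descending, clip round-off
    evecs = evecs[:, ::-1]
    if small_sample:
        if n < 4:
            raise ValueError("small-sample constant needs n >= 4")
        scale = 2.0 * (n - 1) / (n - 2) * stats.f.ppf(coverage, 2, n - 2)
    else:
        scale = stats.chi2.ppf(coverage, df=2)
    degenerate = bool(evals[1] <= 0.0)
    area = float(np.pi * scale * np.sqrt(evals[0] * evals[1]))
    major = evecs[:, 0]
    orientation = float(np.arctan2(major[1], major[0]))
    return EllipseFit(
        center=center,
        eigenvalues=(float(evals[0]), float(evals[1])),
        orientation=orientation,
        coverage=coverage,
        scale_constant=float(scale),
        area=0.0 if degenerate else area,
        degenerate=degenerate,
    )
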