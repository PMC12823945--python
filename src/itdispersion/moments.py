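"""Spatial moments of tracer-intensity profiles.

The first moment of an intensity profile locates the tracer's centre of
gravity along the neuraxis; the left-sided second moment measures the
spread of the profile over positions caudal of the centroid only, which
stays well defined on the bounded, asymmetric spinal domain where the
full variance is distorted by the nearby sacral wall.  The caudocranial
velocity is the drift speed of the centroid, obtained as the OLS slope
of the first-moment time series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

# Frames whose caudal-side mass is below this fraction of the frame total
# have an ill-conditioned left moment and are dropped from the series.
MIN_LEFT_MASS_FRACTION = 1e-6


@dataclass(frozen=True)
class MomentSeries:
    """Per-frame first and left-sided second moments of a tracer record."""

    times: np.ndarray  # min
    m1: np.ndarray  # cm
    m2_left: np.ndarray  # cm^2
    total_intensity: np.ndarray  # arbitrary units (trapezoidal integral)

    def __post_init__(self) -> None:
        for name in ("times", "m1", "m2_left", "total_intensity"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (
            self.times.shape == self.m1.shape == self.m2_left.shape == self.total_intensity.shape
        ):
            raise ValueError("moment series arrays must share one shape")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.m2_left < 0):
            raise ValueError("left second moments must be non-negative")


def first_moment(positions: np.ndarray, intensities: np.ndarray) -> float:
    """Intensity-weighted mean position (trapezoidal quadrature), cm."""
    positions = np.asarray(positions, dtype=float)
    intensities = np.asarray(intensities, dtype=float)
    if positions.ndim != 1 or positions.shape != intensities.shape:
        raise ValueError("positions and intensities must be matching 1D arrays")
    if np.any(np.diff(positions) <= 0):
        raise ValueError("positions must be strictly increasing")
    denom = np.trapezoid(intensities, positions)
    if denom <= 0:
        raise ValueError("centroid undefined: profile has no positive mass")
    return float(np.trapezoid(positions * intensities, positions) / denom)


def left_second_moment(
    positions: np.ndarray, intensities: np.ndarray, centroid: float | None = None
) -> float:
    """Second central moment over the caudal side of the centroid, cm^2.

    Integrates (x - xbar)^2 C and C over x <= xbar by the trapezoidal
    rule; when the centroid falls inside a sampling cell the profile is
    split there with linearly interpolated intensity.  For a symmetric
    profile this equals the full variance.
    """
    positions = np.asarray(positions, dtype=float)
    intensities = np.asarray(intensities, dtype=float)
    if centroid is None:
        centroid = first_moment(positions, intensities)
    if not positions[0] <= centroid <= positions[-1]:
        raise ValueError("centroid outside the sampled interval")

    mask = positions <= centroid
    xs = positions[mask]
    cs = intensities[mask]
    if xs.size == 0:
        raise ValueError("no samples caudal of the centroid")
    if centroid > xs[-1]:
        c_at = float(np.interp(centroid, positions, intensities))
        xs = np.append(xs, centroid)
        cs = np.append(cs, c_at)
    if xs.size < 2:
        return 0.0
    denom = np.trapezoid(cs, xs)
    if denom <= 0:
        raise ValueError("left-side mass is zero: left moment undefined")
    num = np.trapezoid((xs - centroid) ** 2 * cs, xs)
    return float(num / denom)


def moment_series(
    record,
    roi: tuple[float, float] | None = None,
    subtract_baseline: bool = False,
) -> MomentSeries:
    """First and left-sided second moments per frame of an intensity record.

    Parameters
    ----------
    record : object with ``times`` (min), ``positions`` (cm) and
        ``intensities`` of shape (n_times, n_positions) — e.g. an
        :class:`~itdispersion.synthetic.IntensityRecord`.
    roi : optional (lower, upper) analysis window in cm; moments are
        computed over samples inside the window.
    subtract_baseline : subtract each frame's minimum intensity before
        integrating (a constant-background correction for uneven
        lighting; off by default).

    Frames with no usable mass — zero total, or caudal-side mass below
    ``MIN_LEFT_MASS_FRACTION`` of the frame total — are excluded with a
    logged warning.
    """
    positions = np.asarray(record.positions, dtype=float)
    frames = np.asarray(record.intensities, dtype=float)
    times = np.asarray(record.times, dtype=float)
    if frames.shape != (times.size, positions.size):
        raise ValueError("record intensities shape does not match times x positions")
    if times.size < 2:
        raise ValueError("moment series requires at least two frames")
    if roi is not None:
        lo, hi = roi
        if hi <= lo:
            raise ValueError("roi bounds inverted")
        sel = (positions >= lo) & (positions <= hi)
        if sel.sum() < 3:
            raise ValueError("roi contains fewer than 3 samples")
        positions = positions[sel]
        frames = frames[:, sel]

    kept_t, kept_m1, kept_m2, kept_tot = [], [], [], []
    for t, profile in zip(times, frames):
        if subtract_baseline:
            profile = profile - profile.min()
        total = np.trapezoid(profile, positions)
        if total <= 0:
            logger.warning("frame t=%.3g min has no mass in the ROI; excluded", t)
            continue
        xbar = first_moment(positions, profile)
        left = positions <= xbar
        left_mass = np.trapezoid(profile[left], positions[left]) if left.sum() > 1 else 0.0
        if left_mass < MIN_LEFT_MASS_FRACTION * total:
            logger.warning(
                "frame t=%.3g min has negligible caudal-side mass; excluded", t
            )
            continue
        kept_t.append(t)
        kept_m1.append(xbar)
        kept_m2.append(left_second_moment(positions, profile, xbar))
        kept_tot.append(total)
    if len(kept_t) < 2:
        raise ValueError("fewer than two usable frames in the record")
    return MomentSeries(
        times=np.array(kept_t),
        m1=np.array(kept_m1),
        m2_left=np.array(kept_m2),
        total_intensity=np.array(kept_tot),
    )


def caudocranial_velocity(series: MomentSeries) -> tuple[float, float]:
    """Centroid drift speed toward the cranial direction, cm/min.

    Ordinary-least-squares slope of m1 versus time; returns
    ``(slope, standard_error)``.
    """
    if series.times.size < 3:
        raise ValueError("caudocranial velocity requires at least 3 time points")
    result = stats.linregress(series.times, series.m1)
    return float(result.slope), float(result.stderr)
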