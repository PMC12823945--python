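"""Neuraxis geometry and cerebrospinal-fluid pulsation descriptors.

The spinal subarachnoid space is modelled as a sequence of elliptical
cross-sections along the neuraxis, each partially occupied by spinal
tissue (cord and nerve roots).  The module provides

* a station-based geometry container with piecewise-linear interpolation
  of radii and tissue fraction between stations,
* percent-difference metrics for validating a manufactured phantom
  against in vivo reference dimensions, and
* derivation of the dimensionless descriptors of oscillatory CSF motion
  (Womersley number, Peclet number, pulsatile amplitude ratio) from the
  pulsation frequency and stroke volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

#: Kinematic viscosity of the working fluid (water at room temperature), cm^2/s.
DEFAULT_KINEMATIC_VISCOSITY = 0.01
#: Hydraulic diameter of the spinal canal, cm.
DEFAULT_HYDRAULIC_DIAMETER = 0.5
#: Characteristic axial length of the CSF column (cisterna magna to S3), cm.
DEFAULT_CHARACTERISTIC_LENGTH = 65.0
#: Molecular (reference) diffusivity of the tracer, cm^2/min.
DEFAULT_MOLECULAR_DIFFUSIVITY = 1.938e-6


@dataclass(frozen=True)
class NeuraxisStation:
    """Elliptical cross-section of the subarachnoid space at one landmark.

    Parameters
    ----------
    label : anatomical landmark name (e.g. ``"CM"``, ``"C3"``, ``"T2"``).
    position : axial distance from the cisterna magna, cm.
    major_radius, minor_radius : ellipse semi-axes, cm.
    tissue_fraction : fraction of the cross-sectional area occupied by
        spinal tissue, in [0, 1]; the remainder is CSF.
    """

    label: str
    position: float
    major_radius: float
    minor_radius: float
    tissue_fraction: float

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError(f"station position must be >= 0, got {self.position}")
        if self.major_radius <= 0 or self.minor_radius <= 0:
            raise ValueError("station radii must be positive")
        if not 0.0 <= self.tissue_fraction <= 1.0:
            raise ValueError(
                f"tissue_fraction must lie in [0, 1], got {self.tissue_fraction}"
            )

    @property
    def ellipse_area(self) -> float:
        """Full elliptical cross-sectional area, cm^2."""
        return math.pi * self.major_radius * self.minor_radius

    @property
    def csf_area(self) -> float:
        """CSF-occupied cross-sectional area, cm^2."""
        return self.ellipse_area * (1.0 - self.tissue_fraction)


@dataclass(frozen=True)
class NeuraxisGeometry:
    """Ordered sequence of stations spanning the neuraxis."""

    stations: tuple[NeuraxisStation, ...]
    total_length: float
    hydraulic_diameter: float = DEFAULT_HYDRAULIC_DIAMETER

    def __post_init__(self) -> None:
        if len(self.stations) < 2:
            raise ValueError("geometry requires at least two stations")
        positions = [s.position for s in self.stations]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValueError("station positions must be strictly increasing")
        if self.total_length < positions[-1]:
            raise ValueError("total_length must cover the last station")
        if self.hydraulic_diameter <= 0:
            raise ValueError("hydraulic_diameter must be positive")

    def station(self, label: str) -> NeuraxisStation:
        for s in self.stations:
            if s.label == label:
                return s
        raise KeyError(f"no station labelled {label!r}")


@dataclass(frozen=True)
class GeometryMeasurementPair:
    """In-vivo reference dimension paired with a measured phantom dimension."""

    label: str
    reference_value: float
    measured_value: float
    quantity: str  # "diameter" or "area"

    def __post_init__(self) -> None:
        if self.reference_value <= 0 or self.measured_value <= 0:
            raise ValueError("measurement values must be positive")
        if self.quantity not in ("diameter", "area"):
            raise ValueError(f"unknown quantity {self.quantity!r}")


@dataclass(frozen=True)
class CSFState:
    """Pulsation descriptors of oscillatory CSF motion.

    All derived quantities follow from the pulsation frequency (beats/min)
    and the stroke volume (mL displaced per beat at the reference
    cross-section), assuming a sinusoidal volumetric waveform.
    """

    frequency: float  # beats/min
    stroke_volume: float  # mL/beat
    angular_frequency: float  # rad/s
    reference_area: float  # cm^2, CSF-occupied area at the reference station
    urms: float  # cm/s, root-mean-square bulk velocity
    womersley: float
    peclet: float
    amplitude_ratio: float
    kinematic_viscosity: float = DEFAULT_KINEMATIC_VISCOSITY
    characteristic_length: float = DEFAULT_CHARACTERISTIC_LENGTH
    reference_diffusivity: float = DEFAULT_MOLECULAR_DIFFUSIVITY


def percent_difference(pair: GeometryMeasurementPair) -> float:
    """Unsigned percent difference of a measured dimension from its reference.

    Returns ``100 * |measured - reference| / reference``; rounding is left
    to the caller.
    """
    if pair.reference_value <= 0:
        raise ValueError("reference value must be positive")
    return 100.0 * abs(pair.measured_value - pair.reference_value) / pair.reference_value


def validation_summary(
    pairs: Sequence[GeometryMeasurementPair],
) -> dict[str, float]:
    """Mean percent difference per quantity (``diameter``, ``area``).

    The mean is the arithmetic average of the per-pair percent differences
    within each quantity group.
    """
    if not pairs:
        raise ValueError("validation_summary requires at least one pair")
    groups: dict[str, list[float]] = {}
    for pair in pairs:
        groups.setdefault(pair.quantity, []).append(percent_difference(pair))
    return {quantity: float(np.mean(vals)) for quantity, vals in groups.items()}


def interpolate_geometry(
    geometry: NeuraxisGeometry, position: float
) -> tuple[float, float, float, float]:
    """Piecewise-linear interpolation of the cross-section at ``position``.

    Returns ``(major_radius, minor_radius, tissue_fraction, csf_area)``
    where ``csf_area = pi * a * b * (1 - tissue_fraction)`` evaluated on
    the interpolated radii and tissue fraction.
    """
    xs = np.array([s.position for s in geometry.stations])
    if not xs[0] <= position <= xs[-1]:
        raise ValueError(
            f"position {position} cm outside the station range "
            f"[{xs[0]}, {xs[-1]}] cm"
        )
    major = float(np.interp(position, xs, [s.major_radius for s in geometry.stations]))
    minor = float(np.interp(position, xs, [s.minor_radius for s in geometry.stations]))
    tissue = float(np.interp(position, xs, [s.tissue_fraction for s in geometry.stations]))
    csf_area = math.pi * major * minor * (1.0 - tissue)
    return major, minor, tissue, csf_area


def csf_state(
    frequency: float,
    stroke_volume: float,
    reference_area: float | None = None,
    kinematic_viscosity: float = DEFAULT_KINEMATIC_VISCOSITY,
    hydraulic_diameter: float = DEFAULT_HYDRAULIC_DIAMETER,
    characteristic_length: float = DEFAULT_CHARACTERISTIC_LENGTH,
    reference_diffusivity: float = DEFAULT_MOLECULAR_DIFFUSIVITY,
) -> CSFState:
    """Derive oscillatory-flow descriptors from frequency and stroke volume.

    The volumetric waveform is sinusoidal, ``Q(t) = Qa sin(omega t)``, and
    the volume displaced over a half period equals the stroke volume,
    hence ``Qa = stroke_volume * omega / 2``.  The root-mean-square bulk
    velocity at the reference CSF cross-section is ``Urms =
    Qa / (A_ref * sqrt(2))``.

    Parameters
    ----------
    frequency : pulsation frequency, beats/min, in (0, 300].
    stroke_volume : displaced CSF volume per beat, mL.
    reference_area : CSF-occupied cross-sectional area at the reference
        station, cm^2.  Defaults to the C3 station of the packaged
        geometry.
    kinematic_viscosity : cm^2/s.
    hydraulic_diameter : cm.
    characteristic_length : axial extent of the CSF column, cm.
    reference_diffusivity : molecular diffusivity of the tracer, cm^2/min.
    """
    if not 0 < frequency <= 300:
        raise ValueError(f"frequency must lie in (0, 300] bpm, got {frequency}")
    if stroke_volume < 0:
        raise ValueError("stroke_volume must be non-negative")
    for name, value in [
        ("kinematic_viscosity", kinematic_viscosity),
        ("hydraulic_diameter", hydraulic_diameter),
        ("characteristic_length", characteristic_length),
        ("reference_diffusivity", reference_diffusivity),
    ]:
        if value <= 0:
            raise ValueError(f"{name} must be positive")
    if reference_area is None:
        reference_area = default_geometry().station("C3").csf_area
    if reference_area <= 0:
        raise ValueError("reference_area must be positive")

    omega = 2.0 * math.pi * frequency / 60.0  # rad/s
    peak_flow = stroke_volume * omega / 2.0  # mL/s
    urms = peak_flow / (reference_area * math.sqrt(2.0))  # cm/s
    womersley = (hydraulic_diameter / 2.0) * math.sqrt(omega / kinematic_viscosity)
    d0_cm2_s = reference_diffusivity / 60.0
    peclet = urms * hydraulic_diameter / d0_cm2_s
    amplitude_ratio = urms / (omega * characteristic_length)
    return CSFState(
        frequency=frequency,
        stroke_volume=stroke_volume,
        angular_frequency=omega,
        reference_area=reference_area,
        urms=urms,
        womersley=womersley,
        peclet=peclet,
        amplitude_ratio=amplitude_ratio,
        kinematic_viscosity=kinematic_viscosity,
        characteristic_length=characteristic_length,
        reference_diffusivity=reference_diffusivity,
    )


def load_geometry(path) -> NeuraxisGeometry:
    """Read a geometry-station table (CSV) into a :class:`NeuraxisGeometry`.

    Expected columns: ``label, position_cm, major_radius_cm,
    minor_radius_cm, tissue_fraction``.
    """
    frame = pd.read_csv(path)
    required = {
        "label",
        "position_cm",
        "major_radius_cm",
        "minor_radius_cm",
        "tissue_fraction",
    }
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"geometry table missing columns: {sorted(missing)}")
    stations = tuple(
        NeuraxisStation(
            label=str(row.label),
            position=float(row.position_cm),
            major_radius=float(row.major_radius_cm),
            minor_radius=float(row.minor_radius_cm),
            tissue_fraction=float(row.tissue_fraction),
        )
        for row in frame.itertuples()
    )
    return NeuraxisGeometry(stations=stations, total_length=stations[-1].position)


def load_validation_pairs(path) -> list[GeometryMeasurementPair]:
    """Read a validation-pair table (CSV) with columns
    ``label, quantity, reference_value, measured_value``."""
    frame = pd.read_csv(path)
    required = {"label", "quantity", "reference_value", "measured_value"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"validation table missing columns: {sorted(missing)}")
    return [
        GeometryMeasurementPair(
            label=str(row.label),
            quantity=str(row.quantity),
            reference_value=float(row.reference_value),
            measured_value=float(row.measured_value),
        )
        for row in frame.itertuples()
    ]


def default_geometry() -> NeuraxisGeometry:
    """Packaged neuraxis geometry.

    A synthetic station table: a plausible elliptical-cross-section model
    of an adult spinal subarachnoid space whose anchor stations (CM, T2,
    L1, S3) are consistent with published in vivo diameters and areas;
    intermediate stations are smooth interpolants, not measurements.
    """
    with resources.as_file(
        resources.files("itdispersion.data") / "neuraxis_geometry_synthetic.csv"
    ) as path:
        return load_geometry(path)


def default_validation_pairs() -> list[GeometryMeasurementPair]:
    """Packaged phantom-validation measurement pairs (in vivo vs phantom)."""
    with resources.as_file(
        resources.files("itdispersion.data") / "phantom_validation_pairs.csv"
    ) as path:
        return load_validation_pairs(path)
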