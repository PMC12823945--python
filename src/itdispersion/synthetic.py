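"""Synthetic tracer-experiment generator.

Emulates the benchtop recordings of a lumbar bolus dispersing in a
closed spinal-canal phantom: a 2 mL injection over 1 min (phase 1)
followed by 10 min of observation at 1-min frame intervals (phase 2).
Tracer spreads by an effective diffusivity on the bounded domain
(sacral end a few cm caudal of the injection point), drifts slowly in
the caudocranial direction, and is read out as a radially averaged
optical intensity corrupted by multiplicative (lighting) and additive
(sensor) Gaussian noise.

The generated records have the statistical structure of real phantom
video profiles, so the moment analysis and the dispersion inversion can
be exercised — and their parameter recovery quantified — without bench
data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from itdispersion import correlations, physiology
from itdispersion.diffusion import (
    ConcentrationField,
    Grid1D,
    build_grid,
    diffuse_interval,
    diffusion_substeps,
    solve_diffusion,
)

#: Default analysis domain in injection-centric coordinates: the lumbar
#: injection site is x = 0, the closed sacral end is 6 cm caudal and the
#: canal extends 59 cm cranially (65 cm total), at 0.1 cm resolution.
DEFAULT_DOMAIN = (-6.0, 59.0)
DEFAULT_N_CELLS = 650


def default_grid() -> Grid1D:
    return build_grid(*DEFAULT_DOMAIN, DEFAULT_N_CELLS)


@dataclass(frozen=True)
class ExperimentProtocol:
    """Injection and observation protocol of one tracer experiment."""

    injection_volume: float = 2.0  # mL
    injection_duration: float = 60.0  # s
    injection_position: float = 0.0  # cm
    injection_width: float = 1.0  # cm
    observation_duration: float = 10.0  # min
    frame_interval: float = 1.0  # min
    roi: tuple[float, float] | None = None  # cm

    def __post_init__(self) -> None:
        if self.injection_volume <= 0 or self.injection_duration <= 0:
            raise ValueError("injection volume and duration must be positive")
        if self.injection_width <= 0:
            raise ValueError("injection width must be positive")
        if self.observation_duration <= 0 or self.frame_interval <= 0:
            raise ValueError("observation durations must be positive")
        if self.roi is not None and self.roi[1] <= self.roi[0]:
            raise ValueError("roi bounds inverted")


@dataclass(frozen=True)
class NoiseSpec:
    """Optical noise model: relative (multiplicative) and absolute terms.

    ``multiplicative`` is the standard deviation of per-sample Gaussian
    gain fluctuations; ``additive`` is the standard deviation of additive
    Gaussian noise expressed as a fraction of the record's peak
    noise-free intensity.  Negative intensities are clipped to zero.
    """

    multiplicative: float = 0.05
    additive: float = 0.02

    def __post_init__(self) -> None:
        if self.multiplicative < 0 or self.additive < 0:
            raise ValueError("noise amplitudes must be non-negative")

    @property
    def silent(self) -> bool:
        return self.multiplicative == 0 and self.additive == 0


NOISE_OFF = NoiseSpec(multiplicative=0.0, additive=0.0)


@dataclass(frozen=True)
class IntensityRecord:
    """Time-stamped axial intensity profiles of one tracer experiment."""

    times: np.ndarray  # min, t = 0 at end of injection
    positions: np.ndarray  # cm
    intensities: np.ndarray  # (n_times, n_positions), >= 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        positions = np.asarray(self.positions, dtype=float)
        intensities = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "positions", positions)
        object.__setattr__(self, "intensities", intensities)
        if intensities.shape != (times.size, positions.size):
            raise ValueError("intensities must have shape (n_times, n_positions)")
        if times.size > 1 and np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(np.diff(positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(intensities < 0):
            raise ValueError("intensities must be non-negative")


def _advect_upwind(values: np.ndarray, velocity: float, dt: float, dx: float) -> np.ndarray:
    """Flux-form first-order upwind advection with closed (no-flux) ends.

    Sub-steps internally to respect the CFL limit.  Mass is conserved;
    tracer reaching a closed end accumulates against the wall.
    """
    if velocity == 0 or dt == 0:
        return values
    n_sub = max(1, math.ceil(abs(velocity) * dt / (0.9 * dx)))
    c = velocity * (dt / n_sub) / dx
    out = values.copy()
    for _ in range(n_sub):
        flux = np.zeros(out.size + 1)
        if c > 0:
            flux[1:-1] = c * out[:-1]
        else:
            flux[1:-1] = c * out[1:]
        out = out - np.diff(flux)
    return out


def _injection_phase(
    protocol: ExperimentProtocol, grid: Grid1D, d_true: float
) -> np.ndarray:
    """Run phase 1: a uniform volumetric source switched on for the
    injection duration, diffusing with the effective D as it fills.

    Concentration carries units of injected volume per cm of canal, so
    the spatial integral of the final profile equals the injected volume.
    """
    half_width = protocol.injection_width / 2.0
    centers = grid.cell_centers
    src = np.abs(centers - protocol.injection_position) <= half_width + 1e-12
    if not src.any():
        raise ValueError("injection window contains no grid cells")
    duration_min = protocol.injection_duration / 60.0
    n_steps = max(20, diffusion_substeps(d_true, duration_min, grid.dx))
    dt = duration_min / n_steps
    rate_per_cell = protocol.injection_volume / duration_min / (src.sum() * grid.dx)
    v = np.zeros(grid.n_cells)
    for _ in range(n_steps):
        v = v + np.where(src, rate_per_cell * dt, 0.0)
        v = diffuse_interval(v, d_true, dt, grid.dx, n_sub=1)
    return v


def simulate_tracer_experiment(
    protocol: ExperimentProtocol | None = None,
    d_true: float = 7.4,
    drift_velocity: float = 0.0,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    grid: Grid1D | None = None,
    gain: float = 1.0,
    nerve_root_factor: float = 1.0,
    frequency: float | None = None,
    stroke_volume: float | None = None,
) -> IntensityRecord:
    """Generate one synthetic tracer record.

    Phase 1 injects the bolus (source on, diffusion with ``d_true``
    scaled by ``nerve_root_factor``); phase 2 observes the dispersal
    under effective diffusion plus a constant caudocranial drift.  Frames
    are sampled every ``frame_interval`` starting at t = 0, the end of
    the injection.  With ``drift_velocity = 0`` phase 2 reduces exactly
    to the finite-volume diffusion solver.

    Fully reproducible for a given ``seed``.
    """
    protocol = protocol or ExperimentProtocol()
    noise = noise or NOISE_OFF
    grid = grid or default_grid()
    if d_true < 0:
        raise ValueError("d_true must be non-negative")
    if nerve_root_factor <= 0:
        raise ValueError("nerve_root_factor must be positive")
    d_eff = d_true * nerve_root_factor

    initial = _injection_phase(protocol, grid, d_eff)
    n_frames = int(round(protocol.observation_duration / protocol.frame_interval))
    times = np.arange(n_frames + 1) * protocol.frame_interval

    frames = np.empty((times.size, grid.n_cells))
    frames[0] = initial
    if drift_velocity == 0.0:
        if times.size > 1:
            solved = solve_diffusion(
                ConcentrationField(grid=grid, times=np.array([0.0]), values=initial),
                d_eff,
                times[1:],
            )
            frames[1:] = solved.values
    else:
        v = initial
        for k in range(1, times.size):
            dt = times[k] - times[k - 1]
            n_sub = diffusion_substeps(d_eff, dt, grid.dx)
            sub_dt = dt / n_sub
            for _ in range(n_sub):
                v = _advect_upwind(v, drift_velocity, sub_dt, grid.dx)
                v = diffuse_interval(v, d_eff, sub_dt, grid.dx, n_sub=1)
            frames[k] = v

    clean = gain * frames
    if noise.silent:
        intensities = clean
    else:
        rng = np.random.default_rng(seed)
        peak = clean.max()
        intensities = clean * (1.0 + noise.multiplicative * rng.standard_normal(clean.shape))
        intensities = intensities + noise.additive * peak * rng.standard_normal(clean.shape)
        intensities = np.clip(intensities, 0.0, None)

    metadata = {
        "frequency_bpm": frequency,
        "stroke_volume_ml": stroke_volume,
        "true_dispersion_cm2_min": d_true,
        "drift_velocity_cm_min": drift_velocity,
        "seed": int(seed),
        "nerve_root_factor": nerve_root_factor,
        "noise_multiplicative": noise.multiplicative,
        "noise_additive": noise.additive,
        "gain": gain,
        "injection_volume_ml": protocol.injection_volume,
        "injection_duration_s": protocol.injection_duration,
        "roi": list(protocol.roi) if protocol.roi else None,
    }
    return IntensityRecord(
        times=times, positions=grid.cell_centers, intensities=intensities, metadata=metadata
    )


def generate_cohort(
    frequencies,
    stroke_volumes,
    coefficients: dict[str, float] | None = None,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    scatter_sigma: float = 0.0,
    protocol: ExperimentProtocol | None = None,
    grid: Grid1D | None = None,
    nerve_root_factor: float = 1.0,
    reference_area: float | None = None,
) -> list[tuple[physiology.CSFState, IntensityRecord, float]]:
    """Generate a cohort of records across a (frequency, stroke volume) grid.

    For each condition the true dispersion coefficient follows the
    dimensional correlation evaluated at that condition's Urms (with
    optional log-normal scatter of ``scatter_sigma`` in log10 units), and
    the drift velocity follows the frequency law for the caudocranial
    velocity.  Each run draws its noise from a distinct stream derived
    from the master ``seed``.
    """
    frequencies = list(frequencies)
    stroke_volumes = list(stroke_volumes)
    if not frequencies or not stroke_volumes:
        raise ValueError("frequency and stroke-volume grids must be non-empty")
    coefficients = coefficients or correlations.DIMENSIONAL_COEFFS
    noise = noise or NOISE_OFF
    master = np.random.SeedSequence(seed)
    scatter_rng = np.random.default_rng(master.spawn(1)[0])

    cohort = []
    for f in frequencies:
        for sv in stroke_volumes:
            state = physiology.csf_state(f, sv, reference_area=reference_area)
            d_true = float(correlations.dimensional_law(f, state.urms, coefficients))
            if scatter_sigma > 0:
                d_true *= 10.0 ** (scatter_sigma * scatter_rng.standard_normal())
            drift = float(correlations.ccv_law(f, correlations.CCV_FREQUENCY_COEFFS))
            run_seed = int(master.spawn(1)[0].generate_state(1)[0] % (2**31))
            record = simulate_tracer_experiment(
                protocol=protocol,
                d_true=d_true,
                drift_velocity=drift,
                noise=noise,
                seed=run_seed,
                grid=grid,
                nerve_root_factor=nerve_root_factor,
                frequency=f,
                stroke_volume=sv,
            )
            cohort.append((state, record, d_true * nerve_root_factor))
    return cohort
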