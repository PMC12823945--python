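"""End-to-end orchestration: simulate -> moments -> invert -> fit.

A :class:`RunConfig` describes a cohort of synthetic tracer experiments
(frequency and stroke-volume grids, noise, domain and protocol).  The
pipeline generates the cohort, runs the moment analysis and both
dispersion estimators on every record, assembles per-experiment
summaries, fits the dispersion and caudocranial-velocity correlations,
and writes all artifacts plus a manifest with the config echo, seeds and
SHA-256 checksums.  All randomness flows from the single master seed, so
an identical config reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from itdispersion import correlations, io, physiology
from itdispersion.inversion import mip_estimate, mom_estimate
from itdispersion.moments import caudocranial_velocity, moment_series
from itdispersion.synthetic import (
    DEFAULT_DOMAIN,
    DEFAULT_N_CELLS,
    ExperimentProtocol,
    NoiseSpec,
    generate_cohort,
)
from itdispersion.diffusion import build_grid


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a synthetic-cohort pipeline run."""

    frequencies: tuple = (40.0, 55.0, 72.0, 90.0, 110.0, 127.0)
    stroke_volumes: tuple = (0.5, 1.0)
    seed: int = 0
    noise_multiplicative: float = 0.05
    noise_additive: float = 0.02
    scatter_sigma: float = 0.0
    domain: tuple = DEFAULT_DOMAIN
    n_cells: int = DEFAULT_N_CELLS
    roi: tuple | None = None
    injection_volume: float = 2.0
    injection_duration_s: float = 60.0
    injection_width: float = 1.0
    observation_duration: float = 10.0
    frame_interval: float = 1.0
    output_dir: str = "pipeline_out"

    def __post_init__(self) -> None:
        if not self.frequencies or not self.stroke_volumes:
            raise ValueError("frequency and stroke-volume grids must be non-empty")
        if self.noise_multiplicative < 0 or self.noise_additive < 0:
            raise ValueError("noise amplitudes must be non-negative")
        lo, hi = self.domain
        if hi <= lo:
            raise ValueError("domain bounds inverted")
        if self.roi is not None:
            rlo, rhi = self.roi
            if not (lo <= rlo < rhi <= hi):
                raise ValueError("roi must lie within the solver domain")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in raw:
                value = raw[f.name]
                kwargs[f.name] = tuple(value) if isinstance(value, list) else value
        return cls(**kwargs)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        for key, value in out.items():
            if isinstance(value, tuple):
                out[key] = list(value)
        return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full synthetic-cohort pipeline; returns the manifest."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    grid = build_grid(config.domain[0], config.domain[1], config.n_cells)
    protocol = ExperimentProtocol(
        injection_volume=config.injection_volume,
        injection_duration=config.injection_duration_s,
        injection_width=config.injection_width,
        observation_duration=config.observation_duration,
        frame_interval=config.frame_interval,
        roi=tuple(config.roi) if config.roi else None,
    )
    noise = NoiseSpec(
        multiplicative=config.noise_multiplicative, additive=config.noise_additive
    )

    cohort = generate_cohort(
        config.frequencies,
        config.stroke_volumes,
        noise=noise,
        seed=config.seed,
        scatter_sigma=config.scatter_sigma,
        protocol=protocol,
        grid=grid,
    )

    artifacts: list[str] = []
    summaries = []
    estimates = []
    for i, (state, record, d_true) in enumerate(cohort):
        rec_path = out_dir / f"record_{i:03d}.csv"
        io.write_intensity_record(record, rec_path)
        artifacts += [rec_path.name, rec_path.name + ".meta.json"]

        series = moment_series(record, roi=protocol.roi)
        mom_path = out_dir / f"moments_{i:03d}.csv"
        io.write_moment_series(series, mom_path)
        artifacts.append(mom_path.name)

        mip = mip_estimate(record, grid=grid, roi=protocol.roi)
        mom = mom_estimate(series)
        est_path = out_dir / f"estimate_{i:03d}.json"
        io.write_estimate(mip, est_path, config_echo={"index": i, "d_true": d_true})
        artifacts.append(est_path.name)
        estimates.append((mip, mom, d_true))

        ccv, _ = caudocranial_velocity(series)
        summaries.append(
            correlations.ExperimentSummary(
                frequency=state.frequency,
                stroke_volume=state.stroke_volume,
                urms=state.urms,
                womersley=state.womersley,
                peclet=state.peclet,
                amplitude_ratio=state.amplitude_ratio,
                d_exp=mip.d,
                ccv=ccv,
            )
        )

    sum_path = out_dir / "experiment_summaries.csv"
    io.write_summaries(summaries, sum_path)
    artifacts.append(sum_path.name)

    d0 = physiology.DEFAULT_MOLECULAR_DIFFUSIVITY
    fits = {"dimensional": correlations.fit_dimensional(summaries)}
    try:
        fits["dimensionless"] = correlations.fit_dimensionless(summaries, d0)
    except ValueError:
        pass
    fits["scale"] = correlations.fit_scale(summaries, d0)
    fits["ccv_frequency"] = correlations.fit_ccv(summaries, "frequency")
    for name, fit in fits.items():
        fit_path = out_dir / f"fit_{name}.json"
        io.write_fit(fit, fit_path)
        artifacts.append(fit_path.name)

    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "n_experiments": len(cohort),
        "n_fits": len(fits),
        "artifacts": {name: _sha256(out_dir / name) for name in sorted(artifacts)},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
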