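"""Forward models of the two sizing instruments.

NTA: particles in a small optical sampling volume are tracked while they
diffuse; each track's lag-1 mean-squared displacement gives a diffusion
coefficient, inverted to a hydrodynamic diameter via Stokes–Einstein, and
the mean per-frame occupancy of the (known) volume gives the
number-concentration.  Number-weighted by construction.

DLS: the ensemble z-average and PDI of the population (intensity-weighted,
Rayleigh d⁶), with optional multiplicative measurement noise.

Both are track/ensemble-level models: no imaging, localization noise off by
default, no finite-track-length bias correction (the residual bias at the
default 30-frame tracks is a few percent).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
from pydantic import BaseModel, model_validator

from . import dispersity
from .synthetic import ParticlePopulation

BOLTZMANN = 1.380649e-23  # J/K


class InstrumentConfig(BaseModel):
    """NTA/DLS simulation parameters (water at 25 °C by default)."""

    temperature: float = 298.15  # K
    viscosity: float = 8.9e-4  # Pa·s
    frame_interval: float = 1.0 / 30.0  # s
    track_length_mean: float = 30.0  # frames
    min_track_length: int = 10  # frames
    sampling_volume_ml: float = 1e-7  # field of view × depth
    n_frames_observed: int = 900  # ~30 s of video
    dilution_factor: float = 1.0
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "InstrumentConfig":
        for name in (
            "temperature",
            "viscosity",
            "frame_interval",
            "track_length_mean",
            "sampling_volume_ml",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")
        return self


@dataclass
class Track:
    """One particle's 2-D displacement series (per-frame steps, metres)."""

    dx: np.ndarray
    dy: np.ndarray

    @property
    def n_steps(self) -> int:
        return int(self.dx.size)


@dataclass(frozen=True)
class NtaResult:
    estimated_diameters: np.ndarray  # nm, one per accepted track
    particles_per_ml: float  # dilution-corrected
    mean_size: float  # nm
    span: float
    n_tracks: int


def stokes_einstein(
    diameter_nm: float, temperature: float = 298.15, viscosity: float = 8.9e-4
) -> float:
    """Diffusion coefficient D = k_B·T / (3π·η·d) in m²/s."""
    if diameter_nm <= 0 or temperature <= 0 or viscosity <= 0:
        raise ValueError("all Stokes–Einstein inputs must be > 0")
    return BOLTZMANN * temperature / (3.0 * np.pi * viscosity * diameter_nm * 1e-9)


def diameter_from_diffusion(
    diffusion_m2_s: float, temperature: float = 298.15, viscosity: float = 8.9e-4
) -> float:
    """Hydrodynamic diameter in nm from a diffusion coefficient (inverse)."""
    if diffusion_m2_s <= 0 or temperature <= 0 or viscosity <= 0:
        raise ValueError("all inputs must be > 0")
    return BOLTZMANN * temperature / (3.0 * np.pi * viscosity * diffusion_m2_s) * 1e9


def simulate_tracks(
    population: ParticlePopulation,
    config: InstrumentConfig,
    rng: Optional[np.random.Generator] = None,
) -> List[Track]:
    """Brownian tracks for the particles visiting the sampling volume.

    The diluted suspension puts λ = c/dilution × V_sample particles in view
    per frame on average, so the total occupancy over ``n_frames_observed``
    frames is Poisson(λ·F) particle-frames; it is partitioned into tracks of
    geometrically distributed length (mean ``track_length_mean``), making the
    per-frame occupancy estimator used downstream exact Poisson counting.
    Per-axis steps are Normal(0, √(2·D·Δt)).
    """
    if population.n_particles == 0:
        return []
    rng = rng or np.random.default_rng(config.seed)
    conc_diluted = population.particles_per_ml / config.dilution_factor
    lam = conc_diluted * config.sampling_volume_ml
    particle_frames = int(rng.poisson(lam * config.n_frames_observed))
    if particle_frames == 0:
        return []
    lengths = []
    remaining = particle_frames
    while remaining > 0:
        k = min(int(rng.geometric(1.0 / config.track_length_mean)), remaining)
        lengths.append(k)
        remaining -= k
    n_tracks = len(lengths)
    diam = rng.choice(population.diameters, size=n_tracks, replace=True)
    tracks = []
    for d_nm, length in zip(diam, lengths):
        d_coef = stokes_einstein(d_nm, config.temperature, config.viscosity)
        sigma = np.sqrt(2.0 * d_coef * config.frame_interval)
        tracks.append(
            Track(
                dx=rng.standard_normal(length) * sigma,
                dy=rng.standard_normal(length) * sigma,
            )
        )
    return tracks


def estimate_from_tracks(tracks: List[Track], config: InstrumentConfig) -> NtaResult:
    """Per-track MSD sizing plus occupancy-based concentration.

    D̂ = Σ(Δx² + Δy²) / (4·n·Δt) over lag-1 displacements, inverted through
    Stokes–Einstein; tracks shorter than ``min_track_length`` are dropped
    from sizing (but still occupy frames, so they count toward
    concentration).  Concentration = mean particles per frame / sampling
    volume × dilution factor.
    """
    accepted = [t for t in tracks if t.n_steps >= config.min_track_length]
    if not accepted:
        raise ValueError("no track passes the minimum-length filter")
    diameters = np.array(
        [
            diameter_from_diffusion(
                float(np.sum(t.dx**2 + t.dy**2))
                / (4.0 * t.n_steps * config.frame_interval),
                config.temperature,
                config.viscosity,
            )
            for t in accepted
        ]
    )
    particle_frames = sum(t.n_steps for t in tracks)
    per_frame = particle_frames / config.n_frames_observed
    conc = per_frame / config.sampling_volume_ml * config.dilution_factor
    d10, d50, d90 = dispersity.weighted_percentiles(diameters, [0.1, 0.5, 0.9])
    return NtaResult(
        estimated_diameters=diameters,
        particles_per_ml=float(conc),
        mean_size=float(np.mean(diameters)),
        span=dispersity.span(float(d10), float(d50), float(d90)),
        n_tracks=len(accepted),
    )


def simulate_nta(
    population: ParticlePopulation, config: InstrumentConfig
) -> NtaResult:
    """Convenience: simulate tracks then run the estimator."""
    rng = np.random.default_rng(config.seed)
    return estimate_from_tracks(simulate_tracks(population, config, rng), config)


def simulate_dls(
    population: ParticlePopulation,
    config: InstrumentConfig,
    noise_sd: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> tuple[float, float]:
    """(z-average nm, PDI) with optional multiplicative Gaussian noise."""
    if population.n_particles == 0:
        raise ValueError("empty population")
    z, pdi = dispersity.z_average_and_pdi(population.diameters)
    if noise_sd > 0:
        rng = rng or np.random.default_rng(config.seed)
        z *= 1.0 + rng.normal(0.0, noise_sd)
        pdi *= 1.0 + rng.normal(0.0, noise_sd)
    return float(z), float(pdi)
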