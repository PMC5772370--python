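"""Synthetic colloid generator.

Produces ground-truth particle populations and transforms them with the
three processes the stability analysis is built to detect:

* extrusion through a membrane pore — many small vesicles from few large
  ones, membrane area conserved;
* solvent-induced vesicle fusion — fewer, larger vesicles, membrane area
  conserved;
* surfactant-depletion aggregation of solid particles — fewer, larger
  particles, core volume conserved.

Vesicle excipient resides in the shell, so vesicle operations conserve
Σd² (∝ membrane area ∝ lipid count); solid-core excipient resides in the
bulk, so solid operations conserve Σd³ (∝ volume ∝ excipient mass).  Either
way the product particles/mL × mean molecules/particle is invariant, which
is exactly the conservation audit run on measured tables.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class ParticlePopulation:
    """Explicit list of particle diameters in a known suspension volume."""

    diameters: np.ndarray  # nm, one entry per particle
    suspension_volume_ml: float = 1e-9  # simulated aliquot
    architecture: str = "vesicle"  # vesicle | solid

    def __post_init__(self):
        d = np.asarray(self.diameters, dtype=float)
        object.__setattr__(self, "diameters", d)
        if d.size and np.any(d <= 0):
            raise ValueError("diameters must be > 0")
        if self.suspension_volume_ml <= 0:
            raise ValueError("suspension_volume_ml must be > 0")
        if self.architecture not in ("vesicle", "solid"):
            raise ValueError("architecture must be 'vesicle' or 'solid'")

    @property
    def n_particles(self) -> int:
        return int(self.diameters.size)

    @property
    def particles_per_ml(self) -> float:
        return self.n_particles / self.suspension_volume_ml

    @property
    def total_area(self) -> float:
        """Σd², ∝ total membrane area (vesicles' conserved quantity)."""
        return float(np.sum(self.diameters**2))

    @property
    def total_volume(self) -> float:
        """Σd³, ∝ total core volume (solids' conserved quantity)."""
        return float(np.sum(self.diameters**3))


def make_population(
    n: int,
    modes: Sequence[tuple[float, float, float]],
    seed: int,
    suspension_volume_ml: float = 1e-9,
    architecture: str = "vesicle",
) -> ParticlePopulation:
    """Draw ``n`` diameters from a lognormal mixture.

    ``modes`` is a list of (median nm, geometric SD >= 1, weight) tuples with
    weights summing to 1.  A geometric SD of exactly 1 gives a degenerate
    (monodisperse) mode.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    modes = list(modes)
    medians = np.array([m[0] for m in modes], dtype=float)
    gsds = np.array([m[1] for m in modes], dtype=float)
    weights = np.array([m[2] for m in modes], dtype=float)
    if np.any(medians <= 0) or np.any(gsds < 1) or np.any(weights < 0):
        raise ValueError("invalid mixture: need median > 0, gsd >= 1, weight >= 0")
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError("mixture weights must sum to 1")
    rng = np.random.default_rng(seed)
    which = rng.choice(len(modes), size=n, p=weights)
    d = medians[which] * np.exp(rng.standard_normal(n) * np.log(gsds[which]))
    return ParticlePopulation(d, suspension_volume_ml, architecture)


def extrude(
    population: ParticlePopulation,
    pore_diameter_nm: float,
    passages: int,
    seed: int,
    jitter_gsd: float = 1.10,
    equal_daughters: bool = False,
    efficiency: float = 1.0,
) -> ParticlePopulation:
    """Fragment over-pore vesicles through a membrane, conserving Σd².

    Per passage each vesicle large enough to fragment — m = round(d²/pore²)
    of at least 2 — splits into m daughters drawn around the pore size
    (geometric jitter ``jitter_gsd``, or exactly equal daughters) and
    rescaled so the daughters' Σd² equals the parent's d².  Rounding the
    fragment count keeps every daughter within ~15% of the pore, so vesicles
    just above the pore squeeze through intact, as extruded formulations
    (final sizes at or somewhat above the pore) show.  ``efficiency`` is the
    per-passage fragmentation probability; below 1 it spreads break-up over
    several passages, reproducing the gradual size decrease of a real
    extrusion series.  Particle count is non-decreasing and the
    number-weighted mean non-increasing.
    """
    if population.architecture != "vesicle":
        raise ValueError("extrusion is only defined for vesicles")
    if pore_diameter_nm <= 0:
        raise ValueError("pore_diameter_nm must be > 0")
    if passages < 0:
        raise ValueError("passages must be >= 0")
    if not 0.0 <= efficiency <= 1.0:
        raise ValueError("efficiency must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    d = population.diameters.copy()
    for _ in range(passages):
        m_all = np.round((d / pore_diameter_nm) ** 2).astype(int)
        fragments = (m_all >= 2) & (rng.random(d.size) < efficiency)
        out = [d[~fragments]]
        for parent, m in zip(d[fragments], m_all[fragments]):
            if equal_daughters or jitter_gsd == 1.0:
                daughters = np.full(m, parent / np.sqrt(m))
            else:
                daughters = pore_diameter_nm * np.exp(
                    rng.standard_normal(m) * np.log(jitter_gsd)
                )
                daughters *= parent / np.sqrt(np.sum(daughters**2))
            out.append(daughters)
        d = np.concatenate(out)
    return replace(population, diameters=d)


def fuse(
    population: ParticlePopulation,
    fusion_rounds: int,
    pair_fraction: float,
    seed: int,
) -> ParticlePopulation:
    """Merge random disjoint vesicle pairs, conserving membrane area.

    Per round a ``pair_fraction`` of the possible disjoint pairs merges;
    the merged diameter is √(d₁² + d₂²) so Σd² is exact.  Count decreases
    by the number of merges.
    """
    if population.architecture != "vesicle":
        raise ValueError("fusion is only defined for vesicles")
    if not 0.0 <= pair_fraction <= 1.0:
        raise ValueError("pair_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    d = population.diameters.copy()
    for _ in range(fusion_rounds):
        n_pairs = int(np.floor(pair_fraction * (d.size // 2)))
        if n_pairs == 0:
            continue
        idx = rng.permutation(d.size)
        a, b = idx[:n_pairs], idx[n_pairs : 2 * n_pairs]
        merged = np.sqrt(d[a] ** 2 + d[b] ** 2)
        d = np.concatenate([merged, d[idx[2 * n_pairs :]]])
    return replace(population, diameters=d)


def aggregate(
    population: ParticlePopulation,
    surfactant_fraction: float,
    seed: int,
    gamma: float = 2.0,
) -> ParticlePopulation:
    """Cluster solid particles as surfactant coverage drops, conserving Σd³.

    The merge propensity is p = 1 − surfactant_fraction^γ: full coverage
    (fraction 1) leaves the population untouched, depletion drives it toward
    large clusters.  Particles are partitioned into random clusters whose
    sizes follow a geometric(1 − p) law — expected cluster size 1/(1 − p) —
    and each cluster collapses to one particle of diameter (Σd³)^{1/3}.
    """
    if population.architecture != "solid":
        raise ValueError("surfactant-depletion aggregation is only defined for solids")
    if not 0.0 <= surfactant_fraction <= 1.0:
        raise ValueError("surfactant_fraction must lie in [0, 1]")
    p = 1.0 - surfactant_fraction**gamma
    if p <= 0:
        return replace(population, diameters=population.diameters.copy())
    rng = np.random.default_rng(seed)
    d = rng.permutation(population.diameters)
    success = max(1.0 - p, 1e-12)  # p = 1 (no surfactant) collapses everything
    sizes = []
    remaining = d.size
    while remaining > 0:
        k = min(int(rng.geometric(success)), remaining)
        sizes.append(k)
        remaining -= k
    merged = np.empty(len(sizes))
    start = 0
    for i, k in enumerate(sizes):
        merged[i] = np.sum(d[start : start + k] ** 3) ** (1.0 / 3.0)
        start += k
    return replace(population, diameters=merged)
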