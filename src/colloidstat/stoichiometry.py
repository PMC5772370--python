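"""Excipient stoichiometry of colloidal particles.

Links the molar concentration of an excipient (phospholipid, solid lipid)
to the number-concentration of particles measured by particle counting,
yielding the mean number of excipient molecules per particle and the molar
concentration of particles themselves.  Also provides the geometric
counterpart for unilamellar vesicles: the number of lipids a sphere of a
given diameter can accommodate in its bilayer, from the area per headgroup.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional

from pydantic import BaseModel, model_validator

#: Avogadro constant, 1/mol (2019 SI exact value).
AVOGADRO = 6.02214076e23

#: Area per phosphatidylcholine headgroup, Å² (literature consensus value).
DEFAULT_HEADGROUP_AREA_A2 = 55.0


class FormulationSpec(BaseModel):
    """Composition and architecture of one colloidal formulation.

    Parameters
    ----------
    excipient_name
        Label of the structural excipient (e.g. ``"DPPC"``, ``"cetyl palmitate"``).
    molar_concentration
        Excipient concentration in mol/L.  May be derived from a mass
        fraction via :func:`mass_fraction_to_molarity`.
    molecular_weight
        g/mol; only needed when the input was a mass fraction.
    headgroup_area
        Å² per molecule at the membrane surface (vesicles only).
    leaflets
        Number of monolayers contributing area; 2 for a unilamellar vesicle.
    architecture
        ``"vesicle"`` (excipient in the shell) or ``"solid"`` (excipient in
        the bulk core).
    """

    excipient_name: str
    molar_concentration: float
    molecular_weight: Optional[float] = None
    headgroup_area: float = DEFAULT_HEADGROUP_AREA_A2
    leaflets: int = 2
    architecture: Literal["vesicle", "solid"] = "vesicle"

    @model_validator(mode="after")
    def _check(self) -> "FormulationSpec":
        if self.molar_concentration < 0:
            raise ValueError("molar_concentration must be >= 0")
        if self.architecture == "vesicle" and self.headgroup_area <= 0:
            raise ValueError("headgroup_area must be > 0 for vesicles")
        if self.leaflets < 1:
            raise ValueError("leaflets must be >= 1")
        return self


@dataclass(frozen=True)
class StoichiometryResult:
    """Per-particle stoichiometry derived from counts and molarity."""

    molecules_per_ml: float
    particles_per_ml: float
    molecules_per_particle: float
    particle_molarity: float


def molecules_per_ml(concentration_mol_l: float) -> float:
    """Number of excipient molecules per mL of suspension.

    ``c`` mol/L × N_A / 1000 mL/L.  A 0.125 mM lipid suspension holds
    7.5 × 10¹⁶ molecules/mL (2 s.f.).
    """
    if concentration_mol_l < 0:
        raise ValueError("concentration must be >= 0")
    return concentration_mol_l * AVOGADRO / 1000.0


def mass_fraction_to_molarity(mass_percent: float, molecular_weight: float) -> float:
    """Convert % w/v to mol/L.

    ``x`` % w/v is ``10·x`` g/L, so molarity is ``10·x / MW``.
    10% cetyl palmitate (MW 480.85) → 0.208 mol/L.
    """
    if molecular_weight <= 0:
        raise ValueError("molecular_weight must be > 0")
    if mass_percent < 0:
        raise ValueError("mass_percent must be >= 0")
    return 10.0 * mass_percent / molecular_weight


def molecules_per_particle(n_molecules_per_ml: float, particles_per_ml: float) -> float:
    """Mean excipient molecules per particle: molecules/mL ÷ particles/mL."""
    if particles_per_ml <= 0:
        raise ZeroDivisionError(
            "stoichiometry undefined: particles_per_ml must be > 0"
        )
    if n_molecules_per_ml <= 0:
        raise ValueError("molecules_per_ml must be > 0")
    return n_molecules_per_ml / particles_per_ml


def theoretical_molecules_per_vesicle(
    diameter_nm: float,
    headgroup_area_a2: float = DEFAULT_HEADGROUP_AREA_A2,
    leaflets: int = 2,
) -> float:
    """Lipids accommodated by a spherical vesicle of given diameter.

    Both monolayers of a unilamellar bilayer contribute surface area, so the
    count is ``leaflets × 4π(d/2)² / a`` with the diameter in Å and ``a`` the
    area per headgroup in Å².  Scales as d².
    """
    if diameter_nm <= 0 or headgroup_area_a2 <= 0:
        raise ValueError("diameter and headgroup area must be > 0")
    if leaflets < 1:
        raise ValueError("leaflets must be >= 1")
    d_angstrom = diameter_nm * 10.0
    return leaflets * math.pi * d_angstrom**2 / headgroup_area_a2


def predicted_particle_concentration(
    n_molecules_per_ml: float, n_molecules_per_particle: float
) -> float:
    """Particles/mL predicted from total molecules and molecules per particle."""
    if n_molecules_per_particle <= 0:
        raise ZeroDivisionError("molecules_per_particle must be > 0")
    return n_molecules_per_ml / n_molecules_per_particle


def particle_molarity(particles_per_ml: float) -> float:
    """Molar concentration of the particles themselves, mol/L."""
    if particles_per_ml < 0:
        raise ValueError("particles_per_ml must be >= 0")
    return particles_per_ml * 1000.0 / AVOGADRO


def compute_stoichiometry(
    formulation: FormulationSpec, particles_per_ml: float
) -> StoichiometryResult:
    """Full per-particle stoichiometry for one measured particle count."""
    n_ml = molecules_per_ml(formulation.molar_concentration)
    return StoichiometryResult(
        molecules_per_ml=n_ml,
        particles_per_ml=particles_per_ml,
        molecules_per_particle=molecules_per_particle(n_ml, particles_per_ml),
        particle_molarity=particle_molarity(particles_per_ml),
    )


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (display helper; raw values kept)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))
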