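"""Spherical-particle dosimetry: mass <-> number <-> surface-area concentration.

All particles are treated as monodisperse spheres at their nominal diameter.
Interface units follow the conventions of in vitro nanotoxicology screens:
diameters in nm, mass concentrations in µg/mL, particle numbers in
particles/mL and surface area in cm²/mL.  Internally lengths are converted
to cm so that densities in g/cm³ combine without hidden factors.

Doses may be given on a whole-particle-mass basis or on an element-mass
basis (e.g. µg Cd/mL for CdTe quantum dots, where only the cadmium content
is assayed); element-mass doses are divided by the element mass fraction
before any geometry is applied.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
from pydantic import BaseModel, Field, model_validator

NM_PER_CM = 1.0e7
UG_PER_G = 1.0e6

DoseBasis = Literal["particle_mass", "element_mass"]


class ParticleSpec(BaseModel):
    """Physical description of one particle type.

    Parameters
    ----------
    name : str
        Particle identifier, e.g. ``"CdTe-2.6nm"``.
    diameter_nm : float
        Nominal spherical diameter in nm (> 0).
    density_g_cm3 : float
        Bulk mass density in g/cm³ (> 0).
    element_mass_fraction : float
        Mass fraction of the assayed element in the particle, in (0, 1].
        1.0 means doses refer to whole-particle mass.
    dose_basis : {"particle_mass", "element_mass"}
        Basis on which dose columns for this particle are expressed.
    """

    name: str
    diameter_nm: float = Field(gt=0)
    density_g_cm3: float = Field(gt=0)
    element_mass_fraction: float = Field(gt=0, le=1, default=1.0)
    dose_basis: DoseBasis = "particle_mass"

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _element_basis_needs_fraction(self) -> "ParticleSpec":
        # element-mass dosing with f == 1 is allowed (element == particle)
        # but f must be strictly positive, which Field(gt=0) enforces.
        return self

    @property
    def particle_mass_g(self) -> float:
        """Mass of a single spherical particle in grams."""
        d_cm = self.diameter_nm / NM_PER_CM
        return self.density_g_cm3 * (np.pi / 6.0) * d_cm**3

    @property
    def particle_surface_cm2(self) -> float:
        """Surface area of a single spherical particle in cm²."""
        d_cm = self.diameter_nm / NM_PER_CM
        return np.pi * d_cm**2


def to_particle_mass(dose_ug_ml, spec: ParticleSpec):
    """Normalise a dose to whole-particle-mass basis (µg/mL).

    Element-mass doses are divided by the element mass fraction; doses
    already on particle-mass basis pass through unchanged.
    """
    dose = np.asarray(dose_ug_ml, dtype=float)
    if np.any(dose < 0):
        raise ValueError("dose must be >= 0")
    if spec.dose_basis == "element_mass":
        out = dose / spec.element_mass_fraction
    else:
        out = dose
    return out if out.ndim else float(out)


def particles_per_ml(dose_ug_ml, spec: ParticleSpec):
    """Number concentration (particles/mL) at a mass dose in µg/mL.

    N = C / m_p with C the whole-particle mass concentration in g/mL and
    m_p = rho * (pi/6) * d³ the single-particle mass.
    """
    mass = np.asarray(to_particle_mass(dose_ug_ml, spec), dtype=float)
    n = (mass / UG_PER_G) / spec.particle_mass_g
    return n if n.ndim else float(n)


def surface_area_per_ml(dose_ug_ml, spec: ParticleSpec):
    """Surface-area concentration (cm²/mL) at a mass dose in µg/mL.

    SA = N * pi * d², equivalently 6 C / (rho d) for spheres.
    """
    n = np.asarray(particles_per_ml(dose_ug_ml, spec), dtype=float)
    sa = n * spec.particle_surface_cm2
    return sa if sa.ndim else float(sa)


def volume_per_ml(dose_ug_ml, spec: ParticleSpec):
    """Total particle volume concentration (cm³/mL) at a mass dose in µg/mL."""
    mass = np.asarray(to_particle_mass(dose_ug_ml, spec), dtype=float)
    v = (mass / UG_PER_G) / spec.density_g_cm3
    return v if v.ndim else float(v)


def mass_dose_for_metric(metric: str, amount: float, spec: ParticleSpec) -> float:
    """Invert the conversions: mass dose (µg/mL, particle-mass basis) at which
    the chosen metric equals ``amount``.

    metric "number": amount in particles/mL; "surface": cm²/mL;
    "volume": cm³/mL; "mass": µg/mL (identity).
    """
    if amount < 0:
        raise ValueError("amount must be >= 0")
    if metric == "mass":
        return float(amount)
    if metric == "number":
        return float(amount * spec.particle_mass_g * UG_PER_G)
    if metric == "surface":
        n = amount / spec.particle_surface_cm2
        return float(n * spec.particle_mass_g * UG_PER_G)
    if metric == "volume":
        return float(amount * spec.density_g_cm3 * UG_PER_G)
    raise ValueError(
        f"unknown metric {metric!r}; allowed: 'surface', 'volume', 'number', 'mass'"
    )
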