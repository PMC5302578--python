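"""Particle dosimetry for hollow nanotube suspensions.

Halloysite clay nanotubes (HNTs) are hollow aluminosilicate cylinders,
typically ~50 nm outer diameter, ~15 nm lumen, 0.5–1.5 µm long, with a
mass density of 2.55 g/cm³.  Suspension doses are quoted either as mass
concentration (mg/mL) or as particle-number concentration (part/mL);
this module converts between the two from a hollow-cylinder volume model
and provides the cube-root scaling of mean inter-particle spacing with
number density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "HNTGeometry",
    "Concentration",
    "HNT_DENSITY_G_CM3",
    "particle_volume",
    "particle_mass_mg",
    "mass_to_number",
    "number_to_mass",
    "mean_spacing_ratio",
]

#: Mass density of halloysite, g/cm^3.
HNT_DENSITY_G_CM3 = 2.55

_NM3_TO_CM3 = 1e-21  # (1 nm)^3 in cm^3


@dataclass(frozen=True)
class HNTGeometry:
    """Hollow-cylinder nanotube geometry, all lengths in nanometres.

    Defaults are the representative halloysite dimensions: 50 nm outer
    diameter, 15 nm lumen diameter and a 1000 nm representative length
    (midpoint of the usual 500–1500 nm polydispersity range).
    """

    outer_diameter_nm: float = 50.0
    lumen_diameter_nm: float = 15.0
    length_nm: float = 1000.0

    def __post_init__(self) -> None:
        if not (self.outer_diameter_nm > 0 and self.lumen_diameter_nm > 0
                and self.length_nm > 0):
            raise ValueError("all geometry dimensions must be positive")
        if self.lumen_diameter_nm > self.outer_diameter_nm:
            raise ValueError(
                f"lumen diameter ({self.lumen_diameter_nm} nm) exceeds outer "
                f"diameter ({self.outer_diameter_nm} nm)")


def particle_volume(geom: HNTGeometry) -> float:
    """Wall volume of one hollow cylinder, in nm³.

    V = π/4 · (d_outer² − d_lumen²) · L — the annular cross-section times
    the tube length (the empty lumen carries no mass).
    """
    return (math.pi / 4.0
            * (geom.outer_diameter_nm ** 2 - geom.lumen_diameter_nm ** 2)
            * geom.length_nm)


def particle_mass_mg(geom: HNTGeometry,
                     density_g_cm3: float = HNT_DENSITY_G_CM3) -> float:
    """Mass of one particle in mg, from geometry and mass density."""
    if density_g_cm3 <= 0:
        raise ValueError("density must be positive")
    v_nm3 = particle_volume(geom)
    if v_nm3 == 0:
        raise ValueError("particle volume is zero (degenerate geometry)")
    return v_nm3 * _NM3_TO_CM3 * density_g_cm3 * 1e3  # g -> mg


def mass_to_number(mass_conc_mg_ml: float,
                   geom: HNTGeometry = HNTGeometry(),
                   density_g_cm3: float = HNT_DENSITY_G_CM3) -> float:
    """Convert mass concentration (mg/mL) to number concentration (part/mL)."""
    if mass_conc_mg_ml < 0:
        raise ValueError("mass concentration must be non-negative")
    return mass_conc_mg_ml / particle_mass_mg(geom, density_g_cm3)


def number_to_mass(number_conc_per_ml: float,
                   geom: HNTGeometry = HNTGeometry(),
                   density_g_cm3: float = HNT_DENSITY_G_CM3) -> float:
    """Convert number concentration (part/mL) to mass concentration (mg/mL)."""
    if number_conc_per_ml < 0:
        raise ValueError("number concentration must be non-negative")
    return number_conc_per_ml * particle_mass_mg(geom, density_g_cm3)


@dataclass(frozen=True)
class Concentration:
    """A suspension dose expressed both ways, kept mutually consistent."""

    mass_mg_ml: float
    number_per_ml: float

    @classmethod
    def from_mass(cls, mass_mg_ml: float,
                  geom: HNTGeometry = HNTGeometry(),
                  density_g_cm3: float = HNT_DENSITY_G_CM3) -> "Concentration":
        return cls(mass_mg_ml, mass_to_number(mass_mg_ml, geom, density_g_cm3))

    @classmethod
    def from_number(cls, number_per_ml: float,
                    geom: HNTGeometry = HNTGeometry(),
                    density_g_cm3: float = HNT_DENSITY_G_CM3) -> "Concentration":
        return cls(number_to_mass(number_per_ml, geom, density_g_cm3),
                   number_per_ml)


def mean_spacing_ratio(density_factor: float) -> float:
    """Ratio of mean inter-particle spacing after scaling number density.

    For particles dispersed uniformly in a volume the mean nearest-
    neighbour spacing scales as n^(−1/3); multiplying the number density
    by ``density_factor`` therefore multiplies the mean spacing by
    ``density_factor**(-1/3)``.  Doubling the density shrinks the mean
    spacing by ≈20.6%.
    """
    if density_factor <= 0:
        raise ValueError("density factor must be positive")
    return density_factor ** (-1.0 / 3.0)
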