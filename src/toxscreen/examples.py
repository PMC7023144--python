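"""Worked example: CdTe quantum-dot size series.

Literature-reported LD50 values for a CdTe quantum-dot size series dosed on
a cadmium-mass basis (µg Cd/mL), together with the physical constants
needed to convert those doses to particle numbers: bulk CdTe density and
the Cd mass fraction from standard atomic masses
(Cd 112.414, Te 127.60 g/mol).  The density and composition are assumptions
— suppliers of such dots do not publish per-lot values — but they enter the
equi-response log-log slope only through the intercept, not the slope.
"""

from __future__ import annotations

import pandas as pd

from .dosimetry import ParticleSpec

ATOMIC_MASS_CD = 112.414
ATOMIC_MASS_TE = 127.60

#: Cd mass fraction of stoichiometric CdTe (~0.4684)
CDTE_CD_MASS_FRACTION = ATOMIC_MASS_CD / (ATOMIC_MASS_CD + ATOMIC_MASS_TE)

#: bulk density of CdTe, g/cm³
CDTE_DENSITY_G_CM3 = 5.85

#: reported diameters (nm) and LD50s (µg Cd/mL) of the five-dot size series
CDTE_QD_DIAMETERS_NM = (1.5, 2.6, 4.5, 6.5, 8.6)
CDTE_QD_LD50_UG_CD_ML = (1.0, 2.0, 4.0, 8.7, 15.8)


def cdte_qd_specs(
    density_g_cm3: float = CDTE_DENSITY_G_CM3,
    cd_mass_fraction: float = CDTE_CD_MASS_FRACTION,
) -> list[ParticleSpec]:
    """Particle specs for the five CdTe dots, doses on element (Cd) basis."""
    return [
        ParticleSpec(
            name=f"CdTe-{d:g}nm",
            diameter_nm=d,
            density_g_cm3=density_g_cm3,
            element_mass_fraction=cd_mass_fraction,
            dose_basis="element_mass",
        )
        for d in CDTE_QD_DIAMETERS_NM
    ]


def cdte_qd_ld50_table() -> pd.DataFrame:
    """Reported LD50s of the CdTe size series as a tidy table."""
    return pd.DataFrame(
        {
            "particle": [f"CdTe-{d:g}nm" for d in CDTE_QD_DIAMETERS_NM],
            "diameter_nm": CDTE_QD_DIAMETERS_NM,
            "ld50_ug_cd_ml": CDTE_QD_LD50_UG_CD_ML,
        }
    )
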