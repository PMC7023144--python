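import numpy as np
import pytest

from toxscreen.dosimetry import ParticleSpec
from toxscreen.synthetic_data import FoldCurve, PanelConfig


@pytest.fixture
def unit_sphere_spec():
    """100 nm sphere of unit density, particle-mass dosing."""
    return ParticleSpec(name="ref", diameter_nm=100, density_g_cm3=1.0)


@pytest.fixture
def small_panel():
    """Three-particle, two-reporter panel with known generative parameters."""
    return PanelConfig(
        particle_names=["NP-10", "NP-20", "NP-40"],
        diameters=[10.0, 20.0, 40.0],
        density=5.0,
        true_ld50s={"NP-10": 4.0, "NP-20": 8.0, "NP-40": {"Srxn1": 16.0, "Ddit3": None}},
        reporters=["Srxn1", "Ddit3"],
        fold_curves={
            "Srxn1": FoldCurve(f_max=5.0, d_half=5.0),
            "Ddit3": FoldCurve(f_max=1.2, d_half=5.0),
        },
        noise_cv=0.1,
        n_replicates=3,
        seed=11,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
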