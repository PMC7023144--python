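"""Tests for the synthetic screen generator and metric-series scenarios."""

import numpy as np
import pytest
from pydantic import ValidationError

from toxscreen.dose_response import fit_hill_ld50
from toxscreen.dosimetry import ParticleSpec, particles_per_ml
from toxscreen.synthetic_data import (FoldCurve, MetricScenario, PanelConfig,
                                      generate_metric_series, generate_screen)


def single_particle_config(**overrides):
    base = dict(
        particle_names=["NP"],
        diameters=[20.0],
        density=5.0,
        true_ld50s={"NP": 12.5},
        reporters=["Srxn1"],
        fold_curves={"Srxn1": FoldCurve(f_max=4.0, d_half=5.0)},
        noise_cv=0.0,
        n_replicates=1,
        seed=3,
    )
    base.update(overrides)
    return PanelConfig(**base)


class TestGenerateScreen:
    def test_noiseless_hill_midpoint_and_control_identity(self):
        screen = generate_screen(single_particle_config())
        at_ld50 = screen[screen["dose_ug_ml"] == 12.5]
        assert not at_ld50.empty
        assert at_ld50["viability_pct"].iloc[0] == pytest.approx(50.0, abs=1e-12)
        control = screen[screen["dose_ug_ml"] == 0.0]
        assert control["viability_pct"].iloc[0] == 100.0
        # control GFP equals the configured control level -> fold 1
        assert control["gfp_mean"].iloc[0] == pytest.approx(200.0)

    def test_same_seed_regenerates_byte_identical_table(self):
        cfg = single_particle_config(noise_cv=0.1, n_replicates=3, seed=7)
        a = generate_screen(cfg).to_csv(index=False)
        b = generate_screen(cfg).to_csv(index=False)
        assert a == b
        c = generate_screen(single_particle_config(noise_cv=0.1,
                                                   n_replicates=3, seed=8))
        assert c.to_csv(index=False) != a

    def test_noiseless_screen_round_trips_to_configured_ld50(self):
        screen = generate_screen(single_particle_config())
        fit = fit_hill_ld50(screen["dose_ug_ml"], screen["viability_pct"])
        assert fit.ld50 == pytest.approx(12.5, rel=1e-6)

    def test_non_cytotoxic_particle_has_full_viability_and_top_dose_100(self):
        screen = generate_screen(single_particle_config(true_ld50s={"NP": None}))
        assert (screen["viability_pct"] == 100.0).all()
        assert screen["dose_ug_ml"].max() == 100.0

    def test_control_fold_mean_converges_to_one(self):
        """Mean-1 multiplicative noise: the sample mean of control GFP over
        many replicates approaches the control level within 3 SE."""
        cv = 0.1
        n = 10_000
        cfg = single_particle_config(noise_cv=cv, n_replicates=n, seed=13)
        screen = generate_screen(cfg)
        control = screen.loc[screen["dose_ug_ml"] == 0.0, "gfp_mean"] / 200.0
        se = cv / np.sqrt(n)
        assert abs(control.mean() - 1.0) < 3 * se

    def test_autofluorescence_column_added_to_gfp(self):
        cfg = single_particle_config(autofluorescence_per_dose={"NP": 2.0})
        screen = generate_screen(cfg)
        row = screen[screen["dose_ug_ml"] == 6.25].iloc[0]
        assert row["autofluorescence"] == pytest.approx(12.5)
        # subtracting the reported autofluorescence recovers the pure signal
        fold_true = 1 + 3.0 * 6.25 / 11.25
        assert row["gfp_mean"] - row["autofluorescence"] == pytest.approx(
            200.0 * fold_true
        )

    @pytest.mark.parametrize(
        "bad, field",
        [
            (dict(diameters=[-5.0]), "diameters"),
            (dict(noise_cv=-0.1), "noise_cv"),
            (dict(n_replicates=0), "n_replicates"),
            (dict(true_ld50s={"NP": -1.0}), "true_ld50s"),
            (dict(true_ld50s={"ghost": 5.0}), "true_ld50s"),
        ],
    )
    def test_invalid_config_names_field(self, bad, field):
        with pytest.raises((ValidationError, ValueError)) as exc:
            single_particle_config(**bad)
        assert field in str(exc.value)


class TestGenerateMetricSeries:
    DIAMETERS = [10.0, 20.0, 40.0]

    def scenario(self, metric, ed, **kw):
        return MetricScenario(metric_name=metric, ed_value=ed,
                              diameters=self.DIAMETERS, density=5.0, **kw)

    def test_number_series_has_identical_particle_number(self):
        series = generate_metric_series(self.scenario("number", 1e10))
        numbers = [
            particles_per_ml(
                dose, ParticleSpec(name="p", diameter_nm=d, density_g_cm3=5.0)
            )
            for d, dose in zip(series["diameter_nm"],
                               series["equi_response_mass_dose_ug_ml"])
        ]
        assert np.allclose(numbers, 1e10, rtol=1e-9)

    def test_surface_series_dose_scales_linearly_with_diameter(self):
        series = generate_metric_series(self.scenario("surface", 1.0))
        doses = series.set_index("diameter_nm")["equi_response_mass_dose_ug_ml"]
        assert doses[20.0] == pytest.approx(2 * doses[10.0], rel=1e-12)
        # hand value: C = ed * rho * d_cm / 6 * 1e6 µg/mL
        assert doses[10.0] == pytest.approx(1.0 * 5.0 * 1e-6 / 6 * 1e6,
                                            rel=1e-12)

    def test_volume_series_dose_independent_of_diameter(self):
        series = generate_metric_series(self.scenario("volume", 1e-6))
        doses = series["equi_response_mass_dose_ug_ml"]
        assert np.allclose(doses, doses.iloc[0], rtol=1e-12)

    def test_unknown_metric_lists_allowed_values(self):
        with pytest.raises(ValidationError, match="surface"):
            self.scenario("area", 1.0)

    def test_fewer_than_three_diameters_rejected(self):
        with pytest.raises(ValidationError):
            MetricScenario(metric_name="surface", ed_value=1.0,
                           diameters=[10.0, 20.0], density=5.0)

    def test_noise_is_seed_deterministic(self):
        s1 = generate_metric_series(self.scenario("surface", 1.0,
                                                  noise_cv=0.1, seed=5))
        s2 = generate_metric_series(self.scenario("surface", 1.0,
                                                  noise_cv=0.1, seed=5))
        assert s1.equals(s2)
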