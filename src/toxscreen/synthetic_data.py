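"""Synthetic screen generator emulating well-level reporter readouts.

Generates long-format screen tables with the statistical structure the
analysis pipeline assumes: unit-slope Hill viability loss around a
configured true LD50, saturating GFP fold induction

    fold(C) = 1 + (F_max - 1) * C / (C + D_half)

and multiplicative lognormal replicate noise with a configured coefficient
of variation (readouts are strictly positive, so a lognormal is the natural
noise family; the mean of the noise factor is 1).  Exposure doses follow
the screen's own ladder rule: the top dose targets 50-75 % cytotoxicity,
capped at 100 µg/mL, with four two-fold dilutions below it.

Reproducibility: a single integer seed governs the whole table through a
counter-based substream per (particle, reporter), so regeneration is
byte-identical and independent of row order.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .dosimetry import DoseBasis, ParticleSpec, mass_dose_for_metric
from .reporter_calls import select_doses

DEFAULT_REPORTERS = ("Srxn1", "Blvrb", "Rtkn", "Bscl2", "Ddit3", "Btg2")

SCREEN_COLUMNS = [
    "particle", "reporter", "dose_ug_ml", "dose_basis",
    "replicate", "viability_pct", "gfp_mean", "autofluorescence",
]


class FoldCurve(BaseModel):
    """Saturating induction curve: fold = 1 + (f_max-1) * C / (C + d_half)."""

    f_max: float = Field(ge=1.0)
    d_half: float = Field(gt=0.0)

    model_config = {"frozen": True}

    def fold(self, dose):
        dose = np.asarray(dose, dtype=float)
        out = 1.0 + (self.f_max - 1.0) * dose / (dose + self.d_half)
        return out if out.ndim else float(out)


class PanelConfig(BaseModel):
    """Generative description of one synthetic screen panel.

    ``true_ld50s`` maps particle -> LD50 (µg/mL on ``dose_basis``), either a
    single value for all reporter lines or a per-reporter mapping; ``None``
    flags a non-cytotoxic particle (no finite LD50).  ``fold_curves`` maps
    reporter -> FoldCurve, applied to every particle; reporters absent from
    the mapping stay flat at fold 1.
    """

    particle_names: list[str] = Field(min_length=1)
    diameters: list[float] = Field(min_length=1)
    density: float = Field(gt=0)
    element_mass_fraction: float = Field(gt=0, le=1, default=1.0)
    dose_basis: DoseBasis = "particle_mass"
    reporters: list[str] = Field(default_factory=lambda: list(DEFAULT_REPORTERS))
    true_ld50s: dict[str, float | dict[str, float | None] | None]
    fold_curves: dict[str, FoldCurve] = Field(default_factory=dict)
    noise_cv: float = Field(ge=0, default=0.1)
    n_replicates: int = Field(ge=1, default=3)
    seed: int = 0
    gfp_control_level: float = Field(gt=0, default=200.0)
    autofluorescence_per_dose: dict[str, float] = Field(default_factory=dict)

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _check_lengths(self) -> "PanelConfig":
        if len(self.diameters) != len(self.particle_names):
            raise ValueError(
                "diameters must have one entry per particle_names entry"
            )
        if any(d <= 0 for d in self.diameters):
            raise ValueError("diameters must be > 0")
        missing = set(self.true_ld50s) - set(self.particle_names)
        if missing:
            raise ValueError(f"true_ld50s names unknown particles: {sorted(missing)}")
        for p, v in self.true_ld50s.items():
            vals = v.values() if isinstance(v, dict) else [v]
            if any(x is not None and x <= 0 for x in vals):
                raise ValueError(f"true_ld50s for {p!r} must be > 0 or None")
        return self

    def ld50(self, particle: str, reporter: str) -> float | None:
        entry = self.true_ld50s.get(particle)
        if isinstance(entry, dict):
            return entry.get(reporter)
        return entry

    def particle_specs(self) -> dict[str, ParticleSpec]:
        return {
            name: ParticleSpec(
                name=name,
                diameter_nm=d,
                density_g_cm3=self.density,
                element_mass_fraction=self.element_mass_fraction,
                dose_basis=self.dose_basis,
            )
            for name, d in zip(self.particle_names, self.diameters)
        }


class MetricScenario(BaseModel):
    """A size series whose equi-response dose is fixed in one metric.

    ``ed_value`` is the per-mL amount of ``metric_name`` (cm²/mL for
    surface, cm³/mL for volume, particles/mL for number, µg/mL for mass)
    that produces the target response at every diameter.
    """

    metric_name: str
    ed_value: float = Field(gt=0)
    diameters: list[float] = Field(min_length=3)
    density: float = Field(gt=0)
    element_mass_fraction: float = Field(gt=0, le=1, default=1.0)
    noise_cv: float = Field(ge=0, default=0.0)
    seed: int = 0

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _check(self) -> "MetricScenario":
        if self.metric_name not in {"surface", "volume", "number", "mass"}:
            raise ValueError(
                f"unknown metric_name {self.metric_name!r}; "
                "allowed: 'surface', 'volume', 'number', 'mass'"
            )
        if len(set(self.diameters)) < 3:
            raise ValueError("at least 3 distinct diameters required")
        if any(d <= 0 for d in self.diameters):
            raise ValueError("diameters must be > 0")
        return self


def _noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-1 multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def _dose_ladder(config: PanelConfig, particle: str) -> list[float]:
    """Five-dose two-fold ladder from the particle's noiseless cytotoxicity.

    Emulates the initial dose-finding screen: candidate doses on a two-fold
    grid up to 100 µg/mL, noiseless Hill viability at the particle's
    geometric-mean finite LD50, then the standard top-dose rule.
    """
    finite = [
        config.ld50(particle, rep)
        for rep in config.reporters
        if config.ld50(particle, rep) is not None
    ]
    candidates = np.array([100.0 / 2**k for k in range(10)][::-1])
    if not finite:
        viab = np.full(candidates.shape, 100.0)
    else:
        ld50 = float(np.exp(np.mean(np.log(finite))))
        viab = 100.0 / (1.0 + candidates / ld50)
    return select_doses(candidates, viab)


def generate_screen(config: PanelConfig) -> pd.DataFrame:
    """Generate a long-format screen table for the configured panel.

    One row per (particle, reporter, dose, replicate) including
    vehicle-control rows at dose 0.  Viability is Hill-shaped around the
    true LD50 (truncated to [0, 100] after noise); GFP is the control level
    times the reporter's fold curve times noise, plus any dose-proportional
    particle autofluorescence (reported separately in the
    ``autofluorescence`` column so it can be subtracted downstream).
    """
    rows: list[dict] = []
    for p_idx, particle in enumerate(config.particle_names):
        doses = [0.0] + _dose_ladder(config, particle)
        af_coeff = config.autofluorescence_per_dose.get(particle, 0.0)
        for r_idx, reporter in enumerate(config.reporters):
            ss = np.random.SeedSequence(config.seed, spawn_key=(p_idx, r_idx))
            rng = np.random.default_rng(ss)
            shape = (len(doses), config.n_replicates)
            eps_v = _noise(rng, config.noise_cv, shape)
            eps_g = _noise(rng, config.noise_cv, shape)
            ld50 = config.ld50(particle, reporter)
            curve = config.fold_curves.get(reporter)
            for d_idx, dose in enumerate(doses):
                if ld50 is None:
                    viab_true = 100.0
                else:
                    viab_true = 100.0 / (1.0 + dose / ld50)
                fold_true = curve.fold(dose) if curve is not None else 1.0
                af = af_coeff * dose
                for rep in range(config.n_replicates):
                    viab = np.clip(viab_true * eps_v[d_idx, rep], 0.0, 100.0)
                    gfp = (config.gfp_control_level * fold_true
                           * eps_g[d_idx, rep]) + af
                    rows.append(
                        {
                            "particle": particle,
                            "reporter": reporter,
                            "dose_ug_ml": dose,
                            "dose_basis": config.dose_basis,
                            "replicate": rep + 1,
                            "viability_pct": float(viab),
                            "gfp_mean": float(gfp),
                            "autofluorescence": float(af),
                        }
                    )
    return pd.DataFrame(rows, columns=SCREEN_COLUMNS)


def generate_metric_series(scenario: MetricScenario) -> pd.DataFrame:
    """Equi-response mass doses for a size series driven by one metric.

    For each diameter, returns the mass concentration (µg/mL,
    particle-mass basis) at which the administered amount of the chosen
    metric equals ``ed_value``; optional multiplicative lognormal noise on
    the doses emulates equi-response-dose estimation error.
    """
    rng = np.random.default_rng(np.random.SeedSequence(scenario.seed))
    eps = _noise(rng, scenario.noise_cv, len(scenario.diameters))
    rows = []
    for d, e in zip(scenario.diameters, eps):
        spec = ParticleSpec(
            name=f"d{d:g}nm",
            diameter_nm=d,
            density_g_cm3=scenario.density,
            element_mass_fraction=scenario.element_mass_fraction,
        )
        dose = mass_dose_for_metric(scenario.metric_name, scenario.ed_value, spec)
        rows.append(
            {"diameter_nm": d, "equi_response_mass_dose_ug_ml": dose * e}
        )
    return pd.DataFrame(rows)


def write_screen_csv(screen: pd.DataFrame, path: str | Path) -> None:
    screen.to_csv(path, index=False)


def write_particle_metadata_csv(config: PanelConfig, path: str | Path) -> None:
    """Particle metadata table consumed by the dosimetry stage."""
    meta = pd.DataFrame(
        {
            "name": config.particle_names,
            "diameter_nm": config.diameters,
            "density_g_cm3": config.density,
            "element_mass_fraction": config.element_mass_fraction,
            "dose_basis": config.dose_basis,
        }
    )
    meta.to_csv(path, index=False)
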