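"""End-to-end orchestration: screen table -> fits, calls, dose-metric report,
summary heatmap table.

Every stage reads and writes plain CSV so the stages are independently
testable and the whole run is a pure function of the config and seed.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, ValidationError

from . import dose_metric as dm
from .dose_response import HillFit, equi_response_dose, fit_hill_ld50
from .dosimetry import ParticleSpec, particles_per_ml
from .errors import (CensoredFitError, DegenerateDataError,
                     InsufficientDataError, SchemaError)
from .reporter_calls import call_table, fold_table
from .synthetic_data import (PanelConfig, generate_screen,
                             write_particle_metadata_csv, write_screen_csv)

logger = logging.getLogger(__name__)

SCREEN_REQUIRED = {"particle", "reporter", "dose_ug_ml", "replicate",
                   "viability_pct", "gfp_mean"}
META_REQUIRED = {"name", "diameter_nm", "density_g_cm3",
                 "element_mass_fraction", "dose_basis"}


class AnalysisConfig(BaseModel):
    equi_response_level: float = Field(gt=0, lt=100, default=20.0)
    metric_tolerance: float = Field(gt=0, default=dm.DEFAULT_TOLERANCE)
    ld50_reporter: str = "Srxn1"

    model_config = {"frozen": True}


class PipelineConfig(BaseModel):
    """Declarative run description: either a synthesis block or input paths."""

    synthesis: PanelConfig | None = None
    screen_csv: str | None = None
    particle_metadata_csv: str | None = None
    analysis: AnalysisConfig = AnalysisConfig()

    model_config = {"frozen": True}


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        return PipelineConfig.model_validate(raw)
    except ValidationError as exc:
        raise SchemaError(f"invalid pipeline config: {exc}") from exc


def read_screen_csv(path: str | Path) -> pd.DataFrame:
    screen = pd.read_csv(path)
    missing = SCREEN_REQUIRED - set(screen.columns)
    if missing:
        raise SchemaError(f"screen table missing columns: {sorted(missing)}")
    return screen


def read_particle_metadata_csv(path: str | Path) -> dict[str, ParticleSpec]:
    meta = pd.read_csv(path)
    missing = META_REQUIRED - set(meta.columns)
    if missing:
        raise SchemaError(f"particle metadata missing columns: {sorted(missing)}")
    return {
        row["name"]: ParticleSpec(
            name=row["name"],
            diameter_nm=row["diameter_nm"],
            density_g_cm3=row["density_g_cm3"],
            element_mass_fraction=row["element_mass_fraction"],
            dose_basis=row["dose_basis"],
        )
        for _, row in meta.iterrows()
    }


def fit_screen(screen: pd.DataFrame) -> pd.DataFrame:
    """Unit-slope Hill fit per (particle, reporter): the fits table."""
    rows = []
    for (particle, reporter), grp in screen.groupby(["particle", "reporter"],
                                                    sort=True):
        try:
            fit = fit_hill_ld50(grp["dose_ug_ml"], grp["viability_pct"])
        except (InsufficientDataError, DegenerateDataError) as exc:
            logger.warning("(%s, %s): %s", particle, reporter, exc)
            continue
        logger.info("(%s, %s): %s", particle, reporter,
                    fit.bound if fit.censored else f"LD50 = {fit.ld50:.4g}")
        rows.append(
            {
                "particle": particle,
                "reporter": reporter,
                "ld50": fit.ld50,
                "censored": fit.censored,
                "bound": fit.bound,
                "max_dose_tested": fit.max_dose_tested,
                "rss": fit.rss,
                "n_points": fit.n_points,
            }
        )
    return pd.DataFrame(rows)


def _hill_from_row(row) -> HillFit:
    return HillFit(
        ld50=None if row["censored"] else float(row["ld50"]),
        censored=bool(row["censored"]),
        max_dose_tested=float(row["max_dose_tested"]),
        rss=float(row["rss"]),
        n_points=int(row["n_points"]),
    )


def dose_metric_report(
    fits: pd.DataFrame,
    specs: dict[str, ParticleSpec],
    equi_response_level: float = 20.0,
    tolerance: float = dm.DEFAULT_TOLERANCE,
) -> pd.DataFrame:
    """Per-reporter equi-response log-log fit over the available size series.

    Non-censored fits are inverted at the configured response level, the
    equi-response doses converted to particles/mL, and the slope of
    log10 N on log10 d fitted and classified.  Reporters with fewer than
    three usable sizes are reported with NaN slope and metric
    "insufficient_sizes".
    """
    unknown = set(fits["particle"]) - set(specs)
    if unknown:
        raise SchemaError(
            f"particles in fits absent from metadata: {sorted(unknown)}"
        )
    rows = []
    for reporter, grp in fits.groupby("reporter", sort=True):
        usable = grp[~grp["censored"].astype(bool)]
        series = []
        for _, row in usable.iterrows():
            spec = specs[row["particle"]]
            ed = equi_response_dose(_hill_from_row(row), equi_response_level)
            n = particles_per_ml(ed.dose, spec)
            series.append((spec.diameter_nm, n))
        base = {
            "reporter": reporter,
            "equi_response_level": equi_response_level,
            "tolerance": tolerance,
            "n_sizes": len({d for d, _ in series}),
        }
        try:
            fit = dm.fit_loglog(series, tolerance=tolerance)
        except (InsufficientDataError, ValueError):
            rows.append({**base, "slope": np.nan, "intercept": np.nan,
                         "r_squared": np.nan, "classified_metric":
                         "insufficient_sizes"})
            continue
        rows.append(
            {
                **base,
                "slope": fit.slope_m,
                "intercept": fit.intercept_q,
                "r_squared": fit.r_squared,
                "classified_metric": fit.classified_metric,
            }
        )
    return pd.DataFrame(rows)


def build_summary(
    fits: pd.DataFrame,
    calls: pd.DataFrame,
    specs: dict[str, ParticleSpec] | None = None,
    ld50_reporter: str = "Srxn1",
) -> pd.DataFrame:
    """One summary row per particle: size, LD50 label, verdict per reporter.

    The LD50 column comes from the chosen reporter line's cytotoxicity
    (censored fits are shown as a "> max dose" bound); verdict cells are
    "not tested" for reporters without a call.
    """
    particles = sorted(set(fits["particle"]) | set(calls["particle"]))
    reporters = sorted(set(fits["reporter"]) | set(calls["reporter"]))
    fit_ix = fits.set_index(["particle", "reporter"])
    call_ix = calls.set_index(["particle", "reporter"])
    rows = []
    for particle in particles:
        row: dict = {"particle": particle}
        row["size_label"] = (
            f"{specs[particle].diameter_nm:g}" if specs and particle in specs
            else ""
        )
        try:
            frow = fit_ix.loc[(particle, ld50_reporter)]
            if bool(frow["censored"]):
                row["ld50_label"] = f"> {frow['max_dose_tested']:g}"
            else:
                row["ld50_label"] = f"{frow['ld50']:.3g}"
        except KeyError:
            row["ld50_label"] = "not tested"
        for reporter in reporters:
            try:
                row[reporter] = call_ix.loc[(particle, reporter)]["verdict"]
            except KeyError:
                row[reporter] = "not tested"
        rows.append(row)
    return pd.DataFrame(rows)


def summary_text(summary: pd.DataFrame) -> str:
    """Plain-text aligned rendering of the summary table."""
    return summary.to_string(index=False) + "\n"


def run_pipeline(config_path: str | Path, outdir: str | Path) -> Path:
    """Run every stage and write all intermediate and final tables.

    Returns the output directory, which contains screen.csv (when
    synthesized), particles.csv, fits.csv, folds.csv, calls.csv,
    dose_metric.csv, summary.csv and summary.txt.  Deterministic for a
    fixed config (the synthesis seed lives in the config).
    """
    cfg = load_config(config_path)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    if cfg.synthesis is not None:
        screen = generate_screen(cfg.synthesis)
        specs = cfg.synthesis.particle_specs()
        write_screen_csv(screen, out / "screen.csv")
        write_particle_metadata_csv(cfg.synthesis, out / "particles.csv")
    else:
        if not cfg.screen_csv or not cfg.particle_metadata_csv:
            raise SchemaError(
                "config needs either a synthesis block or both screen_csv "
                "and particle_metadata_csv"
            )
        screen = read_screen_csv(cfg.screen_csv)
        specs = read_particle_metadata_csv(cfg.particle_metadata_csv)

    unknown = set(screen["particle"]) - set(specs)
    if unknown:
        raise SchemaError(
            f"particles in screen absent from metadata: {sorted(unknown)}"
        )

    fits = fit_screen(screen)
    folds = fold_table(screen)
    calls = call_table(folds)
    metric = dose_metric_report(
        fits, specs,
        equi_response_level=cfg.analysis.equi_response_level,
        tolerance=cfg.analysis.metric_tolerance,
    )
    summary = build_summary(fits, calls, specs,
                            ld50_reporter=cfg.analysis.ld50_reporter)

    fits.to_csv(out / "fits.csv", index=False)
    folds.to_csv(out / "folds.csv", index=False)
    calls.to_csv(out / "calls.csv", index=False)
    metric.to_csv(out / "dose_metric.csv", index=False)
    summary.to_csv(out / "summary.csv", index=False)
    (out / "summary.txt").write_text(summary_text(summary))
    return out
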