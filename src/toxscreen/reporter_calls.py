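"""GFP reporter-activation calling with viability gating.

Implements the screen's decision rules: autofluorescence-corrected fold
induction relative to vehicle control, a >2-fold threshold for a positive
call and a (1.5, 2] band for a weak positive, with doses at <=25 % viability
excluded from calling (cytotoxicity artifacts), plus the dose-selection
ladder used to pick exposure doses from an initial cytotoxicity screen.

Fold 2.0 exactly is assigned to the weak-positive band so that the bands
are exhaustive: "positive" requires strictly exceeding 2-fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AlignmentError, DegenerateDataError, GatedOutError

logger = logging.getLogger(__name__)

POSITIVE_FOLD = 2.0
WEAK_FOLD = 1.5
VIABILITY_GATE = 25.0
MAX_DOSE_UG_ML = 100.0


@dataclass(frozen=True)
class ReporterCall:
    """Per (particle, reporter) verdict with gating provenance."""

    particle: str
    reporter: str
    verdict: str  # negative | weak_positive | positive | uninterpretable
    max_valid_fold: float | None
    lowest_positive_dose: float | None
    gated_doses: tuple[float, ...] = ()


def correct_autofluorescence(gfp_mean, autofluorescence_mean):
    """Subtract particle-intrinsic fluorescence from the GFP signal.

    Values are floored at zero; a floor event is logged as a warning since
    it indicates autofluorescence comparable to the reporter signal.
    """
    gfp = np.asarray(gfp_mean, dtype=float)
    auto = np.asarray(autofluorescence_mean, dtype=float)
    if gfp.shape != auto.shape:
        raise AlignmentError(
            "GFP and autofluorescence series have different shapes: "
            f"{gfp.shape} vs {auto.shape}"
        )
    if np.any(gfp < 0) or np.any(auto < 0):
        raise ValueError("fluorescence values must be >= 0")
    corrected = gfp - auto
    if np.any(corrected < 0):
        logger.warning(
            "autofluorescence exceeds GFP signal in %d wells; floored at 0",
            int(np.sum(corrected < 0)),
        )
        corrected = np.clip(corrected, 0.0, None)
    return corrected if corrected.ndim else float(corrected)


def fold_induction(corrected_dose, corrected_control):
    """Fold induction: ratio of replicate means, dose over vehicle control."""
    dose_mean = float(np.mean(np.asarray(corrected_dose, dtype=float)))
    control_mean = float(np.mean(np.asarray(corrected_control, dtype=float)))
    if control_mean <= 0:
        raise DegenerateDataError(
            "vehicle-control GFP signal is <= 0 after correction; "
            "fold induction undefined"
        )
    return dose_mean / control_mean


def fold_table(screen: pd.DataFrame) -> pd.DataFrame:
    """Per (particle, reporter, dose) fold induction from a long screen table.

    Expects columns particle, reporter, dose_ug_ml, viability_pct, gfp_mean
    and optionally autofluorescence.  Replicates are averaged before the
    ratio is taken; autofluorescence is subtracted per well, before
    averaging.  Vehicle-control rows are dose 0.
    """
    df = screen.copy()
    auto = df["autofluorescence"] if "autofluorescence" in df else 0.0
    df["gfp_corrected"] = correct_autofluorescence(
        df["gfp_mean"].to_numpy(), np.broadcast_to(np.asarray(auto, dtype=float),
                                                   len(df)).copy()
    )
    rows = []
    for (particle, reporter), grp in df.groupby(["particle", "reporter"], sort=True):
        control = grp.loc[grp["dose_ug_ml"] == 0, "gfp_corrected"]
        if control.empty:
            raise DegenerateDataError(
                f"no vehicle-control rows for ({particle}, {reporter})"
            )
        control_mean = float(control.mean())
        for dose, dgrp in grp[grp["dose_ug_ml"] > 0].groupby("dose_ug_ml"):
            fold = fold_induction(dgrp["gfp_corrected"].to_numpy(),
                                  control.to_numpy())
            viab = float(dgrp["viability_pct"].mean())
            rows.append(
                {
                    "particle": particle,
                    "reporter": reporter,
                    "dose_ug_ml": float(dose),
                    "fold": fold,
                    "viability_pct": viab,
                    "gated_out": viab <= VIABILITY_GATE,
                    "control_mean": control_mean,
                }
            )
    return pd.DataFrame(rows)


def call_reporter(folds: pd.DataFrame) -> ReporterCall:
    """Verdict for one (particle, reporter) fold-induction series.

    ``folds`` needs columns dose_ug_ml, fold, viability_pct (one row per
    dose, replicates already averaged).  Doses at <=25 % viability are
    excluded; the verdict is read off the maximum remaining fold:
    > 2 -> positive, (1.5, 2] -> weak_positive, else negative.
    """
    if folds.empty:
        raise DegenerateDataError("no non-control doses to call")
    particle = str(folds["particle"].iloc[0]) if "particle" in folds else ""
    reporter = str(folds["reporter"].iloc[0]) if "reporter" in folds else ""
    gated = folds["viability_pct"] <= VIABILITY_GATE
    valid = folds[~gated]
    gated_doses = tuple(sorted(folds.loc[gated, "dose_ug_ml"].astype(float)))
    if gated_doses:
        logger.warning(
            "(%s, %s): %d dose(s) below the %g%% viability gate excluded",
            particle, reporter, len(gated_doses), VIABILITY_GATE,
        )
    if valid.empty:
        return ReporterCall(particle, reporter, "uninterpretable",
                            None, None, gated_doses)
    max_fold = float(valid["fold"].max())
    if max_fold > POSITIVE_FOLD:
        verdict = "positive"
        pos = valid[valid["fold"] > POSITIVE_FOLD]
        lowest = float(pos["dose_ug_ml"].min())
    elif max_fold > WEAK_FOLD:
        verdict, lowest = "weak_positive", None
    else:
        verdict, lowest = "negative", None
    return ReporterCall(particle, reporter, verdict, max_fold, lowest, gated_doses)


def call_table(folds: pd.DataFrame) -> pd.DataFrame:
    """Apply ``call_reporter`` per (particle, reporter) group."""
    calls = [
        call_reporter(grp)
        for _, grp in folds.groupby(["particle", "reporter"], sort=True)
    ]
    return pd.DataFrame(
        {
            "particle": c.particle,
            "reporter": c.reporter,
            "verdict": c.verdict,
            "max_valid_fold": c.max_valid_fold,
            "lowest_positive_dose": c.lowest_positive_dose,
            "gated_doses": ";".join(f"{d:g}" for d in c.gated_doses),
        }
        for c in calls
    )


def select_doses(doses, viabilities, max_dose: float = MAX_DOSE_UG_ML) -> list[float]:
    """Pick the five exposure doses from an initial cytotoxicity screen.

    The top dose is the smallest tested dose whose cytotoxicity
    (100 - viability) lies in [50, 75] %.  If no tested dose reaches 50 %
    cytotoxicity the top dose is ``max_dose`` (default 100 µg/mL).  If
    cytotoxicity jumps over the band, the largest tested dose still below
    50 % cytotoxicity is used.  Four two-fold dilutions below the top dose
    complete the ladder.
    """
    dose = np.asarray(doses, dtype=float)
    viab = np.asarray(viabilities, dtype=float)
    if dose.size < 4:
        raise DegenerateDataError("cytotoxicity screen must span >= 4 doses")
    order = np.argsort(dose)
    dose, viab = dose[order], viab[order]
    cyto = 100.0 - viab
    in_band = (cyto >= 50.0) & (cyto <= 75.0)
    if in_band.any():
        top = float(dose[in_band][0])
    elif cyto.max() < 50.0:
        top = float(max_dose)
    else:
        below = dose[cyto < 50.0]
        if below.size == 0:
            raise DegenerateDataError(
                "cytotoxicity exceeds 75% at the lowest tested dose; "
                "re-screen with a lower dose range"
            )
        top = float(below[-1])
    return [top / 16, top / 8, top / 4, top / 2, top]
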