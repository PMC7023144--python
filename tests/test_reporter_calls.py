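"""Tests for fold-induction computation, viability gating and dose selection."""

import logging

import numpy as np
import pandas as pd
import pytest

from toxscreen.errors import AlignmentError, DegenerateDataError
from toxscreen.reporter_calls import (call_reporter, correct_autofluorescence,
                                      fold_induction, fold_table, select_doses)


def folds_frame(rows):
    return pd.DataFrame(
        rows, columns=["particle", "reporter", "dose_ug_ml", "fold",
                       "viability_pct"]
    )


class TestAutofluorescenceCorrection:
    def test_zero_autofluorescence_is_identity(self):
        assert correct_autofluorescence(500.0, 0.0) == 500.0

    def test_subtraction(self):
        assert correct_autofluorescence(500.0, 120.0) == 380.0

    def test_floor_at_zero_logs_warning(self, caplog):
        with caplog.at_level(logging.WARNING):
            out = correct_autofluorescence(np.array([100.0, 50.0]),
                                           np.array([30.0, 80.0]))
        assert out.tolist() == [70.0, 0.0]
        assert "floored" in caplog.text

    def test_misaligned_series_rejected(self):
        with pytest.raises(AlignmentError):
            correct_autofluorescence(np.ones(3), np.ones(2))


class TestFoldInduction:
    def test_identical_to_control_is_one(self):
        assert fold_induction([200.0, 210.0], [200.0, 210.0]) == 1.0

    def test_ratio_of_means(self):
        assert fold_induction([650.0, 750.0], [200.0]) == pytest.approx(3.5)

    def test_scale_invariance(self):
        a, c = np.array([300.0, 500.0]), np.array([150.0, 250.0])
        assert fold_induction(2 * a, 2 * c) == pytest.approx(
            fold_induction(a, c)
        )

    def test_degenerate_control(self):
        with pytest.raises(DegenerateDataError, match="control"):
            fold_induction([100.0], [0.0])


class TestCallReporter:
    def test_clear_positive_at_viable_doses(self):
        call = call_reporter(folds_frame(
            [("Mn", "Rtkn", d, f, 60.0)
             for d, f in [(6.25, 2.1), (12.5, 3.3), (25.0, 3.5)]]
        ))
        assert call.verdict == "positive"
        assert call.max_valid_fold == pytest.approx(3.5)
        assert call.lowest_positive_dose == 6.25

    def test_induction_only_below_viability_gate_is_not_positive(self):
        """A >2-fold response at <=25 % viability does not count."""
        call = call_reporter(folds_frame(
            [("Sb", "Ddit3", 5.0, 1.2, 80.0),
             ("Sb", "Ddit3", 10.0, 1.4, 50.0),
             ("Sb", "Ddit3", 20.0, 2.5, 20.0)]
        ))
        assert call.verdict == "negative"
        assert call.gated_doses == (20.0,)
        assert call.max_valid_fold == pytest.approx(1.4)

    def test_all_low_folds_negative(self):
        call = call_reporter(folds_frame(
            [("Au", "Btg2", d, f, 95.0) for d, f in [(5, 0.9), (10, 1.0)]]
        ))
        assert call.verdict == "negative"

    @pytest.mark.parametrize(
        "max_fold, verdict",
        [(2.01, "positive"), (2.0, "weak_positive"), (1.6, "weak_positive"),
         (1.5, "negative")],
    )
    def test_band_boundaries(self, max_fold, verdict):
        """Positive strictly above 2; weak band (1.5, 2]; 2.0 is weak."""
        call = call_reporter(folds_frame([("X", "Srxn1", 10.0, max_fold, 80.0)]))
        assert call.verdict == verdict

    def test_everything_gated_is_uninterpretable(self):
        call = call_reporter(folds_frame(
            [("Y", "Srxn1", d, 3.0, 10.0) for d in (5, 10)]
        ))
        assert call.verdict == "uninterpretable"
        assert call.max_valid_fold is None

    def test_gating_never_raises_max_fold(self):
        """Removing gated doses can only lower the usable maximum fold."""
        rows = [("Z", "Srxn1", d, f, v)
                for d, f, v in [(5, 1.2, 90), (10, 1.9, 60), (20, 4.0, 15)]]
        gated = call_reporter(folds_frame(rows))
        ungated = call_reporter(folds_frame(
            [(p, r, d, f, 90.0) for p, r, d, f, _ in rows]
        ))
        assert gated.max_valid_fold <= ungated.max_valid_fold
        assert gated.verdict == "weak_positive"
        assert ungated.verdict == "positive"


class TestFoldTable:
    def test_fold_table_corrects_and_averages(self):
        screen = pd.DataFrame(
            {
                "particle": ["QD"] * 6,
                "reporter": ["Srxn1"] * 6,
                "dose_ug_ml": [0, 0, 5, 5, 10, 10],
                "replicate": [1, 2, 1, 2, 1, 2],
                "viability_pct": [100, 100, 80, 84, 20, 24],
                "gfp_mean": [210, 190, 420, 380, 820, 780],
                "autofluorescence": [0, 0, 20, 20, 40, 40],
            }
        )
        folds = fold_table(screen)
        assert folds.loc[folds["dose_ug_ml"] == 5, "fold"].iloc[0] == pytest.approx(
            (400 - 20) / 200, rel=1e-12
        )
        assert bool(folds.loc[folds["dose_ug_ml"] == 10, "gated_out"].iloc[0])

    def test_missing_control_errors(self):
        screen = pd.DataFrame(
            {"particle": ["A"], "reporter": ["Srxn1"], "dose_ug_ml": [5.0],
             "replicate": [1], "viability_pct": [90.0], "gfp_mean": [100.0]}
        )
        with pytest.raises(DegenerateDataError, match="vehicle-control"):
            fold_table(screen)


class TestSelectDoses:
    def test_dose_in_band_sets_ladder(self):
        doses = [5, 10, 20, 40, 80]
        viab = [95, 85, 70, 40, 15]  # 60 % cytotoxicity at 40
        assert select_doses(doses, viab) == [2.5, 5, 10, 20, 40]

    def test_no_cytotoxicity_caps_at_100(self):
        doses = [12.5, 25, 50, 100]
        assert select_doses(doses, [98, 97, 96, 95]) == [6.25, 12.5, 25, 50, 100]

    def test_band_overshoot_takes_smallest_qualifying_dose(self):
        doses = [2.5, 5, 10, 20]
        viab = [90, 70, 45, 20]  # 55 % cytotoxicity at 10, 80 % at 20
        assert select_doses(doses, viab) == [0.625, 1.25, 2.5, 5, 10]

    def test_too_toxic_everywhere_errors(self):
        with pytest.raises(DegenerateDataError, match="lower dose range"):
            select_doses([5, 10, 20, 40], [10, 8, 5, 2])
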