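"""Behavioural comparison: percent error, band check, closed loop, report."""

import json

import numpy as np
import pandas as pd
import pytest

from dbsim.pipeline import ActivationCurve, DEFAULT_AMP_GRID, activation_curve
from dbsim.report import (
    BehavioralTable,
    acceptance_band_check,
    build_report,
    comparison_table,
    percent_activated_at_behavioral,
    percent_error,
    synthetic_behavioral_table,
)


def curve_from_thresholds(thr, contact=7):
    return activation_curve(np.asarray(thr, float), DEFAULT_AMP_GRID, contact=contact)


class TestPercentError:
    def test_equal_inputs_zero(self):
        assert percent_error(1.0, 1.0) == 0.0

    def test_published_denominator_convention(self):
        # 1.4 mA behavioural vs a 1.5 mA grid prediction: of the plausible
        # normalizations only |e - p| / p reproduces 6.67%
        assert percent_error(1.4, 1.5) == pytest.approx(6.67, abs=0.01)
        assert 100 * abs(1.4 - 1.5) / 1.4 == pytest.approx(7.14, abs=0.01)
        grid = np.round(np.arange(0.1, 3.51, 0.1), 10)
        hits = [p for p in grid if abs(100 * abs(1.4 - p) / p - 6.67) < 0.01]
        assert hits == [1.5]

    def test_scale_invariance(self):
        assert percent_error(1.4, 1.5) == pytest.approx(
            percent_error(2.8, 3.0), rel=1e-12
        )

    def test_sentinel_prediction(self):
        assert np.isnan(percent_error(1.0, float("nan")))

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            percent_error(-1.0, 1.0)


class TestBandCheck:
    def test_inside(self):
        assert acceptance_band_check(7.7) is True

    def test_outside(self):
        assert acceptance_band_check(2.9) is False

    def test_closed_boundaries(self):
        assert acceptance_band_check(5.0) is True
        assert acceptance_band_check(15.0) is True

    def test_vectorized(self):
        out = acceptance_band_check(np.array([4.9, 5.0, 10.0, 15.0, 15.1]))
        assert out.tolist() == [False, True, True, True, False]


class TestBehavioralTable:
    def test_duplicate_contacts_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            BehavioralTable(
                rows=pd.DataFrame(
                    {"contact": [7, 7], "threshold_ma": [1.0, 1.1]}
                )
            )

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            BehavioralTable(
                rows=pd.DataFrame({"contact": [7], "threshold_ma": [0.0]})
            )

    def test_csv_round_trip(self, tmp_path):
        t = BehavioralTable(
            rows=pd.DataFrame(
                {
                    "contact": [7, 6],
                    "frequency_hz": [20.0, 20.0],
                    "threshold_ma": [1.0, 1.1],
                    "side_effect": ["eyelid flutter", "eyelid flutter"],
                }
            )
        )
        p = tmp_path / "behavior.csv"
        t.to_csv(p)
        back = BehavioralTable.from_csv(p)
        pd.testing.assert_frame_equal(back.rows, t.rows)


class TestPercentAtBehavioral:
    def test_reads_curve_at_threshold(self):
        # 1000 axons, 77 with threshold <= 1.0 mA -> 7.7% at 1.0 mA
        thr = np.concatenate([np.full(77, 0.8), np.full(923, 3.0)])
        curves = {7: curve_from_thresholds(thr)}
        table = BehavioralTable(
            rows=pd.DataFrame({"contact": [7], "threshold_ma": [1.0]})
        )
        out = percent_activated_at_behavioral(curves, table)
        assert out["percent_activated"].iloc[0] == pytest.approx(7.7)

    def test_flat_zero_curve(self):
        curves = {4: curve_from_thresholds(np.full(10, np.nan), contact=4)}
        table = BehavioralTable(
            rows=pd.DataFrame({"contact": [4], "threshold_ma": [1.4]})
        )
        out = percent_activated_at_behavioral(curves, table)
        assert out["percent_activated"].iloc[0] == 0.0

    def test_off_grid_snaps_down_with_warning(self):
        thr = np.concatenate([np.full(10, 1.0), np.full(10, 2.0)])
        curves = {5: curve_from_thresholds(thr, contact=5)}
        table = BehavioralTable(
            rows=pd.DataFrame({"contact": [5], "threshold_ma": [1.234]})
        )
        with pytest.warns(UserWarning, match="off-grid"):
            out = percent_activated_at_behavioral(curves, table)
        assert out["percent_activated"].iloc[0] == pytest.approx(50.0)

    def test_matches_direct_threshold_recount(self):
        rng = np.random.default_rng(8)
        thr = rng.uniform(0.05, 4.0, 200)
        curves = {6: curve_from_thresholds(thr, contact=6)}
        table = BehavioralTable(
            rows=pd.DataFrame({"contact": [6], "threshold_ma": [1.1]})
        )
        out = percent_activated_at_behavioral(curves, table)
        direct = 100.0 * (thr <= 1.1).mean()
        assert out["percent_activated"].iloc[0] == pytest.approx(direct)


class TestClosedLoop:
    def test_synthetic_table_recovers_zero_error(self):
        rng = np.random.default_rng(21)
        curves = {
            c: curve_from_thresholds(rng.uniform(0.1, 3.0, 500), contact=c)
            for c in (4, 5, 6, 7)
        }
        table = synthetic_behavioral_table(curves, target_percent=5.0)
        comp = comparison_table(curves, table, target_percent=5.0)
        assert np.allclose(comp["percent_error"], 0.0)
        assert (comp["behavioral_ma"] == comp["predicted_ma"]).all()


class TestBuildReport:
    def make_results(self):
        rng = np.random.default_rng(2)
        curves = {
            "ON-like": {
                c: curve_from_thresholds(rng.uniform(0.1, 3.0, 100), contact=c)
                for c in (5, 7)
            }
        }
        table = synthetic_behavioral_table(curves["ON-like"])
        comp = comparison_table(curves["ON-like"], table)
        sweep = pd.concat(
            [
                cv.to_frame().assign(tract="ON-like", sweep="s", sweep_value="0.844")
                for cv in curves["ON-like"].values()
            ],
            ignore_index=True,
        )
        return {
            "curves": curves,
            "sweep": sweep,
            "iso_aniso": {"ON-like": {"anisotropic": curves["ON-like"][5],
                                      "isotropic": curves["ON-like"][7]}},
            "behavioral": table,
            "comparison": comp,
        }

    def test_complete_report_has_all_sections(self, tmp_path):
        text, payload = build_report(self.make_results(), out_dir=tmp_path)
        assert payload["missing"] == []
        for section in ("curves", "sweep", "iso_aniso", "behavioral", "comparison"):
            assert section in payload["sections"]
        assert (tmp_path / "report.md").exists()

    def test_json_round_trips(self, tmp_path):
        _, payload = build_report(self.make_results(), out_dir=tmp_path)
        with open(tmp_path / "report.json") as fh:
            back = json.load(fh)
        assert back == json.loads(json.dumps(payload, default=float))

    def test_report_totals_match_sweep_csv(self, tmp_path):
        results = self.make_results()
        _, payload = build_report(results, out_dir=tmp_path)
        sweep_csv = pd.read_csv(tmp_path / "sweep.csv")
        assert len(sweep_csv) == len(results["sweep"])
        max_from_csv = (
            sweep_csv.groupby("contact")["percent_activated"].max().to_dict()
        )
        for rec in payload["sweep_summary"]:
            assert rec["percent_activated"] == pytest.approx(
                max_from_csv[rec["contact"]]
            )

    def test_partial_report_lists_missing(self):
        text, payload = build_report({"curves": self.make_results()["curves"]})
        assert "sweep" in payload["missing"]
        assert "Missing sections" in text
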