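"""LC-MS calibration, LOD/LOQ, recovery correction, and quantification."""

import numpy as np
import pandas as pd
import pytest

from b1cycle import synth, vitquant


def cal_rows(levels, areas, compound="B1", batch="b1"):
    return pd.DataFrame(
        {
            "sample_id": [f"cal_{l}" for l in levels],
            "compound": compound,
            "replicate_injection": 1,
            "batch": batch,
            "row_type": "calibration",
            "level_pM": levels,
            "peak_area": areas,
            "is_area": np.nan,
        }
    )


def blank_rows(areas, compound="B1"):
    return pd.DataFrame(
        {
            "sample_id": [f"blank_{i}" for i in range(len(areas))],
            "compound": compound,
            "replicate_injection": 1,
            "batch": "b1",
            "row_type": "blank",
            "level_pM": 0.0,
            "peak_area": areas,
            "is_area": np.nan,
        }
    )


def sample_rows(conc_areas, compound="B1", is_area=np.nan):
    rows = []
    for sid, areas in conc_areas.items():
        for inj, a in enumerate(areas, start=1):
            rows.append(
                {"sample_id": sid, "compound": compound, "replicate_injection": inj,
                 "batch": "b1", "row_type": "sample", "level_pM": np.nan,
                 "peak_area": a, "is_area": is_area}
            )
    return pd.DataFrame(rows)


class TestCalibration:
    def test_exact_line(self):
        tbl = cal_rows([5.0, 10.0, 25.0], [10.0, 20.0, 50.0])
        model = vitquant.fit_calibration(tbl, "B1")
        assert model.slope == pytest.approx(2.0)
        assert model.intercept == pytest.approx(0.0, abs=1e-9)
        assert model.r_squared == pytest.approx(1.0)

    def test_noisy_matches_normal_equations(self, rng):
        levels = np.array([1.0, 5.0, 10.0, 25.0, 50.0])
        areas = 3.0 * levels + 7.0 + rng.normal(0, 2.0, size=5)
        model = vitquant.fit_calibration(cal_rows(levels, areas), "B1")
        slope_oracle, intercept_oracle = np.polyfit(levels, areas, 1)
        assert model.slope == pytest.approx(slope_oracle)
        assert model.intercept == pytest.approx(intercept_oracle)

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError, match="3 distinct levels"):
            vitquant.fit_calibration(cal_rows([5.0, 10.0], [10.0, 20.0]), "B1")

    def test_nonpositive_slope_rejected(self):
        tbl = cal_rows([5.0, 10.0, 25.0], [50.0, 20.0, 10.0])
        with pytest.raises(ValueError, match="slope"):
            vitquant.fit_calibration(tbl, "B1")


class TestLodLoq:
    def test_three_ten_rule(self, rng):
        areas = rng.normal(100, 1.0, size=20)
        ll = vitquant.compute_lod_loq(blank_rows(areas), "B1")
        sd = float(np.std(areas, ddof=1))
        assert ll.lod_area == pytest.approx(3.0 * sd)
        assert ll.loq_area == pytest.approx(10.0 * sd)
        assert ll.lod_area <= ll.loq_area

    def test_identical_blanks_zero_limits(self):
        ll = vitquant.compute_lod_loq(blank_rows([5.0] * 4), "B1")
        assert ll.lod_area == 0.0 and ll.loq_area == 0.0

    def test_qc_variation_mode(self, rng):
        tbl = blank_rows(rng.normal(0, 10, size=5))
        tbl.loc[:, "row_type"] = "qc"
        ll = vitquant.compute_lod_loq(tbl, "B1", mode="qc_variation")
        assert ll.mode == "qc_variation"
        assert ll.sd == pytest.approx(float(tbl["peak_area"].std(ddof=1)))

    def test_too_few_rows(self):
        with pytest.raises(ValueError, match=">=3"):
            vitquant.compute_lod_loq(blank_rows([1.0, 2.0]), "B1")

    def test_pm_conversion_via_slope(self):
        cal = vitquant.fit_calibration(cal_rows([5.0, 10.0, 25.0], [10.0, 20.0, 50.0]), "B1")
        ll = vitquant.compute_lod_loq(blank_rows([0.0, 2.0, 4.0]), "B1", calibration=cal)
        assert ll.lod_pm == pytest.approx(ll.lod_area / 2.0)


class TestRecovery:
    def test_division(self):
        rows = sample_rows({"s1": [10.0, 10.0]}, is_area=50_000.0)
        rec = vitquant.recovery_correct(rows, is_expected_area=100_000.0)
        assert rec.loc["s1", "recovery"] == pytest.approx(0.5)

    def test_out_of_range_flagged(self):
        rows = sample_rows({"s1": [10.0, 10.0]}, is_area=200_000.0)
        rec = vitquant.recovery_correct(rows, is_expected_area=100_000.0)
        assert rec.loc["s1", "recovery_flag"] == "excluded"

    def test_simulated_recovery_024_recovered(self):
        conc = pd.DataFrame(
            {f"s{i}": [100.0] for i in range(12)}, index=["B1"]
        )
        tbl, truth = synth.simulate_ms_dataset(
            conc, recovery=0.24, noise_cv=0.05, seed=8
        )
        rows = tbl[(tbl.row_type == "sample") & (tbl.compound == "B1")]
        rec = vitquant.recovery_correct(rows, truth["is_expected_area"])
        assert rec["recovery"].mean() == pytest.approx(0.24, rel=0.05)


class TestQuantify:
    def setup_method(self):
        self.cal = vitquant.fit_calibration(
            cal_rows([10.0, 50.0, 100.0, 200.0], [10.0, 50.0, 100.0, 200.0]), "B1"
        )  # slope 1, intercept 0: area == pM
        self.ll = vitquant.LodLoq("B1", lod_area=20.0, loq_area=50.0, sd=2.0, n=5, mode="blanks")

    def test_mean_of_two_injections(self):
        tbl = sample_rows({"s1": [100.0, 110.0]})
        out = vitquant.quantify(tbl, "B1", self.cal, self.ll)
        assert out.loc[0, "concentration_pM"] == pytest.approx(105.0)
        assert out.loc[0, "flag"] == "ok"

    def test_one_injection_below_lod_rejects(self):
        tbl = sample_rows({"s1": [100.0, 15.0]})
        out = vitquant.quantify(tbl, "B1", self.cal, self.ll)
        assert out.loc[0, "flag"] == "below_LOD"
        assert np.isnan(out.loc[0, "concentration_pM"])

    def test_between_lod_and_loq_needs_review(self):
        tbl = sample_rows({"s1": [30.0, 40.0]})
        unreviewed = vitquant.quantify(tbl, "B1", self.cal, self.ll)
        assert unreviewed.loc[0, "flag"] == "LOD_to_LOQ"
        assert np.isnan(unreviewed.loc[0, "concentration_pM"])
        accepted = vitquant.quantify(tbl, "B1", self.cal, self.ll, review={"s1": "accept"})
        assert accepted.loc[0, "concentration_pM"] == pytest.approx(35.0)
        assert accepted.loc[0, "flag"] == "LOD_to_LOQ"

    def test_single_injection_rejected(self):
        tbl = sample_rows({"s1": [100.0]})
        out = vitquant.quantify(tbl, "B1", self.cal, self.ll)
        assert out.loc[0, "flag"] == "single_injection_reject"

    def test_three_injections_error(self):
        tbl = sample_rows({"s1": [100.0, 100.0, 100.0]})
        with pytest.raises(ValueError, match="3 injections"):
            vitquant.quantify(tbl, "B1", self.cal, self.ll)

    def test_outlier_exclusion(self):
        tbl = sample_rows({"s1": [100.0, 110.0]})
        out = vitquant.quantify(tbl, "B1", self.cal, self.ll, exclusions={"s1"})
        assert out.loc[0, "flag"] == "outlier_removed"

    def test_recovery_division(self):
        tbl = sample_rows({"s1": [100.0, 100.0]})
        out = vitquant.quantify(tbl, "B1", self.cal, self.ll, recovery=0.5)
        assert out.loc[0, "concentration_pM"] == pytest.approx(200.0)

    def test_flags_partition(self, rng):
        tbl = sample_rows(
            {f"s{i}": list(rng.uniform(0, 200, size=2)) for i in range(20)}
        )
        out = vitquant.quantify(tbl, "B1", self.cal, self.ll)
        assert out["flag"].isin(vitquant.FLAGS).all()
        assert len(out) == 20


class TestPoolSummaries:
    def records(self, entries):
        return pd.DataFrame(
            [{"sample_id": s, "compound": c, "concentration_pM": v, "flag": f}
             for s, c, v, f in entries]
        )

    def test_addition(self):
        recs = self.records(
            [("s1", "B1", 10.0, "ok"), ("s1", "HET", 20.0, "ok"),
             ("s1", "HMP", 30.0, "ok"), ("s1", "FAMP", 40.0, "ok")]
        )
        out = vitquant.pool_summaries(recs)
        assert out.loc[0, "combined_pM"] == pytest.approx(100.0)

    def test_below_lod_contributes_zero_and_is_counted(self):
        recs = self.records(
            [("s1", "B1", 10.0, "ok"), ("s1", "HET", np.nan, "below_LOD")]
        )
        out = vitquant.pool_summaries(recs)
        assert out.loc[0, "combined_pM"] == pytest.approx(10.0)
        assert out.loc[0, "n_missing"] == 1

    def test_group_sum_oracle(self, rng):
        entries = []
        for s in range(5):
            for c in ("B1", "HET", "HMP", "FAMP"):
                entries.append((f"s{s}", c, float(rng.uniform(1, 50)), "ok"))
        recs = self.records(entries)
        out = vitquant.pool_summaries(recs).set_index("sample_id")
        oracle = recs.groupby("sample_id")["concentration_pM"].sum()
        for s in oracle.index:
            assert out.loc[s, "combined_pM"] == pytest.approx(oracle[s])

    def test_poc_normalization_and_missing_poc(self):
        recs = self.records([("s1", "B1", 10.0, "ok")])
        poc = pd.Series({"s1": 5.0})
        out = vitquant.pool_summaries(recs, poc=poc)
        assert out.loc[0, "combined_per_poc"] == pytest.approx(2.0)
        with pytest.raises(ValueError, match="POC"):
            vitquant.pool_summaries(recs, poc=pd.Series(dtype=float))


class TestRoundTrip:
    def test_noiseless_batch_returns_truth_exactly(self):
        conc = pd.DataFrame(
            {"s1": [100.0, 12.0], "s2": [80.0, 30.0]}, index=["B1", "HMP"]
        )
        tbl, truth = synth.simulate_ms_dataset(
            conc, recovery=1.0, noise_cv=0.0, blank_sd=0.0, seed=0
        )
        for compound in ("B1", "HMP"):
            cal = vitquant.fit_calibration(tbl, compound)
            ll = vitquant.compute_lod_loq(tbl, compound, calibration=cal)
            out = vitquant.quantify(tbl, compound, cal, ll).set_index("sample_id")
            for s in conc.columns:
                assert out.loc[s, "concentration_pM"] == pytest.approx(
                    conc.loc[compound, s], rel=1e-9
                )

    def test_recovery_and_calibration_commute_noiseless(self):
        conc = pd.DataFrame({"s1": [50.0]}, index=["B1"])
        tbl, truth = synth.simulate_ms_dataset(
            conc, recovery=0.4, noise_cv=0.0, blank_sd=0.0, seed=0
        )
        cal = vitquant.fit_calibration(tbl, "B1")
        ll = vitquant.compute_lod_loq(tbl, "B1", calibration=cal)
        rows = tbl[(tbl.row_type == "sample") & (tbl.compound == "B1")]
        rec = vitquant.recovery_correct(rows, truth["is_expected_area"])
        # correct-then-calibrate equals calibrate-then-correct
        a = vitquant.quantify(tbl, "B1", cal, ll, recovery=rec["recovery"])
        corrected_tbl = tbl.copy()
        mask = (corrected_tbl.row_type == "sample") & (corrected_tbl.compound == "B1")
        corrected_tbl.loc[mask, "peak_area"] /= 0.4
        b = vitquant.quantify(corrected_tbl, "B1", cal, ll)
        assert a.loc[0, "concentration_pM"] == pytest.approx(b.loc[0, "concentration_pM"])
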