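"""ICH M10-style validation statistics and their inclusive acceptance bands."""

import numpy as np
import pandas as pd
import pytest

from redquant import (
    accuracy,
    carryover_assess,
    intra_inter_run,
    matrix_effect,
    precision_cv,
    recovery,
    reinjection_compare,
    round_half_up,
    selectivity_assess,
    stability_assess,
)
from redquant.validation import qc_stat

ANALYTE = "ropivacaine"
IS_NAME = "d7-ropivacaine"


class TestAccuracyPrecision:
    @pytest.mark.parametrize(
        "mean,nominal,expected",
        [
            (305.82, 300.0, 101.9),   # MQC inter-run
            (821.76, 750.0, 109.6),   # matrix-effect HQC 1:4
            (748.79, 750.0, 99.8),    # HQC inter-run
            (802.56, 750.0, 107.0),   # freeze/thaw HQC
            (100.0, 100.0, 100.0),
        ],
    )
    def test_accuracy_percent_of_nominal(self, mean, nominal, expected):
        assert accuracy(mean, nominal) == pytest.approx(expected, abs=0.05)

    def test_accuracy_rejects_nonpositive_nominal(self):
        with pytest.raises(ValueError):
            accuracy(1.0, 0.0)

    @pytest.mark.parametrize(
        "values,expected",
        [([5.0, 5.0, 5.0], 0.0), ([1, 2, 3], 50.0), ([10, 10, 10, 12], 9.52)],
    )
    def test_cv_with_sample_sd(self, values, expected):
        assert precision_cv(values) == pytest.approx(expected, abs=0.005)

    def test_cv_needs_two_values(self):
        with pytest.raises(ValueError):
            precision_cv([1.0])

    def test_rounding_is_half_up(self):
        assert round_half_up(94.695) == 94.70
        assert round_half_up(1.005) == 1.01
        assert round_half_up(-1.005) == -1.01


def _qc_table(level, nominal, runs):
    rows = []
    for day, values in runs.items():
        for v in values:
            rows.append({"level_name": level, "nominal_ng_ml": nominal,
                         "run_day": day, "measured_ng_ml": v})
    return pd.DataFrame(rows)


class TestIntraInterRun:
    def test_perfect_run_passes_with_zero_cv(self):
        table = _qc_table("MQC", 300.0, {1: [300.0] * 6})
        stats = intra_inter_run(table)
        assert all(s.passed for s in stats)
        inter = next(s for s in stats if s.scope == "inter-run")
        assert inter.accuracy_pct == 100.0 and inter.cv_pct == 0.0

    def test_inter_run_pools_all_replicates(self):
        table = _qc_table("HQC", 750.0, {1: [700.0] * 6, 2: [750.0] * 6,
                                         3: [800.0] * 6})
        inter = next(s for s in intra_inter_run(table) if s.scope == "inter-run")
        assert inter.n == 18
        assert inter.mean == pytest.approx(750.0)

    def test_lloq_band_is_wider(self):
        """118% accuracy passes at the LLOQ but the same bias fails at LQC."""
        lloq = _qc_table("LLOQ", 1.0, {1: [1.18] * 6})
        lqc = _qc_table("LQC", 1.0, {1: [1.18] * 6})
        assert next(s for s in intra_inter_run(lloq)).accuracy_pass
        assert not next(s for s in intra_inter_run(lqc)).accuracy_pass

    def test_band_edges_inclusive(self):
        exact = _qc_table("MQC", 100.0, {1: [115.0] * 6})
        assert next(s for s in intra_inter_run(exact)).accuracy_pass

    def test_missing_level_reported_absent(self):
        table = _qc_table("MQC", 300.0, {1: [300.0] * 6})
        stats = intra_inter_run(table, expected_levels=["MQC", "HQC"])
        absent = [s for s in stats if s.scope == "absent"]
        assert len(absent) == 1 and absent[0].level_name == "HQC" and not absent[0].passed


class TestMatrixEffect:
    def _lot_table(self, factors):
        rows = []
        for lot, f in factors.items():
            for rep in range(3):
                rows.append({"lot": lot, "level_name": "LQC",
                             "nominal_ng_ml": 1.0, "measured_ng_ml": f})
        return pd.DataFrame(rows)

    def test_unbiased_lots_all_pass(self):
        stats, warns = matrix_effect(self._lot_table(
            {f"lot{i}": 1.0 for i in range(1, 7)}))
        assert all(s.passed for s in stats) and not warns

    def test_biased_lot_fails_accuracy(self):
        factors = {f"lot{i}": 1.0 for i in range(1, 6)}
        factors["lot6"] = 1.25
        stats, _ = matrix_effect(self._lot_table(factors))
        by_lot = {s.scope: s for s in stats}
        assert not by_lot["lot6"].accuracy_pass
        assert all(by_lot[f"lot{i}"].passed for i in range(1, 6))

    def test_too_few_lots_warns_but_computes(self):
        stats, warns = matrix_effect(self._lot_table({"lot1": 1.0, "lot2": 1.0}))
        assert len(stats) == 2 and any("lots" in w for w in warns)


def _peak_rows(sample_ids, analyte_area, is_area):
    rows = []
    for sid in sample_ids:
        rows.append({"sample_id": sid, "analyte": ANALYTE, "role": "quantifier",
                     "area": analyte_area})
        rows.append({"sample_id": sid, "analyte": IS_NAME, "role": "quantifier",
                     "area": is_area})
    return pd.DataFrame(rows)


class TestCarryover:
    def test_clean_blank_passes(self):
        res = carryover_assess(_peak_rows(["b"], 0.0, 0.0),
                               _peak_rows(["l1", "l2"], 1000.0, 90000.0))
        assert res.passed

    def test_blank_above_20_percent_fails_analyte(self):
        res = carryover_assess(_peak_rows(["b"], 250.0, 0.0),
                               _peak_rows(["l"], 1000.0, 90000.0))
        assert res.analyte_flag and not res.passed

    def test_exactly_20_percent_is_inclusive_pass(self):
        res = carryover_assess(_peak_rows(["b"], 200.0, 0.0),
                               _peak_rows(["l"], 1000.0, 90000.0))
        assert not res.analyte_flag

    def test_is_channel_has_5_percent_limit(self):
        res = carryover_assess(_peak_rows(["b"], 0.0, 5000.0),
                               _peak_rows(["l"], 1000.0, 90000.0))
        assert res.is_flag and not res.passed

    def test_missing_blank_is_explicit_failure(self):
        with pytest.raises(ValueError, match="blank"):
            carryover_assess(pd.DataFrame(columns=["analyte", "role", "area"]),
                             _peak_rows(["l"], 1000.0, 90000.0))


class TestStability:
    def _table(self, cond, values, nominal=750.0):
        return pd.DataFrame(
            {"condition": cond, "level_name": "HQC", "nominal_ng_ml": nominal,
             "measured_ng_ml": values}
        )

    def test_freeze_thaw_reported_row(self):
        """Mean 802.56 vs nominal 750 is 107.0% and passes +/-15%."""
        stats = stability_assess(self._table("freeze_thaw",
                                             [802.56, 802.56, 802.56]))
        assert stats[0].accuracy_pct == pytest.approx(107.0, abs=0.05)
        assert stats[0].passed

    def test_20_percent_degradation_fails(self):
        stats = stability_assess(self._table("benchtop", [600.0, 600.0, 600.0]))
        assert stats[0].accuracy_pct == pytest.approx(80.0)
        assert not stats[0].passed

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            stability_assess(self._table("microwave", [750.0] * 3))


class TestReinjection:
    def _stats(self, means):
        return [qc_stat([m, m, m + 0.001], nominal, level, scope)
                for (level, nominal, scope), m in means.items()]

    def test_identical_runs_give_zero_differences(self):
        first = self._stats({("MQC", 300.0, "intra-run 1"): 300.0})
        reinj = self._stats({("MQC", 300.0, "reinjection"): 300.0})
        table = reinjection_compare(first, reinj)
        assert table["accuracy_diff_pct"].abs().max() < 1e-9
        assert table["reinjection_vs_first_pct"].iloc[0] == pytest.approx(100.0)

    def test_reports_both_reference_bases(self):
        first = self._stats({("MQC", 300.0, "intra-run 1"): 320.0})
        reinj = self._stats({("MQC", 300.0, "reinjection"): 304.0})
        row = reinjection_compare(first, reinj).iloc[0]
        assert row.first_accuracy_pct == pytest.approx(106.67, abs=0.01)
        assert row.reinjection_vs_first_pct == pytest.approx(95.0, abs=0.01)

    def test_level_mismatch_is_explicit_failure(self):
        first = self._stats({("MQC", 300.0, "intra-run 1"): 300.0})
        reinj = self._stats({("HQC", 750.0, "reinjection"): 750.0})
        with pytest.raises(ValueError, match="mismatch"):
            reinjection_compare(first, reinj)


class TestRecovery:
    def _areas(self, analyte_area, is_area, n=5, prefix="r"):
        return _peak_rows([f"{prefix}{i}" for i in range(n)], analyte_area, is_area)

    def test_identical_approaches_give_100(self):
        a = self._areas(120.0, 100.0)
        res = recovery(a, a.copy(), a.copy(), spike_level=10.0)
        assert res.precipitation_pct[ANALYTE] == pytest.approx(100.0)
        assert res.overall_pct[IS_NAME] == pytest.approx(100.0)
        assert res.ratio_overall_pct == pytest.approx(100.0)
        assert res.passed

    def test_precipitation_recovery_is_mean_ratio(self):
        res = recovery(self._areas(120.0, 100.0), self._areas(100.0, 100.0),
                       self._areas(110.0, 100.0), spike_level=10.0)
        assert res.precipitation_pct[ANALYTE] == pytest.approx(120.0)

    def test_is_within_15_points_of_analyte_passes(self):
        """Overall recoveries 99.7% vs 103.5% differ by <= 15 points: pass."""
        res = recovery(self._areas(99.7, 103.5), self._areas(100.0, 100.0),
                       self._areas(100.0, 100.0), spike_level=2000.0)
        assert res.overall_pct[ANALYTE] == pytest.approx(99.7)
        assert res.overall_pct[IS_NAME] == pytest.approx(103.5)
        assert res.passed

    def test_divergent_is_recovery_fails(self):
        res = recovery(self._areas(100.0, 130.0), self._areas(100.0, 100.0),
                       self._areas(100.0, 100.0), spike_level=10.0)
        assert not res.passed

    def test_zero_denominator_is_failure(self):
        with pytest.raises(ValueError):
            recovery(self._areas(100.0, 100.0), self._areas(0.0, 100.0),
                     self._areas(100.0, 100.0), spike_level=10.0)


class TestSelectivity:
    def _blanks(self, lot_areas):
        rows = []
        for lot, (a, i) in lot_areas.items():
            for name, area in ((ANALYTE, a), (IS_NAME, i)):
                rows.append({"sample_id": f"b-{lot}", "lot": lot, "analyte": name,
                             "role": "quantifier", "area": area})
        return pd.DataFrame(rows)

    def test_zero_blank_signal_passes(self):
        table = selectivity_assess(
            self._blanks({f"lot{i}": (0.0, 0.0) for i in range(1, 7)}),
            lloq_analyte_response=1000.0, lloq_is_response=90000.0)
        assert table["passed"].all()
        assert table.attrs["n_lots_ok"]

    def test_exactly_20_percent_is_inclusive(self):
        table = selectivity_assess(self._blanks({"lot1": (200.0, 0.0)}),
                                   1000.0, 90000.0, min_lots=1)
        assert bool(table["passed"].iloc[0])

    def test_21_percent_fails(self):
        table = selectivity_assess(self._blanks({"lot1": (210.0, 0.0)}),
                                   1000.0, 90000.0, min_lots=1)
        assert not bool(table["passed"].iloc[0])
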