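"""Synthetic-data generator: prep chain, peak areas, PK profiles, seeding."""

import numpy as np
import pandas as pd
import pytest

from redquant import (
    REDGeometry,
    ResponseModel,
    StudyDesign,
    generate_study,
    simulate_peak_areas,
    simulate_pk_profile,
    simulate_prep,
)

ANALYTE = "ropivacaine"
IS_NAME = "d7-ropivacaine"


def _manifest(n, dilution="1:1"):
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "dilution_label": dilution,
            "injection_index": range(n),
        }
    )


class TestPrep:
    def test_buffer_prep_factor(self, geometry):
        assert simulate_prep(9.09, "buffer", geometry) == pytest.approx(1.0)

    def test_zero_in_zero_out(self, geometry):
        assert simulate_prep(0.0, "plasma", geometry) == 0.0

    def test_unknown_compartment_rejected(self, geometry):
        with pytest.raises(ValueError):
            simulate_prep(1.0, "csf", geometry)


class TestPeakAreas:
    def test_noiseless_ratio_proportional_to_concentration(self, quiet_response, geometry):
        concs = np.array([0.5, 1.0, 2.0, 8.0])
        peaks = simulate_peak_areas(_manifest(4), concs, quiet_response, seed=0,
                                    geometry=geometry)
        quant = peaks[peaks["role"] == "quantifier"].pivot(
            index="sample_id", columns="analyte", values="area"
        )
        ratio = (quant[ANALYTE] / quant[IS_NAME]).reindex([f"s{i}" for i in range(4)])
        assert np.allclose(ratio / ratio.iloc[0], concs / concs[0], rtol=1e-12)

    def test_fixed_seed_is_bit_identical(self, response, geometry):
        concs = np.linspace(0.1, 10, 5)
        a = simulate_peak_areas(_manifest(5), concs, response, seed=42, geometry=geometry)
        b = simulate_peak_areas(_manifest(5), concs, response, seed=42, geometry=geometry)
        pd.testing.assert_frame_equal(a, b)
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_carryover_blank_after_uloq(self, geometry):
        """1% carry-over leaves a blank at 1% of the preceding ULOQ area."""
        resp = ResponseModel(sigma_prop=0.0, sigma_add=0.0, carryover_frac=0.01)
        manifest = _manifest(2)
        peaks = simulate_peak_areas(manifest, np.array([110.0, 0.0]), resp, seed=0,
                                    geometry=geometry)
        quant = peaks[(peaks["analyte"] == ANALYTE) & (peaks["role"] == "quantifier")]
        uloq_area = float(quant[quant["sample_id"] == "s0"]["area"].iloc[0])
        blank_area = float(quant[quant["sample_id"] == "s1"]["area"].iloc[0])
        assert blank_area == pytest.approx(0.01 * uloq_area, rel=1e-12)

    def test_lot_factor_biases_analyte_channel_only(self, geometry):
        resp = ResponseModel(sigma_prop=0.0, sigma_add=0.0,
                             lot_effects={"lotX": 1.25})
        manifest = _manifest(2)
        manifest["lot"] = ["", "lotX"]
        peaks = simulate_peak_areas(manifest, np.array([1.0, 1.0]), resp, seed=0,
                                    geometry=geometry)
        quant = peaks[peaks["role"] == "quantifier"].pivot(
            index="sample_id", columns="analyte", values="area"
        )
        assert quant[ANALYTE]["s1"] / quant[ANALYTE]["s0"] == pytest.approx(1.25)
        assert quant[IS_NAME]["s1"] == pytest.approx(quant[IS_NAME]["s0"])

    def test_carryover_bounds_enforced(self):
        with pytest.raises(ValueError):
            ResponseModel(carryover_frac=0.2)


class TestPKProfile:
    def test_predose_time_is_zero(self, design):
        prof = simulate_pk_profile(1.0, design, seed=3)
        assert (prof.loc[prof["time_min"] <= 0, "total_ng_ml"] == 0).all()
        assert (prof["total_ng_ml"] >= 0).all()

    def test_zero_variability_gives_identical_animals(self, design):
        prof = simulate_pk_profile(1.0, design, seed=3, cv_lognormal=0.0)
        per_animal = prof.pivot(index="time_min", columns="animal",
                                values="total_ng_ml")
        assert per_animal.nunique(axis=1).max() == 1

    def test_dose_linearity(self, design):
        """A 3:1 dose ratio triples every noiseless concentration."""
        low = simulate_pk_profile(1.0, design, seed=0, cv_lognormal=0.0)
        high = simulate_pk_profile(3.0, design, seed=0, cv_lognormal=0.0)
        post = low["time_min"] > 0
        assert np.allclose(
            high.loc[post, "total_ng_ml"], 3.0 * low.loc[post, "total_ng_ml"]
        )


class TestStudyBundle:
    def test_seed_contract_identical_csv_bytes(self):
        a = generate_study(seed=11)
        b = generate_study(seed=11)
        for x, y in ((a.manifest, b.manifest), (a.peaks, b.peaks), (a.truth, b.truth)):
            assert x.to_csv(index=False) == y.to_csv(index=False)

    def test_blank_immediately_follows_uloq_standard(self, design):
        bundle = generate_study(design=design, seed=0, components=("qc_runs",))
        run = bundle.manifest[bundle.manifest["batch_id"] == "run1-11"]
        run = run.sort_values("injection_index").reset_index(drop=True)
        blank_pos = run.index[run["sample_type"] == "blank"][0]
        prev = run.iloc[blank_pos - 1]
        assert prev["sample_type"] == "calibration"
        assert prev["nominal_ng_ml"] == design.calibration_levels_1to1[-1]

    def test_truth_conserves_mass_per_specimen(self, geometry):
        bundle = generate_study(seed=5, components=("workflow",))
        t = bundle.truth
        amount = (
            t["chamber_plasma_ng_ml"] * geometry.v_plasma
            + t["chamber_buffer_ng_ml"] * geometry.v_buffer
        )
        assert np.allclose(amount, t["true_total_ng_ml"] * geometry.v_plasma,
                           rtol=1e-9)

    def test_stability_degradation_scales_condition(self):
        deg = {"benchtop": 0.8}
        bundle = generate_study(
            seed=1, components=("qc_runs", "stability"), stability_degradation=deg
        )
        # degraded benchtop samples must carry ~80% of the T0 analyte signal
        man = bundle.manifest
        stab = man[(man["sample_type"] == "stability_qc")
                   & (man["dilution_label"] == "1:1")
                   & (man["level_name"] == "HQC")]
        peaks = bundle.peaks
        quant = peaks[(peaks["analyte"] == "ropivacaine")
                      & (peaks["role"] == "quantifier")]
        areas = stab.merge(quant, on="sample_id")
        t0 = areas[areas["condition"] == "T0"]["area"].mean()
        bench = areas[areas["condition"] == "benchtop"]["area"].mean()
        assert bench / t0 == pytest.approx(0.8, rel=0.1)

    def test_design_validators(self):
        with pytest.raises(ValueError):
            StudyDesign(sampling_times=[0, 5, 5])
        with pytest.raises(ValueError):
            StudyDesign(calibration_levels_1to1=[10, 1])
        with pytest.raises(ValueError):
            StudyDesign(qc_levels={"1:1": {"HQC": 5000.0}})
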