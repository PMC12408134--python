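"""Synthetic-data building blocks: instrument response, study design, simulators.

The generator emulates spiked dog plasma pushed through the RED / protein-
precipitation / LC-MS/MS workflow this package quantifies:

* binding equilibrium across the dialysis membrane (:mod:`redquant.binding`),
* the deterministic prep volume chain (:mod:`redquant.geometry`),
* a linear instrument response per MRM channel with proportional noise that
  is partly shared between analyte and internal standard (so the response
  ratio cancels part of it, as an isotope-labelled IS does in practice),
  additive baseline noise, per-matrix-lot recovery factors, and first-order
  injection carry-over,
* two-dose one-compartment pharmacokinetic time courses.

Peak areas are the atomic unit; no chromatograms are synthesised.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator
from scipy.signal import lfilter

from .geometry import REDGeometry, dilution_chain

__all__ = [
    "ResponseModel",
    "StudyDesign",
    "simulate_prep",
    "injected_concentration",
    "simulate_peak_areas",
    "simulate_pk_profile",
]

ANALYTE = "ropivacaine"
IS_NAME = "d7-ropivacaine"


class ResponseModel(BaseModel):
    """Linear MRM response with noise, matrix-lot and carry-over structure.

    ``sigma_prop`` is the total per-channel proportional noise SD; a fraction
    ``prop_shared_frac`` of its *variance* is shared between the analyte and
    IS channels of one injection, so the area ratio retains roughly
    ``sigma_prop * sqrt(2 * (1 - prop_shared_frac))`` relative noise.
    ``sigma_add`` is additive baseline noise in area units (default about
    0.5% of the analyte area at the 0.05 ng/mL buffer-curve LLOQ).
    ``lot_effects`` multiply the analyte channel only — a differential matrix
    effect the IS does not fully track.  ``carryover_frac`` of each channel's
    area bleeds into the next injection.
    """

    sensitivity_analyte: float = 6.54689e5  # area per ng/mL injected
    sensitivity_is: float = 1.0e5
    sigma_prop: float = 0.03
    sigma_add: float = 18.0
    prop_shared_frac: float = 0.5
    lot_effects: dict[str, float] = Field(default_factory=dict)
    carryover_frac: float = 0.0
    qualifier_frac_analyte: float = 0.35
    qualifier_frac_is: float = 0.30
    is_working_conc: float = 100.0  # ng/mL IS working solution added via v_is
    precip_recovery_analyte: float = 1.0
    precip_recovery_is: float = 1.0

    @field_validator("sensitivity_analyte", "sensitivity_is")
    @classmethod
    def _pos_sens(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("sensitivities must be > 0")
        return v

    @field_validator("carryover_frac")
    @classmethod
    def _carry(cls, v: float) -> float:
        if not (0.0 <= v <= 0.05):
            raise ValueError("carryover_frac must be in [0, 0.05]")
        return v

    @field_validator("lot_effects")
    @classmethod
    def _lots(cls, v: dict[str, float]) -> dict[str, float]:
        if any(f <= 0 for f in v.values()):
            raise ValueError("lot factors must be > 0")
        return v

    @model_validator(mode="after")
    def _nonneg(self) -> "ResponseModel":
        for name in ("sigma_prop", "sigma_add"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.prop_shared_frac <= 1.0):
            raise ValueError("prop_shared_frac must be in [0, 1]")
        return self

    def lot_factor(self, lot: str) -> float:
        return self.lot_effects.get(lot, 1.0)

    def is_extract_conc(self, dilution_label: str, geometry: REDGeometry) -> float:
        """IS concentration (ng/mL) in the injected extract for one curve."""
        conc = self.is_working_conc * geometry.v_is / geometry.prep_volume
        if dilution_label == "1:4":
            conc /= geometry.plasma_post_dilution_factor
        return conc


class StudyDesign(BaseModel):
    """Calibration/QC levels, spike levels and sampling scheme of the study.

    Defaults reproduce the validated design: a 9-level 0.05–1000 ng/mL curve
    for the undiluted buffer fraction, a 13-level 0.075–1000 ng/mL curve for
    the 1:4-diluted plasma fraction, QCs at LLOQ / 3xLLOQ / 300 / 750 ng/mL,
    whole-workflow spikes at 88 and 1742.5 ng/mL, and jugular sampling at
    -2, 5, 10, 15, 30, 45, 60, 120, 240 min for 1 and 3 mg/kg dose groups.
    """

    calibration_levels_1to1: list[float] = Field(
        default_factory=lambda: [0.05, 1, 10, 100, 200, 400, 600, 800, 1000]
    )
    calibration_levels_1to4: list[float] = Field(
        default_factory=lambda: [0.075, 0.1, 0.25, 0.3, 0.5, 1, 10, 100, 200, 400, 600, 800, 1000]
    )
    qc_levels: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {
            "1:1": {"LLOQ": 0.05, "LQC": 0.15, "MQC": 300.0, "HQC": 750.0},
            "1:4": {"LLOQ": 0.30, "LQC": 1.00, "MQC": 300.0, "HQC": 750.0},
        }
    )
    spike_levels_workflow: tuple[float, float] = (88.0, 1742.50)
    recovery_spike_levels: tuple[float, float] = (10.0, 2000.0)
    dose_groups: list[float] = Field(default_factory=lambda: [1.0, 3.0])
    sampling_times: list[float] = Field(
        default_factory=lambda: [-2, 5, 10, 15, 30, 45, 60, 120, 240]
    )
    n_lots: int = 6
    n_replicates: int = 6
    n_cal_replicates: int = 3
    n_runs: int = 3
    seed: int = 0

    @field_validator("calibration_levels_1to1", "calibration_levels_1to4")
    @classmethod
    def _sorted_pos(cls, v: list[float]) -> list[float]:
        if any(x <= 0 for x in v):
            raise ValueError("calibration levels must be > 0")
        if sorted(v) != v:
            raise ValueError("calibration levels must be sorted ascending")
        return v

    @field_validator("sampling_times")
    @classmethod
    def _strict_increasing(cls, v: list[float]) -> list[float]:
        if any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("sampling times must be strictly increasing")
        return v

    @model_validator(mode="after")
    def _qc_in_range(self) -> "StudyDesign":
        ranges = {
            "1:1": self.calibration_levels_1to1,
            "1:4": self.calibration_levels_1to4,
        }
        for label, levels in self.qc_levels.items():
            if label not in ranges:
                raise ValueError(f"unknown dilution label {label!r}")
            lo, hi = ranges[label][0], ranges[label][-1]
            for name, conc in levels.items():
                if not (lo <= conc <= hi):
                    raise ValueError(
                        f"QC {name} ({conc} ng/mL) outside the {label} range [{lo}, {hi}]"
                    )
        return self

    def calibration_levels(self, dilution_label: str) -> list[float]:
        if dilution_label == "1:1":
            return self.calibration_levels_1to1
        if dilution_label == "1:4":
            return self.calibration_levels_1to4
        raise ValueError(f"unknown dilution label {dilution_label!r}")


def simulate_prep(
    chamber_conc: float, compartment: str, geometry: REDGeometry
) -> float:
    """Deterministic prep: chamber concentration -> injected extract concentration.

    Applies the full volume chain (aliquot + complement + acid + IS + ACN,
    then the 1:4 post-dilution for the plasma fraction only).
    """
    if chamber_conc < 0:
        raise ValueError("chamber concentration must be >= 0")
    return chamber_conc / dilution_chain(compartment, geometry)


def injected_concentration(
    nominal: float, dilution_label: str, geometry: REDGeometry
) -> float:
    """Injected extract concentration for a standard/QC at chamber-level nominal.

    Standards are prepared exactly like the fraction their curve is matched
    to, so a "1:1" (buffer-fraction) standard passes the base prep chain and
    a "1:4" (plasma-fraction) standard additionally the x4 post-dilution.
    """
    comp = {"1:1": "buffer", "1:4": "plasma"}.get(dilution_label)
    if comp is None:
        raise ValueError(f"unknown dilution label {dilution_label!r}")
    return simulate_prep(nominal, comp, geometry)


def _carry(base: np.ndarray, frac: float) -> np.ndarray:
    if frac == 0.0 or base.size == 0:
        return base
    # a_n = base_n + frac * a_{n-1}  — first-order IIR recursion
    return lfilter([1.0], [1.0, -frac], base)


def simulate_peak_areas(
    manifest: pd.DataFrame,
    injected_concs: Sequence[float] | np.ndarray,
    response: ResponseModel,
    seed: int | np.random.Generator,
    geometry: REDGeometry | None = None,
) -> pd.DataFrame:
    """Simulate quantifier and qualifier peak areas for an injection sequence.

    Parameters
    ----------
    manifest:
        One row per injection, ordered by injection sequence (carry-over
        follows this order).  Uses columns ``sample_id``, ``dilution_label``
        and optionally ``lot`` and ``approach``.
    injected_concs:
        Analyte concentration (ng/mL) in each injected extract, aligned with
        ``manifest`` rows.
    seed:
        Integer seed or a ``numpy.random.Generator``; a fixed seed gives a
        bit-identical table.

    Returns
    -------
    Long-format table with columns ``sample_id, analyte, role, area``
    (four rows per injection).
    """
    geometry = geometry or REDGeometry()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    conc = np.asarray(injected_concs, dtype=float)
    if conc.shape[0] != len(manifest):
        raise ValueError("injected_concs must align with manifest rows")
    n = conc.shape[0]

    lots = (
        manifest["lot"].fillna("").astype(str).to_numpy()
        if "lot" in manifest.columns
        else np.array([""] * n)
    )
    lot_fac = np.array([response.lot_factor(l) for l in lots])

    approaches = (
        manifest["approach"].fillna("").astype(str).to_numpy()
        if "approach" in manifest.columns
        else np.array([""] * n)
    )
    # only approach-A samples pass the analyte/IS through precipitation losses
    precip_a = np.where(approaches == "A", response.precip_recovery_analyte, 1.0)
    precip_i = np.where(approaches == "A", response.precip_recovery_is, 1.0)

    is_conc = np.array(
        [
            response.is_extract_conc(lbl, geometry)
            for lbl in manifest["dilution_label"].astype(str)
        ]
    )
    if "sample_type" in manifest.columns:
        # true blanks (carry-over / selectivity) receive no internal standard;
        # any IS signal there can only be interference or carry-over
        no_is = manifest["sample_type"].isin(["blank", "selectivity_blank"]).to_numpy()
        is_conc = np.where(no_is, 0.0, is_conc)

    sd_sh = response.sigma_prop * np.sqrt(response.prop_shared_frac)
    sd_ind = response.sigma_prop * np.sqrt(1.0 - response.prop_shared_frac)
    eps_shared = rng.normal(0.0, sd_sh, n) if sd_sh > 0 else np.zeros(n)
    eps_a = rng.normal(0.0, sd_ind, n) if sd_ind > 0 else np.zeros(n)
    eps_i = rng.normal(0.0, sd_ind, n) if sd_ind > 0 else np.zeros(n)

    sig_a = response.sensitivity_analyte * conc * lot_fac * precip_a
    sig_i = response.sensitivity_is * is_conc * precip_i

    channels = {
        (ANALYTE, "quantifier"): sig_a * (1.0 + eps_shared + eps_a),
        (ANALYTE, "qualifier"): response.qualifier_frac_analyte * sig_a * (1.0 + eps_shared + eps_a),
        (IS_NAME, "quantifier"): sig_i * (1.0 + eps_shared + eps_i),
        (IS_NAME, "qualifier"): response.qualifier_frac_is * sig_i * (1.0 + eps_shared + eps_i),
    }

    frames = []
    for (analyte, role), base in channels.items():
        if response.sigma_add > 0:
            base = base + rng.normal(0.0, response.sigma_add, n)
        area = np.maximum(_carry(base, response.carryover_frac), 0.0)
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": manifest["sample_id"].to_numpy(),
                    "analyte": analyte,
                    "role": role,
                    "area": area,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_pk_profile(
    dose_group: float,
    design: StudyDesign,
    seed: int | np.random.Generator,
    n_animals: int = 4,
    ka_per_min: float = 0.09,
    ke_per_min: float = 0.012,
    scale_per_mg_kg: float = 369.0,
    cv_lognormal: float = 0.3,
) -> pd.DataFrame:
    """One-compartment absorption/elimination total-plasma time course.

    ``C(t) = dose * scale * (exp(-ke t) - exp(-ka t))`` for t > 0 (0 at and
    before dosing), multiplied per animal by a lognormal factor with
    geometric CV ``cv_lognormal``.  The default rate constants put the peak
    near 26 min and the default scale puts the noiseless 1 mg/kg peak near
    the mid-200s ng/mL, plausible for intraperitoneal instillation.

    Returns
    -------
    DataFrame with columns ``animal, time_min, total_ng_ml``.
    """
    if dose_group < 0:
        raise ValueError("dose must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    t = np.asarray(design.sampling_times, dtype=float)
    base = np.where(
        t > 0,
        dose_group * scale_per_mg_kg * (np.exp(-ke_per_min * t) - np.exp(-ka_per_min * t)),
        0.0,
    )
    base = np.maximum(base, 0.0)

    rows = []
    for animal in range(n_animals):
        factor = (
            rng.lognormal(mean=0.0, sigma=cv_lognormal) if cv_lognormal > 0 else 1.0
        )
        for time, c in zip(t, base * factor):
            rows.append({"animal": animal + 1, "time_min": time, "total_ng_ml": c})
    return pd.DataFrame(rows)
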