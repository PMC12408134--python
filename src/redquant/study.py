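"""Assemble complete synthetic validation studies: manifests, areas, truth.

A "study" is everything a bioanalytical validation campaign injects:

* per run (day) and per dilution: calibration standards in ascending order
  (technical triplicates), a blank immediately after the ULOQ standard (the
  carry-over check position), then QC replicates at four levels,
* matrix-effect QCs across independent plasma lots,
* selectivity blanks across those lots,
* stability QCs per storage condition,
* a reinjection replay of the first run's QCs,
* recovery approaches A (spike before precipitation), B (spike after),
  C (solvent spike),
* whole-workflow RED specimens at the two repeatability spike levels, and
  optionally two-dose PK time-course specimens.

Every RED specimen contributes two injections (plasma fraction on the 1:4
curve, buffer fraction on the 1:1 curve) and one ground-truth row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binding import BindingModel, simulate_red_equilibrium
from .geometry import REDGeometry
from .massbalance import original_concentrations
from .simulate import (
    ResponseModel,
    StudyDesign,
    injected_concentration,
    simulate_peak_areas,
    simulate_pk_profile,
    simulate_prep,
)

__all__ = ["StudyBundle", "STABILITY_CONDITIONS", "generate_study", "qc_run_manifest"]

#: storage conditions exercised by the stability assessment
STABILITY_CONDITIONS = (
    "T0",
    "benchtop",
    "freeze_thaw",
    "longterm_minus20",
    "longterm_minus80",
    "processed",
)

MANIFEST_COLUMNS = [
    "sample_id",
    "specimen_id",
    "sample_type",
    "compartment",
    "dilution_label",
    "level_name",
    "nominal_ng_ml",
    "run_day",
    "lot",
    "condition",
    "approach",
    "batch_id",
    "injection_index",
    "dose_group",
    "animal",
    "time_min",
]


@dataclass
class StudyBundle:
    """All tables of one simulated study."""

    manifest: pd.DataFrame
    peaks: pd.DataFrame
    truth: pd.DataFrame  # per RED specimen: true free/bound/total
    injected: pd.DataFrame = field(default_factory=pd.DataFrame)  # per injection


def _finalize(rows: list[dict], batch_id: str) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    df["batch_id"] = batch_id
    df["injection_index"] = range(len(df))
    return df


def qc_run_manifest(
    design: StudyDesign,
    dilution_label: str,
    run_day: int,
    n_blanks: int = 1,
) -> pd.DataFrame:
    """One acquisition run: ascending calibration, blank(s) after ULOQ, QCs."""
    rows: list[dict] = []
    tag = dilution_label.replace(":", "")
    for level in design.calibration_levels(dilution_label):
        for rep in range(1, design.n_cal_replicates + 1):
            rows.append(
                {
                    "sample_id": f"CAL-{tag}-D{run_day}-{level:g}-{rep}",
                    "sample_type": "calibration",
                    "dilution_label": dilution_label,
                    "nominal_ng_ml": level,
                    "run_day": run_day,
                }
            )
    for b in range(1, n_blanks + 1):
        rows.append(
            {
                "sample_id": f"BLK-{tag}-D{run_day}-{b}",
                "sample_type": "blank",
                "dilution_label": dilution_label,
                "nominal_ng_ml": 0.0,
                "run_day": run_day,
            }
        )
    for name, conc in design.qc_levels[dilution_label].items():
        for rep in range(1, design.n_replicates + 1):
            rows.append(
                {
                    "sample_id": f"QC-{tag}-D{run_day}-{name}-{rep}",
                    "sample_type": "qc",
                    "dilution_label": dilution_label,
                    "level_name": name,
                    "nominal_ng_ml": conc,
                    "run_day": run_day,
                }
            )
    return _finalize(rows, batch_id=f"run{run_day}-{tag}")


def _lot_qc_manifest(design: StudyDesign, dilution_label: str) -> pd.DataFrame:
    """Matrix-effect QCs (LQC/HQC, 3 reps) plus one blank per matrix lot."""
    rows: list[dict] = []
    tag = dilution_label.replace(":", "")
    qcs = design.qc_levels[dilution_label]
    for lot_i in range(1, design.n_lots + 1):
        lot = f"lot{lot_i}"
        rows.append(
            {
                "sample_id": f"SEL-{tag}-{lot}",
                "sample_type": "selectivity_blank",
                "dilution_label": dilution_label,
                "nominal_ng_ml": 0.0,
                "run_day": 1,
                "lot": lot,
            }
        )
        for name in ("LQC", "HQC"):
            for rep in range(1, 4):
                rows.append(
                    {
                        "sample_id": f"MTX-{tag}-{lot}-{name}-{rep}",
                        "sample_type": "matrix_qc",
                        "dilution_label": dilution_label,
                        "level_name": name,
                        "nominal_ng_ml": qcs[name],
                        "run_day": 1,
                        "lot": lot,
                    }
                )
    return _finalize(rows, batch_id=f"matrix-{tag}")


def _stability_manifest(design: StudyDesign, dilution_label: str) -> pd.DataFrame:
    rows: list[dict] = []
    tag = dilution_label.replace(":", "")
    qcs = design.qc_levels[dilution_label]
    for condition in STABILITY_CONDITIONS:
        for name in ("LQC", "HQC"):
            for rep in range(1, 4):
                rows.append(
                    {
                        "sample_id": f"STB-{tag}-{condition}-{name}-{rep}",
                        "sample_type": "stability_qc",
                        "dilution_label": dilution_label,
                        "level_name": name,
                        "nominal_ng_ml": qcs[name],
                        "run_day": 1,
                        "condition": condition,
                    }
                )
    return _finalize(rows, batch_id=f"stability-{tag}")


def _recovery_manifest(design: StudyDesign, n_reps: int = 5) -> pd.DataFrame:
    """Recovery approaches A/B/C at the two recovery spike levels (1:1 prep)."""
    rows: list[dict] = []
    for spike in design.recovery_spike_levels:
        for approach in ("A", "B", "C"):
            for rep in range(1, n_reps + 1):
                rows.append(
                    {
                        "sample_id": f"REC-{approach}-{spike:g}-{rep}",
                        "sample_type": "recovery",
                        "dilution_label": "1:1",
                        "nominal_ng_ml": spike,
                        "run_day": 1,
                        "approach": approach,
                    }
                )
    return _finalize(rows, batch_id="recovery")


def _workflow_manifest(design: StudyDesign) -> tuple[pd.DataFrame, list[dict]]:
    """Whole-workflow RED specimens: 2 spike levels x n_runs days x n reps."""
    rows: list[dict] = []
    specimens: list[dict] = []
    for li, spike in enumerate(design.spike_levels_workflow):
        level = "low" if li == 0 else "high"
        for day in range(1, design.n_runs + 1):
            for rep in range(1, design.n_replicates + 1):
                spec = f"WF-{level}-D{day}-{rep}"
                specimens.append(
                    {"specimen_id": spec, "level_name": level, "run_day": day,
                     "nominal_ng_ml": spike}
                )
                for comp, lbl in (("plasma", "1:4"), ("buffer", "1:1")):
                    rows.append(
                        {
                            "sample_id": f"{spec}-{comp[0].upper()}",
                            "specimen_id": spec,
                            "sample_type": "workflow",
                            "compartment": comp,
                            "dilution_label": lbl,
                            "level_name": level,
                            "nominal_ng_ml": spike,
                            "run_day": day,
                        }
                    )
    return _finalize(rows, batch_id="workflow"), specimens


def _pk_manifest(
    design: StudyDesign, rng: np.random.Generator, n_animals: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    rows: list[dict] = []
    profiles = []
    for dose in design.dose_groups:
        prof = simulate_pk_profile(dose, design, rng, n_animals=n_animals)
        prof["dose_group"] = dose
        profiles.append(prof)
        for _, r in prof.iterrows():
            spec = f"PK-R{dose:g}-A{int(r.animal)}-t{r.time_min:g}"
            for comp, lbl in (("plasma", "1:4"), ("buffer", "1:1")):
                rows.append(
                    {
                        "sample_id": f"{spec}-{comp[0].upper()}",
                        "specimen_id": spec,
                        "sample_type": "study",
                        "compartment": comp,
                        "dilution_label": lbl,
                        "nominal_ng_ml": r.total_ng_ml,
                        "run_day": 1,
                        "dose_group": dose,
                        "animal": int(r.animal),
                        "time_min": r.time_min,
                    }
                )
    return _finalize(rows, batch_id="pk"), pd.concat(profiles, ignore_index=True)


def _injected_for(
    manifest: pd.DataFrame,
    binding: BindingModel,
    geometry: REDGeometry,
) -> tuple[np.ndarray, list[dict]]:
    """Injected analyte concentration per row, plus truth rows for RED specimens."""
    concs = np.zeros(len(manifest))
    truth: dict[str, dict] = {}
    for i, row in enumerate(manifest.itertuples(index=False)):
        stype = row.sample_type
        if stype in ("blank", "selectivity_blank"):
            concs[i] = 0.0
        elif stype in ("workflow", "study"):
            c_p, c_b = simulate_red_equilibrium(row.nominal_ng_ml, binding, geometry)
            concs[i] = simulate_prep(
                c_p if row.compartment == "plasma" else c_b, row.compartment, geometry
            )
            spec = row.specimen_id
            if spec not in truth:
                res = original_concentrations(c_p, c_b, geometry)
                truth[spec] = {
                    "specimen_id": spec,
                    "true_total_ng_ml": row.nominal_ng_ml,
                    "true_free_ng_ml": res.free_conc,
                    "true_bound_ng_ml": res.bound_conc,
                    "chamber_plasma_ng_ml": c_p,
                    "chamber_buffer_ng_ml": c_b,
                }
        else:
            # standards / QCs prepared like the matching fraction
            concs[i] = injected_concentration(
                row.nominal_ng_ml, row.dilution_label, geometry
            )
    return concs, list(truth.values())


def generate_study(
    design: StudyDesign | None = None,
    binding: BindingModel | None = None,
    response: ResponseModel | None = None,
    geometry: REDGeometry | None = None,
    seed: int | None = None,
    include_pk: bool = False,
    n_animals: int = 4,
    stability_degradation: dict[str, float] | None = None,
    components: tuple[str, ...] = (
        "qc_runs", "matrix", "stability", "reinjection", "recovery", "workflow",
    ),
) -> StudyBundle:
    """Simulate a complete validation study.

    Parameters
    ----------
    seed:
        Overrides ``design.seed`` when given.  One seed drives every noise
        source; a fixed seed yields bit-identical tables.
    stability_degradation:
        Optional map of storage condition -> surviving analyte fraction
        (e.g. ``{"benchtop": 0.8}`` for 20% degradation); default none.

    Returns
    -------
    :class:`StudyBundle` with the concatenated manifest, the simulated
    long-format peak-area table, the RED ground truth, and the per-injection
    injected concentrations.
    """
    design = design or StudyDesign()
    binding = binding or BindingModel()
    response = response or ResponseModel()
    geometry = geometry or REDGeometry()
    rng = np.random.default_rng(design.seed if seed is None else seed)

    batches: list[pd.DataFrame] = []
    if "qc_runs" in components:
        for day in range(1, design.n_runs + 1):
            for lbl in ("1:1", "1:4"):
                batches.append(qc_run_manifest(design, lbl, day))
    if "matrix" in components:
        for lbl in ("1:1", "1:4"):
            batches.append(_lot_qc_manifest(design, lbl))
    if "stability" in components:
        for lbl in ("1:1", "1:4"):
            batches.append(_stability_manifest(design, lbl))
    if "reinjection" in components:
        # reinjection: replay of run 1 QCs + standards after autosampler storage
        for lbl in ("1:1", "1:4"):
            reinj = qc_run_manifest(design, lbl, run_day=1, n_blanks=1)
            reinj["sample_id"] = reinj["sample_id"] + "-RI"
            reinj["batch_id"] = f"reinjection-{lbl.replace(':', '')}"
            batches.append(reinj)
    if "recovery" in components:
        batches.append(_recovery_manifest(design))
    if "workflow" in components:
        wf_manifest, _ = _workflow_manifest(design)
        batches.append(wf_manifest)
    if not batches and not include_pk:
        raise ValueError("no study components selected")
    pk_profiles = None
    if include_pk:
        pk_batch, pk_profiles = _pk_manifest(design, rng, n_animals)
        batches.append(pk_batch)

    manifest = pd.concat(batches, ignore_index=True)
    for col in MANIFEST_COLUMNS:
        if col not in manifest.columns:
            manifest[col] = np.nan
    manifest = manifest[MANIFEST_COLUMNS]

    concs, truth_rows = _injected_for(manifest, binding, geometry)

    if stability_degradation:
        unknown = set(stability_degradation) - set(STABILITY_CONDITIONS)
        if unknown:
            raise ValueError(f"unknown stability conditions: {sorted(unknown)}")
        stab = manifest["sample_type"] == "stability_qc"
        factors = manifest.loc[stab, "condition"].map(
            lambda c: stability_degradation.get(c, 1.0)
        )
        concs[stab.to_numpy()] *= factors.to_numpy()

    peak_parts = []
    for batch_id, idx in manifest.groupby("batch_id", sort=True).groups.items():
        sub = manifest.loc[idx].sort_values("injection_index")
        peak_parts.append(
            simulate_peak_areas(sub, concs[sub.index.to_numpy()], response, rng, geometry)
        )
    peaks = pd.concat(peak_parts, ignore_index=True)

    injected = manifest[["sample_id"]].copy()
    injected["injected_ng_ml"] = concs
    truth = pd.DataFrame(truth_rows)
    if pk_profiles is not None and not truth.empty:
        truth = truth  # PK specimens already included via workflow-style rows

    return StudyBundle(manifest=manifest, peaks=peaks, truth=truth, injected=injected)
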