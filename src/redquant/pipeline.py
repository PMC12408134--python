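"""End-to-end orchestration: simulate -> calibrate -> quantify -> fractionate
-> validate -> report.

`run_pipeline` drives a full synthetic validation campaign from a single
:class:`RunConfig` and writes a report bundle (curve, fraction, QC, matrix,
stability, reinjection, recovery, selectivity and carry-over tables, a
plain-text summary, and a provenance record with the config hash and seed).
Outputs are deterministic for a fixed config+seed: rerunning yields
byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import io as rio
from .binding import BindingModel
from .calibration import CalibrationCurve, assess_curve, back_calculate, fit_calibration
from .geometry import REDGeometry
from .massbalance import fractionate_table
from .simulate import ResponseModel, StudyDesign
from .study import StudyBundle, generate_study
from .validation import (
    QCStat,
    carryover_assess,
    intra_inter_run,
    matrix_effect,
    qc_stat,
    recovery,
    reinjection_compare,
    round_half_up,
    selectivity_assess,
    stability_assess,
)

__all__ = ["RunConfig", "PipelineError", "PipelineResult", "run_pipeline",
           "quantify_samples", "fit_batch_curves", "workflow_repeatability",
           "fractionate_files"]

ANALYTE = "ropivacaine"
IS_NAME = "d7-ropivacaine"


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and samples."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")


class RunConfig(BaseModel):
    """Everything one end-to-end run needs."""

    seed: int = 0
    outdir: str = "redquant-out"
    geometry: REDGeometry = Field(default_factory=REDGeometry)
    binding: BindingModel = Field(default_factory=BindingModel)
    response: ResponseModel = Field(default_factory=ResponseModel)
    design: StudyDesign = Field(default_factory=StudyDesign)
    include_pk: bool = False
    band_lloq: float = 20.0
    band_other: float = 15.0
    r2_min: float = 0.99
    verbosity: int = 0

    def config_hash(self) -> str:
        # paths/verbosity are not part of the scientific configuration
        payload = json.dumps(
            self.model_dump(mode="json", exclude={"outdir", "verbosity"}),
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    """In-memory report bundle from one pipeline run."""

    bundle: StudyBundle
    curves: dict[str, CalibrationCurve]
    curve_table: pd.DataFrame
    measured: pd.DataFrame  # per sample: analyzed_ng_ml
    fractions: pd.DataFrame
    qc_stats: dict[str, list[QCStat]]  # per dilution
    workflow: pd.DataFrame
    matrix: pd.DataFrame
    stability: pd.DataFrame
    reinjection: pd.DataFrame
    recovery_results: list
    selectivity: pd.DataFrame
    carryover: pd.DataFrame
    outputs: dict[str, Path] = field(default_factory=dict)


def _ratio_table(manifest: pd.DataFrame, peaks: pd.DataFrame) -> pd.DataFrame:
    """Analyte/IS quantifier area ratio per sample, joined onto the manifest."""
    quant = peaks[peaks["role"] == "quantifier"]
    wide = quant.pivot_table(index="sample_id", columns="analyte", values="area")
    for name in (ANALYTE, IS_NAME):
        if name not in wide.columns:
            raise PipelineError("quantification", f"no quantifier areas for {name!r}")
    wide = wide.rename(columns={ANALYTE: "area_analyte", IS_NAME: "area_is"})
    out = manifest.merge(wide.reset_index(), on="sample_id", how="left", validate="m:1")
    zero_is = out["area_is"] <= 0
    out["response_ratio"] = np.where(
        zero_is, np.nan, out["area_analyte"] / out["area_is"].where(~zero_is)
    )
    return out


def fit_batch_curves(
    manifest: pd.DataFrame,
    peaks: pd.DataFrame,
    r2_min: float = 0.99,
) -> tuple[dict[str, CalibrationCurve], pd.DataFrame]:
    """Fit a 1/x-weighted curve for every batch containing calibration standards.

    Returns the curves keyed by ``batch_id`` and a long diagnostics table
    (slope, intercept, R^2, per-level back-calculated accuracy, acceptance).
    """
    ratios = _ratio_table(manifest, peaks)
    cal = ratios[ratios["sample_type"] == "calibration"]
    curves: dict[str, CalibrationCurve] = {}
    rows = []
    for batch, grp in cal.groupby("batch_id", sort=True):
        pts = grp.rename(columns={"nominal_ng_ml": "nominal_conc"})[
            ["nominal_conc", "response_ratio"]
        ].dropna()
        label = str(grp["dilution_label"].iloc[0])
        curve = fit_calibration(pts, weighting="1/x", dilution_label=label)
        curves[str(batch)] = curve
        acc = assess_curve(curve, r2_min=r2_min)
        for level, level_acc in sorted(curve.accuracy_by_level.items()):
            rows.append(
                {
                    "batch_id": batch,
                    "dilution_label": label,
                    "slope": curve.slope,
                    "intercept": curve.intercept,
                    "r_squared": curve.r_squared,
                    "level_ng_ml": level,
                    "accuracy_pct": level_acc,
                    "level_pass": acc.level_pass[level],
                    "curve_accepted": acc.accepted,
                }
            )
    if not curves:
        raise PipelineError("calibration", "no calibration standards in manifest")
    return curves, pd.DataFrame(rows)


def _curve_for_row(row, curves: dict[str, CalibrationCurve]) -> CalibrationCurve:
    batch = str(row.batch_id)
    if batch in curves:
        return curves[batch]
    tag = str(row.dilution_label).replace(":", "")
    run = row.run_day
    key = f"run{int(run)}-{tag}" if pd.notna(run) else f"run1-{tag}"
    if key not in curves:
        key = f"run1-{tag}"
    if key not in curves:
        raise PipelineError(
            "quantification",
            f"no calibration curve for sample {row.sample_id} "
            f"(batch {batch}, dilution {row.dilution_label})",
        )
    return curves[key]


def quantify_samples(
    manifest: pd.DataFrame,
    peaks: pd.DataFrame,
    curves: dict[str, CalibrationCurve],
) -> pd.DataFrame:
    """Back-calculate analyzed concentrations for every non-calibration sample.

    Each sample is quantified against its own batch's curve when the batch
    carries calibration standards, otherwise against the run-1 curve of the
    matching dilution.  Negative back-calculated values are clamped to zero
    and flagged ``below-zero``.
    """
    ratios = _ratio_table(manifest, peaks)
    sel = ratios[~ratios["sample_type"].isin(["calibration"])].copy()
    concs, flags = [], []
    for row in sel.itertuples(index=False):
        if pd.isna(row.response_ratio):
            concs.append(np.nan)
            flags.append("zero-is-area")
            continue
        curve = _curve_for_row(row, curves)
        conc, below = back_calculate(curve, float(row.response_ratio))
        concs.append(conc)
        flags.append("below-zero" if below else "")
    sel["analyzed_ng_ml"] = concs
    sel["quant_flags"] = flags
    return sel


def workflow_repeatability(
    fractions: pd.DataFrame,
    manifest: pd.DataFrame,
    band: float = 15.0,
) -> pd.DataFrame:
    """Repeatability table for the whole-workflow RED specimens.

    Per spike level: intra-run (per day) and pooled inter-run mean, SD, CV
    of the bound, free, and total concentrations, plus the accuracy of the
    total against the nominal spike (the complete-workflow acceptance
    quantity, bands +/-15%).
    """
    meta = (
        manifest[manifest["sample_type"] == "workflow"]
        .drop_duplicates("specimen_id")[["specimen_id", "level_name", "run_day",
                                         "nominal_ng_ml"]]
    )
    df = fractions.merge(meta, on="specimen_id", validate="1:1")
    rows = []
    for level, lv in df.groupby("level_name", sort=True):
        nominal = float(lv["nominal_ng_ml"].iloc[0])
        scopes = [(f"intra-run {d}", g) for d, g in lv.groupby("run_day", sort=True)]
        scopes.append(("inter-run", lv))
        for scope, g in scopes:
            row = {"level_name": level, "nominal_ng_ml": nominal, "scope": scope,
                   "n": len(g)}
            for quantity in ("bound", "free", "total"):
                vals = g[f"{quantity}_ng_ml"].to_numpy()
                row[f"{quantity}_mean"] = vals.mean()
                row[f"{quantity}_sd"] = vals.std(ddof=1)
                row[f"{quantity}_cv_pct"] = 100.0 * vals.std(ddof=1) / vals.mean()
            acc = 100.0 * row["total_mean"] / nominal
            row["total_accuracy_pct"] = acc
            row["passed"] = (
                abs(acc - 100.0) <= band and row["total_cv_pct"] <= band
            )
            rows.append(row)
    return pd.DataFrame(rows)


def _qc_stats_frame(stats: list[QCStat]) -> pd.DataFrame:
    return pd.DataFrame([s.as_dict() for s in stats])


def run_pipeline(config: RunConfig, write: bool = True) -> PipelineResult:
    """Run the full synthetic study end-to-end and (optionally) write reports."""
    outdir = Path(config.outdir)

    try:
        bundle = generate_study(
            design=config.design,
            binding=config.binding,
            response=config.response,
            geometry=config.geometry,
            seed=config.seed,
            include_pk=config.include_pk,
        )
    except Exception as exc:
        raise PipelineError("simulation", str(exc)) from exc

    try:
        curves, curve_table = fit_batch_curves(
            bundle.manifest, bundle.peaks, r2_min=config.r2_min
        )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("calibration", str(exc)) from exc

    try:
        measured = quantify_samples(bundle.manifest, bundle.peaks, curves)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("quantification", str(exc)) from exc

    try:
        red = measured[measured["sample_type"].isin(["workflow", "study"])]
        analyzed = red.rename(columns={"analyzed_ng_ml": "analyzed_ng_ml"})[
            ["specimen_id", "compartment", "analyzed_ng_ml"]
        ]
        fractions = fractionate_table(analyzed, config.geometry)
    except Exception as exc:
        raise PipelineError("fractionation", str(exc)) from exc

    try:
        qc = measured[
            (measured["sample_type"] == "qc")
            & measured["batch_id"].astype(str).str.startswith("run")
        ].rename(columns={"analyzed_ng_ml": "measured_ng_ml"})
        qc_stats = {
            lbl: intra_inter_run(
                grp,
                expected_levels=sorted(config.design.qc_levels[lbl]),
                band_lloq=config.band_lloq,
                band_other=config.band_other,
            )
            for lbl, grp in qc.groupby("dilution_label", sort=True)
        }

        wf = workflow_repeatability(fractions, bundle.manifest, band=config.band_other)

        mtx = measured[measured["sample_type"] == "matrix_qc"].rename(
            columns={"analyzed_ng_ml": "measured_ng_ml"}
        )
        matrix_rows = []
        for lbl, grp in mtx.groupby("dilution_label", sort=True):
            stats, warns = matrix_effect(grp, min_lots=config.design.n_lots)
            frame = _qc_stats_frame(stats)
            frame.insert(0, "dilution_label", lbl)
            frame["warnings"] = "; ".join(warns)
            matrix_rows.append(frame)
        matrix = pd.concat(matrix_rows, ignore_index=True)

        stab = measured[measured["sample_type"] == "stability_qc"].rename(
            columns={"analyzed_ng_ml": "measured_ng_ml"}
        )
        stab_rows = []
        for lbl, grp in stab.groupby("dilution_label", sort=True):
            frame = _qc_stats_frame(stability_assess(grp, band=config.band_other))
            frame.insert(0, "dilution_label", lbl)
            stab_rows.append(frame)
        stability = pd.concat(stab_rows, ignore_index=True)

        reinj_frames = []
        for lbl in ("1:1", "1:4"):
            tag = lbl.replace(":", "")
            first = [
                s for s in qc_stats[lbl] if s.scope == "intra-run 1"
            ]
            ri = measured[
                (measured["batch_id"] == f"reinjection-{tag}")
                & (measured["sample_type"] == "qc")
            ].rename(columns={"analyzed_ng_ml": "measured_ng_ml"})
            reinj_stats = [
                qc_stat(g["measured_ng_ml"], float(g["nominal_ng_ml"].iloc[0]),
                        str(level), scope="reinjection")
                for level, g in ri.groupby("level_name", sort=True)
            ]
            frame = reinjection_compare(first, reinj_stats)
            frame.insert(0, "dilution_label", lbl)
            reinj_frames.append(frame)
        reinjection = pd.concat(reinj_frames, ignore_index=True)

        rec_results = []
        rec_manifest = bundle.manifest[bundle.manifest["sample_type"] == "recovery"]
        rec_peaks = bundle.peaks.merge(
            rec_manifest[["sample_id", "approach", "nominal_ng_ml"]], on="sample_id"
        )
        for spike, grp in rec_peaks.groupby("nominal_ng_ml", sort=True):
            rec_results.append(
                recovery(
                    grp[grp["approach"] == "A"],
                    grp[grp["approach"] == "B"],
                    grp[grp["approach"] == "C"],
                    spike_level=float(spike),
                )
            )

        sel_manifest = bundle.manifest[
            bundle.manifest["sample_type"] == "selectivity_blank"
        ]
        lloq_11 = bundle.manifest[
            (bundle.manifest["sample_type"] == "calibration")
            & (bundle.manifest["dilution_label"] == "1:1")
            & (bundle.manifest["nominal_ng_ml"]
               == config.design.calibration_levels_1to1[0])
        ]
        lloq_peaks = bundle.peaks[bundle.peaks["sample_id"].isin(lloq_11["sample_id"])]
        sel_peaks = bundle.peaks.merge(
            sel_manifest[["sample_id", "lot", "dilution_label"]], on="sample_id"
        )
        lloq_a = lloq_peaks[
            (lloq_peaks["analyte"] == ANALYTE) & (lloq_peaks["role"] == "quantifier")
        ]["area"].mean()
        lloq_i = lloq_peaks[
            (lloq_peaks["analyte"] == IS_NAME) & (lloq_peaks["role"] == "quantifier")
        ]["area"].mean()
        selectivity = selectivity_assess(
            sel_peaks[sel_peaks["dilution_label"] == "1:1"], lloq_a, lloq_i,
            min_lots=config.design.n_lots,
        )

        co_frames = []
        for day in range(1, config.design.n_runs + 1):
            for lbl in ("1:1", "1:4"):
                tag = lbl.replace(":", "")
                batch = bundle.manifest[bundle.manifest["batch_id"] == f"run{day}-{tag}"]
                blanks = batch[batch["sample_type"] == "blank"]
                lloq_cal = batch[
                    (batch["sample_type"] == "calibration")
                    & (batch["nominal_ng_ml"]
                       == config.design.calibration_levels(lbl)[0])
                ]
                res = carryover_assess(
                    bundle.peaks[bundle.peaks["sample_id"].isin(blanks["sample_id"])],
                    bundle.peaks[bundle.peaks["sample_id"].isin(lloq_cal["sample_id"])],
                )
                co_frames.append(
                    {"run_day": day, "dilution_label": lbl,
                     "blank_analyte_area": res.blank_analyte_area,
                     "blank_is_area": res.blank_is_area,
                     "lloq_analyte_mean": res.lloq_analyte_mean,
                     "analyte_flag": res.analyte_flag, "is_flag": res.is_flag,
                     "passed": res.passed}
                )
        carryover = pd.DataFrame(co_frames)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("validation", str(exc)) from exc

    result = PipelineResult(
        bundle=bundle, curves=curves, curve_table=curve_table, measured=measured,
        fractions=fractions, qc_stats=qc_stats, workflow=wf, matrix=matrix,
        stability=stability, reinjection=reinjection, recovery_results=rec_results,
        selectivity=selectivity, carryover=carryover,
    )

    if write:
        try:
            result.outputs = _write_reports(config, result, outdir)
        except Exception as exc:
            raise PipelineError("report", str(exc)) from exc
    return result


def _write_reports(config: RunConfig, result: PipelineResult, outdir: Path) -> dict[str, Path]:
    outputs: dict[str, Path] = {}
    outdir.mkdir(parents=True, exist_ok=True)

    tables = {
        "manifest": result.bundle.manifest,
        "peaks": result.bundle.peaks,
        "truth": result.bundle.truth,
        "curves": result.curve_table,
        "fractions": result.fractions,
        "workflow_repeatability": result.workflow,
        "matrix_effect": result.matrix,
        "stability": result.stability,
        "reinjection": result.reinjection,
        "selectivity": result.selectivity,
        "carryover": result.carryover,
    }
    qc_frames = []
    for lbl, stats in sorted(result.qc_stats.items()):
        frame = _qc_stats_frame(stats)
        frame.insert(0, "dilution_label", lbl)
        qc_frames.append(frame)
    tables["qc_accuracy_precision"] = pd.concat(qc_frames, ignore_index=True)
    tables["recovery"] = pd.DataFrame(
        [
            {
                "spike_ng_ml": r.spike_level,
                "precip_analyte_pct": r.precipitation_pct[ANALYTE],
                "precip_is_pct": r.precipitation_pct[IS_NAME],
                "overall_analyte_pct": r.overall_pct[ANALYTE],
                "overall_is_pct": r.overall_pct[IS_NAME],
                "ratio_precip_pct": r.ratio_precipitation_pct,
                "ratio_overall_pct": r.ratio_overall_pct,
                "passed": r.passed,
            }
            for r in result.recovery_results
        ]
    )

    for name, df in tables.items():
        outputs[name] = rio.write_table(df, outdir / f"{name}.csv")

    try:
        pkg_version = version("redquant")
    except PackageNotFoundError:  # pragma: no cover
        pkg_version = "unknown"
    provenance = {
        "package": "redquant",
        "version": pkg_version,
        "seed": config.seed,
        "config_sha256_16": config.config_hash(),
        "config": config.model_dump(mode="json", exclude={"outdir", "verbosity"}),
    }
    prov_path = outdir / "provenance.json"
    prov_path.write_text(json.dumps(provenance, indent=2, sort_keys=True))
    outputs["provenance"] = prov_path

    summary_path = outdir / "summary.txt"
    summary_path.write_text(_summary_text(result))
    outputs["summary"] = summary_path
    return outputs


def _summary_text(result: PipelineResult) -> str:
    lines = ["redquant pipeline summary", "=" * 26, ""]
    lines.append("Calibration curves (per run x dilution):")
    seen = set()
    for batch, curve in sorted(result.curves.items()):
        if batch in seen:
            continue
        lines.append(
            f"  {batch:<18} slope={curve.slope:.6f} intercept={curve.intercept:.6f} "
            f"R2={curve.r_squared:.4f}"
        )
    lines.append("")
    lines.append("QC accuracy/precision (inter-run):")
    for lbl, stats in sorted(result.qc_stats.items()):
        for s in stats:
            if s.scope == "inter-run":
                lines.append(
                    f"  {lbl} {s.level_name:<5} acc={round_half_up(s.accuracy_pct):6.2f}% "
                    f"CV={round_half_up(s.cv_pct):5.2f}% n={s.n} "
                    f"{'PASS' if s.passed else 'FAIL'}"
                )
    lines.append("")
    lines.append("Whole-workflow repeatability (inter-run totals):")
    wf = result.workflow
    for _, r in wf[wf["scope"] == "inter-run"].iterrows():
        lines.append(
            f"  {r.level_name:<5} nominal={r.nominal_ng_ml:8.2f} "
            f"total={round_half_up(r.total_mean):8.2f} "
            f"acc={round_half_up(r.total_accuracy_pct):6.2f}% "
            f"CV={round_half_up(r.total_cv_pct):5.2f}% "
            f"{'PASS' if r.passed else 'FAIL'}"
        )
    lines.append("")
    lines.append(
        f"Carry-over: {'PASS' if result.carryover['passed'].all() else 'FAIL'}; "
        f"Selectivity: {'PASS' if result.selectivity['passed'].all() else 'FAIL'}; "
        f"Recovery: "
        f"{'PASS' if all(r.passed for r in result.recovery_results) else 'FAIL'}"
    )
    lines.append("")
    return "\n".join(lines)


def fractionate_files(
    plasma_csv: str | Path,
    buffer_csv: str | Path,
    geometry: REDGeometry | None = None,
) -> pd.DataFrame:
    """Fractionation entry point over per-compartment analyzed-concentration CSVs.

    Each CSV needs ``specimen_id`` (or ``sample_id``) and ``analyzed_ng_ml``.
    A missing file aborts naming the fractionation stage.
    """
    geometry = geometry or REDGeometry()
    frames = []
    for comp, path in (("plasma", plasma_csv), ("buffer", buffer_csv)):
        path = Path(path)
        if not path.exists():
            raise PipelineError("fractionation", f"missing {comp}-fraction file {path}")
        df = pd.read_csv(path)
        if "specimen_id" not in df.columns:
            if "sample_id" in df.columns:
                df = df.rename(columns={"sample_id": "specimen_id"})
            else:
                raise PipelineError(
                    "fractionation", f"{path}: needs a specimen_id column"
                )
        if "analyzed_ng_ml" not in df.columns:
            raise PipelineError(
                "fractionation", f"{path}: needs an analyzed_ng_ml column"
            )
        df["compartment"] = comp
        frames.append(df[["specimen_id", "compartment", "analyzed_ng_ml"]])
    return fractionate_table(pd.concat(frames, ignore_index=True), geometry)
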