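"""Bioanalytical validation statistics and acceptance rules (ICH M10 style).

Implements the statistics a regulated bioanalytical validation reports:
accuracy (% of nominal), precision (CV%, n-1 sample SD), intra-/inter-run
QC summaries, per-lot matrix effect, carry-over, storage stability,
reinjection reproducibility, the A/B/C recovery design, and per-lot
selectivity.  Acceptance bands are inclusive and applied exactly as stated:
85–115% accuracy and CV <= 15% (80–120% / 20% at the LLOQ), blank signal
<= 20% of the LLOQ analyte response and <= 5% of the IS response, stability
mean within +/-15% of nominal, and IS overall recovery within 15 percentage
points of the analyte's.

Reported tables carry both raw values and values rounded half-up to two
decimals, matching the conventional presentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

__all__ = [
    "QCStat",
    "RecoveryResult",
    "accuracy",
    "precision_cv",
    "round_half_up",
    "qc_stat",
    "intra_inter_run",
    "matrix_effect",
    "carryover_assess",
    "stability_assess",
    "reinjection_compare",
    "recovery",
    "selectivity_assess",
]

# acceptance bands (percent deviation from 100%)
BAND_DEFAULT = 15.0
BAND_LLOQ = 20.0


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero to ``ndigits`` decimals (table presentation)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def accuracy(mean_measured: float, nominal: float) -> float:
    """Accuracy as percent of nominal: ``100 * mean_measured / nominal``."""
    if nominal <= 0:
        raise ValueError("nominal must be > 0")
    return 100.0 * mean_measured / nominal


def precision_cv(values) -> float:
    """Coefficient of variation in percent: ``100 * sample SD / mean``.

    Uses the n-1 denominator; requires at least two values and a nonzero mean.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("precision needs >= 2 replicates")
    mean = arr.mean()
    if mean == 0:
        raise ValueError("precision undefined for zero mean")
    return 100.0 * arr.std(ddof=1) / mean


@dataclass
class QCStat:
    """Accuracy/precision summary for one QC level under one scope/condition."""

    level_name: str
    nominal: float
    mean: float
    sd: float
    accuracy_pct: float
    cv_pct: float
    n: int
    scope: str  # "intra-run" | "inter-run" | condition / lot label
    accuracy_pass: bool
    cv_pass: bool
    passed: bool

    def as_dict(self) -> dict:
        d = self.__dict__.copy()
        for k in ("mean", "sd", "accuracy_pct", "cv_pct"):
            d[f"{k}_rounded"] = round_half_up(d[k])
        return d


def _bands_for(level_name: str, band_lloq: float, band_other: float) -> float:
    return band_lloq if level_name == "LLOQ" else band_other


def qc_stat(
    values,
    nominal: float,
    level_name: str,
    scope: str,
    band_lloq: float = BAND_LLOQ,
    band_other: float = BAND_DEFAULT,
) -> QCStat:
    """Summarise one set of replicate measured concentrations into a QCStat."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError(f"{level_name}/{scope}: need >= 2 replicates for SD")
    band = _bands_for(level_name, band_lloq, band_other)
    mean = float(arr.mean())
    acc = accuracy(mean, nominal)
    cv = precision_cv(arr)
    acc_ok = abs(acc - 100.0) <= band
    cv_ok = cv <= band
    return QCStat(
        level_name=level_name,
        nominal=nominal,
        mean=mean,
        sd=float(arr.std(ddof=1)),
        accuracy_pct=acc,
        cv_pct=cv,
        n=int(arr.size),
        scope=scope,
        accuracy_pass=acc_ok,
        cv_pass=cv_ok,
        passed=acc_ok and cv_ok,
    )


def intra_inter_run(
    qc_table: pd.DataFrame,
    expected_levels: list[str] | None = None,
    band_lloq: float = BAND_LLOQ,
    band_other: float = BAND_DEFAULT,
) -> list[QCStat]:
    """Per-run (intra) and pooled (inter) accuracy/precision per QC level.

    Parameters
    ----------
    qc_table:
        Columns ``level_name``, ``nominal_ng_ml``, ``run_day``,
        ``measured_ng_ml``; typically 6 replicates x 3 runs per level.
    expected_levels:
        Levels that must be present; an absent level is reported as a
        zero-n failing QCStat rather than silently skipped.

    The inter-run statistic pools all replicates of all runs (not the mean
    of run means), so a 3x6 design yields n=18.
    """
    stats: list[QCStat] = []
    seen = set()
    for level, lv_grp in qc_table.groupby("level_name", sort=True):
        seen.add(level)
        nominal = float(lv_grp["nominal_ng_ml"].iloc[0])
        for run, run_grp in lv_grp.groupby("run_day", sort=True):
            stats.append(
                qc_stat(
                    run_grp["measured_ng_ml"], nominal, str(level),
                    scope=f"intra-run {run}", band_lloq=band_lloq,
                    band_other=band_other,
                )
            )
        stats.append(
            qc_stat(
                lv_grp["measured_ng_ml"], nominal, str(level),
                scope="inter-run", band_lloq=band_lloq, band_other=band_other,
            )
        )
    for level in expected_levels or []:
        if level not in seen:
            stats.append(
                QCStat(level, np.nan, np.nan, np.nan, np.nan, np.nan, 0,
                       "absent", False, False, False)
            )
    return stats


def matrix_effect(
    lot_table: pd.DataFrame,
    min_lots: int = 6,
    band: float = BAND_DEFAULT,
) -> tuple[list[QCStat], list[str]]:
    """Per-lot accuracy and CV with +/-15% bands across independent matrix lots.

    Parameters
    ----------
    lot_table:
        Columns ``lot``, ``level_name``, ``nominal_ng_ml``,
        ``measured_ng_ml`` with >= 3 replicates per lot/level.

    Returns
    -------
    (stats, warnings): one QCStat per lot x level (scope = lot label), and a
    warning list (fewer lots than required still computes, but warns).
    """
    warnings: list[str] = []
    n_lots = lot_table["lot"].nunique()
    if n_lots < min_lots:
        warnings.append(f"only {n_lots} matrix lots (< {min_lots} required)")
    stats: list[QCStat] = []
    for (lot, level), grp in lot_table.groupby(["lot", "level_name"], sort=True):
        if len(grp) < 3:
            warnings.append(f"lot {lot} level {level}: fewer than 3 replicates")
        stats.append(
            qc_stat(
                grp["measured_ng_ml"], float(grp["nominal_ng_ml"].iloc[0]),
                str(level), scope=str(lot), band_lloq=band, band_other=band,
            )
        )
    return stats, warnings


@dataclass
class CarryoverResult:
    blank_analyte_area: float
    blank_is_area: float
    lloq_analyte_mean: float
    lloq_is_mean: float
    analyte_flag: bool  # True = carry-over detected (blank > 20% of LLOQ)
    is_flag: bool       # True = blank IS signal > 5% of IS response
    passed: bool


def carryover_assess(
    blank_records: pd.DataFrame,
    lloq_records: pd.DataFrame,
    analyte: str = "ropivacaine",
    is_name: str = "d7-ropivacaine",
    analyte_limit: float = 0.20,
    is_limit: float = 0.05,
) -> CarryoverResult:
    """Check blanks injected after the ULOQ against LLOQ-referenced limits.

    The blank analyte response must not exceed ``analyte_limit`` (20%) of the
    mean LLOQ analyte response, and the blank IS response must not exceed
    ``is_limit`` (5%) of the mean IS response; limits are inclusive.
    Operates on quantifier areas.

    Raises
    ------
    ValueError
        If either record set is empty (e.g. no post-ULOQ blank in the run).
    """
    def quant_mean(records: pd.DataFrame, name: str) -> float:
        sel = records[(records["analyte"] == name) & (records["role"] == "quantifier")]
        if sel.empty:
            raise ValueError(f"no quantifier records for {name!r}")
        return float(sel["area"].mean())

    if blank_records.empty:
        raise ValueError("no post-ULOQ blank records found; cannot assess carry-over")
    if lloq_records.empty:
        raise ValueError("no LLOQ records found; carry-over limits undefined")

    blank_a = quant_mean(blank_records, analyte)
    blank_i = quant_mean(blank_records, is_name)
    lloq_a = quant_mean(lloq_records, analyte)
    lloq_i = quant_mean(lloq_records, is_name)
    a_flag = blank_a > analyte_limit * lloq_a
    i_flag = blank_i > is_limit * lloq_i
    return CarryoverResult(blank_a, blank_i, lloq_a, lloq_i, a_flag, i_flag,
                           passed=not (a_flag or i_flag))


STABILITY_CONDITIONS = (
    "T0", "benchtop", "freeze_thaw", "longterm_minus20", "longterm_minus80",
    "processed",
)


def stability_assess(
    stability_table: pd.DataFrame,
    band: float = BAND_DEFAULT,
    allowed_conditions: tuple[str, ...] = STABILITY_CONDITIONS,
) -> list[QCStat]:
    """Accuracy/CV per storage condition and level; pass iff mean within +/-15%.

    ``stability_table`` needs columns ``condition``, ``level_name``,
    ``nominal_ng_ml``, ``measured_ng_ml``.  Unknown condition labels are
    rejected.
    """
    unknown = set(stability_table["condition"].unique()) - set(allowed_conditions)
    if unknown:
        raise ValueError(f"unknown stability conditions: {sorted(unknown)}")
    stats = []
    for (cond, level), grp in stability_table.groupby(
        ["condition", "level_name"], sort=True
    ):
        stats.append(
            qc_stat(
                grp["measured_ng_ml"], float(grp["nominal_ng_ml"].iloc[0]),
                str(level), scope=str(cond), band_lloq=band, band_other=band,
            )
        )
    return stats


def reinjection_compare(
    first_run: list[QCStat],
    reinjection: list[QCStat],
) -> pd.DataFrame:
    """Side-by-side first-injection vs reinjection accuracy per QC level.

    Informational: reports the nominal-referenced accuracy of both runs,
    their difference, and the reinjection mean as a percent of the first-run
    mean (a first-injection-referenced basis), since a nominal-referenced
    accuracy alone cannot distinguish autosampler degradation from assay
    bias.  Raises on mismatched level sets.
    """
    first = {s.level_name: s for s in first_run}
    reinj = {s.level_name: s for s in reinjection}
    if set(first) != set(reinj):
        raise ValueError(
            f"level mismatch: first={sorted(first)} reinjection={sorted(reinj)}"
        )
    rows = []
    for level in sorted(first):
        f, r = first[level], reinj[level]
        rows.append(
            {
                "level_name": level,
                "nominal_ng_ml": f.nominal,
                "first_accuracy_pct": f.accuracy_pct,
                "reinjection_accuracy_pct": r.accuracy_pct,
                "accuracy_diff_pct": r.accuracy_pct - f.accuracy_pct,
                "reinjection_vs_first_pct": 100.0 * r.mean / f.mean,
                "first_cv_pct": f.cv_pct,
                "reinjection_cv_pct": r.cv_pct,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class RecoveryResult:
    """Precipitation (A/B) and overall (A/C) recovery for one spike level."""

    spike_level: float
    precipitation_pct: dict[str, float] = field(default_factory=dict)  # per analyte
    overall_pct: dict[str, float] = field(default_factory=dict)
    ratio_precipitation_pct: float = np.nan  # on per-replicate analyte/IS ratios
    ratio_overall_pct: float = np.nan
    passed: bool = False


def recovery(
    areas_a: pd.DataFrame,
    areas_b: pd.DataFrame,
    areas_c: pd.DataFrame,
    spike_level: float,
    analyte: str = "ropivacaine",
    is_name: str = "d7-ropivacaine",
    tolerance_points: float = 15.0,
) -> RecoveryResult:
    """A/B/C recovery design on quantifier peak areas.

    * precipitation recovery = 100 * mean(A) / mean(B) per analyte,
    * overall recovery       = 100 * mean(A) / mean(C) per analyte,
    * ratio recovery applies the same formulas to the per-replicate
      analyte/IS area ratios (the acceptance quantity),
    * pass iff |overall(IS) - overall(analyte)| <= 15 percentage points.

    Each ``areas_*`` table holds quantifier rows (columns ``sample_id``,
    ``analyte``, ``area``) for one approach, >= 1 replicate per analyte.
    """
    def channel(df: pd.DataFrame, name: str) -> np.ndarray:
        sub = df[df["analyte"] == name]
        if "role" in df.columns:
            sub = sub[sub["role"] == "quantifier"]
        if sub.empty:
            raise ValueError(f"approach table has no rows for {name!r}")
        return sub.sort_values("sample_id")["area"].to_numpy(dtype=float)

    result = RecoveryResult(spike_level)
    per_rep_ratio = {}
    for label, df in (("A", areas_a), ("B", areas_b), ("C", areas_c)):
        a = channel(df, analyte)
        i = channel(df, is_name)
        if np.any(i == 0):
            raise ValueError(f"approach {label}: zero IS area")
        per_rep_ratio[label] = a / i

    for name in (analyte, is_name):
        mean_a = channel(areas_a, name).mean()
        mean_b = channel(areas_b, name).mean()
        mean_c = channel(areas_c, name).mean()
        if mean_b == 0 or mean_c == 0:
            raise ValueError("zero denominator mean in recovery computation")
        result.precipitation_pct[name] = 100.0 * mean_a / mean_b
        result.overall_pct[name] = 100.0 * mean_a / mean_c

    result.ratio_precipitation_pct = float(
        100.0 * per_rep_ratio["A"].mean() / per_rep_ratio["B"].mean()
    )
    result.ratio_overall_pct = float(
        100.0 * per_rep_ratio["A"].mean() / per_rep_ratio["C"].mean()
    )
    result.passed = (
        abs(result.overall_pct[is_name] - result.overall_pct[analyte])
        <= tolerance_points
    )
    return result


def selectivity_assess(
    blank_table: pd.DataFrame,
    lloq_analyte_response: float,
    lloq_is_response: float,
    analyte: str = "ropivacaine",
    is_name: str = "d7-ropivacaine",
    analyte_limit: float = 0.20,
    is_limit: float = 0.05,
    min_lots: int = 6,
) -> pd.DataFrame:
    """Per-lot interference check against 20%-of-LLOQ / 5%-of-IS thresholds.

    ``blank_table`` holds quantifier areas of blank injections with a ``lot``
    column.  Thresholds are inclusive: a blank at exactly 20% of the LLOQ
    response passes.
    """
    rows = []
    for lot, grp in blank_table.groupby("lot", sort=True):
        a = grp.loc[
            (grp["analyte"] == analyte) & (grp["role"] == "quantifier"), "area"
        ].mean()
        i = grp.loc[
            (grp["analyte"] == is_name) & (grp["role"] == "quantifier"), "area"
        ].mean()
        a_ok = a <= analyte_limit * lloq_analyte_response
        i_ok = i <= is_limit * lloq_is_response
        rows.append(
            {
                "lot": lot,
                "blank_analyte_area": a,
                "blank_is_area": i,
                "analyte_pass": a_ok,
                "is_pass": i_ok,
                "passed": a_ok and i_ok,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["n_lots_ok"] = out["lot"].nunique() >= min_lots
    return out
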