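"""Matrix-matched calibration: weighted 1/x linear fits and their acceptance.

Quantification uses the response ratio y = analyte quantifier peak area /
internal-standard quantifier peak area against nominal concentration x
(ng/mL).  Two curves are carried in parallel: a "1:1" curve matched to the
undiluted buffer fraction and a "1:4" curve matched to the 4-fold diluted
plasma fraction.  Fits minimise sum(w_i * (y_i - a - b x_i)^2) with
w_i = 1/x_i, the standard bioanalytical down-weighting of high standards.

Curve acceptance follows common bioanalytical practice: coefficient of
determination R^2 > 0.99, back-calculated accuracy within +/-20% of nominal
at the LLOQ and +/-15% at every other level, and at least 75% of the
calibration levels meeting their band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "MRMTransition",
    "MRM_TRANSITIONS",
    "CalibrationPoint",
    "CalibrationCurve",
    "CurveAcceptance",
    "IonRatioResult",
    "fit_calibration",
    "back_calculate",
    "assess_curve",
    "ion_ratio_check",
]


@dataclass(frozen=True)
class MRMTransition:
    """One precursor->fragment transition of the MRM acquisition method."""

    analyte: str
    q1_mass: float
    q3_mass: float
    role: str  # "quantifier" | "qualifier"
    collision_energy: float
    cxp: float

    def __post_init__(self) -> None:
        if self.q1_mass <= 0 or self.q3_mass <= 0:
            raise ValueError("transition masses must be > 0")
        if self.role not in ("quantifier", "qualifier"):
            raise ValueError(f"unknown transition role {self.role!r}")


#: The acquisition method's transition table: ropivacaine and its
#: deuterated internal standard, one quantifier + one qualifier each.
MRM_TRANSITIONS: tuple[MRMTransition, ...] = (
    MRMTransition("ropivacaine", 275.1, 84.0, "quantifier", 59, 12),
    MRMTransition("ropivacaine", 275.1, 98.2, "qualifier", 55, 12),
    MRMTransition("d7-ropivacaine", 282.1, 85.1, "quantifier", 57, 10),
    MRMTransition("d7-ropivacaine", 282.1, 105.1, "qualifier", 55, 12),
)


@dataclass(frozen=True)
class CalibrationPoint:
    """One calibration standard replicate: nominal conc and response ratio."""

    nominal_conc: float
    response_ratio: float
    replicate_index: int = 0

    def __post_init__(self) -> None:
        if self.nominal_conc <= 0:
            raise ValueError("nominal concentration must be > 0 (1/x weights)")
        if self.response_ratio < 0:
            raise ValueError("response ratio must be >= 0")


@dataclass
class CalibrationCurve:
    """A fitted weighted linear calibration curve and its diagnostics.

    ``accuracy_by_level`` maps each nominal level to the mean back-calculated
    accuracy (%) of its replicates.  ``r_squared`` is the unweighted
    coefficient of determination of the fitted line on (x, y);
    ``r_squared_weighted`` applies the 1/x weights to both sums of squares.
    """

    slope: float
    intercept: float
    r_squared: float
    r_squared_weighted: float
    weighting: str = "1/x"
    dilution_label: str = ""
    n_points: int = 0
    accuracy_by_level: dict[float, float] = field(default_factory=dict)

    def predict(self, conc: float | np.ndarray) -> float | np.ndarray:
        """Expected response ratio at a nominal concentration."""
        return self.intercept + self.slope * np.asarray(conc, dtype=float)


class SingularCurveError(ValueError):
    """Raised when the calibration design cannot identify slope and intercept."""


def _weights(x: np.ndarray, weighting: str) -> np.ndarray:
    if weighting == "1/x":
        return 1.0 / x
    if weighting == "1/x2":
        return 1.0 / x**2
    if weighting in ("none", None):
        return np.ones_like(x)
    raise ValueError(f"unsupported weighting {weighting!r}")


def fit_calibration(
    points: list[CalibrationPoint] | pd.DataFrame,
    weighting: str = "1/x",
    dilution_label: str = "",
) -> CalibrationCurve:
    """Fit the weighted linear calibration curve.

    Parameters
    ----------
    points:
        Calibration standards, either ``CalibrationPoint`` objects or a
        DataFrame with columns ``nominal_conc`` and ``response_ratio``.
        Replicates enter as individual points (no pre-averaging), which
        preserves the weighting semantics.
    weighting:
        ``"1/x"`` (default), ``"1/x2"``, or ``"none"``.

    Raises
    ------
    SingularCurveError
        With fewer than two distinct nominal levels.
    ValueError
        For non-positive nominal concentrations.
    """
    if isinstance(points, pd.DataFrame):
        x = points["nominal_conc"].to_numpy(dtype=float)
        y = points["response_ratio"].to_numpy(dtype=float)
    else:
        x = np.array([p.nominal_conc for p in points], dtype=float)
        y = np.array([p.response_ratio for p in points], dtype=float)

    if np.any(x <= 0):
        raise ValueError("all nominal concentrations must be > 0")
    if np.unique(x).size < 2:
        raise SingularCurveError("need >= 2 distinct nominal levels to fit a line")

    w = _weights(x, weighting)
    # centre the predictor before solving: with x spanning 0.05-1000 the raw
    # [1, x] design is ill-conditioned and costs ~5 digits of the intercept
    x_wmean = float(np.sum(w * x) / np.sum(w))
    model = sm.WLS(y, sm.add_constant(x - x_wmean), weights=w).fit()
    slope = float(model.params[1])
    intercept = float(model.params[0]) - slope * x_wmean

    yhat = intercept + slope * x
    resid = y - yhat

    def _r2(weights: np.ndarray) -> float:
        ss_res = float(np.sum(weights * resid**2))
        ybar = float(np.sum(weights * y) / np.sum(weights))
        ss_tot = float(np.sum(weights * (y - ybar) ** 2))
        return 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    curve = CalibrationCurve(
        slope=slope,
        intercept=intercept,
        r_squared=_r2(np.ones_like(w)),
        r_squared_weighted=_r2(w),
        weighting=weighting,
        dilution_label=dilution_label,
        n_points=int(x.size),
    )

    back = (y - intercept) / slope if slope != 0 else np.full_like(y, np.nan)
    for level in np.unique(x):
        sel = x == level
        curve.accuracy_by_level[float(level)] = float(
            100.0 * np.mean(back[sel]) / level
        )
    return curve


def back_calculate(
    curve: CalibrationCurve,
    response_ratio: float | np.ndarray,
) -> tuple[np.ndarray, np.ndarray] | tuple[float, bool]:
    """Invert the curve: analyzed concentration for a response ratio.

    ``analyzed = (ratio - intercept) / slope``; negative results are clamped
    to 0 and flagged (they arise from blank-level noise below the intercept).

    Returns
    -------
    ``(conc, below_zero_flag)`` — scalars for scalar input, arrays otherwise.
    """
    if curve.slope == 0:
        raise ZeroDivisionError("calibration slope is zero; cannot back-calculate")
    ratio = np.asarray(response_ratio, dtype=float)
    conc = (ratio - curve.intercept) / curve.slope
    flag = conc < 0
    conc = np.where(flag, 0.0, conc)
    if np.isscalar(response_ratio) or ratio.ndim == 0:
        return float(conc), bool(flag)
    return conc, flag


@dataclass
class CurveAcceptance:
    """Outcome of calibration-curve acceptance assessment."""

    r_squared: float
    r2_pass: bool
    level_accuracy: dict[float, float]
    level_pass: dict[float, bool]
    fraction_levels_passing: float
    accepted: bool


def assess_curve(
    curve: CalibrationCurve,
    lloq: float | None = None,
    r2_min: float = 0.99,
    band_lloq: float = 20.0,
    band_other: float = 15.0,
    min_fraction: float = 0.75,
) -> CurveAcceptance:
    """Apply curve acceptance: R^2 and per-level back-calculated accuracy bands.

    The LLOQ level (lowest level unless given) must be within +/-``band_lloq``
    % of nominal, every other level within +/-``band_other`` %; the curve is
    accepted iff R^2 > ``r2_min`` and at least ``min_fraction`` of the levels
    meet their band.  Band edges are inclusive.
    """
    levels = sorted(curve.accuracy_by_level)
    if not levels:
        raise ValueError("curve has no back-calculated level accuracies")
    if lloq is None:
        lloq = levels[0]

    level_pass: dict[float, bool] = {}
    for level in levels:
        band = band_lloq if level == lloq else band_other
        acc = curve.accuracy_by_level[level]
        level_pass[level] = abs(acc - 100.0) <= band

    frac = sum(level_pass.values()) / len(levels)
    r2_ok = curve.r_squared > r2_min
    return CurveAcceptance(
        r_squared=curve.r_squared,
        r2_pass=r2_ok,
        level_accuracy=dict(curve.accuracy_by_level),
        level_pass=level_pass,
        fraction_levels_passing=frac,
        accepted=r2_ok and frac >= min_fraction,
    )


@dataclass(frozen=True)
class IonRatioResult:
    passed: bool
    observed_ratio: float | None
    reference_ratio: float
    reason: str = ""


def ion_ratio_check(
    quantifier_area: float,
    qualifier_area: float,
    reference_ratio: float,
    tolerance_frac: float = 0.30,
) -> IonRatioResult:
    """Confirm analyte identity via the qualifier/quantifier area ratio.

    The observed ratio must agree with the reference ratio (mean of passing
    standards) within ``tolerance_frac`` relative (+/-30% by default, a common
    bioanalytical convention).  A zero qualifier area fails with a distinct
    reason rather than dividing by zero.
    """
    if reference_ratio <= 0:
        raise ValueError("reference ion ratio must be > 0")
    if qualifier_area <= 0:
        return IonRatioResult(False, None, reference_ratio, reason="zero-qualifier-area")
    if quantifier_area <= 0:
        return IonRatioResult(False, None, reference_ratio, reason="zero-quantifier-area")
    observed = qualifier_area / quantifier_area
    ok = abs(observed / reference_ratio - 1.0) <= tolerance_frac
    return IonRatioResult(ok, observed, reference_ratio, reason="" if ok else "outside-tolerance")
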