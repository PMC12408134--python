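"""Back-calculation of free, bound, and total drug in the original plasma.

After RED, the buffer chamber holds only free drug at the common equilibrium
free concentration, while the plasma chamber holds that free concentration
plus everything still protein-bound.  Writing ``B`` for the analyzed buffer-
fraction concentration and ``P`` for the analyzed plasma-fraction
concentration (both chamber-level, because each fraction is quantified
against its own identically prepared matrix-matched curve), amount
bookkeeping over the two chambers gives, per mL of original plasma:

    free  = B * (V_plasma + V_buffer) / V_plasma     (all free drug, both chambers)
    bound = P - B                                    (plasma chamber minus its free part)
    total = P + (V_buffer / V_plasma) * B            (everything, re-referenced to plasma)

and ``total == free + bound`` holds as an exact algebraic identity.  Note
that ``free`` is the free amount liberated at dialysis equilibrium re-
referenced to the plasma volume; with linear binding it equals
``fu * (V_plasma + V_buffer) / (V_plasma + fu * V_buffer) * total``, which is
slightly larger than ``fu * total`` because dialysis pulls bound drug free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .geometry import REDGeometry

__all__ = ["FractionResult", "original_concentrations", "combine_fractions", "fractionate_table"]


@dataclass
class FractionResult:
    """Free/bound/total concentrations (ng/mL) in one original plasma specimen."""

    free_conc: float
    bound_conc: float
    total_conc: float
    flags: list[str] = field(default_factory=list)


def original_concentrations(
    c_plasma_chamber: float,
    c_buffer_chamber: float,
    geometry: REDGeometry,
) -> FractionResult:
    """Convert the two analyzed chamber concentrations to original-plasma terms.

    Negative bound (buffer reading above plasma reading, possible under noise
    near the LLOQ) is clamped to 0 and flagged ``negative-bound``; the total
    is then reported as ``free`` alone so that ``total == free + bound``
    survives clamping.
    """
    if c_plasma_chamber < 0 or c_buffer_chamber < 0:
        raise ValueError("chamber concentrations must be >= 0 (clamp upstream)")

    vp, vb = geometry.v_plasma, geometry.v_buffer
    free = c_buffer_chamber * (vp + vb) / vp
    bound = c_plasma_chamber - c_buffer_chamber
    flags: list[str] = []
    if bound < 0:
        bound = 0.0
        flags.append("negative-bound")
    return FractionResult(free, bound, free + bound, flags)


def combine_fractions(free: float, bound: float) -> float:
    """Total concentration as the sum of the free and bound fractions."""
    if free < 0 or bound < 0:
        raise ValueError("fractions must be >= 0")
    return free + bound


def fractionate_table(
    analyzed: pd.DataFrame,
    geometry: REDGeometry,
    specimen_col: str = "specimen_id",
) -> pd.DataFrame:
    """Apply :func:`original_concentrations` to a table of analyzed fractions.

    Parameters
    ----------
    analyzed:
        One row per analyzed fraction, columns ``specimen_id``,
        ``compartment`` (plasma|buffer) and ``analyzed_ng_ml``.  Every
        specimen must contribute exactly one plasma and one buffer row.

    Returns
    -------
    DataFrame with columns ``specimen_id, free_ng_ml, bound_ng_ml,
    total_ng_ml, flags``.
    """
    required = {specimen_col, "compartment", "analyzed_ng_ml"}
    missing = required - set(analyzed.columns)
    if missing:
        raise ValueError(f"analyzed table is missing columns: {sorted(missing)}")

    rows = []
    for specimen, grp in analyzed.groupby(specimen_col, sort=True):
        by_comp = grp.set_index("compartment")["analyzed_ng_ml"]
        if "plasma" not in by_comp.index or "buffer" not in by_comp.index:
            raise ValueError(
                f"specimen {specimen!r} lacks a plasma and/or buffer fraction"
            )
        res = original_concentrations(
            float(by_comp["plasma"]), float(by_comp["buffer"]), geometry
        )
        rows.append(
            {
                specimen_col: specimen,
                "free_ng_ml": res.free_conc,
                "bound_ng_ml": res.bound_conc,
                "total_ng_ml": res.total_conc,
                "flags": ";".join(res.flags),
            }
        )
    return pd.DataFrame(rows)
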