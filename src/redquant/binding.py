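"""Plasma protein binding models and the RED equilibrium endpoint.

Two binding models are supported:

* ``linear`` — the bound/free concentration ratio in plasma is constant,
  ``bound/free = (1 - fu) / fu`` where ``fu`` is the fraction unbound in
  undialyzed plasma.  This is the usual regime for drugs far below binding
  capacity and has a closed-form dialysis equilibrium.
* ``saturable`` — a single-site Langmuir isotherm,
  ``bound = bmax * free / (kd + free)``, solved numerically.

The equilibrium endpoint assumes dialysis runs to completion with no volume
shift across the membrane: the free concentration is equal in both chambers
and the total drug amount spiked into the plasma chamber is conserved.
"""

from __future__ import annotations

from typing import Literal

from pydantic import BaseModel, model_validator
from scipy.optimize import brentq

from .geometry import REDGeometry

__all__ = ["BindingModel", "EquilibriumError", "simulate_red_equilibrium"]

#: relative mass-balance tolerance for the saturable solver
_MASS_TOL = 1e-9


class EquilibriumError(RuntimeError):
    """Raised when the saturable equilibrium solver fails to converge."""


class BindingModel(BaseModel):
    """Protein binding of the analyte in plasma.

    Parameters
    ----------
    mode:
        ``"linear"`` (constant bound/free ratio) or ``"saturable"``
        (Langmuir single-site isotherm).
    fu:
        Fraction unbound in undialyzed plasma, 0 < fu <= 1 (linear mode).
    bmax, kd:
        Binding capacity and dissociation constant in ng/mL (saturable mode).
    """

    mode: Literal["linear", "saturable"] = "linear"
    fu: float = 0.05
    bmax: float | None = None
    kd: float | None = None

    @model_validator(mode="after")
    def _check(self) -> "BindingModel":
        if self.mode == "linear":
            if not (0.0 < self.fu <= 1.0):
                raise ValueError("fu must be in (0, 1]")
        else:
            if self.bmax is None or self.kd is None:
                raise ValueError("saturable mode requires bmax and kd")
            if self.bmax < 0 or self.kd <= 0:
                raise ValueError("bmax must be >= 0 and kd > 0")
        return self

    def bound_conc(self, free: float) -> float:
        """Bound concentration in plasma at a given free concentration."""
        if free < 0:
            raise ValueError("free concentration must be >= 0")
        if self.mode == "linear":
            return free * (1.0 - self.fu) / self.fu
        return self.bmax * free / (self.kd + free)


def simulate_red_equilibrium(
    total_plasma_conc: float,
    binding: BindingModel,
    geometry: REDGeometry,
) -> tuple[float, float]:
    """Chamber concentrations after complete RED equilibration.

    Solves the mass balance for the common free concentration ``f``::

        (f + bound(f)) * V_plasma + f * V_buffer = total * V_plasma

    The plasma chamber then holds ``f + bound(f)`` and the buffer chamber
    holds ``f``.  Linear binding has the closed form
    ``f = total * V_plasma / (V_plasma / fu + V_buffer)``.

    Parameters
    ----------
    total_plasma_conc:
        Total analyte concentration (ng/mL) spiked into the plasma chamber.

    Returns
    -------
    (chamber_plasma_conc, chamber_buffer_conc) in ng/mL.

    Raises
    ------
    ValueError
        For a negative input concentration.
    EquilibriumError
        If the saturable solver cannot reach |mass residual| <= 1e-9 of the
        total amount.
    """
    if total_plasma_conc < 0:
        raise ValueError("total plasma concentration must be >= 0")
    if total_plasma_conc == 0:
        return 0.0, 0.0

    vp, vb = geometry.v_plasma, geometry.v_buffer
    amount = total_plasma_conc * vp

    if binding.mode == "linear":
        free = amount / (vp / binding.fu + vb)
    else:
        def residual(f: float) -> float:
            return (f + binding.bound_conc(f)) * vp + f * vb - amount

        try:
            free = brentq(
                residual, 0.0, total_plasma_conc, xtol=1e-15, rtol=8.9e-16, maxiter=200
            )
        except (RuntimeError, ValueError) as exc:  # pragma: no cover - defensive
            raise EquilibriumError(f"saturable equilibrium solve failed: {exc}") from exc
        if abs(residual(free)) > _MASS_TOL * amount:
            raise EquilibriumError(
                "saturable equilibrium solve did not meet the mass-balance tolerance"
            )

    plasma_chamber = free + binding.bound_conc(free)
    return plasma_chamber, free
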