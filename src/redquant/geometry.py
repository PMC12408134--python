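"""Rapid-equilibrium-dialysis (RED) device geometry and sample-prep volume chain.

A RED insert holds two chambers separated by a dialysis membrane: a plasma
chamber (``v_plasma``) and a buffer chamber (``v_buffer``).  Free drug
equilibrates across the membrane while protein-bound drug stays on the plasma
side.  After dialysis a fixed aliquot from each chamber is carried through a
matrix-complementation / acidification / internal-standard / protein-
precipitation chain, and the plasma fraction receives one extra post-
precipitation dilution so that the very different bound and free
concentrations both land inside the calibrated range.

All volumes are in microlitres and concentrations in ng/mL throughout the
package.
"""

from __future__ import annotations

from pydantic import BaseModel, field_validator

__all__ = ["REDGeometry", "chamber_free_partition", "dilution_chain"]

#: Compartment labels used throughout manifests and results.
PLASMA = "plasma"
BUFFER = "buffer"


class REDGeometry(BaseModel):
    """Chamber and prep volumes governing partition shares and dilution factors.

    Defaults are the volumes of the workflow this package models: 200 uL
    plasma vs 333 uL buffer chambers; a 25 uL chamber aliquot complemented
    with 25 uL of the opposite matrix, 5 uL acid, 2.25 uL internal-standard
    working solution and 170 uL acetonitrile; and a 4-fold post-precipitation
    dilution of the plasma fraction only ("1:4" read as 1 part + 3 parts).
    """

    v_plasma: float = 200.0
    v_buffer: float = 333.0
    v_aliquot: float = 25.0
    v_complement: float = 25.0
    v_acid: float = 5.0
    v_is: float = 2.25
    v_acn: float = 170.0
    plasma_post_dilution_factor: float = 4.0

    @field_validator(
        "v_plasma", "v_buffer", "v_aliquot", "v_complement", "v_acid",
        "v_is", "v_acn", "plasma_post_dilution_factor",
    )
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("all RED geometry volumes/factors must be > 0")
        return v

    @property
    def prep_volume(self) -> float:
        """Final extract volume of one prepared chamber aliquot (uL)."""
        return self.v_aliquot + self.v_complement + self.v_acid + self.v_is + self.v_acn


def chamber_free_partition(geometry: REDGeometry) -> tuple[float, float]:
    """Volume shares of the *free* drug amount held by each chamber at equilibrium.

    Because the free concentration is identical on both sides of the membrane
    at equilibrium, the free amount splits in proportion to chamber volume:

        plasma_share = V_plasma / (V_plasma + V_buffer)
        buffer_share = V_buffer / (V_plasma + V_buffer)

    For the default 200/333 uL chambers this is (0.375, 0.625): the buffer
    chamber holds 62.5% of the absolute free amount.

    Returns
    -------
    (plasma_share, buffer_share), summing to 1 exactly.
    """
    total = geometry.v_plasma + geometry.v_buffer
    plasma_share = geometry.v_plasma / total
    return plasma_share, 1.0 - plasma_share


def dilution_chain(compartment: str, geometry: REDGeometry) -> float:
    """Overall concentration dilution factor from chamber to injected extract.

    The 25 uL chamber aliquot ends up in ``prep_volume`` uL of extract, a
    factor of 227.25/25 = 9.09 for the default volumes.  The plasma fraction
    is additionally diluted ``plasma_post_dilution_factor``-fold (x4) after
    precipitation; the buffer fraction is injected undiluted.

    Parameters
    ----------
    compartment:
        ``"plasma"`` or ``"buffer"``.

    Returns
    -------
    factor such that ``injected_conc = chamber_conc / factor``.
    """
    base = geometry.prep_volume / geometry.v_aliquot
    if compartment == BUFFER:
        return base
    if compartment == PLASMA:
        return base * geometry.plasma_post_dilution_factor
    raise ValueError(f"unknown compartment {compartment!r}; expected 'plasma' or 'buffer'")
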