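"""Scalar dose conversions from the intravenous benchmark dose to reported doses.

Three linear conversions close the extrapolation: i.v. -> oral through an
oral bioavailability factor F (dose_oral = dose_iv / F; human default
F = 0.65, rat default F = 0.35), per-kg -> total through body weight
(default 73 kg), and free -> total dose through plasma protein binding
(Fu = 0.06).

The free-dose correction exists in two conventions.  ``fraction_standard``
divides by the unbound fraction (dose / Fu), which is the dimensionally
standard form.  ``paper_printed`` multiplies by 100 / Fu, the convention in
which a published summary table of this analysis is stated; it is retained so
that the published table column can be reproduced verbatim, and every result
records which convention produced it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "ConversionFactors",
    "iv_to_oral",
    "perkg_to_total",
    "free_to_total",
    "oral_dose_summary",
    "total_oral_dose_table",
]

logger = logging.getLogger(__name__)

CONVENTIONS = ("paper_printed", "fraction_standard")


@dataclass(frozen=True)
class ConversionFactors:
    """Scalar factors of the dose-conversion chain."""

    oral_bioavailability: float = 0.65  # human default; rat: 0.35
    body_weight: float = 73.0  # kg
    fu_plasma: float = 0.06
    free_correction_convention: str = "fraction_standard"

    def __post_init__(self) -> None:
        if not 0 < self.oral_bioavailability <= 1:
            raise ValueError("oral bioavailability must be in (0, 1]")
        if self.body_weight <= 0:
            raise ValueError("body_weight must be > 0")
        if not 0 < self.fu_plasma <= 1:
            raise ValueError("fu_plasma must be in (0, 1]")
        if self.free_correction_convention not in CONVENTIONS:
            raise ValueError(
                f"unknown convention {self.free_correction_convention!r}"
            )


def iv_to_oral(dose_iv: float, bioavailability: float) -> float:
    """Convert an i.v. dose (mg/kg) to the equivalent oral dose (mg/kg)."""
    if not 0 < bioavailability <= 1:
        raise ValueError("bioavailability must be in (0, 1]")
    return dose_iv / bioavailability


def perkg_to_total(dose_per_kg: float, body_weight: float) -> float:
    """Convert a weight-normalized dose (mg/kg) to a total dose (mg)."""
    if body_weight <= 0:
        raise ValueError("body_weight must be > 0")
    return dose_per_kg * body_weight


def free_to_total(dose_free: float, fu: float, convention: str) -> float:
    """Correct a free-drug dose for plasma protein binding.

    ``fraction_standard``: dose / fu.  ``paper_printed``: dose * 100 / fu
    (the published-table convention; dimensionally irregular but retained for
    verbatim reproduction).
    """
    if not 0 < fu <= 1:
        raise ValueError("fu must be in (0, 1]")
    if convention == "fraction_standard":
        return dose_free / fu
    if convention == "paper_printed":
        return dose_free * 100.0 / fu
    raise ValueError(f"unknown convention {convention!r}")


def oral_dose_summary(
    dose_iv_per_kg: float, factors: ConversionFactors
) -> dict[str, float]:
    """Oral mg/kg and total mg for an i.v. dose, with report-style rounding.

    Raw unrounded values are kept alongside the rounded report values
    (mg/kg to 2 decimals, totals to 1 decimal).
    """
    oral = iv_to_oral(dose_iv_per_kg, factors.oral_bioavailability)
    total = perkg_to_total(oral, factors.body_weight)
    return {
        "iv_mg_per_kg": dose_iv_per_kg,
        "oral_mg_per_kg": oral,
        "total_mg": total,
        "oral_mg_per_kg_rounded": round(oral, 2),
        "total_mg_rounded": round(total, 1),
    }


def total_oral_dose_table(
    bmdu_iv_auc: float,
    bmdu_iv_cmax: float,
    bmdu_oral_free_nominal: float,
    factors: ConversionFactors = ConversionFactors(),
) -> pd.DataFrame:
    """Total human oral doses for the three metric approaches.

    The AUC and Cmax rows take i.v. BMDU values in mg/kg; the nominal row
    takes an oral free-drug BMDU in mg and applies the protein-binding
    correction in the published-table convention (a notice is logged because
    that convention is dimensionally irregular).
    """
    rows = []
    for approach, bmdu in (("AUC", bmdu_iv_auc), ("Cmax", bmdu_iv_cmax)):
        s = oral_dose_summary(bmdu, factors)
        rows.append(
            {
                "approach": approach,
                "bmdu_input": bmdu,
                "oral_mg_per_kg": s["oral_mg_per_kg"],
                "total_oral_dose_mg": s["total_mg"],
                "convention": "iv_to_oral/perkg_to_total",
            }
        )
    logger.info(
        "nominal row uses the published-table free-dose convention (x100/Fu)"
    )
    rows.append(
        {
            "approach": "nominal",
            "bmdu_input": bmdu_oral_free_nominal,
            "oral_mg_per_kg": free_to_total(
                bmdu_oral_free_nominal, factors.fu_plasma, "paper_printed"
            )
            / factors.body_weight,
            "total_oral_dose_mg": free_to_total(
                bmdu_oral_free_nominal, factors.fu_plasma, "paper_printed"
            ),
            "convention": "paper_printed",
        }
    )
    return pd.DataFrame(rows)
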