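"""Internal-standard relative quantitation normalized to total lipid
phosphate.

Amounts are reported both as pmol per sample and as pmol per nmol total
lipid phosphate (the phosphate assay value is an input, not computed here).
Response factors default to 1.0 for every species; a hook is provided for
per-species factors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "SampleMeta",
    "DEFAULT_STANDARD",
    "SECONDARY_STANDARD",
    "LINEAR_RANGE_PMOL",
    "quantify_species",
    "total_class_amount",
    "check_linear_range",
]

DEFAULT_STANDARD = "PA(17:0/14:1)"
SECONDARY_STANDARD = "PA(12:0/13:0)"

#: Verified linear response range for PA standards (1 fmol .. 12 pmol).
LINEAR_RANGE_PMOL = (0.001, 12.0)

FLAG_OK = "ok"
FLAG_LOW = "below_linear_range"
FLAG_HIGH = "above_linear_range"
FLAG_NOT_DETECTED = "not_detected"


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata: group, spiked standards and phosphate assay."""

    sample_id: str
    group: str
    replicate: int
    is_amounts: Mapping[str, float]  # standard species name -> pmol spiked
    total_phosphate_nmol: float

    def __post_init__(self) -> None:
        if self.total_phosphate_nmol <= 0:
            raise ValueError("total_phosphate_nmol must be > 0")
        if not self.is_amounts:
            raise ValueError("at least one internal standard amount is required")
        for name, pmol in self.is_amounts.items():
            if pmol <= 0:
                raise ValueError(f"standard {name} amount must be > 0")


def check_linear_range(
    amount_pmol: float,
    lo: float = LINEAR_RANGE_PMOL[0],
    hi: float = LINEAR_RANGE_PMOL[1],
) -> str:
    """Flag amounts outside the verified linear response range."""
    if amount_pmol < lo:
        return FLAG_LOW
    if amount_pmol > hi:
        return FLAG_HIGH
    return FLAG_OK


def quantify_species(
    areas: pd.DataFrame,
    meta: Sequence[SampleMeta],
    standard: str = DEFAULT_STANDARD,
    response_factors: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """Ratio-based quantitation against one spiked internal standard.

    ``areas`` must have columns ``sample_id``, ``species``, ``area``.  For
    each sample, ``amount_pmol = area_species / area_standard * spiked_pmol``
    and ``amount_per_phosphate = amount_pmol / total_phosphate_nmol``.

    Returns a long-format table with columns sample_id, group, species,
    amount_pmol, amount_per_phosphate, flag.
    """
    required = {"sample_id", "species", "area"}
    missing = required - set(areas.columns)
    if missing:
        raise ValueError(f"areas table lacks columns {sorted(missing)}")
    meta_by_id = {m.sample_id: m for m in meta}
    factors = dict(response_factors or {})

    rows = []
    for sample_id, sample_areas in areas.groupby("sample_id", sort=True):
        if sample_id not in meta_by_id:
            raise ValueError(f"no metadata for sample {sample_id!r}")
        sample_meta = meta_by_id[sample_id]
        if standard not in sample_meta.is_amounts:
            raise ValueError(
                f"sample {sample_id!r} has no spiked amount for standard {standard!r}"
            )
        std_rows = sample_areas[sample_areas["species"] == standard]
        if std_rows.empty:
            raise ValueError(
                f"internal standard {standard!r} not found in sample {sample_id!r}"
            )
        std_area = float(std_rows["area"].sum())
        if std_area <= 0:
            raise ValueError(
                f"internal standard {standard!r} has zero area in sample "
                f"{sample_id!r}"
            )
        spiked_pmol = sample_meta.is_amounts[standard]

        for _, row in sample_areas.iterrows():
            species = row["species"]
            if species == standard:
                continue
            factor = factors.get(species, 1.0)
            amount_pmol = float(row["area"]) / std_area * spiked_pmol / factor
            flag = check_linear_range(amount_pmol)
            if float(row["area"]) == 0.0:
                flag = FLAG_NOT_DETECTED
                amount_pmol = 0.0
            rows.append(
                {
                    "sample_id": sample_id,
                    "group": sample_meta.group,
                    "species": species,
                    "amount_pmol": amount_pmol,
                    "amount_per_phosphate":
                        amount_pmol / sample_meta.total_phosphate_nmol,
                    "flag": flag,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["sample_id", "group", "species", "amount_pmol",
                 "amount_per_phosphate", "flag"],
    )


def total_class_amount(results: pd.DataFrame) -> pd.DataFrame:
    """Per-sample total over all species, in the same units."""
    if results.empty:
        warnings.warn("total_class_amount called on an empty quantitation table")
        return pd.DataFrame(
            columns=["sample_id", "group", "total_pmol", "total_per_phosphate"]
        )
    grouped = results.groupby(["sample_id", "group"], sort=True).agg(
        total_pmol=("amount_pmol", "sum"),
        total_per_phosphate=("amount_per_phosphate", "sum"),
    )
    return grouped.reset_index()
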