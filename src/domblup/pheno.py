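"""Phenotype pre-adjustment and derived-trait construction.

Yield deviations arrive already corrected for age/parity and herd-management
effects; the remaining printed corrections are linear regressions on
inbreeding percentage and heterosis, applied here.  Component-percentage
traits (fat%, protein%) are derived from milk and component yield deviations
around published base-cow means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AdjustmentCoefficients",
    "DEFAULT_COEFFICIENTS",
    "BASE_MEANS",
    "adjust_phenotype",
    "derive_percent_deviation",
    "collapse_smgs_groups",
]


@dataclass
class AdjustmentCoefficients:
    """Regression coefficients for inbreeding (per %) and heterosis (per unit)."""

    b_inbreeding: float
    b_heterosis: float

    def __post_init__(self):
        if not (np.isfinite(self.b_inbreeding) and np.isfinite(self.b_heterosis)):
            raise ValueError("adjustment coefficients must be finite")


# Published multi-breed regression coefficients per trait.
DEFAULT_COEFFICIENTS: dict[str, AdjustmentCoefficients] = {
    "milk": AdjustmentCoefficients(-66.12, 172.23),
    "fat": AdjustmentCoefficients(-2.47, 22.12),
    "protein": AdjustmentCoefficients(-1.96, 11.29),
    "pl": AdjustmentCoefficients(-0.268, 0.349),
    "dpr": AdjustmentCoefficients(-0.072, 1.973),
    "scs": AdjustmentCoefficients(0.004, 0.019),
}

# Base-cow trait means (kg) used for percentage-trait derivation.
BASE_MEANS: dict[str, dict[str, float]] = {
    "holstein": {"milk": 11839.0, "fat": 432.0, "protein": 396.0},
    "jersey": {"milk": 8379.0, "fat": 384.0, "protein": 298.0},
}


def adjust_phenotype(y, inbreeding, heterosis, coeffs: AdjustmentCoefficients):
    """y_adj = y - b_inbreeding * inbreeding - b_heterosis * heterosis.

    Vectorized over numpy arrays / pandas Series.
    """
    return y - coeffs.b_inbreeding * inbreeding - coeffs.b_heterosis * heterosis


def derive_percent_deviation(milk_dev, comp_dev, base_milk, base_comp):
    """Component-percentage yield deviation from milk/component deviations.

    percent_dev = ((base_comp + comp_dev) / (base_milk + milk_dev)
                   - base_comp / base_milk) * 100
    """
    milk_dev = np.asarray(milk_dev, dtype=float)
    denom = base_milk + milk_dev
    if base_milk <= 0 or np.any(denom <= 0):
        raise ValueError("base milk plus milk deviation must be positive")
    comp_dev = np.asarray(comp_dev, dtype=float)
    out = ((base_comp + comp_dev) / denom - base_comp / base_milk) * 100.0
    return float(out) if out.ndim == 0 else out


def collapse_smgs_groups(
    daughter_records: pd.DataFrame, min_group_size: int
) -> pd.DataFrame:
    """Collapse daughter records to one mean record per (sire, MGS) pair.

    Pairs with fewer than ``min_group_size`` daughters are dropped (count
    logged).  Returns columns sire, mgs, phenotype (arithmetic mean of the
    daughters) and n_daughters.
    """
    if len(daughter_records) == 0:
        raise ValueError("no daughter records to collapse")
    grouped = (
        daughter_records.groupby(["sire", "mgs"], sort=True)["phenotype"]
        .agg(["mean", "size"])
        .reset_index()
        .rename(columns={"mean": "phenotype", "size": "n_daughters"})
    )
    keep = grouped["n_daughters"] >= min_group_size
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "dropping %d sire-MGS groups with fewer than %d daughters",
            n_dropped,
            min_group_size,
        )
    out = grouped[keep].reset_index(drop=True)
    out["group"] = "SMGS"
    return out
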