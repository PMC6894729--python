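"""Phenotype adjustment and strain-by-sex summaries.

Individual-level records are adjusted for age by regressing each trait on
log10(age) within sex (or pooled with a sex cofactor) and adding the
residuals back to the group mean, so corrected values read as values at a
typical age.  Outliers can be winsorized to a bound rather than dropped,
and strain-by-sex summaries (mean, SE, n) feed the heritability and mapping
stages.  Derived cortical quantities follow the standard uCT conventions
for a 100-slice (0.8 mm) midshaft segment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "log_age_correct",
    "winsorize",
    "strain_summaries",
    "derive_microct",
    "TraitSummary",
]


def _ols_residuals(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def log_age_correct(
    table: pd.DataFrame,
    trait: str,
    grouping: str = "per-sex",
    adjust_weight: bool = False,
) -> pd.DataFrame:
    """Remove the log10(age) trend from a trait.

    ``grouping='per-sex'`` fits trait ~ log10(age) separately for females
    and males and adds residuals to the per-sex grand mean.
    ``grouping='pooled'`` fits trait ~ sex + log10(age) across the whole
    table (no strain grouping) and adds residuals to the grand mean, giving
    sex-averaged corrected values.  ``adjust_weight`` co-adjusts for body
    weight (a robustness variant; off by default because body size is itself
    a variable of interest).

    Returns a copy of the table with the trait column replaced by corrected
    values and the original kept as ``<trait>_raw``.  Record order is
    preserved.  If all ages in a group are equal the slope is treated as 0
    and values pass through unchanged.
    """
    if grouping not in ("per-sex", "pooled"):
        raise ValueError(f"unknown grouping {grouping!r}")
    if (table["age_days"] <= 0).any():
        raise ValueError("ages must be positive")
    out = table.copy()
    out[f"{trait}_raw"] = out[trait]
    logage = np.log10(out["age_days"].to_numpy(float))
    y_all = out[trait].to_numpy(float)
    corrected = np.array(y_all, dtype=float)

    def correct_group(mask: np.ndarray) -> None:
        y = y_all[mask]
        if mask.sum() < 3:
            raise ValueError(f"fewer than 3 records in group (got {int(mask.sum())})")
        cols = [np.ones(mask.sum()), logage[mask]]
        if grouping == "pooled":
            cols.insert(1, (out.loc[mask, "sex"] == "M").to_numpy(float))
        if adjust_weight:
            cols.append(out.loc[mask, "weight_g"].to_numpy(float))
        X = np.column_stack(cols)
        if np.ptp(logage[mask]) == 0 and not adjust_weight:
            corrected[mask] = y  # no regressor variance: slope treated as 0
            return
        resid = _ols_residuals(y, X)
        corrected[mask] = resid + y.mean()

    if grouping == "per-sex":
        for sex in ("F", "M"):
            mask = (out["sex"] == sex).to_numpy()
            if mask.any():
                correct_group(mask)
    else:
        correct_group(np.ones(len(out), dtype=bool))
    out[trait] = corrected
    return out


def winsorize(
    values,
    bounds: tuple[float | None, float | None] | None = None,
    k_sd: float | None = None,
):
    """Clip outliers to a boundary value instead of dropping them.

    Either explicit ``bounds=(lower, upper)`` (None for an open side) or a
    ``k_sd`` rule, where the bounds are mean +/- k * SD of the input vector.
    Returns ``(winsorized array, n_replaced)``; every replacement is logged
    with the original value so provenance is never lost.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty vector")
    if bounds is None and k_sd is None:
        raise ValueError("provide bounds or k_sd")
    if k_sd is not None:
        mu, sd = float(np.mean(x)), float(np.std(x, ddof=1))
        lower, upper = mu - k_sd * sd, mu + k_sd * sd
    else:
        lower, upper = bounds
        lower = -np.inf if lower is None else lower
        upper = np.inf if upper is None else upper
    if lower > upper:
        raise ValueError(f"lower bound {lower} exceeds upper bound {upper}")
    clipped = np.clip(x, lower, upper)
    changed = np.flatnonzero(clipped != x)
    for i in changed:
        log.warning("winsorized value %g -> %g at index %d", x[i], clipped[i], i)
    return clipped, int(changed.size)


@dataclass
class TraitSummary:
    """Strain-by-sex trait summary: mean +/- SE with the cell size."""

    strain: str
    sex: str  # "F", "M" or "pooled"
    mean: float
    se: float  # NaN when n == 1
    n: int


def strain_summaries(
    table: pd.DataFrame, trait: str, by_sex: bool = True
) -> list[TraitSummary]:
    """Per strain (x sex) mean, SE = SD/sqrt(n) and n.

    Single-record cells are retained with SE reported as missing.
    """
    keys = ["strain", "sex"] if by_sex else ["strain"]
    out = []
    for key, sub in table.groupby(keys, sort=True):
        vals = sub[trait].dropna().to_numpy(float)
        if vals.size == 0:
            continue
        se = float(np.std(vals, ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else np.nan
        strain = key[0] if by_sex else key[0]
        sex = key[1] if by_sex else "pooled"
        out.append(TraitSummary(strain, sex, float(np.mean(vals)), se, int(vals.size)))
    return out


def strain_means(table: pd.DataFrame, trait: str) -> pd.Series:
    """Strain means of a trait (pooled over sexes), indexed by strain."""
    return table.groupby("strain")[trait].mean()


#: 100 slices at 8 um give a 0.8 mm segment; volumes (mm^3) divide by 0.8 mm
#: to yield cross-sectional areas (mm^2).
_SEGMENT_LENGTH_MM = 0.008 * 100


def derive_microct(record: dict) -> dict:
    """Derived cortical quantities from CSV, Ct.V and BV/TV.

    Ct.Porosity = (1 - BV/TV) * 100 (%), CSA = CSV / 0.8 (mm^2),
    Ct.Ar = Ct.V / 0.8, Ct.Ma.V = CSV - Ct.V, Ct.Ma.Ar = Ct.Ma.V / 0.8.
    """
    csv = float(record["CSV"])
    ctv = float(record["Ct.V"])
    bvtv = float(record["Ct.BV/TV"])
    if csv < 0 or ctv < 0:
        raise ValueError("volumes must be nonnegative")
    if not 0.0 <= bvtv <= 1.0:
        raise ValueError(f"BV/TV must be in [0, 1], got {bvtv}")
    out = dict(record)
    out["Ct.Porosity"] = (1.0 - bvtv) * 100.0
    out["CSA"] = csv / _SEGMENT_LENGTH_MM
    out["Ct.Ar"] = ctv / _SEGMENT_LENGTH_MM
    out["Ct.Ma.V"] = csv - ctv
    out["Ct.Ma.Ar"] = out["Ct.Ma.V"] / _SEGMENT_LENGTH_MM
    return out
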