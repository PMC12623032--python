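"""Gower-distance k-nearest-neighbour imputation for mixed-type predictors.

Gower's dissimilarity averages per-variable contributions over the
variables observed in *both* rows: absolute difference scaled by the
cohort range for continuous variables, 0/1 mismatch for categorical ones.
Missing cells are filled by aggregating each incomplete row's k nearest
neighbours among rows that observe the variable — mean for continuous,
mode for categorical.  Donor values are always original observations;
imputed values are never chained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: predictor columns used both as distance variables and imputation targets
DEFAULT_CONTINUOUS = ("age", "fpg", "hba1c", "bmi", "triglycerides")
DEFAULT_CATEGORICAL = ("sex",)


@dataclass
class GowerSpace:
    """Variable kinds and continuous ranges defining the Gower metric."""

    continuous: tuple[str, ...] = DEFAULT_CONTINUOUS
    categorical: tuple[str, ...] = DEFAULT_CATEGORICAL
    ranges: dict[str, float] = field(default_factory=dict)

    @classmethod
    def from_cohort(
        cls,
        cohort: pd.DataFrame,
        continuous: tuple[str, ...] = DEFAULT_CONTINUOUS,
        categorical: tuple[str, ...] = DEFAULT_CATEGORICAL,
    ) -> "GowerSpace":
        """Derive ranges (max − min over observed values) from the cohort.

        Constant columns carry no distance information; they are dropped
        from the space with a warning.
        """
        keep, ranges = [], {}
        for col in continuous:
            vals = cohort[col].astype(float)
            rng = float(vals.max() - vals.min())
            if not np.isfinite(rng) or rng <= 0:
                warnings.warn(
                    f"column {col!r} is constant or unobserved; "
                    "excluded from the Gower distance",
                    stacklevel=2,
                )
                continue
            keep.append(col)
            ranges[col] = rng
        return cls(continuous=tuple(keep), categorical=categorical, ranges=ranges)

    def __post_init__(self) -> None:
        for col in self.continuous:
            if col in self.ranges and self.ranges[col] <= 0:
                raise ValueError(f"range for {col!r} must be > 0")

    @property
    def columns(self) -> tuple[str, ...]:
        return self.continuous + self.categorical


def gower_distance(row_a: pd.Series, row_b: pd.Series, space: GowerSpace) -> float:
    """Gower dissimilarity in [0, 1]; NaN if no variable is pairwise observed."""
    num = 0.0
    denom = 0
    for col in space.continuous:
        a, b = row_a.get(col), row_b.get(col)
        if pd.isna(a) or pd.isna(b):
            continue
        num += abs(float(a) - float(b)) / space.ranges[col]
        denom += 1
    for col in space.categorical:
        a, b = row_a.get(col), row_b.get(col)
        if pd.isna(a) or pd.isna(b):
            continue
        num += 0.0 if a == b else 1.0
        denom += 1
    if denom == 0:
        return float("nan")
    return num / denom


def _cross_gower(query: pd.DataFrame, donors: pd.DataFrame, space: GowerSpace
                 ) -> np.ndarray:
    """Gower distances between query rows and donor rows (vectorized)."""
    nq, nd = len(query), len(donors)
    num = np.zeros((nq, nd))
    denom = np.zeros((nq, nd))
    for col in space.continuous:
        a = query[col].to_numpy(dtype=float)
        b = donors[col].to_numpy(dtype=float)
        both = np.outer(~np.isnan(a), ~np.isnan(b))
        d = np.abs(np.nan_to_num(a)[:, None] - np.nan_to_num(b)[None, :]) / space.ranges[col]
        num += np.where(both, d, 0.0)
        denom += both
    for col in space.categorical:
        a = query[col].to_numpy(dtype=object)
        b = donors[col].to_numpy(dtype=object)
        both = np.outer(~pd.isna(a), ~pd.isna(b))
        mism = (a[:, None] != b[None, :]).astype(float)
        num += np.where(both, mism, 0.0)
        denom += both
    with np.errstate(invalid="ignore"):
        return np.where(denom > 0, num / np.maximum(denom, 1), np.nan)


def impute_knn(
    cohort: pd.DataFrame,
    k: int = 5,
    space: GowerSpace | None = None,
    reference: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Fill missing predictor cells from the k nearest Gower neighbours.

    For each missing cell the k smallest-distance rows observing that
    variable act as donors; ties in distance break by position in the
    table (stable subject-id order).  Continuous targets get the donor
    mean, categorical targets the donor mode (ties to the alphabetically
    lowest label).

    ``reference`` restricts donors to an external frame (e.g. a training
    fold) instead of the cohort itself; distances and ranges then come
    from the reference, and a query row is never its own donor.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    self_mode = reference is None
    donors_frame = cohort if self_mode else reference
    donors_frame = donors_frame.reset_index(drop=True)
    if space is None:
        space = GowerSpace.from_cohort(donors_frame)

    targets = [c for c in space.columns if c in cohort.columns]
    if not cohort[targets].isna().any().any():
        return cohort.copy()
    for col in cohort.columns:
        if cohort[col].isna().any() and col in donors_frame.columns \
                and donors_frame[col].isna().all():
            raise ValueError(f"column {col!r} is 100% missing among donors")

    out = cohort.reset_index(drop=True).copy()
    query_idx = np.flatnonzero(out[targets].isna().any(axis=1).to_numpy())
    dist = _cross_gower(out.iloc[query_idx], donors_frame, space)
    if self_mode:
        dist[np.arange(len(query_idx)), query_idx] = np.inf
    row_of = {int(q): j for j, q in enumerate(query_idx)}

    for col in targets:
        miss_idx = np.flatnonzero(out[col].isna().to_numpy())
        if miss_idx.size == 0:
            continue
        donors_mask = ~donors_frame[col].isna().to_numpy()
        if donors_mask.sum() == 0:
            raise ValueError(f"column {col!r} is 100% missing among donors")
        donor_pos = np.flatnonzero(donors_mask)
        for i in miss_idx:
            d = dist[row_of[int(i)], donor_pos]
            valid = np.isfinite(d)
            eligible = donor_pos[valid]
            dd = d[valid]
            if eligible.size < k:
                warnings.warn(
                    f"row {out.loc[i, 'id'] if 'id' in out else i}: only "
                    f"{eligible.size} eligible donors for {col!r} (k={k})",
                    stacklevel=2,
                )
            if eligible.size == 0:
                raise ValueError(f"no eligible donors for row {i}, column {col!r}")
            order = np.argsort(dd, kind="stable")[: min(k, eligible.size)]
            donor_vals = donors_frame.loc[eligible[order], col]
            if col in space.continuous:
                out.loc[i, col] = float(donor_vals.astype(float).mean())
            else:
                counts = donor_vals.value_counts()
                top = counts[counts == counts.max()].index
                out.loc[i, col] = sorted(top)[0]
    out.index = cohort.index
    return out
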