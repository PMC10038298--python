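"""Food-security indicators: FCS, HDDS, weighted HDDS, and prevalences.

The Food Consumption Score (FCS) is the weighted sum of weekly consumption
days over 8 aggregate food groups,

    FCS = 2*Starches + 3*Pulses + Vegetables + Fruit + 4*Meat + 4*Dairy
          + 0.5*Fats + 0.5*Sugar,

with weights summing to 16 and a maximum of 112.  Households at or below 28
are below minimal consumption ("severe"); at or below 42, below acceptable
consumption ("borderline" between 29 and 42).  The Household Dietary
Diversity Score (HDDS) counts how many of 12 standard groups were consumed
at all; its frequency-weighted variant divides each group's weekly days by 7
before summing, giving a 0-12 daily-average diversity score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ConsumptionMatrix

__all__ = [
    "FCS_WEIGHTS",
    "HDDS_GROUPS",
    "IndicatorScheme",
    "default_yemen_scheme",
    "fcs",
    "hdds_unweighted",
    "hdds_weighted",
    "prevalence",
    "compute_indicators",
]

FCS_WEIGHTS: dict[str, float] = {
    "Starches": 2.0,
    "Pulses": 3.0,
    "Vegetables": 1.0,
    "Fruit": 1.0,
    "Meat": 4.0,
    "Dairy": 4.0,
    "Fats": 0.5,
    "Sugar": 0.5,
}

HDDS_GROUPS: list[str] = [
    "Cereals",
    "Roots and tubers",
    "Vegetables",
    "Fruits",
    "Meat/poultry/offal",
    "Eggs",
    "Fish and seafood",
    "Pulses/legumes/nuts",
    "Milk and milk products",
    "Oil/fats",
    "Sugar/honey",
    "Miscellaneous",
]

# 13 standard survey groups -> FCS aggregate (condiments carry no FCS weight)
_YEMEN_FCS_MAP = {
    "bread": "Starches",
    "potatoes": "Starches",
    "rice": "Starches",
    "vegetables": "Vegetables",
    "fruit": "Fruit",
    "pulses": "Pulses",
    "eggs": "Meat",
    "meat": "Meat",
    "fish": "Meat",
    "dairy": "Dairy",
    "oil": "Fats",
    "sugar": "Sugar",
}

_YEMEN_HDDS_MAP = {
    "bread": "Cereals",
    "rice": "Cereals",
    "potatoes": "Roots and tubers",
    "vegetables": "Vegetables",
    "fruit": "Fruits",
    "meat": "Meat/poultry/offal",
    "eggs": "Eggs",
    "fish": "Fish and seafood",
    "pulses": "Pulses/legumes/nuts",
    "dairy": "Milk and milk products",
    "oil": "Oil/fats",
    "sugar": "Sugar/honey",
    "condiments": "Miscellaneous",
}


@dataclass
class IndicatorScheme:
    """Mapping from survey food groups to FCS and HDDS aggregates.

    Survey subgroups mapping to the same aggregate have their days summed and
    capped at the recall-window length (7), keeping scores within the stated
    maxima of 112 (FCS) and 12 (HDDS).
    """

    fcs_map: dict[str, str]
    hdds_map: dict[str, str]
    fcs_weights: dict[str, float] = field(default_factory=lambda: dict(FCS_WEIGHTS))
    severe_threshold: float = 28.0
    acceptable_threshold: float = 42.0
    m: int = 7

    def __post_init__(self):
        total = sum(self.fcs_weights.values())
        if not np.isclose(total, 16.0):
            raise ValueError(f"FCS weights must sum to 16, got {total}")
        bad = set(self.fcs_map.values()) - set(self.fcs_weights)
        if bad:
            raise ValueError(f"unknown FCS aggregate(s): {sorted(bad)}")
        bad = set(self.hdds_map.values()) - set(HDDS_GROUPS)
        if bad:
            raise ValueError(f"unknown HDDS group(s): {sorted(bad)}")

    @property
    def max_fcs(self) -> float:
        return self.m * sum(self.fcs_weights.values())


def default_yemen_scheme(group_names=None) -> IndicatorScheme:
    """Default scheme for the 13 standard survey groups.

    If ``group_names`` is given, the maps are restricted to those groups (so
    sub-models on a group subset work without edits).
    """
    fcs_map, hdds_map = dict(_YEMEN_FCS_MAP), dict(_YEMEN_HDDS_MAP)
    if group_names is not None:
        unknown = [g for g in group_names if g not in _YEMEN_HDDS_MAP]
        if unknown:
            raise ValueError(f"no default mapping for group(s): {unknown}")
        fcs_map = {g: fcs_map[g] for g in group_names if g in fcs_map}
        hdds_map = {g: hdds_map[g] for g in group_names}
    return IndicatorScheme(fcs_map=fcs_map, hdds_map=hdds_map)


def _validate_counts(counts: np.ndarray, m: int) -> np.ndarray:
    arr = np.atleast_2d(np.asarray(counts))
    if np.any(arr < 0) or np.any(arr > m) or np.any(arr != np.floor(arr)):
        raise ValueError(f"counts must be integers in [0, {m}]")
    return arr


def _aggregate(counts: np.ndarray, group_names: list[str], mapping: dict[str, str],
               targets: list[str], m: int) -> np.ndarray:
    """Sum survey-group days into aggregate groups, capping at m days."""
    n = counts.shape[0]
    out = np.zeros((n, len(targets)))
    for j, g in enumerate(group_names):
        tgt = mapping.get(g)
        if tgt is not None:
            out[:, targets.index(tgt)] += counts[:, j]
    return np.minimum(out, m)


def fcs(counts, group_names: list[str], scheme: IndicatorScheme) -> np.ndarray:
    """Food Consumption Score per household (vectorized over rows)."""
    arr = _validate_counts(counts, scheme.m)
    targets = list(scheme.fcs_weights)
    days = _aggregate(arr, group_names, scheme.fcs_map, targets, scheme.m)
    w = np.array([scheme.fcs_weights[t] for t in targets])
    return days @ w


def hdds_unweighted(counts, group_names: list[str], scheme: IndicatorScheme) -> np.ndarray:
    """Number of HDDS groups with any consumption in the recall window (0-12)."""
    arr = _validate_counts(counts, scheme.m)
    days = _aggregate(arr, group_names, scheme.hdds_map, HDDS_GROUPS, scheme.m)
    return (days > 0).sum(axis=1)


def hdds_weighted(counts, group_names: list[str], scheme: IndicatorScheme) -> np.ndarray:
    """Frequency-weighted HDDS: sum of capped group-days divided by 7 (0-12)."""
    arr = _validate_counts(counts, scheme.m)
    days = _aggregate(arr, group_names, scheme.hdds_map, HDDS_GROUPS, scheme.m)
    return (days / scheme.m).sum(axis=1)


def prevalence(scores, severe: float = 28.0, acceptable: float = 42.0) -> tuple[float, float]:
    """Shares of households at or below the severe and acceptable FCS cutoffs."""
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0:
        raise ValueError("empty score vector")
    return float(np.mean(arr <= severe)), float(np.mean(arr <= acceptable))


def compute_indicators(matrix: ConsumptionMatrix, scheme: IndicatorScheme | None = None) -> pd.DataFrame:
    """Per-household indicator table: FCS, HDDS, weighted HDDS, and class."""
    if scheme is None:
        scheme = default_yemen_scheme(matrix.group_names)
    scores = fcs(matrix.counts, matrix.group_names, scheme)
    h = hdds_unweighted(matrix.counts, matrix.group_names, scheme)
    hw = hdds_weighted(matrix.counts, matrix.group_names, scheme)
    cls = np.where(
        scores <= scheme.severe_threshold, "severe",
        np.where(scores <= scheme.acceptable_threshold, "borderline", "acceptable"),
    )
    return pd.DataFrame({
        "household_id": matrix.household_ids,
        "fcs": scores,
        "hdds": h,
        "hdds_weighted": hw,
        "fcs_class": cls,
    })
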