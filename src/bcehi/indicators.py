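"""Indicator normalization and Benefit / Pressure aggregation.

Benefit is the mean of normalized fitness indicators (all six for mangrove;
area alone for salt marsh and seagrass).  Pressure is the mean of four
compound scores (climate, land, marine, species) built by summing raw
pressure layers; salt marsh excludes the species compound.  Normalization is
min-max per ecotone with optional quantile winsorization.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from bcehi.synthetic_world import FITNESS_COLUMNS

#: raw layers feeding each compound pressure
COMPOUND_LAYERS: dict[str, tuple[str, ...]] = {
    "p_climate": ("oa", "sst_pressure", "slr"),
    "p_land": ("ocp", "dp", "np"),
    "p_marine": ("af", "cfplb", "cfphb", "cfdnlb", "cfdnhb", "dd", "ligt", "ship"),
    "p_species": ("species_threat_fraction",),
}

PRESSURE_COMPOUNDS = tuple(COMPOUND_LAYERS)

#: compounds entering the pressure mean, per ecotone
ECOTONE_COMPOUNDS: dict[str, tuple[str, ...]] = {
    "mangrove": PRESSURE_COMPOUNDS,
    "seagrass": PRESSURE_COMPOUNDS,
    "salt_marsh": ("p_climate", "p_land", "p_marine"),  # species excluded
}

#: fitness indicators entering the benefit mean, per ecotone
ECOTONE_BENEFIT_INDICATORS: dict[str, tuple[str, ...]] = {
    "mangrove": FITNESS_COLUMNS,
    "salt_marsh": ("area",),
    "seagrass": ("area",),
}

DEFAULT_MIN_PRESENT_BENEFIT = 3
DEFAULT_MIN_PRESENT_PRESSURE = 2


def normalize_minmax(
    values,
    clip_quantiles: tuple[float, float] | None = None,
    return_stats: bool = False,
):
    """Min-max scale to [0, 1], optionally winsorizing at quantiles first.

    Missing (NaN) entries stay missing.  A degenerate input (min == max)
    maps every present value to 0.5 with a warning.
    """
    arr = np.asarray(values, dtype=float)
    present = ~np.isnan(arr)
    if not present.any():
        raise ValueError("normalize_minmax: all values missing")

    x = arr.copy()
    lo = hi = None
    if clip_quantiles is not None:
        lo_q, hi_q = clip_quantiles
        if not (0.0 <= lo_q < hi_q <= 1.0):
            raise ValueError(f"invalid clip_quantiles: {clip_quantiles}")
        lo = float(np.nanquantile(arr, lo_q))
        hi = float(np.nanquantile(arr, hi_q))
        x[present] = np.clip(x[present], lo, hi)

    mn = float(np.nanmin(x))
    mx = float(np.nanmax(x))
    if mx == mn:
        warnings.warn(
            "normalize_minmax: degenerate input (min == max); mapping to 0.5",
            stacklevel=2,
        )
        out = np.where(present, 0.5, np.nan)
    else:
        out = (x - mn) / (mx - mn)

    stats = {"min": mn, "max": mx, "clip_lo": lo, "clip_hi": hi}
    if return_stats:
        return out, stats
    return out


def _check_unit_interval(values: np.ndarray, what: str) -> None:
    present = values[~np.isnan(values)]
    if present.size and (present.min() < -1e-9 or present.max() > 1 + 1e-9):
        raise ValueError(f"{what} must be normalized to [0, 1]")


def compute_benefit(
    fitness: Mapping[str, float] | pd.Series,
    ecotone: str,
    min_present: int = DEFAULT_MIN_PRESENT_BENEFIT,
) -> float:
    """Benefit score for one record from already-normalized fitness values.

    Mangrove: mean of the available of the six indicators, requiring at
    least ``min_present``; salt marsh and seagrass: normalized area alone.
    Returns NaN (no-data) when the requirement is unmet.
    """
    indicators = ECOTONE_BENEFIT_INDICATORS[ecotone]
    values = np.array([float(fitness.get(c, np.nan)) for c in indicators])
    _check_unit_interval(values, "fitness indicators")
    present = values[~np.isnan(values)]
    if ecotone == "mangrove":
        if present.size < min_present:
            return float("nan")
        return float(present.mean())
    if present.size == 0:
        return float("nan")
    return float(present[0])


def compute_pressure(
    compounds: Mapping[str, float] | pd.Series,
    ecotone: str,
    min_present: int = DEFAULT_MIN_PRESENT_PRESSURE,
) -> float:
    """Total pressure for one record from already-normalized compounds.

    Mean of the compounds applicable to the ecotone (species excluded for
    salt marsh); NaN when fewer than ``min_present`` compounds are present.
    """
    names = ECOTONE_COMPOUNDS[ecotone]
    values = np.array([float(compounds.get(c, np.nan)) for c in names])
    _check_unit_interval(values, "pressure compounds")
    present = values[~np.isnan(values)]
    if present.size < min_present:
        return float("nan")
    return float(present.mean())


def score_benefits(
    table: pd.DataFrame,
    min_present: int = DEFAULT_MIN_PRESENT_BENEFIT,
    clip_quantiles: tuple[float, float] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Normalize fitness indicators per ecotone and add a ``b`` column.

    Returns a new frame with ``norm_<indicator>`` columns and the benefit
    score, plus the per-ecotone normalization statistics for the sidecar.
    """
    out = table.copy()
    stats: dict[str, dict] = {}
    for col in FITNESS_COLUMNS:
        out[f"norm_{col}"] = np.nan

    for ecotone, group in table.groupby("ecotone", sort=True):
        stats[ecotone] = {}
        for col in FITNESS_COLUMNS:
            raw = group[col].to_numpy(dtype=float)
            if np.isnan(raw).all():
                stats[ecotone][col] = None
                continue
            normed, st = normalize_minmax(
                raw, clip_quantiles=clip_quantiles, return_stats=True
            )
            out.loc[group.index, f"norm_{col}"] = normed
            stats[ecotone][col] = st

    out["b"] = np.nan
    for ecotone, group in out.groupby("ecotone", sort=True):
        cols = [f"norm_{c}" for c in ECOTONE_BENEFIT_INDICATORS[ecotone]]
        block = group[cols].to_numpy(dtype=float)
        if ecotone == "mangrove":
            n_present = (~np.isnan(block)).sum(axis=1)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                means = np.nanmean(block, axis=1)
            means[n_present < min_present] = np.nan
            out.loc[group.index, "b"] = means
        else:
            out.loc[group.index, "b"] = block[:, 0]
    return out, stats


def score_pressures(
    table: pd.DataFrame,
    normalize_layers: bool = True,
    min_present: int = DEFAULT_MIN_PRESENT_PRESSURE,
    clip_quantiles: tuple[float, float] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Build compound pressures and the total pressure score.

    Per ecotone: each raw layer is min-max normalized (unless
    ``normalize_layers`` is off), layers are summed into the four compounds,
    each compound sum is re-normalized to [0, 1], and ``p_total`` is the
    mean of the applicable compounds.  A record with fewer than
    ``min_present`` compounds is no-data (NaN).
    """
    out = table.copy()
    stats: dict[str, dict] = {}
    for compound in PRESSURE_COMPOUNDS:
        out[compound] = np.nan
    out["p_total"] = np.nan

    for ecotone, group in table.groupby("ecotone", sort=True):
        stats[ecotone] = {}
        compound_values: dict[str, np.ndarray] = {}
        for compound, layers in COMPOUND_LAYERS.items():
            parts = []
            for layer in layers:
                raw = group[layer].to_numpy(dtype=float)
                if np.isnan(raw).all():
                    parts.append(raw)
                    continue
                if normalize_layers:
                    normed, st = normalize_minmax(
                        raw, clip_quantiles=clip_quantiles, return_stats=True
                    )
                    stats[ecotone][layer] = st
                    parts.append(normed)
                else:
                    parts.append(raw)
            total = np.sum(np.column_stack(parts), axis=1)  # NaN if any layer missing
            if np.isnan(total).all():
                compound_values[compound] = total
                stats[ecotone][compound] = None
                continue
            normed, st = normalize_minmax(total, return_stats=True)
            compound_values[compound] = normed
            stats[ecotone][compound] = st
            out.loc[group.index, compound] = normed

        applicable = ECOTONE_COMPOUNDS[ecotone]
        block = np.column_stack([compound_values[c] for c in applicable])
        n_present = (~np.isnan(block)).sum(axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            p_total = np.nanmean(block, axis=1)
        p_total[n_present < min_present] = np.nan
        out.loc[group.index, "p_total"] = p_total

    return out, stats
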