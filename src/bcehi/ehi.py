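"""EHI assembly and natural-breaks classification.

EHI = B * (1 - P * T) per pixel, where T (transformation risk) is a single
value per ecotone x region collapsed from its pairwise hypervolume overlaps.
Pixels are classed High / Medium / Low by exact Fisher-Jenks natural breaks
fitted per ecotone, with no-data tracked as its own share.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from bcehi.hypervolume import OverlapMatrix

T_RULES = ("max", "mean", "sum_capped")
CLASS_LABELS = ("High", "Medium", "Low", "NoData")


@dataclass(frozen=True)
class TransformationRisk:
    """Per ecotone x region transformation risk collapsed from overlaps."""

    value: float
    source_region: str
    rule: str

    @property
    def is_missing(self) -> bool:
        return np.isnan(self.value)


@dataclass(frozen=True)
class ClassBreaks:
    """Three-class natural breaks for one ecotone (upper edges of classes)."""

    ecotone: str
    low_upper: float
    medium_upper: float
    method: str = "jenks-3"


def _collapse(values: np.ndarray, rule: str) -> float:
    if rule == "max":
        return float(values.max())
    if rule == "mean":
        return float(values.mean())
    if rule == "sum_capped":
        return float(min(values.sum(), 1.0))
    raise ValueError(f"unknown transformation-risk rule {rule!r}; use one of {T_RULES}")


def assign_transformation_risk(
    overlaps: Mapping[str, OverlapMatrix],
    ecotone: str,
    continent: str,
    rule: str = "max",
) -> TransformationRisk:
    """Collapse an ecotone's pairwise overlaps on a continent into one T.

    Falls back continent -> worldwide when the continental matrix is absent
    or has no overlap data for this ecotone; returns a no-data risk (NaN)
    when neither level has data.
    """
    if rule not in T_RULES:
        raise ValueError(f"unknown transformation-risk rule {rule!r}")
    for region in (continent, "worldwide"):
        om = overlaps.get(region)
        if om is None or ecotone not in om.matrix.index:
            continue
        row = om.matrix.loc[ecotone].drop(labels=[ecotone])
        pairs = row.to_numpy(dtype=float)
        pairs = pairs[~np.isnan(pairs)]
        if pairs.size:
            return TransformationRisk(_collapse(pairs, rule), region, rule)
    return TransformationRisk(float("nan"), "none", rule)


def compute_ehi(b, p, t):
    """EHI = B * (1 - P * T); inputs in [0, 1], NaN (no-data) propagates."""
    b = np.asarray(b, dtype=float)
    p = np.asarray(p, dtype=float)
    t = np.asarray(t, dtype=float)
    for name, arr in (("b", b), ("p", p), ("t", t)):
        present = arr[~np.isnan(arr)]
        if present.size and (present.min() < 0 or present.max() > 1):
            raise ValueError(f"{name} outside [0, 1]")
    out = b * (1.0 - p * t)
    if out.ndim == 0:
        return float(out)
    return out


def jenks_breaks(values, k: int = 3, return_ssd: bool = False):
    """Exact Fisher-Jenks natural breaks.

    Returns the k-1 break values (the maximum value inside each of the
    lower k-1 classes); the partition minimizes the total within-class sum
    of squared deviations, with ties broken toward the lower break value.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if k < 1:
        raise ValueError("k must be >= 1")
    if np.unique(x).size < k:
        raise ValueError(
            f"need at least {k} distinct finite values, got {np.unique(x).size}"
        )
    x = np.sort(x)
    n = x.size

    prefix = np.concatenate([[0.0], np.cumsum(x)])
    prefix_sq = np.concatenate([[0.0], np.cumsum(x * x)])

    def seg_ssd(i: np.ndarray, j: int) -> np.ndarray:
        # within-class SSD of x[i..j] inclusive, vectorized over i
        s = prefix[j + 1] - prefix[i]
        sq = prefix_sq[j + 1] - prefix_sq[i]
        m = j + 1 - i
        return sq - s * s / m

    idx = np.arange(n)
    cost = np.full((k + 1, n), np.inf)
    start = np.zeros((k + 1, n), dtype=int)  # first index of the last class
    ends = np.arange(1, n + 1)
    cost[1] = prefix_sq[ends] - prefix[ends] ** 2 / ends
    for c in range(2, k + 1):
        for j in range(c - 1, n):
            firsts = idx[c - 1 : j + 1]  # last class starts at x[first]
            total = cost[c - 1, firsts - 1] + seg_ssd(firsts, j)
            best = int(np.argmin(total))  # first minimum -> lowest break
            cost[c, j] = total[best]
            start[c, j] = firsts[best]

    # recover class boundaries
    bounds = []
    j = n - 1
    for c in range(k, 1, -1):
        first = start[c, j]
        bounds.append(first)
        j = first - 1
    bounds.reverse()  # indices where a new class starts

    breaks = np.array([x[b - 1] for b in bounds], dtype=float)
    if return_ssd:
        return breaks, float(cost[k, n - 1])
    return breaks


def fit_class_breaks(values, ecotone: str) -> ClassBreaks:
    """Three-class Jenks breaks for one ecotone's non-missing EHI values."""
    low_upper, medium_upper = jenks_breaks(values, k=3)
    return ClassBreaks(ecotone=ecotone, low_upper=float(low_upper),
                       medium_upper=float(medium_upper))


def classify_values(values, breaks: ClassBreaks) -> np.ndarray:
    """Class labels for EHI values; values exactly at a break go to the
    lower class."""
    x = np.asarray(values, dtype=float)
    labels = np.full(x.shape, "NoData", dtype=object)
    present = ~np.isnan(x)
    labels[present & (x <= breaks.low_upper)] = "Low"
    labels[present & (x > breaks.low_upper) & (x <= breaks.medium_upper)] = "Medium"
    labels[present & (x > breaks.medium_upper)] = "High"
    return labels


def classify_ehi(
    records: pd.DataFrame,
    breaks: Mapping[str, ClassBreaks],
    ehi_column: str = "ehi",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Attach ``ehi_class`` labels and summarize class proportions.

    The summary counts no-data as its own share so proportions over ALL
    records sum to 1 per ecotone.
    """
    out = records.copy()
    out["ehi_class"] = "NoData"
    for ecotone, group in records.groupby("ecotone", sort=True):
        if ecotone not in breaks:
            if group[ehi_column].notna().any():
                raise KeyError(f"no fitted class breaks for ecotone {ecotone!r}")
            continue  # every record is no-data; nothing to classify
        out.loc[group.index, "ehi_class"] = classify_values(
            group[ehi_column].to_numpy(dtype=float), breaks[ecotone]
        )

    rows = []
    for ecotone, group in out.groupby("ecotone", sort=True):
        counts = group["ehi_class"].value_counts()
        n = len(group)
        row = {"ecotone": ecotone, "n": n}
        for label in CLASS_LABELS:
            row[f"prop_{label.lower()}"] = counts.get(label, 0) / n
            row[f"count_{label.lower()}"] = int(counts.get(label, 0))
        rows.append(row)
    summary = pd.DataFrame(rows)
    return out, summary
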