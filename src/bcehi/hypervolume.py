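"""Kernel-density climatic hypervolumes and their pairwise overlaps.

A hypervolume is the super-level set of an equal-weight Gaussian mixture
centred on the (log10-transformed) data points, with per-dimension Silverman
bandwidths.  The density threshold retains a fixed probability mass q and
the set's Lebesgue measure is estimated by importance sampling from the
mixture itself:

    volume = (1/m) * sum_j 1{f(x_j) >= c} / f(x_j),   x_j ~ f

Pairwise similarity is the Sorensen overlap 2 * V_shared / (V_a + V_b),
with the shared volume estimated symmetrically from both sample clouds.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from bcehi.synthetic_world import CLIMATE_COLUMNS, ECOTONES

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)
DEFAULT_MIN_POINTS = 20
DEFAULT_SAMPLE_FLOOR = 10_000


def silverman_bandwidths(
    data: np.ndarray, dim_labels: Sequence[str] | None = None
) -> np.ndarray:
    """Per-dimension Silverman rule-of-thumb bandwidths.

    bandwidth_j = sd_j * (4 / (d + 2))^(1/(d+4)) * n^(-1/(d+4))
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n, d = data.shape
    if n < 2:
        raise ValueError("silverman_bandwidths requires at least 2 points")
    sd = data.std(axis=0, ddof=1)
    if np.any(sd <= 0):
        bad = np.flatnonzero(sd <= 0)
        names = (
            [dim_labels[i] for i in bad]
            if dim_labels is not None
            else [f"dim {i}" for i in bad]
        )
        raise ValueError(f"zero-variance dimension(s): {', '.join(map(str, names))}")
    factor = (4.0 / (d + 2.0)) ** (1.0 / (d + 4.0)) * n ** (-1.0 / (d + 4.0))
    return sd * factor


@dataclass
class Hypervolume:
    """A fitted kernel-density hypervolume (all arrays on transformed scale)."""

    dim_labels: tuple[str, ...]
    data: np.ndarray                 # n x d
    bandwidths: np.ndarray           # d
    sample_cloud: np.ndarray         # m x d, drawn from the mixture
    cloud_log_density: np.ndarray    # m
    log_threshold: float
    volume: float
    mass_quantile: float
    seed: int | None = None
    shifts: Mapping[str, float] = field(default_factory=dict)

    @property
    def n_points(self) -> int:
        return self.data.shape[0]

    def log_density(self, points: np.ndarray, chunk: int = 2048) -> np.ndarray:
        """Log mixture density at arbitrary points (chunked for memory)."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        n, d = self.data.shape
        h = self.bandwidths
        xs = self.data / h
        x_sq = np.einsum("ij,ij->i", xs, xs)
        log_norm = math.log(n) + d * _LOG_SQRT_2PI + float(np.log(h).sum())
        out = np.empty(points.shape[0])
        for start in range(0, points.shape[0], chunk):
            ps = points[start : start + chunk] / h
            d2 = (
                np.einsum("ij,ij->i", ps, ps)[:, None]
                + x_sq[None, :]
                - 2.0 * ps @ xs.T
            )
            np.maximum(d2, 0.0, out=d2)
            out[start : start + chunk] = logsumexp(-0.5 * d2, axis=1) - log_norm
        return out

    def contains(self, points: np.ndarray) -> np.ndarray:
        return self.log_density(points) >= self.log_threshold


def fit_hypervolume(
    data: np.ndarray,
    mass_quantile: float = 0.95,
    n_samples: int | None = None,
    seed: int = 0,
    dim_labels: Sequence[str] | None = None,
    shifts: Mapping[str, float] | None = None,
) -> Hypervolume:
    """Fit a hypervolume to (already transformed) data points.

    ``n_samples`` defaults to ``max(10^4, ceil(10^4 / n) * n)`` total Monte
    Carlo samples.  Deterministic under ``seed``.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.ndim != 2 or data.shape[0] < 2:
        raise ValueError("fit_hypervolume requires an n x d matrix with n >= 2")
    if not 0.0 < mass_quantile <= 1.0:
        raise ValueError(f"mass_quantile outside (0, 1]: {mass_quantile}")
    if not np.isfinite(data).all():
        raise ValueError("fit_hypervolume: data must be finite")

    n, d = data.shape
    labels = tuple(dim_labels) if dim_labels is not None else tuple(
        f"dim_{i}" for i in range(d)
    )
    bandwidths = silverman_bandwidths(data, labels)

    if n_samples is None:
        n_samples = max(DEFAULT_SAMPLE_FLOOR, math.ceil(DEFAULT_SAMPLE_FLOOR / n) * n)

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=n_samples)
    cloud = data[idx] + rng.normal(size=(n_samples, d)) * bandwidths

    hv = Hypervolume(
        dim_labels=labels,
        data=data,
        bandwidths=bandwidths,
        sample_cloud=cloud,
        cloud_log_density=np.empty(0),
        log_threshold=-np.inf,
        volume=0.0,
        mass_quantile=mass_quantile,
        seed=seed,
        shifts=dict(shifts) if shifts else {},
    )
    log_f = hv.log_density(cloud)
    # retained probability mass under f equals the fraction of f-samples
    # above the cutoff, so the cutoff is the (1 - q) sample quantile
    log_c = float(np.quantile(log_f, 1.0 - mass_quantile))
    inside = log_f >= log_c
    volume = float(np.exp(-log_f[inside]).sum() / n_samples)

    hv.cloud_log_density = log_f
    hv.log_threshold = log_c
    hv.volume = volume
    return hv


def _directional_shared(a: Hypervolume, b: Hypervolume) -> tuple[float, float]:
    """Shared-volume estimate (and its MC standard error) from a's cloud."""
    in_a = a.cloud_log_density >= a.log_threshold
    log_fb = b.log_density(a.sample_cloud)
    weights = np.where(
        in_a & (log_fb >= b.log_threshold), np.exp(-a.cloud_log_density), 0.0
    )
    m = weights.size
    est = float(weights.mean())
    se = float(weights.std(ddof=1) / math.sqrt(m)) if m > 1 else float("nan")
    return est, se


def sorensen_overlap(
    hv_a: Hypervolume, hv_b: Hypervolume, return_se: bool = False
):
    """Sorensen overlap 2 * V_shared / (V_a + V_b), clipped to [0, 1].

    The shared volume is the mean of the two directional importance-sampling
    estimates, so the result is exactly symmetric in its arguments.
    """
    if hv_a.dim_labels != hv_b.dim_labels:
        raise ValueError(
            f"dimension mismatch: {hv_a.dim_labels} vs {hv_b.dim_labels}"
        )
    s_ab, se_ab = _directional_shared(hv_a, hv_b)
    s_ba, se_ba = _directional_shared(hv_b, hv_a)
    v_shared = 0.5 * (s_ab + s_ba)
    se = 0.5 * math.hypot(se_ab, se_ba)
    denom = hv_a.volume + hv_b.volume
    overlap = 0.0 if denom == 0 else min(max(2.0 * v_shared / denom, 0.0), 1.0)
    if return_se:
        return overlap, se
    return overlap


@dataclass
class OverlapMatrix:
    """Pairwise Sorensen overlaps between ecotone hypervolumes in a region."""

    region: str
    ecotones: tuple[str, ...]
    matrix: pd.DataFrame                  # square; NaN where data insufficient
    volumes: dict[str, float]
    shared_se: dict[tuple[str, str], float]
    n_points: dict[str, int]

    def pair(self, ecotone_a: str, ecotone_b: str) -> float:
        return float(self.matrix.loc[ecotone_a, ecotone_b])


def climate_shifts(
    table: pd.DataFrame, dims: Sequence[str] = CLIMATE_COLUMNS
) -> dict[str, float]:
    """Per-dimension additive offsets so log10 is defined: when a column's
    minimum is <= 0 it is shifted so the minimum maps to +1."""
    shifts = {}
    for dim in dims:
        mn = float(np.nanmin(table[dim].to_numpy(dtype=float)))
        shifts[dim] = 1.0 - mn if mn <= 0 else 0.0
    return shifts


def transform_climate(
    table: pd.DataFrame,
    dims: Sequence[str] = CLIMATE_COLUMNS,
    shifts: Mapping[str, float] | None = None,
    log10_transform: bool = True,
) -> tuple[np.ndarray, dict[str, float]]:
    """Stack climate columns into an n x d matrix, shifted and log10-scaled."""
    if shifts is None:
        shifts = climate_shifts(table, dims) if log10_transform else {d: 0.0 for d in dims}
    cols = []
    for dim in dims:
        x = table[dim].to_numpy(dtype=float) + shifts.get(dim, 0.0)
        if log10_transform:
            if np.nanmin(x) <= 0:
                raise ValueError(
                    f"climate dimension {dim!r} not positive after shift; "
                    "increase the configured offset"
                )
            x = np.log10(x)
        cols.append(x)
    return np.column_stack(cols), dict(shifts)


def overlap_matrix(
    table: pd.DataFrame,
    grouping: str = "worldwide",
    dims: Sequence[str] = CLIMATE_COLUMNS,
    ecotones: Sequence[str] = ECOTONES,
    mass_quantile: float = 0.95,
    n_samples: int | None = None,
    min_points: int = DEFAULT_MIN_POINTS,
    seed: int = 0,
    log10_transform: bool = True,
    shifts: Mapping[str, float] | None = None,
) -> dict[str, OverlapMatrix]:
    """Fit per-ecotone hypervolumes and their overlaps, per region.

    ``grouping`` is ``"worldwide"`` (one region) or ``"continent"``.  The
    log10 shift is computed once from the pooled table so every ecotone in a
    region lives in the same coordinate system.  Ecotones with fewer than
    ``min_points`` complete climate rows in a region are reported missing
    (NaN), not zero.
    """
    if grouping not in ("worldwide", "continent"):
        raise ValueError(f"unknown grouping {grouping!r}")

    complete = table.dropna(subset=list(dims))
    if shifts is None and log10_transform:
        shifts = climate_shifts(complete, dims)

    if grouping == "worldwide":
        region_iter = [("worldwide", complete)]
    else:
        region_iter = sorted(complete.groupby("continent"), key=lambda kv: kv[0])

    results: dict[str, OverlapMatrix] = {}
    ss = np.random.SeedSequence(seed)
    for region, region_table in region_iter:
        fitted: dict[str, Hypervolume] = {}
        n_points: dict[str, int] = {}
        for ecotone in ecotones:
            sub = region_table[region_table["ecotone"] == ecotone]
            n_points[ecotone] = len(sub)
            if len(sub) < min_points:
                continue
            data, used_shifts = transform_climate(
                sub, dims, shifts=shifts, log10_transform=log10_transform
            )
            # zlib.crc32 is stable across processes (str hash is not)
            child_seed = int(
                np.random.SeedSequence(
                    entropy=ss.entropy,
                    spawn_key=(zlib.crc32(region.encode()), ecotones.index(ecotone)),
                ).generate_state(1)[0]
            )
            fitted[ecotone] = fit_hypervolume(
                data,
                mass_quantile=mass_quantile,
                n_samples=n_samples,
                seed=child_seed,
                dim_labels=dims,
                shifts=used_shifts,
            )

        matrix = pd.DataFrame(
            np.nan, index=list(ecotones), columns=list(ecotones), dtype=float
        )
        shared_se: dict[tuple[str, str], float] = {}
        for ecotone in fitted:
            matrix.loc[ecotone, ecotone] = 1.0
        names = [e for e in ecotones if e in fitted]
        for i, ea in enumerate(names):
            for eb in names[i + 1 :]:
                ov, se = sorensen_overlap(fitted[ea], fitted[eb], return_se=True)
                matrix.loc[ea, eb] = ov
                matrix.loc[eb, ea] = ov
                shared_se[(ea, eb)] = se
        results[region] = OverlapMatrix(
            region=region,
            ecotones=tuple(ecotones),
            matrix=matrix,
            volumes={e: hv.volume for e, hv in fitted.items()},
            shared_se=shared_se,
            n_points=n_points,
        )
    return results


def overlap_table(matrices: Mapping[str, OverlapMatrix]) -> pd.DataFrame:
    """Arrange overlap matrices as rows = ecotone pairs, columns = regions."""
    regions = list(matrices)
    if "worldwide" in regions:  # lead with the global column
        regions = ["worldwide"] + [r for r in regions if r != "worldwide"]
    any_matrix = next(iter(matrices.values()))
    ecotones = list(any_matrix.ecotones)
    pairs = [
        (ecotones[i], ecotones[j])
        for i in range(len(ecotones))
        for j in range(i + 1, len(ecotones))
    ]
    rows = {}
    for ea, eb in pairs:
        rows[f"{ea}-{eb}"] = [
            matrices[r].pair(ea, eb) if r in matrices else np.nan for r in regions
        ]
    return pd.DataFrame.from_dict(rows, orient="index", columns=regions)
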