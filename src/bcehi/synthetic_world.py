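"""Synthetic coastal-pixel world generator.

Produces a pixel table with the structure the EHI analysis assumes: one row
per 1-degree coastal pixel x ecotone, ecotone-specific latitude bands,
latitudinal climate and fitness gradients, raw pressure layers, and
configurable missingness.  Everything is driven by a single seeded
``numpy.random.Generator`` so identical configs give byte-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

ECOTONES = ("mangrove", "salt_marsh", "seagrass")

FITNESS_COLUMNS = ("area", "fragment_area", "age", "height", "agb", "soc")
CLIMATE_COLUMNS = ("par", "tidal_amplitude", "sst", "air_temperature", "precipitation")
PRESSURE_LAYER_COLUMNS = (
    "oa", "sst_pressure", "slr",                     # climate compound
    "ocp", "dp", "np",                               # land compound
    "af", "cfplb", "cfphb", "cfdnlb", "cfdnhb",      # marine compound
    "dd", "ligt", "ship",
    "species_threat_fraction",                       # species compound
)

#: columns blanked when a record is flagged no-data
MISSABLE_COLUMNS = FITNESS_COLUMNS + PRESSURE_LAYER_COLUMNS

DEFAULT_LATITUDE_BANDS: dict[str, tuple[tuple[float, float], ...]] = {
    "mangrove": ((-38.5, 29.5),),
    "salt_marsh": ((-46.5, -3.5), (17.5, 71.5)),
    "seagrass": ((-43.5, 69.5),),
}

DEFAULT_MISSING_FRACTIONS = {"mangrove": 0.16, "salt_marsh": 0.15, "seagrass": 0.29}

# (lon_min, lon_max, label): crude longitude sectors; geometry fidelity is
# irrelevant for testing the statistics, only a stable grouping is needed.
DEFAULT_CONTINENT_SECTORS: tuple[tuple[float, float, str], ...] = (
    (-180.0, -100.0, "north_america"),
    (-100.0, -30.0, "south_america"),
    (-30.0, 20.0, "africa"),
    (20.0, 60.0, "europe"),
    (60.0, 110.0, "asia"),
    (110.0, 180.0, "oceania"),
)


@dataclass(frozen=True)
class Gradient:
    """Linear trend ``intercept + slope * |latitude| + N(0, noise_sd)``."""

    intercept: float
    slope: float
    noise_sd: float = 0.0
    minimum: float | None = 0.0
    maximum: float | None = None

    def sample(self, abs_latitude: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        values = self.intercept + self.slope * abs_latitude
        if self.noise_sd > 0:
            values = values + rng.normal(0.0, self.noise_sd, size=abs_latitude.shape)
        if self.minimum is not None:
            values = np.maximum(values, self.minimum)
        if self.maximum is not None:
            values = np.minimum(values, self.maximum)
        return values


DEFAULT_CLIMATE_GRADIENTS: dict[str, Gradient] = {
    "par": Gradient(45.0, -0.25, 2.0, minimum=1.0),
    "tidal_amplitude": Gradient(1.5, 0.012, 0.3, minimum=0.05),
    "sst": Gradient(29.0, -0.35, 1.0, minimum=-2.0),
    "air_temperature": Gradient(28.0, -0.55, 1.5, minimum=None),
    "precipitation": Gradient(2200.0, -25.0, 200.0, minimum=10.0),
}

DEFAULT_FITNESS_GRADIENTS: dict[str, Gradient] = {
    "area": Gradient(5000.0, -40.0, 800.0),
    "fragment_area": Gradient(300.0, -2.0, 60.0),
    "age": Gradient(40.0, -0.2, 8.0),
    "height": Gradient(20.0, -0.15, 3.0),
    "agb": Gradient(250.0, -2.0, 40.0),
    "soc": Gradient(400.0, -2.5, 60.0),
}

DEFAULT_PRESSURE_LEVELS: dict[str, tuple[float, float]] = {
    **{c: (1.0, 0.4) for c in PRESSURE_LAYER_COLUMNS},
    "species_threat_fraction": (0.2, 0.1),
}


class ConfigurationError(ValueError):
    """Raised when a WorldConfig violates its invariants."""


@dataclass
class WorldConfig:
    """Configuration for :func:`generate_world`.

    ``n_pixels_per_ecotone`` may be a single integer (same count for every
    ecotone) or a mapping ecotone -> count.  Latitude bands are unions of
    closed intervals in degrees; sampling is uniform over the union.
    """

    n_pixels_per_ecotone: int | Mapping[str, int] = 1000
    ecotones: Sequence[str] = ECOTONES
    latitude_bands: Mapping[str, Sequence[tuple[float, float]]] = field(
        default_factory=lambda: dict(DEFAULT_LATITUDE_BANDS)
    )
    continent_sectors: Sequence[tuple[float, float, str]] = DEFAULT_CONTINENT_SECTORS
    climate_gradients: Mapping[str, Gradient] = field(
        default_factory=lambda: dict(DEFAULT_CLIMATE_GRADIENTS)
    )
    fitness_gradients: Mapping[str, Gradient] = field(
        default_factory=lambda: dict(DEFAULT_FITNESS_GRADIENTS)
    )
    pressure_levels: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PRESSURE_LEVELS)
    )
    missing_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MISSING_FRACTIONS)
    )
    missing_mode: str = "record"
    shared_pixels: bool = False
    seed: int = 0

    def n_for(self, ecotone: str) -> int:
        if isinstance(self.n_pixels_per_ecotone, Mapping):
            return int(self.n_pixels_per_ecotone[ecotone])
        return int(self.n_pixels_per_ecotone)

    def validate(self) -> None:
        for ecotone in self.ecotones:
            if ecotone not in self.latitude_bands:
                raise ConfigurationError(f"no latitude band configured for {ecotone!r}")
            for lo, hi in self.latitude_bands[ecotone]:
                if lo >= hi:
                    raise ConfigurationError(
                        f"latitude band for {ecotone!r} has min >= max: ({lo}, {hi})"
                    )
                if lo < -90 or hi > 90:
                    raise ConfigurationError(
                        f"latitude band for {ecotone!r} outside [-90, 90]: ({lo}, {hi})"
                    )
            if self.n_for(ecotone) <= 0:
                raise ConfigurationError(
                    f"n_pixels_per_ecotone must be positive for {ecotone!r}"
                )
            frac = self.missing_fractions.get(ecotone, 0.0)
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError(
                    f"missing fraction for {ecotone!r} outside [0, 1]: {frac}"
                )
        if self.missing_mode not in ("record", "field"):
            raise ConfigurationError(f"unknown missing_mode {self.missing_mode!r}")


def _sample_latitudes(
    bands: Sequence[tuple[float, float]], n: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform sample over a union of intervals: pick a band with probability
    proportional to its width, then uniform within the band."""
    widths = np.array([hi - lo for lo, hi in bands], dtype=float)
    choice = rng.choice(len(bands), size=n, p=widths / widths.sum())
    u = rng.uniform(0.0, 1.0, size=n)
    lows = np.array([lo for lo, _ in bands])[choice]
    return lows + u * widths[choice]


def _band_intersection(
    band_sets: Sequence[Sequence[tuple[float, float]]],
) -> list[tuple[float, float]]:
    current = [tuple(b) for b in band_sets[0]]
    for bands in band_sets[1:]:
        nxt = []
        for lo1, hi1 in current:
            for lo2, hi2 in bands:
                lo, hi = max(lo1, lo2), min(hi1, hi2)
                if lo < hi:
                    nxt.append((lo, hi))
        current = nxt
    if not current:
        raise ConfigurationError(
            "shared_pixels requested but ecotone latitude bands do not intersect"
        )
    return current


def _snap_to_cell_center(x: np.ndarray) -> np.ndarray:
    return np.floor(x) + 0.5


def assign_continent(
    longitude: np.ndarray,
    sectors: Sequence[tuple[float, float, str]] = DEFAULT_CONTINENT_SECTORS,
) -> np.ndarray:
    labels = np.empty(len(longitude), dtype=object)
    labels[:] = "unassigned"
    for lo, hi, name in sectors:
        mask = (longitude >= lo) & (longitude < hi)
        labels[mask] = name
    return labels


def generate_world(config: WorldConfig) -> pd.DataFrame:
    """Generate the synthetic pixel table.

    Returns one row per pixel x ecotone with coordinates, continent label,
    fitness indicators, raw pressure layers, climate covariates and a
    ``no_data`` flag.  Deterministic under ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    shared_coords = None
    if config.shared_pixels:
        bands = _band_intersection(
            [config.latitude_bands[e] for e in config.ecotones]
        )
        n0 = config.n_for(config.ecotones[0])
        lat = _snap_to_cell_center(_sample_latitudes(bands, n0, rng))
        lon = _snap_to_cell_center(rng.uniform(-180.0, 180.0, size=n0))
        shared_coords = (lat, lon)

    frames = []
    for ecotone in config.ecotones:
        n = config.n_for(ecotone)
        if shared_coords is not None:
            lat, lon = shared_coords
            pixel_id = np.array([f"px_{i:06d}" for i in range(n)], dtype=object)
        else:
            lat = _snap_to_cell_center(
                _sample_latitudes(config.latitude_bands[ecotone], n, rng)
            )
            lon = _snap_to_cell_center(rng.uniform(-180.0, 180.0, size=n))
            pixel_id = np.array(
                [f"{ecotone}_{i:06d}" for i in range(n)], dtype=object
            )

        abs_lat = np.abs(lat)
        data: dict[str, np.ndarray] = {
            "pixel_id": pixel_id,
            "latitude": lat,
            "longitude": lon,
            "continent": assign_continent(lon, config.continent_sectors),
            "ecotone": np.full(n, ecotone, dtype=object),
        }
        for name in FITNESS_COLUMNS:
            data[name] = config.fitness_gradients[name].sample(abs_lat, rng)
        for name in PRESSURE_LAYER_COLUMNS:
            mean, sd = config.pressure_levels[name]
            values = rng.normal(mean, sd, size=n)
            values = np.maximum(values, 0.0)
            if name == "species_threat_fraction":
                values = np.minimum(values, 1.0)
            data[name] = values
        for name in CLIMATE_COLUMNS:
            data[name] = config.climate_gradients[name].sample(abs_lat, rng)

        frame = pd.DataFrame(data)
        frame = inject_missingness(
            frame,
            config.missing_fractions.get(ecotone, 0.0),
            rng,
            mode=config.missing_mode,
        )
        frames.append(frame)

    world = pd.concat(frames, ignore_index=True)
    return world


def inject_missingness(
    records: pd.DataFrame,
    fraction: float,
    rng: np.random.Generator | int,
    mode: str = "record",
    columns: Sequence[str] = MISSABLE_COLUMNS,
) -> pd.DataFrame:
    """Blank a fraction of the table.

    ``record`` mode flags exactly ``round(fraction * n)`` whole rows
    (round-half-up) as no-data and blanks every missable column in them;
    ``field`` mode blanks each column independently at the same rate.
    Returns a new frame; the input is not mutated.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"missing fraction outside [0, 1]: {fraction}")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)

    out = records.copy()
    columns = [c for c in columns if c in out.columns]
    n = len(out)
    k = int(math.floor(fraction * n + 0.5))  # round half up

    if "no_data" not in out.columns:
        out["no_data"] = False

    if k == 0:
        return out

    if mode == "record":
        idx = rng.choice(n, size=k, replace=False)
        out.iloc[idx, [out.columns.get_loc(c) for c in columns]] = np.nan
        out.iloc[idx, out.columns.get_loc("no_data")] = True
    elif mode == "field":
        for c in columns:
            idx = rng.choice(n, size=k, replace=False)
            out.iloc[idx, out.columns.get_loc(c)] = np.nan
    else:
        raise ValueError(f"unknown missingness mode {mode!r}")
    return out
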