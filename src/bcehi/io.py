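"""Pixel-table readers/writers, run configuration and the pipeline driver.

The pixel table is a UTF-8 comma-separated CSV, "." decimal, with missing
cells encoded as one of {"", "NA", "NaN"}.  Mandatory columns: pixel_id,
latitude, longitude, ecotone.  ``run_pipeline`` chains the stages
normalize -> benefit/pressure -> hypervolumes -> transformation risk ->
EHI -> breaks/classes -> sensitivity analysis -> trends, writing one file
per report plus a provenance sidecar; reruns with the same config are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from bcehi.synthetic_world import (
    CLIMATE_COLUMNS,
    ECOTONES,
    FITNESS_COLUMNS,
    PRESSURE_LAYER_COLUMNS,
    Gradient,
    WorldConfig,
    generate_world,
)
from bcehi import indicators
from bcehi.hypervolume import overlap_matrix, overlap_table
from bcehi.ehi import (
    assign_transformation_risk,
    classify_ehi,
    compute_ehi,
    fit_class_breaks,
)
from bcehi.stats import covariate_trend, latitudinal_trend, sobol_first_order

MISSING_TOKENS = ("", "NA", "NaN")
MANDATORY_COLUMNS = ("pixel_id", "latitude", "longitude", "ecotone")
NUMERIC_COLUMNS = (
    ("latitude", "longitude")
    + FITNESS_COLUMNS
    + PRESSURE_LAYER_COLUMNS
    + CLIMATE_COLUMNS
)

#: report files produced by a full run
REPORT_FILES = (
    "ehi_table.csv",
    "overlap_matrices.csv",
    "class_summary.csv",
    "class_breaks.csv",
    "sobol.csv",
    "trends.csv",
    "provenance.json",
)

STAGES = ("score", "hypervolume", "ehi", "classify", "gsa", "trends")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def read_pixel_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a pixel-table CSV.

    Missing tokens {"", "NA", "NaN"} become missing values; unknown columns
    are preserved as passthrough.
    """
    table = pd.read_csv(path, na_values=list(MISSING_TOKENS), keep_default_na=False)
    missing_cols = [c for c in MANDATORY_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ValueError(f"missing mandatory column(s): {', '.join(missing_cols)}")

    for col in NUMERIC_COLUMNS:
        if col not in table.columns:
            continue
        coerced = pd.to_numeric(table[col], errors="coerce")
        bad = coerced.isna() & table[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ValueError(
                f"non-numeric cell in column {col!r}, row {row}: "
                f"{table.loc[row, col]!r}"
            )
        table[col] = coerced

    lat = table["latitude"]
    lon = table["longitude"]
    if (lat.dropna().abs() > 90).any():
        raise ValueError("latitude outside [-90, 90]")
    if (lon.dropna().abs() > 180).any():
        raise ValueError("longitude outside [-180, 180]")

    if "no_data" in table.columns:
        table["no_data"] = table["no_data"].astype(str).str.lower().isin(
            ("true", "1")
        )
    else:
        table["no_data"] = False
    return table


def write_pixel_table(table: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)


def pixel_geojson(
    table: pd.DataFrame,
    path: str | Path,
    properties: Sequence[str] = ("ecotone", "ehi", "ehi_class"),
) -> None:
    """Write 1-degree pixel polygons (cell around each centre) as GeoJSON."""
    features = []
    props = [p for p in properties if p in table.columns]
    for _, row in table.iterrows():
        lat0 = float(np.floor(row["latitude"]))
        lon0 = float(np.floor(row["longitude"]))
        ring = [
            [lon0, lat0],
            [lon0 + 1, lat0],
            [lon0 + 1, lat0 + 1],
            [lon0, lat0 + 1],
            [lon0, lat0],
        ]
        val = {}
        for p in props:
            v = row[p]
            val[p] = None if (isinstance(v, float) and np.isnan(v)) else v
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {"pixel_id": row["pixel_id"], **val},
            }
        )
    payload = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(payload, sort_keys=True))


@dataclass
class RunConfig:
    """Effective configuration of one pipeline run (all options defaulted)."""

    input_path: str | None = None
    world: WorldConfig = field(default_factory=WorldConfig)
    ecotones: Sequence[str] = ECOTONES
    clip_quantiles: tuple[float, float] | None = None
    min_present_benefit: int = indicators.DEFAULT_MIN_PRESENT_BENEFIT
    min_present_pressure: int = indicators.DEFAULT_MIN_PRESENT_PRESSURE
    normalize_layers: bool = True
    mass_quantile: float = 0.95
    hv_samples: int | None = None
    hv_min_points: int = 20
    log10_climate: bool = True
    climate_shifts: Mapping[str, float] | None = None
    t_rule: str = "max"
    gsa_n_base: int = 4096
    gsa_n_boot: int = 100
    run_gsa: bool = True
    run_trends: bool = True
    out_dir: str | Path = "bcehi_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        world_raw = raw.pop("world", None)
        config = cls(**raw)
        if world_raw is not None:
            for key in ("climate_gradients", "fitness_gradients"):
                if key in world_raw:
                    world_raw[key] = {
                        name: Gradient(*spec) if not isinstance(spec, Gradient) else spec
                        for name, spec in world_raw[key].items()
                    }
            config.world = WorldConfig(**world_raw)
        return config

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["out_dir"] = str(out["out_dir"])
        out["ecotones"] = list(self.ecotones)
        return out


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True, default=_json_default)
    return hashlib.sha256(payload.encode()).hexdigest()


def _empirical_sampler(columns: dict[str, np.ndarray]):
    names = list(columns)
    pools = [columns[c] for c in names]

    def sampler(rng: np.random.Generator, n: int) -> np.ndarray:
        return np.column_stack([rng.choice(pool, size=n) for pool in pools])

    return sampler


def _gsa_for_ecotone(table: pd.DataFrame, ecotone: str, config: RunConfig, seed: int):
    """Sensitivity of the Benefit/Pressure/EHI closure to its normalized
    inputs, sampled independently from the ecotone's empirical marginals."""
    sub = table[table["ecotone"] == ecotone]
    fitness_cols = [f"norm_{c}" for c in indicators.ECOTONE_BENEFIT_INDICATORS[ecotone]]
    compound_cols = list(indicators.ECOTONE_COMPOUNDS[ecotone])
    labels = fitness_cols + compound_cols + ["t"]

    pools = {}
    for col in labels:
        values = sub[col].to_numpy(dtype=float)
        values = values[~np.isnan(values)]
        if values.size == 0:
            return None  # nothing to resample for this input
        pools[col] = values

    n_fit = len(fitness_cols)
    n_comp = len(compound_cols)

    def model(x: np.ndarray) -> np.ndarray:
        b = x[:, :n_fit].mean(axis=1)
        p = x[:, n_fit : n_fit + n_comp].mean(axis=1)
        t = x[:, n_fit + n_comp]
        return b * (1.0 - p * t)

    result = sobol_first_order(
        model,
        _empirical_sampler(pools),
        n_base=config.gsa_n_base,
        n_boot=config.gsa_n_boot,
        seed=seed,
        labels=labels,
    )
    frame = result.to_frame()
    frame.insert(0, "ecotone", ecotone)
    return frame


def run_pipeline(config: RunConfig, stop_after: str | None = None) -> Path:
    """Run the pipeline and write reports into ``config.out_dir``.

    ``stop_after`` truncates the stage chain (one of ``STAGES``).  Returns
    the output directory.
    """
    if stop_after is not None and stop_after not in STAGES:
        raise ValueError(f"unknown stage {stop_after!r}")
    rank = len(STAGES) if stop_after is None else STAGES.index(stop_after)

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config_hash = _config_hash(config)
    provenance: dict = {"config_hash": config_hash, "seed": config.seed}

    # --- load or synthesize ------------------------------------------------
    if config.input_path is not None:
        table = read_pixel_table(config.input_path)
        provenance["input"] = str(config.input_path)
    else:
        world = dataclasses.replace(config.world, seed=config.seed)
        table = generate_world(world)
        write_pixel_table(table, out_dir / "pixel_table.csv")
        provenance["input"] = "synthetic"
    table = table[table["ecotone"].isin(config.ecotones)].reset_index(drop=True)
    if table.empty:
        raise PipelineError("score", "no records for the requested ecotones")

    # --- benefit / pressure ------------------------------------------------
    try:
        scored, benefit_stats = indicators.score_benefits(
            table,
            min_present=config.min_present_benefit,
            clip_quantiles=config.clip_quantiles,
        )
        scored, pressure_stats = indicators.score_pressures(
            scored,
            normalize_layers=config.normalize_layers,
            min_present=config.min_present_pressure,
            clip_quantiles=config.clip_quantiles,
        )
    except Exception as exc:  # pragma: no cover - defensive
        raise PipelineError("score", str(exc)) from exc
    provenance["normalization"] = {
        "benefit": benefit_stats,
        "pressure": pressure_stats,
    }

    if rank >= STAGES.index("hypervolume"):
        # --- hypervolumes and overlaps ------------------------------------
        try:
            matrices = overlap_matrix(
                scored,
                grouping="worldwide",
                ecotones=tuple(config.ecotones),
                mass_quantile=config.mass_quantile,
                n_samples=config.hv_samples,
                min_points=config.hv_min_points,
                seed=config.seed,
                log10_transform=config.log10_climate,
                shifts=config.climate_shifts,
            )
            matrices.update(
                overlap_matrix(
                    scored,
                    grouping="continent",
                    ecotones=tuple(config.ecotones),
                    mass_quantile=config.mass_quantile,
                    n_samples=config.hv_samples,
                    min_points=config.hv_min_points,
                    seed=config.seed,
                    log10_transform=config.log10_climate,
                    shifts=config.climate_shifts,
                )
            )
        except Exception as exc:
            raise PipelineError("hypervolume", str(exc)) from exc
        overlap_table(matrices).to_csv(out_dir / "overlap_matrices.csv")
        provenance["hypervolume"] = {
            "mass_quantile": config.mass_quantile,
            "volumes": {r: m.volumes for r, m in matrices.items()},
            "n_points": {r: m.n_points for r, m in matrices.items()},
        }

    if rank >= STAGES.index("ehi"):
        # --- transformation risk and EHI ----------------------------------
        try:
            risk_cache: dict[tuple[str, str], float] = {}
            t_sources: dict[str, str] = {}
            for key in set(
                zip(scored["ecotone"], scored["continent"].astype(str))
            ):
                risk = assign_transformation_risk(
                    matrices, key[0], key[1], rule=config.t_rule
                )
                risk_cache[key] = risk.value
                t_sources[f"{key[0]}|{key[1]}"] = risk.source_region
            scored["t"] = [
                risk_cache[(e, str(c))]
                for e, c in zip(scored["ecotone"], scored["continent"])
            ]
            scored["ehi"] = compute_ehi(
                scored["b"].to_numpy(),
                scored["p_total"].to_numpy(),
                scored["t"].to_numpy(),
            )
        except Exception as exc:
            raise PipelineError("ehi", str(exc)) from exc
        provenance["transformation_risk"] = {
            "rule": config.t_rule,
            "sources": dict(sorted(t_sources.items())),
        }

    if rank >= STAGES.index("classify"):
        # --- natural breaks and classes -----------------------------------
        try:
            breaks = {}
            for ecotone in sorted(scored["ecotone"].unique()):
                values = scored.loc[scored["ecotone"] == ecotone, "ehi"].dropna()
                if values.nunique() < 3:
                    warnings.warn(
                        f"too few distinct EHI values to fit breaks for "
                        f"{ecotone}; all records classed NoData"
                    )
                    continue
                breaks[ecotone] = fit_class_breaks(values.to_numpy(), ecotone)
            scored, class_summary = classify_ehi(scored, breaks)
        except Exception as exc:
            raise PipelineError("classify", str(exc)) from exc
        pd.DataFrame(
            [dataclasses.asdict(b) for b in breaks.values()]
        ).to_csv(out_dir / "class_breaks.csv", index=False)
        class_summary.to_csv(out_dir / "class_summary.csv", index=False)

        ehi_columns = [
            "pixel_id", "latitude", "longitude", "continent", "ecotone",
            "b", "p_climate", "p_land", "p_marine", "p_species", "p_total",
            "t", "ehi", "ehi_class", "no_data",
        ]
        scored[ehi_columns].to_csv(out_dir / "ehi_table.csv", index=False)

        # record-count conservation: classified + no-data == input, per ecotone
        for _, row in class_summary.iterrows():
            counted = sum(
                row[f"count_{label.lower()}"]
                for label in ("High", "Medium", "Low", "NoData")
            )
            if counted != row["n"]:
                raise PipelineError(
                    "classify",
                    f"record-count conservation violated for {row['ecotone']}",
                )

    if rank >= STAGES.index("gsa") and config.run_gsa:
        # --- global sensitivity analysis ----------------------------------
        try:
            gsa_seed = int(
                np.random.SeedSequence(
                    entropy=config.seed, spawn_key=(1,)
                ).generate_state(1)[0]
            )
            frames = [
                frame
                for ecotone in sorted(scored["ecotone"].unique())
                if (frame := _gsa_for_ecotone(scored, ecotone, config, gsa_seed))
                is not None
            ]
        except Exception as exc:
            raise PipelineError("gsa", str(exc)) from exc
        sobol = (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(columns=["ecotone", "variable", "s1", "se", "q05"])
        )
        sobol.to_csv(out_dir / "sobol.csv", index=False)
        provenance["gsa"] = {
            "n_base": config.gsa_n_base,
            "n_boot": config.gsa_n_boot,
            "inputs": "independent resampling of empirical marginals "
            "(rank correlations ignored)",
        }

    if rank >= STAGES.index("trends") and config.run_trends:
        # --- trend regressions --------------------------------------------
        rows = []
        for ecotone in sorted(scored["ecotone"].unique()):
            try:
                fit = latitudinal_trend(scored, ecotone)
            except ValueError as exc:
                warnings.warn(f"latitudinal trend skipped for {ecotone}: {exc}")
                continue
            rows.append({"ecotone": ecotone, "kind": "latitudinal",
                         **dataclasses.asdict(fit)})
        mangrove = scored[scored["ecotone"] == "mangrove"]
        if not mangrove.empty and "soc" in mangrove.columns:
            try:
                fit = covariate_trend(mangrove, "ehi", "soc")
                rows.append({"ecotone": "mangrove", "kind": "covariate",
                             **dataclasses.asdict(fit)})
            except ValueError as exc:
                warnings.warn(f"EHI-SOC trend skipped: {exc}")
        pd.DataFrame(rows).to_csv(out_dir / "trends.csv", index=False)

    # --- provenance + config echo -----------------------------------------
    (out_dir / "provenance.json").write_text(
        json.dumps(provenance, sort_keys=True, indent=2, default=_json_default)
    )
    (out_dir / "config.yaml").write_text(
        yaml.safe_dump(
            {"config_hash": config_hash, **json.loads(
                json.dumps(config.to_dict(), default=_json_default)
            )},
            sort_keys=True,
        )
    )
    return out_dir
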