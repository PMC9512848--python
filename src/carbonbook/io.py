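"""NetCDF/CSV readers and writers, conservative regridding, configuration.

Gridded fields travel as CF-style NetCDF (dimensions time/lat/lon, written
with the NetCDF3-classic backend), tabular summaries as CSV.  Densities
are expected in t C ha^-1; kg C m^-2 inputs are converted (x10) on read.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import xarray as xr
import yaml
from pydantic import BaseModel, ConfigDict, field_validator

from .assimilation import DensitySeries, ThresholdPolicy
from .core import GridSpec, TransitionForcing, ValidationError, FLUX_CATEGORIES

NC_ENGINE = "scipy"
FILL = -9999.0
DENSITY_UNITS = ("t C ha-1", "tC ha-1", "t ha-1", "Mg ha-1", "MgC ha-1")
KG_M2_UNITS = ("kg C m-2", "kgC m-2", "kg m-2")


# ---------------------------------------------------------------------------
# Gridded I/O
# ---------------------------------------------------------------------------

def grid_from_dataset(ds: xr.Dataset) -> GridSpec:
    for dim in ("lat", "lon"):
        if dim not in ds.coords:
            raise ValidationError(f"input file lacks a '{dim}' coordinate")
    return GridSpec(lat=ds["lat"].values, lon=ds["lon"].values)


def write_density_netcdf(path, densities: DensitySeries, grid: GridSpec,
                         units: str = "t C ha-1") -> None:
    vals = np.where(densities.valid, densities.values, FILL)
    vals = vals.reshape(densities.values.shape[0], grid.n_lat, grid.n_lon)
    ds = xr.Dataset(
        {"woody_biomass_density": (("time", "lat", "lon"), vals,
                                   {"units": units, "_FillValue": FILL})},
        coords={"time": densities.years, "lat": grid.lat, "lon": grid.lon})
    ds.to_netcdf(path, engine=NC_ENGINE)


def read_density_netcdf(path) -> tuple[DensitySeries, GridSpec]:
    """Read an annual density cube; mask from the fill value, units checked."""
    ds = xr.open_dataset(path, engine=NC_ENGINE, mask_and_scale=False)
    name = "woody_biomass_density" if "woody_biomass_density" in ds else None
    if name is None:
        cands = [v for v in ds.data_vars
                 if set(ds[v].dims) == {"time", "lat", "lon"}]
        if not cands:
            raise ValidationError("no (time, lat, lon) variable found")
        name = cands[0]
    var = ds[name]
    for dim in ("time", "lat", "lon"):
        if dim not in var.dims:
            raise ValidationError(f"density variable lacks dimension '{dim}'")
    units = var.attrs.get("units")
    if units is None:
        raise ValidationError("density variable lacks a 'units' attribute")
    vals = var.transpose("time", "lat", "lon").values.astype(float)
    fill = var.attrs.get("_FillValue", FILL)
    valid = np.isfinite(vals) & (vals != fill)
    if units in KG_M2_UNITS:
        vals = np.where(valid, vals * 10.0, vals)  # 1 kg m^-2 = 10 t ha^-1
    elif units not in DENSITY_UNITS:
        raise ValidationError(f"unsupported density units {units!r}")
    grid = grid_from_dataset(ds)
    n_yr = vals.shape[0]
    series = DensitySeries(years=ds["time"].values.astype(int),
                           values=np.where(valid, vals, 0.0).reshape(n_yr, -1),
                           valid=valid.reshape(n_yr, -1))
    return series, grid


def write_field_netcdf(path, fields: dict, grid: GridSpec,
                       years: Optional[np.ndarray] = None,
                       units: Optional[dict] = None) -> None:
    """Write named per-cell fields ((n_cell,) or (n_yr, n_cell)) as NetCDF."""
    data = {}
    units = units or {}
    for name, arr in fields.items():
        arr = np.asarray(arr, dtype=float)
        attrs = {"units": units.get(name, "")}
        if arr.ndim == 1:
            data[name] = (("lat", "lon"),
                          arr.reshape(grid.n_lat, grid.n_lon), attrs)
        else:
            data[name] = (("time", "lat", "lon"),
                          arr.reshape(arr.shape[0], grid.n_lat, grid.n_lon),
                          attrs)
    coords = {"lat": grid.lat, "lon": grid.lon}
    if years is not None:
        coords["time"] = np.asarray(years)
    xr.Dataset(data, coords=coords).to_netcdf(path, engine=NC_ENGINE)


def read_region_mask_netcdf(path) -> tuple[np.ndarray, GridSpec]:
    ds = xr.open_dataset(path, engine=NC_ENGINE, mask_and_scale=False)
    grid = grid_from_dataset(ds)
    name = next(iter(ds.data_vars))
    return ds[name].values.astype(int).reshape(-1), grid


# ---------------------------------------------------------------------------
# Conservative (area-weighted) regridding
# ---------------------------------------------------------------------------

def _edges(centres: np.ndarray) -> np.ndarray:
    centres = np.asarray(centres, dtype=float)
    if centres.size == 1:
        return np.array([centres[0] - 0.5, centres[0] + 0.5])
    d = centres[1] - centres[0]
    return np.concatenate([[centres[0] - d / 2.0],
                           centres[:-1] + d / 2.0, [centres[-1] + d / 2.0]])


def _overlap_matrix(src_edges, tgt_edges) -> np.ndarray:
    """ (n_tgt, n_src) interval-overlap lengths; orientation-agnostic."""
    s0 = np.minimum(src_edges[:-1], src_edges[1:])
    s1 = np.maximum(src_edges[:-1], src_edges[1:])
    t0 = np.minimum(tgt_edges[:-1], tgt_edges[1:])
    t1 = np.maximum(tgt_edges[:-1], tgt_edges[1:])
    lo = np.maximum(t0[:, None], s0[None, :])
    hi = np.minimum(t1[:, None], s1[None, :])
    return np.clip(hi - lo, 0.0, None)


def conservative_remap(field: np.ndarray, source: GridSpec,
                       target: GridSpec) -> np.ndarray:
    """Area-weighted (conservative) remap of a 2-D field between regular grids.

    Weights are the product of longitudinal overlap and the spherical band
    measure sin(lat) overlap, so the global area-weighted integral of an
    intensive field is preserved.
    """
    f = np.asarray(field, dtype=float).reshape(source.n_lat, source.n_lon)
    w_lon = _overlap_matrix(_edges(source.lon), _edges(target.lon))
    lat_s = np.sin(np.radians(np.clip(_edges(source.lat), -90, 90)))
    lat_t = np.sin(np.radians(np.clip(_edges(target.lat), -90, 90)))
    w_lat = _overlap_matrix(lat_s, lat_t)
    if w_lon.sum() == 0 or w_lat.sum() == 0:
        raise ValidationError("source and target grids do not overlap")
    num = w_lat @ f @ w_lon.T
    den = np.outer(w_lat.sum(axis=1), w_lon.sum(axis=1))
    if np.any(den <= 0):
        raise ValidationError("target grid extends beyond the source grid")
    return num / den


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------

def write_annual_series_csv(path, decomposition) -> None:
    df = decomposition.summary()
    for cat in FLUX_CATEGORIES:
        df[f"E_LUC_transient_{cat}"] = decomposition.eluc_transient[cat]
        df[f"E_LUC_fixed_{cat}"] = decomposition.eluc_fixed[cat]
    df.to_csv(path, float_format="%.10g")


def write_forcing_netcdf(path, forcing: TransitionForcing, grid: GridSpec) -> None:
    n_yr = forcing.years.size

    def cube(a):
        return a.reshape(n_yr, grid.n_lat, grid.n_lon)

    ds = xr.Dataset(
        {
            "clearing_vc": (("time", "lat", "lon"), cube(forcing.clearing[:, :, 0, 0])),
            "clearing_vp": (("time", "lat", "lon"), cube(forcing.clearing[:, :, 0, 1])),
            "clearing_sc": (("time", "lat", "lon"), cube(forcing.clearing[:, :, 1, 0])),
            "clearing_sp": (("time", "lat", "lon"), cube(forcing.clearing[:, :, 1, 1])),
            "abandonment_c": (("time", "lat", "lon"), cube(forcing.abandonment[:, :, 0])),
            "abandonment_p": (("time", "lat", "lon"), cube(forcing.abandonment[:, :, 1])),
            "harvest": (("time", "lat", "lon"), cube(forcing.harvest)),
        },
        coords={"time": forcing.years, "lat": grid.lat, "lon": grid.lon})
    ds.to_netcdf(path, engine=NC_ENGINE)


def read_forcing_netcdf(path) -> tuple[TransitionForcing, GridSpec]:
    ds = xr.open_dataset(path, engine=NC_ENGINE, mask_and_scale=False)
    grid = grid_from_dataset(ds)
    years = ds["time"].values.astype(int)
    n_yr = years.size

    def flat(name):
        return ds[name].transpose("time", "lat", "lon").values.reshape(n_yr, -1)

    clearing = np.stack([
        np.stack([flat("clearing_vc"), flat("clearing_vp")], axis=-1),
        np.stack([flat("clearing_sc"), flat("clearing_sp")], axis=-1),
    ], axis=-2)
    aband = np.stack([flat("abandonment_c"), flat("abandonment_p")], axis=-1)
    return TransitionForcing(years=years, clearing=clearing,
                             abandonment=aband, harvest=flat("harvest")), grid


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

class PipelineConfig(BaseModel):
    """Schema-validated run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    out_dir: str = "out"
    seed: int = 0
    t0: int = 2000
    t_end: int = 2019
    n_lat: int = 20
    n_lon: int = 20
    threshold_modes: list[str] = ["uniform", "percentile"]
    uniform_limit: float = 375.0
    percentile: float = 99.0
    harvest_intensity: float = 1.0
    tau_clearing: float = 1.0
    tau_harvest_decay: float = 2.0
    tau_regrowth: float = 15.0
    density_path: Optional[str] = None
    forcing_path: Optional[str] = None
    log_level: str = "INFO"
    # synthetic-world knobs (used by the `synth` stage)
    env_trend: float = 0.005
    env_noise_sd: float = 0.01
    temp_coupling: float = 0.02
    clearing_rate: float = 0.003
    harvest_rate: float = 0.002
    abandonment_rate: float = 0.001
    noise_sd: float = 2.0
    missing_fraction: float = 0.02

    @field_validator("threshold_modes")
    @classmethod
    def _modes(cls, v):
        for m in v:
            if m not in ("uniform", "percentile"):
                raise ValueError(f"unknown threshold mode {m!r}")
        return v

    def policies(self) -> list[ThresholdPolicy]:
        return [ThresholdPolicy(mode=m, uniform_limit=self.uniform_limit,
                                percentile=self.percentile)
                for m in self.threshold_modes]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def write_manifest(path, config: PipelineConfig, extra: Optional[dict] = None) -> None:
    import numpy
    from . import __version__
    manifest = {"package": "carbonbook", "version": __version__,
                "numpy": numpy.__version__,
                "config": config.model_dump()}
    manifest.update(extra or {})
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))
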