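"""Readers and writers for the gridded and flat tabular dialects.

Two dialects carry a :class:`~ecoprov.preprocess.GriddedEcosystemField`:

``flat_csv``
    One row per grid cell with columns ``lat, lon, biomass_group_1..7``
    (and/or ``biomass_type_01..51``), ``flux_N/Fe/P/Si``, ``ice_fraction``
    and optionally ``true_label``.  Plain text, diffable, the default.
``netcdf_grid``
    The same variables as 2-D (lat, lon) arrays in a NetCDF file (written
    with xarray's scipy backend, i.e. NetCDF-3).

Derived artifacts (feature matrices, embeddings, labelings, scans) are CSVs
with ``#``-prefixed provenance header lines plus a JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import xarray as xr

from .clustering import DBSCANParams, ProvinceLabeling
from .embedding import Embedding3D
from .errors import ValidationError
from .preprocess import (
    FEATURE_COLUMNS,
    FeatureMatrix,
    GriddedEcosystemField,
    N_GROUPS,
    N_TYPES,
    NUTRIENT_NAMES,
    default_type_groups,
)

_GROUP_COLS = [f"biomass_group_{g + 1}" for g in range(N_GROUPS)]
_TYPE_COLS = [f"biomass_type_{t + 1:02d}" for t in range(N_TYPES)]
_FLUX_COLS = [f"flux_{n}" for n in NUTRIENT_NAMES]


def _provenance_lines(**kw) -> str:
    return "".join(f"# {k}: {v}\n" for k, v in kw.items())


def _detect_dialect(path: Union[str, Path], dialect: Optional[str]) -> str:
    if dialect:
        return dialect
    suffix = Path(path).suffix.lower()
    return "netcdf_grid" if suffix in (".nc", ".cdf", ".netcdf") else "flat_csv"


# ---------------------------------------------------------------------------
# gridded field
# ---------------------------------------------------------------------------

def write_field(field: GriddedEcosystemField, path: Union[str, Path],
                dialect: Optional[str] = None, include_types: bool = True) -> Path:
    """Write a field in either dialect; returns the path written."""
    path = Path(path)
    dialect = _detect_dialect(path, dialect)
    field.validate()
    n_lat, n_lon = field.shape
    if dialect == "flat_csv":
        glat, glon = np.meshgrid(field.lat, field.lon, indexing="ij")
        data = {"lat": glat.ravel(), "lon": glon.ravel()}
        if field.group_biomass is not None:
            for g, col in enumerate(_GROUP_COLS):
                data[col] = field.group_biomass[g].ravel()
        if include_types and field.type_biomass is not None:
            for t, col in enumerate(_TYPE_COLS):
                data[col] = field.type_biomass[t].ravel()
        for i, col in enumerate(_FLUX_COLS):
            data[col] = field.nutrient_flux[i].ravel()
        data["ice_fraction"] = field.ice_fraction.ravel()
        if field.true_labels is not None:
            data["true_label"] = field.true_labels.ravel()
        pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")
        return path
    ds = field_to_dataset(field, include_types=include_types)
    ds.to_netcdf(path, engine="scipy")
    return path


def field_to_dataset(field: GriddedEcosystemField, include_types: bool = True) -> xr.Dataset:
    coords = {"lat": field.lat, "lon": field.lon}
    data_vars = {}
    if field.group_biomass is not None:
        for g, col in enumerate(_GROUP_COLS):
            data_vars[col] = (("lat", "lon"), field.group_biomass[g])
    if include_types and field.type_biomass is not None:
        for t, col in enumerate(_TYPE_COLS):
            data_vars[col] = (("lat", "lon"), field.type_biomass[t])
    for i, col in enumerate(_FLUX_COLS):
        data_vars[col] = (("lat", "lon"), field.nutrient_flux[i])
    data_vars["ice_fraction"] = (("lat", "lon"), field.ice_fraction)
    if field.true_labels is not None:
        data_vars["true_label"] = (("lat", "lon"), field.true_labels)
    attrs = {k: v for k, v in field.attrs.items() if isinstance(v, (str, int, float))}
    return xr.Dataset(data_vars, coords=coords, attrs=attrs)


def _field_from_arrays(lat, lon, cols: dict[str, np.ndarray]) -> GriddedEcosystemField:
    has_groups = all(c in cols for c in _GROUP_COLS)
    has_types = all(c in cols for c in _TYPE_COLS)
    if not (has_groups or has_types):
        raise ValidationError(
            "missing variable: need biomass_group_1..7 or biomass_type_01..51"
        )
    missing = [c for c in _FLUX_COLS + ["ice_fraction"] if c not in cols]
    if missing:
        raise ValidationError(f"missing variable(s): {missing}")
    shape = (len(lat), len(lon))
    for name, arr in cols.items():
        if arr.shape != shape:
            raise ValidationError(f"shape mismatch for {name}: {arr.shape} != {shape}")
    field = GriddedEcosystemField(
        lat=np.asarray(lat, dtype=float),
        lon=np.asarray(lon, dtype=float),
        nutrient_flux=np.stack([cols[c] for c in _FLUX_COLS]),
        ice_fraction=cols["ice_fraction"],
        group_biomass=np.stack([cols[c] for c in _GROUP_COLS]) if has_groups else None,
        type_biomass=np.stack([cols[c] for c in _TYPE_COLS]) if has_types else None,
        type_groups=default_type_groups() if has_types else None,
        true_labels=cols["true_label"].astype(int) if "true_label" in cols else None,
    )
    return field.validate()


def read_field(path: Union[str, Path], dialect: Optional[str] = None) -> GriddedEcosystemField:
    """Read and validate a gridded field from either dialect.

    NaN entries are normalised to a single missing-data sentinel (NaN).
    Raises named :class:`ValidationError`\\ s for missing variables, shape
    mismatches and non-monotone coordinates.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    dialect = _detect_dialect(path, dialect)
    if dialect == "netcdf_grid":
        with xr.open_dataset(path, engine="scipy") as ds:
            lat = ds["lat"].values
            lon = ds["lon"].values
            cols = {name: ds[name].values.astype(float) for name in ds.data_vars}
            if "true_label" in cols:
                cols["true_label"] = ds["true_label"].values
        return _field_from_arrays(lat, lon, cols)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    for c in ("lat", "lon"):
        if c not in df.columns:
            raise ValidationError(f"missing variable: {c}")
    lat = np.unique(df["lat"].to_numpy())
    lon = np.unique(df["lon"].to_numpy())
    if len(df) != len(lat) * len(lon):
        raise ValidationError(
            f"flat CSV is not a full grid: {len(df)} rows != {len(lat)} x {len(lon)}"
        )
    df = df.sort_values(["lat", "lon"])
    shape = (len(lat), len(lon))
    cols = {
        c: df[c].to_numpy().reshape(shape)
        for c in df.columns
        if c not in ("lat", "lon")
    }
    return _field_from_arrays(lat, lon, cols)


def write_truth_labels(field: GriddedEcosystemField, path: Union[str, Path]) -> Path:
    """Sidecar truth-label table (lat, lon, true_label) for synthetic fields."""
    if field.true_labels is None:
        raise ValidationError("field has no true labels")
    glat, glon = np.meshgrid(field.lat, field.lon, indexing="ij")
    pd.DataFrame(
        {"lat": glat.ravel(), "lon": glon.ravel(), "true_label": field.true_labels.ravel()}
    ).to_csv(path, index=False, float_format="%.17g")
    return Path(path)


# ---------------------------------------------------------------------------
# derived artifacts (CSV + JSON sidecar, '#' provenance header)
# ---------------------------------------------------------------------------

def _write_csv_with_provenance(df: pd.DataFrame, path: Path, provenance: dict) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_lines(**provenance))
        df.to_csv(fh, index=False, float_format="%.17g")


def write_feature_matrix(fm: FeatureMatrix, path: Union[str, Path],
                         provenance: Optional[dict] = None) -> Path:
    path = Path(path)
    df = fm.index_map.copy()
    for i, col in enumerate(fm.columns):
        df[col] = fm.values[:, i]
    _write_csv_with_provenance(df, path, {"stage": fm.stage, **(provenance or {})})
    sidecar = {"stage": fm.stage, "columns": fm.columns, "meta": _jsonable(fm.meta),
               **(provenance or {})}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_feature_matrix(path: Union[str, Path]) -> FeatureMatrix:
    path = Path(path)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    sidecar = json.loads(path.with_suffix(".json").read_text())
    columns = sidecar.get("columns", list(FEATURE_COLUMNS))
    fm = FeatureMatrix(
        values=df[columns].to_numpy(float),
        index_map=df[["cell_id", "lon", "lat"]].copy(),
        stage=sidecar.get("stage", "raw11"),
        columns=list(columns),
        meta=sidecar.get("meta", {}),
    )
    return fm.validate()


def write_embedding(emb: Embedding3D, cell_ids: np.ndarray, path: Union[str, Path],
                    provenance: Optional[dict] = None) -> Path:
    path = Path(path)
    df = pd.DataFrame({"cell_id": cell_ids, "y1": emb.Y[:, 0], "y2": emb.Y[:, 1],
                       "y3": emb.Y[:, 2]})
    _write_csv_with_provenance(df, path, {"seed": emb.seed, "stage": "embedding",
                                          **(provenance or {})})
    sidecar = {
        "seed": emb.seed, "perplexity": emb.perplexity, "n_iter": emb.n_iter,
        "kl_final": emb.kl_final, "method": emb.method, "params": _jsonable(emb.params),
        **(provenance or {}),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_embedding(path: Union[str, Path]) -> tuple[Embedding3D, np.ndarray]:
    path = Path(path)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    sc = json.loads(path.with_suffix(".json").read_text())
    emb = Embedding3D(
        Y=df[["y1", "y2", "y3"]].to_numpy(float),
        kl_final=float(sc["kl_final"]),
        seed=int(sc["seed"]),
        perplexity=float(sc["perplexity"]),
        n_iter=int(sc["n_iter"]),
        method=sc.get("method", "exact"),
        params=sc.get("params", {}),
    )
    return emb, df["cell_id"].to_numpy()


def write_labeling(labeling: ProvinceLabeling, path: Union[str, Path],
                   provenance: Optional[dict] = None) -> Path:
    path = Path(path)
    if labeling.cell_ids is None:
        raise ValidationError("labeling carries no cell_ids")
    df = pd.DataFrame({"cell_id": labeling.cell_ids, "label": labeling.labels})
    prov = {"eps": labeling.params.eps, "min_pts": labeling.params.min_pts,
            "realization": labeling.realization_id, "stage": "labels",
            **(provenance or {})}
    _write_csv_with_provenance(df, path, prov)
    path.with_suffix(".json").write_text(json.dumps(prov, indent=2))
    return path


def read_labeling(path: Union[str, Path]) -> ProvinceLabeling:
    path = Path(path)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    sc = json.loads(path.with_suffix(".json").read_text())
    return ProvinceLabeling(
        labels=df["label"].to_numpy(int),
        params=DBSCANParams(eps=float(sc["eps"]), min_pts=int(sc["min_pts"])),
        cell_ids=df["cell_id"].to_numpy(),
        realization_id=int(sc.get("realization", 0)),
    )


def write_label_grid(grid: np.ndarray, lat: np.ndarray, lon: np.ndarray,
                     path: Union[str, Path], fill: int = -1,
                     var_name: str = "label") -> Path:
    """Merge a back-projected integer label layer into the gridded dialect."""
    path = Path(path)
    ds = xr.Dataset(
        {var_name: (("lat", "lon"), grid.astype(np.int32))},
        coords={"lat": lat, "lon": lon},
        attrs={"fill_value": fill},
    )
    if path.suffix.lower() in (".nc", ".cdf", ".netcdf"):
        ds.to_netcdf(path, engine="scipy")
    else:
        glat, glon = np.meshgrid(lat, lon, indexing="ij")
        pd.DataFrame({"lat": glat.ravel(), "lon": glon.ravel(),
                      var_name: grid.ravel()}).to_csv(path, index=False)
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
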