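"""Raw-field containers, functional-group summation, masking and feature transforms.

The pipeline works on a gridded (lat x lon) surface field carrying the biomass
of 51 plankton types organised into 7 biogeochemical functional groups, four
nutrient supply rates (N, Fe, P, Si) and an ice-cover fraction.  Summing the 51
types within their functional groups reduces the feature space from 55 to 11
dimensions (7 group biomasses + 4 fluxes).  Grid cells with negligible total
biomass or persistent ice cover are discarded, and the surviving 11-dimensional
vectors are log-transformed (biomass), min-max normalised and standardised
before the embedding stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Functional-group names in canonical order.
GROUP_NAMES = [
    "pico_prokaryotes",
    "pico_eukaryotes",
    "coccolithophores",
    "diazotrophs",
    "diatoms",
    "dinoflagellates",
    "zooplankton",
]

#: Number of plankton types in each functional group (sums to 51).
GROUP_SIZES = [2, 2, 5, 5, 11, 10, 16]

#: Nutrient supply-rate names in canonical order (mmol/m^3/yr).
NUTRIENT_NAMES = ["N", "Fe", "P", "Si"]

N_TYPES = sum(GROUP_SIZES)  # 51
N_GROUPS = len(GROUP_NAMES)  # 7
N_FEATURES = N_GROUPS + len(NUTRIENT_NAMES)  # 11

#: Default masking thresholds.
BIOMASS_THRESHOLD = 1.2e-3  # mg Chl/m^3, total per cell
ICE_THRESHOLD = 0.7  # ice-cover fraction

#: Feature-column names of the 11-dimensional vector x.
FEATURE_COLUMNS = GROUP_NAMES + [f"flux_{n}" for n in NUTRIENT_NAMES]


def default_type_groups() -> np.ndarray:
    """Group index (0..6) for each of the 51 plankton types, in block order."""
    return np.repeat(np.arange(N_GROUPS), GROUP_SIZES)


@dataclass
class GriddedEcosystemField:
    """Surface lat/lon field of plankton biomass, nutrient fluxes and ice cover.

    Parameters
    ----------
    lat, lon
        Cell-centre coordinates in degrees; latitude in [-90, 90], longitude
        in [-180, 180).  Both strictly monotone increasing.
    nutrient_flux
        Array of shape (4, n_lat, n_lon): N, Fe, P, Si supply rates
        (mmol/m^3/yr).
    ice_fraction
        Array of shape (n_lat, n_lon) in [0, 1].
    group_biomass
        Optional (7, n_lat, n_lon) functional-group biomass (mg C/m^3, or
        mg Chl/m^3 depending on the source field's convention).
    type_biomass
        Optional (51, n_lat, n_lon) per-type biomass.
    type_groups
        Group membership index for each type layer; defaults to the canonical
        block ordering when type_biomass is present.
    true_labels
        Optional (n_lat, n_lon) integer layer of planted province labels for
        synthetic fields (-1 = no province: masked, iced or low-biomass cell).
    attrs
        Free-form provenance metadata (seed, generator bookkeeping, ...).
    """

    lat: np.ndarray
    lon: np.ndarray
    nutrient_flux: np.ndarray
    ice_fraction: np.ndarray
    group_biomass: Optional[np.ndarray] = None
    type_biomass: Optional[np.ndarray] = None
    type_groups: Optional[np.ndarray] = None
    true_labels: Optional[np.ndarray] = None
    attrs: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        self.nutrient_flux = np.asarray(self.nutrient_flux, dtype=float)
        self.ice_fraction = np.asarray(self.ice_fraction, dtype=float)
        if self.type_biomass is not None and self.type_groups is None:
            self.type_groups = default_type_groups()

    # -- geometry helpers -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return len(self.lat), len(self.lon)

    @property
    def n_cells(self) -> int:
        return len(self.lat) * len(self.lon)

    def cell_latlon(self, cell_id: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map flat cell ids (ilat * n_lon + ilon) to (lat, lon) degrees."""
        cell_id = np.asarray(cell_id)
        n_lon = len(self.lon)
        return self.lat[cell_id // n_lon], self.lon[cell_id % n_lon]

    def total_biomass(self) -> np.ndarray:
        """Per-cell total biomass, summed over the 7 functional groups."""
        if self.group_biomass is None:
            raise ValidationError("group_biomass not populated; run sum_functional_groups first")
        return self.group_biomass.sum(axis=0)

    # -- validation --------------------------------------------------------
    def validate(self, rtol: float = 1e-6) -> "GriddedEcosystemField":
        n_lat, n_lon = self.shape
        if n_lat < 1 or n_lon < 1:
            raise ValidationError("grid dimensions must be positive")
        for name, vec in (("lat", self.lat), ("lon", self.lon)):
            if np.any(np.diff(vec) <= 0):
                raise ValidationError(f"non-monotone {name} coordinate")
        if np.any(self.lat < -90) or np.any(self.lat > 90):
            raise ValidationError("latitude outside [-90, 90]")
        if self.nutrient_flux.shape != (len(NUTRIENT_NAMES), n_lat, n_lon):
            raise ValidationError(
                f"nutrient_flux shape {self.nutrient_flux.shape} != (4, {n_lat}, {n_lon})"
            )
        if self.ice_fraction.shape != (n_lat, n_lon):
            raise ValidationError("ice_fraction shape mismatch")
        finite_ice = self.ice_fraction[np.isfinite(self.ice_fraction)]
        if np.any(finite_ice < 0) or np.any(finite_ice > 1):
            raise ValidationError("ice_fraction outside [0, 1]")
        for name, arr, d in (
            ("group_biomass", self.group_biomass, N_GROUPS),
            ("type_biomass", self.type_biomass, N_TYPES),
        ):
            if arr is None:
                continue
            if arr.shape != (d, n_lat, n_lon):
                raise ValidationError(f"{name} shape {arr.shape} != ({d}, {n_lat}, {n_lon})")
            if np.any(arr[np.isfinite(arr)] < 0):
                raise ValidationError(f"negative values in {name}")
        if np.any(self.nutrient_flux[np.isfinite(self.nutrient_flux)] < 0):
            raise ValidationError("negative nutrient fluxes")
        if self.group_biomass is not None and self.type_biomass is not None:
            summed = _sum_types(self.type_biomass, self.type_groups)
            scale = np.maximum(np.abs(self.group_biomass), 1e-300)
            if np.nanmax(np.abs(summed - self.group_biomass) / scale) > rtol:
                raise ValidationError(
                    "group_biomass inconsistent with per-type sums (relative tolerance "
                    f"{rtol:g} exceeded)"
                )
        return self


@dataclass
class FeatureMatrix:
    """Masked n x 11 feature table with an index map back to grid cells.

    ``values[i]`` is the 11-dimensional vector x_i of cell ``index_map.cell_id[i]``;
    ``stage`` records the transform state (raw11 -> logged -> minmax ->
    standardized) and ``intermediates`` keeps every earlier stage's values so
    either normalisation convention can be retrieved.
    """

    values: np.ndarray
    index_map: pd.DataFrame  # columns: cell_id, lon, lat
    stage: str = "raw11"
    columns: list[str] = dc_field(default_factory=lambda: list(FEATURE_COLUMNS))
    intermediates: dict = dc_field(default_factory=dict)
    meta: dict = dc_field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def cell_ids(self) -> np.ndarray:
        return self.index_map["cell_id"].to_numpy()

    def validate(self) -> "FeatureMatrix":
        if self.values.ndim != 2 or self.values.shape[1] != len(self.columns):
            raise ValidationError("feature matrix shape inconsistent with columns")
        if len(self.index_map) != self.n:
            raise ValidationError("index_map length mismatch")
        if self.index_map["cell_id"].duplicated().any():
            raise ValidationError("index_map is not injective into grid cells")
        return self


def _sum_types(type_biomass: np.ndarray, type_groups: np.ndarray) -> np.ndarray:
    out = np.zeros((N_GROUPS,) + type_biomass.shape[1:])
    for g in range(N_GROUPS):
        out[g] = type_biomass[type_groups == g].sum(axis=0)
    return out


def sum_functional_groups(
    field: GriddedEcosystemField, type_groups: Optional[np.ndarray] = None
) -> GriddedEcosystemField:
    """Populate the 7 group-biomass layers by summing the 51 type layers.

    ``type_groups`` maps each type layer to a functional group and must
    partition all 51 types over the 7 groups (the canonical block sizes are
    2 + 2 + 5 + 5 + 11 + 10 + 16).
    """
    if field.type_biomass is None:
        raise ValidationError("field has no type_biomass layers to sum")
    tg = np.asarray(type_groups if type_groups is not None else field.type_groups)
    if tg.shape != (N_TYPES,):
        raise ValidationError(f"membership table must assign all {N_TYPES} types")
    if not np.array_equal(np.unique(tg), np.arange(N_GROUPS)):
        raise ValidationError("membership table does not partition types over the 7 groups")
    group = _sum_types(field.type_biomass, tg)
    return GriddedEcosystemField(
        lat=field.lat,
        lon=field.lon,
        nutrient_flux=field.nutrient_flux,
        ice_fraction=field.ice_fraction,
        group_biomass=group,
        type_biomass=field.type_biomass,
        type_groups=tg,
        true_labels=field.true_labels,
        attrs=dict(field.attrs),
    )


def apply_masks(
    field: GriddedEcosystemField,
    biomass_threshold: float = BIOMASS_THRESHOLD,
    ice_threshold: float = ICE_THRESHOLD,
    per_group: bool = False,
) -> FeatureMatrix:
    """Discard low-biomass and ice-covered cells; assemble the raw 11-D matrix.

    A cell survives iff its total biomass (sum over the 7 groups; with
    ``per_group=True``, every group individually) is >= ``biomass_threshold``
    and its ice fraction is <= ``ice_threshold``.  Cells with non-finite
    features are also dropped.  Returns a FeatureMatrix at stage ``raw11``
    whose index map records the survivors.
    """
    field.validate()
    if field.group_biomass is None:
        raise ValidationError("group layers required; run sum_functional_groups first")
    n_lat, n_lon = field.shape
    groups = field.group_biomass.reshape(N_GROUPS, -1).T  # (n_cells, 7)
    fluxes = field.nutrient_flux.reshape(len(NUTRIENT_NAMES), -1).T
    ice = field.ice_fraction.reshape(-1)
    total = groups.sum(axis=1)

    finite = np.isfinite(groups).all(axis=1) & np.isfinite(fluxes).all(axis=1) & np.isfinite(ice)
    if per_group:
        biomass_ok = (groups >= biomass_threshold).all(axis=1)
    else:
        biomass_ok = total >= biomass_threshold
    ice_ok = ice <= ice_threshold
    keep = finite & biomass_ok & ice_ok

    if not keep.any():
        raise ValidationError(
            "no grid cells survive masking: "
            f"{int((~biomass_ok & finite).sum())} below biomass threshold {biomass_threshold:g}, "
            f"{int((~ice_ok & finite).sum())} above ice threshold {ice_threshold:g}, "
            f"{int((~finite).sum())} non-finite, of {len(keep)} cells"
        )

    cell_id = np.flatnonzero(keep)
    lat_deg, lon_deg = field.cell_latlon(cell_id)
    values = np.hstack([groups[keep], fluxes[keep]])
    index_map = pd.DataFrame({"cell_id": cell_id, "lon": lon_deg, "lat": lat_deg})
    fm = FeatureMatrix(
        values=values,
        index_map=index_map,
        stage="raw11",
        meta={
            "biomass_threshold": biomass_threshold,
            "ice_threshold": ice_threshold,
            "per_group": per_group,
            "n_cells": int(len(keep)),
            "n_below_biomass": int((finite & ~biomass_ok).sum()),
            "n_iced": int((finite & ~ice_ok).sum()),
            "n_iced_and_below": int((finite & ~ice_ok & ~biomass_ok).sum()),
            "grid_shape": (n_lat, n_lon),
        },
    )
    return fm.validate()


def transform_features(
    fm: FeatureMatrix,
    log_biomass: bool = True,
    log_fluxes: bool = False,
    eps_log: float = 1e-10,
) -> FeatureMatrix:
    """Log / min-max / standardise the raw 11-D features.

    The transform pipeline is: natural log of the 7 biomass columns (fluxes
    too when ``log_fluxes``), then per-column min-max scaling to [0, 1], then
    per-column mean removal and unit-variance scaling.  Zero entries in logged
    columns are floored at ``eps_log`` beforehand so the log stays finite
    (masking guarantees cell *totals* are positive, but an individual group
    may be absent).  Constant columns are set to 0 after standardisation with
    a warning.  All intermediate stages are kept in ``intermediates``.
    """
    if fm.stage != "raw11":
        raise ValidationError(f"transform_features expects stage 'raw11', got '{fm.stage}'")
    X = np.array(fm.values, dtype=float)
    intermediates = {"raw11": X.copy()}

    logged = X.copy()
    log_cols = (list(range(N_GROUPS)) if log_biomass else []) + (
        list(range(N_GROUPS, N_FEATURES)) if log_fluxes else []
    )
    for c in log_cols:
        col = np.maximum(logged[:, c], eps_log)
        logged[:, c] = np.log(col)
    intermediates["logged"] = logged.copy()

    mins = logged.min(axis=0)
    maxs = logged.max(axis=0)
    span = maxs - mins
    constant = span <= 0
    span_safe = np.where(constant, 1.0, span)
    minmax = (logged - mins) / span_safe
    minmax[:, constant] = 0.0
    intermediates["minmax"] = minmax.copy()

    mean = minmax.mean(axis=0)
    std = minmax.std(axis=0)  # population std so the variance is exactly 1
    zero_std = std <= 0
    if np.any(zero_std):
        bad = [fm.columns[i] for i in np.flatnonzero(zero_std)]
        warnings.warn(f"constant feature column(s) set to 0 after standardization: {bad}")
    std_safe = np.where(zero_std, 1.0, std)
    standardized = (minmax - mean) / std_safe
    standardized[:, zero_std] = 0.0

    return FeatureMatrix(
        values=standardized,
        index_map=fm.index_map,
        stage="standardized",
        columns=list(fm.columns),
        intermediates=intermediates,
        meta={
            **fm.meta,
            "log_biomass": log_biomass,
            "log_fluxes": log_fluxes,
            "eps_log": eps_log,
            "column_min": mins.tolist(),
            "column_max": maxs.tolist(),
            "column_mean": mean.tolist(),
            "column_std": std.tolist(),
        },
    ).validate()
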