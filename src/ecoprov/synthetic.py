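"""Synthetic gridded ecosystem fields with planted province structure.

The generator emulates the 11-dimensional input the pipeline consumes — the
biomass of 7 plankton functional groups plus 4 nutrient supply rates on a
regular lat/lon grid — with a known ("planted") province label per cell, so
every downstream stage can be tested against ground truth.  Three feature
geometries are supported:

``blobs``
    Gaussian clusters in the 11-D feature space (log-space for biomass),
    provinces laid out as spatially contiguous Voronoi patches.
``curved_manifolds``
    Each province lies on a 1-D quadratic curve embedded in 11-D with small
    transverse noise — deliberately non-Gaussian cluster shapes of the kind
    density-based clustering must handle and centroid methods cannot.
``zonal_bands``
    Blob-style features, provinces assigned as latitude bands.

Realism knobs shared by all geometries: a polar ice band (ice fraction > 0.7
poleward of ``ice_band_lat``), and a ``low_biomass_frac`` share of otherwise
eligible cells whose total biomass falls below the masking threshold.  Both
kinds of cells carry true label -1 (no province).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np

from .errors import ValidationError
from .preprocess import (
    BIOMASS_THRESHOLD,
    GROUP_SIZES,
    GriddedEcosystemField,
    N_GROUPS,
    N_TYPES,
    NUTRIENT_NAMES,
    default_type_groups,
)

GEOMETRIES = ("blobs", "curved_manifolds", "zonal_bands")


@dataclass
class SyntheticSpec:
    """Conditions for one synthetic field realisation.

    ``group_profiles`` (n_provinces x 7, mean natural-log biomass in
    mg C/m^3), ``flux_profiles`` (n_provinces x 4, mmol/m^3/yr) and
    ``within_group_composition`` (n_provinces x 51 weights whose block inside
    each functional group sums to 1) may be left as None, in which case they
    are drawn deterministically from ``seed``.  ``noise_sd`` is the iid
    per-cell noise, applied in log space for biomass (the inter-province
    spread of the default profiles is ~1 in log space, so 0.25 is moderate).
    """

    n_lat: int = 40
    n_lon: int = 80
    n_provinces: int = 5
    geometry: str = "blobs"
    group_profiles: Optional[np.ndarray] = None
    flux_profiles: Optional[np.ndarray] = None
    within_group_composition: Optional[np.ndarray] = None
    noise_sd: float = 0.25
    ice_band_lat: float = 70.0
    low_biomass_frac: float = 0.05
    biomass_threshold: float = BIOMASS_THRESHOLD
    seed: int = 0

    def validate(self) -> "SyntheticSpec":
        if self.n_lat < 1 or self.n_lon < 1:
            raise ValidationError("grid dimensions must be positive")
        if self.n_provinces < 1:
            raise ValidationError("n_provinces must be >= 1")
        if self.n_lat * self.n_lon < self.n_provinces:
            raise ValidationError("grid must have at least n_provinces cells")
        if self.geometry not in GEOMETRIES:
            raise ValidationError(f"geometry must be one of {GEOMETRIES}")
        if not 0.0 <= self.low_biomass_frac <= 1.0:
            raise ValidationError("low_biomass_frac must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be nonnegative")
        if self.within_group_composition is not None:
            comp = np.asarray(self.within_group_composition, dtype=float)
            if comp.shape != (self.n_provinces, N_TYPES):
                raise ValidationError("within_group_composition must be n_provinces x 51")
            if np.any(comp < 0):
                raise ValidationError("composition weights must be nonnegative")
            tg = default_type_groups()
            for g in range(N_GROUPS):
                block = comp[:, tg == g].sum(axis=1)
                if np.any(np.abs(block - 1.0) > 1e-9):
                    raise ValidationError(
                        "composition weights must sum to 1 inside each functional group"
                    )
        return self


def _default_profiles(spec: SyntheticSpec, rng: np.random.Generator):
    """Draw per-province group/flux mean profiles and type compositions."""
    p = spec.n_provinces
    if spec.group_profiles is not None:
        group = np.asarray(spec.group_profiles, dtype=float)
    else:
        # mean log biomass per group ~ N(ln 5, 1); spread between provinces ~ 1
        group = rng.normal(np.log(5.0), 1.0, size=(p, N_GROUPS))
    if spec.flux_profiles is not None:
        flux = np.asarray(spec.flux_profiles, dtype=float)
    else:
        # supply rates are lognormal across provinces around 1 mmol/m^3/yr
        flux = np.exp(rng.normal(0.0, 1.0, size=(p, len(NUTRIENT_NAMES))))
    if spec.within_group_composition is not None:
        comp = np.asarray(spec.within_group_composition, dtype=float)
    else:
        comp = np.empty((p, N_TYPES))
        tg = default_type_groups()
        for g, size in enumerate(GROUP_SIZES):
            comp[:, tg == g] = rng.dirichlet(np.full(size, 2.0), size=p)
    return group, flux, comp


def _province_map(spec: SyntheticSpec, lat: np.ndarray, lon: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """Spatial province assignment for every grid cell (n_lat x n_lon)."""
    n_lat, n_lon = spec.n_lat, spec.n_lon
    if spec.geometry == "zonal_bands":
        edges = np.linspace(-90.0, 90.0, spec.n_provinces + 1)
        band = np.clip(np.searchsorted(edges, lat, side="right") - 1, 0, spec.n_provinces - 1)
        return np.repeat(band[:, None], n_lon, axis=1)
    # Voronoi patches around random seed cells; lon wraps around the globe.
    seeds = rng.choice(n_lat * n_lon, size=spec.n_provinces, replace=False)
    slat = lat[seeds // n_lon]
    slon = lon[seeds % n_lon]
    glat, glon = np.meshgrid(lat, lon, indexing="ij")
    dlon = np.abs(glon[..., None] - slon)
    dlon = np.minimum(dlon, 360.0 - dlon)
    d2 = (glat[..., None] - slat) ** 2 + dlon**2
    return d2.argmin(axis=-1)


def _curve_basis(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Two random orthonormal directions in 11-D for a quadratic curve."""
    u = rng.normal(size=N_GROUPS + len(NUTRIENT_NAMES))
    u /= np.linalg.norm(u)
    v = rng.normal(size=u.shape)
    v -= (v @ u) * u
    v /= np.linalg.norm(v)
    return u, v


def generate_field(spec: SyntheticSpec) -> GriddedEcosystemField:
    """Generate one synthetic gridded field with planted province labels.

    Returns a validated :class:`GriddedEcosystemField` with ``true_labels``
    (-1 for iced and low-biomass cells) and generator bookkeeping in
    ``attrs`` (counts of iced/low-biomass cells, the seed, the geometry).
    Same spec (same seed) => bit-identical field.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_lat, n_lon = spec.n_lat, spec.n_lon
    lat = -90.0 + (np.arange(n_lat) + 0.5) * 180.0 / n_lat
    lon = -180.0 + (np.arange(n_lon) + 0.5) * 360.0 / n_lon

    group_mu, flux_mu, comp = _default_profiles(spec, rng)
    labels = _province_map(spec, lat, lon, rng)
    flat_labels = labels.reshape(-1)
    n_cells = n_lat * n_lon

    # per-cell features: province mean + iid noise (log space for biomass)
    log_group = group_mu[flat_labels]  # (n_cells, 7)
    flux = flux_mu[flat_labels].copy()  # (n_cells, 4)

    if spec.geometry == "curved_manifolds":
        # province p occupies a quadratic curve c_p + t u_p + t^2 v_p in the
        # 11-D (log-biomass, log-flux) space; transverse noise added below
        flux = np.log(np.maximum(flux, 1e-12))
        feat = np.hstack([log_group, flux])
        for p in range(spec.n_provinces):
            u, v = _curve_basis(rng)
            members = np.flatnonzero(flat_labels == p)
            t = rng.uniform(-1.0, 1.0, size=len(members))
            feat[members] += 1.5 * t[:, None] * u + 1.5 * (t**2)[:, None] * v
        if spec.noise_sd > 0:
            feat += rng.normal(0.0, spec.noise_sd, size=feat.shape)
        log_group = feat[:, :N_GROUPS]
        flux = np.exp(feat[:, N_GROUPS:])
    else:
        if spec.noise_sd > 0:
            log_group = log_group + rng.normal(0.0, spec.noise_sd, size=log_group.shape)
            flux = np.maximum(
                flux * (1.0 + rng.normal(0.0, spec.noise_sd, size=flux.shape)), 0.0
            )

    group = np.exp(log_group)  # (n_cells, 7), nonnegative by construction

    # polar ice band: poleward of ice_band_lat carries ice fraction > 0.7
    glat = np.repeat(lat, n_lon)
    iced = np.abs(glat) > spec.ice_band_lat
    ice = rng.uniform(0.0, 0.15, size=n_cells)
    ice[iced] = rng.uniform(0.75, 1.0, size=int(iced.sum()))

    # low-biomass tail: a fraction of otherwise-eligible cells falls below
    # the masking threshold
    eligible = np.flatnonzero(~iced)
    n_low = int(round(spec.low_biomass_frac * len(eligible)))
    low = rng.choice(eligible, size=n_low, replace=False) if n_low else np.array([], dtype=int)
    if n_low:
        target_total = 0.5 * spec.biomass_threshold
        scale = target_total / group[low].sum(axis=1)
        group[low] *= scale[:, None]

    truth = flat_labels.copy()
    truth[iced] = -1
    truth[low] = -1

    type_biomass = comp[flat_labels] * group[:, default_type_groups()]
    # comp block sums are 1 inside each group, so per-group type sums equal
    # the group biomass exactly

    field = GriddedEcosystemField(
        lat=lat,
        lon=lon,
        nutrient_flux=flux.T.reshape(len(NUTRIENT_NAMES), n_lat, n_lon),
        ice_fraction=ice.reshape(n_lat, n_lon),
        group_biomass=group.T.reshape(N_GROUPS, n_lat, n_lon),
        type_biomass=type_biomass.T.reshape(N_TYPES, n_lat, n_lon),
        type_groups=default_type_groups(),
        true_labels=truth.reshape(n_lat, n_lon),
        attrs={
            "generator": "ecoprov.synthetic",
            "seed": int(spec.seed),
            "geometry": spec.geometry,
            "n_provinces": int(spec.n_provinces),
            "noise_sd": float(spec.noise_sd),
            "n_iced": int(iced.sum()),
            "n_low_biomass": int(n_low),
            "low_biomass_cells": np.sort(low).tolist(),
        },
    )
    return field.validate()
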