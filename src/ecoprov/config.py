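"""Pipeline configuration with the published operating point as defaults."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field as dc_field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .errors import ValidationError


@dataclass
class PipelineConfig:
    """Resolved configuration for one end-to-end run.

    Defaults are the published operating point for a ~1-degree global field
    (~40k retained cells): biomass threshold 1.2e-3 mg Chl/m^3, ice threshold
    0.7, perplexity 400 with 300 t-SNE iterations, eps = 0.39 with
    min_pts = 100, and R = 10 realizations.  For smaller (synthetic) inputs
    set ``scale_to_n`` so perplexity/min_pts are rescaled to the retained
    cell count, and/or supply an explicit ``eps_grid`` to re-select eps.
    """

    input_path: Optional[str] = None
    dialect: str = "flat_csv"  # flat_csv | netcdf_grid
    output_dir: str = "ecoprov_out"

    # masking
    biomass_threshold: float = 1.2e-3
    ice_threshold: float = 0.7
    per_group_threshold: bool = False

    # feature transform
    log_fluxes: bool = False
    eps_log: float = 1e-10

    # t-SNE
    perplexity: float = 400.0
    n_iter: int = 300
    n_realizations: int = 10
    seed: int = 0

    # DBSCAN
    eps: Optional[float] = 0.39  # None -> run the eps scan
    min_pts: Optional[int] = 100  # None -> scale from retained cell count
    eps_scan_points: int = 24

    # aggregation
    k_range: Optional[list[int]] = None
    benchmark_value: Optional[float] = None  # e.g. 0.227 from a reference partition
    benchmark_labels_path: Optional[str] = None
    bc_level: str = "types"
    area_weighted: bool = True
    two_sigma_factor: float = 1.5

    # scaling for non-reference problem sizes
    scale_to_n: bool = False

    extras: dict = dc_field(default_factory=dict)

    def validate(self) -> "PipelineConfig":
        if self.dialect not in ("flat_csv", "netcdf_grid"):
            raise ValidationError("dialect must be flat_csv or netcdf_grid")
        if self.n_realizations < 1:
            raise ValidationError("n_realizations must be >= 1")
        if self.bc_level not in ("types", "groups"):
            raise ValidationError("bc_level must be 'types' or 'groups'")
        return self

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data).validate()

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def realization_seeds(self) -> list[int]:
        """Expand the global seed into one sub-31-bit seed per realization."""
        rng = np.random.default_rng(self.seed)
        return [int(s) for s in rng.integers(0, 2**31 - 1, size=self.n_realizations)]
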