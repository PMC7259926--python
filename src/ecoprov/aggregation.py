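"""Nesting eco-provinces into aggregated eco-provinces (AEPs).

Provinces are nodes of a complete weighted graph whose edge weights are the
interprovince Bray-Curtis dissimilarities (distance semantics).  A province's
connectivity score is its total similarity strength sum_j (1 - BC_ij); the k
highest-scoring provinces become "dominants" and every other province is
assigned to the dominant it is most similar to (minimal BC).  k is the
"complexity" of the aggregation: k = m (one AEP per province) is the identity,
k = 1 collapses everything onto the single best-connected province.

Because the embedding step is stochastic, the whole pipeline is repeated R
times (R = 10 by default) and the aggregation statistics are collected per
realization.  The degeneracy of a complexity level is the 2-sigma spread of
the intraprovince BC across realizations; the minimum robust complexity
k_min is the smallest k whose worst-realization intraprovince BC beats the
benchmark partition while the degeneracy stays within a factor of the
full-complexity spread.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence, Union

import networkx as nx
import numpy as np
import pandas as pd

from .clustering import ProvinceLabeling
from .dissimilarity import BCMatrix, interprovince_bc, intraprovince_bc
from .errors import ValidationError
from .preprocess import GriddedEcosystemField


@dataclass
class AEPResult:
    """Province -> AEP assignment at one complexity level.

    AEP ids are the dominant province ids; dominants map to themselves.
    """

    complexity_k: int
    mapping: dict[int, int]
    dominant_ids: list[int]
    aep_labels: Optional[np.ndarray] = None  # per retained cell, -1 = noise
    intraprovince_bc_mean: Optional[float] = None

    def validate(self) -> "AEPResult":
        if len(set(self.mapping.values())) != self.complexity_k:
            raise ValidationError("number of distinct AEP ids != complexity k")
        for d in self.dominant_ids:
            if self.mapping[d] != d:
                raise ValidationError("dominant provinces must map to themselves")
        return self


@dataclass
class ComplexityScan:
    """Per-(k, realization) intraprovince BC with degeneracy statistics."""

    per_run: pd.DataFrame  # columns: k, realization, intra_bc
    per_k: pd.DataFrame  # columns: k, mean, two_sigma, max_intra
    benchmark: float
    k_min: Optional[int]
    two_sigma_factor: float
    meta: dict = dc_field(default_factory=dict)


def build_connectivity_graph(bc: BCMatrix) -> nx.Graph:
    """Complete weighted graph on provinces; edge weight = BC distance,
    node attribute ``connectivity`` = sum_j (1 - BC_ij)."""
    bc.validate()
    g = nx.Graph()
    ids = [int(i) for i in bc.province_ids]
    scores = (1.0 - bc.values).sum(axis=1)
    for idx, pid in enumerate(ids):
        g.add_node(pid, connectivity=float(scores[idx]))
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            g.add_edge(ids[i], ids[j], weight=float(bc.values[i, j]))
    return g


def aggregate(bc: BCMatrix, k: int) -> AEPResult:
    """Sort provinces under the k most-connected dominants.

    Dominants are the k provinces with the highest connectivity score
    (ties: lower province id); every remaining province maps to the dominant
    with minimal BC to it (ties: lower dominant id).
    """
    bc.validate()
    m = len(bc.province_ids)
    if not 1 <= k <= m:
        raise ValidationError(f"complexity k={k} outside [1, {m}]")
    ids = np.asarray(bc.province_ids, dtype=int)
    scores = (1.0 - bc.values).sum(axis=1)
    # descending score, ascending id on ties
    order = np.lexsort((ids, -scores))
    dominant_idx = np.sort(order[:k])
    dominant_ids = ids[dominant_idx].tolist()

    mapping: dict[int, int] = {}
    for i, pid in enumerate(ids):
        if i in dominant_idx:
            mapping[int(pid)] = int(pid)
        else:
            j = dominant_idx[np.argmin(bc.values[i, dominant_idx])]
            mapping[int(pid)] = int(ids[j])
    return AEPResult(complexity_k=k, mapping=mapping, dominant_ids=dominant_ids).validate()


def apply_mapping(labels: Union[ProvinceLabeling, np.ndarray],
                  mapping: dict[int, int]) -> np.ndarray:
    """Relabel per-cell province labels to AEP labels; noise (-1) is kept."""
    lab = labels.labels if isinstance(labels, ProvinceLabeling) else np.asarray(labels)
    out = np.full_like(lab, -1)
    for pid, aep in mapping.items():
        out[lab == pid] = aep
    out[lab == -1] = -1
    return out


def complexity_scan(
    realizations: Sequence[ProvinceLabeling],
    field: GriddedEcosystemField,
    benchmark: float,
    k_range: Optional[Sequence[int]] = None,
    level: str = "types",
    area_weighted: bool = True,
    two_sigma_factor: float = 1.5,
) -> ComplexityScan:
    """Scan aggregation complexity across pipeline realizations.

    Each realization is a full pipeline rerun (distinct embedding seed).  For
    every complexity k and realization, provinces are aggregated and the
    cell-weighted mean intraprovince BC of the resulting AEP partition is
    recorded (k above a realization's province count falls back to its full
    complexity, the identity mapping).  k_min is the smallest k whose
    worst-realization mean stays below ``benchmark`` and whose degeneracy
    2-sigma is <= ``two_sigma_factor`` times the full-complexity 2-sigma.
    """
    if len(realizations) < 2:
        raise ValidationError("complexity scan needs >= 2 realizations")
    bcs = [interprovince_bc(r, field, level=level, area_weighted=area_weighted)
           for r in realizations]
    m_max = max(len(bc.province_ids) for bc in bcs)
    if k_range is None:
        k_range = range(1, m_max + 1)
    k_range = sorted(set(int(k) for k in k_range))
    if k_range[0] < 1:
        raise ValidationError("complexity values must be >= 1")

    rows = []
    for r, (labeling, bc) in enumerate(zip(realizations, bcs)):
        m_r = len(bc.province_ids)
        for k in k_range:
            res = aggregate(bc, min(k, m_r))
            aep_labels = apply_mapping(labeling, res.mapping)
            _, summary = intraprovince_bc(
                aep_labels, field, np.asarray(labeling.cell_ids), level, area_weighted
            )
            rows.append({"k": k, "realization": r,
                         "intra_bc": summary["cell_weighted_mean"]})
    per_run = pd.DataFrame(rows)
    per_k = (
        per_run.groupby("k")["intra_bc"]
        .agg(mean="mean", two_sigma=lambda v: 2.0 * v.std(ddof=1), max_intra="max")
        .reset_index()
    )
    k_full = max(k_range)
    ts_full = float(per_k.loc[per_k["k"] == k_full, "two_sigma"].iloc[0])
    qualifying = per_k[
        (per_k["max_intra"] < benchmark)
        & (per_k["two_sigma"] <= two_sigma_factor * max(ts_full, 1e-12))
    ]
    k_min = int(qualifying["k"].min()) if len(qualifying) else None
    return ComplexityScan(
        per_run=per_run,
        per_k=per_k,
        benchmark=float(benchmark),
        k_min=k_min,
        two_sigma_factor=two_sigma_factor,
        meta={"k_full": k_full, "two_sigma_full": ts_full,
              "n_realizations": len(realizations),
              "flagged_no_k": k_min is None},
    )


def back_project(
    labels: Union[ProvinceLabeling, np.ndarray],
    cell_ids: Optional[np.ndarray],
    grid_shape: tuple[int, int],
    fill: int = -1,
) -> np.ndarray:
    """Project per-cell labels back onto the (n_lat, n_lon) grid.

    Masked cells and noise cells both carry ``fill`` (the "black dots" of an
    eco-province map).  Cell ids are flat indices ilat * n_lon + ilon; ids
    outside the grid are rejected.
    """
    if isinstance(labels, ProvinceLabeling):
        cell_ids = labels.cell_ids if cell_ids is None else cell_ids
        labels = labels.labels
    lab = np.asarray(labels)
    if cell_ids is None:
        raise ValidationError("cell_ids required to back-project")
    cid = np.asarray(cell_ids)
    n_lat, n_lon = grid_shape
    if np.any(cid < 0) or np.any(cid >= n_lat * n_lon):
        raise ValidationError("cell id outside grid")
    grid = np.full(n_lat * n_lon, fill, dtype=int)
    grid[cid] = np.where(lab < 0, fill, lab)
    return grid.reshape(n_lat, n_lon)
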