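"""DBSCAN province identification in the 3-D embedding, with eps selection.

Provinces are density-connected sets of embedded points: a point is a core
point when its closed eps-ball holds at least ``min_pts`` points (itself
included), clusters are the connected components of core points plus any
border points within eps of them, and everything else is noise (label -1).
Cluster ids are assigned in discovery order under a fixed ascending-index
visit, which makes the partition deterministic: the only order-dependent
outcome in DBSCAN is which cluster claims a shared border point, and here it
is always the first-discovered (lowest-id) one.

The eps parameter is chosen by scanning a grid and reading off two curves:
"connectivity" (the resulting number of clusters) and coverage (fraction of
points assigned to any cluster).  Very small eps leaves everything as noise,
very large eps merges the data into one cluster; in between lies an unstable
over-fit regime and then a stable plateau (the "elbow") from which the
largest-coverage eps is selected.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .embedding import Embedding3D
from .errors import SelectionError, ValidationError

#: Operating point used at the reference scale of ~40k retained 1-degree cells.
DEFAULT_EPS = 0.39
DEFAULT_MIN_PTS = 100
#: Above this minimum cluster size a robust eps plateau is unlikely to exist.
MIN_PTS_ROBUST_LIMIT = 135
#: Retained-cell count the default min_pts refers to.
REFERENCE_N = 40000


@dataclass
class DBSCANParams:
    """eps (distance in embedding space) and minimum cluster membership."""

    eps: float
    min_pts: int

    def validate(self) -> "DBSCANParams":
        if not self.eps > 0:
            raise ValidationError("eps must be positive")
        if self.min_pts < 1:
            raise ValidationError("min_pts must be >= 1")
        if self.min_pts > MIN_PTS_ROBUST_LIMIT:
            warnings.warn(
                f"min_pts={self.min_pts} exceeds ~{MIN_PTS_ROBUST_LIMIT}; a robust eps "
                "plateau is unlikely at this membership requirement"
            )
        return self


@dataclass
class ProvinceLabeling:
    """Integer province labels per retained cell; -1 marks noise."""

    labels: np.ndarray
    params: DBSCANParams
    cell_ids: Optional[np.ndarray] = None
    realization_id: int = 0
    seed: Optional[int] = None

    @property
    def n_clusters(self) -> int:
        return int(len(np.unique(self.labels[self.labels >= 0])))

    @property
    def coverage(self) -> float:
        return float(np.mean(self.labels >= 0)) if len(self.labels) else 0.0

    def province_ids(self) -> np.ndarray:
        return np.unique(self.labels[self.labels >= 0])


@dataclass
class EpsScan:
    """Grid of (eps, min_pts) -> (n_clusters, coverage) plus the chosen point."""

    table: pd.DataFrame  # columns: eps, min_pts, n_clusters, coverage
    chosen: Optional[DBSCANParams] = None
    meta: dict = dc_field(default_factory=dict)


def scaled_min_pts(n: int, base: int = DEFAULT_MIN_PTS, n_reference: int = REFERENCE_N,
                   floor: int = 5) -> int:
    """Scale the reference minimum cluster size to a smaller problem."""
    return max(floor, int(round(base * n / n_reference)))


def _embedding_points(Y: Union[Embedding3D, np.ndarray]) -> np.ndarray:
    pts = Y.Y if isinstance(Y, Embedding3D) else np.asarray(Y, dtype=float)
    if not np.all(np.isfinite(pts)):
        raise ValidationError("embedding contains non-finite coordinates")
    return pts


def dbscan(Y: Union[Embedding3D, np.ndarray], params: DBSCANParams) -> ProvinceLabeling:
    """Density-reachability clustering with closed Euclidean eps-neighbourhoods.

    Visit order is ascending point index; cluster labels count up in the
    order clusters are discovered.  Border points reachable from several
    clusters go to the first-discovered one.  Points in no cluster get -1,
    and any cluster left with fewer than ``min_pts`` members (possible when
    shared border points were claimed by an earlier cluster) is dissolved
    into noise, so every reported cluster meets the minimum-membership rule.
    """
    params.validate()
    pts = _embedding_points(Y)
    n = len(pts)
    labels = np.full(n, -1, dtype=int)
    if n == 0:
        return ProvinceLabeling(labels=labels, params=params,
                                cell_ids=getattr(Y, "cell_ids", None))
    tree = cKDTree(pts)
    neigh = tree.query_ball_point(pts, params.eps)  # closed ball, includes self
    core = np.fromiter((len(nb) >= params.min_pts for nb in neigh), dtype=bool, count=n)

    cluster = 0
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        labels[i] = cluster
        frontier = deque([i])
        while frontier:
            j = frontier.popleft()
            if not core[j]:
                continue  # border point: belongs to the cluster, not expanded
            for k in sorted(neigh[j]):
                if labels[k] == -1:
                    labels[k] = cluster
                    frontier.append(k)
        cluster += 1
    labels = _dissolve_small_clusters(labels, params.min_pts)
    return ProvinceLabeling(labels=labels, params=params)


def _dissolve_small_clusters(labels: np.ndarray, min_pts: int) -> np.ndarray:
    """Turn clusters below the membership minimum into noise; renumber the
    survivors compactly, preserving discovery order."""
    out = np.full_like(labels, -1)
    next_id = 0
    for c in range(labels.max() + 1 if labels.size else 0):
        members = labels == c
        if members.sum() >= min_pts:
            out[members] = next_id
            next_id += 1
    return out


def scan_eps(
    Y: Union[Embedding3D, np.ndarray],
    eps_grid: Sequence[float],
    min_pts_grid: Sequence[int],
) -> EpsScan:
    """Evaluate cluster count (connectivity) and coverage over a parameter grid."""
    eps_grid = np.asarray(list(eps_grid), dtype=float)
    min_pts_grid = [int(m) for m in min_pts_grid]
    if len(eps_grid) == 0 or len(min_pts_grid) == 0:
        raise ValidationError("eps and min_pts grids must be nonempty")
    rows = []
    for m in min_pts_grid:
        for e in np.sort(eps_grid):
            lab = dbscan(Y, DBSCANParams(eps=float(e), min_pts=m))
            rows.append(
                {"eps": float(e), "min_pts": m,
                 "n_clusters": lab.n_clusters, "coverage": lab.coverage}
            )
    return EpsScan(table=pd.DataFrame(rows))


def auto_eps_grid(Y: Union[Embedding3D, np.ndarray], n_points: int = 24) -> np.ndarray:
    """Geometric eps grid spanning below the nearest-neighbour scale up to
    beyond the embedding diameter, so a scan covers the all-noise and
    single-cluster regimes."""
    pts = _embedding_points(Y)
    tree = cKDTree(pts)
    d_nn, _ = tree.query(pts, k=2)
    d_min = max(float(np.min(d_nn[:, 1])), 1e-9)
    diameter = float(np.linalg.norm(pts.max(axis=0) - pts.min(axis=0)))
    return np.geomspace(0.5 * d_min, 1.1 * max(diameter, 2 * d_min), n_points)


def _stable_runs(counts: np.ndarray, stability_tol: float) -> list[tuple[int, int]]:
    """Maximal index runs where adjacent cluster counts change by at most
    stability_tol (relative) and the count stays >= 2."""
    runs = []
    start = None
    for j in range(len(counts)):
        if counts[j] < 2:
            if start is not None:
                runs.append((start, j - 1))
                start = None
            continue
        if start is None:
            start = j
        elif abs(counts[j] - counts[j - 1]) > stability_tol * max(counts[j], counts[j - 1]):
            runs.append((start, j - 1))
            start = j
    if start is not None:
        runs.append((start, len(counts) - 1))
    return [(a, b) for a, b in runs if b > a]


def select_eps(
    scan: EpsScan,
    stability_tol: float = 0.10,
    min_run_length: int = 2,
) -> DBSCANParams:
    """Pick the eps/min_pts pair from the stable plateau, favouring coverage.

    For each min_pts the eps-sorted cluster counts must show an under-fit
    regime (<= 1 cluster at large eps) and a noise/over-fit regime at small
    eps (0 clusters, or more clusters than the plateau).  Within the stable
    plateau (adjacent counts changing by <= ``stability_tol`` relative, i.e.
    ~+-10 at a few hundred clusters) the eps with the highest coverage is
    chosen; across min_pts values the largest stable plateau wins.
    """
    best = None  # (plateau_count, coverage, -min_pts, eps, row)
    for m, sub in scan.table.groupby("min_pts"):
        sub = sub.sort_values("eps").reset_index(drop=True)
        counts = sub["n_clusters"].to_numpy()
        if not np.any(counts <= 1) or counts.max() < 2:
            continue
        for a, b in _stable_runs(counts, stability_tol):
            if b - a + 1 < min_run_length:
                continue
            plateau = int(np.round(np.median(counts[a : b + 1])))
            # demand evidence of both regimes around the plateau
            before = counts[:a]
            after = counts[b + 1 :]
            overfit_side = np.any((before == 0) | (before > plateau)) if len(before) else False
            underfit_side = np.any(after <= 1) if len(after) else False
            if not (overfit_side and underfit_side):
                continue
            seg = sub.iloc[a : b + 1]
            row = seg.loc[seg["coverage"].idxmax()]
            # tie-break on coverage -> larger eps
            ties = seg[np.isclose(seg["coverage"], row["coverage"])]
            row = ties.loc[ties["eps"].idxmax()]
            cand = (plateau, float(row["coverage"]), -int(m), float(row["eps"]))
            if best is None or cand > best:
                best = cand
    if best is None:
        raise SelectionError(
            "no stable eps plateau bracketed by noise/over-fit (small eps) and "
            "single-cluster (large eps) regimes; widen the eps grid"
        )
    chosen = DBSCANParams(eps=best[3], min_pts=-best[2])
    scan.chosen = chosen
    scan.meta["plateau_n_clusters"] = best[0]
    scan.meta["coverage_at_chosen"] = best[1]
    return chosen
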