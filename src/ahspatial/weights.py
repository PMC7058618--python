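"""Spatial weights matrices over districts.

Three constructors cover the proximity notions used in the analysis:
first-order queen contiguity (polygons sharing at least one boundary
point), k-nearest neighbours on centroids (k = 5 by default), and inverse
distance decay with a cut-off (50 km by default).  All are returned
row-standardized so that ``W x`` averages over neighbours; islands (rows
with no neighbour) are kept as zero rows with a logged warning rather than
dropped, so the district set never silently changes between models.

Distances are Euclidean on projected kilometre coordinates.  Longitude/
latitude input is rejected: a 50 km cut-off has no meaning in degrees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from shapely import STRtree
from shapely.geometry.base import BaseGeometry

__all__ = [
    "SpatialWeights",
    "queen_contiguity",
    "knn",
    "distance_decay",
    "row_standardize",
    "rho_interval",
    "read_centroids",
    "write_triplet",
    "read_triplet",
    "write_gal",
]

logger = logging.getLogger(__name__)


@dataclass
class SpatialWeights:
    """An N x N sparse spatial weights matrix with district labels.

    Attributes
    ----------
    district_ids : list of str
        Row/column order of ``matrix``.
    matrix : scipy.sparse.csr_matrix
        Nonnegative weights, zero diagonal.
    kind : str
        ``"queen"``, ``"knn"``, ``"distance_decay"`` or ``"custom"``.
    params : dict
        Constructor parameters (k; cutoff_km and exponent; ...).
    row_standardized : bool
    """

    district_ids: list[str]
    matrix: sp.csr_matrix
    kind: str = "custom"
    params: dict = field(default_factory=dict)
    row_standardized: bool = False

    def __post_init__(self) -> None:
        n = len(self.district_ids)
        self.matrix = sp.csr_matrix(self.matrix)
        if self.matrix.shape != (n, n):
            raise ValueError("weights matrix shape does not match district_ids")
        if self.matrix.diagonal().any():
            raise ValueError("weights matrix must have a zero diagonal")
        if (self.matrix.data < 0).any():
            raise ValueError("weights must be nonnegative")

    @property
    def n(self) -> int:
        return len(self.district_ids)

    def islands(self) -> list[str]:
        """Ids of districts with no neighbours (zero rows)."""
        rowsum = np.asarray(self.matrix.sum(axis=1)).ravel()
        return [d for d, s in zip(self.district_ids, rowsum) if s == 0]

    def dense(self) -> np.ndarray:
        return self.matrix.toarray()

    def lag(self, x: np.ndarray) -> np.ndarray:
        """Spatial lag ``W x`` (column-wise for 2-d input)."""
        return self.matrix @ np.asarray(x)


def row_standardize(W: SpatialWeights) -> SpatialWeights:
    """Divide every nonzero row by its sum; zero (island) rows are kept.

    Idempotent; raises on negative entries.
    """
    m = W.matrix.tocsr(copy=True).astype(float)
    if (m.data < 0).any():
        raise ValueError("cannot row-standardize negative weights")
    rowsum = np.asarray(m.sum(axis=1)).ravel()
    scale = np.ones_like(rowsum)
    nz = rowsum > 0
    scale[nz] = 1.0 / rowsum[nz]
    m = sp.diags(scale) @ m
    return SpatialWeights(
        list(W.district_ids), m.tocsr(), W.kind, dict(W.params), row_standardized=True
    )


def _warn_islands(W: SpatialWeights) -> None:
    isl = W.islands()
    if isl:
        logger.warning(
            "%d island district(s) with no neighbours kept as zero rows: %s",
            len(isl), ", ".join(isl[:10]),
        )


def queen_contiguity(
    geometries: Mapping[str, BaseGeometry] | Sequence[tuple[str, BaseGeometry]],
    standardize: bool = True,
) -> SpatialWeights:
    """First-order queen contiguity: neighbours share >= 1 boundary point.

    Parameters
    ----------
    geometries : mapping district_id -> shapely polygon (or sequence of pairs)
    standardize : row-standardize the binary matrix (default True).
    """
    items = list(geometries.items()) if isinstance(geometries, Mapping) else list(geometries)
    ids = [str(i) for i, _ in items]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate district ids in geometries")
    geoms = [g for _, g in items]
    tree = STRtree(geoms)
    rows, cols = [], []
    for i, g in enumerate(geoms):
        for j in tree.query(g, predicate="intersects"):
            j = int(j)
            if j != i:
                rows.append(i)
                cols.append(j)
    m = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(ids), len(ids))
    )
    m = m.maximum(m.T)  # symmetric before standardization
    W = SpatialWeights(ids, m, "queen", {}, row_standardized=False)
    _warn_islands(W)
    return row_standardize(W) if standardize else W


def _centroid_array(
    centroids: Mapping[str, tuple[float, float]] | pd.DataFrame,
) -> tuple[list[str], np.ndarray]:
    if isinstance(centroids, pd.DataFrame):
        ids = [str(i) for i in centroids["district_id"]]
        xy = centroids[["x_km", "y_km"]].to_numpy(float)
    else:
        ids = [str(k) for k in centroids]
        xy = np.array([centroids[k] for k in centroids], dtype=float)
    if not np.isfinite(xy).all():
        raise ValueError("non-finite centroid coordinates")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate district ids in centroids")
    return ids, xy


def _check_projected(xy: np.ndarray, assume_projected: bool) -> None:
    # a real projected grid in km practically always exceeds the lon/lat box
    if assume_projected:
        return
    if (np.abs(xy[:, 0]) <= 180).all() and (np.abs(xy[:, 1]) <= 90).all():
        span = np.ptp(xy, axis=0).max()
        if span <= 10:  # degrees-sized extent: almost surely unprojected
            raise ValueError(
                "centroids look like lon/lat degrees; distance-based weights "
                "need projected km coordinates (pass assume_projected=True to "
                "override for small km grids)"
            )


def knn(
    centroids: Mapping[str, tuple[float, float]] | pd.DataFrame,
    k: int = 5,
) -> SpatialWeights:
    """k-nearest-neighbour weights on Euclidean centroid distances.

    Each row links to its ``k`` nearest centroids (ties broken by district
    id order); the matrix is generally asymmetric.  Row-standardized, so
    every non-island row holds k entries of 1/k.
    """
    ids, xy = _centroid_array(centroids)
    n = len(ids)
    if k < 1 or k >= n:
        raise ValueError(f"need 1 <= k < n_districts, got k={k}, n={n}")
    d = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    order = np.arange(n)
    rows, cols = [], []
    for i in range(n):
        # stable sort on (distance, id order) makes tie-breaks deterministic
        nearest = np.lexsort((order, d[i]))[:k]
        rows.extend([i] * k)
        cols.extend(nearest.tolist())
    m = sp.csr_matrix((np.ones(n * k), (rows, cols)), shape=(n, n))
    W = SpatialWeights(ids, m, "knn", {"k": k}, row_standardized=False)
    return row_standardize(W)


def distance_decay(
    centroids: Mapping[str, tuple[float, float]] | pd.DataFrame,
    cutoff_km: float = 50.0,
    exponent: float = 1.0,
    assume_projected: bool = False,
    standardize: bool = True,
) -> SpatialWeights:
    """Inverse-distance weights with a hard cut-off.

    ``w_ij = d_ij ** -exponent`` for ``0 < d_ij <= cutoff_km``, else 0, then
    row-standardized.  ``exponent=0`` gives binary distance-band weights.
    Coincident centroids are an error (zero distance cannot be inverted).
    """
    if cutoff_km <= 0:
        raise ValueError("cutoff_km must be positive")
    ids, xy = _centroid_array(centroids)
    _check_projected(xy, assume_projected)
    n = len(ids)
    d = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=-1)
    iu, ju = np.where(~np.eye(n, dtype=bool) & (d == 0))
    if len(iu):
        raise ValueError(
            f"coincident centroids: {ids[iu[0]]} and {ids[ju[0]]} at zero distance"
        )
    mask = (d > 0) & (d <= cutoff_km)
    w = np.zeros_like(d)
    with np.errstate(divide="ignore"):
        w[mask] = d[mask] ** (-float(exponent))
    W = SpatialWeights(
        ids,
        sp.csr_matrix(w),
        "distance_decay",
        {"cutoff_km": float(cutoff_km), "exponent": float(exponent)},
        row_standardized=False,
    )
    _warn_islands(W)
    return row_standardize(W) if standardize else W


def rho_interval(W: SpatialWeights) -> tuple[float, float]:
    """Admissible interval for a spatial autoregressive parameter.

    For row-standardized W the largest real eigenvalue is 1, so the search
    interval is ``(1/min_real_eig, 1)``; without a negative real eigenvalue
    the lower bound falls back to -1.
    """
    eig = np.linalg.eigvals(W.dense())
    real = eig.real[np.abs(eig.imag) < 1e-9]
    mn = real.min() if len(real) else -1.0
    lower = 1.0 / mn if mn < 0 else -1.0
    upper = 1.0 if W.row_standardized else 1.0 / max(eig.real.max(), 1e-12)
    return float(lower), float(upper)


# ---------------------------------------------------------------------------
# interchange formats

def read_centroids(path: str | Path) -> pd.DataFrame:
    """Read a centroid CSV with columns district_id, x_km, y_km."""
    df = pd.read_csv(path, dtype={"district_id": str})
    missing = {"district_id", "x_km", "y_km"} - set(df.columns)
    if missing:
        raise ValueError(f"centroid file missing columns {sorted(missing)}")
    return df


def write_triplet(W: SpatialWeights, path: str | Path) -> None:
    """Write weights as sparse triplets (i_id, j_id, weight)."""
    coo = W.matrix.tocoo()
    df = pd.DataFrame(
        {
            "i_id": [W.district_ids[i] for i in coo.row],
            "j_id": [W.district_ids[j] for j in coo.col],
            "weight": coo.data,
        }
    ).sort_values(["i_id", "j_id"])
    df.to_csv(path, index=False)


def read_triplet(
    path: str | Path,
    district_ids: Sequence[str] | None = None,
    row_standardized: bool | None = None,
) -> SpatialWeights:
    """Read triplet-CSV weights; id order defaults to sorted union of ids."""
    df = pd.read_csv(path, dtype={"i_id": str, "j_id": str})
    ids = (
        [str(d) for d in district_ids]
        if district_ids is not None
        else sorted(set(df["i_id"]) | set(df["j_id"]))
    )
    idx = {d: i for i, d in enumerate(ids)}
    m = sp.csr_matrix(
        (
            df["weight"].to_numpy(float),
            (df["i_id"].map(idx).to_numpy(), df["j_id"].map(idx).to_numpy()),
        ),
        shape=(len(ids), len(ids)),
    )
    rowsum = np.asarray(m.sum(axis=1)).ravel()
    std = bool(np.all((np.abs(rowsum - 1) < 1e-9) | (rowsum == 0)))
    if row_standardized is not None:
        std = row_standardized
    return SpatialWeights(ids, m, "custom", {}, row_standardized=std)


def write_gal(W: SpatialWeights, path: str | Path) -> None:
    """Write a GAL-style neighbour list (binary adjacency view)."""
    lines = [f"{W.n}"]
    m = W.matrix.tolil()
    for i, d in enumerate(W.district_ids):
        nbrs = [W.district_ids[j] for j in m.rows[i]]
        lines.append(f"{d} {len(nbrs)}")
        lines.append(" ".join(nbrs))
    Path(path).write_text("\n".join(lines) + "\n")
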