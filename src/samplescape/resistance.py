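"""Circuit-theory effective resistance on raster landscapes.

Each single-variable hypothesis becomes a resistance raster: binary land
cover (2 in the focal class, 1 elsewhere), a raw continuous surface
(min-shifted to be strictly positive), or a uniform all-ones layer for
isolation by distance.  Cells are nodes of a conductance-weighted grid
graph; the effective resistance between two site cells is

    R_eff(s, t) = (e_s - e_t)^T L^+ (e_s - e_t)

with ``L`` the graph Laplacian, computed here via one sparse
factorization of the grounded Laplacian and one solve per site.

Also provides the iterative VIF screen used to flag collinear resistance
predictors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csc_matrix
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import splu

from .genotypes import SiteRegistry
from .distance import DistanceMatrix
from .raster import Raster

__all__ = [
    "SurfaceSpec",
    "parameterize",
    "build_graph",
    "effective_resistance",
    "resistance_distances",
    "uniform_ibd_predictor",
    "vif_screen",
]

SQRT2 = float(np.sqrt(2.0))


@dataclass(frozen=True)
class SurfaceSpec:
    """How to turn a landscape layer into a resistance surface.

    mode: ``binary_cover`` (resistance 2 inside ``cover_class``, 1
    elsewhere), ``raw`` (continuous values, min-shifted above 0), or
    ``uniform`` (all cells 1; the isolation-by-distance layer).
    """

    name: str
    mode: str
    cover_class: float | None = None

    def __post_init__(self):
        if self.mode not in ("binary_cover", "raw", "uniform"):
            raise ValueError(f"unknown surface mode {self.mode!r}")
        if self.mode == "binary_cover" and self.cover_class is None:
            raise ValueError("binary_cover mode requires a cover class")


def parameterize(raster: Raster, spec: SurfaceSpec) -> Raster:
    """Build a strictly positive resistance raster from a layer."""
    vals = raster.values
    if spec.mode == "uniform":
        out = np.where(raster.mask, 1.0, np.nan)
    elif spec.mode == "binary_cover":
        if not np.any(vals[raster.mask] == spec.cover_class):
            raise ValueError(
                f"cover class {spec.cover_class} absent from raster"
            )
        out = np.where(vals == spec.cover_class, 2.0, 1.0)
        out = np.where(raster.mask, out, np.nan)
    else:  # raw
        finite = vals[raster.mask]
        lo = finite.min()
        shift = 1.0 - lo if lo <= 0 else 0.0
        out = np.where(raster.mask, vals + shift, np.nan)
    return raster.copy_with(out)


def build_graph(raster: Raster, connectivity: int = 8):
    """Sparse graph Laplacian over unmasked cells of a resistance raster.

    Neighboring cells a, b get conductance ``2 / (r_a + r_b)`` (the
    average-resistance rule), scaled by 1/sqrt(2) for diagonal neighbors.
    Returns ``(L, cell_index)`` where ``cell_index`` is an (nrows, ncols)
    int array mapping cells to graph node ids (-1 for masked cells).
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    mask = raster.mask
    vals = raster.values
    if (vals[mask] <= 0).any():
        raise ValueError("resistance values must be strictly positive")
    n_nodes = int(mask.sum())
    if n_nodes < 2:
        raise ValueError("raster must have at least 2 unmasked cells")
    cell_index = -np.ones(mask.shape, dtype=np.int64)
    cell_index[mask] = np.arange(n_nodes)

    offsets = [(0, 1), (1, 0)]
    if connectivity == 8:
        offsets += [(1, 1), (1, -1)]
    def shift(n, d):
        if d >= 0:
            return slice(0, n - d), slice(d, n)
        return slice(-d, n), slice(0, n + d)

    rows_i, rows_j, conds = [], [], []
    for dr, dc in offsets:
        scale = 1.0 if (dr == 0 or dc == 0) else 1.0 / SQRT2
        r0, r1 = shift(vals.shape[0], dr)
        c0, c1 = shift(vals.shape[1], dc)
        a = cell_index[r0, c0]
        b = cell_index[r1, c1]
        ra = vals[r0, c0]
        rb = vals[r1, c1]
        ok = (a >= 0) & (b >= 0)
        rows_i.append(a[ok])
        rows_j.append(b[ok])
        conds.append(scale * 2.0 / (ra[ok] + rb[ok]))
    i = np.concatenate(rows_i)
    j = np.concatenate(rows_j)
    w = np.concatenate(conds)
    # L = D - A, assembled as: +w on both diagonals, -w off-diagonal (sym)
    data = np.concatenate([w, w, -w, -w])
    ri = np.concatenate([i, j, i, j])
    rj = np.concatenate([i, j, j, i])
    L = csc_matrix((data, (ri, rj)), shape=(n_nodes, n_nodes))
    return L, cell_index


def effective_resistance(L, node_ids) -> np.ndarray:
    """Pairwise effective resistance between graph nodes ``node_ids``.

    Grounds one of the requested nodes, factorizes the reduced Laplacian
    once, and solves for each remaining node's indicator vector; then
    R(s, t) = G_ss + G_tt - 2 G_st on the grounded inverse G.  Raises if
    the nodes do not share one connected component.
    """
    node_ids = np.asarray(node_ids, dtype=np.int64)
    n = L.shape[0]
    ncomp, labels = connected_components(abs(L), directed=False)
    if ncomp > 1 and len(set(labels[node_ids])) > 1:
        raise ValueError("node cells fall in disconnected landscape components")
    ground = int(node_ids[0])
    keep = np.ones(n, dtype=bool)
    keep[ground] = False
    # restrict to the ground's component (other components are irrelevant)
    keep &= labels == labels[ground]
    reduced = L[np.ix_(keep, keep)].tocsc()
    pos = -np.ones(n, dtype=np.int64)
    pos[keep] = np.arange(int(keep.sum()))
    lu = splu(reduced)
    m = len(node_ids)
    G = np.zeros((m, m))
    sols = {}
    for a, na in enumerate(node_ids):
        if na == ground:
            continue
        e = np.zeros(int(keep.sum()))
        e[pos[na]] = 1.0
        sols[a] = lu.solve(e)
    for a, na in enumerate(node_ids):
        for b in range(a, m):
            nb = node_ids[b]
            if na == ground and nb == ground:
                G[a, b] = 0.0
            elif na == ground:
                G[a, b] = G[b, a] = 0.0
            elif nb == ground:
                G[a, b] = G[b, a] = 0.0
            else:
                G[a, b] = G[b, a] = sols[a][pos[nb]]
    d = np.diag(G).copy()
    R = d[:, None] + d[None, :] - 2.0 * G
    np.fill_diagonal(R, 0.0)
    return R


def resistance_distances(
    resistance: Raster, registry: SiteRegistry, connectivity: int = 8,
    metric: str = "effective_resistance",
) -> DistanceMatrix:
    """Effective resistance between all registered sites on a raster."""
    registry.validate_extent(resistance.nrows, resistance.ncols)
    L, cell_index = build_graph(resistance, connectivity)
    sites = registry.sites
    ids = []
    for s in sites:
        r, c = registry.cells[s]
        nid = cell_index[r, c]
        if nid < 0:
            raise ValueError(f"site {s} sits on a masked (nodata) cell")
        ids.append(nid)
    R = effective_resistance(L, ids)
    return DistanceMatrix(sites, R, metric, "population")


def uniform_ibd_predictor(
    raster: Raster, registry: SiteRegistry, connectivity: int = 8
) -> DistanceMatrix:
    """Effective resistance on the all-ones raster (circuit-theory IBD)."""
    uniform = parameterize(raster, SurfaceSpec("distance", "uniform"))
    return resistance_distances(uniform, registry, connectivity,
                                metric="uniform_ibd")


# ---------------------------------------------------------------------------
# collinearity screen
# ---------------------------------------------------------------------------


def _vif_values(X: np.ndarray) -> np.ndarray:
    """VIF of each column of X against the others (with intercept)."""
    n, p = X.shape
    out = np.empty(p)
    for j in range(p):
        y = X[:, j]
        others = np.delete(X, j, axis=1)
        A = np.column_stack([np.ones(n), others])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        if ss_tot == 0:
            raise ValueError("constant predictor in VIF screen")
        r2 = 1.0 - ss_res / ss_tot
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def vif_screen(predictors: dict, threshold: float = 4.0):
    """Iteratively drop the highest-VIF predictor until all are below threshold.

    ``predictors`` maps name → DistanceMatrix (sharing labels); the VIF is
    computed on the lower-triangle vectors, the quantities that enter the
    pairwise models.  Returns ``(retained names, removal log)`` where the
    log lists ``(removed name, its VIF)`` in removal order.
    """
    names = list(predictors)
    if len(names) < 2:
        raise ValueError("VIF screen needs at least 2 predictors")
    vectors = {k: predictors[k].condensed() for k in names}
    removed = []
    while len(names) >= 2:
        X = np.column_stack([vectors[k] for k in names])
        vifs = _vif_values(X)
        worst = int(np.argmax(vifs))
        if vifs[worst] < threshold:
            break
        removed.append((names[worst], float(vifs[worst])))
        names.pop(worst)
    return names, removed


def vif_table(predictors: dict) -> pd.Series:
    """Current VIF score of every predictor (no removal)."""
    names = list(predictors)
    X = np.column_stack([predictors[k].condensed() for k in names])
    return pd.Series(_vif_values(X), index=names)
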