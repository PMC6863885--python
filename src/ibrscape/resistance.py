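"""Resistance surfaces and circuit-theory (effective-resistance) distances.

A resistance surface assigns every raster cell a cost >= 1 to gene movement.
Categorical surfaces map land-cover classes to values; continuous layers are
transformed through monomolecular or Ricker curves with a shape and a
maximum parameter.  Pairwise distances between sample points are effective
resistances on the lattice graph of the surface (8-neighborhood by default),
computed from sparse Laplacian solves.

Effective resistance is reported rather than random-walk commute time:
commute time equals (total conductance) x (effective resistance), a single
scale factor per surface, and predictors are standardized before model
fitting, so the two are equivalent for inference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix, csc_matrix
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import splu

from .raster import RasterGrid

__all__ = [
    "ResistanceSurface", "DistanceMatrix", "categorical_surface",
    "transform_continuous", "commute_distance", "null_ibd_surface",
    "EIGHT_TRANSFORMS",
]


@dataclass
class ResistanceSurface:
    """Per-cell resistance grid with provenance.

    Finite cells are >= 1 (the surface is rescaled so its minimum is exactly
    1); NaN cells are impassable.  ``n_free_params`` counts the free
    parameters that were (or could be) optimized for this surface: it enters
    the AIC penalty when surfaces of different complexity compete.
    """

    grid: RasterGrid
    provenance: dict = field(default_factory=dict)
    n_free_params: int = 0

    @property
    def values(self) -> np.ndarray:
        return self.grid.data


@dataclass
class DistanceMatrix:
    """Pairwise effective-resistance distances between sample points."""

    matrix: np.ndarray
    provenance: dict = field(default_factory=dict)
    snapped_cells: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        _check_metric(self.matrix)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def condensed(self) -> np.ndarray:
        """Upper-triangle values in row-major (scipy condensed) order."""
        iu = np.triu_indices(self.n, 1)
        return self.matrix[iu]


def _check_metric(m: np.ndarray, atol: float = 1e-8) -> None:
    """Assert symmetry, zero diagonal and the triangle inequality."""
    if m.shape[0] != m.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(m, m.T, atol=atol):
        raise ValueError("distance matrix not symmetric")
    if not np.allclose(np.diag(m), 0.0, atol=atol):
        raise ValueError("distance matrix diagonal not zero")
    # triangle inequality: d(i,j) <= d(i,k) + d(k,j) for all k
    n = m.shape[0]
    if n <= 200:
        viol = m - (m[:, :, None] + m[None, :, :]).min(axis=1)
        if viol.max() > 1e-6 * max(1.0, m.max()):
            raise ValueError("triangle inequality violated")


def categorical_surface(class_raster: RasterGrid, class_values: dict) -> ResistanceSurface:
    """Build a resistance surface from a categorical land-cover raster.

    Every class present in the raster must have a positive value in
    ``class_values``; the surface is divided by its minimum so the most
    permeable class has resistance exactly 1 (making the surface invariant
    to a common scale factor in the class values).
    """
    data = class_raster.data
    present = np.unique(data[data != class_raster.nodata])
    for code in present:
        if int(code) not in class_values and code not in class_values:
            raise ValueError(f"no resistance value for class code {code!r}")
    vals = {int(k): float(v) for k, v in class_values.items()}
    if any(v <= 0 for v in vals.values()):
        raise ValueError("class resistance values must be > 0")
    out = np.full(data.shape, np.nan)
    for code, v in vals.items():
        out[data == code] = v
    out = out / np.nanmin(out)
    grid = class_raster.copy_with(data=out, name=f"{class_raster.name}_resistance")
    return ResistanceSurface(
        grid=grid,
        provenance={"kind": "categorical", "class_values": vals,
                    "source": class_raster.name, "year": class_raster.year},
        n_free_params=max(len(vals) - 1, 0),
    )


#: The eight continuous transformations: each family combined with
#: forward/reverse (argument complemented) and plain/inverse (curve flipped).
EIGHT_TRANSFORMS = [
    (fam, var)
    for fam in ("monomolecular", "ricker")
    for var in ("forward", "reverse", "inverse", "inverse_reverse")
]

_VARIANT_BY_INDEX = {i + 1: fv for i, fv in enumerate(EIGHT_TRANSFORMS)}


def transform_continuous(layer: RasterGrid, family: str = "monomolecular",
                         variant="forward", shape: float = 1.0,
                         maximum: float = 100.0) -> ResistanceSurface:
    """Transform a continuous layer into a resistance surface.

    The layer is min-max rescaled to [0, 1]; the base curves are
    M(x) = 1 - exp(-x/shape) and R(x) = x * exp(-x/shape).  "reverse"
    variants apply the curve to 1 - x; "inverse" variants flip the curve
    vertically (max(y) - y).  The result is affinely rescaled to
    [1, maximum].  ``variant`` may also be an integer 1..8 indexing
    :data:`EIGHT_TRANSFORMS` (in that case ``family`` is ignored).
    """
    if isinstance(variant, (int, np.integer)):
        family, variant = _VARIANT_BY_INDEX[int(variant)]
    if shape <= 0:
        raise ValueError("shape must be > 0")
    if maximum <= 1:
        raise ValueError("maximum must be > 1")
    raw = np.asarray(layer.data, dtype=float)
    finite = raw != layer.nodata
    vals = raw[finite]
    rng = vals.max() - vals.min()
    out = np.full(raw.shape, np.nan)
    if rng == 0:
        warnings.warn("constant layer: returning a uniform surface of 1s")
        out[finite] = 1.0
    else:
        x = (raw - vals.min()) / rng
        if "reverse" in variant:
            x = 1.0 - x
        if family == "monomolecular":
            y = 1.0 - np.exp(-x / shape)
        elif family == "ricker":
            y = x * np.exp(-x / shape)
        else:
            raise ValueError(f"unknown family {family!r}")
        if variant in ("inverse", "inverse_reverse"):
            ymax = y[finite].max()
            y = ymax - y
        ymin, ymax = y[finite].min(), y[finite].max()
        if ymax - ymin < 1e-300:
            out[finite] = 1.0
        else:
            out[finite] = 1.0 + (maximum - 1.0) * (y[finite] - ymin) / (ymax - ymin)
    grid = layer.copy_with(data=out, name=f"{layer.name}_resistance")
    return ResistanceSurface(
        grid=grid,
        provenance={"kind": "continuous", "family": family, "variant": variant,
                    "shape": float(shape), "maximum": float(maximum),
                    "source": layer.name},
        n_free_params=2,
    )


def null_ibd_surface(extent: RasterGrid | tuple) -> ResistanceSurface:
    """Uniform unit surface: the isolation-by-distance null model.

    ``extent`` is a template raster (geometry reused; values ignored) or a
    (nrows, ncols) shape.
    """
    if isinstance(extent, RasterGrid):
        grid = extent.copy_with(data=np.ones(extent.shape), name="ibd_null")
    else:
        grid = RasterGrid(data=np.ones(extent), name="ibd_null")
    return ResistanceSurface(grid=grid, provenance={"kind": "ibd_null"},
                             n_free_params=0)


def _build_laplacian(res: np.ndarray, neighborhood: int = 8):
    """Sparse Laplacian of the lattice graph of a resistance grid.

    Conductance between neighboring cells u, v is 1 / mean(r_u, r_v) for
    cardinal moves and 1 / (sqrt(2) * mean(r_u, r_v)) for diagonal moves
    (the longer step costs proportionally more).  NaN cells are excluded.

    Returns (laplacian_csc, node_index_grid) where node_index_grid maps
    cell (row, col) -> node id or -1.
    """
    nr, nc = res.shape
    finite = np.isfinite(res)
    node = -np.ones((nr, nc), dtype=np.int64)
    node[finite] = np.arange(finite.sum())
    n = int(finite.sum())
    offsets = [(0, 1, 1.0), (1, 0, 1.0)]
    if neighborhood == 8:
        offsets += [(1, 1, np.sqrt(2.0)), (1, -1, np.sqrt(2.0))]
    elif neighborhood != 4:
        raise ValueError("neighborhood must be 4 or 8")
    rows, cols, vals = [], [], []
    for dr, dc, mult in offsets:
        r0 = slice(max(0, -dr), nr - max(0, dr))
        c0 = slice(max(0, -dc), nc - max(0, dc))
        r1 = slice(max(0, dr), nr - max(0, -dr))
        c1 = slice(max(0, dc), nc - max(0, -dc))
        a = node[r0, c0]
        b = node[r1, c1]
        ra = res[r0, c0]
        rb = res[r1, c1]
        ok = (a >= 0) & (b >= 0)
        g = 1.0 / (mult * 0.5 * (ra[ok] + rb[ok]))
        rows.append(a[ok]); cols.append(b[ok]); vals.append(g)
    rows = np.concatenate(rows); cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    # symmetric adjacency
    i = np.concatenate([rows, cols])
    j = np.concatenate([cols, rows])
    w = np.concatenate([vals, vals])
    adj = coo_matrix((w, (i, j)), shape=(n, n)).tocsr()
    deg = np.asarray(adj.sum(axis=1)).ravel()
    lap = (coo_matrix((deg, (np.arange(n), np.arange(n))), shape=(n, n)) - adj).tocsc()
    return lap, node, adj


def commute_distance(surface: ResistanceSurface, points: np.ndarray,
                     neighborhood: int = 8) -> DistanceMatrix:
    """Pairwise effective resistance between sample points on a surface.

    Points (x, y coordinates, shape (m, 2)) are snapped to the nearest
    finite cell center.  The effective resistance between nodes u and v is
    (e_u - e_v)^T L^+ (e_u - e_v), obtained by grounding one node and
    solving the reduced Laplacian once per distinct source node.
    """
    res = surface.values
    grid = surface.grid
    lap, node, adj = _build_laplacian(res, neighborhood=neighborhood)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    # snap to nearest finite cell center
    cx, cy = grid.cell_centers()
    fin = np.isfinite(res)
    cand = np.column_stack([cx[fin], cy[fin]])
    cand_nodes = node[fin]
    snapped = []
    for x, y in pts:
        d2 = (cand[:, 0] - x) ** 2 + (cand[:, 1] - y) ** 2
        k = int(np.argmin(d2))
        snapped.append(int(cand_nodes[k]))
    # connectivity across snapped nodes
    ncomp, labels = connected_components(adj, directed=False)
    comp = {labels[s] for s in snapped}
    if len(comp) > 1:
        raise ValueError(
            f"sample points fall in {len(comp)} disconnected graph components: "
            f"{sorted(comp)}")
    m = len(snapped)
    uniq = sorted(set(snapped))
    ground = uniq[0]
    keep = np.ones(lap.shape[0], dtype=bool)
    # restrict to the component containing the samples, then drop ground
    keep &= labels == labels[ground]
    keep[ground] = False
    keep_idx = np.flatnonzero(keep)
    pos = -np.ones(lap.shape[0], dtype=np.int64)
    pos[keep_idx] = np.arange(keep_idx.size)
    lred = lap[np.ix_(keep_idx, keep_idx)].tocsc()
    lu = splu(lred)
    cols = {ground: np.zeros(keep_idx.size)}
    for s in uniq:
        if s == ground:
            continue
        e = np.zeros(keep_idx.size)
        e[pos[s]] = 1.0
        cols[s] = lu.solve(e)

    def entry(c, s):
        return 0.0 if s == ground else c[pos[s]]

    dm = np.zeros((m, m))
    for a in range(m):
        for b in range(a + 1, m):
            u, v = snapped[a], snapped[b]
            r = (entry(cols[u], u) - entry(cols[u], v)
                 - entry(cols[v], u) + entry(cols[v], v))
            dm[a, b] = dm[b, a] = max(r, 0.0)
    cells = [tuple(int(q) for q in np.argwhere(node == s)[0]) for s in snapped]
    prov = dict(surface.provenance)
    prov.update({"distance": "effective_resistance", "neighborhood": neighborhood,
                 "n_free_params": surface.n_free_params})
    return DistanceMatrix(matrix=dm, provenance=prov, snapped_cells=cells)
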