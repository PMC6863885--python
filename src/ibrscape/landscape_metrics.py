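"""Buffer-based habitat metrics, grain resampling and climate-variable
pre-selection.

Habitat amount is the proportion of the focal class (canga) among cells
whose centers fall inside a circular buffer around an individual; habitat
loss in a later year is the pre-mining amount minus that year's amount, in
area units.  The buffer radius is chosen by AIC over univariate models —
among radii whose model is within 2 AIC of the best, the largest is taken,
to encompass a greater portion of the lost areas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster import RasterGrid

__all__ = [
    "habitat_amount", "habitat_loss", "habitat_records",
    "select_buffer_size", "resample_categorical", "select_climate_variables",
    "extract_at_points",
]


def _buffer_mask(raster: RasterGrid, point, radius: float) -> np.ndarray:
    """Boolean mask of cells whose centers lie within ``radius`` of point."""
    x0, y0 = point
    cx, cy = raster.cell_centers()
    return (cx - x0) ** 2 + (cy - y0) ** 2 <= radius ** 2


def habitat_amount(raster: RasterGrid, point, radius: float,
                   target_class: int) -> tuple[float, float]:
    """(proportion, area) of ``target_class`` in a circular buffer.

    The proportion denominator counts in-bounds, non-missing cells whose
    centers fall in the circle; area is target cell count times cell area.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    xmin, xmax, ymin, ymax = raster.extent
    x0, y0 = point
    if not (xmin <= x0 <= xmax and ymin <= y0 <= ymax):
        raise ValueError(f"point {point} outside raster bounds")
    mask = _buffer_mask(raster, point, radius)
    valid = mask & (raster.data != raster.nodata)
    n_in = int(valid.sum())
    if n_in == 0:
        raise ValueError("buffer contains no raster cells")
    n_target = int((valid & (raster.data == target_class)).sum())
    area = n_target * raster.cell_size ** 2
    return n_target / n_in, area


def habitat_loss(raster_pre: RasterGrid, raster_year: RasterGrid, point,
                 radius: float, target_class: int) -> float:
    """Habitat area lost between the pre-mining map and a later year.

    loss = amount(pre) - amount(year) in area units; negative values
    (habitat gain) are allowed but unusual when the only transition is
    habitat -> mine.
    """
    if not raster_pre.aligned_with(raster_year):
        raise ValueError("rasters are not aligned (geometry differs)")
    _, a_pre = habitat_amount(raster_pre, point, radius, target_class)
    _, a_now = habitat_amount(raster_year, point, radius, target_class)
    return a_pre - a_now


def habitat_records(class_maps: dict, points: np.ndarray, radius: float,
                    target_class: int, pre_year: int | None = None) -> pd.DataFrame:
    """Habitat amount (pre-mining) and per-year loss for each individual."""
    years = sorted(class_maps)
    pre_year = pre_year if pre_year is not None else years[0]
    pre = class_maps[pre_year]
    rows = []
    for i, pt in enumerate(np.atleast_2d(points)):
        prop, area = habitat_amount(pre, pt, radius, target_class)
        row = {"index": i, "radius": radius,
               f"amount_{pre_year}_prop": prop, f"amount_{pre_year}_area": area}
        for y in years:
            if y == pre_year:
                continue
            row[f"loss_{y}"] = habitat_loss(pre, class_maps[y], pt, radius,
                                            target_class)
        rows.append(row)
    return pd.DataFrame(rows)


def select_buffer_size(data_by_radius: dict, fit_fn,
                       best_cutoff: float = 2.0) -> tuple[float, pd.DataFrame]:
    """Choose a buffer radius by AIC over univariate models.

    ``data_by_radius`` maps radius -> argument for ``fit_fn`` (which returns
    an object with ``.aic`` and ``.converged``); the chosen radius is the
    LARGEST whose model sits within ``best_cutoff`` AIC of the best.
    Non-converged models are excluded with a note.
    """
    if len(data_by_radius) < 1:
        raise ValueError("need at least one candidate radius")
    rows = []
    for radius, payload in sorted(data_by_radius.items()):
        try:
            fit = fit_fn(payload)
        except Exception as exc:  # noqa: BLE001 - records the failure
            rows.append({"radius": radius, "AIC": np.nan,
                         "note": f"fit failed: {exc}"})
            continue
        if not getattr(fit, "converged", True):
            rows.append({"radius": radius, "AIC": np.nan,
                         "note": "not converged"})
            continue
        rows.append({"radius": radius, "AIC": fit.aic, "note": ""})
    table = pd.DataFrame(rows)
    ok = table.dropna(subset=["AIC"]).copy()
    if ok.empty:
        raise RuntimeError("no buffer model converged")
    ok["dAIC"] = ok["AIC"] - ok["AIC"].min()
    table = table.merge(ok[["radius", "dAIC"]], on="radius", how="left")
    chosen = float(ok.loc[ok["dAIC"] <= best_cutoff, "radius"].max())
    return chosen, table


def resample_categorical(raster: RasterGrid, new_cell_size: float,
                         priority: tuple = (2, 0, 1)) -> RasterGrid:
    """Aggregate a categorical raster to a coarser grain by majority rule.

    Ties are broken by the fixed class priority (default mine > canga >
    forest, recorded in metadata).  Non-integer aggregation factors are
    handled by nearest-cell-center assignment.
    """
    if new_cell_size < raster.cell_size:
        raise ValueError("new cell size must be >= current cell size")
    factor = new_cell_size / raster.cell_size
    nr, nc = raster.shape
    out_nr = max(int(np.ceil(nr / factor)), 1)
    out_nc = max(int(np.ceil(nc / factor)), 1)
    src_rows = np.minimum((np.arange(nr) / factor).astype(int), out_nr - 1)
    src_cols = np.minimum((np.arange(nc) / factor).astype(int), out_nc - 1)
    out = np.full((out_nr, out_nc), raster.nodata)
    rank = {c: i for i, c in enumerate(priority)}
    for R in range(out_nr):
        rows = np.flatnonzero(src_rows == R)
        for C in range(out_nc):
            cols = np.flatnonzero(src_cols == C)
            block = raster.data[np.ix_(rows, cols)]
            block = block[block != raster.nodata]
            if block.size == 0:
                continue
            vals, counts = np.unique(block, return_counts=True)
            top = counts.max()
            cands = vals[counts == top]
            out[R, C] = min(cands, key=lambda c: rank.get(int(c), len(rank)))
    # keep the same top-left origin; the bottom edge moves with the new size
    ymax = raster.yll + nr * raster.cell_size
    grid = RasterGrid(data=out, xll=raster.xll,
                      yll=ymax - out_nr * new_cell_size,
                      cell_size=new_cell_size, nodata=raster.nodata,
                      name=raster.name, year=raster.year,
                      meta={**raster.meta, "tie_priority": list(priority),
                            "resampled_from": raster.cell_size})
    return grid


def extract_at_points(layers: dict, points: np.ndarray) -> pd.DataFrame:
    """Extract layer values at sample points (cell containing each point)."""
    rows = {}
    for name, grid in layers.items():
        vals = []
        for x, y in np.atleast_2d(points):
            r, c = grid.index_of(x, y)
            v = grid.data[r, c]
            vals.append(np.nan if v == grid.nodata else v)
        rows[name] = vals
    return pd.DataFrame(rows)


def select_climate_variables(layers: dict, sample_points: np.ndarray,
                             n_axes: int = 3, variance_target: float = 0.85
                             ) -> tuple[list, pd.DataFrame, dict]:
    """Pick one variable per leading PCA axis of the scaled extractions.

    A PCA is run on the column-scaled matrix of layer values at the sample
    points.  For each of the first ``n_axes`` axes the layer with the
    largest absolute Pearson correlation to the axis scores is selected,
    without repetition.  A warning is recorded when those axes explain less
    than ``variance_target`` of total variance; constant layers are dropped
    with a note.
    """
    from sklearn.decomposition import PCA

    if len(layers) < n_axes:
        raise ValueError(f"need >= {n_axes} layers")
    df = extract_at_points(layers, sample_points)
    notes = {"dropped_constant": [], "warnings": []}
    keep = []
    for c in df.columns:
        if np.nanstd(df[c].to_numpy()) > 0:
            keep.append(c)
        else:
            notes["dropped_constant"].append(c)
    df = df[keep]
    X = (df - df.mean()) / df.std(ddof=0)
    pca = PCA(n_components=min(n_axes, X.shape[1], X.shape[0] - 1))
    scores = pca.fit_transform(X.to_numpy())
    explained = float(pca.explained_variance_ratio_.sum())
    if explained < variance_target:
        notes["warnings"].append(
            f"first {n_axes} axes explain {explained:.2%} < "
            f"{variance_target:.0%} of variance")
    cors = pd.DataFrame(index=df.columns,
                        columns=[f"PC{i+1}" for i in range(scores.shape[1])],
                        dtype=float)
    for i in range(scores.shape[1]):
        for c in df.columns:
            cors.loc[c, f"PC{i+1}"] = np.corrcoef(df[c], scores[:, i])[0, 1]
    chosen: list = []
    for i in range(scores.shape[1]):
        col = cors[f"PC{i+1}"].abs()
        for name in col.sort_values(ascending=False).index:
            if name not in chosen:
                chosen.append(name)
                break
    notes["explained_variance"] = explained
    return chosen, cors, notes
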