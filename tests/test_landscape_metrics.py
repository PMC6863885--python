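"""Buffer habitat metrics, grain resampling and climate pre-selection."""

import numpy as np
import pandas as pd
import pytest

from ibrscape.landscape_metrics import (habitat_amount, habitat_loss,
                                        resample_categorical,
                                        select_buffer_size,
                                        select_climate_variables)
from ibrscape.model_engine import fit_gls
from ibrscape.raster import RasterGrid, read_ascii_grid, write_ascii_grid


class TestHabitatAmount:
    def test_uniform_raster_proportion_one(self):
        grid = RasterGrid(data=np.zeros((20, 20)), cell_size=10.0)
        prop, area = habitat_amount(grid, (100.0, 100.0), 40.0, 0)
        assert prop == 1.0
        assert area > 0

    def test_absent_class_zero(self):
        grid = RasterGrid(data=np.ones((20, 20)), cell_size=10.0)
        prop, area = habitat_amount(grid, (100.0, 100.0), 40.0, 0)
        assert prop == 0.0 and area == 0.0

    def test_half_plane_boundary_near_half(self):
        data = np.zeros((200, 200))
        data[:, 100:] = 1  # right half is class 1
        grid = RasterGrid(data=data, cell_size=1.0)
        prop, _ = habitat_amount(grid, (100.0, 100.0), 40.0, 0)
        assert prop == pytest.approx(0.5, abs=0.02)

    def test_nested_buffers_monotone(self):
        rng = np.random.default_rng(0)
        grid = RasterGrid(data=(rng.random((50, 50)) < 0.4).astype(float))
        pt = (25.0, 25.0)
        areas = [habitat_amount(grid, pt, r, 1)[1] for r in (3, 6, 12)]
        assert areas == sorted(areas)

    def test_off_raster_buffer_raises(self):
        grid = RasterGrid(data=np.zeros((5, 5)))
        with pytest.raises(ValueError):
            habitat_amount(grid, (100.0, 100.0), 1.0, 0)

    def test_storage_order_invariance(self):
        rng = np.random.default_rng(1)
        data = (rng.random((30, 30)) < 0.5).astype(float)
        g1 = RasterGrid(data=data)
        g2 = RasterGrid(data=np.ascontiguousarray(data[::-1])[::-1])
        assert habitat_amount(g1, (15, 15), 5, 1) == \
            habitat_amount(g2, (15, 15), 5, 1)


class TestHabitatLoss:
    def test_identical_maps_zero(self):
        grid = RasterGrid(data=np.zeros((20, 20)), cell_size=10.0)
        assert habitat_loss(grid, grid, (100, 100), 50, 0) == 0.0

    def test_planted_conversion_area(self):
        pre = RasterGrid(data=np.zeros((30, 30)), cell_size=10.0)
        post = pre.copy_with()
        # convert 25 cells near the center to mine (class 2)
        post.data[13:18, 13:18] = 2
        loss = habitat_loss(pre, post, (152.0, 148.0), 100.0, 0)
        assert loss == pytest.approx(25 * 100.0)

    def test_additive_over_disjoint_patches(self):
        pre = RasterGrid(data=np.zeros((30, 30)), cell_size=10.0)
        a = pre.copy_with()
        a.data[5:7, 5:7] = 2
        b = pre.copy_with()
        b.data[20:22, 20:22] = 2
        both = pre.copy_with()
        both.data[5:7, 5:7] = 2
        both.data[20:22, 20:22] = 2
        pt, r = (150.0, 150.0), 200.0
        assert habitat_loss(pre, both, pt, r, 0) == pytest.approx(
            habitat_loss(pre, a, pt, r, 0) + habitat_loss(pre, b, pt, r, 0))

    def test_misaligned_rasters_raise(self):
        a = RasterGrid(data=np.zeros((10, 10)), cell_size=10.0)
        b = RasterGrid(data=np.zeros((10, 10)), cell_size=20.0)
        with pytest.raises(ValueError):
            habitat_loss(a, b, (50, 50), 30, 0)


class TestBufferSelection:
    def _fit(self, payload):
        df = pd.DataFrame({"y": payload["y"], "x": payload["x"]})
        return fit_gls(df, "y", ["x"], family="none")

    def test_single_candidate(self):
        rng = np.random.default_rng(2)
        data = {300.0: {"y": rng.normal(size=30), "x": rng.normal(size=30)}}
        chosen, table = select_buffer_size(data, self._fit)
        assert chosen == 300.0

    def test_largest_radius_in_plausible_set_wins(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=50)
        x = rng.normal(size=50)
        # identical payloads: all radii tie, the largest must be chosen
        data = {r: {"y": y, "x": x} for r in (100.0, 300.0, 900.0)}
        chosen, _ = select_buffer_size(data, self._fit)
        assert chosen == 900.0

    def test_generating_radius_in_plausible_set(self):
        hits = 0
        radii = (100.0, 300.0, 500.0, 700.0, 900.0)
        for rep in range(10):
            rng = np.random.default_rng(100 + rep)
            xs = {r: rng.normal(size=60) for r in radii}
            # amounts at nearby radii are correlated, as in real buffers
            for i, r in enumerate(radii[1:], 1):
                xs[r] = 0.7 * xs[radii[i - 1]] + 0.3 * xs[r]
            y = 1.0 + 1.5 * xs[500.0] + rng.normal(0, 1.0, 60)
            data = {r: {"y": y, "x": xs[r]} for r in radii}
            chosen, table = select_buffer_size(data, self._fit)
            in_set = table.dropna(subset=["dAIC"])
            hits += 500.0 in set(in_set.loc[in_set["dAIC"] <= 2, "radius"])
        assert hits >= 8


class TestResample:
    def test_uniform_stays_uniform(self):
        grid = RasterGrid(data=np.full((12, 12), 1.0), cell_size=10.0)
        out = resample_categorical(grid, 30.0)
        assert np.all(out.data == 1.0)
        assert out.cell_size == 30.0

    def test_majority_rule_block(self):
        data = np.array([[0.0, 0.0], [0.0, 2.0]])
        out = resample_categorical(RasterGrid(data=data, cell_size=1.0), 2.0)
        assert out.data[0, 0] == 0.0

    def test_tie_priority_mine_over_canga(self):
        data = np.array([[0.0, 2.0], [2.0, 0.0]])
        out = resample_categorical(RasterGrid(data=data, cell_size=1.0), 2.0)
        assert out.data[0, 0] == 2.0  # mine wins ties

    def test_class_proportions_roughly_preserved(self):
        # land cover is spatially autocorrelated; majority aggregation of a
        # smooth categorical map keeps class proportions nearly unchanged
        from scipy.ndimage import gaussian_filter
        rng = np.random.default_rng(4)
        field = gaussian_filter(rng.normal(size=(120, 120)), 6.0)
        q = np.quantile(field, [0.5, 0.8])
        data = np.digitize(field, q).astype(float)
        grid = RasterGrid(data=data, cell_size=1.0)
        out = resample_categorical(grid, 3.0)
        for cls in (0.0, 1.0, 2.0):
            before = (grid.data == cls).mean()
            after = (out.data == cls).mean()
            assert abs(before - after) < 0.02

    def test_refining_rejected(self):
        grid = RasterGrid(data=np.zeros((4, 4)), cell_size=10.0)
        with pytest.raises(ValueError):
            resample_categorical(grid, 5.0)


class TestClimateSelection:
    def test_orthogonal_fields_each_axis_distinct(self):
        rng = np.random.default_rng(5)
        n = 80
        pts = rng.uniform(1, 39, (n, 2))
        # three orthogonal spatial fields with decreasing variance, plus noise
        base = {
            "f1": 3.0 * np.sin(2 * np.pi * np.arange(40) / 40),
            "f2": 2.0 * np.cos(2 * np.pi * np.arange(40) / 13),
            "f3": 1.0 * np.sin(2 * np.pi * np.arange(40) / 7),
        }
        layers = {}
        for name, profile in base.items():
            data = np.tile(profile, (40, 1)) if name != "f2" \
                else np.tile(profile[:, None], (1, 40))
            layers[name] = RasterGrid(data=data + rng.normal(0, 0.01, (40, 40)))
        chosen, cors, notes = select_climate_variables(layers, pts)
        assert len(set(chosen)) == 3

    def test_duplicate_layer_not_selected_twice(self):
        rng = np.random.default_rng(6)
        pts = rng.uniform(1, 19, (50, 2))
        a = RasterGrid(data=rng.normal(size=(20, 20)))
        layers = {"a": a, "a_copy": a.copy_with(), "b":
                  RasterGrid(data=rng.normal(size=(20, 20))),
                  "c": RasterGrid(data=rng.normal(size=(20, 20)))}
        chosen, _, _ = select_climate_variables(layers, pts)
        assert len(set(chosen)) == 3

    def test_axis1_pick_has_max_correlation(self):
        rng = np.random.default_rng(7)
        pts = rng.uniform(1, 19, (60, 2))
        layers = {f"l{i}": RasterGrid(data=rng.normal(size=(20, 20)))
                  for i in range(4)}
        chosen, cors, _ = select_climate_variables(layers, pts)
        assert cors["PC1"].abs().idxmax() == chosen[0]

    def test_constant_layer_dropped(self):
        rng = np.random.default_rng(8)
        pts = rng.uniform(1, 19, (40, 2))
        layers = {"const": RasterGrid(data=np.full((20, 20), 2.0)),
                  "a": RasterGrid(data=rng.normal(size=(20, 20))),
                  "b": RasterGrid(data=rng.normal(size=(20, 20))),
                  "c": RasterGrid(data=rng.normal(size=(20, 20)))}
        chosen, _, notes = select_climate_variables(layers, pts)
        assert "const" in notes["dropped_constant"]
        assert "const" not in chosen


def test_ascii_grid_round_trip(tmp_path):
    rng = np.random.default_rng(9)
    grid = RasterGrid(data=rng.normal(size=(15, 11)), xll=1000.0, yll=500.0,
                      cell_size=25.0, nodata=-9999.0, name="elev")
    path = write_ascii_grid(grid, tmp_path / "elev.asc")
    back = read_ascii_grid(path)
    assert back.shape == grid.shape
    assert back.cell_size == grid.cell_size
    assert back.xll == grid.xll and back.yll == grid.yll
    assert np.allclose(back.data, grid.data, atol=1e-9)
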