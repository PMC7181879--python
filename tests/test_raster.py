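"""Raster plumbing: clipping, bilinear alignment, and GeoTIFF/GeoJSON I/O."""

import numpy as np
import pytest
from shapely.geometry import Polygon, box

from oroshift import (
    DisjointGridsError,
    EmptyClipError,
    Grid,
    RangeBoundary,
    align_bilinear,
    clip_values,
    read_boundary,
    read_geotiff,
    write_boundary,
    write_geotiff,
)


def make_grid(values, cell_size=1.0, origin=None, mask=None):
    values = np.asarray(values, dtype=float)
    if origin is None:
        origin = (0.0, values.shape[0] * cell_size)
    if mask is None:
        mask = np.zeros_like(values, dtype=bool)
    return Grid(values=values, nodata_mask=mask, cell_size=cell_size, origin=origin)


def point_in_polygon(px, py, vertices):
    """Ray-casting point-in-polygon, independent of shapely."""
    inside = False
    n = len(vertices)
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        if (y1 > py) != (y2 > py):
            xcross = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < xcross:
                inside = not inside
    return inside


class TestClipValues:
    def test_constant_field_middle_block(self):
        grid = make_grid(np.full((4, 4), 7.0))
        boundary = RangeBoundary(polygon=box(1.0, 1.0, 3.0, 3.0), id="mid")
        assert clip_values(grid, boundary).tolist() == [7.0, 7.0, 7.0, 7.0]

    def test_boundary_outside_raises(self):
        grid = make_grid(np.zeros((4, 4)))
        boundary = RangeBoundary(polygon=box(10.0, 10.0, 12.0, 12.0), id="far")
        with pytest.raises(EmptyClipError):
            clip_values(grid, boundary)

    def test_masked_cells_excluded(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 1] = True
        grid = make_grid(np.full((4, 4), 7.0), mask=mask)
        boundary = RangeBoundary(polygon=box(1.0, 1.0, 3.0, 3.0), id="mid")
        assert len(clip_values(grid, boundary)) == 3

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_point_in_polygon(self, seed):
        rng = np.random.default_rng(seed)
        n = 24
        grid = make_grid(rng.normal(size=(n, n)))
        # random simple polygon: star-convex around a center
        angles = np.sort(rng.uniform(0, 2 * np.pi, size=7))
        radii = rng.uniform(3.0, n / 2, size=7)
        cx0, cy0 = n / 2, n / 2
        verts = [
            (cx0 + r * np.cos(a), cy0 + r * np.sin(a)) for a, r in zip(angles, radii)
        ]
        boundary = RangeBoundary(polygon=Polygon(verts), id="star")

        got = clip_values(grid, boundary)
        xs, ys = grid.cell_centers()
        expected = [
            grid.values[i, j]
            for i in range(n)
            for j in range(n)
            if point_in_polygon(xs[i, j], ys[i, j], verts)
        ]
        # permutation-identical (and in fact row-major identical)
        assert sorted(got.tolist()) == sorted(expected)
        assert got.tolist() == expected


class TestAlignBilinear:
    def test_constant_source(self):
        src = make_grid(np.full((8, 8), 5.0))
        template = make_grid(np.zeros((3, 3)), cell_size=2.0, origin=(1.0, 7.0))
        out = align_bilinear(src, template)
        assert np.allclose(out.values[~out.nodata_mask], 5.0)
        assert (~out.nodata_mask).any()

    def test_linear_plane_exact(self):
        # z = x at cell centers; bilinear must reproduce the plane exactly
        xs = np.arange(10) + 0.5
        src = make_grid(np.tile(xs, (10, 1)))
        template = make_grid(np.zeros((4, 4)), cell_size=1.7, origin=(1.0, 8.5))
        out = align_bilinear(src, template)
        txs, _ = template.cell_centers()
        valid = ~out.nodata_mask
        assert np.allclose(out.values[valid], txs[valid])

    def test_matches_four_point_formula(self, rng):
        src = make_grid(rng.normal(size=(12, 12)))
        template = make_grid(np.zeros((5, 5)), cell_size=2.0, origin=(0.5, 11.0))
        out = align_bilinear(src, template)
        txs, tys = template.cell_centers()
        for i in range(5):
            for j in range(5):
                if out.nodata_mask[i, j]:
                    continue
                fx = (txs[i, j] - src.origin[0]) / src.cell_size - 0.5
                fy = (src.origin[1] - tys[i, j]) / src.cell_size - 0.5
                x0, y0 = int(np.floor(fx)), int(np.floor(fy))
                dx, dy = fx - x0, fy - y0
                expected = (
                    src.values[y0, x0] * (1 - dx) * (1 - dy)
                    + src.values[y0, x0 + 1] * dx * (1 - dy)
                    + src.values[y0 + 1, x0] * (1 - dx) * dy
                    + src.values[y0 + 1, x0 + 1] * dx * dy
                )
                assert out.values[i, j] == pytest.approx(expected)
                # no overshoot beyond the four contributing cells
                four = src.values[y0 : y0 + 2, x0 : x0 + 2]
                assert four.min() - 1e-12 <= out.values[i, j] <= four.max() + 1e-12

    def test_disjoint_extents_raise(self):
        src = make_grid(np.zeros((4, 4)))
        template = make_grid(np.zeros((4, 4)), origin=(100.0, 104.0))
        with pytest.raises(DisjointGridsError):
            align_bilinear(src, template)

    def test_masked_source_cells_propagate(self):
        mask = np.zeros((6, 6), dtype=bool)
        mask[2, 2] = True
        src = make_grid(np.ones((6, 6)), mask=mask)
        template = make_grid(np.zeros((6, 6)))
        out = align_bilinear(src, template)
        assert out.nodata_mask[2, 2]


class TestIO:
    def test_geotiff_roundtrip(self, tmp_path, rng):
        mask = rng.random((9, 7)) < 0.15
        values = rng.normal(size=(9, 7)) * 100
        values[mask] = 0.0
        grid = Grid(
            values=values,
            nodata_mask=mask,
            cell_size=90.0,
            origin=(12345.0, 67890.0),
            crs_tag="EPSG:32633",
        )
        path = write_geotiff(grid, tmp_path / "g.tif")
        back = read_geotiff(path)
        assert back.cell_size == 90.0
        assert back.origin == (12345.0, 67890.0)
        assert back.crs_tag == "EPSG:32633"
        assert np.array_equal(back.nodata_mask, mask)
        assert np.allclose(back.values[~mask], values[~mask])

    def test_boundary_roundtrip(self, tmp_path):
        b = RangeBoundary(polygon=box(0, 0, 10, 5), name="Testberge", id="rng-1")
        path = write_boundary(b, tmp_path / "b.geojson")
        back = read_boundary(path)
        assert back.id == "rng-1"
        assert back.name == "Testberge"
        assert back.polygon.equals(b.polygon)

    def test_values_to_csv(self, tmp_path):
        import pandas as pd

        from oroshift.raster import values_to_csv

        path = values_to_csv("rng-7", np.array([1.5, 2.0]), tmp_path / "v.csv")
        df = pd.read_csv(path)
        assert list(df.columns) == ["range_id", "value"]
        assert df["range_id"].tolist() == ["rng-7", "rng-7"]
        assert df["value"].tolist() == [1.5, 2.0]

    def test_grid_invariants(self):
        with pytest.raises(ValueError):
            Grid(np.zeros((3, 3)), np.zeros((2, 2), bool), 1.0)
        with pytest.raises(ValueError):
            Grid(np.zeros((3, 3)), np.zeros((3, 3), bool), -1.0)
        bad = np.zeros((3, 3))
        bad[0, 0] = np.inf
        with pytest.raises(ValueError):
            Grid(bad, np.zeros((3, 3), bool), 1.0)
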