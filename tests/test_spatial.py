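import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon, box

from ptrtools.spatial import (
    BACKGROUND,
    TARGET,
    UNASSIGNED,
    RegionSet,
    assign_regions,
    cell_density,
    nearest_neighbor_distances,
    paired_region_comparison,
    proximity_fraction,
)


def cell_table(xy, flags=None, sample_id="S1"):
    df = pd.DataFrame(np.asarray(xy, float), columns=["x_um", "y_um"])
    df.insert(0, "sample_id", sample_id)
    df.insert(0, "cell_id", [f"c{i}" for i in range(len(df))])
    for name, values in (flags or {}).items():
        df[name] = values
    return df


def ray_cast_inside(poly_coords, x, y):
    """Independent even-odd ray casting point-in-polygon test."""
    inside = False
    n = len(poly_coords)
    for i in range(n):
        x1, y1 = poly_coords[i]
        x2, y2 = poly_coords[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            x_cross = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < x_cross:
                inside = not inside
    return inside


class TestAssignRegions:
    SQUARE = box(100, 100, 300, 300)

    def test_centroid_is_target(self):
        regions = RegionSet("S1", [(TARGET, self.SQUARE)])
        cells = cell_table([[200, 200]])
        assert assign_regions(cells, regions)["region_label"].iloc[0] == TARGET

    def test_outside_is_background_without_control_polygons(self):
        regions = RegionSet("S1", [(TARGET, self.SQUARE)])
        cells = cell_table([[50, 50]])
        assert assign_regions(cells, regions)["region_label"].iloc[0] == BACKGROUND

    def test_explicit_control_polygons_give_unassigned_elsewhere(self):
        regions = RegionSet("S1", [(TARGET, self.SQUARE),
                                   (BACKGROUND, box(400, 400, 600, 600))])
        cells = cell_table([[200, 200], [500, 500], [10, 10]])
        labels = assign_regions(cells, regions)["region_label"].tolist()
        assert labels == [TARGET, BACKGROUND, UNASSIGNED]

    def test_sample_mismatch_error(self):
        regions = RegionSet("OTHER", [(TARGET, self.SQUARE)])
        with pytest.raises(ValueError, match="mismatch"):
            assign_regions(cell_table([[0, 0]]), regions)

    def test_degenerate_polygon_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            RegionSet("S1", [(TARGET, Polygon([(0, 0), (1, 1), (2, 2)]))])

    def test_ray_casting_oracle_on_random_points(self):
        # non-convex polygon; random points almost surely off the boundary
        coords = [(0, 0), (400, 0), (400, 400), (200, 150), (0, 400)]
        regions = RegionSet("S1", [(TARGET, Polygon(coords))])
        rng = np.random.default_rng(77)
        pts = rng.uniform(-50, 450, size=(1000, 2))
        labels = assign_regions(cell_table(pts), regions)["region_label"]
        expected = [TARGET if ray_cast_inside(coords, x, y) else BACKGROUND
                    for x, y in pts]
        assert labels.tolist() == expected


class TestCellDensity:
    def test_hundred_cells_per_mm2(self):
        regions = RegionSet("S1", [(TARGET, box(0, 0, 1000, 1000))])
        rng = np.random.default_rng(1)
        xy = rng.uniform(0, 1000, size=(100, 2))
        cells = cell_table(xy, flags={"macrophage": [True] * 100})
        out = cell_density(cells, regions, "macrophage", field_size_um=(2000, 2000))
        d = out.set_index("region_class")["density_per_mm2"]
        assert d[TARGET] == pytest.approx(100.0)
        assert d[BACKGROUND] == 0.0

    def test_no_flagged_cells_zero_density(self):
        regions = RegionSet("S1", [(TARGET, box(0, 0, 1000, 1000))])
        cells = cell_table([[500, 500]], flags={"macrophage": [False]})
        out = cell_density(cells, regions, "macrophage", field_size_um=(2000, 2000))
        assert (out["density_per_mm2"] == 0).all()

    def test_disjoint_polygons_pool_additively(self):
        polys = [(TARGET, box(0, 0, 1000, 1000)), (TARGET, box(2000, 0, 3000, 500))]
        regions = RegionSet("S1", polys)
        rng = np.random.default_rng(2)
        xy = np.vstack([rng.uniform((0, 0), (1000, 1000), (60, 2)),
                        rng.uniform((2000, 0), (3000, 500), (30, 2))])
        cells = cell_table(xy, flags={"macrophage": [True] * 90})
        out = cell_density(cells, regions, "macrophage", field_size_um=(4000, 2000))
        pooled = out.set_index("region_class").loc[TARGET]
        # per-polygon recomputation: counts and areas add
        assert pooled["density_per_mm2"] == pytest.approx(90 / (1.0 + 0.5))

    def test_missing_field_size_error(self):
        regions = RegionSet("S1", [(TARGET, box(0, 0, 10, 10))])
        cells = cell_table([[5, 5]], flags={"macrophage": [True]})
        with pytest.raises(ValueError, match="field_size_um"):
            cell_density(cells, regions, "macrophage")


class TestProximityFraction:
    @staticmethod
    def _with_regions(xy, a_flags, b_flags):
        cells = cell_table(xy, flags={"A": a_flags, "B": b_flags})
        regions = RegionSet("S1", [(TARGET, box(-1000, -1000, 1000, 1000))])
        return assign_regions(cells, regions)

    def test_coincident_points_fraction_one(self):
        cells = self._with_regions([[0, 0], [0, 0]], [True, False], [False, True])
        r = proximity_fraction(cells, "A", "B", radius_um=1e-6)
        assert r.fraction_within == 1.0
        assert r.mean_nn_distance_um == 0.0

    def test_worked_toy_geometry(self):
        # A at (0,0) and (0,300); one B at (0,50); radius 100 um
        cells = self._with_regions([[0, 0], [0, 300], [0, 50]],
                                   [True, True, False], [False, False, True])
        r = proximity_fraction(cells, "A", "B", radius_um=100.0)
        assert r.fraction_within == pytest.approx(0.5)
        assert r.mean_nn_distance_um == pytest.approx(150.0)
        assert (r.n_a, r.n_b) == (2, 1)

    def test_brute_force_all_pairs_oracle(self):
        rng = np.random.default_rng(9)
        xy = rng.uniform(-900, 900, size=(200, 2))
        a = rng.uniform(size=200) < 0.5
        cells = self._with_regions(xy, a, ~a)
        r = proximity_fraction(cells, "A", "B", radius_um=120.0)
        # O(n^2) oracle
        a_xy, b_xy = xy[a], xy[~a]
        d = np.sqrt(((a_xy[:, None, :] - b_xy[None, :, :]) ** 2).sum(-1)).min(axis=1)
        assert r.fraction_within == pytest.approx(np.mean(d <= 120.0))
        assert r.mean_nn_distance_um == pytest.approx(d.mean())

    def test_monotone_in_radius_and_limit(self):
        rng = np.random.default_rng(10)
        xy = rng.uniform(-500, 500, size=(60, 2))
        a = np.arange(60) < 30
        cells = self._with_regions(xy, a, ~a)
        fracs = [proximity_fraction(cells, "A", "B", r).fraction_within
                 for r in (10, 50, 100, 500, 1e7)]
        assert all(f1 <= f2 for f1, f2 in zip(fracs, fracs[1:]))
        assert fracs[-1] == 1.0

    def test_translation_invariance(self):
        rng = np.random.default_rng(12)
        xy = rng.uniform(0, 500, size=(50, 2))
        a = np.arange(50) < 25
        cells = cell_table(xy, flags={"A": a, "B": ~a})
        regions = RegionSet("S1", [(TARGET, box(0, 0, 500, 500))])
        r0 = proximity_fraction(assign_regions(cells, regions), "A", "B", 80.0)
        shift = np.array([123.0, -456.0])
        cells2 = cell_table(xy + shift, flags={"A": a, "B": ~a})
        regions2 = RegionSet("S1", [(TARGET, box(123, -456, 623, 44))])
        r1 = proximity_fraction(assign_regions(cells2, regions2), "A", "B", 80.0)
        assert r0.fraction_within == pytest.approx(r1.fraction_within)
        assert r0.mean_nn_distance_um == pytest.approx(r1.mean_nn_distance_um)

    def test_no_a_or_b_error(self):
        cells = self._with_regions([[0, 0]], [True], [False])
        with pytest.raises(ValueError, match="no B"):
            proximity_fraction(cells, "A", "B")


class TestPairedComparison:
    @staticmethod
    def _frame(target_vals, background_vals):
        rows = []
        for i, (t, b) in enumerate(zip(target_vals, background_vals)):
            rows.append({"sample_id": f"S{i}", "region_class": TARGET, "v": t})
            rows.append({"sample_id": f"S{i}", "region_class": BACKGROUND, "v": b})
        return pd.DataFrame(rows)

    def test_identical_values_give_t0_p1(self):
        t, p, n = paired_region_comparison(self._frame([1, 2, 3], [1, 2, 3]), "v")
        assert (t, p, n) == (0.0, 1.0, 3)

    def test_closed_form_paired_t_oracle(self):
        tv = np.array([0.8, 0.7, 0.9, 0.6, 0.75])
        bv = np.array([0.5, 0.6, 0.7, 0.55, 0.65])
        t, p, n = paired_region_comparison(self._frame(tv, bv), "v")
        d = tv - bv
        t_exp = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        from scipy.stats import t as t_dist
        p_exp = 2 * t_dist.sf(abs(t_exp), df=len(d) - 1)
        assert t == pytest.approx(t_exp)
        assert p == pytest.approx(p_exp)

    def test_too_few_pairs_error(self):
        with pytest.raises(ValueError, match=">= 2"):
            paired_region_comparison(self._frame([1.0], [0.5]), "v")


class TestRegionSetIO:
    def test_geojson_round_trip(self, tmp_path):
        regions = RegionSet("S1", [(TARGET, box(0, 0, 100, 100)),
                                   (BACKGROUND, box(200, 200, 300, 300))])
        path = tmp_path / "regions.geojson"
        regions.to_geojson(path)
        back = RegionSet.from_geojson(path)
        assert back.sample_id == "S1"
        assert len(back.polygons) == 2
        for (l0, p0), (l1, p1) in zip(regions.polygons, back.polygons):
            assert l0 == l1 and p0.equals(p1)
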