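"""Cyclone-impact grid engine against brute-force geometric oracles."""

import numpy as np
import pytest
from shapely.geometry import LineString, Point, Polygon, box

from cyclemur import (
    ImpactGrid,
    SimConfig,
    SpeciesRange,
    StormTrack,
    filter_tracks,
    gen_tracks,
    impact_index,
    range_impact,
    saffir_weight,
)
from cyclemur.errors import ConfigError, DomainError
from cyclemur.impact import summarise_cells


class TestSaffirWeight:
    @pytest.mark.parametrize("cls,weight", [(0, 1), (1, 2), (3, 4), (5, 6)])
    def test_weight_is_class_plus_one(self, cls, weight):
        assert saffir_weight(cls) == weight

    @pytest.mark.parametrize("bad", [-1, 6, 2.5])
    def test_rejects_out_of_domain(self, bad):
        with pytest.raises(DomainError):
            saffir_weight(bad)


class TestFilterTracks:
    island = box(0, 0, 100, 100)

    def _track(self, x, wind):
        return StormTrack("t", np.array([[x, 50.0]]), [wind], [1])

    def test_far_point_dropped(self):
        kept, counts = filter_tracks([self._track(700.0, 50.0)], self.island)
        assert kept == [] and counts["points_dropped"] == 1

    def test_weak_wind_dropped(self):
        kept, _ = filter_tracks([self._track(110.0, 33.0)], self.island)
        assert kept == []

    def test_boundary_point_kept(self):
        kept, _ = filter_tracks([self._track(600.0, 34.0)], self.island)
        assert len(kept) == 1  # exactly 500 km offshore, exactly 34 kt

    def test_mixed_set_matches_loop_oracle(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(-600, 700, size=(100, 2))
        wind = rng.uniform(20, 80, 100)
        tracks = [
            StormTrack(f"s{i}", pts[i : i + 1], wind[i : i + 1], [0]) for i in range(100)
        ]
        kept, counts = filter_tracks(tracks, self.island)
        expected = sum(
            1
            for i in range(100)
            if self.island.distance(Point(*pts[i])) <= 500.0 and wind[i] >= 34.0
        )
        assert counts["points_kept"] == expected
        assert sum(t.n_points for t in kept) == expected

    def test_empty_input_is_empty_output(self):
        kept, counts = filter_tracks([], self.island)
        assert kept == [] and counts["points_kept"] == 0


def brute_force_impact(grid, tracks, diameter, per_point=False):
    """Literal O(cells x tracks) oracle using shapely distances only."""
    radius = diameter / 2.0
    out = np.zeros((grid.n_rows, grid.n_cols))
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            cell = grid.cell_box(r, c)
            for tr in tracks:
                line = (
                    Point(tr.points[0]) if tr.n_points == 1 else LineString(tr.points)
                )
                if cell.distance(line) > radius:
                    continue
                in_buf = [
                    k
                    for k in range(tr.n_points)
                    if cell.distance(Point(tr.points[k])) <= radius
                ]
                if per_point:
                    out[r, c] += sum(tr.saffir[k] + 1 for k in in_buf)
                elif in_buf:
                    out[r, c] += max(tr.saffir[k] for k in in_buf) + 1
                else:
                    k = min(
                        range(tr.n_points),
                        key=lambda k: cell.distance(Point(tr.points[k])),
                    )
                    out[r, c] += tr.saffir[k] + 1
    return out


class TestImpactIndex:
    grid = ImpactGrid(origin=(0.0, 0.0), cell_size=50.0, n_rows=10, n_cols=10)

    def test_no_tracks_all_zero(self):
        g = impact_index(self.grid, [], 175.0)
        assert (g.values[175.0] == 0).all()

    def test_single_track_single_cell(self):
        # class-1 storm crossing the middle of cell (2, 2); tiny buffer
        tr = StormTrack("s", np.array([[125.0, 120.0], [125.0, 130.0]]), [70, 70], [1, 1])
        g = impact_index(self.grid, [tr], 10.0, allow_any_diameter=True)
        v = g.values[10.0]
        assert v[2, 2] == 2.0
        assert v.sum() == 2.0

    def test_unknown_diameter_rejected(self):
        with pytest.raises(ConfigError):
            impact_index(self.grid, [], 100.0)

    @pytest.mark.parametrize("diameter", [87.5, 175.0, 350.0])
    @pytest.mark.parametrize("per_point", [False, True])
    def test_matches_brute_force_oracle(self, synthetic_tracks, diameter, per_point):
        _, tracks = synthetic_tracks
        g = impact_index(self.grid, tracks, diameter, per_point=per_point)
        oracle = brute_force_impact(self.grid, tracks, diameter, per_point=per_point)
        np.testing.assert_allclose(g.values[diameter], oracle)

    def test_scale_monotonicity(self, synthetic_tracks):
        _, tracks = synthetic_tracks
        g = self.grid
        for d in (87.5, 175.0, 350.0):
            g = impact_index(g, tracks, d)
        assert (g.values[175.0] >= g.values[87.5]).all()
        assert (g.values[350.0] >= g.values[175.0]).all()

    def test_adding_a_storm_never_decreases_cells(self, synthetic_tracks):
        _, tracks = synthetic_tracks
        g1 = impact_index(self.grid, tracks[:10], 175.0)
        g2 = impact_index(self.grid, tracks[:11], 175.0)
        assert (g2.values[175.0] >= g1.values[175.0]).all()

    def test_invariant_to_storm_and_point_order(self, synthetic_tracks):
        _, tracks = synthetic_tracks
        fwd = impact_index(self.grid, tracks, 175.0).values[175.0]
        rev_tracks = [
            StormTrack(t.storm_id, t.points[::-1], t.wind[::-1], t.saffir[::-1])
            for t in reversed(tracks)
        ]
        rev = impact_index(self.grid, rev_tracks, 175.0).values[175.0]
        np.testing.assert_allclose(fwd, rev)


class TestRangeImpact:
    def _grid_with(self, values):
        g = ImpactGrid(origin=(0.0, 0.0), cell_size=50.0, n_rows=10, n_cols=10)
        g.values[175.0] = np.asarray(values, dtype=float)
        return g

    def test_single_cell_range(self):
        vals = np.zeros((10, 10))
        vals[1, 1] = 7.0
        g = self._grid_with(vals)
        rng = SpeciesRange("sp", box(55.0, 55.0, 95.0, 95.0))
        scored, flagged = range_impact(g, [rng])
        s = scored[0].impact_summaries[175.0]
        assert s["sum"] == 7 and s["mean"] == 7 and s["count"] == 1 and s["sd"] == 0

    def test_two_cell_arithmetic(self):
        vals = np.zeros((10, 10))
        vals[0, 0], vals[0, 1] = 2.0, 4.0
        g = self._grid_with(vals)
        rng = SpeciesRange("sp", box(10.0, 10.0, 90.0, 40.0))  # spans cells (0,0),(0,1)
        scored, _ = range_impact(g, [rng])
        s = scored[0].impact_summaries[175.0]
        assert s["mean"] == 3 and s["sum"] == 6 and s["range"] == 2

    def test_boundary_touch_counts(self):
        vals = np.arange(100.0).reshape(10, 10)
        g = self._grid_with(vals)
        # polygon exactly covering cell (0,0); touches (0,1),(1,0),(1,1) at edges
        rng = SpeciesRange("sp", box(0.0, 0.0, 50.0, 50.0))
        scored, _ = range_impact(g, [rng])
        assert scored[0].impact_summaries[175.0]["count"] == 4

    def test_random_ranges_match_rasterization_oracle(self, synthetic_tracks):
        cfg, tracks = synthetic_tracks
        g = ImpactGrid(origin=(0.0, 0.0), cell_size=50.0, n_rows=10, n_cols=10)
        g = impact_index(g, tracks, 175.0)
        ranges = [
            SpeciesRange(f"r{i}", Point(p).buffer(60.0 + 10 * i))
            for i, p in enumerate(
                np.random.default_rng(5).uniform(50, 450, size=(5, 2))
            )
        ]
        scored, _ = range_impact(g, ranges)
        for rng in scored:
            cells = [
                g.values[175.0][r, c]
                for r in range(10)
                for c in range(10)
                if g.cell_box(r, c).intersects(rng.polygon)
            ]
            oracle = summarise_cells(np.array(cells))
            for key, val in oracle.items():
                assert rng.impact_summaries[175.0][key] == pytest.approx(val), key

    def test_disjoint_range_is_flagged(self):
        g = self._grid_with(np.zeros((10, 10)))
        rng = SpeciesRange("far", box(1000.0, 1000.0, 1100.0, 1100.0))
        with pytest.warns(UserWarning):
            scored, flagged = range_impact(g, [rng])
        assert flagged == ["far"] and scored == []


def test_mode_ties_take_smallest():
    s = summarise_cells(np.array([1.0, 1.0, 4.0, 4.0, 9.0]))
    assert s["mode"] == 1.0
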