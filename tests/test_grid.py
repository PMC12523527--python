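"""Grid construction, cave-to-cell assignment, map algebra, and export."""

import json

import pandas as pd
import pytest

from karstprior import (
    GeneratorParams,
    aggregate_layer,
    assign_caves,
    build_grid,
    classify_priority,
    composite_map,
    export_priority,
    generate_dataset,
)


@pytest.fixture
def study_grid():
    return build_grid((0, 0, 40_000, 30_000), ncols=40, nrows=30)


def _caves(rows):
    return pd.DataFrame(
        [(cid, cid, x, y, 10.0, "dry") for cid, x, y in rows],
        columns=["cave_id", "name", "x", "y", "length_m", "season"],
    )


class TestGrid:
    def test_default_grid_has_1200_square_km_cells(self, study_grid):
        assert study_grid.n_cells == 1200
        assert study_grid.cell_width * study_grid.cell_height == 1_000_000.0

    def test_half_open_cells_and_closed_far_edge(self, study_grid):
        assert study_grid.cell_of(500, 500) == (0, 0)
        assert study_grid.cell_of(1000, 0) == (1, 0)  # right edge belongs to next
        assert study_grid.cell_of(40_000, 30_000) == (39, 29)  # bbox corner closed

    def test_degenerate_bbox_rejected(self):
        with pytest.raises(ValueError):
            build_grid((0, 0, 0, 10), 4, 4)

    def test_outside_point_rejected(self, study_grid):
        with pytest.raises(ValueError):
            study_grid.cell_of(-1, 0)


class TestAssignment:
    def test_cohabiting_caves_share_a_cell(self, study_grid):
        mapping = assign_caves(study_grid, _caves([("a", 100, 100), ("b", 900, 900)]))
        assert mapping["a"] == mapping["b"] == (0, 0)

    def test_outside_cave_named_in_error(self, study_grid):
        with pytest.raises(ValueError, match="far"):
            assign_caves(study_grid, _caves([("ok", 10, 10), ("far", 99_999, 0)]))

    def test_every_synthetic_cave_is_assigned(self, study_grid, default_dataset):
        mapping = assign_caves(study_grid, default_dataset.caves)
        assert len(mapping) == len(default_dataset.caves) == 105


class TestMapAlgebra:
    def _scores(self, rows):
        df = pd.DataFrame(rows, columns=["cave_id", "nTS_score"])
        return df

    def test_cell_takes_max_attribute_score(self, study_grid):
        mapping = {"a": (0, 0), "b": (0, 0), "c": (1, 0)}
        scores = self._scores([("a", 250), ("b", 1000), ("c", 100)])
        layer = aggregate_layer(scores, mapping, "nTS")
        assert layer == {(0, 0): 1000, (1, 0): 100}

    def test_adding_a_cave_never_lowers_a_cell(self, study_grid):
        mapping = {"a": (0, 0)}
        base = aggregate_layer(self._scores([("a", 250)]), mapping, "nTS")
        mapping["b"] = (0, 0)
        more = aggregate_layer(self._scores([("a", 250), ("b", 100)]), mapping, "nTS")
        assert more[(0, 0)] >= base[(0, 0)]

    def test_composite_sums_layers(self):
        layers = {
            "nTS": {(0, 0): 1000}, "TbS": {(0, 0): 1000},
            "EnD": {(0, 0): 500}, "VuL": {(0, 0): 1000},
        }
        assert composite_map(layers) == {(0, 0): 3500}

    def test_zero_layers_give_zero(self):
        layers = {a: {(2, 3): 0} for a in ("nTS", "TbS", "EnD", "VuL")}
        assert composite_map(layers) == {(2, 3): 0}

    def test_mismatched_cell_sets_rejected(self):
        layers = {
            "nTS": {(0, 0): 1}, "TbS": {(0, 0): 1},
            "EnD": {(0, 0): 1}, "VuL": {(1, 1): 1},
        }
        with pytest.raises(ValueError):
            composite_map(layers)


class TestPriorityClasses:
    def test_four_nonempty_classes_partition_occupied_cells(self):
        pic = {(i, 0): v for i, v in enumerate(
            [200, 300, 350, 800, 900, 1400, 1500, 2900, 3100, 3500])}
        classes, _ = classify_priority(pic, 4)
        assert set(classes) == set(pic)
        assert set(classes.values()) == {"low", "medium", "high", "extreme"}

    def test_top_value_lands_in_extreme(self):
        pic = {(i, 0): v for i, v in enumerate([300, 500, 700, 1200, 3500])}
        classes, _ = classify_priority(pic, 4)
        assert classes[(4, 0)] == "extreme"

    def test_uniform_values_cannot_be_classified(self):
        pic = {(i, 0): 500 for i in range(10)}
        with pytest.raises(ValueError):
            classify_priority(pic, 4)


class TestExport:
    def test_geojson_round_trip(self, tmp_path, study_grid):
        small = build_grid((0, 0, 3000, 2000), 3, 2)
        layers = {a: {(0, 0): 100, (2, 1): 1000} for a in ("nTS", "TbS", "EnD", "VuL")}
        pic = composite_map(layers)
        classes = {(0, 0): "low", (2, 1): "extreme"}
        gj, cs = tmp_path / "p.geojson", tmp_path / "cells.csv"
        export_priority(small, layers, pic, classes, gj, cs)

        data = json.loads(gj.read_text())
        assert data["type"] == "FeatureCollection"
        assert len(data["features"]) == 6
        by_cell = {
            (f["properties"]["col"], f["properties"]["row"]): f["properties"]
            for f in data["features"]
        }
        assert by_cell[(2, 1)]["PiC"] == 4000
        assert by_cell[(2, 1)]["priority_class"] == "extreme"
        assert by_cell[(1, 0)]["PiC"] is None
        assert by_cell[(1, 0)]["priority_class"] == "unoccupied"

        cells = pd.read_csv(cs)
        assert len(cells) == 6
        assert (cells["occupied"].sum()) == 2
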