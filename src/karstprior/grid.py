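"""Analysis grid, map algebra, and priority classification.

The study area is tiled by a rectangular lattice of ``ncols x nrows`` cells
indexed ``(col, row)`` from the lower-left corner.  Cells are half-open on
their upper/right edges except for the last column/row, which closes the
bbox so every interior point maps to exactly one cell.

Map algebra proceeds per attribute: each occupied cell takes the *maximum*
score of that attribute over the caves it contains, and the composite
conservation value PiC of a cell is the sum of its four attribute-layer
scores.  Occupied cells are then split into priority tiers by exact
natural-breaks classification; unoccupied cells stay outside the
classification entirely.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from .config import PRIORITY_LABELS, UNOCCUPIED_LABEL
from .jenks import BreaksResult, jenks_breaks
from .scoring import ATTRIBUTES

Cell = tuple[int, int]


@dataclass(frozen=True)
class Grid:
    xmin: float
    ymin: float
    xmax: float
    ymax: float
    ncols: int
    nrows: int

    @property
    def cell_width(self) -> float:
        return (self.xmax - self.xmin) / self.ncols

    @property
    def cell_height(self) -> float:
        return (self.ymax - self.ymin) / self.nrows

    @property
    def n_cells(self) -> int:
        return self.ncols * self.nrows

    def cell_of(self, x: float, y: float) -> Cell:
        """Cell containing (x, y); raises if the point is outside the bbox."""
        if not (self.xmin <= x <= self.xmax and self.ymin <= y <= self.ymax):
            raise ValueError(f"point ({x}, {y}) outside grid bbox")
        col = min(int(math.floor((x - self.xmin) / self.cell_width)), self.ncols - 1)
        row = min(int(math.floor((y - self.ymin) / self.cell_height)), self.nrows - 1)
        return (col, row)

    def cell_polygon(self, col: int, row: int) -> list[list[float]]:
        """Closed exterior ring of cell (col, row), counter-clockwise."""
        x0 = self.xmin + col * self.cell_width
        y0 = self.ymin + row * self.cell_height
        x1, y1 = x0 + self.cell_width, y0 + self.cell_height
        return [[x0, y0], [x1, y0], [x1, y1], [x0, y1], [x0, y0]]


def build_grid(
    bbox: tuple[float, float, float, float], ncols: int, nrows: int
) -> Grid:
    xmin, ymin, xmax, ymax = bbox
    if not (xmax > xmin and ymax > ymin):
        raise ValueError(f"degenerate bbox {bbox!r}")
    if ncols < 1 or nrows < 1:
        raise ValueError("grid shape must be positive")
    return Grid(xmin, ymin, xmax, ymax, ncols, nrows)


def assign_caves(grid: Grid, caves: pd.DataFrame) -> dict[str, Cell]:
    """Map each cave to the grid cell containing it.

    Raises ``ValueError`` naming any cave outside the bbox.
    """
    mapping: dict[str, Cell] = {}
    for cave in caves.itertuples(index=False):
        try:
            mapping[cave.cave_id] = grid.cell_of(float(cave.x), float(cave.y))
        except ValueError as exc:
            raise ValueError(f"cave {cave.cave_id!r}: {exc}") from exc
    return mapping


def aggregate_layer(
    scores: pd.DataFrame,
    mapping: Mapping[str, Cell],
    attribute: str,
) -> dict[Cell, int]:
    """Per-cell maximum of one attribute's score over contained caves."""
    column = f"{attribute}_score"
    if column not in scores.columns:
        raise KeyError(f"no score column for attribute {attribute!r}")
    layer: dict[Cell, int] = {}
    for row in scores.itertuples(index=False):
        cell = mapping[row.cave_id]
        value = int(getattr(row, column))
        if cell not in layer or value > layer[cell]:
            layer[cell] = value
    return layer


def composite_map(layers: Mapping[str, Mapping[Cell, int]]) -> dict[Cell, int]:
    """Cell-wise sum of the four attribute layers (the PiC value)."""
    cell_sets = [set(layer) for layer in layers.values()]
    if any(s != cell_sets[0] for s in cell_sets[1:]):
        raise ValueError("attribute layers disagree on the occupied-cell set")
    return {
        cell: sum(int(layer[cell]) for layer in layers.values())
        for cell in cell_sets[0]
    }


def classify_priority(
    pic: Mapping[Cell, float], k: int = 4
) -> tuple[dict[Cell, str], BreaksResult]:
    """Natural-breaks priority classes over occupied cells.

    Classes are labeled low → extreme in ascending PiC order.  Only occupied
    cells are classified; callers label everything else ``unoccupied``.
    """
    if not pic:
        raise ValueError("no occupied cells to classify")
    breaks = jenks_breaks(list(pic.values()), k)
    if k == len(PRIORITY_LABELS):
        labels = PRIORITY_LABELS
    else:
        labels = tuple(f"class_{i + 1}" for i in range(k))
    classes = {cell: labels[breaks.class_of(value)] for cell, value in pic.items()}
    return classes, breaks


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def priority_features(
    grid: Grid,
    layers: Mapping[str, Mapping[Cell, int]],
    pic: Mapping[Cell, int],
    classes: Mapping[Cell, str],
) -> list[dict]:
    """One GeoJSON Feature per grid cell with layer scores, PiC, and class."""
    features = []
    for row in range(grid.nrows):
        for col in range(grid.ncols):
            cell = (col, row)
            occupied = cell in pic
            props = {
                "col": col,
                "row": row,
                "occupied": occupied,
                "PiC": int(pic[cell]) if occupied else None,
                "priority_class": classes.get(cell, UNOCCUPIED_LABEL),
            }
            for name in ATTRIBUTES:
                props[f"{name}_score"] = (
                    int(layers[name][cell]) if occupied else None
                )
            features.append(
                {
                    "type": "Feature",
                    "geometry": {
                        "type": "Polygon",
                        "coordinates": [grid.cell_polygon(col, row)],
                    },
                    "properties": props,
                }
            )
    return features


def export_priority(
    grid: Grid,
    layers: Mapping[str, Mapping[Cell, int]],
    pic: Mapping[Cell, int],
    classes: Mapping[Cell, str],
    geojson_path: str | Path,
    csv_path: str | Path,
) -> None:
    """Write the classified grid as a GeoJSON FeatureCollection and CSV twin."""
    features = priority_features(grid, layers, pic, classes)
    collection = {"type": "FeatureCollection", "features": features}
    with open(geojson_path, "w", encoding="utf-8") as fh:
        json.dump(collection, fh)

    columns = ["col", "row", "occupied"] + [f"{a}_score" for a in ATTRIBUTES] + [
        "PiC",
        "priority_class",
    ]
    with open(csv_path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(columns)
        for feat in features:
            p = feat["properties"]
            writer.writerow(
                [p["col"], p["row"], p["occupied"]]
                + [p[f"{a}_score"] if p[f"{a}_score"] is not None else "" for a in ATTRIBUTES]
                + [p["PiC"] if p["PiC"] is not None else "", p["priority_class"]]
            )
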