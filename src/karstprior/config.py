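"""Study configuration and shared vocabulary.

The analysis is parameterized by a :class:`StudyConfig`: the planar bounding
box of the study area, the grid shape used for map algebra, the buffer radius
for the vulnerability criterion, and the category → weight map applied to all
four cave attributes.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import yaml

#: Closed set of anthropogenic impact types recorded around caves.
IMPACT_TYPES: tuple[str, ...] = (
    "pasture",
    "agriculture_forestry",
    "mining",
    "urbanization",
    "paved_road",
)

#: Sampling-season labels carried by the cave inventory.
SEASONS: tuple[str, ...] = ("dry", "wet", "unknown")


class Category(enum.IntEnum):
    """Ordered attribute category; ``NONE`` means the attribute is absent.

    The integer values encode rank so that monotonicity of the categorizers
    can be asserted directly (``Category.LOW < Category.EXTREME``).
    """

    NONE = 0
    LOW = 1
    AVERAGE = 2
    HIGH = 3
    EXTREME = 4

    @property
    def label(self) -> str:
        return self.name.capitalize() if self is not Category.NONE else "None"


#: Default category weights: absence scores 0, then 100/250/500/1000.
DEFAULT_WEIGHTS: dict[Category, int] = {
    Category.NONE: 0,
    Category.LOW: 100,
    Category.AVERAGE: 250,
    Category.HIGH: 500,
    Category.EXTREME: 1000,
}

#: Priority-class labels in ascending order of conservation value.
PRIORITY_LABELS: tuple[str, ...] = ("low", "medium", "high", "extreme")
UNOCCUPIED_LABEL = "unoccupied"


class ConfigError(ValueError):
    """Raised for inconsistent study configuration."""


@dataclass(frozen=True)
class StudyConfig:
    """Parameters of a prioritization run.

    Attributes
    ----------
    bbox:
        ``(xmin, ymin, xmax, ymax)`` in planar meters.  The default spans a
        40 km x 30 km landscape, matching a 1200 km^2 karst study area.
    ncols, nrows:
        Grid shape; columns count along x, rows along y.  The defaults tile
        the bbox into 1200 cells of 1 km^2 each.
    buffer_radius_m:
        Radius of the circular buffer used to collect impact types around a
        cave (vulnerability criterion).
    n_classes:
        Number of natural-breaks priority classes on occupied cells.
    weights:
        Category -> score map; must be strictly increasing with rank.
    end_zero_policy:
        ``"table_literal"`` maps a stenoendemic count of 0 to the Low
        category (weight 100); ``"zero"`` maps it to absence (weight 0).
    tbs_extreme_min:
        Minimum troglobiont richness for the Extreme category.
    seed:
        Seed forwarded to any stochastic component of a run.
    """

    bbox: tuple[float, float, float, float] = (0.0, 0.0, 40_000.0, 30_000.0)
    ncols: int = 40
    nrows: int = 30
    buffer_radius_m: float = 250.0
    n_classes: int = 4
    weights: Mapping[Category, int] = field(
        default_factory=lambda: dict(DEFAULT_WEIGHTS)
    )
    end_zero_policy: str = "table_literal"
    tbs_extreme_min: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        xmin, ymin, xmax, ymax = self.bbox
        if not (xmax > xmin and ymax > ymin):
            raise ConfigError(f"degenerate bbox {self.bbox!r}")
        if self.ncols < 1 or self.nrows < 1:
            raise ConfigError("grid shape must be positive")
        if self.buffer_radius_m <= 0:
            raise ConfigError("buffer_radius_m must be positive")
        if self.n_classes < 1:
            raise ConfigError("n_classes must be positive")
        if self.end_zero_policy not in ("table_literal", "zero"):
            raise ConfigError(
                f"end_zero_policy must be 'table_literal' or 'zero', "
                f"got {self.end_zero_policy!r}"
            )
        ranked = [self.weights[c] for c in sorted(self.weights) if c != Category.NONE]
        if any(b <= a for a, b in zip(ranked, ranked[1:])):
            raise ConfigError("weights must be strictly increasing with category rank")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "bbox": list(self.bbox),
            "ncols": self.ncols,
            "nrows": self.nrows,
            "buffer_radius_m": self.buffer_radius_m,
            "n_classes": self.n_classes,
            "weights": {c.label: w for c, w in self.weights.items()},
            "end_zero_policy": self.end_zero_policy,
            "tbs_extreme_min": self.tbs_extreme_min,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "StudyConfig":
        kwargs = dict(data)
        if "bbox" in kwargs:
            kwargs["bbox"] = tuple(float(v) for v in kwargs["bbox"])
        if "weights" in kwargs:
            by_label = {c.label: c for c in Category}
            kwargs["weights"] = {
                by_label[str(k)]: int(v) for k, v in kwargs["weights"].items()
            }
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "StudyConfig":
        """Load a YAML (or JSON, a YAML subset) config file."""
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def with_overrides(self, **kwargs) -> "StudyConfig":
        return replace(self, **{k: v for k, v in kwargs.items() if v is not None})
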