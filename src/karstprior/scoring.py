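"""Attribute categorization and weighting.

Each raw attribute maps to one of four ordered categories (Low, Average,
High, Extreme) — or to absence (``NONE``) when the attribute is zero and
nothing in the scheme assigns a zero a class — and each category carries a
weight (default 100 / 250 / 500 / 1000).  A cave's conservation score is the
sum of its four attribute weights, so it ranges over [0, 4000].

Non-troglobite richness is binned by four equal-width intervals over the
dataset's observed range, recomputed per dataset; the remaining three
attributes use fixed small-count bins:

===========  =======  =========  =====  =====
category     weight   TbS        EnD    VuL
===========  =======  =========  =====  =====
Low          100      1–2        0      1
Average      250      3–4        1      2
High         500      5–6        2      3
Extreme      1000     ≥7         ≥3     4–5
===========  =======  =========  =====  =====

A stenoendemic count of zero maps to Low under the default
``table_literal`` policy, or to absence under ``zero``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .config import Category, DEFAULT_WEIGHTS, StudyConfig

ATTRIBUTES = ("nTS", "TbS", "EnD", "VuL")


@dataclass(frozen=True)
class ClassIntervals:
    """Contiguous integer classes over [vmin, vmax].

    Class 1 spans ``[vmin, uppers[0]]`` and class *i* spans
    ``[uppers[i-2] + 1, uppers[i-1]]``; bounds are inclusive.
    """

    vmin: int
    vmax: int
    uppers: tuple[int, ...]

    @property
    def k(self) -> int:
        return len(self.uppers)

    def class_of(self, value: int) -> int:
        """1-based class index of *value*; raises if outside [vmin, vmax]."""
        if not (self.vmin <= value <= self.vmax):
            raise ValueError(
                f"value {value} outside interval range "
                f"[{self.vmin}, {self.vmax}]; rebuild the intervals"
            )
        for i, upper in enumerate(self.uppers, start=1):
            if value <= upper:
                return i
        raise AssertionError("unreachable: uppers end at vmax")


def equal_interval_cutpoints(vmin: int, vmax: int, k: int) -> ClassIntervals:
    """Equal-width integer classes: upper bounds floor(vmin + i*(vmax-vmin)/k).

    Requires ``vmax - vmin >= k - 1`` so every class contains at least one
    integer; the classes then partition [vmin, vmax] ∩ Z with no gaps or
    overlaps.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if vmax <= vmin:
        raise ValueError(f"need vmax > vmin, got [{vmin}, {vmax}]")
    if vmax - vmin < k - 1:
        raise ValueError(
            f"range [{vmin}, {vmax}] cannot hold {k} non-empty integer classes"
        )
    span = vmax - vmin
    uppers = tuple(math.floor(vmin + i * span / k) for i in range(1, k + 1))
    return ClassIntervals(vmin=vmin, vmax=vmax, uppers=uppers)


# ---------------------------------------------------------------------------
# categorizers
# ---------------------------------------------------------------------------

_RANKED = (Category.LOW, Category.AVERAGE, Category.HIGH, Category.EXTREME)


def categorize_nts(nts: int, intervals: ClassIntervals) -> Category:
    """Non-troglobite richness category by equal-interval membership."""
    if intervals.k != len(_RANKED):
        raise ValueError(f"nTS categorization expects {len(_RANKED)} classes")
    return _RANKED[intervals.class_of(nts) - 1]


def categorize_tbs(tbs: int, extreme_min: int = 7) -> Category:
    """Troglobiont richness category: 0 is absence, >=extreme_min is Extreme."""
    if tbs < 0:
        raise ValueError("TbS must be non-negative")
    if tbs == 0:
        return Category.NONE
    if tbs >= extreme_min:
        return Category.EXTREME
    if tbs <= 2:
        return Category.LOW
    if tbs <= 4:
        return Category.AVERAGE
    return Category.HIGH


def categorize_end(end: int, policy: str = "table_literal") -> Category:
    """Stenoendemic-count category; zero handling is policy-dependent."""
    if end < 0:
        raise ValueError("EnD must be non-negative")
    if end == 0:
        return Category.NONE if policy == "zero" else Category.LOW
    if end == 1:
        return Category.AVERAGE
    if end == 2:
        return Category.HIGH
    return Category.EXTREME


def categorize_vul(vul: int) -> Category:
    """Vulnerability category from the distinct-impact-type count (0..5)."""
    if not 0 <= vul <= 5:
        raise ValueError(f"VuL must be in [0, 5], got {vul}")
    if vul == 0:
        return Category.NONE
    if vul >= 4:
        return Category.EXTREME
    return (Category.LOW, Category.AVERAGE, Category.HIGH)[vul - 1]


def weight_of(category: Category, weights: Mapping[Category, int] | None = None) -> int:
    """Score for a category under the (default Table-style) weight map."""
    table = DEFAULT_WEIGHTS if weights is None else weights
    try:
        return int(table[Category(category)])
    except (KeyError, ValueError) as exc:
        raise ValueError(f"unknown category {category!r}") from exc


# ---------------------------------------------------------------------------
# per-cave score vectors
# ---------------------------------------------------------------------------

def cave_attribute_scores(
    attrs: Mapping[str, int],
    intervals: ClassIntervals,
    config: StudyConfig | None = None,
) -> dict:
    """Categorize and weight one cave's raw attributes.

    *attrs* maps ``nTS/TbS/EnD/VuL`` to raw counts.  Returns a flat dict
    with the raw values, a category and score per attribute, and the total.
    """
    cfg = config or StudyConfig()
    cats = {
        "nTS": categorize_nts(int(attrs["nTS"]), intervals),
        "TbS": categorize_tbs(int(attrs["TbS"]), cfg.tbs_extreme_min),
        "EnD": categorize_end(int(attrs["EnD"]), cfg.end_zero_policy),
        "VuL": categorize_vul(int(attrs["VuL"])),
    }
    out: dict = {name: int(attrs[name]) for name in ATTRIBUTES}
    if "cave_id" in attrs:
        out["cave_id"] = attrs["cave_id"]
    total = 0
    for name in ATTRIBUTES:
        score = weight_of(cats[name], cfg.weights)
        out[f"{name}_category"] = cats[name].label
        out[f"{name}_score"] = score
        total += score
    out["total"] = total
    return out


def score_table(
    attrs: pd.DataFrame,
    config: StudyConfig | None = None,
    intervals: ClassIntervals | None = None,
) -> tuple[pd.DataFrame, ClassIntervals]:
    """Score every cave in an attribute table.

    The nTS intervals are built from the observed min/max of the dataset
    unless supplied.  Returns the score table and the intervals used.
    """
    if intervals is None:
        intervals = equal_interval_cutpoints(
            int(attrs["nTS"].min()), int(attrs["nTS"].max()), 4
        )
    rows = [
        cave_attribute_scores(row, intervals, config)
        for row in attrs.to_dict("records")
    ]
    columns = ["cave_id"] + [
        c for name in ATTRIBUTES for c in (name, f"{name}_category", f"{name}_score")
    ] + ["total"]
    return pd.DataFrame(rows)[columns], intervals
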