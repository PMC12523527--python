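"""Per-cave raw conservation attributes.

Four criteria describe each cave:

* **nTS** — non-troglobite species richness: distinct surface-connected
  species recorded in the cave.
* **TbS** — troglobiont richness: distinct cave-restricted species.
* **EnD** — stenoendemic count: troglobiont species whose only known
  occurrence in the whole dataset is this cave.
* **VuL** — vulnerability: number of distinct anthropogenic impact types
  with at least one site within a buffer (default 250 m, boundary
  inclusive) of the cave entrance.

Distances are planar Euclidean; only recorded impact sites contribute to
VuL — the cave itself never does.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


class UnknownCaveError(KeyError):
    """A cave_id was requested that the dataset does not contain."""


def _check_cave(occ: pd.DataFrame, cave_id: str) -> None:
    if cave_id not in set(occ["cave_id"]):
        raise UnknownCaveError(f"cave_id {cave_id!r} not present in occurrence table")


def non_troglobite_richness(occ: pd.DataFrame, cave_id: str) -> int:
    """Distinct non-troglobiont species recorded in *cave_id*."""
    _check_cave(occ, cave_id)
    sub = occ[(occ["cave_id"] == cave_id) & ~occ["troglobiont"]]
    return int(sub["species_id"].nunique())


def troglobite_richness(occ: pd.DataFrame, cave_id: str) -> int:
    """Distinct troglobiont species recorded in *cave_id*."""
    _check_cave(occ, cave_id)
    sub = occ[(occ["cave_id"] == cave_id) & occ["troglobiont"]]
    return int(sub["species_id"].nunique())


def stenoendemic_count(occ: pd.DataFrame, cave_id: str) -> int:
    """Troglobiont species whose only occurrence in the dataset is *cave_id*."""
    _check_cave(occ, cave_id)
    trog = occ[occ["troglobiont"]]
    caves_per_species = trog.groupby("species_id")["cave_id"].nunique()
    singletons = set(caves_per_species[caves_per_species == 1].index)
    here = set(trog.loc[trog["cave_id"] == cave_id, "species_id"])
    return len(here & singletons)


def vulnerability_count(
    cave_x: float,
    cave_y: float,
    impacts: pd.DataFrame,
    radius_m: float = 250.0,
) -> int:
    """Distinct impact types with >=1 site within *radius_m* of the cave.

    The buffer boundary is inclusive (a site exactly at the radius counts).
    """
    if radius_m <= 0:
        raise ValueError("radius_m must be positive")
    if impacts.empty:
        return 0
    dx = impacts["x"].to_numpy(dtype=float) - float(cave_x)
    dy = impacts["y"].to_numpy(dtype=float) - float(cave_y)
    within = np.hypot(dx, dy) <= radius_m
    return int(impacts.loc[within, "impact_type"].nunique())


def attribute_table(
    caves: pd.DataFrame,
    occ: pd.DataFrame,
    impacts: pd.DataFrame,
    radius_m: float = 250.0,
) -> pd.DataFrame:
    """Compute all four raw attributes for every cave in the inventory.

    Returns a DataFrame with columns ``cave_id, nTS, TbS, EnD, VuL`` in the
    cave table's row order.  Caves with no occurrence records get zero
    richness (they were surveyed but yielded nothing).
    """
    trog = occ[occ["troglobiont"]]
    nontrog = occ[~occ["troglobiont"]]

    nts = nontrog.groupby("cave_id")["species_id"].nunique()
    tbs = trog.groupby("cave_id")["species_id"].nunique()

    caves_per_species = trog.groupby("species_id")["cave_id"].nunique()
    singleton_species = set(caves_per_species[caves_per_species == 1].index)
    single = trog[trog["species_id"].isin(singleton_species)]
    end = single.groupby("cave_id")["species_id"].nunique()

    rows = []
    for cave in caves.itertuples(index=False):
        rows.append(
            {
                "cave_id": cave.cave_id,
                "nTS": int(nts.get(cave.cave_id, 0)),
                "TbS": int(tbs.get(cave.cave_id, 0)),
                "EnD": int(end.get(cave.cave_id, 0)),
                "VuL": vulnerability_count(cave.x, cave.y, impacts, radius_m),
            }
        )
    return pd.DataFrame(rows, columns=["cave_id", "nTS", "TbS", "EnD", "VuL"])
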