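"""Raw attribute computations checked against hand enumeration and brute force."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from karstprior import (
    attribute_table,
    non_troglobite_richness,
    stenoendemic_count,
    troglobite_richness,
    vulnerability_count,
)
from karstprior.attributes import UnknownCaveError

from conftest import TOY_TRUTH


def _impacts(rows):
    return pd.DataFrame(rows, columns=["impact_type", "x", "y"])


class TestRichnessCounts:
    def test_toy_table_matches_hand_enumeration(self, toy_occurrences):
        for cave, (nts, tbs, end) in TOY_TRUTH.items():
            assert non_troglobite_richness(toy_occurrences, cave) == nts
            assert troglobite_richness(toy_occurrences, cave) == tbs
            assert stenoendemic_count(toy_occurrences, cave) == end

    def test_unknown_cave_raises(self, toy_occurrences):
        for fn in (non_troglobite_richness, troglobite_richness, stenoendemic_count):
            with pytest.raises(UnknownCaveError):
                fn(toy_occurrences, "nope")

    def test_stenoendemic_definition(self):
        occ = pd.DataFrame(
            [("C1", "s1", True), ("C1", "s2", True), ("C2", "s2", True)],
            columns=["cave_id", "species_id", "troglobiont"],
        )
        assert stenoendemic_count(occ, "C1") == 1  # s1 known only from C1
        assert stenoendemic_count(occ, "C2") == 0

    def test_partition_invariants_on_synthetic(self, default_dataset):
        """EnD <= TbS <= distinct species; nTS + TbS = distinct species per cave."""
        occ = default_dataset.occurrences
        attrs = attribute_table(
            default_dataset.caves, occ, default_dataset.impacts
        )
        totals = occ.groupby("cave_id")["species_id"].nunique()
        for row in attrs.itertuples(index=False):
            assert row.EnD <= row.TbS <= totals[row.cave_id]
            assert row.nTS + row.TbS == totals[row.cave_id]

    def test_stenoendemic_against_brute_force_species_scan(self, default_dataset):
        """A species is stenoendemic iff its whole-table cave count is 1."""
        occ = default_dataset.occurrences
        trog = occ[occ["troglobiont"]]
        expected_total = 0
        for species in trog["species_id"].unique():
            caves = trog.loc[trog["species_id"] == species, "cave_id"].unique()
            if len(caves) == 1:
                expected_total += 1
        attrs = attribute_table(
            default_dataset.caves, occ, default_dataset.impacts
        )
        assert attrs["EnD"].sum() == expected_total


class TestVulnerability:
    def test_boundary_inclusive_distance(self):
        impacts = _impacts([("mining", 100, 0), ("pasture", 300, 0)])
        assert vulnerability_count(0, 0, impacts, 250) == 1
        assert vulnerability_count(0, 0, impacts, 300) == 2  # boundary included

    def test_counts_types_not_sites(self):
        impacts = _impacts([("mining", 10, 0), ("mining", 20, 0)])
        assert vulnerability_count(0, 0, impacts, 250) == 1

    def test_four_types_at_249(self):
        impacts = _impacts(
            [(t, 249, 0) for t in
             ("mining", "pasture", "urbanization", "paved_road")]
        )
        assert vulnerability_count(0, 0, impacts, 250) == 4

    def test_empty_impacts_give_zero(self):
        assert vulnerability_count(0, 0, _impacts([]), 250) == 0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        radii=st.tuples(
            st.floats(1, 1000), st.floats(1, 1000)
        ),
        seed=st.integers(0, 2**16),
    )
    def test_monotone_in_radius(self, radii, seed):
        rng = np.random.default_rng(seed)
        types = ["mining", "pasture", "urbanization", "paved_road",
                 "agriculture_forestry"]
        impacts = _impacts(
            [(types[int(rng.integers(5))],
              float(rng.uniform(-800, 800)), float(rng.uniform(-800, 800)))
             for _ in range(12)]
        )
        r1, r2 = sorted(radii)
        assert vulnerability_count(0, 0, impacts, r1) <= vulnerability_count(
            0, 0, impacts, r2
        )
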