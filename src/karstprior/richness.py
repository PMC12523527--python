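"""First-order jackknife richness estimation and survey completeness.

The incidence-based first-order jackknife (Burnham & Overton) corrects the
observed species count for species so rare they were seen in a single
sampling unit:

    S_jack1 = S_obs + Q1 * (n - 1) / n

where Q1 is the number of species occurring in exactly one unit (here, one
cave) and n is the number of units surveyed.  Survey completeness is the
ratio S_obs / S_jack1 in (0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class RichnessSummary:
    S_obs: int
    Q1: int
    n: int
    S_jack1: float
    completeness: float

    def to_dict(self) -> dict:
        return {
            "S_obs": self.S_obs,
            "Q1": self.Q1,
            "n": self.n,
            "S_jack1": self.S_jack1,
            "completeness": self.completeness,
        }


def singleton_count(occ: pd.DataFrame, troglobionts_only: bool = True) -> int:
    """Number of species recorded in exactly one cave (Q1)."""
    if occ.empty:
        raise ValueError("occurrence table is empty")
    sub = occ[occ["troglobiont"]] if troglobionts_only else occ
    caves_per_species = sub.groupby("species_id")["cave_id"].nunique()
    return int((caves_per_species == 1).sum())


def jackknife1(s_obs: int, q1: int, n: int) -> float:
    """First-order jackknife estimate of total richness."""
    if n < 1:
        raise ValueError("need at least one sampling unit")
    if not 0 <= q1 <= s_obs:
        raise ValueError(f"require 0 <= Q1 <= S_obs, got Q1={q1}, S_obs={s_obs}")
    return s_obs + q1 * (n - 1) / n


def completeness(s_obs: int, s_jack1: float) -> float:
    """Observed / estimated richness, in (0, 1]."""
    if s_jack1 <= 0:
        raise ValueError("estimated richness must be positive")
    if not 0 < s_obs <= s_jack1:
        raise ValueError(
            f"require 0 < S_obs <= S_jack1, got S_obs={s_obs}, S_jack1={s_jack1}"
        )
    return s_obs / s_jack1


def richness_summary(
    occ: pd.DataFrame, n_caves: int, troglobionts_only: bool = True
) -> RichnessSummary:
    """Full completeness block for an assemblage.

    *n_caves* is the number of inventoried caves (the sampling units),
    which may exceed the number of caves with records.
    """
    sub = occ[occ["troglobiont"]] if troglobionts_only else occ
    s_obs = int(sub["species_id"].nunique())
    q1 = singleton_count(occ, troglobionts_only)
    s_jack = jackknife1(s_obs, q1, n_caves)
    return RichnessSummary(
        S_obs=s_obs,
        Q1=q1,
        n=n_caves,
        S_jack1=s_jack,
        completeness=completeness(s_obs, s_jack),
    )
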