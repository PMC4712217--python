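"""Packaged reference tables from the adolescent aggression/anxiety study.

Two summary tables from the published two-cohort study (n = 923
early-to-middle and n = 390 middle-to-late adolescents, five annual waves)
are shipped as CSV transcriptions:

* ``table1`` -- class sizes (counts and percentages) of the four
  aggression/anxiety types (GAD, DA, C-DA, Np) per wave, for the whole-sample
  partitions into cohorts, sexes and friendship-quality groups;
* ``table4`` -- model-based 4-year transition probabilities between the four
  types, per subgroup.

Three printed cells of the class-size table are internally inconsistent
(counts not summing to the subgroup size, or percent not matching
count/n). They were corrected using the marginal cross-checks that the three
subgroup partitions of the same sample must agree on wave totals; the
corrections are noted in the repository methods note. Percentages are
validated against counts at +-0.1 on load.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: the four aggression/anxiety types, in canonical order
TYPES = ["GAD", "DA", "C-DA", "Np"]

#: subgroup labels with their sample sizes
SUBGROUP_N = {
    "early_to_middle": 923,
    "middle_to_late": 390,
    "males": 637,
    "females": 676,
    "higher_quality": 1045,
    "poorer_quality": 268,
}

#: tolerance for a printed transition row summing to one (printed rounding)
ROW_SUM_TOL = 0.02


class FixtureError(KeyError):
    """Unknown fixture id or malformed packaged table."""


def _read(name: str) -> pd.DataFrame:
    ref = importlib.resources.files("panelmix.fixtures").joinpath(name)
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


@dataclass(frozen=True)
class ClassSizeTable:
    """Class sizes per subgroup x wave x type."""

    df: pd.DataFrame

    def n(self, subgroup: str) -> int:
        return SUBGROUP_N[subgroup]

    def count(self, subgroup: str, wave: int, type_: str) -> int:
        sel = self.df[
            (self.df.subgroup == subgroup) & (self.df.wave == wave) & (self.df.type == type_)
        ]
        if sel.empty:
            raise FixtureError(f"no cell ({subgroup}, wave {wave}, {type_})")
        return int(sel["count"].iloc[0])

    def percent(self, subgroup: str, wave: int, type_: str) -> float:
        sel = self.df[
            (self.df.subgroup == subgroup) & (self.df.wave == wave) & (self.df.type == type_)
        ]
        if sel.empty:
            raise FixtureError(f"no cell ({subgroup}, wave {wave}, {type_})")
        return float(sel["percent"].iloc[0])

    def counts_vector(self, subgroup: str, wave: int) -> np.ndarray:
        """Counts over the four types, in :data:`TYPES` order."""
        return np.array([self.count(subgroup, wave, t) for t in TYPES], dtype=float)

    def shares_vector(self, subgroup: str, wave: int) -> np.ndarray:
        v = self.counts_vector(subgroup, wave)
        return v / v.sum()


@dataclass(frozen=True)
class TransitionTable:
    """4-year transition probabilities per subgroup (rows = origin type)."""

    df: pd.DataFrame

    def prob(self, subgroup: str, from_type: str, to_type: str) -> float:
        sel = self.df[
            (self.df.subgroup == subgroup)
            & (self.df.from_type == from_type)
            & (self.df.to_type == to_type)
        ]
        if sel.empty:
            raise FixtureError(f"no cell ({subgroup}, {from_type} -> {to_type})")
        return float(sel["prob"].iloc[0])

    def matrix(self, subgroup: str) -> np.ndarray:
        """4x4 row-stochastic (within printed rounding) matrix in TYPES order."""
        return np.array(
            [[self.prob(subgroup, f, t) for t in TYPES] for f in TYPES], dtype=float
        )

    def row(self, subgroup: str, from_type: str) -> np.ndarray:
        return np.array([self.prob(subgroup, from_type, t) for t in TYPES], dtype=float)


def _validate_class_sizes(df: pd.DataFrame) -> None:
    for (sub, wave), grp in df.groupby(["subgroup", "wave"]):
        n = SUBGROUP_N[sub]
        total = grp["count"].sum()
        if total != n:
            raise FixtureError(f"{sub} wave {wave}: counts sum to {total}, expected {n}")
        recomputed = 100.0 * grp["count"] / n
        if (np.abs(recomputed - grp["percent"]) > 0.1 + 1e-9).any():
            raise FixtureError(f"{sub} wave {wave}: percent inconsistent with count/n")


def _validate_transitions(df: pd.DataFrame) -> None:
    for (sub, frm), grp in df.groupby(["subgroup", "from_type"]):
        s = grp["prob"].sum()
        if abs(s - 1.0) > ROW_SUM_TOL + 1e-12:
            raise FixtureError(f"{sub} row {frm}: probabilities sum to {s:.3f}")


def load_class_sizes() -> ClassSizeTable:
    df = _read("table1_class_sizes.csv")
    _validate_class_sizes(df)
    return ClassSizeTable(df)


def load_transitions() -> TransitionTable:
    df = _read("table4_transitions.csv")
    _validate_transitions(df)
    return TransitionTable(df)


def load_fixture(table_id: str):
    """Load a packaged table by id (``"table1"`` or ``"table4"``)."""
    if table_id == "table1":
        return load_class_sizes()
    if table_id == "table4":
        return load_transitions()
    raise FixtureError(f"unknown fixture id {table_id!r}; expected 'table1' or 'table4'")
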