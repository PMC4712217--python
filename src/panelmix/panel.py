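"""Long-format panel data container with explicit missingness tracking.

The panel holds subject-by-wave observations for a two-cohort accelerated
longitudinal design: an anxiety scale score (0--2), a direct-aggression scale
score (1--4) and three best-friendship dimensions (support, negative
interaction, power; each 1--5), together with time-invariant covariates
(cohort, sex, and -- once assigned -- a binary friendship-quality class).

An explicit boolean *observed* mask is carried alongside the values so that
cells filled in by imputation remain distinguishable from genuinely observed
cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: measurement columns, in canonical CSV order
MEASURE_COLS = ["anx", "agg", "sup", "neg", "pow"]

#: admissible closed ranges of the scale scores
RANGES = {
    "anx": (0.0, 2.0),
    "agg": (1.0, 4.0),
    "sup": (1.0, 5.0),
    "neg": (1.0, 5.0),
    "pow": (1.0, 5.0),
}

CSV_COLUMNS = ["subject_id", "cohort", "sex", "wave"] + MEASURE_COLS

WAVES = (1, 2, 3, 4, 5)


class PanelError(ValueError):
    """Base class for panel I/O and validation problems."""


class PanelParseError(PanelError):
    """Raised when a CSV cannot be parsed into the documented schema."""


class PanelValidationError(PanelError):
    """Raised when parsed rows violate the panel invariants.

    Attributes
    ----------
    diagnostics : list of (row_index, message)
        One entry per offending row (0-based data-row index, i.e. not
        counting the header line).
    """

    def __init__(self, diagnostics):
        self.diagnostics = list(diagnostics)
        lines = "; ".join(f"row {i}: {m}" for i, m in self.diagnostics[:20])
        extra = "" if len(self.diagnostics) <= 20 else f" (+{len(self.diagnostics) - 20} more)"
        super().__init__(f"panel validation failed: {lines}{extra}")


@dataclass
class PanelDataset:
    """Validated long-format panel.

    Parameters
    ----------
    data : pandas.DataFrame
        Columns ``subject_id, cohort, sex, wave`` plus :data:`MEASURE_COLS`
        and optionally ``friendship_class``. One row per (subject, wave).
    observed : pandas.DataFrame
        Boolean frame, same index as ``data``, one column per measure;
        ``True`` where the value was observed (as opposed to imputed).
    """

    data: pd.DataFrame
    observed: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.observed is None:
            self.observed = self.data[MEASURE_COLS].notna()
        diags = validate_panel_frame(self.data)
        if diags:
            raise PanelValidationError(diags)
        self.data = self.data.reset_index(drop=True)
        self.observed = self.observed.reset_index(drop=True)

    # ------------------------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.data["subject_id"].nunique()

    @property
    def n_obs(self) -> int:
        return len(self.data)

    @property
    def has_friendship_class(self) -> bool:
        return "friendship_class" in self.data.columns

    def subjects(self) -> pd.DataFrame:
        """One row per subject with its time-invariant covariates."""
        cols = ["subject_id", "cohort", "sex"]
        if self.has_friendship_class:
            cols.append("friendship_class")
        return (
            self.data[cols].drop_duplicates("subject_id").set_index("subject_id").sort_index()
        )

    def wide(self, variables, waves=WAVES) -> pd.DataFrame:
        """Pivot to one row per subject, one column per (variable, wave).

        Column labels are ``f"{var}_w{wave}"``; cells missing in the long
        frame (including absent rows) become NaN.
        """
        out = {}
        pivots = {
            v: self.data.pivot(index="subject_id", columns="wave", values=v) for v in variables
        }
        index = self.data["subject_id"].drop_duplicates().sort_values()
        for v in variables:
            piv = pivots[v].reindex(index)
            for w in waves:
                out[f"{v}_w{w}"] = piv[w] if w in piv.columns else np.full(len(index), np.nan)
        return pd.DataFrame(out, index=pd.Index(index, name="subject_id"))

    def wave_frame(self, wave: int) -> pd.DataFrame:
        return self.data[self.data["wave"] == wave].set_index("subject_id")

    def with_friendship_class(self, assignment: pd.Series) -> "PanelDataset":
        """Return a copy with a subject-level 0/1 friendship class attached."""
        data = self.data.copy()
        data["friendship_class"] = (
            data["subject_id"].map(assignment).astype("float").astype("Int64")
        )
        return PanelDataset(data, self.observed.copy())

    def copy(self) -> "PanelDataset":
        return PanelDataset(self.data.copy(), self.observed.copy())


def validate_panel_frame(df: pd.DataFrame):
    """Return a list of (row_index, message) diagnostics; empty if valid."""
    diags = []
    missing_cols = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing_cols:
        return [(-1, f"missing required columns: {missing_cols}")]

    dup = df.duplicated(subset=["subject_id", "wave"], keep=False)
    for i in df.index[dup]:
        diags.append((int(i), "duplicated (subject_id, wave) pair"))

    bad_wave = ~df["wave"].isin(WAVES)
    for i in df.index[bad_wave]:
        diags.append((int(i), f"wave {df.at[i, 'wave']!r} outside 1..5"))

    for col in ("cohort", "sex"):
        bad = ~df[col].isin([0, 1])
        for i in df.index[bad]:
            diags.append((int(i), f"{col} {df.at[i, col]!r} not binary"))

    for v, (lo, hi) in RANGES.items():
        vals = pd.to_numeric(df[v], errors="coerce")
        bad = vals.notna() & ((vals < lo) | (vals > hi))
        for i in df.index[bad]:
            diags.append((int(i), f"{v} = {df.at[i, v]} outside range [{lo}, {hi}]"))

    # cohort and sex constant within subject
    for col in ("cohort", "sex"):
        nun = df.groupby("subject_id")[col].nunique()
        for sid in nun.index[nun > 1]:
            i = int(df.index[df["subject_id"] == sid][0])
            diags.append((i, f"{col} not constant within subject {sid!r}"))

    return sorted(set(diags))


def load_panel(path) -> PanelDataset:
    """Read a panel CSV (schema ``subject_id,cohort,sex,wave,anx,agg,sup,neg,pow``).

    Missing cells are empty fields. Rows violating the range or uniqueness
    invariants raise :class:`PanelValidationError` with row-indexed
    diagnostics; malformed CSV raises :class:`PanelParseError`.
    """
    try:
        df = pd.read_csv(path, skip_blank_lines=True)
    except (pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise PanelParseError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise PanelParseError(f"{path}: header lacks required columns {missing}")
    for v in MEASURE_COLS:
        bad = pd.to_numeric(df[v], errors="coerce").isna() & df[v].notna()
        if bad.any():
            i = int(df.index[bad][0])
            raise PanelParseError(
                f"{path}: non-numeric value {df.at[i, v]!r} in column {v} at data row {i} "
                f"(file line {i + 2})"
            )
        df[v] = pd.to_numeric(df[v], errors="coerce")
    return PanelDataset(df)


def save_panel(panel: PanelDataset, path) -> None:
    """Write the panel in the canonical CSV schema (missing cells empty).

    Only observed/imputed *values* are written; the observed mask itself is
    not part of the interchange format, so a round trip through CSV marks
    previously imputed cells as observed.
    """
    cols = list(CSV_COLUMNS)
    if panel.has_friendship_class:
        cols.append("friendship_class")
    panel.data.to_csv(path, index=False, columns=cols)
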