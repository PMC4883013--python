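"""Shared domain types.

Errors raised across the package distinguish format problems
(:class:`FormatError`), inputs that are well-formed but too small or
degenerate to analyse (:class:`InsufficientDataError`), and statistics
whose value is undefined for the given data
(:class:`UndefinedResultError`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ZYGOSITIES = ("MZ", "DZ")
SEXES = ("F", "M")


class FormatError(ValueError):
    """The input file or table does not match the expected layout."""


class InsufficientDataError(ValueError):
    """Too few complete observations to carry out the analysis."""


class UndefinedResultError(ValueError):
    """The requested statistic has no defined value for this input."""


class ConvergenceError(RuntimeError):
    """The likelihood optimiser failed to converge after restarts."""


@dataclass
class MeasurementTable:
    """Subjects x raters matrix of volumes for a single region.

    ``values[i, j]`` is the volume (mm^3) of subject ``subject_ids[i]``
    measured by rater/session/platform/version ``rater_labels[j]``.
    """

    region_name: str
    rater_labels: list[str]
    values: np.ndarray
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FormatError("values must be a 2-D subjects x raters matrix")
        if self.values.shape[1] < 2:
            raise FormatError("a measurement table needs at least 2 rater columns")
        if self.values.shape[1] != len(self.rater_labels):
            raise FormatError("rater_labels length must match number of columns")
        if self.values.shape[0] != len(self.subject_ids):
            raise FormatError("subject_ids length must match number of rows")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("all measurements must be finite")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_raters(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.subject_ids, name="subject_id"),
            columns=self.rater_labels,
        )


@dataclass
class Pedigree:
    """A validated collection of twin pairs.

    Wraps a DataFrame with columns ``individual_id``, ``family_id``,
    ``zygosity`` (MZ/DZ), ``sex`` (F/M) and ``age`` (years).  Every
    family must consist of exactly two members sharing one zygosity
    code; this is the twin-pair design the variance-components model
    assumes.
    """

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ("individual_id", "family_id", "zygosity", "sex", "age")

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise FormatError(f"pedigree is missing columns: {missing}")
        df = df.copy()
        df["individual_id"] = df["individual_id"].astype(str)
        df["family_id"] = df["family_id"].astype(str)
        df["zygosity"] = df["zygosity"].astype(str)
        df["sex"] = df["sex"].astype(str)
        df["age"] = df["age"].astype(float)

        bad_zyg = df.loc[~df["zygosity"].isin(ZYGOSITIES)]
        if len(bad_zyg):
            rows = bad_zyg["individual_id"].tolist()
            raise FormatError(
                f"unknown zygosity code(s) {sorted(set(bad_zyg['zygosity']))} "
                f"for individual(s) {rows}; expected one of {ZYGOSITIES}"
            )
        bad_sex = df.loc[~df["sex"].isin(SEXES)]
        if len(bad_sex):
            raise FormatError(
                f"unknown sex code(s) {sorted(set(bad_sex['sex']))}; "
                f"expected one of {SEXES}"
            )
        if (df["age"] < 0).any():
            raise FormatError("ages must be non-negative")
        if df["individual_id"].duplicated().any():
            dup = df.loc[df["individual_id"].duplicated(), "individual_id"].tolist()
            raise FormatError(f"duplicate individual_id(s): {dup}")

        sizes = df.groupby("family_id").size()
        bad = sizes[sizes != 2]
        if len(bad):
            raise FormatError(
                f"families must have exactly 2 members (twin-pair design); "
                f"offending family_id(s): {bad.index.tolist()}"
            )
        nzyg = df.groupby("family_id")["zygosity"].nunique()
        mixed = nzyg[nzyg != 1]
        if len(mixed):
            raise FormatError(
                f"both members of a family must share one zygosity; "
                f"offending family_id(s): {mixed.index.tolist()}"
            )
        self.table = df.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return len(self.table)

    @property
    def n_families(self) -> int:
        return self.table["family_id"].nunique()

    @property
    def individual_ids(self) -> list[str]:
        return self.table["individual_id"].tolist()

    def families(self):
        """Yield (family_id, sub-frame) in first-appearance order."""
        return self.table.groupby("family_id", sort=False)


@dataclass
class LabelVolume:
    """3-D integer label grid with voxel dimensions and a label dictionary.

    Label 0 is reserved for background.
    """

    grid: np.ndarray
    voxel_size: tuple[float, float, float]
    label_map: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise FormatError("label grid must be 3-D")
        if not np.issubdtype(self.grid.dtype, np.integer):
            raise FormatError("label grid must hold integers")
        if (self.grid < 0).any():
            raise FormatError("labels must be non-negative")
        if min(self.grid.shape) < 1:
            raise FormatError("grid dimensions must be >= 1 in each axis")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise FormatError("voxel_size must be three strictly positive extents")

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.voxel_size
        return dx * dy * dz

    def labels_present(self) -> list[int]:
        """Foreground labels present in the grid, sorted."""
        vals = np.unique(self.grid)
        return [int(v) for v in vals if v != 0]


@dataclass
class ReliabilityResult:
    """Cronbach's-alpha ICC for one region with its confidence interval."""

    region: str
    icc: float
    ci_lower: float
    ci_upper: float
    n_subjects: int
    n_raters: int

    def __post_init__(self) -> None:
        if np.isfinite(self.icc) and self.icc > 1 + 1e-12:
            raise UndefinedResultError("ICC cannot exceed 1")


@dataclass
class DiceResult:
    """Dice similarity coefficient for one label.

    ``dsc`` is NaN when the label is absent from both volumes (0/0 is
    undefined, not 0 or 1).
    """

    label: str
    dsc: float
    voxels_a: int
    voxels_b: int
    voxels_intersect: int

    @property
    def undefined(self) -> bool:
        return not np.isfinite(self.dsc)
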