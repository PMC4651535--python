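"""Census and trait table I/O, plot windows, and the abundance-based species filter.

A census is a stem map: one row per free-standing woody plant with plot id,
x/y coordinates in metres (origin at the plot's lower-left corner), species
code, DBH in centimetres and height in metres.  Plots are rectangular
observation windows.  Species-poor taxa are excluded before pairwise
analysis: a species enters the analysis only if it exceeds a minimum
abundance in enough replicate plots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "Window",
    "CensusTable",
    "TraitTable",
    "SchemaError",
    "CensusParseError",
    "DEFAULT_SCHEMA",
    "read_census",
    "read_traits",
    "write_census",
    "filter_species",
    "FilterResult",
]

CENSUS_COLUMNS = ["plot_id", "tree_id", "species", "x", "y", "dbh", "height"]
TRAIT_COLUMNS = ["species", "life_form", "shade_tolerance", "dispersal"]

#: identity column mapping for census files already in the canonical layout
DEFAULT_SCHEMA = {c: c for c in CENSUS_COLUMNS}


class SchemaError(ValueError):
    """A required column is absent from the input file."""


class CensusParseError(ValueError):
    """A census row failed validation; the message names the offending row."""


@dataclass(frozen=True)
class Window:
    """Rectangular plot window, lower-left corner at the origin.

    Parameters
    ----------
    width, height : float
        Side lengths in metres; must be positive.
    """

    width: float
    height: float

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise ValueError(f"window sides must be positive, got {self.width}x{self.height}")

    @property
    def area(self) -> float:
        """Plot area A in square metres."""
        return self.width * self.height

    def contains(self, x, y) -> bool:
        return bool((0 <= x) and (x <= self.width) and (0 <= y) and (y <= self.height))


@dataclass
class CensusTable:
    """Validated stem map: a DataFrame in canonical columns plus per-plot windows."""

    data: pd.DataFrame
    windows: dict[str, Window]

    def __post_init__(self) -> None:
        missing = [c for c in CENSUS_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"census missing columns: {missing}")

    @property
    def plots(self) -> list[str]:
        return sorted(self.windows)

    @property
    def species(self) -> list[str]:
        return sorted(self.data["species"].unique())

    def plot(self, plot_id: str) -> pd.DataFrame:
        return self.data[self.data["plot_id"] == plot_id]

    def counts(self) -> pd.DataFrame:
        """Species-by-plot abundance table (rows: species, columns: plot ids)."""
        tab = (
            self.data.groupby(["species", "plot_id"]).size().unstack(fill_value=0)
        )
        return tab.reindex(columns=self.plots, fill_value=0)

    def subset_species(self, species: list[str]) -> "CensusTable":
        keep = self.data[self.data["species"].isin(species)].reset_index(drop=True)
        return CensusTable(keep, dict(self.windows))


@dataclass
class TraitTable:
    """Per-species categorical traits (life form, shade tolerance, dispersal, habitat)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in TRAIT_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"trait table missing columns: {missing}")
        if self.data["species"].duplicated().any():
            dup = self.data.loc[self.data["species"].duplicated(), "species"].tolist()
            raise ValueError(f"duplicate trait rows for species: {dup}")
        self.data = self.data.set_index("species", drop=False)

    def get(self, species: str, trait: str):
        """Trait value, or None when the species or the value is missing."""
        if species not in self.data.index:
            return None
        val = self.data.loc[species, trait]
        return None if pd.isna(val) else val


def _to_window(window: Window | tuple[float, float]) -> Window:
    return window if isinstance(window, Window) else Window(*window)


def read_census(
    path,
    window: Window | tuple[float, float] | dict[str, Window],
    schema: dict[str, str] | None = None,
) -> CensusTable:
    """Read a delimited census file into a validated :class:`CensusTable`.

    Parameters
    ----------
    path : str or file-like
        Comma-separated text with a header row.
    window : Window or (width, height) or {plot_id: Window}
        Observation window; a single window is applied to every plot.
    schema : dict, optional
        Mapping from canonical column names to the file's column names,
        e.g. ``{"x": "gx", "y": "gy"}``.  Unmapped names fall back to the
        canonical spelling.

    Raises
    ------
    SchemaError
        If a mapped column is absent.
    CensusParseError
        If a coordinate or DBH fails to parse or a stem lies outside its window.
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    raw = pd.read_csv(path, dtype=str)
    missing = [src for src in schema.values() if src not in raw.columns]
    if missing:
        raise SchemaError(f"input file lacks columns {missing}; available: {list(raw.columns)}")
    df = pd.DataFrame({canon: raw[src] for canon, src in schema.items()})

    for col in ("x", "y", "dbh", "height"):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise CensusParseError(
                f"non-numeric value {df.loc[row, col]!r} in column {col!r} at row {row}"
            )
        df[col] = converted

    if isinstance(window, dict):
        windows = {str(k): _to_window(v) for k, v in window.items()}
    else:
        win = _to_window(window)
        windows = {str(p): win for p in df["plot_id"].unique()}

    for idx, row in df.iterrows():
        win = windows.get(str(row["plot_id"]))
        if win is None:
            raise CensusParseError(f"row {idx}: plot {row['plot_id']!r} has no declared window")
        if not win.contains(row["x"], row["y"]):
            raise CensusParseError(
                f"row {idx}: stem {row['tree_id']!r} at ({row['x']}, {row['y']}) "
                f"falls outside the {win.width}x{win.height} m window of plot {row['plot_id']!r}"
            )
        if not row["dbh"] > 0:
            raise CensusParseError(f"row {idx}: dbh must be positive, got {row['dbh']}")

    for plot_id, grp in df.groupby("plot_id"):
        if grp["tree_id"].duplicated().any():
            dup = grp.loc[grp["tree_id"].duplicated(), "tree_id"].iloc[0]
            raise CensusParseError(f"duplicate tree_id {dup!r} in plot {plot_id!r}")

    df["plot_id"] = df["plot_id"].astype(str)
    return CensusTable(df.reset_index(drop=True), windows)


def write_census(census: CensusTable, path) -> None:
    census.data.to_csv(path, index=False, columns=CENSUS_COLUMNS)


def read_traits(path) -> TraitTable:
    """Read a species-trait CSV (species, life_form, shade_tolerance, dispersal[, habitat])."""
    df = pd.read_csv(path, dtype=str)
    if "habitat" not in df.columns:
        df["habitat"] = pd.NA
    return TraitTable(df)


@dataclass
class FilterResult:
    """Outcome of the abundance filter.

    ``included`` lists species passing the rule; ``usable`` maps each included
    species to the plots where its count clears the threshold (other plots are
    dropped from that species' replicate analysis); ``counts`` is the full
    species-by-plot abundance table.
    """

    included: list[str]
    usable: dict[str, list[str]] = field(default_factory=dict)
    counts: pd.DataFrame | None = None

    @property
    def coverage(self) -> float:
        """Fraction of all individuals belonging to included species."""
        if self.counts is None or self.counts.values.sum() == 0:
            return 0.0
        total = self.counts.values.sum()
        kept = self.counts.loc[self.counts.index.isin(self.included)].values.sum()
        return kept / total


def filter_species(census: CensusTable, min_n: int = 60, min_plots: int | None = None) -> FilterResult:
    """Apply the abundance inclusion rule.

    A species is included when it has strictly more than ``min_n`` individuals
    in at least ``min_plots`` plots.  For an included species, any plot where
    its count is at or below ``min_n`` is flagged unusable and excluded from
    that species' replicate analysis.

    ``min_plots`` defaults to 2 for multi-plot censuses and 1 for a single plot.
    """
    if min_n < 1:
        raise ValueError("min_n must be >= 1")
    if len(census.data) == 0:
        return FilterResult(included=[], usable={}, counts=census.counts())
    if min_plots is None:
        min_plots = 2 if len(census.windows) >= 2 else 1
    counts = census.counts()
    passing = counts > min_n
    included = sorted(counts.index[passing.sum(axis=1) >= min_plots])
    usable = {
        sp: [p for p in counts.columns if passing.loc[sp, p]] for sp in included
    }
    return FilterResult(included=included, usable=usable, counts=counts)
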