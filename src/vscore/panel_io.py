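"""Reading, validation and writing of the tabular inputs and outputs.

The place panel is a tract × year table of area characteristics: *rate*
variables (events per 1000 residents, nonnegative, often zero-inflated) and
*proportion* variables (fractions in [0, 1]). Some variables are unavailable
for whole years; availability is derived from the data itself (a variable is
unavailable in a year when it is missing for every tract that year), so real
extracts need no sidecar metadata.

All delimited files are comma-separated UTF-8 with "." decimals; an empty
field is a missing value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .forest import ForestParams

__all__ = ["PlacePanel", "CohortTable", "RunConfig", "LinkageReport",
           "read_place_panel", "read_cohort", "validate_linkage",
           "write_vscores", "infer_schema"]

log = logging.getLogger("vscore")

_ID_COLS = ["tract_id", "year"]


@dataclass
class PlacePanel:
    """Tract × year rows of place variables plus derived availability flags."""

    data: pd.DataFrame                      # tract_id, year, <variables>
    schema: dict[str, str]                  # variable -> 'rate' | 'proportion'
    availability: pd.DataFrame = None       # bool, index=year, columns=variables
    groups: dict[str, str] | None = None    # variable -> thematic block (optional)

    def __post_init__(self):
        self.validate()

    @property
    def variables(self) -> list[str]:
        return [c for c in self.data.columns if c not in _ID_COLS]

    @property
    def years(self) -> list[int]:
        return sorted(self.data["year"].unique().tolist())

    @property
    def tracts(self) -> list:
        return sorted(self.data["tract_id"].unique().tolist())

    def validate(self):
        df = self.data
        for c in _ID_COLS:
            if c not in df.columns:
                raise ValueError(f"panel is missing required column '{c}'")
        dup = df.duplicated(subset=_ID_COLS)
        if dup.any():
            row = df.loc[dup.idxmax()]
            raise ValueError(
                f"duplicate (tract_id, year) pair: ({row['tract_id']}, "
                f"{row['year']})")
        for v in self.variables:
            if v not in self.schema:
                raise ValueError(f"variable '{v}' has no declared type")
            col = pd.to_numeric(df[v], errors="coerce")
            present = col.notna() & df[v].notna()
            if self.schema[v] == "rate":
                bad = present & (col < 0)
            elif self.schema[v] == "proportion":
                bad = present & ((col < 0) | (col > 1))
            else:
                raise ValueError(f"unknown variable type '{self.schema[v]}'")
            if bad.any():
                i = bad.idxmax()
                raise ValueError(
                    f"variable '{v}' out of range in row {i} "
                    f"(tract {df.loc[i, 'tract_id']}, year {df.loc[i, 'year']}): "
                    f"{df.loc[i, v]!r}")
        if self.availability is None:
            self.availability = derive_availability(df, self.variables)

    def copy(self) -> "PlacePanel":
        return PlacePanel(self.data.copy(), dict(self.schema),
                          self.availability.copy(),
                          dict(self.groups) if self.groups else None)


def derive_availability(df: pd.DataFrame, variables) -> pd.DataFrame:
    """A variable is available in a year iff any tract has a value that year."""
    avail = df.groupby("year")[list(variables)].apply(
        lambda g: g.notna().any())
    avail.index.name = "year"
    return avail.astype(bool)


@dataclass
class CohortTable:
    """Person-visit rows: (person_id, tract_id, year, outcome, weight)."""

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data
        for c in ["person_id", "tract_id", "year", "outcome"]:
            if c not in df.columns:
                raise ValueError(f"cohort is missing required column '{c}'")
        if "weight" not in df.columns:
            df = df.copy()
            df["weight"] = 1.0
            self.data = df
        if len(df):
            out = df["outcome"]
            bad = ~out.isin([0, 1])
            if bad.any():
                raise ValueError(
                    f"outcome not in {{0,1}} at row {bad.idxmax()}: "
                    f"{out[bad.idxmax()]!r}")
            if (df["weight"] <= 0).any() or df["weight"].isna().any():
                i = (~(df["weight"] > 0)).idxmax()
                raise ValueError(f"nonpositive weight at row {i}")

    def __len__(self):
        return len(self.data)

    def copy(self) -> "CohortTable":
        return CohortTable(self.data.copy())


@dataclass
class RunConfig:
    """Run configuration for the scoring pipeline."""

    years: tuple[int, int] | None = None    # inclusive range; None = all in panel
    n_repetitions: int = 10
    max_years_per_person: int = 3
    forest: ForestParams = field(default_factory=ForestParams)
    master_seed: int = 0

    def __post_init__(self):
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")
        if self.max_years_per_person < 1:
            raise ValueError("max_years_per_person must be >= 1")
        if isinstance(self.forest, dict):
            self.forest = ForestParams(**self.forest)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "years" in raw and raw["years"] is not None:
            raw["years"] = tuple(raw["years"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = {"years": list(self.years) if self.years else None,
             "n_repetitions": self.n_repetitions,
             "max_years_per_person": self.max_years_per_person,
             "master_seed": self.master_seed,
             "forest": dict(self.forest.__dict__)}
        return d


@dataclass
class LinkageReport:
    in_sample_tracts: list
    out_of_sample_tracts: list
    orphan_rows: pd.Index
    cell_sizes: pd.Series   # (tract_id, year) -> raw visit count, 0 included

    @property
    def n_in_sample(self) -> int:
        return len(self.in_sample_tracts)

    @property
    def n_out_of_sample(self) -> int:
        return len(self.out_of_sample_tracts)

    @property
    def n_orphans(self) -> int:
        return len(self.orphan_rows)


def infer_schema(df: pd.DataFrame) -> dict[str, str]:
    """Heuristic variable typing: values within [0, 1] -> proportion, else rate."""
    schema = {}
    for v in df.columns:
        if v in _ID_COLS:
            continue
        col = pd.to_numeric(df[v], errors="coerce").dropna()
        schema[v] = "proportion" if (len(col) and col.between(0, 1).all()) else "rate"
    return schema


def read_place_panel(path, schema: Mapping[str, str]) -> PlacePanel:
    """Read and validate a place panel CSV (tract_id, year, variables...)."""
    df = pd.read_csv(path)
    for c in _ID_COLS:
        if c not in df.columns:
            raise ValueError(f"panel file {path} lacks required column '{c}'")
    known = set(_ID_COLS) | set(schema)
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        log.warning("ignoring unknown panel columns: %s", unknown)
        df = df.drop(columns=unknown)
    df["year"] = df["year"].astype(int)
    for v in df.columns:
        if v not in _ID_COLS:
            df[v] = pd.to_numeric(df[v], errors="coerce")
    return PlacePanel(df.reset_index(drop=True), dict(schema))


def read_cohort(path) -> CohortTable:
    """Read and validate a cohort visit CSV; absent weight column -> weight 1."""
    df = pd.read_csv(path)
    for c in ["person_id", "tract_id", "year", "outcome"]:
        if c not in df.columns:
            raise ValueError(f"cohort file {path} lacks required column '{c}'")
    if len(df):
        df["year"] = df["year"].astype(int)
    return CohortTable(df.reset_index(drop=True))


def validate_linkage(panel: PlacePanel, cohort: CohortTable) -> LinkageReport:
    """Report tract coverage and place-by-time cell sizes (no errors raised)."""
    panel_tracts = set(panel.data["tract_id"])
    cohort_tracts = set(cohort.data["tract_id"]) if len(cohort) else set()
    in_sample = sorted(panel_tracts & cohort_tracts)
    out_sample = sorted(panel_tracts - cohort_tracts)
    orphan_mask = ~cohort.data["tract_id"].isin(panel_tracts) if len(cohort) \
        else pd.Series(dtype=bool)
    orphans = cohort.data.index[orphan_mask] if len(cohort) else pd.Index([])

    cells = pd.MultiIndex.from_product(
        [sorted(panel_tracts), panel.years], names=["tract_id", "year"])
    if len(cohort):
        counts = cohort.data[~orphan_mask].groupby(
            ["tract_id", "year"]).size()
        cell_sizes = counts.reindex(cells, fill_value=0)
    else:
        cell_sizes = pd.Series(0, index=cells)
    if len(orphans):
        log.warning("%d cohort rows fall outside the place panel and will be "
                    "excluded from modeling", len(orphans))
    return LinkageReport(in_sample, out_sample, orphans, cell_sizes)


_FLOAT_FMT = "%.17g"  # round-trips float64 exactly


def write_vscores(vtable, importance, path) -> list[Path]:
    """Write year-specific scores, generic scores and variable importance.

    Writes ``vscore_by_year.csv``, ``vscore_generic.csv`` and (when a fit was
    run) ``importance.csv`` under ``path``. Numbers are serialized with enough
    digits that reading them back reproduces the values exactly.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written = []

    by_year = vtable.by_year[["tract_id", "year", "vscore", "prediction_raw",
                              "provenance"]]
    f = path / "vscore_by_year.csv"
    by_year.to_csv(f, index=False, float_format=_FLOAT_FMT)
    written.append(f)

    if vtable.generic is not None:
        f = path / "vscore_generic.csv"
        vtable.generic.to_csv(f, index=False, float_format=_FLOAT_FMT)
        written.append(f)

    if importance is None or len(importance) == 0:
        log.info("no fitted forest importance available; importance.csv omitted")
    else:
        imp = importance
        if isinstance(imp, pd.Series):
            imp = imp.rename("importance").rename_axis("variable").reset_index()
        else:
            imp = imp.rename_axis("variable").reset_index()
        f = path / "importance.csv"
        imp.to_csv(f, index=False, float_format=_FLOAT_FMT)
        written.append(f)
    return written
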