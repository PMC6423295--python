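"""Data model, validation and CSV I/O for pollination visitation censuses.

The canonical on-disk format is a long (tidy) CSV with one row per
(census, plant individual, pollinator species) visit count.  Long format is
canonical because every downstream resampling scheme works at the level of
individual censuses; wide interaction matrices are an *export*, never an
input.

A census with no visits at all is scientifically meaningful — it enters the
denominator of every visit rate — and is represented by a single row whose
``pollinator_species`` field is empty (the :data:`NO_VISIT` sentinel) with a
count of 0.  Such rows survive read/write round trips.

Census types
------------
``focal5min``
    Standard 5-minute focal-plant watches; the backbone of the quantitative
    matrix.
``spot``
    Short (~1-2 min) visual inspections used for vertebrate visitors; they
    contribute visit rates with their own census denominator.
``extra``
    Opportunistic walk-through observations; presence-only, they enter the
    qualitative (0/1) matrix but never a visit rate.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "SurveyDataset",
    "CENSUS_COLUMNS",
    "CENSUS_TYPES",
    "PERIODS",
    "NO_VISIT",
    "read_censuses",
    "write_censuses",
    "summarize",
    "visit_shares",
    "read_reproduction",
    "write_reproduction",
    "read_distance",
    "write_distance",
    "load_schema",
]

PERIODS = ("pre", "apis")
CENSUS_TYPES = ("focal5min", "spot", "extra")

#: Sentinel pollinator label marking a zero-visit census row.
NO_VISIT = ""

CENSUS_COLUMNS = [
    "census_id",
    "year",
    "period",
    "census_type",
    "plant_species",
    "plant_individual",
    "pollinator_species",
    "count",
    "duration_min",
]

#: Metadata columns that must be constant within one census_id.
_CENSUS_META = ["year", "period", "census_type", "plant_species", "plant_individual"]

REPRODUCTION_COLUMNS = [
    "plant_species",
    "plant_individual",
    "period",
    "flowers",
    "fruits",
    "fruit_id",
    "seeds",
    "ovules",
    "seed_mass_mg",
]

DISTANCE_COLUMNS = [
    "plant_species",
    "plant_individual",
    "distance_class_m",
    "fruit_id",
    "seeds",
    "ovules",
    "seed_mass_mg",
]

DISTANCE_CLASSES = (0, 100, 500, 1000, 2000, 4000)


class ValidationError(ValueError):
    """A dataset violates the census/reproduction data contract."""


def _clean_species(series: pd.Series) -> pd.Series:
    """Trim whitespace; species identifiers are case-sensitive otherwise."""
    return series.fillna(NO_VISIT).astype(str).str.strip()


@dataclasses.dataclass
class SurveyDataset:
    """A validated collection of census records plus species registries.

    Parameters
    ----------
    records
        Long-format frame with :data:`CENSUS_COLUMNS`.
    plants, pollinators
        Registries of species names.  Every species appearing in
        ``records`` must be registered; the registries may list additional
        species known to the survey but unobserved in this slice.
    apis_name
        Label of the designated super-generalist invader (the honeybee in
        the motivating system).  Used to split wild vs. invader statistics.
    """

    records: pd.DataFrame
    plants: set
    pollinators: set
    apis_name: str = "Apis mellifera"

    # ------------------------------------------------------------------
    @classmethod
    def from_records(cls, records: pd.DataFrame, apis_name: str = "Apis mellifera") -> "SurveyDataset":
        """Build a dataset auto-registering every species seen in *records*."""
        records = records.copy()
        for col in CENSUS_COLUMNS:
            if col not in records.columns:
                raise ValidationError(f"missing required column: {col!r}")
        records = records[CENSUS_COLUMNS]
        records["plant_species"] = _clean_species(records["plant_species"])
        records["pollinator_species"] = _clean_species(records["pollinator_species"])
        ds = cls(
            records=records,
            plants=set(records["plant_species"].unique()) - {NO_VISIT},
            pollinators=set(records["pollinator_species"].unique()) - {NO_VISIT},
            apis_name=apis_name,
        )
        ds.validate()
        return ds

    # ------------------------------------------------------------------
    def validate(self) -> None:
        """Raise :class:`ValidationError` (with row indices) on any contract breach."""
        df = self.records
        missing = [c for c in CENSUS_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"missing required column(s): {missing}")

        counts = pd.to_numeric(df["count"], errors="coerce")
        bad = df.index[counts.isna() | (counts < 0) | (counts % 1 != 0)]
        if len(bad):
            raise ValidationError(
                f"non-integer or negative visit counts at row(s) {list(bad[:10])}"
            )

        bad = df.index[~df["period"].isin(PERIODS)]
        if len(bad):
            raise ValidationError(f"unknown period at row(s) {list(bad[:10])}")
        bad = df.index[~df["census_type"].isin(CENSUS_TYPES)]
        if len(bad):
            raise ValidationError(f"unknown census_type at row(s) {list(bad[:10])}")

        bad = df.index[(df["plant_species"] == NO_VISIT)]
        if len(bad):
            raise ValidationError(f"empty plant_species at row(s) {list(bad[:10])}")

        # a census_id must carry a single consistent set of metadata
        nuniq = df.groupby("census_id", sort=False)[_CENSUS_META].nunique()
        conflicted = nuniq.index[(nuniq > 1).any(axis=1)]
        if len(conflicted):
            raise ValidationError(
                f"census_id(s) with conflicting metadata: {list(conflicted[:10])}"
            )

        # registry closure
        seen_p = set(df["plant_species"].unique()) - {NO_VISIT}
        seen_a = set(df["pollinator_species"].unique()) - {NO_VISIT}
        if not seen_p <= self.plants:
            raise ValidationError(f"unregistered plant(s): {sorted(seen_p - self.plants)[:10]}")
        if not seen_a <= self.pollinators:
            raise ValidationError(
                f"unregistered pollinator(s): {sorted(seen_a - self.pollinators)[:10]}"
            )

    # ------------------------------------------------------------------
    def filter(
        self,
        period: str | None = None,
        year: int | None = None,
        census_types: Iterable[str] | None = None,
    ) -> "SurveyDataset":
        """Return the sub-dataset matching the given period/year/census types.

        Registries are re-derived from the retained records so that network
        dimensions reflect the species actually observed in the slice.
        """
        df = self.records
        mask = pd.Series(True, index=df.index)
        if period is not None:
            mask &= df["period"] == period
        if year is not None:
            mask &= df["year"] == year
        if census_types is not None:
            mask &= df["census_type"].isin(list(census_types))
        sub = df[mask].reset_index(drop=True)
        return SurveyDataset(
            records=sub,
            plants=set(sub["plant_species"].unique()) - {NO_VISIT},
            pollinators=set(sub["pollinator_species"].unique()) - {NO_VISIT},
            apis_name=self.apis_name,
        )

    # ------------------------------------------------------------------
    def census_index(self) -> pd.DataFrame:
        """One row per census with its metadata (the resampling unit)."""
        return (
            self.records.groupby("census_id", sort=False)[_CENSUS_META]
            .first()
            .reset_index()
        )

    def census_counts(self, by=("plant_species", "period", "year", "census_type")) -> pd.Series:
        """Number of distinct censuses per stratum (the rate denominators)."""
        return self.records.groupby(list(by), sort=False)["census_id"].nunique()

    @property
    def n_censuses(self) -> int:
        return self.records["census_id"].nunique()

    def equals(self, other: "SurveyDataset") -> bool:
        """Field-by-field equality ignoring row order."""
        key = CENSUS_COLUMNS
        a = self.records[key].sort_values(key).reset_index(drop=True)
        b = other.records[key].sort_values(key).reset_index(drop=True)
        # normalise dtypes for the comparison
        a = a.astype(str)
        b = b.astype(str)
        return (
            a.equals(b)
            and self.plants == other.plants
            and self.pollinators == other.pollinators
            and self.apis_name == other.apis_name
        )


# ----------------------------------------------------------------------
# CSV I/O
# ----------------------------------------------------------------------

def load_schema(path) -> dict:
    """Load a JSON column-remapping config: {canonical_name: actual_name}."""
    with open(path) as fh:
        return json.load(fh)


def _apply_schema(df: pd.DataFrame, schema: Mapping[str, str] | None, required) -> pd.DataFrame:
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required column(s): {missing}")
    return df


def read_censuses(path, schema: Mapping[str, str] | None = None,
                  apis_name: str = "Apis mellifera") -> SurveyDataset:
    """Read a long-format census CSV into a validated :class:`SurveyDataset`.

    *schema* optionally maps canonical column names to the file's actual
    headers.  Unknown species are auto-registered; malformed rows raise
    :class:`ValidationError` naming the offending row indices.
    """
    df = pd.read_csv(path, dtype={"census_id": str, "plant_individual": str},
                     keep_default_na=True)
    df = _apply_schema(df, schema, CENSUS_COLUMNS[:-1])  # duration_min optional
    if "duration_min" not in df.columns:
        df["duration_min"] = np.nan
    df["pollinator_species"] = _clean_species(df["pollinator_species"])
    df["plant_species"] = _clean_species(df["plant_species"])
    return SurveyDataset.from_records(df, apis_name=apis_name)


def write_censuses(data: SurveyDataset, path) -> None:
    """Write the canonical long CSV; ``read_censuses`` inverts it exactly."""
    out = data.records[CENSUS_COLUMNS].copy()
    out.to_csv(path, index=False)


# ----------------------------------------------------------------------
# Summaries
# ----------------------------------------------------------------------

def summarize(data: SurveyDataset) -> pd.DataFrame:
    """Per (year, period) table of census effort, species counts and visits.

    ``visits`` is the plain sum of the count column, so totals are conserved
    with respect to the raw rows.
    """
    df = data.records
    rows = []
    for (year, period), g in df.groupby(["year", "period"], sort=True):
        visited = g[g["count"] > 0]
        rows.append(
            {
                "year": year,
                "period": period,
                "censuses": g["census_id"].nunique(),
                "plant_species": g["plant_species"].nunique(),
                "pollinator_species": visited["pollinator_species"].nunique(),
                "visits": int(g["count"].sum()),
            }
        )
    return pd.DataFrame(rows, columns=["year", "period", "censuses", "plant_species",
                                       "pollinator_species", "visits"])


def visit_shares(data: SurveyDataset) -> pd.Series:
    """Fraction of all recorded visits attributed to each pollinator species.

    Shares sum to 1 whenever at least one visit was recorded.
    """
    df = data.records
    df = df[df["pollinator_species"] != NO_VISIT]
    totals = df.groupby("pollinator_species")["count"].sum().astype(float)
    grand = totals.sum()
    if grand == 0:
        raise ValidationError("no visits recorded; shares undefined")
    return (totals / grand).sort_values(ascending=False)


# ----------------------------------------------------------------------
# Reproduction / distance-gradient tables
# ----------------------------------------------------------------------

def _validate_fruit_frame(df: pd.DataFrame, where: str) -> None:
    seeds = pd.to_numeric(df["seeds"], errors="coerce")
    bad = df.index[seeds.notna() & (seeds < 0)]
    if len(bad):
        raise ValidationError(f"{where}: negative seed counts at row(s) {list(bad[:10])}")
    if "ovules" in df.columns:
        ov = pd.to_numeric(df["ovules"], errors="coerce")
        both = seeds.notna() & ov.notna()
        bad = df.index[both & (seeds > ov)]
        if len(bad):
            raise ValidationError(
                f"{where}: seeds exceed ovules at row(s) {list(bad[:10])}"
            )


def read_reproduction(path, schema: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read the per-fruit reproduction table (paired pre/apis design).

    One row per collected fruit; rows repeat the per-(plant, period) flower
    and fruit totals.  A plant-period with zero fruits appears as one row
    with an empty ``fruit_id``.
    """
    df = pd.read_csv(path, dtype={"plant_individual": str, "fruit_id": str})
    df = _apply_schema(df, schema, ["plant_species", "plant_individual", "period",
                                    "flowers", "fruits"])
    for opt in ("fruit_id", "seeds", "ovules", "seed_mass_mg"):
        if opt not in df.columns:
            df[opt] = np.nan
    bad = df.index[~df["period"].isin(list(PERIODS) + ["excluded"])]
    if len(bad):
        raise ValidationError(f"reproduction: unknown period at row(s) {list(bad[:10])}")
    bad = df.index[df["fruits"] > df["flowers"]]
    if len(bad):
        raise ValidationError(f"reproduction: fruits > flowers at row(s) {list(bad[:10])}")
    _validate_fruit_frame(df, "reproduction")
    return df[REPRODUCTION_COLUMNS]


def write_reproduction(df: pd.DataFrame, path) -> None:
    df[REPRODUCTION_COLUMNS].to_csv(path, index=False)


def read_distance(path, schema: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read the per-fruit distance-gradient table (apiary-distance design)."""
    df = pd.read_csv(path, dtype={"plant_individual": str, "fruit_id": str})
    df = _apply_schema(df, schema, ["plant_individual", "distance_class_m", "seeds"])
    if "plant_species" not in df.columns:
        df["plant_species"] = "unknown"
    for opt in ("fruit_id", "ovules", "seed_mass_mg"):
        if opt not in df.columns:
            df[opt] = np.nan
    bad = df.index[~df["distance_class_m"].isin(DISTANCE_CLASSES)]
    if len(bad):
        raise ValidationError(f"distance: unknown distance class at row(s) {list(bad[:10])}")
    _validate_fruit_frame(df, "distance")
    return df[DISTANCE_COLUMNS]


def write_distance(df: pd.DataFrame, path) -> None:
    df[DISTANCE_COLUMNS].to_csv(path, index=False)
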