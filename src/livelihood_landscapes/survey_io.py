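"""Read, validate and write household livelihood surveys.

The survey dialect is long-format CSV, one row per household x occupation:

    household_id,site_id,occupation,rank

with rank 1 the household's most important activity and ranks contiguous
integers 1..k.  Site covariates travel in a second CSV:

    site_id,country,settlement_type,development_index,population_density,n_households

An empty cell means missing; population density may legitimately be missing
(island sites too small for the gridded population database).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .categories import DEFAULT_CATEGORIES, CategorySet

SURVEY_COLUMNS = ["household_id", "site_id", "occupation", "rank"]
COVARIATE_COLUMNS = [
    "site_id",
    "country",
    "settlement_type",
    "development_index",
    "population_density",
    "n_households",
]

SETTLEMENT_TYPES = ("rural", "peri_urban")


@dataclass(frozen=True)
class HouseholdRecord:
    """One household's ranked, distinct occupation portfolio.

    ``occupations[0]`` is the primary (rank-1) activity; positions encode
    ranks 1..k.
    """

    household_id: str
    site_id: str
    occupations: tuple[str, ...]

    @property
    def k(self) -> int:
        return len(self.occupations)

    @property
    def primary(self) -> str:
        return self.occupations[0]


@dataclass(frozen=True)
class CommunityMetadata:
    """Site-level covariates joined to networks downstream."""

    site_id: str
    country: str = ""
    settlement_type: str = ""
    development_index: float = math.nan
    population_density: float | None = None
    n_households: int = 0


@dataclass(frozen=True)
class Violation:
    household_id: str
    rule: str
    message: str


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, household_id: str, rule: str, message: str) -> None:
        self.violations.append(Violation(household_id, rule, message))

    def __len__(self) -> int:
        return len(self.violations)


class SurveyFormatError(ValueError):
    """A survey file violates the dialect or the portfolio invariants."""


def validate_households(
    records: Iterable[HouseholdRecord],
    categories: CategorySet = DEFAULT_CATEGORIES,
) -> ValidationReport:
    """Check every portfolio invariant; violations are reported, never raised.

    Rules: ``empty_portfolio``, ``duplicate_category``, ``unknown_category``,
    ``exclusive_violation`` (an exclusive category such as ``none``
    co-occurring with anything else).
    """
    report = ValidationReport()
    for rec in records:
        if not rec.occupations:
            report.add(rec.household_id, "empty_portfolio", "no occupations listed")
            continue
        seen: set[str] = set()
        for occ in rec.occupations:
            if occ not in categories:
                report.add(
                    rec.household_id,
                    "unknown_category",
                    f"occupation {occ!r} not in the configured category list",
                )
            if occ in seen:
                report.add(
                    rec.household_id,
                    "duplicate_category",
                    f"occupation {occ!r} listed more than once",
                )
            seen.add(occ)
        exclusive_hits = seen & categories.exclusive
        if exclusive_hits and len(rec.occupations) > 1:
            report.add(
                rec.household_id,
                "exclusive_violation",
                f"{sorted(exclusive_hits)} cannot co-occur with other categories",
            )
    return report


def _records_from_frame(
    df: pd.DataFrame, categories: CategorySet
) -> list[HouseholdRecord]:
    records: list[HouseholdRecord] = []
    # groupby(sort=False) keeps first-appearance order so read(write(x)) == x
    for hh_id, group in df.groupby("household_id", sort=False):
        group = group.sort_values("rank")
        ranks = group["rank"].tolist()
        if ranks != list(range(1, len(ranks) + 1)):
            raise SurveyFormatError(
                f"household {hh_id!r}: ranks {ranks} are not contiguous 1..k"
            )
        sites = group["site_id"].unique()
        if len(sites) != 1:
            raise SurveyFormatError(
                f"household {hh_id!r} appears under multiple sites {list(sites)}"
            )
        for row_ix, occ in zip(group.index, group["occupation"]):
            if occ not in categories:
                raise SurveyFormatError(
                    f"row {row_ix}: unknown occupation category {occ!r}"
                )
        rec = HouseholdRecord(str(hh_id), str(sites[0]), tuple(group["occupation"]))
        records.append(rec)
    report = validate_households(records, categories)
    if not report.ok:
        first = report.violations[0]
        raise SurveyFormatError(
            f"{len(report)} invariant violation(s); first: household "
            f"{first.household_id!r} [{first.rule}] {first.message}"
        )
    return records


def read_survey(
    path: str | Path,
    categories: CategorySet = DEFAULT_CATEGORIES,
    covariates_path: str | Path | None = None,
) -> tuple[list[HouseholdRecord], list[CommunityMetadata]]:
    """Read a long-format survey CSV (and optionally a covariates CSV).

    Returns households grouped by ``household_id`` with occupations sorted by
    rank, plus the covariate table (empty when no path is given).  Raises
    :class:`SurveyFormatError` on unknown categories, non-contiguous or
    duplicate ranks, or exclusive-category violations.
    """
    df = pd.read_csv(path, dtype={"household_id": str, "site_id": str})
    missing = set(SURVEY_COLUMNS) - set(df.columns)
    if missing:
        raise SurveyFormatError(f"survey file missing columns {sorted(missing)}")
    if df.empty:
        records: list[HouseholdRecord] = []
    else:
        if df["rank"].isna().any() or (df["rank"] != df["rank"].astype(int)).any():
            raise SurveyFormatError("ranks must be integers")
        df = df.assign(rank=df["rank"].astype(int))
        records = _records_from_frame(df, categories)
    metadata = read_covariates(covariates_path) if covariates_path else []
    if metadata:
        known = {m.site_id for m in metadata}
        surveyed = {r.site_id for r in records}
        orphans = surveyed - known
        if orphans:
            raise SurveyFormatError(
                f"sites {sorted(orphans)} in survey but not in covariates"
            )
    return records, metadata


def read_covariates(path: str | Path) -> list[CommunityMetadata]:
    df = pd.read_csv(path, dtype={"site_id": str, "country": str})
    missing = set(COVARIATE_COLUMNS) - set(df.columns)
    if missing:
        raise SurveyFormatError(f"covariates file missing columns {sorted(missing)}")
    if df["site_id"].duplicated().any():
        dupes = df.loc[df["site_id"].duplicated(), "site_id"].tolist()
        raise SurveyFormatError(f"duplicate site_id in covariates: {dupes}")
    out = []
    for row in df.itertuples(index=False):
        pop = row.population_density
        out.append(
            CommunityMetadata(
                site_id=str(row.site_id),
                country="" if pd.isna(row.country) else str(row.country),
                settlement_type=(
                    "" if pd.isna(row.settlement_type) else str(row.settlement_type)
                ),
                development_index=float(row.development_index)
                if not pd.isna(row.development_index)
                else math.nan,
                population_density=None if pd.isna(pop) else float(pop),
                n_households=int(row.n_households)
                if not pd.isna(row.n_households)
                else 0,
            )
        )
    return out


def write_survey(
    records: Sequence[HouseholdRecord],
    path: str | Path,
    metadata: Sequence[CommunityMetadata] = (),
    covariates_path: str | Path | None = None,
    categories: CategorySet = DEFAULT_CATEGORIES,
) -> Path:
    """Write records (and optionally covariates) back to the CSV dialect.

    ``read_survey(write_survey(x))`` is the identity on valid input.
    """
    report = validate_households(records, categories)
    if not report.ok:
        first = report.violations[0]
        raise SurveyFormatError(
            f"refusing to write invalid records; first violation: household "
            f"{first.household_id!r} [{first.rule}] {first.message}"
        )
    rows = [
        (rec.household_id, rec.site_id, occ, rank)
        for rec in records
        for rank, occ in enumerate(rec.occupations, start=1)
    ]
    pd.DataFrame(rows, columns=SURVEY_COLUMNS).to_csv(path, index=False)
    if covariates_path is not None:
        write_covariates(metadata, covariates_path)
    return Path(path)


def write_covariates(
    metadata: Sequence[CommunityMetadata], path: str | Path
) -> Path:
    rows = []
    for m in metadata:
        rows.append(
            (
                m.site_id,
                m.country,
                m.settlement_type,
                m.development_index,
                "" if m.population_density is None else m.population_density,
                m.n_households,
            )
        )
    pd.DataFrame(rows, columns=COVARIATE_COLUMNS).to_csv(path, index=False)
    return Path(path)
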