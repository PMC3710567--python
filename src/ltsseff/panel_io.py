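"""Read, validate, filter and deflate the state-by-year expenditure panel.

The unit of analysis is a jurisdiction-year record carrying total program
cost, participant counts for institutional and home/community services, and
policy/socioeconomic covariates.  This module owns the sample-construction
rules (jurisdiction exclusions, deflation to a base year) and the CSV
round-trip used by the CLI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    CoverageError,
    InputError,
    IntegrityError,
    SchemaError,
)

logger = logging.getLogger(__name__)

#: 50 states plus the District of Columbia.
JURISDICTIONS: tuple[str, ...] = (
    "AL", "AK", "AZ", "AR", "CA", "CO", "CT", "DE", "DC", "FL",
    "GA", "HI", "ID", "IL", "IN", "IA", "KS", "KY", "LA", "ME",
    "MD", "MA", "MI", "MN", "MS", "MO", "MT", "NE", "NV", "NH",
    "NJ", "NM", "NY", "NC", "ND", "OH", "OK", "OR", "PA", "RI",
    "SC", "SD", "TN", "TX", "UT", "VT", "VA", "WA", "WV", "WI",
    "WY",
)

REQUIRED_COLUMNS: tuple[str, ...] = (
    "state", "year", "total_cost", "q_inst", "q_hcbs", "hcbs_share",
    "waiver_share", "icfmr_share", "managed_care", "con", "population",
    "pc_income", "unemployment",
)

_NUMERIC_COLUMNS = tuple(c for c in REQUIRED_COLUMNS if c not in ("state", "year"))


@dataclass(frozen=True)
class PanelRecord:
    """One validated jurisdiction-year observation."""

    state: str
    year: int
    total_cost: float
    q_inst: float
    q_hcbs: float
    hcbs_share: float
    waiver_share: float
    icfmr_share: float
    managed_care: int
    con: int
    population: float
    pc_income: float
    unemployment: float

    def violations(self, year_range: tuple[int, int] | None = None) -> list[str]:
        """Return human-readable invariant violations (empty when valid)."""
        problems: list[str] = []
        for name in _NUMERIC_COLUMNS:
            value = getattr(self, name)
            if value is None or (isinstance(value, float) and not np.isfinite(value)):
                problems.append(f"{name} is missing or non-finite")
        if problems:
            return problems
        if not self.state or not str(self.state).strip():
            problems.append("state code is empty")
        if self.total_cost <= 0:
            problems.append(f"total_cost must be > 0, got {self.total_cost}")
        if self.q_inst < 0:
            problems.append(f"q_inst must be >= 0, got {self.q_inst}")
        if self.q_hcbs < 0:
            problems.append(f"q_hcbs must be >= 0, got {self.q_hcbs}")
        if self.q_inst + self.q_hcbs <= 0:
            problems.append("q_inst + q_hcbs must be > 0")
        for name in ("hcbs_share", "waiver_share", "icfmr_share"):
            value = getattr(self, name)
            if not 0 <= value <= 100:
                problems.append(f"{name} must lie in [0, 100], got {value}")
        for name in ("managed_care", "con"):
            if getattr(self, name) not in (0, 1):
                problems.append(f"{name} must be 0 or 1, got {getattr(self, name)}")
        if self.population <= 0:
            problems.append(f"population must be > 0, got {self.population}")
        if self.pc_income <= 0:
            problems.append(f"pc_income must be > 0, got {self.pc_income}")
        if not 0 <= self.unemployment <= 100:
            problems.append(f"unemployment must lie in [0, 100], got {self.unemployment}")
        if year_range is not None and not year_range[0] <= self.year <= year_range[1]:
            problems.append(f"year {self.year} outside configured range {year_range}")
        return problems


@dataclass
class PanelDataset:
    """A validated collection of :class:`PanelRecord` rows.

    ``(state, year)`` pairs are unique; the panel may be unbalanced.  States
    observed in a single year only are permitted but flagged, since the
    frontier and second-stage estimators both need repeated observations.
    """

    frame: pd.DataFrame
    base_year: int | None = None
    provenance: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        frame = self.frame.copy()
        missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise SchemaError(f"panel frame missing required columns: {missing}")
        frame["state"] = frame["state"].astype(str)
        frame["year"] = frame["year"].astype(int)
        for col in _NUMERIC_COLUMNS:
            frame[col] = pd.to_numeric(frame[col])
        frame["managed_care"] = frame["managed_care"].astype(int)
        frame["con"] = frame["con"].astype(int)
        dup = frame.duplicated(subset=["state", "year"], keep=False)
        if dup.any():
            first = frame.loc[dup, ["state", "year"]].iloc[0]
            raise IntegrityError(
                f"duplicate (state, year) pair: ({first['state']}, {first['year']})"
            )
        frame = frame.sort_values(["state", "year"]).reset_index(drop=True)
        counts = frame.groupby("state")["year"].size()
        lonely = counts[counts < 2]
        if len(lonely):
            logger.warning(
                "states observed in a single year only: %s", ", ".join(lonely.index)
            )
        self.frame = frame[list(REQUIRED_COLUMNS)]

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def states(self) -> list[str]:
        return sorted(self.frame["state"].unique())

    @property
    def years(self) -> list[int]:
        return sorted(self.frame["year"].unique())

    def to_records(self) -> list[PanelRecord]:
        return [PanelRecord(**row) for row in self.frame.to_dict("records")]


@dataclass(frozen=True)
class CpiSeries:
    """Annual price index; all values strictly positive."""

    values: Mapping[int, float]

    def __post_init__(self) -> None:
        cleaned = {int(y): float(v) for y, v in dict(self.values).items()}
        for year, value in cleaned.items():
            if not (np.isfinite(value) and value > 0):
                raise ConfigurationError(f"CPI value for {year} must be > 0, got {value}")
        object.__setattr__(self, "values", cleaned)

    def __getitem__(self, year: int) -> float:
        try:
            return self.values[int(year)]
        except KeyError:
            raise CoverageError(f"CPI series does not cover year {year}") from None

    def covers(self, years: Iterable[int]) -> bool:
        return all(int(y) in self.values for y in years)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CpiSeries":
        frame = pd.read_csv(path)
        if not {"year", "cpi"}.issubset(frame.columns):
            raise SchemaError("CPI CSV must have columns 'year' and 'cpi'")
        return cls(dict(zip(frame["year"].astype(int), frame["cpi"].astype(float))))


def default_cpi() -> CpiSeries:
    """Bundled synthetic CPI for 1999-2007 (annual-average CPI-U levels)."""
    return CpiSeries(
        {
            1999: 166.6, 2000: 172.2, 2001: 177.1, 2002: 179.9, 2003: 184.0,
            2004: 188.9, 2005: 195.3, 2006: 201.6, 2007: 207.3,
        }
    )


@dataclass(frozen=True)
class ExclusionRule:
    """Drop a jurisdiction, either entirely (``years is None``) or for a year set."""

    state: str
    years: frozenset[int] | None = None

    def __post_init__(self) -> None:
        if self.years is not None:
            object.__setattr__(self, "years", frozenset(int(y) for y in self.years))


#: Sample-construction defaults: AZ dropped entirely (capitated managed care
#: only, no expenditure breakdown), VT dropped for 2006-2007 (1115 waiver).
DEFAULT_EXCLUSIONS: tuple[ExclusionRule, ...] = (
    ExclusionRule("AZ"),
    ExclusionRule("VT", frozenset({2006, 2007})),
)


def load_panel(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    year_range: tuple[int, int] | None = None,
    strict: bool = False,
) -> PanelDataset:
    """Load and validate a state-year panel from CSV.

    Parameters
    ----------
    path:
        CSV file with a header row and one row per state-year.
    schema:
        Optional mapping ``canonical_name -> column_name_in_file`` for files
        whose headers differ from :data:`REQUIRED_COLUMNS`.
    year_range:
        Optional inclusive ``(first, last)`` year bound enforced per record.
    strict:
        When true, any invalid row raises instead of being dropped.

    Rows violating record invariants are rejected with row-level diagnostics
    (logged as warnings).  Duplicate keys raise :class:`IntegrityError`.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise InputError(f"{path} is empty") from None
    if raw.empty:
        raise InputError(f"{path} contains a header but no rows")
    if schema:
        missing_src = [src for src in schema.values() if src not in raw.columns]
        if missing_src:
            raise SchemaError(f"schema maps to absent columns: {missing_src}")
        raw = raw.rename(columns={src: dst for dst, src in schema.items()})
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path} missing required columns: {missing}")

    kept_rows: list[dict] = []
    rejected = 0
    for i, row in raw.iterrows():
        try:
            record = PanelRecord(
                state=str(row["state"]).strip(),
                year=int(row["year"]),
                **{c: float(row[c]) for c in _NUMERIC_COLUMNS if c not in ("managed_care", "con")},
                managed_care=int(row["managed_care"]),
                con=int(row["con"]),
            )
            problems = record.violations(year_range)
        except (TypeError, ValueError) as exc:
            problems = [f"unparseable value ({exc})"]
            record = None
        if problems:
            rejected += 1
            message = f"row {i + 2} of {path.name} rejected: " + "; ".join(problems)
            if strict:
                raise InputError(message)
            logger.warning(message)
            continue
        kept_rows.append(record.__dict__)
    if not kept_rows:
        raise InputError(f"{path}: no valid rows after validation ({rejected} rejected)")
    if rejected:
        logger.warning("%s: rejected %d of %d rows", path.name, rejected, len(raw))
    frame = pd.DataFrame(kept_rows)
    return PanelDataset(frame, provenance=(f"loaded from {path}",))


def write_panel(data: PanelDataset, path: str | Path) -> None:
    """Write a panel back to CSV with full float precision (round-trip safe)."""
    data.frame.to_csv(path, index=False)


def apply_exclusions(
    data: PanelDataset,
    rules: Sequence[ExclusionRule] = DEFAULT_EXCLUSIONS,
) -> PanelDataset:
    """Drop records matched by the exclusion rules.

    Each rule names a jurisdiction and, optionally, the years to drop; with
    no year set the jurisdiction is removed entirely.  Idempotent and
    order-independent.  A rule naming an unknown jurisdiction code raises
    :class:`ConfigurationError`.
    """
    for rule in rules:
        if rule.state not in JURISDICTIONS:
            raise ConfigurationError(f"exclusion rule names unknown state code {rule.state!r}")
    keep = np.ones(len(data.frame), dtype=bool)
    for rule in rules:
        match = data.frame["state"] == rule.state
        if rule.years is not None:
            match &= data.frame["year"].isin(rule.years)
        n = int(match.sum())
        if n:
            logger.info("exclusion %s/%s removed %d records", rule.state,
                        "all years" if rule.years is None else sorted(rule.years), n)
        keep &= ~match
    frame = data.frame.loc[keep].reset_index(drop=True)
    return PanelDataset(
        frame,
        base_year=data.base_year,
        provenance=data.provenance + (f"exclusions applied ({len(data) - len(frame)} removed)",),
    )


def deflate_costs(data: PanelDataset, cpi: CpiSeries, base_year: int = 2005) -> PanelDataset:
    """Convert nominal costs to base-year dollars via annual CPI ratios.

    Each ``total_cost`` is scaled by ``cpi[base_year] / cpi[year]``; the base
    year is recorded on the returned dataset.  Within-year cost ratios are
    preserved exactly.
    """
    years = data.years
    for year in years + [base_year]:
        cpi[year]  # raises CoverageError when absent
    frame = data.frame.copy()
    factors = frame["year"].map(lambda y: cpi[base_year] / cpi[y])
    frame["total_cost"] = frame["total_cost"] * factors
    return PanelDataset(
        frame,
        base_year=int(base_year),
        provenance=data.provenance + (f"deflated to {base_year} dollars",),
    )
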