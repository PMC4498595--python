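"""Domain types for the wetland prioritisation pipeline.

The pipeline revolves around three tabular objects — a planning-unit (PU)
attribute table, a long-format species x PU x year abundance tensor, and an
annual covariate series (flow, regional rainfall, climate index) — plus a
run configuration that carries the prioritisation parameters (representation
target, number of annealing solutions, schedule, phase quantiles).

All tables are thin, validated wrappers around :class:`pandas.DataFrame`;
validation happens at construction and readers never coerce invalid records
silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WETLAND_TYPES",
    "FormatError",
    "ValidationError",
    "ConfigError",
    "PlanningUnitTable",
    "AbundanceTensor",
    "CovariateSeries",
    "RunConfig",
]

#: Recognised wetland type labels.  The four natural types plus artificial
#: reservoirs (dams) and "unmapped" for PUs not intersecting a mapped wetland.
WETLAND_TYPES = (
    "estuarine",
    "lacustrine",
    "palustrine",
    "riverine",
    "reservoir",
    "unmapped",
)


class FormatError(ValueError):
    """A file does not conform to the expected dialect (e.g. missing column)."""


class ValidationError(ValueError):
    """A record violates a domain-type invariant."""


class ConfigError(ValueError):
    """A configuration value is out of its admissible range."""


def _require_columns(frame: pd.DataFrame, columns: Iterable[str], what: str) -> None:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise FormatError(f"{what}: missing required column(s) {missing}")


@dataclass(frozen=True)
class PlanningUnitTable:
    """Per-PU attributes: cost, wetland complex membership, type and area.

    Parameters
    ----------
    frame
        Columns ``pu_id``, ``cost`` (nonnegative, default 1), ``wetland_id``
        (optional complex identifier, may be null), ``wetland_type`` (one of
        :data:`WETLAND_TYPES`) and ``area`` (km^2, nonnegative).  Unknown
        columns are preserved untouched.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        frame = self.frame.copy()
        _require_columns(frame, ["pu_id"], "planning-unit table")
        if "cost" not in frame.columns:
            frame["cost"] = 1.0
        if "wetland_id" not in frame.columns:
            frame["wetland_id"] = pd.NA
        if "wetland_type" not in frame.columns:
            frame["wetland_type"] = "unmapped"
        if "area" not in frame.columns:
            frame["area"] = 0.0
        if frame["pu_id"].duplicated().any():
            dupes = frame.loc[frame["pu_id"].duplicated(), "pu_id"].tolist()
            raise ValidationError(f"duplicate pu_id values: {dupes}")
        frame["cost"] = pd.to_numeric(frame["cost"])
        frame["area"] = pd.to_numeric(frame["area"])
        if (frame["cost"] < 0).any():
            bad = frame.loc[frame["cost"] < 0, "pu_id"].tolist()
            raise ValidationError(f"negative cost for pu_id {bad}")
        if (frame["area"] < 0).any():
            bad = frame.loc[frame["area"] < 0, "pu_id"].tolist()
            raise ValidationError(f"negative area for pu_id {bad}")
        bad_types = set(frame["wetland_type"].dropna()) - set(WETLAND_TYPES)
        if bad_types:
            raise ValidationError(
                f"unknown wetland_type value(s) {sorted(bad_types)}; "
                f"expected one of {WETLAND_TYPES}"
            )
        frame = frame.reset_index(drop=True)
        object.__setattr__(self, "frame", frame)

    @property
    def pu_ids(self) -> list:
        return self.frame["pu_id"].tolist()

    @property
    def costs(self) -> np.ndarray:
        return self.frame["cost"].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class AbundanceTensor:
    """The survey record: nonnegative counts indexed (species, PU, year).

    Stored long-format with one row per (species_id, pu_id, year) key; keys
    must be unique and every ``pu_id`` must appear in the accompanying
    :class:`PlanningUnitTable` when one is supplied for validation.
    """

    frame: pd.DataFrame
    species: tuple = field(default=None)  # type: ignore[assignment]
    years: tuple = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        frame = self.frame.copy()
        _require_columns(frame, ["species_id", "pu_id", "year", "count"], "abundance tensor")
        frame["count"] = pd.to_numeric(frame["count"])
        neg = frame.index[frame["count"] < 0]
        if len(neg):
            raise ValidationError(
                f"negative count at record index {neg[0]} "
                f"(species {frame.loc[neg[0], 'species_id']}, pu {frame.loc[neg[0], 'pu_id']})"
            )
        key = frame[["species_id", "pu_id", "year"]]
        if key.duplicated().any():
            raise ValidationError("duplicate (species, pu, year) keys in abundance tensor")
        frame = frame.reset_index(drop=True)
        object.__setattr__(self, "frame", frame)
        species = self.species or tuple(sorted(frame["species_id"].unique()))
        years = self.years or tuple(sorted(frame["year"].unique()))
        object.__setattr__(self, "species", tuple(species))
        object.__setattr__(self, "years", tuple(years))

    def validate_against(self, pus: PlanningUnitTable) -> None:
        unknown = set(self.frame["pu_id"]) - set(pus.pu_ids)
        if unknown:
            raise ValidationError(f"tensor references unknown pu_id(s): {sorted(unknown)}")

    def matrix(self, pu_ids: Sequence, year=None) -> np.ndarray:
        """Species x PU count matrix for one year, or pooled over all years.

        Rows follow ``self.species``; columns follow the supplied ``pu_ids``
        order.  ``year=None`` pools (sums) over every survey year.
        """
        frame = self.frame
        if year is not None:
            frame = frame[frame["year"] == year]
        pivot = frame.pivot_table(
            index="species_id", columns="pu_id", values="count", aggfunc="sum", fill_value=0
        )
        out = pivot.reindex(index=list(self.species), columns=list(pu_ids), fill_value=0)
        return out.to_numpy(dtype=np.int64 if _is_integral(frame["count"]) else float)

    def totals_by_year(self) -> pd.Series:
        return self.frame.groupby("year")["count"].sum().reindex(list(self.years), fill_value=0)

    def __len__(self) -> int:
        return len(self.frame)


def _is_integral(counts: pd.Series) -> bool:
    if pd.api.types.is_integer_dtype(counts):
        return True
    vals = counts.to_numpy(dtype=float)
    return bool(np.all(vals == np.round(vals)))


@dataclass(frozen=True)
class CovariateSeries:
    """Per-year water-availability drivers: total flow, regional rainfall, SOI.

    ``frame`` has one row per year with columns ``year``, ``flow_total``
    (volume; must be positive wherever present so a log transform is
    defined), any number of ``rain_<region>`` columns (depth) and ``soi``
    (dimensionless climate index).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        frame = self.frame.copy()
        _require_columns(frame, ["year", "flow_total"], "covariate series")
        if frame["year"].duplicated().any():
            raise ValidationError("covariate series has more than one record for a year")
        flow = pd.to_numeric(frame["flow_total"])
        if (flow.dropna() <= 0).any():
            bad = frame.loc[flow <= 0, "year"].tolist()
            raise ValidationError(
                f"flow_total must be positive (log transform required); offending year(s) {bad}"
            )
        frame = frame.sort_values("year").reset_index(drop=True)
        object.__setattr__(self, "frame", frame)

    @property
    def years(self) -> list:
        return self.frame["year"].tolist()

    @property
    def flow(self) -> np.ndarray:
        return self.frame["flow_total"].to_numpy(dtype=float)

    @property
    def rain_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c.startswith("rain_")]

    def flow_for_years(self, years: Sequence) -> np.ndarray:
        lookup = dict(zip(self.frame["year"], self.frame["flow_total"]))
        missing = [y for y in years if y not in lookup]
        if missing:
            raise ValidationError(f"missing flow for year(s) {missing}")
        return np.array([lookup[y] for y in years], dtype=float)


def _as_fraction(x) -> Fraction:
    """Exact representation of a target fraction given as str, Fraction or float.

    Floats are interpreted through their shortest decimal repr, so a target
    of 0.1 means exactly 1/10 (counts are integers; boundary comparisons at
    round targets must not be lost to binary rounding).
    """
    if isinstance(x, Fraction):
        return x
    if isinstance(x, int):
        return Fraction(x)
    return Fraction(str(x))


@dataclass(frozen=True)
class RunConfig:
    """Prioritisation run parameters.

    Attributes
    ----------
    target_fraction
        Proportion p of each species' total abundance the selected PU set
        must contain, in (0, 1].
    n_solutions
        Number of independent annealing solutions R used to estimate
        selection frequency (irreplaceability).
    iterations
        Annealing moves per solution.
    spf
        Species penalty factor multiplying each species' shortfall penalty.
    cooling_floor
        Final temperature as a fraction of the adaptive initial temperature
        (geometric cooling across ``iterations``).
    irsc_threshold
        Irreplaceability cutoff used when counting "selected" wetlands and
        in functional classification.
    q_low, q_high
        Flow quantiles defining dry (< q_low quantile) and wet (> q_high
        quantile) years.
    """

    target_fraction: Fraction = Fraction(4, 5)
    n_solutions: int = 1000
    iterations: int = 100_000
    spf: float = 100.0
    cooling_floor: float = 1e-4
    seed: int = 0
    irsc_threshold: float = 0.6
    q_low: float = 0.25
    q_high: float = 0.75

    def __post_init__(self) -> None:
        object.__setattr__(self, "target_fraction", _as_fraction(self.target_fraction))
        if not (0 < self.target_fraction <= 1):
            raise ConfigError(f"target_fraction must be in (0, 1], got {self.target_fraction}")
        if self.n_solutions < 1:
            raise ConfigError("n_solutions must be >= 1")
        if self.iterations < 1:
            raise ConfigError("iterations must be >= 1")
        if self.spf < 0:
            raise ConfigError("species penalty factor must be >= 0")
        if not (0 < self.cooling_floor <= 1):
            raise ConfigError("cooling_floor must be in (0, 1]")
        if not (0 <= self.irsc_threshold <= 1):
            raise ConfigError("irsc_threshold must be in [0, 1]")
        if not (0 < self.q_low < self.q_high < 1):
            raise ConfigError("phase quantiles must satisfy 0 < q_low < q_high < 1")

    def with_target(self, p) -> "RunConfig":
        return replace(self, target_fraction=_as_fraction(p))

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(self, seed=int(seed))
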