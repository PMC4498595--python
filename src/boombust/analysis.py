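"""Analyses layered on the minimum-set solver.

* target sweep — rerun the prioritisation at 10%..100% representation
  targets, count PUs passing the irreplaceability threshold, and report the
  percent marginal increase between consecutive targets (the knee of this
  curve identifies a cost-effective target);
* annual prioritisation — independent selection-frequency runs per survey
  year;
* phase classification — dry / normal / wet years from flow quantiles;
* functional classification — refuge vs breeding vs both from mean IrSc in
  dry and wet years;
* wetland-type irreplaceability — area-corrected summed IrSc by wetland
  type, with a Pearson chi-squared contrast between phases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import (
    AbundanceTensor,
    CovariateSeries,
    PlanningUnitTable,
    RunConfig,
    ValidationError,
)
from .solver import IrreplaceabilityResult, ProblemInstance, selection_frequency

__all__ = [
    "SweepResult",
    "PhaseAssignment",
    "FunctionalClassification",
    "sweep_targets",
    "marginal_increase",
    "annual_prioritisation",
    "annual_counts",
    "classify_years",
    "phase_mean_irsc",
    "functional_classification",
    "type_irreplaceability",
    "type_phase_table",
    "pearson_chisq",
]

DEFAULT_TARGET_GRID = tuple(Fraction(k, 10) for k in range(1, 11))


@dataclass(frozen=True)
class SweepResult:
    """PU counts (IrSc >= threshold) across an increasing target grid."""

    frame: pd.DataFrame        # target, n_pus, pct_increase
    threshold: float
    results: dict              # target -> IrreplaceabilityResult

    @property
    def counts(self) -> list[int]:
        return self.frame["n_pus"].tolist()


@dataclass(frozen=True)
class PhaseAssignment:
    """Per-year dry/normal/wet labels and the flow cutpoints that made them."""

    frame: pd.DataFrame        # year, flow, phase
    cutpoints: tuple           # (low quantile value, high quantile value)

    def years(self, phase: str) -> list:
        return self.frame.loc[self.frame["phase"] == phase, "year"].tolist()


@dataclass(frozen=True)
class FunctionalClassification:
    """Per-PU mean IrSc under dry and wet years, and the implied role."""

    frame: pd.DataFrame        # pu_id, dry_mean, wet_mean, role
    threshold: float

    def role_ids(self, role: str) -> list:
        return self.frame.loc[self.frame["role"] == role, "pu_id"].tolist()


def sweep_targets(tensor: AbundanceTensor, pus: PlanningUnitTable, config: RunConfig,
                  targets=DEFAULT_TARGET_GRID) -> SweepResult:
    """Selection-frequency prioritisation at each target on pooled counts.

    Counts are pooled over every survey year; for each target fraction the
    number of PUs with IrSc at or above the configured threshold is recorded,
    together with the percent marginal increase between consecutive targets.
    """
    targets = [Fraction(str(t)) if not isinstance(t, Fraction) else t for t in targets]
    if any(t2 <= t1 for t1, t2 in zip(targets, targets[1:])):
        raise ValidationError("target grid must be strictly increasing")
    rows = []
    results = {}
    for p in targets:
        instance = ProblemInstance.from_tensor(tensor, pus, p)
        res = selection_frequency(instance, config.with_target(p))
        results[p] = res
        rows.append({"target": float(p), "n_pus": res.count_at(config.irsc_threshold)})
    frame = pd.DataFrame(rows)
    increases = marginal_increase(frame["n_pus"].tolist())
    frame["pct_increase"] = [np.nan] + increases
    return SweepResult(frame=frame, threshold=config.irsc_threshold, results=results)


def marginal_increase(counts) -> list:
    """Percent increase between consecutive counts, rounded to integer percent.

    ``100 * (n_{k+1} - n_k) / n_k`` for each consecutive pair.  A zero
    denominator makes that increment undefined; it is returned as NaN with a
    warning rather than raising, since later increments remain meaningful.
    """
    counts = list(counts)
    if any(c < 0 for c in counts):
        raise ValidationError("counts must be nonnegative")
    out = []
    for prev, nxt in zip(counts, counts[1:]):
        if prev == 0:
            warnings.warn("marginal increase undefined after a zero count", stacklevel=2)
            out.append(float("nan"))
        else:
            out.append(int(round(100.0 * (nxt - prev) / prev)))
    return out


def annual_prioritisation(tensor: AbundanceTensor, pus: PlanningUnitTable,
                          config: RunConfig) -> dict:
    """Independent selection-frequency prioritisation for every survey year.

    Returns ``{year: IrreplaceabilityResult}``; a year with no counts yields
    zero targets, an empty solution and an all-zero IrSc vector.  Every year
    reuses the same base seed, so two years with identical counts get
    identical IrSc vectors.
    """
    if not tensor.years:
        raise ValidationError("tensor has no survey years")
    out = {}
    for year in tensor.years:
        instance = ProblemInstance.from_tensor(tensor, pus, config.target_fraction, year=year)
        out[year] = selection_frequency(instance, config)
    return out


def annual_counts(results: dict, threshold: float = 0.6) -> pd.Series:
    """Number of PUs with IrSc >= threshold, per year."""
    return pd.Series(
        {year: res.count_at(threshold) for year, res in results.items()}, name="n_pus"
    )


def classify_years(covariates: CovariateSeries, q_low: float = 0.25,
                   q_high: float = 0.75) -> PhaseAssignment:
    """Label years dry / normal / wet from total-flow quantiles.

    Dry years fall strictly below the ``q_low`` flow quantile and wet years
    strictly above the ``q_high`` quantile (type-7 linear interpolation, the
    numpy default).  Constant flow therefore yields all-normal years.
    """
    years = covariates.years
    if len(years) < 4:
        raise ValidationError("phase classification needs at least 4 years")
    flow = covariates.flow_for_years(years)
    lo = float(np.quantile(flow, q_low))
    hi = float(np.quantile(flow, q_high))
    phase = np.where(flow < lo, "dry", np.where(flow > hi, "wet", "normal"))
    frame = pd.DataFrame({"year": years, "flow": flow, "phase": phase})
    return PhaseAssignment(frame=frame, cutpoints=(lo, hi))


def phase_mean_irsc(annual: dict, phases: PhaseAssignment) -> pd.DataFrame:
    """Mean per-PU IrSc over each phase's years (columns dry/normal/wet)."""
    irsc = pd.DataFrame({year: res.irsc() for year, res in annual.items()})
    cols = {}
    for phase in ("dry", "normal", "wet"):
        years = [y for y in phases.years(phase) if y in irsc.columns]
        cols[phase] = irsc[years].mean(axis=1) if years else pd.Series(np.nan, index=irsc.index)
    return pd.DataFrame(cols)


def functional_classification(annual: dict, phases: PhaseAssignment,
                              threshold: float = 0.6) -> FunctionalClassification:
    """Classify PUs as refugia, breeding habitat, both, or neither.

    A PU is a refuge when its mean IrSc across dry years reaches the
    threshold but its wet-year mean does not; breeding habitat in the
    converse case; "both" when both phase means reach the threshold.
    """
    for phase in ("dry", "wet"):
        if not any(y in annual for y in phases.years(phase)):
            raise ValidationError(f"no {phase} years available for functional classification")
    means = phase_mean_irsc(annual, phases)
    dry, wet = means["dry"], means["wet"]
    role = np.where(
        (dry >= threshold) & (wet >= threshold), "both",
        np.where(dry >= threshold, "refuge",
                 np.where(wet >= threshold, "breeding", "neither")),
    )
    frame = pd.DataFrame(
        {
            "pu_id": means.index,
            "dry_mean": dry.to_numpy(),
            "wet_mean": wet.to_numpy(),
            "role": role,
        }
    ).reset_index(drop=True)
    return FunctionalClassification(frame=frame, threshold=threshold)


def type_irreplaceability(irsc: pd.Series, pus: PlanningUnitTable,
                          types=None) -> pd.Series:
    """Area-corrected irreplaceability proportion per wetland type.

    score_type = (sum of IrSc over that type's PUs) / (total area of the
    type); proportions normalise the scores to sum to 1.  An all-zero IrSc
    vector leaves the proportions undefined (NaN, with a warning); a type
    with zero total area but nonzero summed IrSc is an error.
    """
    merged = pus.frame[["pu_id", "wetland_type", "area"]].merge(
        irsc.rename("irsc"), left_on="pu_id", right_index=True, how="left"
    )
    if merged["irsc"].isna().any():
        raise ValidationError("every typed PU needs an IrSc value")
    if types is not None:
        merged = merged[merged["wetland_type"].isin(list(types))]
    grouped = merged.groupby("wetland_type")
    summed = grouped["irsc"].sum()
    areas = grouped["area"].sum()
    bad = summed.index[(areas == 0) & (summed > 0)]
    if len(bad):
        raise ValidationError(f"wetland type(s) {list(bad)} have zero area but nonzero IrSc")
    with np.errstate(invalid="ignore", divide="ignore"):
        score = summed / areas.replace(0, np.nan)
    score = score.fillna(0.0)
    total = score.sum()
    if total == 0:
        warnings.warn("all IrSc are zero; type proportions undefined", stacklevel=2)
        return score * np.nan
    return score / total


def type_phase_table(dry_irsc: pd.Series, wet_irsc: pd.Series,
                     pus: PlanningUnitTable, types=None) -> pd.DataFrame:
    """Type x phase table of area-corrected scores scaled to summed IrSc.

    Each phase's type proportions are rescaled so the column totals equal
    that phase's total summed IrSc, giving the (non-integer) table the
    chi-squared contrast is applied to.
    """
    cols = {}
    for phase, irsc in (("dry", dry_irsc), ("wet", wet_irsc)):
        props = type_irreplaceability(irsc, pus, types=types)
        cols[phase] = props * float(irsc.sum())
    return pd.DataFrame(cols)


def pearson_chisq(observed) -> tuple[float, int, float]:
    """Pearson's chi-squared test of independence on a two-way table.

    Expected counts come from the row/column margins; the statistic is
    ``sum (O - E)^2 / E`` with ``(r - 1)(c - 1)`` degrees of freedom and an
    upper-tail p-value.  Nonnegative non-integer entries are accepted.
    """
    table = np.asarray(observed, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValidationError("chi-squared needs a table with >= 2 rows and >= 2 columns")
    if (table < 0).any():
        raise ValidationError("chi-squared table entries must be nonnegative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValidationError("chi-squared table has a zero row or column margin")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)
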