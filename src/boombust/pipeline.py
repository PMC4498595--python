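"""End-to-end pipeline: simulate (optional) -> sweep -> annual -> phases ->
functional roles -> wetland-type chi-squared -> drivers BMA.

Every stage draws its seed from the master seed by a fixed counter scheme
(stage k uses ``seed + 100_000 * k``; annealing run r within a stage uses
``stage_seed + r``), recorded in the report, so a rerun with the same config
and seed is numerically identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import analysis, bma, io, synthetic
from .datamodel import ConfigError, CovariateSeries, RunConfig

__all__ = ["PipelineReport", "run_pipeline", "pu_driver_bma"]

_STAGE_SEEDS = {"sweep": 1, "annual": 2, "bma": 3}


def _stage_seed(config: RunConfig, stage: str) -> int:
    return (config.seed + 100_000 * _STAGE_SEEDS[stage]) % (2**31)


@dataclass
class PipelineReport:
    """All stage outputs plus the config echo and seed registry."""

    config: RunConfig
    seeds: dict
    sweep: analysis.SweepResult | None
    annual: dict
    annual_n_pus: pd.Series
    phases: analysis.PhaseAssignment | None
    roles: analysis.FunctionalClassification | None
    type_table: pd.DataFrame | None
    chisq: tuple | None
    bma_pu_counts: bma.ModelPosterior | None
    bma_pu_flow: pd.DataFrame | None = None
    truth: synthetic.GroundTruth | None = None

    def to_json(self) -> str:
        doc = {
            "seed": self.config.seed,
            "stage_seeds": self.seeds,
            "target_fraction": float(self.config.target_fraction),
            "n_solutions": self.config.n_solutions,
            "sweep": None if self.sweep is None else self.sweep.frame.to_dict("records"),
            "annual_n_pus": {str(k): int(v) for k, v in self.annual_n_pus.items()},
            "phases": None if self.phases is None else self.phases.frame.to_dict("records"),
            "roles": None if self.roles is None else self.roles.frame.to_dict("records"),
            "chisq": None if self.chisq is None else {
                "statistic": self.chisq[0], "df": self.chisq[1], "p": self.chisq[2]
            },
            "bma": None if self.bma_pu_counts is None
            else self.bma_pu_counts.summary.to_dict("records"),
            "bma_pu_flow": None if self.bma_pu_flow is None
            else self.bma_pu_flow.to_dict("records"),
        }
        return json.dumps(doc, indent=2, default=float)


def _covariate_design(covariates: CovariateSeries, years, predictors=None) -> pd.DataFrame:
    frame = covariates.frame.set_index("year").loc[list(years)]
    X = pd.DataFrame(
        {
            "flow_mdb": frame["flow_total"].to_numpy(),
            "year": np.asarray(years, dtype=float),
            **{c: frame[c].to_numpy() for c in covariates.rain_columns},
            "soi": frame["soi"].to_numpy(),
        }
    )
    return X if predictors is None else X[list(predictors)]


def pu_driver_bma(annual: dict, covariates: CovariateSeries,
                  predictors=("flow_mdb", "year", "soi"),
                  min_years: int = 5, occam_odds: float = 20.0) -> pd.DataFrame:
    """Per-PU drivers analysis: Poisson BMA of selection counts on covariates.

    A PU's response is its integer selection count (IrSc x R) per year;
    only PUs with nonzero IrSc in at least ``min_years`` years are analysed.
    The default predictor set is deliberately small (flow, year, climate
    index: 8 submodels per PU); pass more columns for the full enumeration.
    Returns one row per analysed PU with the flow inclusion probability and
    model-averaged flow coefficient.
    """
    years = sorted(annual)
    irsc = pd.DataFrame({y: annual[y].irsc() for y in years})
    R = annual[years[0]].n_solutions
    keep = irsc.index[(irsc > 0).sum(axis=1) >= min_years]
    X = _covariate_design(covariates, years, predictors)
    rows = []
    for pu in keep:
        counts = np.rint(irsc.loc[pu].to_numpy() * R)
        dm = bma.DesignMatrix(y=counts, X=X, family="poisson")
        dm = bma.scale_predictors(dm, log_columns=("flow_mdb",))
        post = bma.bma_average(dm, occam_odds=occam_odds)
        rows.append(
            {
                "pu_id": pu,
                "pp_flow": post.pp()["flow_mdb"],
                "beta_flow": post.beta()["flow_mdb"],
                "pseudo_r2": post.pseudo_r2,
            }
        )
    return pd.DataFrame(rows, columns=["pu_id", "pp_flow", "beta_flow", "pseudo_r2"])


def _load_inputs(extra: dict, config: RunConfig):
    sim = extra.get("simulate")
    inputs = extra.get("inputs")
    if sim:
        params = synthetic.preset(sim.get("preset", "demo"), seed=config.seed)
        scenario = synthetic.simulate_scenario(params)
        return scenario.pus, scenario.tensor, scenario.covariates, scenario.truth
    if not inputs:
        raise ConfigError("config needs either an 'inputs' or a 'simulate' section")
    pus = io.read_pu_table_csv(inputs["pu_table"])
    tensor = io.read_tensor_csv(inputs["tensor"])
    tensor.validate_against(pus)
    covariates = None
    if "covariates" in inputs:
        covariates = io.read_covariates_csv(inputs["covariates"])
    return pus, tensor, covariates, None


def run_pipeline(config: RunConfig, extra: dict, out_dir=None,
                 do_sweep: bool = True, do_bma: bool = True) -> PipelineReport:
    """Run the full analysis; write CSV outputs when ``out_dir`` is given."""
    pus, tensor, covariates, truth = _load_inputs(extra, config)
    seeds = {stage: _stage_seed(config, stage) for stage in _STAGE_SEEDS}
    if do_bma and covariates is None:
        raise ConfigError("drivers BMA requires a covariate series in the inputs")

    sweep = None
    if do_sweep:
        sweep = analysis.sweep_targets(
            tensor, pus, config.with_seed(seeds["sweep"])
        )

    annual = analysis.annual_prioritisation(
        tensor, pus, config.with_seed(seeds["annual"])
    )
    n_pus = analysis.annual_counts(annual, config.irsc_threshold)

    phases = roles = type_table = chisq = None
    if covariates is not None:
        phases = analysis.classify_years(covariates, config.q_low, config.q_high)
        if phases.years("dry") and phases.years("wet"):
            roles = analysis.functional_classification(
                annual, phases, config.irsc_threshold
            )
            means = analysis.phase_mean_irsc(annual, phases)
            natural = ("estuarine", "lacustrine", "palustrine", "riverine")
            present = [
                t for t in natural
                if (pus.frame["wetland_type"] == t).any()
            ]
            if len(present) >= 2:
                type_table = analysis.type_phase_table(
                    means["dry"], means["wet"], pus, types=present
                )
                if (type_table.sum(axis=0) > 0).all() and (type_table.sum(axis=1) > 0).all():
                    chisq = analysis.pearson_chisq(type_table.to_numpy())

    posterior = pu_flow = None
    if do_bma:
        years = [y for y in tensor.years if y in covariates.years]
        X = _covariate_design(covariates, years)
        y = n_pus.loc[years].to_numpy(dtype=float)
        dm = bma.DesignMatrix(y=y, X=X, family="gaussian")
        dm = bma.scale_predictors(dm, log_columns=("flow_mdb",))
        retained, _ = bma.vif_screen(dm, threshold=5.0)
        posterior = bma.bma_average(dm.subset(retained))
        pu_flow = pu_driver_bma(annual, covariates)

    report = PipelineReport(
        config=config, seeds=seeds, sweep=sweep, annual=annual,
        annual_n_pus=n_pus, phases=phases, roles=roles,
        type_table=type_table, chisq=chisq, bma_pu_counts=posterior,
        bma_pu_flow=pu_flow, truth=truth,
    )
    if out_dir is not None:
        _write_outputs(report, Path(out_dir))
    return report


def _write_outputs(report: PipelineReport, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    if report.sweep is not None:
        report.sweep.frame.to_csv(out_dir / "sweep.csv", index=False)
    report.annual_n_pus.rename_axis("year").to_frame().to_csv(out_dir / "annual.csv")
    for year, res in report.annual.items():
        res.frame.to_csv(out_dir / f"irsc_{year}.csv", index=False)
    if report.roles is not None:
        report.roles.frame.to_csv(out_dir / "roles.csv", index=False)
    if report.type_table is not None:
        report.type_table.rename_axis("wetland_type").to_csv(out_dir / "type_scores.csv")
    if report.bma_pu_counts is not None:
        report.bma_pu_counts.summary.to_csv(out_dir / "bma_summary.csv", index=False)
        report.bma_pu_counts.models.to_csv(out_dir / "bma_models.csv", index=False)
    if report.bma_pu_flow is not None:
        report.bma_pu_flow.to_csv(out_dir / "bma_pu_flow.csv", index=False)
    (out_dir / "report.json").write_text(report.to_json())
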