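"""Readers and writers: the Marxan file dialect, long-format CSV tensors,
covariate CSV, YAML run configuration, and grid-cell -> wetland aggregation.

The Marxan dialect is the classic triplet of delimited tables with header
rows: ``pu`` (id, cost, status), ``spec`` (id, target, spf, name) and
``puvspr`` (species, pu, amount).  Comma- and tab-delimited files are both
accepted on read; writes are comma-delimited with deterministic row order
(pu ascending; puvspr by pu then species) so outputs are byte-stable.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .datamodel import (
    AbundanceTensor,
    ConfigError,
    CovariateSeries,
    FormatError,
    PlanningUnitTable,
    RunConfig,
    ValidationError,
)

__all__ = [
    "read_marxan_dataset",
    "write_marxan_dataset",
    "read_tensor_csv",
    "write_tensor_csv",
    "read_covariates_csv",
    "write_covariates_csv",
    "read_pu_table_csv",
    "write_pu_table_csv",
    "aggregate_cells",
    "load_config",
    "dump_config",
    "setup_run_log",
]

log = logging.getLogger("boombust")


def _read_delimited(path, required: list[str], what: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{what}: file not found: {path}")
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    frame = pd.read_csv(path, sep=sep)
    frame.columns = [str(c).strip().lower() for c in frame.columns]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(f"{what} ({path.name}): missing required column(s) {missing}")
    return frame


def read_marxan_dataset(pu_path, spec_path, puvspr_path):
    """Read a Marxan pu/spec/puvspr triplet.

    Returns ``(PlanningUnitTable, species target DataFrame, AbundanceTensor)``
    where the tensor is a single-scenario slice (all records carry year 0).
    Unknown columns (e.g. ``status``) are preserved as opaque attributes of
    the returned frames; the solver ignores them.
    """
    pu = _read_delimited(pu_path, ["id", "cost"], "pu table")
    spec = _read_delimited(spec_path, ["id"], "spec table")
    puvspr = _read_delimited(puvspr_path, ["species", "pu", "amount"], "puvspr table")

    neg = puvspr.index[pd.to_numeric(puvspr["amount"]) < 0]
    if len(neg):
        raise ValidationError(
            f"puvspr ({Path(puvspr_path).name}): negative amount at record index {neg[0]}"
        )

    pu_frame = pu.rename(columns={"id": "pu_id"})
    pu_table = PlanningUnitTable(pu_frame)

    tensor = AbundanceTensor(
        pd.DataFrame(
            {
                "species_id": puvspr["species"],
                "pu_id": puvspr["pu"],
                "year": 0,
                "count": puvspr["amount"],
            }
        )
    )
    tensor.validate_against(pu_table)
    return pu_table, spec, tensor


def write_marxan_dataset(pus: PlanningUnitTable, targets: pd.DataFrame,
                         tensor: AbundanceTensor, out_dir) -> dict[str, Path]:
    """Write the Marxan triplet for a single-scenario tensor slice.

    ``targets`` needs at least an ``id`` column (one row per species);
    ``target`` and ``spf`` columns are passed through if present.  Non-integer
    amounts are permitted but warned about, since survey counts are integers.
    """
    if len(set(tensor.frame["year"])) > 1:
        raise ValidationError("Marxan files are per-scenario: tensor must hold a single year")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    pu_out = pus.frame.rename(columns={"pu_id": "id"}).sort_values("id")
    if "status" not in pu_out.columns:
        pu_out["status"] = 0
    pu_cols = ["id", "cost", "status"] + [
        c for c in pu_out.columns if c not in ("id", "cost", "status")
    ]
    pu_path = out_dir / "pu.dat"
    pu_out[pu_cols].to_csv(pu_path, index=False)

    spec_out = targets.sort_values("id")
    spec_path = out_dir / "spec.dat"
    spec_out.to_csv(spec_path, index=False)

    amounts = tensor.frame[["species_id", "pu_id", "count"]].rename(
        columns={"species_id": "species", "pu_id": "pu", "count": "amount"}
    )
    if not np.all(amounts["amount"].to_numpy(dtype=float) % 1 == 0):
        warnings.warn("puvspr amounts are not all integers; counts expected", stacklevel=2)
    amounts = amounts.sort_values(["pu", "species"])
    puvspr_path = out_dir / "puvspr.dat"
    amounts.to_csv(puvspr_path, index=False)

    return {"pu": pu_path, "spec": spec_path, "puvspr": puvspr_path}


def read_tensor_csv(path) -> AbundanceTensor:
    frame = _read_delimited(path, ["species_id", "pu_id", "year", "count"], "abundance tensor")
    return AbundanceTensor(frame)


def write_tensor_csv(tensor: AbundanceTensor, path) -> Path:
    path = Path(path)
    out = tensor.frame.sort_values(["year", "species_id", "pu_id"])
    out.to_csv(path, index=False)
    return path


def read_covariates_csv(path) -> CovariateSeries:
    frame = _read_delimited(path, ["year", "flow_total"], "covariate series")
    return CovariateSeries(frame)


def write_covariates_csv(cov: CovariateSeries, path) -> Path:
    path = Path(path)
    cov.frame.to_csv(path, index=False)
    return path


def read_pu_table_csv(path) -> PlanningUnitTable:
    frame = _read_delimited(path, ["pu_id"], "planning-unit table")
    return PlanningUnitTable(frame)


def write_pu_table_csv(pus: PlanningUnitTable, path) -> Path:
    path = Path(path)
    pus.frame.sort_values("pu_id").to_csv(path, index=False)
    return path


def aggregate_cells(cell_table: pd.DataFrame, cell_counts: pd.DataFrame):
    """Merge survey grid cells into wetland-complex planning units.

    All cells sharing a ``wetland_id`` collapse into one PU whose counts and
    areas are sums; cells with no mapped wetland (null ``wetland_id``) become
    singleton PUs under their own cell id — the treatment given to small
    unmapped waterbodies such as farm dams.  The merged PU takes the mapped
    wetland's type.

    Parameters
    ----------
    cell_table
        Columns ``cell_id``, ``wetland_id`` (nullable), ``area``,
        ``wetland_type``; optionally ``cost``.
    cell_counts
        Long format: ``species_id``, ``cell_id``, ``year``, ``count``.

    Returns
    -------
    (PlanningUnitTable, AbundanceTensor)
    """
    cells = cell_table.copy()
    if cells["cell_id"].duplicated().any():
        dupes = cells.loc[cells["cell_id"].duplicated(), "cell_id"].tolist()
        raise ValidationError(f"cell mapped more than once (mapping must be a function): {dupes}")
    if "cost" not in cells.columns:
        cells["cost"] = 1.0

    mapped = cells["wetland_id"].notna()
    cells["pu_id"] = np.where(mapped, cells["wetland_id"], cells["cell_id"])

    grouped = cells.groupby("pu_id", sort=True)
    pu_frame = grouped.agg(
        cost=("cost", "first"),
        wetland_type=("wetland_type", "first"),
        area=("area", "sum"),
    ).reset_index()
    # a merged PU keeps its wetland id; singletons have none
    wid = grouped["wetland_id"].first()
    pu_frame["wetland_id"] = pu_frame["pu_id"].map(wid)
    pu_table = PlanningUnitTable(pu_frame)

    cell_to_pu = dict(zip(cells["cell_id"], cells["pu_id"]))
    unknown = set(cell_counts["cell_id"]) - set(cell_to_pu)
    if unknown:
        raise ValidationError(f"counts reference unknown cell_id(s): {sorted(unknown)}")
    counts = cell_counts.copy()
    counts["pu_id"] = counts["cell_id"].map(cell_to_pu)
    agg = (
        counts.groupby(["species_id", "pu_id", "year"], sort=True)["count"]
        .sum()
        .reset_index()
    )
    tensor = AbundanceTensor(agg)
    tensor.validate_against(pu_table)
    return pu_table, tensor


_CONFIG_KEYS = {
    "target_fraction", "n_solutions", "iterations", "spf", "cooling_floor",
    "seed", "irsc_threshold", "q_low", "q_high",
}


def load_config(path) -> tuple[RunConfig, dict]:
    """Load a YAML run configuration.

    The ``run`` section maps onto :class:`RunConfig`; every other top-level
    section (``inputs``, ``simulate``, ``bma`` ...) is returned verbatim as a
    dict for the pipeline to interpret.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    run = raw.get("run", {}) or {}
    unknown = set(run) - _CONFIG_KEYS
    if unknown:
        raise ConfigError(f"unknown run config key(s): {sorted(unknown)}")
    config = RunConfig(**run)
    extra = {k: v for k, v in raw.items() if k != "run"}
    return config, extra


def dump_config(config: RunConfig, extra: Mapping | None = None) -> str:
    run = {
        "target_fraction": str(config.target_fraction),
        "n_solutions": config.n_solutions,
        "iterations": config.iterations,
        "spf": config.spf,
        "cooling_floor": config.cooling_floor,
        "seed": config.seed,
        "irsc_threshold": config.irsc_threshold,
        "q_low": config.q_low,
        "q_high": config.q_high,
    }
    doc = {"run": run}
    if extra:
        doc.update(dict(extra))
    return yaml.safe_dump(doc, sort_keys=False)


def setup_run_log(out_dir, config: RunConfig, level: str = "INFO") -> Path:
    """Start a run log that echoes the seed and full configuration."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.setLevel(getattr(logging, level.upper()))
    log.addHandler(handler)
    log.info("run config:\n%s", dump_config(config))
    return log_path
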