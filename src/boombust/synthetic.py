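"""Synthetic boom-bust waterbird scenarios with known ground truth.

The generator emulates a dryland-river survey record: an AR(1) log-flow
series coupled to a climate index drives species totals up in wet (boom)
years and down in dry (bust) years, while per-PU habitat weights decide
where the birds sit.  Each PU carries a refuge weight ``r_i`` (water, and
hence birds, in every year — dominant in dry years) and a flood weight
``f_i`` that activates only when standardized log flow is positive
(floodplain habitat hosting wet-year breeding booms).  Counts are drawn
negative-binomially around the expected cell means, reflecting the strong
overdispersion of aerial survey counts.

Designated PU roles (refuge / breeding / both / neither) are assigned from
the weights through recorded cutoffs, so downstream classification can be
scored against an unambiguous truth table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datamodel import (
    AbundanceTensor,
    ConfigError,
    CovariateSeries,
    PlanningUnitTable,
)

__all__ = [
    "ScenarioParams",
    "GroundTruth",
    "SimulatedScenario",
    "simulate_covariates",
    "simulate_counts",
    "simulate_scenario",
    "habitat_shares",
    "make_fixture",
    "make_phase_fixture",
    "PRESETS",
    "preset",
]

#: Rainfall regions tracked alongside basin flow: (mean mm/yr, log-scale
#: correlation with standardized log flow).  In-basin rainfall couples
#: tightly to flow; remote northern/inland regions only weakly.
RAIN_REGIONS = {
    "mdb": (480.0, 0.70),
    "lake_eyre": (220.0, 0.30),
    "southeast": (650.0, 0.50),
    "east": (1100.0, 0.40),
    "north": (1500.0, 0.20),
    "south": (550.0, 0.45),
}

_DEFAULT_TYPE_MIX = {
    "palustrine": 0.45,
    "lacustrine": 0.25,
    "riverine": 0.15,
    "estuarine": 0.05,
    "reservoir": 0.10,
}


@dataclass(frozen=True)
class ScenarioParams:
    """Everything that defines a simulated boom-bust survey system."""

    n_species: int = 12
    n_pus: int = 60
    n_years: int = 30
    type_mix: dict = field(default_factory=lambda: dict(_DEFAULT_TYPE_MIX))
    # flow model: log flow_t = mu + phi*(log flow_{t-1} - mu) + beta_soi*soi_t + eps
    mu_log_flow: float = 9.0
    phi: float = 0.5
    sigma: float = 0.8
    beta_soi: float = 0.3
    soi_phi: float = 0.75
    rain_flow_corr: float = 0.6
    # species guilds: boom elasticity gamma_s and baseline total N_s
    gamma_range: tuple = (0.6, 1.4)
    baseline_abundance: float = 20_000.0
    baseline_sd_log: float = 1.0
    # habitat weights by designated role
    n_refuge: int = 8
    n_breeding: int = 8
    n_both: int = 2
    refuge_weight: float = 20.0
    flood_weight: float = 150.0
    low_weight: float = 1.0
    tiny_weight: float = 0.05
    weight_jitter_sd: float = 0.15
    # counts
    overdispersion: float | None = 5.0   # NB size k; None means Poisson
    first_year: int = 1983
    seed: int = 42

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ConfigError("innovation sd sigma must be >= 0")
        if not (0 <= self.phi < 1):
            raise ConfigError("AR(1) coefficient phi must lie in [0, 1)")
        if self.overdispersion is not None and self.overdispersion <= 0:
            raise ConfigError("overdispersion k must be > 0 (or None for Poisson)")
        if abs(sum(self.type_mix.values()) - 1.0) > 1e-9:
            raise ConfigError("wetland type mix proportions must sum to 1")
        if self.n_refuge + self.n_breeding + self.n_both > self.n_pus:
            raise ConfigError("designated roles exceed the number of PUs")


@dataclass(frozen=True)
class GroundTruth:
    """Designated PU roles and year phases, with the cutoffs that defined them."""

    roles: pd.DataFrame        # pu_id, r, f, role
    phases: pd.DataFrame       # year, z_flow, phase
    cutoffs: dict              # r/f role cutoffs and phase quantile cutpoints

    def role_ids(self, role: str) -> list:
        return self.roles.loc[self.roles["role"] == role, "pu_id"].tolist()


@dataclass(frozen=True)
class SimulatedScenario:
    params: ScenarioParams
    pus: PlanningUnitTable
    covariates: CovariateSeries
    tensor: AbundanceTensor
    truth: GroundTruth


def _years(params: ScenarioParams) -> np.ndarray:
    return np.arange(params.first_year, params.first_year + params.n_years)


def simulate_covariates(params: ScenarioParams, seed: int | None = None) -> CovariateSeries:
    """Simulate the annual covariate series (flow, rainfall by region, SOI).

    log flow follows the AR(1)-plus-climate-index recursion in
    :class:`ScenarioParams`; the SOI is itself a standardized AR(1); each
    rainfall region is lognormal around its mean with log-scale correlation
    ``rain_flow_corr`` to standardized log flow.  Fixed seed, identical output.
    """
    if params.n_years < 2:
        raise ConfigError("need at least 2 years to simulate covariates")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n = params.n_years

    soi = np.empty(n)
    soi[0] = rng.normal()
    innov_sd = np.sqrt(max(0.0, 1.0 - params.soi_phi**2))
    for t in range(1, n):
        soi[t] = params.soi_phi * soi[t - 1] + rng.normal(0.0, innov_sd)

    log_flow = np.empty(n)
    eps = rng.normal(0.0, params.sigma, size=n) if params.sigma > 0 else np.zeros(n)
    log_flow[0] = params.mu_log_flow + params.beta_soi * soi[0] + eps[0]
    for t in range(1, n):
        log_flow[t] = (
            params.mu_log_flow
            + params.phi * (log_flow[t - 1] - params.mu_log_flow)
            + params.beta_soi * soi[t]
            + eps[t]
        )

    sd = log_flow.std()
    z = (log_flow - log_flow.mean()) / (sd if sd > 0 else 1.0)
    data = {"year": _years(params), "flow_total": np.exp(log_flow)}
    for region, (mean, rho) in RAIN_REGIONS.items():
        # rain_flow_corr rescales the per-region table (0.6 leaves it as listed)
        rho = min(0.99, rho * params.rain_flow_corr / 0.6)
        eta = rng.normal(size=n)
        data[f"rain_{region}"] = mean * np.exp(0.35 * (rho * z + np.sqrt(1 - rho**2) * eta))
    data["soi"] = soi
    return CovariateSeries(pd.DataFrame(data))


def _assign_weights(params: ScenarioParams, rng: np.random.Generator):
    """Role-stratified refuge/flood weights with multiplicative jitter."""
    n = params.n_pus
    roles = np.array(["neither"] * n, dtype=object)
    order = rng.permutation(n)
    k = 0
    for role, count in (
        ("refuge", params.n_refuge),
        ("breeding", params.n_breeding),
        ("both", params.n_both),
    ):
        roles[order[k:k + count]] = role
        k += count

    def jitter(size):
        return np.exp(rng.normal(0.0, params.weight_jitter_sd, size=size))

    r = np.full(n, params.low_weight) * jitter(n)
    f = np.full(n, params.low_weight) * jitter(n)
    r[roles == "refuge"] = params.refuge_weight * jitter((roles == "refuge").sum())
    f[roles == "refuge"] = params.tiny_weight
    f[roles == "breeding"] = params.flood_weight * jitter((roles == "breeding").sum())
    r[roles == "breeding"] = params.tiny_weight
    r[roles == "both"] = params.refuge_weight * jitter((roles == "both").sum())
    f[roles == "both"] = params.flood_weight * jitter((roles == "both").sum())
    return r, f


def _roles_from_weights(r: np.ndarray, f: np.ndarray, cut_r: float, cut_f: float) -> np.ndarray:
    roles = np.where(
        (r >= cut_r) & (f >= cut_f), "both",
        np.where(r >= cut_r, "refuge", np.where(f >= cut_f, "breeding", "neither")),
    )
    return roles.astype(object)


def habitat_shares(r: np.ndarray, f: np.ndarray, z: np.ndarray) -> np.ndarray:
    """PU occupancy shares per year: w_{i,t} proportional to r_i + f_i * max(z_t, 0).

    The flood weight only acts in wet-signed years (z > 0).  Columns sum to 1.
    """
    w = r[:, None] + f[:, None] * np.maximum(z[None, :], 0.0)
    totals = w.sum(axis=0)
    if (totals <= 0).any():
        raise ConfigError("all PU habitat weights are zero in some year")
    return w / totals


def _pu_ids(n: int) -> list[str]:
    return [f"pu{i:04d}" for i in range(n)]


def _make_pu_table(params: ScenarioParams, rng: np.random.Generator) -> PlanningUnitTable:
    types = list(params.type_mix)
    probs = np.array([params.type_mix[t] for t in types])
    assigned = rng.choice(types, size=params.n_pus, p=probs / probs.sum())
    areas = np.round(np.exp(rng.normal(2.0, 1.0, size=params.n_pus)), 2)  # km^2, lognormal
    return PlanningUnitTable(
        pd.DataFrame(
            {
                "pu_id": _pu_ids(params.n_pus),
                "cost": 1.0,
                "wetland_id": pd.NA,
                "wetland_type": assigned,
                "area": areas,
            }
        )
    )


def simulate_counts(params: ScenarioParams, covariates: CovariateSeries,
                    seed: int | None = None) -> tuple[AbundanceTensor, GroundTruth]:
    """Draw the abundance tensor given a covariate series.

    Species totals: lambda_{s,t} = N_s * exp(gamma_s * z_t), z_t the
    standardized log flow.  Cell means are lambda * habitat share; counts are
    negative binomial with size ``overdispersion`` (Poisson when None).
    """
    if len(covariates.years) < params.n_years:
        raise ConfigError("covariate series does not cover the requested years")
    rng = np.random.default_rng((params.seed if seed is None else seed) + 1)
    years = _years(params)
    log_flow = np.log(covariates.flow_for_years(years))
    sd = log_flow.std()
    z = (log_flow - log_flow.mean()) / (sd if sd > 0 else 1.0)

    r, f = _assign_weights(params, rng)
    cut_r = float(np.sqrt(params.refuge_weight * params.low_weight))
    cut_f = float(np.sqrt(params.flood_weight * params.low_weight))
    roles = _roles_from_weights(r, f, cut_r, cut_f)
    shares = habitat_shares(r, f, z)                      # (n_pus, n_years)

    gammas = rng.uniform(*params.gamma_range, size=params.n_species)
    n_s = params.baseline_abundance * np.exp(
        rng.normal(0.0, params.baseline_sd_log, size=params.n_species)
    )
    lam = n_s[:, None] * np.exp(gammas[:, None] * z[None, :])   # (S, T)

    mean = lam[:, None, :] * shares[None, :, :]                 # (S, n_pus, T)
    if params.overdispersion is None or np.isinf(params.overdispersion):
        counts = rng.poisson(mean)
    else:
        k = params.overdispersion
        p = k / (k + np.where(mean > 0, mean, 1.0))
        counts = np.where(mean > 0, rng.negative_binomial(k, p), 0)

    species = [f"sp{s:03d}" for s in range(params.n_species)]
    pus = _pu_ids(params.n_pus)
    s_idx, i_idx, t_idx = np.nonzero(counts)
    frame = pd.DataFrame(
        {
            "species_id": np.array(species, dtype=object)[s_idx],
            "pu_id": np.array(pus, dtype=object)[i_idx],
            "year": years[t_idx],
            "count": counts[s_idx, i_idx, t_idx].astype(np.int64),
        }
    )
    tensor = AbundanceTensor(frame, species=tuple(species), years=tuple(years))

    q_low, q_high = np.quantile(z, 0.25), np.quantile(z, 0.75)
    phase = np.where(z < q_low, "dry", np.where(z > q_high, "wet", "normal"))
    truth = GroundTruth(
        roles=pd.DataFrame({"pu_id": pus, "r": r, "f": f, "role": roles}),
        phases=pd.DataFrame({"year": years, "z_flow": z, "phase": phase}),
        cutoffs={"cut_r": cut_r, "cut_f": cut_f,
                 "z_quantiles": (float(q_low), float(q_high))},
    )
    return tensor, truth


def simulate_scenario(params: ScenarioParams, seed: int | None = None) -> SimulatedScenario:
    """Covariates, PU table, abundance tensor and ground truth in one bundle."""
    seed = params.seed if seed is None else seed
    covariates = simulate_covariates(params, seed=seed)
    rng = np.random.default_rng(seed + 2)
    pus = _make_pu_table(params, rng)
    tensor, truth = simulate_counts(params, covariates, seed=seed)
    tensor.validate_against(pus)
    return SimulatedScenario(replace(params, seed=seed), pus, covariates, tensor, truth)


# ---------------------------------------------------------------------------
# deterministic worked fixture


def make_fixture() -> tuple[PlanningUnitTable, AbundanceTensor]:
    """The 4-PU x 3-species worked matrix used across the solver examples.

    ========  ===  ===  ===  ===
    species     A    B    C    D
    ========  ===  ===  ===  ===
    s1         90   10    0    0
    s2          0   10   90    0
    s3          0   80    0   20
    ========  ===  ===  ===  ===

    Each species totals 100.  At a 10% target {B} alone suffices (B holds
    >= 10 of every species); at 80% the unique optimum is {A, B, C}: without
    A species s1 tops out at 10 < 80, without C species s2 at 10 < 80, and
    without B species s3 at 20 < 80.  PU D carries 20 individuals of s3 only.
    """
    pus = PlanningUnitTable(
        pd.DataFrame(
            {
                "pu_id": ["A", "B", "C", "D"],
                "cost": 1.0,
                "wetland_id": pd.NA,
                "wetland_type": ["lacustrine", "palustrine", "riverine", "reservoir"],
                "area": [2.0, 4.0, 1.0, 3.0],
            }
        )
    )
    records = [
        ("s1", "A", 90), ("s1", "B", 10),
        ("s2", "B", 10), ("s2", "C", 90),
        ("s3", "B", 80), ("s3", "D", 20),
    ]
    frame = pd.DataFrame(records, columns=["species_id", "pu_id", "count"])
    frame["year"] = 2000
    tensor = AbundanceTensor(frame, species=("s1", "s2", "s3"), years=(2000,))
    tensor.validate_against(pus)
    return pus, tensor


def make_phase_fixture():
    """A 2-year wet/dry variant for functional-classification tests.

    In the dry year (2001) the birds sit on refuge PU A (plus B); in the wet
    year (2002) they shift to flood PU C (plus B).  At an 80% target the dry
    optimum is {A, B} and the wet optimum is {B, C}, making A a refuge,
    C a breeding PU, B both and D neither.
    """
    pus, _ = make_fixture()
    records = [
        # dry year
        ("s1", "A", 2001, 100),
        ("s2", "A", 2001, 50), ("s2", "B", 2001, 50),
        ("s3", "B", 2001, 100),
        # wet year
        ("s1", "C", 2002, 100),
        ("s2", "C", 2002, 50), ("s2", "B", 2002, 50),
        ("s3", "B", 2002, 100),
    ]
    frame = pd.DataFrame(records, columns=["species_id", "pu_id", "year", "count"])
    tensor = AbundanceTensor(frame, species=("s1", "s2", "s3"), years=(2001, 2002))
    tensor.validate_against(pus)
    return pus, tensor


# ---------------------------------------------------------------------------
# presets

PRESETS: dict[str, ScenarioParams] = {
    # everyday demonstration scenario
    "demo": ScenarioParams(),
    # strong refuge/flood contrast for ground-truth recovery checks
    "recovery": ScenarioParams(
        refuge_weight=20.0, flood_weight=150.0, low_weight=1.0,
        n_refuge=8, n_breeding=8, n_both=2, overdispersion=5.0, seed=42,
    ),
    # closer to the survey's footprint
    "large": ScenarioParams(n_species=50, n_pus=200, n_years=30, seed=42,
                            n_refuge=20, n_breeding=20, n_both=6),
}


def preset(name: str, seed: int | None = None) -> ScenarioParams:
    if name not in PRESETS:
        raise ConfigError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    params = PRESETS[name]
    return params if seed is None else replace(params, seed=int(seed))
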