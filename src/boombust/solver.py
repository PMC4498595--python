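"""Minimum-set reserve selection with per-species abundance targets.

Given a species x planning-unit count matrix ``a``, PU costs ``c`` and a
representation fraction ``p``, the minimum-set problem selects the cheapest
PU set S such that for every species s

    sum_{i in S} a_{s,i}  >=  T_s  =  p * sum_i a_{s,i}.

Four routes are provided:

* :func:`greedy_minset` — the classic fractional-coverage greedy heuristic
  with a reverse prune; also supplies the per-species baseline penalties.
* :func:`exact_minset` — exhaustive subset search (<= 20 PUs) returning one
  optimum plus *all* co-optimal sets; the oracle for tests.
* :func:`anneal_minset` — simulated annealing over single-PU flips with an
  adaptive initial temperature, geometric cooling, and a repair pass that
  guarantees a feasible, irredundant solution.
* :func:`selection_frequency` — R independent annealing solutions; the
  fraction of solutions containing each PU is its irreplaceability score
  (IrSc), in [0, 1].

Targets are held as exact rationals when the counts are integers, so a
target like 10% of 100 individuals is met by exactly 10 — never lost to
binary rounding at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit

from .datamodel import (
    AbundanceTensor,
    ConfigError,
    PlanningUnitTable,
    RunConfig,
    ValidationError,
    _as_fraction,
)

__all__ = [
    "ProblemInstance",
    "Solution",
    "IrreplaceabilityResult",
    "objective_value",
    "greedy_minset",
    "exact_minset",
    "anneal_minset",
    "selection_frequency",
    "classify_irsc",
    "IRSC_CLASSES",
]


# ---------------------------------------------------------------------------
# problem instance


@dataclass
class ProblemInstance:
    """One prioritisation scenario: counts, costs and derived targets."""

    species_ids: tuple
    pu_ids: tuple
    counts: np.ndarray          # (S, N), nonnegative
    costs: np.ndarray           # (N,), nonnegative
    fractions: tuple            # per-species target fraction, exact Fractions
    _base: np.ndarray | None = None

    @classmethod
    def from_matrix(cls, counts, costs=None, target_fraction=Fraction(4, 5),
                    species_ids=None, pu_ids=None) -> "ProblemInstance":
        counts = np.asarray(counts)
        if (counts < 0).any():
            raise ValidationError("counts must be nonnegative")
        S, N = counts.shape
        if costs is None:
            costs = np.ones(N)
        costs = np.asarray(costs, dtype=float)
        if (costs < 0).any():
            raise ValidationError("costs must be nonnegative")
        p = _as_fraction(target_fraction)
        if not (0 < p <= 1):
            raise ConfigError(f"target fraction must be in (0, 1], got {p}")
        species_ids = tuple(species_ids) if species_ids is not None else tuple(range(S))
        pu_ids = tuple(pu_ids) if pu_ids is not None else tuple(range(N))
        return cls(species_ids, pu_ids, counts, costs, (p,) * S)

    @classmethod
    def from_tensor(cls, tensor: AbundanceTensor, pus: PlanningUnitTable,
                    target_fraction, year=None) -> "ProblemInstance":
        counts = tensor.matrix(pus.pu_ids, year=year)
        return cls.from_matrix(
            counts, pus.costs, target_fraction,
            species_ids=tensor.species, pu_ids=pus.pu_ids,
        )

    # -- derived quantities ------------------------------------------------

    @property
    def n_species(self) -> int:
        return self.counts.shape[0]

    @property
    def n_pus(self) -> int:
        return self.counts.shape[1]

    @property
    def integral(self) -> bool:
        return np.issubdtype(self.counts.dtype, np.integer) or bool(
            np.all(self.counts == np.round(self.counts))
        )

    def targets_exact(self) -> list[Fraction]:
        """Per-species targets T_s = p_s * total_s, exact when counts are ints."""
        totals = self.counts.sum(axis=1)
        out = []
        for s in range(self.n_species):
            tot = int(totals[s]) if self.integral else totals[s]
            out.append(self.fractions[s] * Fraction(tot) if self.integral
                       else Fraction(float(self.fractions[s]) * tot))
        return out

    def targets_float(self) -> np.ndarray:
        return np.array([float(t) for t in self.targets_exact()])

    def held(self, selected: Sequence[int]) -> np.ndarray:
        """Per-species abundance captured by a set of PU *indices*."""
        idx = np.asarray(list(selected), dtype=np.int64)
        if len(idx) == 0:
            return np.zeros(self.n_species, dtype=self.counts.dtype)
        return self.counts[:, idx].sum(axis=1)

    def is_feasible(self, held: np.ndarray) -> bool:
        targets = self.targets_exact()
        for s in range(self.n_species):
            t = targets[s]
            if t == 0:
                continue
            h = Fraction(int(held[s])) if self.integral else Fraction(float(held[s]))
            if h < t:
                return False
        return True

    def shortfalls(self, held: np.ndarray) -> np.ndarray:
        return np.maximum(0.0, self.targets_float() - np.asarray(held, dtype=float))

    def base_costs(self) -> np.ndarray:
        """Greedy cost of meeting each species' target alone from the empty set.

        Used to scale shortfall penalties so an entirely-unmet species costs
        about what it would cost to cover it.  Computed once per instance.
        """
        if self._base is None:
            base = np.zeros(self.n_species)
            targets = self.targets_exact()
            for s in range(self.n_species):
                if targets[s] == 0:
                    continue
                safe_costs = np.where(self.costs > 0, self.costs, 1.0)
                free = np.where(self.counts[s] > 0, np.inf, 0.0)  # zero-cost PUs with counts
                rate = np.where(self.costs > 0, self.counts[s] / safe_costs, free)
                order = np.lexsort((np.arange(self.n_pus), -rate))
                acc = Fraction(0)
                cost = 0.0
                for j in order:
                    if self.counts[s, j] == 0:
                        break
                    acc += Fraction(int(self.counts[s, j])) if self.integral else Fraction(float(self.counts[s, j]))
                    cost += self.costs[j]
                    if acc >= targets[s]:
                        break
                base[s] = cost
            self._base = base
        return self._base

    def index_of(self, pu_ids: Sequence) -> list[int]:
        lookup = {p: i for i, p in enumerate(self.pu_ids)}
        return [lookup[p] for p in pu_ids]


@dataclass(frozen=True)
class Solution:
    """A selected PU set with its objective value and per-species shortfalls."""

    selected: tuple            # pu_ids, sorted
    objective: float
    shortfall: np.ndarray      # per species, aligned to instance.species_ids
    feasible: bool

    @property
    def size(self) -> int:
        return len(self.selected)


@dataclass(frozen=True)
class IrreplaceabilityResult:
    """Per-PU selection frequency over R independent solutions."""

    frame: pd.DataFrame        # pu_id, irsc, irsc_class
    n_solutions: int

    def irsc(self) -> pd.Series:
        return self.frame.set_index("pu_id")["irsc"]

    def count_at(self, threshold: float) -> int:
        return int((self.frame["irsc"] >= threshold).sum())


# ---------------------------------------------------------------------------
# objective


def objective_value(instance: ProblemInstance, selected_pu_ids, spf: float = 100.0) -> float:
    """Annealing objective: selected cost plus penalised target shortfalls.

    ``sum_{i in S} c_i + sum_s spf * (shortfall_s / T_s) * base_s`` where
    ``base_s`` is the greedy single-species coverage cost.  Species with a
    zero target contribute nothing.  Feasible sets score exactly their cost.
    """
    if spf < 0:
        raise ConfigError("species penalty factor must be >= 0")
    idx = instance.index_of(selected_pu_ids)
    held = instance.held(idx)
    targets = instance.targets_float()
    base = instance.base_costs()
    cost = float(instance.costs[idx].sum()) if idx else 0.0
    short = instance.shortfalls(held)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(targets > 0, short / np.where(targets > 0, targets, 1), 0.0)
    return cost + float(spf * (frac * base).sum())


# ---------------------------------------------------------------------------
# greedy heuristic


def _greedy_add(instance: ProblemInstance, selected: list[int], held: np.ndarray) -> list[int]:
    """Add PUs by largest summed fractional unmet-target gain per unit cost
    until feasible.  Ties break on lowest PU index (hence lowest pu_id for
    sorted instances).  Returns the addition order of the new PUs."""
    targets = instance.targets_exact()
    tf = instance.targets_float()
    active = tf > 0
    added = []
    in_set = np.zeros(instance.n_pus, dtype=bool)
    in_set[selected] = True
    held = held.astype(float).copy()
    while not instance.is_feasible(held):
        unmet = np.maximum(0.0, tf - held)
        gain = np.minimum(instance.counts.astype(float), unmet[:, None])
        with np.errstate(invalid="ignore", divide="ignore"):
            score = (gain[active] / tf[active, None]).sum(axis=0)
        score[in_set] = -np.inf
        cost = np.where(instance.costs > 0, instance.costs, 1e-12)
        score = score / cost
        j = int(np.argmax(score))  # argmax takes the first (lowest index) on ties
        if not np.isfinite(score[j]) or score[j] <= 0:
            raise ValidationError(
                "cannot reach targets: remaining planning units contribute nothing"
            )
        in_set[j] = True
        added.append(j)
        held += instance.counts[:, j]
    return added


def _prune(instance: ProblemInstance, selected: list[int], scan_order: list[int]) -> list[int]:
    """Drop PUs whose removal keeps every target met, scanning ``scan_order``.

    Removals only shrink holdings, so PUs that survive their scan stay
    non-removable afterwards: a single pass yields an irredundant set.
    """
    keep = set(selected)
    held = instance.held(list(keep)).astype(float)
    for j in scan_order:
        if j not in keep:
            continue
        trial = held - instance.counts[:, j]
        if instance.is_feasible(trial):
            keep.discard(j)
            held = trial
    return sorted(keep)


def _as_solution(instance: ProblemInstance, idx: list[int]) -> Solution:
    held = instance.held(idx)
    short = instance.shortfalls(held)
    feas = instance.is_feasible(held)
    obj = float(instance.costs[idx].sum()) if feas else objective_value(
        instance, [instance.pu_ids[j] for j in idx]
    )
    return Solution(
        selected=tuple(sorted(instance.pu_ids[j] for j in idx)),
        objective=obj,
        shortfall=short,
        feasible=feas,
    )


def greedy_minset(instance: ProblemInstance) -> Solution:
    """Greedy coverage heuristic with reverse prune; always feasible."""
    added = _greedy_add(instance, [], np.zeros(instance.n_species))
    pruned = _prune(instance, added, list(reversed(added)))
    return _as_solution(instance, pruned)


# ---------------------------------------------------------------------------
# exact oracle


def exact_minset(instance: ProblemInstance, max_pu: int = 20):
    """Exhaustive search over subsets of PUs holding any counts.

    Returns ``(Solution, co_optimal)`` where ``co_optimal`` is the list of
    *all* minimum-cost feasible PU-id frozensets.  PUs with no counts are
    never part of an optimum under nonnegative costs and are excluded.
    """
    nz = np.flatnonzero(instance.counts.sum(axis=0) > 0)
    M = len(nz)
    if M > max_pu:
        raise ValidationError(f"exact search limited to {max_pu} PUs with counts; got {M}")
    targets = instance.targets_exact()
    tf = np.array([float(t) for t in targets])
    active = tf > 0
    if not active.any():
        sol = _as_solution(instance, [])
        return sol, [frozenset()]
    counts_nz = instance.counts[:, nz].astype(np.int64 if instance.integral else float)
    costs_nz = instance.costs[nz]

    # exact integer feasibility: held * den >= num, per species
    nums = np.array([t.numerator for t in targets], dtype=object)
    dens = np.array([t.denominator for t in targets], dtype=object)

    best_cost = np.inf
    best_masks: list[int] = []
    chunk = 1 << 14
    total = 1 << M
    shifts = np.arange(M, dtype=np.uint64)
    for start in range(0, total, chunk):
        masks = np.arange(start, min(start + chunk, total), dtype=np.uint64)
        bits = ((masks[:, None] >> shifts) & 1).astype(np.int64)
        held = bits @ counts_nz.T               # (chunk, S)
        if instance.integral:
            ok = np.ones(len(masks), dtype=bool)
            for s in np.flatnonzero(active):
                ok &= held[:, s] * int(dens[s]) >= int(nums[s])
        else:
            ok = (held >= tf[None, :] - 1e-9).all(axis=1)
        if not ok.any():
            continue
        cost = bits @ costs_nz
        for m, c in zip(masks[ok], cost[ok]):
            if c < best_cost - 1e-9:
                best_cost = float(c)
                best_masks = [int(m)]
            elif abs(c - best_cost) <= 1e-9:
                best_masks.append(int(m))
    if not np.isfinite(best_cost):
        raise ValidationError("no feasible subset exists (inconsistent targets)")

    def mask_to_ids(mask: int) -> frozenset:
        return frozenset(instance.pu_ids[nz[b]] for b in range(M) if (mask >> b) & 1)

    co_optimal = sorted((mask_to_ids(m) for m in best_masks), key=lambda s: tuple(sorted(map(str, s))))
    first = sorted(co_optimal[0], key=str)
    sol = _as_solution(instance, instance.index_of(first))
    return sol, co_optimal


# ---------------------------------------------------------------------------
# simulated annealing


@njit(cache=True)
def _flip_delta(counts, costs, tgt, pen, sel, held, j):
    sign = -1.0 if sel[j] else 1.0
    d = sign * costs[j]
    for s in range(counts.shape[0]):
        a = counts[s, j]
        t = tgt[s]
        if a == 0.0 or t <= 0.0:
            continue
        sh_old = t - held[s]
        if sh_old < 0.0:
            sh_old = 0.0
        sh_new = t - (held[s] + sign * a)
        if sh_new < 0.0:
            sh_new = 0.0
        d += pen[s] * (sh_new - sh_old)
    return d


@njit(cache=True)
def _anneal_core(counts, costs, tgt, pen, iterations, cooling_floor, seed):
    """Single annealing trajectory over single-PU flip moves.

    Initial temperature is adaptive: the median |delta| of 100 random probe
    moves from the random start is accepted with probability ~0.8.  Geometric
    cooling multiplies the temperature down to ``cooling_floor`` of its
    initial value across ``iterations`` moves.
    """
    np.random.seed(seed)
    S, N = counts.shape
    sel = np.zeros(N, np.bool_)
    held = np.zeros(S)
    for j in range(N):
        if np.random.random() < 0.5:
            sel[j] = True
            for s in range(S):
                held[s] += counts[s, j]

    nprobe = 100
    deltas = np.empty(nprobe)
    for t in range(nprobe):
        j = np.random.randint(0, N)
        deltas[t] = abs(_flip_delta(counts, costs, tgt, pen, sel, held, j))
    med = np.median(deltas)
    if med <= 0.0:
        med = 1.0
    t0 = med / 0.2231435513142097  # -ln(0.8): accept the median uphill move w.p. 0.8
    cool = cooling_floor ** (1.0 / iterations)

    # current objective, tracked incrementally; the best state seen wins
    obj = 0.0
    for j in range(N):
        if sel[j]:
            obj += costs[j]
    for s in range(S):
        if tgt[s] > 0.0:
            sh = tgt[s] - held[s]
            if sh > 0.0:
                obj += pen[s] * sh
    best_obj = obj
    best_sel = sel.copy()

    temp = t0
    for it in range(iterations):
        j = np.random.randint(0, N)
        d = _flip_delta(counts, costs, tgt, pen, sel, held, j)
        if d <= 0.0 or np.random.random() < np.exp(-d / temp):
            if sel[j]:
                sel[j] = False
                for s in range(S):
                    held[s] -= counts[s, j]
            else:
                sel[j] = True
                for s in range(S):
                    held[s] += counts[s, j]
            obj += d
            if obj < best_obj - 1e-12:
                best_obj = obj
                best_sel = sel.copy()
        temp *= cool
    return best_sel


def anneal_minset(instance: ProblemInstance, config: RunConfig, seed: int | None = None) -> Solution:
    """Simulated annealing followed by a repair pass.

    The repair pass first greedily adds PUs until every target is met, then
    prunes redundant PUs (descending cost, then descending index), so the
    returned solution is always feasible and irredundant.  A fixed seed gives
    an identical trajectory and result.
    """
    if seed is None:
        seed = config.seed
    tf = instance.targets_float()
    if not (tf > 0).any():
        return _as_solution(instance, [])
    base = instance.base_costs()
    with np.errstate(divide="ignore", invalid="ignore"):
        pen = np.where(tf > 0, config.spf * base / np.where(tf > 0, tf, 1), 0.0)
    sel = _anneal_core(
        instance.counts.astype(np.float64),
        instance.costs.astype(np.float64),
        tf, pen,
        int(config.iterations), float(config.cooling_floor),
        int(seed) % (2**31),
    )
    chosen = list(np.flatnonzero(sel))
    held = instance.held(chosen)
    if not instance.is_feasible(held):
        chosen = sorted(chosen + _greedy_add(instance, chosen, held))
    scan = sorted(chosen, key=lambda j: (-instance.costs[j], -j))
    pruned = _prune(instance, chosen, scan)
    return _as_solution(instance, pruned)


def selection_frequency(instance: ProblemInstance, config: RunConfig) -> IrreplaceabilityResult:
    """Irreplaceability as selection frequency over R annealing solutions.

    Run r (r = 1..R) uses seed ``config.seed + r``; IrSc_i is the fraction
    of runs whose solution contains PU i.
    """
    R = config.n_solutions
    hits = np.zeros(instance.n_pus, dtype=np.int64)
    lookup = {p: i for i, p in enumerate(instance.pu_ids)}
    for r in range(1, R + 1):
        sol = anneal_minset(instance, config, seed=config.seed + r)
        for p in sol.selected:
            hits[lookup[p]] += 1
    irsc = hits / R
    frame = pd.DataFrame(
        {
            "pu_id": list(instance.pu_ids),
            "irsc": irsc,
            "irsc_class": [classify_irsc(x) for x in irsc],
        }
    )
    return IrreplaceabilityResult(frame=frame, n_solutions=R)


# ---------------------------------------------------------------------------
# IrSc classes

#: Left-closed, right-open irreplaceability bands, with IrSc = 1 its own class.
IRSC_CLASSES = (
    (0.0, 0.2, "very low"),
    (0.2, 0.4, "low"),
    (0.4, 0.6, "moderate"),
    (0.6, 0.8, "high"),
    (0.8, 1.0, "very high"),
)


def classify_irsc(irsc: float) -> str:
    """Map a selection frequency in [0, 1] to its reporting class."""
    if not (0 <= irsc <= 1):
        raise ValidationError(f"IrSc must lie in [0, 1], got {irsc}")
    if irsc == 1.0:
        return "completely irreplaceable"
    for lo, hi, label in IRSC_CLASSES:
        if lo <= irsc < hi:
            return label
    raise AssertionError("unreachable")
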