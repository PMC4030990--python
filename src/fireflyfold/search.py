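"""Firefly-guided population simulated annealing over pull moves.

The search keeps a population of N conformations, each on its own lattice.
After a greedy-descent initialisation, the member with the lowest energy is
elected S_best.  Search then proceeds in intervals of T shared steps:

* at every step, the elected member proposes one pull move judged by the
  Metropolis rule ``exp(-|dE| / T_n)`` under the geometric cooling schedule
  ``T_n = t0 * theta**n`` (one energy evaluation per step);
* every other member proposes one pull move judged by a *structural*
  objective: the mean absolute change, over the residues the move displaces,
  of their Euclidean distances to a frozen snapshot of S_best taken at the
  interval start (one structural evaluation per member per step);
* the shared step counter ``n`` advances once per population step, not per
  member;
* after each interval all members are energy-evaluated (the elected member's
  energy is already tracked, so N-1 evaluations) and S_best is re-elected,
  ties broken uniformly at random.

The run terminates when, within one interval, the elected member accepted no
annealing move *and* re-election returns the same member — or at a step cap.
Total objective-function work is reported as ``Oval``:

    Oval = sum_i Init_i + N * (k*T + T') + (k + 1) * (N - 1)

with ``Init_i`` the evaluations spent descending member i at initialisation,
``k`` the number of complete intervals before the final one and ``T'`` the
length of the final interval (T' = T unless a step cap cut it short).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .energy import EnergyModel
from .lattice import Conformation, LatticeSpec, random_self_avoiding_walk
from .moves import EvalCounter, apply_pull_move, descend_with_energy, enumerate_pull_moves

__all__ = [
    "AnnealParams",
    "FireflyParams",
    "SearchState",
    "IntervalRecord",
    "RunResult",
    "cooling_temperature",
    "sa_accept",
    "structural_distance",
    "structural_objective",
    "initialize_population",
    "run_search",
    "speed_up",
]

SOF_MODES = ("history", "distance")


@dataclass(frozen=True)
class AnnealParams:
    """Geometric cooling schedule T_n = t0 * theta**n."""

    t0: float = 4000.0
    theta: float = 0.9999

    def __post_init__(self) -> None:
        if self.t0 <= 0:
            raise ValueError("t0 must be > 0")
        if not (0.0 < self.theta < 1.0):
            raise ValueError("theta must be in (0, 1)")


@dataclass(frozen=True)
class FireflyParams:
    """Population settings: size N, re-election interval T, step cap, seed."""

    population_size: int = 8
    interval: int = 15
    max_steps: int = 5_000_000
    seed: int = 0
    sof_mode: str = "history"

    def __post_init__(self) -> None:
        if self.population_size < 1:
            raise ValueError("population_size must be >= 1")
        if self.interval < 1:
            raise ValueError("interval must be >= 1")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")
        if self.sof_mode not in SOF_MODES:
            raise ValueError(f"sof_mode must be one of {SOF_MODES}")


def cooling_temperature(n: int, params: AnnealParams) -> float:
    """Temperature at shared step ``n``; strictly decreasing in n."""
    if n < 0:
        raise ValueError("step index must be >= 0")
    return params.t0 * params.theta**n


def sa_accept(
    delta_e: float, n: int, params: AnnealParams, rng: np.random.Generator
) -> bool:
    """Metropolis decision at step ``n``.

    Improving and equal-energy proposals are always accepted (|dE| = 0 gives
    probability 1); worsening proposals are accepted with probability
    exp(-|dE| / T_n) via a single uniform draw from ``rng``.
    """
    if delta_e <= 0:
        return True
    t = cooling_temperature(n, params)
    return rng.random() < math.exp(-abs(delta_e) / t)


def structural_distance(a: Conformation, b: Conformation, t: int) -> float:
    """Euclidean distance between residue ``t``'s sites in ``a`` and ``b``.

    Raw lattice coordinates, no superposition: conformations are compared in
    the common origin-anchored frame they were generated in.
    """
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    if not (0 <= t < len(a)):
        raise ValueError(f"residue index {t} out of range")
    ax, ay, az = a.coords[t]
    bx, by, bz = b.coords[t]
    return math.sqrt((ax - bx) ** 2 + (ay - by) ** 2 + (az - bz) ** 2)


def structural_objective(
    before: Conformation,
    after: Conformation,
    best: Conformation,
    affected_range: tuple[int, int],
    previous_sof: float = math.inf,
    mode: str = "history",
) -> tuple[float, bool]:
    """Structural objective of a proposed move and its acceptance decision.

    The objective value is the mean, over the residues in ``affected_range``,
    of |d_before(t) - d_after(t)| where d(t) is the residue's distance to the
    S_best snapshot.  Under ``mode="history"`` the move is accepted iff the
    member's previously accepted objective value (+inf at interval start) is
    >= the proposed value; under ``mode="distance"`` iff the mean distance to
    the snapshot over the affected range does not increase.
    """
    j, k = affected_range
    if not (0 <= j <= k < len(before)):
        raise ValueError(f"inconsistent affected range {affected_range}")
    if len(before) != len(after) or len(before) != len(best):
        raise ValueError("conformations must have equal length")
    for t in range(len(before)):
        if not (j <= t <= k) and before.coords[t] != after.coords[t]:
            raise ValueError(
                f"residue {t} changed outside the declared affected range "
                f"{affected_range}"
            )
    m = k - j + 1
    sof = 0.0
    drift = 0.0
    for t in range(j, k + 1):
        d_before = structural_distance(before, best, t)
        d_after = structural_distance(after, best, t)
        sof += abs(d_before - d_after)
        drift += d_after - d_before
    sof /= m
    if mode == "history":
        accept = previous_sof >= sof
    elif mode == "distance":
        accept = drift <= 0.0
    else:
        raise ValueError(f"unknown sof mode {mode!r}")
    return sof, accept


@dataclass
class Counters:
    """Raw evaluation logs; ``oval_total`` is their sum."""

    init_evals: list[int] = field(default_factory=list)
    energy_evals: int = 0
    structural_evals: int = 0
    reelection_evals: int = 0

    @property
    def oval_total(self) -> int:
        return (
            sum(self.init_evals)
            + self.energy_evals
            + self.structural_evals
            + self.reelection_evals
        )

    def eq18(self, n_members: int, k: int, t_interval: int, t_prime: int) -> int:
        """Closed-form total: sum Init_i + N(kT + T') + (k+1)(N-1).

        A zero-step run (k = T' = 0) performs no re-election and costs only
        the initialisation evaluations.
        """
        steps = k * t_interval + t_prime
        if steps == 0:
            return sum(self.init_evals)
        return sum(self.init_evals) + n_members * steps + (k + 1) * (n_members - 1)


@dataclass
class SearchState:
    population: list[Conformation]
    energies: list[float]
    best_index: int
    s_best_snapshot: Conformation
    counters: Counters
    step: int = 0  # shared step counter n
    step_in_interval: int = 0
    member_sof: list[float] = field(default_factory=list)
    sa_accepts_in_interval: int = 0
    best_energy_trace: list[float] = field(default_factory=list)


@dataclass(frozen=True)
class IntervalRecord:
    index: int
    steps: int
    best_index: int
    best_energy: float
    sa_accepted: int
    oval_so_far: int


@dataclass
class RunResult:
    best_conformation: Conformation
    best_energy: float
    oval_total: int
    counters: Counters
    intervals: list[IntervalRecord]
    terminated_by: str  # "converged" | "max_steps"
    k: int
    t_prime: int

    @property
    def total_steps(self) -> int:
        return sum(r.steps for r in self.intervals)

    def summary(self) -> dict:
        """Machine-readable run summary with the Oval decomposition."""
        c = self.counters
        return {
            "best_energy": self.best_energy,
            "terminated_by": self.terminated_by,
            "k": self.k,
            "t_prime": self.t_prime,
            "oval_total": self.oval_total,
            "oval_decomposition": {
                "init": sum(c.init_evals),
                "init_per_member": list(c.init_evals),
                "energy": c.energy_evals,
                "structural": c.structural_evals,
                "reelection": c.reelection_evals,
            },
            "intervals": len(self.intervals),
        }


def _spawn_rngs(seed: int, n: int) -> tuple[np.random.Generator, list[np.random.Generator]]:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n + 1)
    master = np.random.default_rng(children[0])
    members = [np.random.default_rng(c) for c in children[1:]]
    return master, members


def _elect(
    energies: list[float], master: np.random.Generator
) -> int:
    e_min = min(energies)
    tied = [i for i, e in enumerate(energies) if e == e_min]
    if len(tied) == 1:
        return tied[0]
    return tied[int(master.integers(len(tied)))]


def initialize_population(
    sequence: str,
    lattice: LatticeSpec,
    model: EnergyModel,
    params: FireflyParams,
    rng_master: np.random.Generator | None = None,
    rng_members: list[np.random.Generator] | None = None,
) -> SearchState:
    """Random origin-anchored walks, greedily descended; S_best elected.

    Each member's descent evaluations are recorded as its Init_i.  The elected
    member is a minimum-energy member, ties broken uniformly at random.
    """
    model.validate_sequence(sequence)
    if rng_master is None or rng_members is None:
        rng_master, rng_members = _spawn_rngs(params.seed, params.population_size)
    population: list[Conformation] = []
    energies: list[float] = []
    init_evals: list[int] = []
    for i in range(params.population_size):
        counter = EvalCounter()
        walk = random_self_avoiding_walk(sequence, lattice, rng_members[i])
        conf, energy = descend_with_energy(walk, model, rng_members[i], counter)
        population.append(conf)
        energies.append(energy)
        init_evals.append(counter.n)
    best_index = _elect(energies, rng_master)
    counters = Counters(init_evals=init_evals)
    return SearchState(
        population=population,
        energies=energies,
        best_index=best_index,
        s_best_snapshot=population[best_index],
        counters=counters,
        member_sof=[math.inf] * params.population_size,
        best_energy_trace=[energies[best_index]],
    )


def _propose(conf: Conformation, rng: np.random.Generator):
    moves = enumerate_pull_moves(conf)
    if not moves:
        return None
    return moves[int(rng.integers(len(moves)))]


def run_search(
    sequence: str,
    lattice: LatticeSpec,
    model: EnergyModel,
    anneal: AnnealParams | None = None,
    ff: FireflyParams | None = None,
    stop_energy: float | None = None,
) -> RunResult:
    """Run the full firefly-guided population annealing search.

    Deterministic for fixed inputs and seed.  Returns the best conformation
    observed across all energy evaluations, the Oval accounting and a
    per-interval trace.

    ``stop_energy`` (off by default) ends the run as soon as the best observed
    energy reaches the given value.  This is a deliberate deviation from the
    two-condition termination rule, meant for cheap smoke runs against known
    reference minima; production runs leave it unset.
    """
    anneal = anneal or AnnealParams()
    ff = ff or FireflyParams()
    master, members = _spawn_rngs(ff.seed, ff.population_size)
    state = initialize_population(
        sequence, lattice, model, ff, rng_master=master, rng_members=members
    )
    n_pop = ff.population_size
    counters = state.counters

    global_best = state.population[state.best_index]
    global_best_e = state.energies[state.best_index]
    for conf, e in zip(state.population, state.energies):
        if e < global_best_e:
            global_best, global_best_e = conf, e

    intervals: list[IntervalRecord] = []
    terminated_by = "max_steps"
    k_complete = 0
    t_prime = 0

    if stop_energy is not None and global_best_e <= stop_energy:
        terminated_by = "target_reached"

    while state.step < ff.max_steps and terminated_by != "target_reached":
        # ---- one shared step -------------------------------------------------
        for i in range(n_pop):
            conf = state.population[i]
            move = _propose(conf, members[i])
            if i == state.best_index:
                counters.energy_evals += 1  # one energy evaluation per step
                if move is None:
                    continue
                cand = apply_pull_move(conf, move)
                e_new = model.evaluate(cand)
                delta = e_new - state.energies[i]
                if sa_accept(delta, state.step, anneal, members[i]):
                    state.population[i] = cand
                    state.energies[i] = e_new
                    state.sa_accepts_in_interval += 1
                    if e_new < global_best_e:
                        global_best, global_best_e = cand, e_new
            else:
                counters.structural_evals += 1  # one structural evaluation
                if move is None:
                    continue
                cand = apply_pull_move(conf, move)
                sof, accept = structural_objective(
                    conf,
                    cand,
                    state.s_best_snapshot,
                    move.affected_range,
                    previous_sof=state.member_sof[i],
                    mode=ff.sof_mode,
                )
                if accept:
                    state.population[i] = cand
                    state.member_sof[i] = sof
        state.step += 1
        state.step_in_interval += 1

        if stop_energy is not None and global_best_e <= stop_energy:
            terminated_by = "target_reached"
            break

        if state.step_in_interval < ff.interval:
            continue

        # ---- interval boundary: re-election ---------------------------------
        prev_best = state.best_index
        for i in range(n_pop):
            if i != state.best_index:
                state.energies[i] = model.evaluate(state.population[i])
                counters.reelection_evals += 1
                if state.energies[i] < global_best_e:
                    global_best = state.population[i]
                    global_best_e = state.energies[i]
        new_best = _elect(state.energies, master)
        converged = state.sa_accepts_in_interval == 0 and new_best == prev_best
        state.best_index = new_best
        state.s_best_snapshot = state.population[new_best]
        state.member_sof = [math.inf] * n_pop
        state.best_energy_trace.append(state.energies[new_best])
        intervals.append(
            IntervalRecord(
                index=len(intervals),
                steps=ff.interval,
                best_index=new_best,
                best_energy=state.energies[new_best],
                sa_accepted=state.sa_accepts_in_interval,
                oval_so_far=counters.oval_total,
            )
        )
        state.sa_accepts_in_interval = 0
        state.step_in_interval = 0
        if converged:
            terminated_by = "converged"
            break

    if state.step_in_interval > 0:
        # step cap hit mid-interval: close the partial interval with a final
        # re-election so the (k+1)(N-1) term of the accounting holds exactly.
        t_prime = state.step_in_interval
        k_complete = len(intervals)
        for i in range(n_pop):
            if i != state.best_index:
                state.energies[i] = model.evaluate(state.population[i])
                counters.reelection_evals += 1
                if state.energies[i] < global_best_e:
                    global_best = state.population[i]
                    global_best_e = state.energies[i]
        new_best = _elect(state.energies, master)
        state.best_index = new_best
        state.best_energy_trace.append(state.energies[new_best])
        intervals.append(
            IntervalRecord(
                index=len(intervals),
                steps=t_prime,
                best_index=new_best,
                best_energy=state.energies[new_best],
                sa_accepted=state.sa_accepts_in_interval,
                oval_so_far=counters.oval_total,
            )
        )
    elif intervals:
        # run ended exactly at a boundary: the last full interval is the T'
        # interval (T' = T), the k earlier ones are the complete count.
        t_prime = ff.interval
        k_complete = len(intervals) - 1
    else:
        # zero-step run (e.g. a target energy already met at initialisation);
        # outside the closed-form accounting's domain, counters still exact.
        t_prime = 0
        k_complete = 0

    return RunResult(
        best_conformation=global_best,
        best_energy=global_best_e,
        oval_total=counters.oval_total,
        counters=counters,
        intervals=intervals,
        terminated_by=terminated_by,
        k=k_complete,
        t_prime=t_prime,
    )


def speed_up(eval_avg_published: float, oval_avg_observed: float) -> float:
    """Ratio of a published method's average Eval count to an observed average
    Oval count; reporting utility only."""
    if eval_avg_published <= 0 or oval_avg_observed <= 0:
        raise ValueError("speed_up requires positive evaluation counts")
    return eval_avg_published / oval_avg_observed
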