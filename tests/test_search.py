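"""Cooling, acceptance rule, structural objective and the population search."""

import math

import numpy as np
import pytest

from fireflyfold.energy import HPModel
from fireflyfold.lattice import CUBIC, Conformation, random_self_avoiding_walk
from fireflyfold.moves import apply_pull_move, enumerate_pull_moves
from fireflyfold.search import (
    AnnealParams,
    Counters,
    FireflyParams,
    cooling_temperature,
    initialize_population,
    run_search,
    sa_accept,
    speed_up,
    structural_distance,
    structural_objective,
)


class TestCooling:
    def test_schedule_values(self):
        p = AnnealParams()
        assert cooling_temperature(0, p) == 4000.0
        assert cooling_temperature(1, p) == pytest.approx(3999.6)

    def test_strictly_decreasing(self):
        p = AnnealParams()
        temps = [cooling_temperature(n, p) for n in range(0, 5000, 250)]
        assert all(a > b for a, b in zip(temps, temps[1:]))

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            AnnealParams(t0=-1.0)
        with pytest.raises(ValueError):
            AnnealParams(theta=1.0)


class TestSAAccept:
    def test_improving_and_equal_always_accepted(self, rng):
        p = AnnealParams()
        assert all(sa_accept(0.0, n, p, rng) for n in (0, 10, 10**6))
        assert all(sa_accept(-5.0, n, p, rng) for n in (0, 10, 10**6))

    def test_acceptance_rate_matches_boltzmann_factor(self):
        # dE = t0 at n = 0: acceptance probability is exactly exp(-1)
        p = AnnealParams()
        rng = np.random.default_rng(42)
        draws = 100_000
        hits = sum(sa_accept(p.t0, 0, p, rng) for _ in range(draws))
        target = math.exp(-1)
        se = math.sqrt(target * (1 - target) / draws)
        assert abs(hits / draws - target) < 3 * se

    def test_frozen_at_low_temperature(self):
        p = AnnealParams()
        rng = np.random.default_rng(0)
        # T_n ~ 4000 * 0.9999^200000 ~ 8e-6: worsening moves effectively never pass
        assert not any(sa_accept(1.0, 200_000, p, rng) for _ in range(1000))


class TestStructuralObjective:
    def _pair(self, seed, n=10):
        rng = np.random.default_rng(seed)
        before = random_self_avoiding_walk("h" * n, CUBIC, rng)
        moves = enumerate_pull_moves(before)
        mv = moves[int(rng.integers(len(moves)))]
        after = apply_pull_move(before, mv)
        best = random_self_avoiding_walk("h" * n, CUBIC, rng)
        return before, after, best, mv

    def test_distance_examples(self):
        a = Conformation("hh", [(0, 0, 0), (1, 0, 0)], CUBIC)
        b = Conformation("hh", [(3, 4, 0), (4, 4, 0)], CUBIC)
        assert structural_distance(a, a, 0) == 0.0
        assert structural_distance(a, b, 0) == pytest.approx(5.0)
        assert structural_distance(a, b, 1) == structural_distance(b, a, 1)

    def test_distance_length_mismatch(self):
        a = Conformation("hh", [(0, 0, 0), (1, 0, 0)], CUBIC)
        c = Conformation("hhh", [(0, 0, 0), (1, 0, 0), (2, 0, 0)], CUBIC)
        with pytest.raises(ValueError, match="length"):
            structural_distance(a, c, 0)

    def test_null_move_zero_and_accepted(self):
        conf = Conformation("hhh", [(0, 0, 0), (1, 0, 0), (2, 0, 0)], CUBIC)
        best = Conformation("hhh", [(0, 0, 0), (0, 1, 0), (0, 2, 0)], CUBIC)
        sof, accepted = structural_objective(conf, conf, best, (0, 2))
        assert sof == 0.0 and accepted

    def test_single_residue_move_magnitude(self):
        # residue 0 swings around residue 1, from distance 3.0 to 1.0 of the
        # reference: the one-term mean is exactly the distance change
        before = Conformation("hhh", [(0, 0, 0), (0, 1, 0), (1, 1, 0)], CUBIC)
        after = Conformation("hhh", [(0, 2, 0), (0, 1, 0), (1, 1, 0)], CUBIC)
        best = Conformation("hhh", [(0, 3, 0), (0, 4, 0), (1, 4, 0)], CUBIC)
        sof, accepted = structural_objective(before, after, best, (0, 0))
        assert sof == pytest.approx(2.0)
        assert accepted  # previous sof defaults to +inf

    @pytest.mark.parametrize("seed", range(8))
    def test_fuzz_matches_independent_recount(self, seed):
        before, after, best, mv = self._pair(seed)
        j, k = mv.affected_range
        sof, _ = structural_objective(before, after, best, (j, k))
        b = np.array(best.coords, float)
        d0 = np.linalg.norm(np.array(before.coords, float) - b, axis=1)
        d1 = np.linalg.norm(np.array(after.coords, float) - b, axis=1)
        expected = np.abs(d0 - d1)[j : k + 1].mean()
        assert sof == pytest.approx(expected)
        # and the differing residues really are confined to [j, k]
        diff = [t for t in range(10) if before.coords[t] != after.coords[t]]
        assert set(diff) <= set(range(j, k + 1))

    def test_range_violation_detected(self):
        # find a deterministic example whose move leaves the head untouched
        for seed in range(30):
            before, after, best, mv = self._pair(seed)
            j, k = mv.affected_range
            if j > 0:
                break
        assert j > 0
        with pytest.raises(ValueError, match="outside"):
            structural_objective(before, after, best, (j - 1, j - 1))

    def test_history_mode_monotone_in_previous_sof(self, seed=5):
        before, after, best, mv = self._pair(seed)
        sof, acc_inf = structural_objective(
            before, after, best, mv.affected_range, previous_sof=math.inf
        )
        _, acc_tight = structural_objective(
            before, after, best, mv.affected_range, previous_sof=sof / 2 - 1e-9
        )
        assert acc_inf
        if sof > 0:
            assert not acc_tight

    def test_distance_mode_accepts_only_non_increasing_drift(self, seed=6):
        before, after, best, mv = self._pair(seed)
        j, k = mv.affected_range
        b = np.array(best.coords, float)
        d0 = np.linalg.norm(np.array(before.coords, float) - b, axis=1)
        d1 = np.linalg.norm(np.array(after.coords, float) - b, axis=1)
        drift = (d1 - d0)[j : k + 1].sum()
        _, accepted = structural_objective(
            before, after, best, (j, k), mode="distance"
        )
        assert accepted == (drift <= 0)


class TestAccounting:
    def test_closed_form_example(self):
        # N=2, Init=(5,5), k=1, T=15, T'=3 -> 10 + 2*(15+3) + 2*1 = 48
        c = Counters(init_evals=[5, 5])
        assert c.eq18(2, 1, 15, 3) == 48

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_counters_decompose_per_closed_form(self, seed):
        ff = FireflyParams(population_size=4, interval=7, max_steps=40, seed=seed)
        res = run_search("hphph", CUBIC, HPModel(), AnnealParams(), ff)
        c = res.counters
        assert res.oval_total == c.oval_total
        assert res.oval_total == c.eq18(4, res.k, 7, res.t_prime)
        # per-step decomposition: 1 energy + (N-1) structural per shared step
        steps = res.k * 7 + res.t_prime
        assert c.energy_evals == steps
        assert c.structural_evals == steps * 3
        assert c.reelection_evals == (res.k + 1) * 3


class TestInitialisation:
    def test_population_members_are_descended_local_minima(self):
        ff = FireflyParams(population_size=3, seed=9)
        model = HPModel()
        state = initialize_population("hhpph", CUBIC, model, ff)
        assert len(state.population) == 3
        for conf, e in zip(state.population, state.energies):
            assert model.evaluate(conf) == e
            for mv in enumerate_pull_moves(conf):
                assert model.evaluate(apply_pull_move(conf, mv)) >= e
        assert state.energies[state.best_index] == min(state.energies)
        assert all(n > 0 for n in state.counters.init_evals)

    def test_same_seed_identical_state(self):
        ff = FireflyParams(population_size=4, seed=13)
        a = initialize_population("hphhp", CUBIC, HPModel(), ff)
        b = initialize_population("hphhp", CUBIC, HPModel(), ff)
        assert a.population == b.population
        assert a.best_index == b.best_index
        assert a.counters.init_evals == b.counters.init_evals


class TestRunSearch:
    def test_toy_optimum_hhhh(self):
        ff = FireflyParams(seed=1, max_steps=300)
        res = run_search("hhhh", CUBIC, HPModel(), AnnealParams(), ff)
        assert res.best_energy == -1

    def test_best_energy_matches_reapplied_model(self):
        ff = FireflyParams(seed=4, max_steps=60)
        model = HPModel()
        res = run_search("hhpphh", CUBIC, model, AnnealParams(), ff)
        assert model.evaluate(res.best_conformation) == res.best_energy

    def test_deterministic_for_fixed_seed(self):
        ff = FireflyParams(seed=7, max_steps=90)
        a = run_search("hphphh", CUBIC, HPModel(), AnnealParams(), ff)
        b = run_search("hphphh", CUBIC, HPModel(), AnnealParams(), ff)
        assert a.best_conformation == b.best_conformation
        assert a.best_energy == b.best_energy
        assert a.oval_total == b.oval_total
        assert [r.best_energy for r in a.intervals] == [
            r.best_energy for r in b.intervals
        ]

    def test_single_member_population_is_plain_sa(self):
        ff = FireflyParams(population_size=1, seed=2, max_steps=50)
        res = run_search("hhpphh", CUBIC, HPModel(), AnnealParams(), ff)
        assert res.counters.structural_evals == 0
        assert res.counters.reelection_evals == 0

    def test_max_steps_reported_not_raised(self):
        ff = FireflyParams(seed=3, max_steps=20, interval=15)
        res = run_search("hphp", CUBIC, HPModel(), AnnealParams(), ff)
        assert res.terminated_by == "max_steps"
        assert res.k * 15 + res.t_prime == 20

    def test_cold_schedule_converges_by_termination_rule(self):
        # near-zero temperature freezes the annealing member quickly, so the
        # two-condition rule (no accepted SA move and unchanged S_best) fires
        ff = FireflyParams(seed=5, max_steps=100_000)
        res = run_search(
            "hhhh", CUBIC, HPModel(), AnnealParams(t0=0.05, theta=0.5), ff
        )
        assert res.terminated_by == "converged"
        assert res.t_prime == ff.interval

    def test_stop_energy_short_circuits(self):
        ff = FireflyParams(seed=6, max_steps=10_000)
        res = run_search(
            "hhhh", CUBIC, HPModel(), AnnealParams(), ff, stop_energy=-1
        )
        assert res.terminated_by == "target_reached"
        assert res.best_energy <= -1


class TestSpeedUp:
    def test_identity(self):
        assert speed_up(10, 10) == 1.0

    def test_positive_inputs_required(self):
        with pytest.raises(ValueError):
            speed_up(0, 5)
        with pytest.raises(ValueError):
            speed_up(5, -1)


def test_firefly_params_validation():
    with pytest.raises(ValueError):
        FireflyParams(population_size=0)
    with pytest.raises(ValueError):
        FireflyParams(interval=0)
    with pytest.raises(ValueError):
        FireflyParams(sof_mode="other")
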