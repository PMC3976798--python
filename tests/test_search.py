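"""Spiral-search components and whole-run invariants."""

import math

import numpy as np
import pytest

from spiralfold import (
    Conformation,
    core_centre,
    distance_to_centre,
    hp_energy,
    random_saw,
    spiral_search_run,
    tabu_tenure,
)
from spiralfold.search import SearchState, relay_restart, select_h_move, select_move_bm

from conftest import random_conformation


class TestTenure:
    @pytest.mark.parametrize("count,expected", [(0, 10), (48, 14), (105, 20), (9, 10), (10, 11)])
    def test_formula(self, count, expected):
        assert tabu_tenure(count) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            tabu_tenure(-1)


class TestCoreCentre:
    def test_single_residue(self):
        conf = Conformation("H", [(2, 2, 0)])
        assert core_centre(conf, [0]) == (2.0, 2.0, 0.0)

    def test_midpoint(self):
        conf = Conformation("HH", [(0, 0, 0), (1, 1, 0)])
        c = core_centre(conf, [0, 1])
        assert c == (0.5, 0.5, 0.0)

    def test_empty_subset_rejected(self):
        conf = Conformation("H", [(0, 0, 0)])
        with pytest.raises(ValueError):
            core_centre(conf, [])

    @pytest.mark.parametrize(
        "p,c,d",
        [((0, 0, 0), (0.0, 0.0, 0.0), 0.0),
         ((1, 1, 0), (0.0, 0.0, 0.0), math.sqrt(2)),
         ((3, 4, 0), (0.0, 0.0, 0.0), 5.0)],
    )
    def test_distance(self, p, c, d):
        assert distance_to_centre(p, c) == pytest.approx(d)


def make_state(conf, guidance="HP"):
    from spiralfold.energy import classify_hp, is_hp_string

    hp = (conf.sequence if is_hp_string(conf.sequence) else classify_hp(conf.sequence)) \
        if guidance == "HP" else ""
    return SearchState(
        sequence=conf.sequence,
        hp=hp,
        guidance=guidance,
        current=conf,
        best=conf,
        best_energy=0.0,
        rng=np.random.default_rng(0),
    )


def enumerate_admissible(conf, guided_idx, centre):
    """Exhaustive oracle for the best admissible diagonal move."""
    from spiralfold import common_free_neighbors

    best = None
    for i in guided_idx:
        if i in (0, len(conf) - 1):
            continue
        pts = common_free_neighbors(conf, i)
        if not pts:
            continue
        d, p = min(((distance_to_centre(q, centre), q) for q in pts), key=lambda t: t[0])
        if d < distance_to_centre(conf.coords[i], centre):
            if best is None or d < best[0]:
                best = (d, i, p)
    return best


class TestHMoveSelection:
    def test_matches_exhaustive_oracle(self):
        hits = 0
        for seed in range(40):
            conf = random_conformation(20, seed)
            state = make_state(conf)
            h_idx = [i for i, c in enumerate(state.hp) if c == "H"]
            if not h_idx:
                continue
            centre = core_centre(conf, h_idx)
            expected = enumerate_admissible(conf, h_idx, centre)
            got = select_h_move(state)
            if expected is None:
                assert got is None
            else:
                hits += 1
                assert got.residue_index == expected[1]
                assert got.target == expected[2]
                assert got.new_distance == pytest.approx(expected[0])
                assert got.new_distance < got.old_distance
        assert hits > 10

    def test_all_h_tabu_gives_none(self):
        conf = random_conformation(20, 0, h_fraction=1.0)
        state = make_state(conf)
        state.tabu = {i: 10**9 for i in range(len(conf))}
        assert select_h_move(state) is None

    def test_all_polar_gives_none(self):
        conf = random_conformation(20, 0, h_fraction=0.0)
        assert select_h_move(make_state(conf)) is None


class TestBMMoveSelection:
    def test_matches_exhaustive_oracle(self):
        recs = [r.sequence for r in __import__("spiralfold").load_benchmarks()[:2]]
        for seed, seq in enumerate(recs):
            conf = Conformation(seq, random_saw(len(seq), np.random.default_rng(seed)))
            state = make_state(conf, "BM")
            centre = core_centre(conf, list(range(len(conf))))
            expected = enumerate_admissible(conf, range(len(conf)), centre)
            got = select_move_bm(state)
            assert (got is None) == (expected is None)
            if got is not None:
                assert (got.residue_index, got.target) == (expected[1], expected[2])
                assert got.new_distance < got.old_distance


class TestRelayRestart:
    def test_single_member(self):
        conf = random_conformation(10, 0)
        state = make_state(conf)
        state.improving_list = [(conf, -3.0)]
        assert relay_restart(state).coords == conf.coords

    def test_pick_comes_from_list_deterministically(self):
        confs = [random_conformation(10, s) for s in range(5)]
        state = make_state(confs[0])
        state.improving_list = [(c, -float(i)) for i, c in enumerate(confs)]
        state.rng = np.random.default_rng(4)
        a = relay_restart(state)
        state.rng = np.random.default_rng(4)
        b = relay_restart(state)
        assert a.coords == b.coords
        assert any(a.coords == c.coords for c in confs)


class TestSpiralSearchRun:
    def test_zero_budget_returns_input(self):
        conf = random_conformation(30, 1)
        state = spiral_search_run(conf, "HP", 0, np.random.default_rng(0))
        assert state.best.coords == conf.coords
        assert state.best_energy == hp_energy(conf.sequence, conf)

    @pytest.mark.parametrize("guidance", ["HP", "BM"])
    def test_invariants_20_seed_sweep(self, guidance):
        """Best-so-far never worsens; improving list strictly decreases;
        final conformation is a valid SAW; runs are deterministic."""
        seq = (
            "HPHHPPHHPPHPHHHPPHPPHHPPHHPHPHHPPHPHPPHHPPHPHHPH"
            if guidance == "HP"
            else __import__("spiralfold").load_benchmarks()[0].sequence[:48]
        )
        for seed in range(20):
            conf = Conformation(seq, random_saw(48, np.random.default_rng(seed)))
            state = spiral_search_run(conf, guidance, 300, np.random.default_rng(seed))
            energies = [e for _, e in state.improving_list]
            assert all(b < a for a, b in zip(energies, energies[1:]))
            assert state.best_energy == min(energies)
            assert state.best_energy <= energies[0]
            assert state.best.is_valid()
            assert state.current.is_valid()
            repeat = spiral_search_run(conf, guidance, 300, np.random.default_rng(seed))
            assert repeat.best.coords == state.best.coords
            assert repeat.best_energy == state.best_energy
            assert repeat.current.coords == state.current.coords

    def test_tabu_respected(self):
        """A residue moved at iteration t is not re-selected before
        t + tenure (checked through the event log)."""
        conf = random_conformation(40, 5, h_fraction=0.8)
        state = spiral_search_run(
            conf, "HP", 400, np.random.default_rng(5), log_events=True
        )
        # replay H-move events: residue index recoverable via state.events?
        # events carry iteration+energy; instead verify via a fresh run
        # with instrumented selection
        from spiralfold.search import tabu_tenure as tt

        assert state.tenure == tt(conf.sequence.count("H"))

    def test_moved_residue_not_reselected_within_tenure(self, monkeypatch):
        import spiralfold.search as search_mod

        picks = []
        orig = search_mod.select_h_move

        def spy(state):
            cand = orig(state)
            if cand is not None:
                picks.append((state.iteration, cand.residue_index))
            return cand

        monkeypatch.setattr(search_mod, "select_h_move", spy)
        conf = random_conformation(40, 5, h_fraction=0.9)
        # stagnation disabled so the tabu list is never reset mid-run
        state = search_mod.spiral_search_run(
            conf, "HP", 200, np.random.default_rng(5), stagnation_moves=10**9
        )
        last_moved: dict[int, int] = {}
        for it, res in picks:
            if res in last_moved:
                assert it - last_moved[res] >= state.tenure
            last_moved[res] = it + 1  # move applied at iteration it+1
        assert picks

    def test_all_polar_sequence_runs_p_moves_only(self):
        conf = random_conformation(20, 3, h_fraction=0.0)
        state = spiral_search_run(conf, "HP", 50, np.random.default_rng(0))
        assert state.best_energy == 0.0
        assert state.current.is_valid()

    def test_search_beats_random_baseline(self):
        """Mean best HP energy over 20 runs is strictly below the mean
        energy of 20 random SAWs of the same 48-mer."""
        seq = "HPHHPPHHPPHPHHHPPHPPHHPPHHPHPHHPPHPHPPHHPPHPHHPH"
        assert len(seq) == 48
        search_best, random_e = [], []
        for seed in range(1, 21):
            conf = Conformation(seq, random_saw(48, np.random.default_rng(seed)))
            random_e.append(hp_energy(seq, conf))
            state = spiral_search_run(conf, "HP", 300, np.random.default_rng(seed))
            search_best.append(state.best_energy)
        assert np.mean(search_best) < np.mean(random_e)
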