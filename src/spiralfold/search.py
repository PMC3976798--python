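"""Tabu-guided spiral search (SS-Tabu) on the FCC lattice.

The search squeezes a conformation around a core centre by repeated
diagonal moves.  Two guidance modes exist:

* **HP** — hydrophobic residues are pulled toward the hydrophobic core
  centre (HCC), the centroid of the H residues; polar residues take
  occasional random diagonal moves to free up space.  Conformations are
  scored with the HP contact energy.
* **BM** — every residue is pulled toward the centroid of the whole
  chain (CC); conformations are scored with the Berrera 20x20 contact
  potential.

A per-residue tabu list (tenure ``10 + floor(h/10)`` where ``h`` is the
number of guided residues) keeps the spiral from revisiting the same
corner; stagnation is escaped first with a pull-move random walk, then
with a relay-restart from a random member of the improving-solution
list.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .energy import classify_hp, evaluate, is_hp_string
from .lattice import Conformation, Point, common_free_neighbors
from .moves import random_walk

logger = logging.getLogger("spiralfold")

#: Default stagnation thresholds: applied moves without improving the
#: best before a random walk fires, and consecutive fruitless random
#: walks before a relay-restart fires.
STAGNATION_MOVES = 200
STAGNATION_WALKS = 2
RANDOM_WALK_STEPS = 20


def tabu_tenure(count: int) -> int:
    """Tabu tenure ``floor(10 + count/10)`` for ``count`` guided residues."""
    if count < 0:
        raise ValueError("count must be >= 0")
    return 10 + count // 10


def core_centre(conf: Conformation, subset: list[int]) -> tuple[float, float, float]:
    """Componentwise mean of the coordinates of the residues in
    ``subset`` (H residues for HP guidance, all residues for BM)."""
    if not subset:
        raise ValueError("core centre of an empty residue subset is undefined")
    pts = np.array([conf.coords[i] for i in subset], dtype=float)
    c = pts.mean(axis=0)
    return (float(c[0]), float(c[1]), float(c[2]))


def distance_to_centre(p: Point, c: tuple[float, float, float]) -> float:
    return math.sqrt(
        (p[0] - c[0]) ** 2 + (p[1] - c[1]) ** 2 + (p[2] - c[2]) ** 2
    )


@dataclass
class MoveCandidate:
    """A diagonal-move proposal: residue, target point, and its distance
    to the core centre before/after (admitted only if strictly closer)."""

    residue_index: int
    target: Point
    new_distance: float
    old_distance: float


@dataclass
class SearchState:
    """Mutable state of one spiral-search run."""

    sequence: str
    hp: str                      # H/P classification (guidance HP) or "" if unused
    guidance: str                # "HP" or "BM"
    current: Conformation
    best: Conformation
    best_energy: float
    rng: np.random.Generator
    improving_list: list[tuple[Conformation, float]] = field(default_factory=list)
    iteration: int = 0
    non_improving_count: int = 0
    walks_since_improve: int = 0
    tabu: dict[int, int] = field(default_factory=dict)   # residue -> expiry iteration
    tenure: int = 10
    events: list[dict] = field(default_factory=list)
    log_events: bool = False

    def is_tabu(self, i: int) -> bool:
        return self.iteration < self.tabu.get(i, 0)

    def mark_tabu(self, i: int) -> None:
        self.tabu[i] = self.iteration + self.tenure

    def reset_tabu(self) -> None:
        self.tabu.clear()

    def record(self, event: str, energy: float) -> None:
        if self.log_events:
            self.events.append(
                {
                    "iteration": self.iteration,
                    "event": event,
                    "energy": energy,
                    "best_energy": self.best_energy,
                }
            )


def _evaluate(state: SearchState, conf: Conformation) -> float:
    seq = state.hp if state.guidance == "HP" else state.sequence
    return evaluate(seq, conf, state.guidance)


def _best_candidate_for_residue(
    conf: Conformation, i: int, centre: tuple[float, float, float]
) -> MoveCandidate | None:
    """Closest-to-centre free common neighbour of residue ``i``'s flanks,
    admitted only if strictly closer than the residue's current point.
    Ties break on the earliest point in basis-vector order."""
    points = common_free_neighbors(conf, i)
    if not points:
        return None
    best_p = None
    best_d = math.inf
    for p in points:  # A..L order of the left flank => deterministic ties
        d = distance_to_centre(p, centre)
        if d < best_d:
            best_d, best_p = d, p
    old_d = distance_to_centre(conf.coords[i], centre)
    if best_d < old_d:
        return MoveCandidate(i, best_p, best_d, old_d)
    return None


def select_h_move(state: SearchState) -> MoveCandidate | None:
    """Best admissible H-move: over all non-tabu interior H residues,
    the candidate with the globally smallest distance to the HCC
    (ties: lowest residue index).  None signals the P-move phase."""
    conf = state.current
    h_idx = [i for i, c in enumerate(state.hp) if c == "H"]
    if not h_idx:
        return None
    centre = core_centre(conf, h_idx)
    best: MoveCandidate | None = None
    for i in h_idx:
        if i in (0, len(conf) - 1) or state.is_tabu(i):
            continue
        cand = _best_candidate_for_residue(conf, i, centre)
        if cand is not None and (best is None or cand.new_distance < best.new_distance):
            best = cand
    return best


def select_move_bm(state: SearchState) -> MoveCandidate | None:
    """Best admissible move under BM guidance: as :func:`select_h_move`
    but over all non-tabu interior residues, with the centre taken over
    the whole chain."""
    conf = state.current
    centre = core_centre(conf, list(range(len(conf))))
    best: MoveCandidate | None = None
    for i in range(1, len(conf) - 1):
        if state.is_tabu(i):
            continue
        cand = _best_candidate_for_residue(conf, i, centre)
        if cand is not None and (best is None or cand.new_distance < best.new_distance):
            best = cand
    return best


def _apply_candidate(state: SearchState, cand: MoveCandidate, event: str, *, tabu: bool) -> None:
    state.current = state.current.moved(cand.residue_index, cand.target)
    state.iteration += 1
    if tabu:
        state.mark_tabu(cand.residue_index)
    e = _evaluate(state, state.current)
    if e < state.best_energy:
        state.best = state.current
        state.best_energy = e
        state.improving_list.append((state.current, e))
        state.non_improving_count = 0
        state.walks_since_improve = 0
    else:
        state.non_improving_count += 1
    state.record(event, e)


def select_p_move(state: SearchState, budget: int | None = None) -> MoveCandidate | None:
    """One P-move phase: each interior polar residue gets one try, in
    index order; a residue with free common neighbours of its flanks
    takes a uniformly random one (no core centre, no tabu list).  Moves
    are applied to the state as they are chosen; returns the last
    applied candidate, or None if no polar residue could move."""
    last: MoveCandidate | None = None
    for i in range(1, len(state.current) - 1):
        if state.hp[i] != "P":
            continue
        if budget is not None and state.iteration >= budget:
            break
        points = common_free_neighbors(state.current, i)
        if not points:
            continue
        target = points[int(state.rng.integers(len(points)))]
        cand = MoveCandidate(i, target, 0.0, 0.0)
        _apply_candidate(state, cand, "P-move", tabu=False)
        last = cand
    return last


def relay_restart(state: SearchState) -> Conformation:
    """Pick a restart point uniformly at random from the improving
    solution list (fresh random SAW if the list is somehow empty); the
    tabu list is reset by the caller."""
    if not state.improving_list:
        logger.warning("relay-restart with empty improving list: fresh random walk")
        return Conformation.random(state.current.sequence, state.rng)
    k = int(state.rng.integers(len(state.improving_list)))
    return state.improving_list[k][0]


def spiral_search_run(
    conf: Conformation,
    guidance: str,
    budget: int,
    rng: np.random.Generator,
    *,
    stagnation_moves: int = STAGNATION_MOVES,
    stagnation_walks: int = STAGNATION_WALKS,
    walk_steps: int = RANDOM_WALK_STEPS,
    log_events: bool = False,
) -> SearchState:
    """Run SS-Tabu for ``budget`` applied-move iterations.

    HP guidance alternates exhaustive best-H-move phases with single
    P-move passes; BM guidance applies the best admissible move over
    all residues each iteration.  The guidance model is also the
    scoring model inside the run.  Returns the final
    :class:`SearchState` with the best-so-far conformation; the best
    energy is non-increasing in iteration count and the whole run is a
    pure function of (conformation, guidance, budget, generator state).
    """
    if guidance not in ("HP", "BM"):
        raise ValueError(f"unknown guidance {guidance!r}")
    conf.validate()
    seq = conf.sequence
    if guidance == "HP":
        hp = seq if is_hp_string(seq) else classify_hp(seq)
        guided = hp.count("H")
    else:
        if is_hp_string(seq):
            raise ValueError("BM guidance needs a 20-letter amino-acid sequence")
        hp = ""
        guided = len(seq)

    state = SearchState(
        sequence=seq,
        hp=hp,
        guidance=guidance,
        current=conf,
        best=conf,
        best_energy=math.inf,
        rng=rng,
        tenure=tabu_tenure(guided),
        log_events=log_events,
    )
    e0 = _evaluate(state, conf)
    state.best_energy = e0
    state.improving_list.append((conf, e0))
    state.record("initial", e0)

    while state.iteration < budget:
        moved = False
        if guidance == "HP":
            cand = select_h_move(state)
            if cand is not None:
                _apply_candidate(state, cand, "H-move", tabu=True)
                moved = True
            else:
                moved = select_p_move(state, budget) is not None
        else:
            cand = select_move_bm(state)
            if cand is not None:
                _apply_candidate(state, cand, "BM-move", tabu=True)
                moved = True
        if not moved:
            # no admissible move anywhere: burn one iteration and escape
            state.iteration += 1
            state.non_improving_count = max(state.non_improving_count, stagnation_moves)

        if state.non_improving_count >= stagnation_moves:
            if state.walks_since_improve >= stagnation_walks:
                state.current = relay_restart(state)
                state.walks_since_improve = 0
                state.record("relay-restart", _evaluate(state, state.current))
            else:
                state.current = random_walk(state.current, walk_steps, state.rng)
                state.walks_since_improve += 1
                e = _evaluate(state, state.current)
                if e < state.best_energy:
                    state.best = state.current
                    state.best_energy = e
                    state.improving_list.append((state.current, e))
                    state.walks_since_improve = 0
                state.record("random-walk", e)
            state.reset_tabu()
            state.non_improving_count = 0
    return state
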