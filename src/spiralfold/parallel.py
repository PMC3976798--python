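"""Multipoint parallel spiral search (PSS).

A portfolio of independent SS-Tabu workers — each guided by either the
HP or the BM energy model — runs in rounds.  Each round starts every
worker from one of ``k`` current solutions; when all workers finish,
their improving solutions are merged, duplicates are removed, and the
``k`` most promising survivors seed the next round.  Workers are pure
functions of (start conformation, worker config), so the result is
bit-identical however they are scheduled; with a single CPU they simply
run sequentially.

Mixed portfolios score the shared pool with the BM model (the finer
model is the better evaluator even when the HP model is the better
guide); pure-HP portfolios, and any run on a plain H/P string, score
with the HP model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .energy import evaluate, is_hp_string
from .lattice import Conformation, encode_absolute
from .search import SearchState, spiral_search_run

logger = logging.getLogger("spiralfold")

#: The canonical 4-worker portfolio mixes: (BM workers, HP workers).
PORTFOLIO_MIXES: dict[str, tuple[int, int]] = {
    "PSSB4H0": (4, 0),
    "PSSB3H1": (3, 1),
    "PSSB2H2": (2, 2),
    "PSSB1H3": (1, 3),
    "PSSB0H4": (0, 4),
}

# The 48 signed coordinate permutations form the full symmetry group of
# the FCC lattice; used only by the optional strict dedupe mode.
_SYMMETRIES: list[np.ndarray] = []
for perm in ((0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)):
    for sx in (1, -1):
        for sy in (1, -1):
            for sz in (1, -1):
                m = np.zeros((3, 3), dtype=int)
                for row, col in enumerate(perm):
                    m[row, col] = (sx, sy, sz)[row]
                _SYMMETRIES.append(m)


@dataclass(frozen=True)
class WorkerConfig:
    """One worker of the portfolio: guidance model, per-round iteration
    budget, and its private seed."""

    guidance: str          # "HP" or "BM"
    budget: int
    seed: np.random.SeedSequence


@dataclass
class PortfolioMix:
    """A named BM/HP worker split, e.g. PSSB1H3 = 1 BM + 3 HP workers."""

    label: str
    bm_workers: int
    hp_workers: int

    @classmethod
    def from_label(cls, label: str) -> "PortfolioMix":
        key = label if label.startswith("PSS") else "PSS" + label
        try:
            bm, hp = PORTFOLIO_MIXES[key]
        except KeyError:
            raise ValueError(f"unknown portfolio mix {label!r}")
        return cls(key, bm, hp)

    @property
    def total_workers(self) -> int:
        return self.bm_workers + self.hp_workers

    def guidances(self) -> list[str]:
        return ["BM"] * self.bm_workers + ["HP"] * self.hp_workers


@dataclass
class SolutionPool:
    """Deduplicated, scored conformations exchanged between rounds."""

    evaluation_model: str  # "HP" or "BM"
    members: list[tuple[Conformation, float]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.members)

    def best(self) -> tuple[Conformation, float]:
        return min(self.members, key=lambda m: m[1])


def canonical_key(conf: Conformation, symmetry: bool = False) -> str:
    """Translation-invariant identity of a walk: its absolute move
    string.  With ``symmetry=True`` the key is additionally minimised
    over the 48 lattice symmetries, collapsing rotated/mirrored copies."""
    if not symmetry:
        return encode_absolute(conf.coords)
    pts = np.array(conf.coords, dtype=int)
    keys = []
    for m in _SYMMETRIES:
        keys.append(encode_absolute([tuple(int(v) for v in row) for row in pts @ m.T]))
    return min(keys)


def merge_and_dedupe(
    solution_lists: list[list[tuple[Conformation, float]]],
    evaluation_model: str,
    *,
    symmetry: bool = False,
) -> SolutionPool:
    """Union the workers' solution lists, drop duplicates (first
    occurrence kept), and re-score every survivor under the pool's
    evaluation model.  Idempotent."""
    pool = SolutionPool(evaluation_model)
    seen: set[str] = set()
    for solutions in solution_lists:
        for conf, _ in solutions:
            key = canonical_key(conf, symmetry)
            if key in seen:
                continue
            seen.add(key)
            pool.members.append((conf, evaluate(conf.sequence, conf, evaluation_model)))
    return pool


def select_distinct_subset(
    pool: SolutionPool,
    k: int,
    rng: np.random.Generator,
    sequence: str,
) -> list[Conformation]:
    """The ``k`` lowest-score pool members (ties by insertion order),
    topped up with fresh random SAWs if the pool is smaller than ``k``."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(range(len(pool.members)), key=lambda i: (pool.members[i][1], i))
    chosen = [pool.members[i][0] for i in ranked[:k]]
    while len(chosen) < k:
        logger.info("solution pool smaller than k=%d: topping up with a random walk", k)
        chosen.append(Conformation.random(sequence, rng))
    return chosen


def worker_seed(master_seed: int, round_index: int, worker_index: int) -> np.random.SeedSequence:
    """Stable per-worker seed derivation (documented splitting rule)."""
    return np.random.SeedSequence(entropy=(master_seed, round_index + 1, worker_index))


def framework_seed(master_seed: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=(master_seed, 0))


@dataclass
class RoundSummary:
    round_index: int
    pool_size: int
    worker_best: list[float]          # per-worker best energy under its guidance
    pool_best: float                  # best pool score under the evaluation model


def pss_run(
    sequence: str,
    mix: PortfolioMix | str,
    rounds: int,
    per_round_budget: int,
    k: int | None = None,
    master_seed: int = 0,
    *,
    evaluation_model: str | None = None,
    stagnation_moves: int | None = None,
    symmetry_dedupe: bool = False,
) -> tuple[Conformation, float, list[RoundSummary]]:
    """Run the full multipoint framework.

    ``k`` initial self-avoiding walks are generated; each round assigns
    them round-robin to the workers of ``mix``, runs each worker for
    ``per_round_budget`` iterations, merges all improving solutions,
    dedupes, re-scores, and keeps the best ``k`` for the next round.
    Returns the best conformation and score under the evaluation model,
    plus per-round summaries.  Fully deterministic in
    (sequence, mix, rounds, budgets, master_seed).
    """
    if isinstance(mix, str):
        mix = PortfolioMix.from_label(mix)
    if mix.total_workers < 1:
        raise ValueError("portfolio needs at least one worker")
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    if k is None:
        k = mix.total_workers
    if evaluation_model is None:
        if is_hp_string(sequence):
            evaluation_model = "HP"
        else:
            evaluation_model = "BM" if mix.bm_workers > 0 else "HP"
    guidances = mix.guidances()
    fw_rng = np.random.default_rng(framework_seed(master_seed))

    extra = {}
    if stagnation_moves is not None:
        extra["stagnation_moves"] = stagnation_moves

    solutions = [Conformation.random(sequence, fw_rng) for _ in range(k)]
    history: list[RoundSummary] = []
    best_conf: Conformation | None = None
    best_score = np.inf
    for r in range(rounds):
        worker_lists: list[list[tuple[Conformation, float]]] = []
        worker_best: list[float] = []
        for w, guidance in enumerate(guidances):
            rng = np.random.default_rng(worker_seed(master_seed, r, w))
            start = solutions[w % len(solutions)]
            state: SearchState = spiral_search_run(
                start, guidance, per_round_budget, rng, **extra
            )
            worker_lists.append(state.improving_list)
            worker_best.append(state.best_energy)
        pool = merge_and_dedupe(worker_lists, evaluation_model, symmetry=symmetry_dedupe)
        conf, score = pool.best()
        if score < best_score:
            best_conf, best_score = conf, score
        history.append(RoundSummary(r, len(pool), worker_best, score))
        solutions = select_distinct_subset(pool, k, fw_rng, sequence)
    assert best_conf is not None
    return best_conf, float(best_score), history
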