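"""Conformation perturbation operators.

Two operators drive the search: the *diagonal move* (corner flip), the
workhorse of spiral search, and a generalised *pull move*, used by the
random-walk stagnation-escape routine to break up premature hydrophobic
cores.  Both return new conformations; inputs are never mutated.
"""

from __future__ import annotations

import numpy as np

from .lattice import (
    Conformation,
    Point,
    common_free_neighbors,
    fcc_neighbors,
    is_lattice_step,
)


def diagonal_move(conf: Conformation, i: int, target: Point) -> Conformation:
    """Relocate interior residue ``i`` to ``target``, a free common
    neighbour of its two chain neighbours.  All other residues stay
    put; the result is a valid self-avoiding walk by construction."""
    if target in conf.occupancy:
        raise ValueError(f"target {target} is occupied")
    if target not in common_free_neighbors(conf, i):
        raise ValueError(
            f"target {target} is not a free common neighbour of the flanks of residue {i}"
        )
    return conf.moved(i, target)


def _pull_move(conf: Conformation, i: int, direction: int, q: Point) -> Conformation | None:
    """Apply one generalised pull move; return None if infeasible.

    Residue ``i`` relocates to free point ``q``.  ``direction`` is +1 or
    -1: the bond to residue ``i + direction`` is kept, so ``q`` must be
    adjacent to that residue's position.  Trailing residues on the other
    side are dragged into the vacated positions until the chain
    reconnects.  For interior residues ``q`` must also be adjacent to
    the *old* position of ``i`` so that the first dragged residue stays
    bonded; each later dragged residue lands on the old position of its
    successor, which is adjacent to its own old position by chain
    construction, so the walk stays self-avoiding throughout.
    """
    n = len(conf)
    coords = list(conf.coords)
    keep = i + direction
    tail = i - direction
    if not 0 <= keep < n:
        return None
    if q in conf.occupancy:
        return None
    if not is_lattice_step(coords[keep], q):
        return None
    if 0 <= tail < n and not is_lattice_step(coords[i], q):
        # interior pull needs q adjacent to the vacated position too
        return None
    old = coords[i]
    coords[i] = q
    k = tail
    prev_old = old  # vacated position awaiting the next dragged residue
    while 0 <= k < n:
        if is_lattice_step(coords[k], coords[k + direction]):
            break
        prev_old, coords[k] = coords[k], prev_old
        k -= direction
    return Conformation(conf.sequence, coords)


def pull_move_candidates(conf: Conformation, i: int) -> list[tuple[int, Point]]:
    """Feasible (direction, target) pairs for a pull move at residue ``i``,
    in deterministic order."""
    n = len(conf)
    occ = conf.occupancy
    out: list[tuple[int, Point]] = []
    for direction in (+1, -1):
        keep = i + direction
        tail = i - direction
        if not 0 <= keep < n:
            continue
        for q in fcc_neighbors(conf.coords[keep]):
            if q in occ:
                continue
            if 0 <= tail < n and not is_lattice_step(conf.coords[i], q):
                continue
            out.append((direction, q))
    return out


def random_walk(
    conf: Conformation, steps: int, rng: np.random.Generator
) -> Conformation:
    """Apply ``steps`` random pull moves to diversify a conformation.

    Each step picks a residue uniformly, then a uniformly random
    feasible (direction, target) pair for it; steps with no feasible
    pull at the drawn residue are skipped but still counted, so the
    routine always terminates after ``steps`` attempts.  Moves are
    accepted unconditionally (this is an escape mechanism, not an
    optimiser).  Deterministic for a fixed generator state.
    """
    if steps < 0:
        raise ValueError("steps must be >= 0")
    n = len(conf)
    current = conf
    for _ in range(steps):
        i = int(rng.integers(n))
        cands = pull_move_candidates(current, i)
        if not cands:
            continue
        direction, q = cands[int(rng.integers(len(cands)))]
        moved = _pull_move(current, i, direction, q)
        if moved is not None:
            current = moved
    return current
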