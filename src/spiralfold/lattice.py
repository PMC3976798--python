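"""Face-centred-cubic lattice geometry and lattice conformations.

The FCC lattice used here is the sublattice of Z^3 with even coordinate
sum.  Each point has 12 unit neighbours, reached by the basis vectors
A..L (each with exactly two nonzero components of +/-1, squared length
2).  A protein conformation is a self-avoiding walk (SAW) on this
lattice, one point per residue, consecutive residues one basis step
apart.  Walks are encoded as absolute move strings over the alphabet
A..L.

Indexing convention: residues are 0-based in every function of this
package; prose and docstrings that speak of "residue i" with flanks
"i-1"/"i+1" use the same 0-based index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger("spiralfold")

Point = tuple[int, int, int]

#: The 12 FCC basis vectors in fixed A..L order.  Closed under negation:
#: A<->J, B<->K, C<->L, D<->G, E<->H, F<->I.
BASIS_VECTORS: tuple[Point, ...] = (
    (1, 1, 0),    # A
    (0, 1, 1),    # B
    (1, 0, 1),    # C
    (-1, 1, 0),   # D
    (0, -1, 1),   # E
    (-1, 0, 1),   # F
    (1, -1, 0),   # G
    (0, 1, -1),   # H
    (1, 0, -1),   # I
    (-1, -1, 0),  # J
    (0, -1, -1),  # K
    (-1, 0, -1),  # L
)

MOVE_ALPHABET = "ABCDEFGHIJKL"

_VECTOR_BY_LETTER: dict[str, Point] = dict(zip(MOVE_ALPHABET, BASIS_VECTORS))
_LETTER_BY_VECTOR: dict[Point, str] = {v: c for c, v in _VECTOR_BY_LETTER.items()}
_BASIS_SET = frozenset(BASIS_VECTORS)


class SawGenerationError(RuntimeError):
    """Raised when random SAW generation exhausts its restart budget."""


def fcc_neighbors(p: Point) -> list[Point]:
    """Return the 12 unit lattice neighbours of ``p`` in A..L order."""
    x, y, z = p
    return [(x + dx, y + dy, z + dz) for dx, dy, dz in BASIS_VECTORS]


def is_lattice_step(a: Point, b: Point) -> bool:
    """True iff ``b - a`` is one of the 12 basis vectors."""
    return (b[0] - a[0], b[1] - a[1], b[2] - a[2]) in _BASIS_SET


def is_self_avoiding_walk(coords: Sequence[Point]) -> bool:
    """True iff all points are distinct and consecutive points are unit
    lattice neighbours."""
    if len(coords) == 0:
        return False
    if len(set(coords)) != len(coords):
        return False
    return all(is_lattice_step(a, b) for a, b in zip(coords, coords[1:]))


def random_saw(
    n: int,
    rng: np.random.Generator,
    max_attempts: int = 1000,
) -> list[Point]:
    """Grow a random self-avoiding walk of ``n`` points from the origin.

    Each step picks a basis vector uniformly among those leading to an
    unoccupied point.  A dead end (no free neighbour) restarts the whole
    walk; after ``max_attempts`` restarts a :class:`SawGenerationError`
    is raised.  Deterministic for a fixed generator state.
    """
    if n < 1:
        raise ValueError("walk length must be >= 1")
    for _ in range(max_attempts):
        coords: list[Point] = [(0, 0, 0)]
        occupied = {(0, 0, 0)}
        while len(coords) < n:
            free = [q for q in fcc_neighbors(coords[-1]) if q not in occupied]
            if not free:
                break  # dead end: restart from scratch
            q = free[int(rng.integers(len(free)))]
            coords.append(q)
            occupied.add(q)
        else:
            return coords
    raise SawGenerationError(
        f"failed to generate a self-avoiding walk of length {n} "
        f"after {max_attempts} restarts"
    )


def encode_absolute(coords: Sequence[Point]) -> str:
    """Encode a walk as its absolute move string (one letter per step)."""
    letters = []
    for a, b in zip(coords, coords[1:]):
        step = (b[0] - a[0], b[1] - a[1], b[2] - a[2])
        try:
            letters.append(_LETTER_BY_VECTOR[step])
        except KeyError:
            raise ValueError(f"displacement {step} is not an FCC basis vector")
    return "".join(letters)


def decode_absolute(moves: str, origin: Point = (0, 0, 0)) -> list[Point]:
    """Decode an absolute move string into coordinates.

    Self-avoidance is *not* checked; validate separately with
    :func:`is_self_avoiding_walk`.
    """
    coords = [origin]
    x, y, z = origin
    for c in moves:
        try:
            dx, dy, dz = _VECTOR_BY_LETTER[c]
        except KeyError:
            raise ValueError(f"unknown move letter {c!r}")
        x, y, z = x + dx, y + dy, z + dz
        coords.append((x, y, z))
    return coords


@dataclass
class Conformation:
    """A residue sequence mapped to a self-avoiding walk on the FCC lattice.

    ``sequence`` holds one-letter amino-acid codes or an H/P string;
    ``coords`` holds one lattice point per residue.  Instances are
    treated as immutable by the search operators, which return fresh
    conformations.
    """

    sequence: str
    coords: list[Point]
    _occupancy: dict[Point, int] | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.coords):
            raise ValueError(
                f"sequence length {len(self.sequence)} != "
                f"coordinate count {len(self.coords)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def occupancy(self) -> dict[Point, int]:
        """Constant-time point -> residue-index map (built lazily)."""
        if self._occupancy is None:
            self._occupancy = {p: i for i, p in enumerate(self.coords)}
        return self._occupancy

    def is_valid(self) -> bool:
        return is_self_avoiding_walk(self.coords)

    def validate(self) -> None:
        if not self.is_valid():
            raise ValueError("conformation is not a valid self-avoiding walk")

    def moved(self, i: int, target: Point) -> "Conformation":
        """Copy of this conformation with residue ``i`` relocated to
        ``target`` (occupancy updated incrementally)."""
        coords = list(self.coords)
        old = coords[i]
        coords[i] = target
        occ = dict(self.occupancy)
        del occ[old]
        occ[target] = i
        return Conformation(self.sequence, coords, occ)

    def with_coords(self, coords: list[Point]) -> "Conformation":
        return Conformation(self.sequence, coords)

    @property
    def moves(self) -> str:
        return encode_absolute(self.coords)

    @classmethod
    def from_moves(cls, sequence: str, moves: str, origin: Point = (0, 0, 0)) -> "Conformation":
        conf = cls(sequence, decode_absolute(moves, origin))
        conf.validate()
        return conf

    @classmethod
    def random(
        cls, sequence: str, rng: np.random.Generator, max_attempts: int = 1000
    ) -> "Conformation":
        return cls(sequence, random_saw(len(sequence), rng, max_attempts))

    def translated_to_origin(self) -> "Conformation":
        """Copy with the first residue moved to (0,0,0)."""
        x0, y0, z0 = self.coords[0]
        return Conformation(
            self.sequence, [(x - x0, y - y0, z - z0) for x, y, z in self.coords]
        )


def common_free_neighbors(conf: Conformation, i: int) -> list[Point]:
    """Unoccupied points that are unit neighbours of both flanks of
    interior residue ``i`` (0-based, ``1 <= i <= n-2``).

    These are the legal diagonal-move targets for residue ``i``.  The
    result follows the A..L neighbour order of the ``i-1`` flank, so
    selection tie-breaks are deterministic.  The current position of
    residue ``i`` is occupied and therefore never included.
    """
    n = len(conf)
    if not 1 <= i <= n - 2:
        raise IndexError(f"residue {i} is terminal; diagonal moves need both flanks")
    left = conf.coords[i - 1]
    right = conf.coords[i + 1]
    right_nbrs = set(fcc_neighbors(right))
    occ = conf.occupancy
    return [
        q for q in fcc_neighbors(left)
        if q in right_nbrs and q not in occ
    ]
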