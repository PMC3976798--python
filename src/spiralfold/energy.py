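"""Contact energy models: binary hydrophobic-polar (HP) and the Berrera
et al. 20x20 empirical contact-potential (BM) model.

Both models score only *nonconsecutive* residue pairs that sit at unit
lattice distance (squared Euclidean distance 2 on the FCC lattice).  The
HP model contributes -1 per hydrophobic-hydrophobic contact; the BM
model sums empirical pairwise potentials read from the packaged matrix
file.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import numpy as np

from .lattice import Conformation, fcc_neighbors

#: One-letter codes treated as hydrophobic (H); the remaining ten
#: standard residues are polar (P).
HYDROPHOBIC = frozenset("GAPVLIMFYW")
POLAR = frozenset("STCNQKHRDE")
STANDARD_RESIDUES = HYDROPHOBIC | POLAR

THREE_TO_ONE = {
    "Cys": "C", "Met": "M", "Phe": "F", "Ile": "I", "Leu": "L",
    "Val": "V", "Trp": "W", "Tyr": "Y", "Ala": "A", "Gly": "G",
    "Thr": "T", "Ser": "S", "Gln": "Q", "Asn": "N", "Glu": "E",
    "Asp": "D", "His": "H", "Arg": "R", "Lys": "K", "Pro": "P",
}

#: Row/column order of the published BM matrix (one-letter codes).
BM_RESIDUE_ORDER = "CMFILVWYAGTSQNEDHRKP"


def classify_hp(seq: str) -> str:
    """Map a one-letter amino-acid sequence to its H/P string.

    Gly, Ala, Pro, Val, Leu, Ile, Met, Phe, Tyr and Trp are hydrophobic;
    the other ten standard residues are polar.  Raises ``ValueError`` on
    any non-standard letter (including B/Z/X placeholders).
    """
    out = []
    for c in seq:
        if c in HYDROPHOBIC:
            out.append("H")
        elif c in POLAR:
            out.append("P")
        else:
            raise ValueError(f"unknown residue letter {c!r}")
    return "".join(out)


def is_hp_string(seq: str) -> bool:
    return len(seq) > 0 and set(seq) <= {"H", "P"}


@lru_cache(maxsize=1)
def load_bm_matrix() -> dict[tuple[str, str], float]:
    """Load the packaged Berrera contact matrix as a symmetric dict
    keyed by one-letter residue pairs (all 400 ordered pairs present)."""
    text = (
        resources.files("spiralfold.data")
        .joinpath("bm_contact_energies.txt")
        .read_text()
    )
    entries: dict[tuple[str, str], float] = {}
    order: list[str] = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        label, *values = line.split()
        a = THREE_TO_ONE[label]
        order.append(a)
        if len(values) != len(order):
            raise ValueError(f"malformed matrix row for {label}")
        for b, v in zip(order, values):
            e = float(v)
            entries[(a, b)] = e
            entries[(b, a)] = e
    if len(order) != 20 or "".join(order) != BM_RESIDUE_ORDER:
        raise ValueError("corrupted contact-matrix file")
    return entries


def bm_matrix_lookup(a: str, b: str) -> float:
    """Symmetric contact-potential lookup for a one-letter residue pair."""
    matrix = load_bm_matrix()
    try:
        return matrix[(a, b)]
    except KeyError:
        raise ValueError(f"unknown residue pair ({a!r}, {b!r})")


def contact_pairs(conf: Conformation) -> set[tuple[int, int]]:
    """All nonconsecutive residue pairs (i, j), j > i+1, at unit lattice
    distance.  Found by probing the 12 neighbours of each residue
    against the occupancy index (O(12 n))."""
    occ = conf.occupancy
    pairs: set[tuple[int, int]] = set()
    for i, p in enumerate(conf.coords):
        for q in fcc_neighbors(p):
            j = occ.get(q)
            if j is not None and j > i + 1:
                pairs.add((i, j))
    return pairs


def hp_energy(hpseq: str, conf: Conformation) -> int:
    """HP-model energy: -1 per nonconsecutive H-H lattice contact."""
    if len(hpseq) != len(conf):
        raise ValueError("sequence/conformation length mismatch")
    occ = conf.occupancy
    count = 0
    for i, p in enumerate(conf.coords):
        if hpseq[i] != "H":
            continue
        for q in fcc_neighbors(p):
            j = occ.get(q)
            if j is not None and j > i + 1 and hpseq[j] == "H":
                count += 1
    return -count


def bm_energy(seq: str, conf: Conformation) -> float:
    """BM-model energy: sum of Berrera contact potentials over all
    nonconsecutive unit-distance residue pairs (sign-free; individual
    entries may be positive)."""
    if len(seq) != len(conf):
        raise ValueError("sequence/conformation length mismatch")
    matrix = load_bm_matrix()
    total = 0.0
    for i, j in contact_pairs(conf):
        try:
            total += matrix[(seq[i], seq[j])]
        except KeyError:
            raise ValueError(f"unknown residue letter in pair ({seq[i]!r}, {seq[j]!r})")
    return total


def evaluate(sequence: str, conf: Conformation, model: str) -> float:
    """Score a conformation under ``model`` ("HP" or "BM").

    For the HP model an amino-acid sequence is first classified to H/P;
    the BM model requires a 20-letter amino-acid sequence.
    """
    if model == "HP":
        hp = sequence if is_hp_string(sequence) else classify_hp(sequence)
        return float(hp_energy(hp, conf))
    if model == "BM":
        if is_hp_string(sequence):
            raise ValueError("BM model needs a 20-letter amino-acid sequence")
        return bm_energy(sequence, conf)
    raise ValueError(f"unknown energy model {model!r}")
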