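"""Evaluation metrics: relative improvement (RI) and distance-matrix RMSD.

RI expresses how much of the remaining energy gap to the lower bound of
free energy (LBFE) a target method closes relative to a reference
method:

    RI = 100 * (E_t - E_r) / (E_l - E_r)

where ``E_t`` / ``E_r`` are the target/reference average energies and
``E_l`` is the LBFE.  The distance-matrix RMSD (dRMSD) compares two
structures through their all-pairs intramolecular distance matrices and
therefore needs no superposition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

#: Angstroms per lattice unit such that bonded residues (Euclidean
#: separation sqrt(2) on the FCC lattice) sit 3.8 A apart, the mean
#: CA-CA distance in native protein backbones.
LATTICE_CA_SCALE = 3.8 / math.sqrt(2)


@dataclass(frozen=True)
class RIInput:
    """Average energies entering the RI formula.  For meaningful inputs
    the LBFE is the most negative of the three."""

    e_target: float
    e_reference: float
    e_lower_bound: float


def relative_improvement(inp: RIInput | None = None, *, e_t: float | None = None,
                         e_r: float | None = None, e_l: float | None = None) -> float:
    """RI in percent (unrounded).  Raises on a zero gap ``E_l == E_r``."""
    if inp is not None:
        e_t, e_r, e_l = inp.e_target, inp.e_reference, inp.e_lower_bound
    if e_t is None or e_r is None or e_l is None:
        raise TypeError("provide an RIInput or all of e_t, e_r, e_l")
    if e_l == e_r:
        raise ZeroDivisionError("LBFE equals the reference energy: RI undefined")
    return 100.0 * (e_t - e_r) / (e_l - e_r)


def relative_improvement_rounded(inp: RIInput | None = None, **kw) -> int:
    """RI rounded to the nearest integer percent, matching how the
    benchmark tables print it (round-half-away-from-zero)."""
    ri = relative_improvement(inp, **kw)
    return int(math.floor(ri + 0.5)) if ri >= 0 else -int(math.floor(-ri + 0.5))


def drmsd(pred, native, scale: float = 1.0) -> float:
    """Root-mean-square deviation between all-pairs distance matrices.

    ``pred`` is typically in lattice units and is multiplied by
    ``scale`` (see :data:`LATTICE_CA_SCALE`) before comparison with the
    native coordinates in Angstroms; with ``scale=1`` both inputs are
    taken as-is.  Invariant under rigid motion of either structure.
    """
    p = np.asarray(pred, dtype=float)
    q = np.asarray(native, dtype=float)
    if p.shape != q.shape or p.ndim != 2 or p.shape[1] != 3:
        raise ValueError("coordinate sets must both be (n, 3) with equal n")
    if p.shape[0] < 2:
        raise ValueError("need at least two residues")
    dp = pdist(p) * scale
    dn = pdist(q)
    return float(np.sqrt(np.mean((dp - dn) ** 2)))


def hp_benchmark_consistency() -> list[dict]:
    """Recompute the rounded RI of every HP-benchmark row from the
    tabulated average energies and LBFE and compare with the printed
    percentage.  Rows whose printed value is not reproducible from the
    printed integers are flagged (``consistent=False``), not forced."""
    from .io import load_hp_benchmark_results

    out = []
    for row in load_hp_benchmark_results().itertuples():
        if not np.isfinite(row.lbfe):
            continue
        for ref, avg_col, printed_col in (
            ("SS-Tabu", "ss_avg", "ri_ss_printed"),
            ("GA+", "ga_avg", "ri_ga_printed"),
        ):
            ri = relative_improvement_rounded(
                e_t=row.pss_avg, e_r=getattr(row, avg_col), e_l=row.lbfe
            )
            printed = int(getattr(row, printed_col))
            out.append(
                {
                    "instance": row.instance,
                    "reference": ref,
                    "recomputed": ri,
                    "printed": printed,
                    "consistent": ri == printed,
                }
            )
    return out
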