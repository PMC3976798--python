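"""Benchmark fixtures, sequence I/O, synthetic instances, and reports.

Ships two small data tables: the 12 benchmark protein sequences used
with the BM model, and the published HP-benchmark average energies and
free-energy lower bounds that feed the relative-improvement metric.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .energy import STANDARD_RESIDUES, THREE_TO_ONE, evaluate, is_hp_string
from .lattice import Conformation, decode_absolute, encode_absolute
from .metrics import LATTICE_CA_SCALE

REPORT_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class BenchmarkRecord:
    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


def load_benchmarks() -> list[BenchmarkRecord]:
    """The 12 benchmark proteins (PDB-derived sequences, 54-160 aa)."""
    text = (
        resources.files("spiralfold.data")
        .joinpath("benchmark_proteins.tsv")
        .read_text()
    )
    records = []
    for line in text.strip().splitlines()[1:]:
        pid, length, seq = line.split("\t")
        if int(length) != len(seq) or not set(seq) <= STANDARD_RESIDUES:
            raise ValueError(f"corrupted benchmark record {pid}")
        records.append(BenchmarkRecord(pid, seq))
    if len(records) != 12:
        raise ValueError("benchmark fixture must hold exactly 12 records")
    return records


def load_hp_benchmark_results() -> pd.DataFrame:
    """Published HP-benchmark table: average energies of the parallel
    framework (PSS), single-thread spiral search (SS-Tabu) and the
    genetic algorithm (GA+), with per-instance LBFE and printed RI."""
    with resources.files("spiralfold.data").joinpath(
        "hp_benchmark_energies.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t", na_values=["NA"])


def read_sequences(path: str | Path, format: str = "fasta") -> list[str]:
    """Read sequences from FASTA (uppercased) or plain H/P text (one
    sequence per line)."""
    path = Path(path)
    if format == "fasta":
        seqs = [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")]
        if not seqs:
            raise ValueError(f"no FASTA records in {path}")
        for s in seqs:
            bad = set(s) - STANDARD_RESIDUES
            if bad:
                raise ValueError(f"non-standard residue letters {sorted(bad)} in {path}")
        return seqs
    if format == "hp-text":
        seqs = [l.strip().upper() for l in path.read_text().splitlines() if l.strip()]
        for s in seqs:
            if not is_hp_string(s):
                raise ValueError(f"line {s[:20]!r}... is not an H/P string")
        return seqs
    raise ValueError(f"unknown format {format!r}")


def generate_random_instance(
    n: int, h_fraction: float, seed: int | np.random.Generator
) -> str:
    """Random H/P string of length ``n``; each position is H with
    probability ``h_fraction`` independently."""
    if not 0.0 <= h_fraction <= 1.0:
        raise ValueError("h_fraction must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return "".join("H" if u < h_fraction else "P" for u in rng.random(n))


# --- conformation text format ------------------------------------------------
# line 1: sequence; line 2: absolute move string; optional lines "i x y z".

def write_conformation(conf: Conformation, path: str | Path, coords: bool = True) -> None:
    lines = [conf.sequence, encode_absolute(conf.coords)]
    if coords:
        lines += [f"{i} {x} {y} {z}" for i, (x, y, z) in enumerate(conf.coords)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_conformation(path: str | Path) -> Conformation:
    lines = Path(path).read_text().splitlines()
    seq, moves = lines[0].strip(), lines[1].strip()
    origin = (0, 0, 0)
    if len(lines) > 2:
        _, x, y, z = lines[2].split()
        origin = (int(x), int(y), int(z))
    conf = Conformation(seq, decode_absolute(moves, origin))
    conf.validate()
    return conf


_ONE_TO_THREE = {v: k.upper() for k, v in THREE_TO_ONE.items()}


def write_ca_pdb(conf: Conformation, path: str | Path, scale: float = LATTICE_CA_SCALE) -> None:
    """Minimal CA-trace PDB export, lattice coordinates scaled so that
    bonded residues sit 3.8 A apart.  H/P-only sequences are written
    with UNK residue names."""
    hp_only = is_hp_string(conf.sequence)
    lines = []
    for i, (aa, (x, y, z)) in enumerate(zip(conf.sequence, conf.coords), start=1):
        res = "UNK" if hp_only else _ONE_TO_THREE.get(aa, "UNK")
        lines.append(
            f"ATOM  {i:5d}  CA  {res:<3s} A{i:4d}    "
            f"{x * scale:8.3f}{y * scale:8.3f}{z * scale:8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_ca_coordinates(path: str | Path) -> np.ndarray:
    """Native-structure coordinates for dRMSD: a whitespace xyz table
    (optionally with a leading index column) or the CA records of a PDB
    file."""
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith(("ATOM", "HEADER", "MODEL", "REMARK", "TITLE")):
        coords = [
            (float(l[30:38]), float(l[38:46]), float(l[46:54]))
            for l in text.splitlines()
            if l.startswith("ATOM") and l[12:16].strip() == "CA"
        ]
        return np.array(coords, dtype=float)
    rows = []
    for line in text.splitlines():
        parts = line.split()
        if not parts:
            continue
        vals = [float(v) for v in parts]
        rows.append(vals[-3:])
    return np.array(rows, dtype=float)


def write_report(results: dict, path: str | Path) -> None:
    """Write a run report as schema-versioned JSON.

    ``results`` must contain a ``best`` entry with a
    :class:`Conformation` (or its sequence/moves); the report records
    the structure's energy under both models where computable.
    """
    best: Conformation = results["best"]
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "config": results.get("config", {}),
        "rounds": results.get("rounds", []),
        "best": {
            "sequence": best.sequence,
            "moves": encode_absolute(best.coords),
            "coords": [list(p) for p in best.translated_to_origin().coords],
            "energy_hp": evaluate(best.sequence, best, "HP"),
            "energy_bm": (
                None if is_hp_string(best.sequence) else evaluate(best.sequence, best, "BM")
            ),
        },
    }
    Path(path).write_text(json.dumps(report, indent=2) + "\n")


def read_report(path: str | Path) -> dict:
    report = json.loads(Path(path).read_text())
    best = report["best"]
    report["best_conformation"] = Conformation.from_moves(best["sequence"], best["moves"])
    return report
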