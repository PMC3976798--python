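# spiralfold

Multipoint parallel spiral search for *ab initio* protein structure
prediction on the 3D face-centred-cubic (FCC) lattice.

Given only an amino-acid sequence (or a binary hydrophobic/polar
string), the package searches for a low-energy backbone conformation:
a self-avoiding walk on the FCC lattice, one point per residue, scored
by counting residue contacts. It is aimed at researchers studying
lattice models of protein folding and portfolio metaheuristics for
combinatorial search.

## The method

A conformation is a self-avoiding walk `p_1..p_n` on the FCC lattice
(12 unit neighbours per point). Its energy sums over the contact set
`c_ij = 1` iff residues i and j are nonconsecutive unit-distance
neighbours:

    E = Σ_{i<j−1} c_ij · e_ij

with `e_ij = −1` for hydrophobic–hydrophobic pairs (the **HP model**) or
`e_ij` taken from the Berrera et al. empirical 20×20 contact-potential
matrix (the **BM model**).

The core optimiser is **SS-Tabu**, a tabu-guided spiral search: it
repeatedly applies diagonal moves (corner flips) that pull residues
toward a core centre — the centroid of the hydrophobic residues (HP
guidance) or of the whole chain (BM guidance) — with a per-residue
tabu tenure `10 + ⌊h/10⌋`, escaping stagnation by pull-move random
walks and relay-restarts from the improving-solution list.

The **parallel framework (PSS)** runs a portfolio of SS-Tabu workers,
each guided by HP or BM (mixes `PSSB4H0` … `PSSB0H4` for 4 workers), in
rounds: workers explore independently from a shared set of k
solutions; their improving solutions are then merged, deduplicated
(translation-canonical move strings) and the k best re-seed the next
round. Mixed portfolios evaluate the shared pool with the BM model.
Progress is measured by the **relative improvement**
`RI = 100·(E_t−E_r)/(E_l−E_r)` toward the free-energy lower bound, and
structures are compared by superposition-free distance-matrix RMSD
(**dRMSD**), with lattice units scaled `3.8/√2` Å so bonded residues sit
3.8 Å apart.

## Worked example

```python
import spiralfold as sf

rec = sf.load_benchmarks()[0]           # 4RXN, 54 residues
best, score, history = sf.pss_run(
    rec.sequence, "PSSB1H3", rounds=2, per_round_budget=500, master_seed=42
)
print(f"{rec.id}: best BM energy {score:.3f} after {len(history)} rounds")
print("pool sizes per round:", [h.pool_size for h in history])
print("HP contacts of best structure:", -int(sf.evaluate(rec.sequence, best, "HP")))
```

prints

```
4RXN: best BM energy -109.942 after 2 rounds
pool sizes per round: [79, 22]
HP contacts of best structure: 48
```

— a 1-BM + 3-HP worker portfolio folded rubredoxin's 54-residue
sequence for 2 × 500 iterations per worker; the merged pools held 79
and 22 distinct improving structures, and the best one scores −109.942
in BM contact-potential units while burying 48 H–H contacts. Longer
budgets reach much lower energies. The same run is available from the
shell:

```sh
pss run --input 4rxn.fasta --mix B1H3 --rounds 2 --budget 500 --seed 42 \
    --out report.json --export-pdb best.pdb
```

The JSON report records the configuration, per-round summaries, and
the best conformation (move string, coordinates, and its energy under
both models); `--export-pdb` writes a CA trace for visualisation.

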