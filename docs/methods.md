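# Methods

## Model

Protein backbones are modelled as self-avoiding walks (SAWs) on the
face-centred-cubic (FCC) lattice, the sublattice of Z^3 with even
coordinate sum. Every point has 12 unit neighbours, reached by the
basis vectors A..L (two nonzero components of ±1 each, Euclidean length
√2); walks are stored as coordinates and exchanged as absolute move
strings over A..L. Only backbone (CA-level) geometry is represented:
no side chains, no relative encodings, no other lattices.

Two contact-energy models score a conformation over its *contact set* —
all residue pairs (i, j), j > i+1, at unit lattice distance:

* **HP**: residues are classed hydrophobic
  (G, A, P, V, L, I, M, F, Y, W) or polar (the other ten); each H–H
  contact contributes −1. Energies are integers ≤ 0.
* **BM**: the Berrera et al. empirical 20×20 contact-potential matrix,
  shipped as a lower-triangular text table (`data/bm_contact_energies.txt`)
  and mirrored at load; the sum over contacts may be positive. The
  matrix minimum is the Cys–Cys entry (−3.477), which falls in the
  first ten rows of the published ordering but is a *polar–polar* pair
  under the H/P classification above — the disulfide outlier.

Strings over exactly {H, P} are always interpreted as HP instances,
never as His/Pro amino-acid sequences; BM scoring of such strings is
refused.

## Spiral search (SS-Tabu)

The local search repeatedly applies **diagonal moves** (corner flips): an
interior residue relocates to a free point that neighbours both of its
chain neighbours, so chain validity is preserved by construction.
Guidance modes:

* **HP guidance** pulls hydrophobic residues toward the hydrophobic core
  centre (HCC), the centroid of the H residues. Each phase takes the
  best admissible H-move — the candidate strictly reducing its
  residue's Euclidean distance to the HCC, with the globally smallest
  new distance — until none exists, then gives every interior polar
  residue one uniformly random diagonal move (no centre, no tabu for
  P-moves), then resumes H-moves. The HCC is recomputed after every
  applied move. Scoring uses the HP energy.
* **BM guidance** treats all residues alike, pulling toward the centroid
  of the whole chain, and scores with the BM matrix.

A per-residue tabu list bars a just-moved residue for
`tenure = 10 + floor(h/10)` iterations, where `h` is the number of
guided residues (H count under HP guidance; chain length under BM
guidance, an interpretation — the published tenure formula is stated
only for the HP case). There is no aspiration criterion. Ties in move
selection break toward the lowest residue index, then the earliest
basis-vector-order target, so runs are fully deterministic given
(sequence, guidance, budget, seed).

**Stagnation.** After 200 applied moves without improving the best
(`stagnation_moves`), a **random walk** of 20 attempted **pull moves**
perturbs the current structure; after 2 consecutive fruitless walks
(`stagnation_walks`), a **relay-restart** resumes from a uniformly
random member of the improving-solution list (every strictly improving
conformation seen this run). Both escapes reset the tabu list. The
thresholds are package choices; the original description names the
mechanisms but no values. The pull move is a generalised Lesh-style
move adapted to 12-neighbour connectivity: residue i relocates to a
free point adjacent to both its old position and the neighbour whose
bond is kept, and trailing residues are dragged into vacated positions
until the chain reconnects; terminal residues degenerate to end moves.
Worsening pulls are accepted unconditionally — the walk is an escape
mechanism, not an optimiser.

Budgets are counted in applied-move iterations, not wall-clock time,
so every result is reproducible; terminal residues never move (the
diagonal move needs both flanks).

## Parallel framework (PSS)

`pss_run` executes a portfolio of workers — each an independent SS-Tabu
with its own guidance model, budget and seed — in rounds. Per round,
each of k current solutions (k defaults to the worker count) seeds one
worker; afterwards all workers' improving lists are merged, duplicates
removed, every survivor re-scored under the pool's evaluation model,
and the k lowest-energy members (topped up with fresh random SAWs if
needed) seed the next round. The canonical five 4-worker mixes
PSSB4H0..PSSB0H4 (x BM + y HP workers) are predefined. Mixed pools are
evaluated with the BM model — the finer model is the better evaluator
even where the HP model is the better guide; pure-HP portfolios and
H/P-string instances use HP.

Duplicates are walks with identical absolute move strings, i.e.
translation-invariant identity; an optional strict mode minimises the
key over the 48 signed-permutation lattice symmetries. Workers are
pure functions of (start, config), so results are identical under any
scheduling; per-worker generators derive from
`SeedSequence((master_seed, round+1, worker))` and the framework's own
randomness (initial walks, top-ups) from `SeedSequence((master_seed, 0))`.

## Metrics

* **Relative improvement**: `RI = 100·(E_t − E_r)/(E_l − E_r)` — the
  fraction of the remaining gap to the free-energy lower bound (LBFE)
  closed by a target method relative to a reference. The rounded
  variant rounds half away from zero, matching how benchmark tables
  print it. `hp_benchmark_consistency()` recomputes every bundled
  benchmark row from its printed averages: three rows are not
  reproducible from the printed integers (S3/SS-Tabu: 24 vs 26;
  F90_1/SS-Tabu and F90_5/GA+: printed 0 although the target average
  is one unit worse than the reference, giving −100; presumably
  computed from unrounded averages). These are flagged, never forced.
* **dRMSD**: RMSD between the all-pairs intramolecular distance
  matrices of two structures — superposition-free, so it is invariant
  under rigid motion of either input. Lattice coordinates scale by
  `3.8/√2` Å per lattice unit, placing bonded residues 3.8 Å apart
  (mean native CA–CA distance); the factor is a parameter.

## Synthetic instances and what the tests show

`generate_random_instance(n, h_fraction, seed)` draws i.i.d. H/P
strings; tests use h_fraction = 0.5 at lengths 48 and 90, bracketing
the published F90-class instances' composition and length range.
Random SAWs serve as initial structures and as fixtures. These
instances have no native structure, secondary-structure propensity, or
correlated hydrophobicity patterns of real proteins, so passing tests
demonstrate correctness and the comparative behaviour of the search —
not biological prediction accuracy. Bundled real inputs are limited to
the 12 benchmark amino-acid sequences and the published HP-benchmark
average-energy/LBFE table feeding the RI metric; the HP-specific
F90/S/F180/R instances are external and accepted as H/P text files.

## Numerical choices and problem sizes

Distances are exact floats of integer-coordinate differences; energy
equality in tests uses 1e−9 where sums of matrix entries are involved
and exact comparison for HP counts. SAW generation restarts from
scratch on dead ends (cap 1000 restarts). Degenerate inputs: all-P
sequences under HP guidance run P-moves only (the HCC is undefined and
skipped); an empty improving list falls back to a fresh random walk
with a log warning.

The comparative acceptance checks run at desk scale: invariants sweep
20 seeds × 300 iterations on a 48-mer; the multipoint-vs-single
comparison fixes a 90-mer and grants each arm 16 000 total iterations —
4 workers × 4 000 (four exchange rounds) against one start × 16 000 —
over 20 seeds per arm. The per-worker budget was set from a
convergence profile so that the single-start arm has entered its
stagnation-dominated plateau, the regime the equal-total-budget
comparison is designed around; at much smaller budgets a single start
is still in free fall and extra budget on one trajectory beats
portfolio diversification.

## Limitations

Wall-clock budgets (the published experiments' stopping rule) exist
only as a CLI convenience and are not reproducible; the testable core
is iteration-budgeted. Rotational/mirror duplicate detection is off by
default (cheap translation-canonical keys). No crankshaft or other
move repertoires; no lower-bound computation for arbitrary HP
instances (LBFE values come from the bundled table); native structures
for dRMSD must be supplied by the user.
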