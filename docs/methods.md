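# Methods

This note documents the models implemented in `helixpack`, the
parameter choices that matter, what the synthetic data does and does
not emulate, and the numerical conventions. It states no result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Problem setting and assumptions

Input is a protein sequence, its TM topology (ordered 1-based
inclusive helix spans), and a sequence profile (the 20 log-odds
columns of a PSI-BLAST ASCII PSSM; a flag is not provided for the
frequency columns — synthetic profiles are written and read in the
same dialect). The membrane normal is treated as a symmetry axis:
helices are assumed to span the bilayer with a common alignment, so
packing is solved in the 2-D membrane plane. Re-entrant helices and
inter-chain contacts are outside the model: only residues inside TM
spans ever enter contact sets, and loops contribute nothing but
sequence separation.

## Lipid-exposure classifier

- Labels: a TM residue is lipid-exposed iff its fraction of
  simulation time in lipid contact is **strictly** greater than 0.5.
- Features: concatenated profile rows for a window of 7 residues
  centred on the target (140 values); windows crossing a terminus are
  zero-padded *before* normalization, so after Z-scoring a padded
  block maps to −μ/σ. Z-score statistics (population SD) are always
  fitted on the training fold only; constant columns transform to 0.
- Model: RBF-kernel SVM; raw decision values are the predictor output
  and the label threshold is fixed at 0 (no top-L/5 reranking mode).

## Contact classifier

- Pairs: all inter-helix residue pairs (i < j); contacts within one
  helix are undefined by construction.
- Features per pair (292 total): window(i) ‖ window(j) (280), the two
  raw lipid SVM scores, an 8-bin one-hot sequence-separation encoding
  with inclusive-left boundaries (d ≤ 50 → bin 1, …, d > 200 → bin 8;
  a cumulative "thermometer" variant is available behind a config
  flag), and the relative in-helix positions z_i, z_j.
- Relative Z: z = (pos − start + 1)/length ∈ (0, 1]. When the helix
  index difference is odd the second residue's value is flipped to
  1 − (pos − start)/length: sequence-adjacent TM helices run
  antiparallel, so equal membrane heights lie at opposite span ends.
  The flip is the mirror involution on within-helix positions and
  stays in (0, 1].
- Class balance: positives are all kept; negatives are undersampled
  without replacement to the positive count (seeded), and any residual
  imbalance is carried by the SVM cost factor j = n_neg/n_pos applied
  as the positive-class weight. At parity j = 1.
- Contact definitions for labelling: (1) Cβ–Cβ ≤ 8.0 Å with Cα
  substituted for glycine (and, with a warning, for residues missing
  Cβ); (2) any heavy-atom pair < r_vdW(a) + r_vdW(b) + 0.6 Å, Bondi
  radii C 1.70 / N 1.55 / O 1.52 / S 1.80 / P 1.80 Å; (3) any
  heavy-atom pair < 5.5 Å. Definition 1 is inclusive ("a maximal
  distance of 8 Å"), 2 and 3 strict ("less than"). Hydrogens are
  excluded from 2 and 3. With these radii the vdW criterion is at most
  4.2 Å, so definition 2 contact sets nest inside definition 3 — the
  property the tests assert. The production search uses a k-d tree and
  is validated for exact set equality against a quadratic brute-force
  oracle.

## Cross-validation and hyperparameters

Evaluation is leave-one-protein-out: the held-out protein and every
sequence with pairwise E-value < 1e-4 to it (from a precomputed
homology table; no aligner is run) are excluded from the training
fold, and normalization is refitted per fold. Hyperparameters are
chosen by grid search maximizing pooled MCC, ties broken by smaller C
then smaller gamma. Metric conventions: accuracy =
(TP+TN)/(TP+TN+FP+FN); MCC by the product formula with 0 substituted
for vanishing denominator factors; empty-denominator rates report 0
and flag the report degenerate.

Package defaults when grid search is skipped are gamma 0.6 / C 1.5
(lipid) and gamma 24 / C 1 (contact). These suit real PSSM feature
scales; on the synthetic features they sit far above the useful
kernel bandwidth (pairwise distances grow with the 140–292
dimensions), so the benchmark harnesses follow the protocol's own
grid search over a small log grid (gamma ∈ {1e-3, 1e-2, 0.1, 1},
C ∈ {1, 10}).

## Interaction graphs and decoy discrimination

Helix pairs with at least one positive-scoring residue pair form the
predicted interaction graph. A candidate arrangement (native, native
model, or decoy interaction set) scores +1 for every one of the
C(n,2) helix pairs whose interaction status matches the prediction —
interacting and non-interacting pairs count equally. The native is
"ranked first" iff no other candidate scores strictly higher; a decoy
tying the native therefore counts as a success by default (a
`strict_ties` switch inverts this).

## Force-directed layout

Energy E = Σ_{i<j} (K/d_ij²)(‖p_i − p_j‖ − L0·d_ij)² with
graph-theoretic shortest-path distances d_ij; K = 1 and L0 = 1 layout
unit. Minimization starts from a regular n-gon (vertex k at angle
2πk/n, radius 1) and repeatedly applies a damped 2×2 Newton step to
the vertex with the largest gradient norm, halving the step until the
energy does not increase — so the energy is non-increasing by
construction, which is asserted on every call. Convergence: max
gradient norm < 1e-6 or 1000 updates. Disconnected graphs are a hard
error (no arrangement exists without at least one interaction per
helix). After layout, coordinates are rescaled so the closest pair of
helix axes sits at 10 Å, a typical packing distance.

Helices with identical neighbour sets (comparing N(u)∖{v} with
N(v)∖{u}) are interchangeable; classes are closed transitively, the
assignments are the products of within-class permutations filtered to
graph automorphisms, and at most 10,000 are enumerated (seeded
sampling beyond, with a warning). Note the rule counts the end swap
of a 3-path (both ends neighbour only the centre); the resulting
layouts are mirror images and rank identically.

Loop i joins the layout positions of sequence-adjacent helices i and
i+1 and lies on membrane side i mod 2. Two same-side loops cross when
their open segments properly intersect — strict opposite orientations
both ways, computed on exact rationals so collinear touching and
shared endpoints never miscount. Arrangements are ranked by total
same-side crossovers, then total contact distance, then id.

## Rotation optimization

Residue k of a helix starting at `start` sits on its helix's wheel at
azimuth rotation + 100°·(k − start) (3.6 residues/turn), radius
2.3 Å (≈ Cβ), centred on the scaled layout position; the
membrane-normal coordinate is ignored. Azimuths increase
counter-clockwise for every helix; per-helix twist-sign flags exist
for the mirrored convention but default to uniform. One integer
rotation per helix (0–359°) minimises the summed Euclidean distance
over predicted contact pairs. The optimizer is a generational GA —
population 100, 200 generations, tournament size 3, uniform crossover
at rate 0.9, per-gene uniform mutation at 0.05, elitism 1, seeded
numpy Generator — with the objective vectorized across the
population. Elitism makes the best objective non-increasing and never
worse than the initial population's best.

## Synthetic generator

Bundles are ideal α-helices (rise 1.5 Å/residue, twist 100°/residue)
with backbone N/Cα/C/O, Cβ at 3.3 Å from the axis, and one extended
side-chain pseudo-atom 2.5 Å beyond Cβ. Helices alternate direction
(odd up, even down), sit on explicit centers or a ring with 9.5 Å
adjacent spacing, and are joined by ≥4-residue loops without
coordinates. True contacts are computed by the brute-force oracle.
Profiles plant the signal real profiles carry — conserved/polar
core-facing positions versus variable hydrophobic lipid-facing ones —
as ±5 times a hydrophobic/polar template vector plus Gaussian noise
of SD 5/signal_strength (default signal_strength 4; 0 gives pure
noise, ∞ the noiseless limit). Lipid fractions are 0.5 + 0.49·e for
signed exposure e, so fraction > 0.5 exactly when the residue's
azimuth points ≥ 90° from the bundle centroid.

What this does **not** emulate: real evolutionary profiles (column
correlations, gap structure, family depth), side-chain packing
geometry, kinked/tilted helices, or inter-chain contacts. Passing the
signal-recovery tests shows the feature, normalization, balancing and
CV machinery is correct — not that real membrane proteins are
separable at these accuracies.

## Benchmark problem sizes

Chosen to exercise each component at desk scale: oracle agreement on
100 random bundles (2–8 helices, 3 contact definitions) and 1000
random layouts (≤10 helices); GA optimality against the exhaustive
360×360 search (2 helices, 1 contact) and the 10°-grid optimum (3
helices); classifier recovery on 20 two-helix proteins (moderate
signal), 30 (null), and a 1-train/1-test noiseless split; decoy
discrimination over 50 proteins × 24 decoys; arrangement recovery
over 50 seeded 7-helix rings plus one 13-helix run. Ring benchmarks
default to sequence ring order — the architecture of native TM
bundles and the case the circular initialization is designed for.
With scrambled ring slots the descent minimizer recovers most small
rings (the suite checks a majority at n = 5) but can stick in twisted
local minima for larger n; supplying a better initial order, not a
different minimizer, is the intended remedy, mirroring how the
circular start is used in the first place.

## Known limitations

- Consecutively-connected graphs (e.g. a path) carry no information
  to distinguish circular from linear arrangements; the layout
  defaults to the spring minimum.
- The decoy stage ranks interaction sets, not coordinates; decoy
  structure generation and refinement are out of scope, and the
  synthetic decoys are random edge flips of the native graph.
- Wheel geometry is rigid (no kinks, uniform twist), and rotations are
  optimized after the layout is frozen; frustration between layout
  and rotations is not revisited.
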