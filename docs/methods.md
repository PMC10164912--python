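# Methods

## Problem and model

O-GlcNAc transferase (OGT) attaches a single N-acetylglucosamine to serine
or threonine hydroxyls of nuclear and cytoplasmic proteins. Its substrate
repertoire is broad and poorly captured by short linear motifs; most sites
sit in intrinsically disordered regions (IDRs), and the enzyme's
tetratricopeptide-repeat (TPR) superhelix appears to read the amino-acid
*composition* of an extended disordered segment around the acceptor site.
`glycopssm` models this with a position-specific scoring matrix (PSSM) over
long S/T-centered windows:

- A candidate site is an S or T residue; its context is the window of
  `L` residues centered on it (default `L = 39`, i.e. 19 flanking residues
  per side). Windows that run past a terminus are padded with `-`.
- The matrix assigns a real score to each of 18 amino acids (the canonical
  20 minus W and C, which are too rare in IDRs for their cells to be
  constrained) at each of the `L − 1` non-center offsets — an 18 × 38 table
  at the default length.
- A window's score is the sum of the cells selected by its flanking
  residues. The center residue, `W`, `C`, `X` (unknown) and the pad `-`
  contribute exactly zero. Scoring is therefore linear in the matrix.
- A site is called glycosylatable at a stringency tier when its score is
  `>= threshold`; the shipped defaults are 123 (low), 148 (medium) and
  160 (high), the operating points of the trained 39-mer matrix (high
  trades sensitivity for precision). The `>=` convention makes boundary
  behavior explicit.

Because the center is unscored, any S-versus-T preference can only be
expressed through neighboring residues (e.g. a threonine-rich C-terminal
flank).

## Training objective (MAS)

Given positive (known-site) and negative (verified non-substrate) window
sets, the matrix assessment score is

    MAS = (P − Pstd − N − Nstd) / P

with `P`, `N` the medians and `Pstd`, `Nstd` the sample (n−1) standard
deviations of the two score distributions; medians of even-length lists are
the mean of the middle two, and a singleton list has standard deviation 0.
The numerator is the gap between the lower edge of the positive
distribution and the upper edge of the negative one; dividing by `P` makes
the objective invariant to uniform rescaling of the matrix. A variant that
adds rather than subtracts `Nstd` is available (`literal_nstd=True`);
rewarding a wider negative distribution contradicts the goal of separating
the two sets, so it is not the default.

Two properties of this objective are worth knowing:

- It is undefined at `P = 0` and not meaningful for `P < 0`. The optimizer
  ranks all such states strictly below every `P > 0` state and orders them
  among themselves by the raw numerator, which pushes the positive median
  up and the negative median down until normalization becomes meaningful.
  Trajectories report `-inf` for MAS during this phase.
- When the negative distribution lies far below zero, `MAS = 1 −
  (Pstd + N + Nstd)/P` is unbounded as `P → 0+`, and a hill climber will
  legitimately shrink the positive median toward zero to inflate the
  ratio. On the synthetic benchmark this is exactly what happens: final
  MAS magnitudes vary strongly between seeds (hundreds to thousands) while
  the *separation* between the populations, the recovered residue
  preferences, and held-out classification accuracy are stable. MAS values
  should therefore be compared within a run (the trajectory is strictly
  increasing over accepted steps), not across runs.

## Optimizer

Pure accept-if-better stochastic hill climbing: each iteration picks one
matrix cell uniformly at random, perturbs it by `+step_size` or
`−step_size` with equal probability, and keeps the change iff the objective
strictly increases (ties are rejected, which keeps the accepted-step MAS
sequence strictly increasing and makes runs reproducible). One seeded
generator (`numpy` PCG64) drives initialization, cell choice and step sign,
so identical config plus identical data give a bitwise-identical matrix.
Defaults: 100 000 iterations, `step_size = 1.0`.

Initialization defaults to uniform-random cells in `[−init_range,
+init_range]` (`init_range = 1.0`). An all-zero start is supported but is a
*fixed point* of this move set: from zero, any single ±step move leaves
both medians at zero (no single cell is populated in more than half the
windows of either set) while increasing both standard deviations, so every
move strictly decreases the objective and nothing is ever accepted. This is
regression-tested rather than hidden. Runs from different random starts
converge to matrices with strongly correlated per-residue row means
(tested at Pearson r > 0.7), so the compositional reading of the trained
matrix does not depend on the start.

Scaling `init_range` and `step_size` by the same positive constant scales
the final matrix by that constant and changes no accept/reject decision
(exact in floating point for power-of-two factors; tested at ×2).

## Synthetic data and the recovery benchmark

The generator emulates the statistical structure the trainer assumes: two
window populations differing only in flank composition. Flanking residues
are drawn i.i.d. from a 20-residue probability spec; the center is S or T
with equal probability. The positive-like spec up-weights A, V, T, I, L, M,
P by +50 % relative and down-weights G, Q, N, D, E, R by the reciprocal
factor (renormalized); the negative-like spec is the mirror image. The +50 %
magnitude is an artifact choice giving comfortable statistical power at
n = 500 windows; it is configurable.

What the generator deliberately does **not** emulate: positional structure
(no motifs near the center — the planted signal is position-free by
design, matching the view that the discriminating signal is compositional
and roughly uniform along the window), overlapping windows from shared
parent sequences, database-realistic residue frequencies, or any
S-versus-T asymmetry. Passing the recovery benchmark therefore shows that
the trainer recovers a planted *compositional* contrast; it says nothing
about recovering catalytic-site sequence motifs from real data.

`recovery_benchmark(seed)` generates 500 + 500 windows at L = 39, trains
for 50 000 iterations, and reports: initial and final MAS, per-residue
row means of the trained matrix, the sign-agreement fraction (trained
row-mean sign vs planted direction over the 13 planted residues present in
the matrix alphabet), and the two population median scores. Expected under
defaults: sign agreement ≥ 80 % (observed: 100 % across tested seeds),
final MAS > initial, positive median > negative median.

## Dataset diagnostics

- **Positional frequencies**: per-offset residue frequencies of a window
  set, center column included (which is 100 % S+T by construction); pads
  and `X` are excluded from numerator and denominator, so every populated
  column sums to 1 within 1e−9.
- **Compositional bias**: for each residue, the exact binomial upper tail
  P(X ≥ k) of observing k copies in n pooled residues under a background
  frequency — small values mean enrichment. The tail is summed in log
  space (logsumexp over per-count log-pmf terms) so magnitudes far below
  the double-precision floor remain usable through the reported `log10_p`.
  This is the plain whole-set statistic; the windowed
  lowest-probability-subsequence search of fLPS-style tools is out of
  scope, so comparisons with such outputs are order-of-magnitude only.
  For window sets produced by exhaustive S/T windowing, pass the parent
  region sequences, not the overlapping windows, or every residue is
  counted up to L times. No multiple-testing correction is applied; raw
  p-values are reported.
- **Evaluation**: confusion counts over a test protein's full S/T site
  universe (sensitivity, specificity, accuracy, precision), with
  whole-percent display helpers for benchmark-style tables; rates with a
  zero denominator are reported as undefined (`None`) rather than forced
  to a number. A Pearson-correlation utility (two-sided p from the
  t-distribution on n−2 df) supports correlating predicted site counts
  with observed modification stoichiometries.

## Numerical and interface choices

- Coordinates are 1-based inclusive everywhere; mutation strings
  (`G34A`) use parent numbering; duplicate mutation positions are
  rejected, making application order-independent.
- Matrix TSV: header row of signed offsets, 18 residue rows in
  alphabetical order; the reader accepts rows in any order and ignores an
  offset-0 column with a warning. Values are written with full `repr`
  precision, so write→read is the identity.
- Data files written by the CLI contain no timestamps or hostnames;
  reruns with identical inputs and seeds are byte-identical. Provenance
  goes to the log stream.
- The fixture registry ships accession references and residue spans for
  the benchmark IDR regions (FET-family low-complexity regions, the five
  verified non-substrate IDRs, the CBP disordered segments, Lamin A,
  RNA-polymerase-II CTD) but no sequences; operations that need one fail
  with the accession and span to fetch. The Lamin A isoform numbering
  used by published site tables is ambiguous and recorded without a span.

## Known limitations

- Re-training cannot be expected to reproduce any previously published
  matrix cell-for-cell: hill climbing from a random start with an
  unstated seed, step size and iteration budget fixes only the matrix's
  qualitative structure, not its values.
- The MAS ratio's behavior as `P → 0+` (above) makes absolute MAS values
  incomparable across runs.
- The predictor is purely compositional at heart; it carries no
  structural or disorder information, and sites in folded regions will be
  called solely on sequence context.
- Problem sizes in the shipped tests and acceptance script (hundreds of
  windows, 10⁴–10⁵ iterations, seconds per run) were chosen as the
  smallest sizes at which the planted-bias recovery is statistically
  comfortable; they are not a performance ceiling.
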