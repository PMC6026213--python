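# Methods

## Model

PSRSM predicts per-residue 3-state secondary structure (H/E/C) from
PSI-BLAST PSSM profiles by combining three ideas: windowed profile
features, length-based data partitioning with routed prediction, and
majority-vote ensembles of SVMs trained on occurrence-balanced feature
subspaces.

### Feature encoding

A residue is described by the PSSM rows of the `w = 13` residues
centred on it.  Profiles are optionally squashed elementwise by the
logistic function `x ↦ 1/(1+e⁻ˣ)` (the default; raw log-odds span
roughly ±15, and bounded inputs suit an RBF kernel), then `w//2 = 6`
all-zero rows are prepended and appended to the chain, so windows that
run past a terminus carry literal zero blocks.  The result is an
`L × 260` matrix; columns 121..140 (1-based) always hold the central
residue's own (scaled) profile.  Whether profile scaling is applied,
and whether padding zeros are inserted before or after it, are
genuinely open choices; we scale first and pad with exact zeros so the
padding is invariant across scaling modes, and expose `scaling="none"`
for raw log-odds.  We store residues as rows (`L × 260`) purely as a
memory-layout convention; all indexing in documentation and serialized
artifacts is 1-based.

DSSP 8-state strings reduce to 3 states by the common convention
H, G, I → H; E, B → E; T, S, L, C and blank → C.  Labels may also be
supplied directly as 3-state strings (the synthetic generator does).

### Length partitioning and routing

Breakpoints `r₁ < … < r_{k−1}` split `(0, ∞)` into half-open intervals
`(r_{i−1}, r_i]`; the defaults 100, 200, 300, 400, 500 give `k = 6`
bins.  A protein whose length equals a breakpoint belongs to the lower
bin.  One ensemble is trained per bin and a query is predicted by
exactly the ensemble its length routes to.  Breakpoints are
configurable because desk-scale synthetic experiments use fewer,
narrower bins than the reference six.

### Occurrence-balanced semi-random subspaces

Each of the `t` subspaces is `Sᵢ = Lᵢ ∪ S₀ ∪ Rᵢ` with `S₀` the fixed
central 20 columns and `Lᵢ`, `Rᵢ` drawn `d`-at-a-time from the 120-dim
left and right flanks, so `r = 2d + 20`.  Defaults `t = 12`, `r = 160`
give `d = 70`.  Exact balance — every flank feature occurring
`t·d/120` times on its side — requires `t·d` divisible by 120 and is
enforced, because the ordered-pair overlap `Σᵢⱼ|Sᵢ∩Sⱼ| = Σ_f o_f²` is
Schur-convex in the occurrence vector and minimized exactly at equal
counts (we verify this by exhaustive enumeration on small pools in the
test suite, and the convention question of whether the `i = j`
diagonal is included does not change the minimizer).

Balancing starts from uniform random subsets and repeatedly applies a
swap: choose uniformly at random a triple `(i, j, k)` with feature `j`
at minimum occurrence and missing from subset `i`, and `k` at maximum
occurrence and present in `i`; insert `j`, remove `k`.  When counts
are unequal and `t·d/120` is an integer, max − min ≥ 2, so each such
move strictly decreases `Σ o_f²` and the loop terminates.  The strict
min/max pairing can in principle be empty while counts are unequal; we
then widen to the per-subset best donor/receiver pair with the largest
count gap.  A move cap of `10·t·d·120` guards the loop (never reached
in practice; exceeding it raises).  Left and right flanks are balanced
on independent child streams of one master seed, and the flank pool
size is a parameter (`20·(w//2)` per side) so small property-test
instances exist.

### Ensembles, voting, routing

Base classifiers are scikit-learn `SVC` (libsvm) with RBF kernel,
`C = 0.9956`, `γ = 0.065` and libsvm's one-vs-one multiclass scheme;
classifier `j` of a bin is fit on the projection of the bin's residue
vectors onto `Sⱼ`.  Prediction collects `t` hard labels per residue
and takes the majority; ties (possible with `t = 12` and 3 classes)
break by the fixed priority C > H > E, coil being the most frequent
state in globular proteins.  Votes are hard labels throughout — no
probability calibration.

Because reference-scale training (millions of residues per bin, SVM
cost superlinear in sample count) is far beyond a desktop, training
accepts a stratified residue cap: each base classifier draws its own
class-proportional sample of exactly `cap` residues (largest-remainder
allocation, per-classifier seed), which adds sample diversity on top
of subspace diversity.  Whether the reference pipeline trained on all
residues or a sample is not something the method itself fixes; the cap
default is `None` (use everything).

All randomness descends from one master seed through fixed
`SeedSequence` derivations (per bin, per classifier), so training and
prediction are bit-reproducible; models persist as a JSON manifest
plus one joblib file per SVM and reload to identical predictions.

## Evaluation

`Q3 = 100·(N_H+N_E+N_C)/N` per protein; dataset **average Q3** is the
unweighted mean over proteins with valid predictions — not
residue-weighted, so short proteins count as much as long ones.
Region accuracy tags each residue of the *true* structure internal
(both neighbors exist and share its state) or boundary (everything
else, including termini) and pools residues across proteins within
each region.  The classical definition speaks only of helix/strand
residues; whether coil enters the tally is ambiguous, so both modes
exist — the default applies the rule to all three classes, and
`he_only` excludes coil from both regions.  The identity
`overall Q3 = residue-weighted mix of internal and boundary Q3` holds
by construction in the default mode and is property-tested.

The packaged T100 table (100 PDB chains of length 18–1460, per-chain
Q3 of the public PSRSM and DeepCNF servers) is the worked example for
this arithmetic.  The DeepCNF mean runs over its 96 valid chains
(four are below the server's 26-residue minimum) and equals 82.78.
The plain mean of all 100 PSRSM values is 85.00; the widely quoted
summary figure 85.09 corresponds to the mean over the 99 chains
excluding the single 1460-residue protein, and the package computes
both rather than choosing.

## Synthetic data

The generator emulates exactly the structure the method exploits and
nothing more:

* **Labels** form a 3-state semi-Markov chain: geometric run lengths
  with per-class means (defaults H 6.0, E 4.5, C 8.0 residues —
  helices longest, strands shortest, coil the majority state), uniform
  switching between the other two classes.  Residue-level class
  frequencies are then proportional to the run-length means
  (≈ 32/24/43 % H/E/C, close to globular-protein composition).
* **Profiles** are class-conditional Gaussians: a 3×20 mean matrix
  (the default places disjoint column blocks at equal pairwise
  Euclidean distance, `separation = 3` with unit noise sd — a strongly
  but not trivially separable problem, since boundary windows mix
  classes) plus isotropic noise, then convex smoothing with the
  neighbor average (weight 0.3) to mimic the local correlation of real
  profiles.
* **Length effect**: each (bin, class) pair gets a fixed random unit
  direction, scaled by `length_effect`, added to the class mean —
  train and test generated from one config share the shifts.  This
  plants the signal that makes the bin-matched ensemble beat
  mismatched ones, the qualitative behavior length routing exists for.

What the generator does *not* emulate: real amino-acid composition,
PSI-BLAST profile statistics (values are continuous, not integer
log-odds), long-range contact effects, or any sequence–profile
dependence.  Passing tests therefore demonstrate that the machinery —
encoding, balance, routing, voting, scoring — behaves as specified,
not that the method reaches any particular accuracy on real proteins.

Default conditions for the end-to-end checks: 200 proteins over two
bins (lengths 30–200) with separation 3 and a 2000-residue cap for
signal recovery; 140 single-bin proteins with zero class separation
for the chance-level control; three 150-protein, 3-bin benchmarks
(`length_effect = 3`, separation 2.5, `t = 4`, `r = 80`, cap 800) for
the routing check.  These sizes were fixed once as a desk-scale run
that keeps every SVM fit in the low seconds while leaving thousands of
held-out residues per measurement.

## Numerical and degenerate-input choices

* Half-open bins make breakpoint lengths unambiguous; lengths are
  integers, breakpoints stored as floats.
* `r` not of the form `2d+20`, `t·d` not divisible by the pool size,
  `d` larger than the pool, empty bins, missing classes in a bin,
  length/label mismatches and malformed PSSM rows all fail fast with
  the offending item named.
* The ASCII-PSSM parser accepts floats in the score columns (the
  synthetic writer emits 4-decimal values; real PSI-BLAST files carry
  integers, which round-trip exactly) and ignores everything after the
  first 20 score columns.
* A region with zero residues yields `None`, excluded from summaries,
  rather than NaN arithmetic.
* Percentages print at 2 decimals; full precision is kept internally.

## Known limitations

* No 8-state prediction, SOV/segment-overlap scores, or PSI-BLAST
  invocation (profiles are consumed, not produced; the reference
  profile recipe — BLOSUM62 against NR filtered at 90 %, inclusion
  threshold 0.001, 3 iterations — is documented here for users who
  generate their own).
* Reference-scale accuracy claims on real benchmarks are out of scope
  at desk scale; the package validates mechanism, arithmetic and
  qualitative behavior.
* libsvm's internal one-vs-one tie-breaking is version-dependent; only
  the ensemble-level vote order is under this package's control.
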