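# Methods

This note documents the models and procedures implemented in `regval`, the
defaults and why they were chosen, the synthetic data the package is tested
on, and the numerical conventions that matter when reproducing results.

## Inputs and geometry

A model chain is reduced to one representative atom per residue: Cβ, or Cα
for glycine; non-glycine residues lacking a Cβ (e.g. trace-only models)
fall back to Cα with a warning. Residue indices are 1-based reference
positions throughout; unmodelled positions are kept as placeholders and
masked out of every metric denominator rather than silently dropped.
Predicted per-residue confidences (pLDDT, 0–100) are read from the B-factor
column, following the convention of AlphaFold-class predictors.
`renumber_to_reference` aligns the modelled sequence to a reference with a
free-end-gap global alignment and refuses chains under 90% identity, since
a wrong numbering would poison every downstream comparison.

Two residues are in contact when their representative atoms are within
8 Å. The confusion metrics use a minimum sequence separation of 5 —
standard contact-prediction practice, preventing trivial near-diagonal
contacts from saturating the top-L/2 set — applied identically to the
predicted and observed maps.

## Distograms

A distogram stores, per residue pair, a probability distribution over B
distance bins described by B+1 edges; the final bin is open-ended from its
lower edge. The predicted distance is the midpoint of the argmax bin and
the confidence is that bin's mass; exact ties resolve to the
lower-distance bin (deterministic, conservative toward contact). The
open-ended bin's nominal midpoint is its lower edge plus half the previous
bin's width. Contact probabilities sum the mass of bins whose upper edge
is at most the 8 Å cutoff; the cutoff must coincide with a bin edge so no
bin is ever split. The default binning is 2–22 Å in 0.5 Å steps plus the
open bin, configurable; real predictors bin differently and their output
must be converted to the documented JSON/TSV dialect (see
`regval.predictions`), which keeps the tool independent of any particular
predictor.

## The 24 per-residue metrics

For residue i with partner universe U(i):

* **wRMSD(i)** = sqrt(Σ_{j∈U(i)} w_ij (x_ij − x̂_ij)² / Σ w_ij), the
  confidence-weighted deviation between observed and predicted distances.
  Normalisation is by total weight Σw, which reduces to a plain RMSD when
  all confidences are 1 and is invariant to rescaling the confidences;
  dividing by the partner count instead is available via `per_n=True`.
  wRMSD uses all partners (min_sep 1) — near-diagonal distance deviations
  are informative even where near-diagonal contacts are not. Pairs whose
  argmax bin is the open-ended last bin carry no usable midpoint and are
  given zero weight; without this every long-range pair in a compact fold
  would inflate wRMSD by the (arbitrary) open-bin midpoint.
* **Contact confusion**: TP/FP/TN/FN per residue between the top-L/2
  predicted map and the observed map give Accuracy, Precision,
  Sensitivity, Specificity, FP rate, and the raw FP and FN counts.
* Each of the 8 base metrics has a **smoothed** variant (five-point
  unweighted moving average whose window shrinks at the chain ends, so no
  residue is lost) and a **spatial Z-score** variant (standardized against
  the values of all residues within 10 Å, population standard deviation).
  Z-scores are computed from the unsmoothed values, treating smoothing and
  standardization as parallel views of the same base signal.

Degenerate denominators (no partners, zero weight, zero variance) yield 0
plus a False validity flag — the table never contains NaN, because it
feeds a classifier directly.

## Classifier

The shipped feature set is fixed: Accuracy, FP rate, smoothed Sensitivity,
smoothed wRMSD, Z-Accuracy, Z-Sensitivity and Z-wRMSD, plus relative
solvent accessibility and a 3-state secondary-structure one-hot (11
numbers per residue). `correlation_prune` — greedy transitive grouping at
|Pearson r| ≥ 0.4 with the group representative chosen by largest absolute
linear-discriminant coefficient — ships as the reusable utility that
motivates this set; it is not re-run at inference.

Training uses a class-balanced 80:20 split (positives split
floor(0.8·P)/rest, an equal number of negatives sampled into each side).
For synthetic experiments the split is group-aware by default — whole
chains go to one side — because residue-level splitting lets residues from
the same error appear on both sides and overestimates accuracy; group
splits cannot hit the 80:20 ratio exactly, so each side is balanced to the
rows it has. The model is a linear-kernel SVM behind a standard scaler
fitted on training rows only. Hyperparameters (C log-uniform in
[1e-3, 1e3]; class weight balanced/none) come from a seeded 200-iteration
random search scored by 5-fold cross-validated mean accuracy. Calibrated
probabilities use Platt (sigmoid) scaling fitted on out-of-fold decision
values, since downstream thresholds (50–90%) need probabilities, not
margins. The trained model serializes to a single versioned JSON file —
scaler, weights, calibration, metadata — never an opaque pickle.

Error calls are maximal runs of ≥ `min_run` consecutive residues with
probability ≥ `threshold`; defaults 6 and 0.9 favour precision, and both
are exposed on the command line. The shipped default classifier was
trained on the default synthetic dataset (seed 1); retrain with
`regval train` for other conditions.

## Contact-map alignment (CMO)

The contact maximum overlap between two maps — the largest matchable
contact weight under a monotone, gapped residue alignment — is NP-hard, so
the aligner is a heuristic verified against an exhaustive oracle
(`brute_force_cmo`, enumeration of all monotone mappings over
contact-bearing residues, maps ≤ 12 residues). Design:

* Outer alignment: Gotoh affine-gap DP with free end gaps
  (gap_open −3, gap_extend −0.1 in matched-contact units — large enough to
  forbid one-residue jitter, small enough to allow genuine shifts).
* Inner similarity: initialized from binned contact-separation profiles,
  then iterated (3 rounds): S[i,k] = weight of contacts of i matched by
  contacts of k under the current alignment.
* Starting points: the profile similarity plus diagonal-seeded banded DPs
  for every register offset up to ±10 — register shifts live on
  off-diagonals, so seeding them directly makes constant shifts easy to
  find. On maps of ≤ 20 residues, additional anchor-seeded starts pin each
  plausible residue pairing and each contact-to-contact match, and the DP
  runs with vanishing gap penalties to chase the pure CMO.
* Candidates are ranked by matched contact weight — the CMO objective
  itself — with the gap-penalised score as tie-break. Ranking by penalised
  score alone would reject optima that need an interior gap (one gap costs
  more than one contact); the penalties' role is steering each DP pass and
  choosing the cleanest among equal-overlap alignments.

A matched contact contributes min(w_observed, w_predicted, 1); observed
contacts have weight 1 and predicted contacts carry their contact
probability. The alignment step uses a denser contact map than the
metrics: all pairs with contact probability ≥ 0.5 at minimum separation 3.
Local (i, i±3..4) contacts are register-insensitive individually but pin
the alignment at segment boundaries, where long-range contacts vanish
(a residue adjacent to a shifted segment loses its partners); without
them, call endpoints float by several residues on contact-free boundary
stretches.

Runs of constant nonzero offset with ≥ 5 aligned residues become
register-shift calls; calls with the same shift separated by ≤ 5 residues
are merged. The minimum call length is a package choice: shorter
misalignments are dominated by false positives, and errors under ~10
residues carry too few contacts to be reliably detectable at all.

## False-positive filters

1. **Contact density**: fail when the mean or the median predicted
   contacts per residue over the call range is below 2 — too little
   information for a reliable alignment.
2. **pLDDT**: fail when the mean predictor confidence over the range is
   below 65; skipped (with a warning) when no predicted model or pLDDT is
   available, rather than failing the run.
3. **Q-score**: superpose the model on the predicted model (Kabsch,
   proper rotation enforced) using sequence-identity pairs *outside* the
   call range — the presumably correct bulk. Within the range, model
   residue i is paired with predicted residue i + shift, i.e. the register
   the call proposes, and Q = N_align² / ((1 + (rmsd/R₀)²)·N₁·N₂) with
   R₀ = 3 Å is computed over those pairs; fail when Q < 0.5. Pairing the
   range by sequence identity instead would compare position i against
   position i in a region claimed to be shifted by k — a genuine register
   error would then always fail its own filter. Pairing by the proposed
   register scores precisely what the filter is after: whether the
   predicted structure supports the proposed assignment.

Filters annotate calls (pass / fail / skipped) rather than deleting them;
`--no-filters` records `not_run` but never removes a call.

## Synthetic study conditions

The generator defines the conditions under which the package's numbers are
produced:

* **Folds**: self-avoiding toy backbones from parametric segments —
  antiparallel 18-residue helices (1.5 Å rise, 100°/residue, 2.3 Å radius)
  on a serpentine two-row grid 8.5–9 Å apart, or antiparallel 8-residue
  strands (3.3 Å rise) 4.8 Å apart with interleaved coil segments — plus
  0.15 Å seeded jitter; default length 100, pLDDT 90.
* **Distograms**: per-pair discretized Gaussians centred on the true
  distance, sharpness (std) 0.5 Å by default — emulating a confident
  predictor — with a noise fraction (default 5%) of pairs whose centre is
  displaced by ≥ 4 Å, emulating locally wrong predictions.
* **Register errors**: residues [start, end] take the coordinates of
  residue i + shift (`inject_register_shift`; coordinates outside the
  segment are untouched). The literal construction duplicates geometry —
  residues just past the segment end coincide with the segment's tail —
  which real register errors do not exhibit (the compensating residues are
  simply absent from real models), so the dataset/recovery wrapper
  `corrupt_chain` marks those duplicated residues unmodelled by default.
* **Labelled datasets**: 40 chains, each with 0–2 non-overlapping error
  segments of 6–40 residues and |shift| 1–5 (covering both the detectable
  ≥ 10-residue regime and the hard shorter one), features computed from
  the corrupted chain against the pristine chain's distogram; group id =
  chain. Under the defaults roughly a quarter of residues are positive.

What these conditions do *not* emulate: real side-chain packing,
predictor-correlated error modes (distogram noise here is independent per
pair), missing-density stretches unrelated to register errors, multi-chain
contacts, and maps/FSC evidence. Passing numbers therefore demonstrate
method correctness and internal consistency, not performance on
experimental depositions.

Problem sizes in the test-suite and acceptance runs (100 trials of L=100
recovery, 100 8-residue oracle comparisons, 40-chain training sets, 50
clean-chain control seeds) keep a full run within minutes on a single core
while leaving the statistics stable across seeds.

## Numerical conventions

* All randomness flows through seeded NumPy generators; sub-seeds are
  drawn below 2³¹. Same seed, same output, bit for bit.
* Argmax ties in the distogram pick the lower-distance bin; DP traceback
  prefers match over vertical over horizontal moves; top-L/2 selection
  breaks probability ties by (i, j) ascending.
* The Q-score filter compares at `threshold − 1e−9` so an exactly-boundary
  Q of 0.5 passes regardless of floating-point noise.
* Kabsch superposition requires ≥ 3 non-collinear pairs and raises on
  degenerate input rather than returning an ill-defined rotation.
* DSSP 8-state codes collapse as H/G/I → helix, E/B → sheet, rest → coil;
  relative accessibility divides by per-residue-type maxima and clamps to
  [0, 1]. Without a DSSP file, a geometric fallback assigns secondary
  structure from Cα virtual dihedrals (helix: ≈ 50° ± 30° with
  d(i, i+3) < 6 Å; sheet: |dihedral| > 120° with d(i, i+3) > 9 Å) and
  accessibility from a 10 Å neighbour count mapped monotonically to
  [0, 1] — crude but ordinal, and accessibility is a minor feature.

## Known limitations

* The CMO aligner is a heuristic; optimality is verified only on small
  maps (against the exhaustive oracle) and via recovery statistics at
  scale. Pathological maps can still defeat it.
* The shipped classifier is trained on synthetic geometry; scores on real
  models are meaningful only after retraining on real labelled data.
* Contact-only input (CASP-RR) supports map alignment but not wRMSD, which
  requires full distance distributions.
* Single chains only; inter-chain contacts are invisible to the method and
  a register error stabilized by a partner chain may present weaker
  signal.
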