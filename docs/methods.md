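# Methods

`rristack` predicts partner-specific residue–residue interactions (RRIs):
given a two-partner protein complex with declared receptor and ligand
chains, it classifies every (receptor residue, ligand residue) pair as
interacting or not. Two residues interact when at least one of their
heavy-atom cross distances is ≤ 6.0 Å (the inclusive boundary is part of
the contract and is tested at 5.99/6.00/6.01 Å). This note documents the
model, its parameters, the synthetic benchmark, and the numerical choices
made where the design was open.

## Feature model

Each residue gets a 66-value *primitive* block:

* **Sequence (55)** — 14 physicochemical scale values (two hydrophobicity
  scales, hydrophilicity, net charge index, two polarity scales,
  polarizability, SASA scale, side-chain volume, flexibility,
  accessibility, exposure, turn propensity, antigenicity; packaged as
  `data/physchem_scales.csv` and loaded verbatim), the residue's 20 PSSM
  log-odds and 20 PSFM frequencies, and one conservation value in [0, 1].
  Profiles come from PSI-BLAST ASCII files when supplied; otherwise a
  pseudo-profile is synthesized (one-hot PSFM, BLOSUM62 PSSM rows,
  conservation 1). Conservation defaults to the normalized entropy
  complement C = 1 − H/ln 20; an externally computed per-position file can
  be ingested instead. The packaged tyrosine row prints NCI = 117.3 and
  side-chain volume = 0.024, which look transposed relative to every other
  row; the table is stored as printed and an off-by-default
  `fix_tyr_row` flag swaps the two entries.
* **Structure (11)** — residue ASA and RASA (Shrake–Rupley, probe 1.4 Å,
  960-point quadrature, vdW radii C 1.70/N 1.55/O 1.52/S 1.80 Å; RASA
  normalized by theoretical Gly-X-Gly maxima, clipped below at 0 only),
  depth index DPX (mean and max over atoms; an atom's depth is 0 if
  solvent-accessible, else the distance to the nearest accessible atom),
  protrusion index CX (mean and max; CX = max(V_ext/V_int, 0) in a 10 Å
  sphere assuming 20.1 Å³ per heavy atom), a 3-state secondary-structure
  one-hot (Kabsch–Sander hydrogen-bond energies
  E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol, bond iff
  E < −0.5, amide H rebuilt 1 Å from N opposite the preceding carbonyl;
  helix/strand/coil collapse), and half-sphere exposure counts (13 Å
  sphere split by the CA→CB direction, pseudo-CB from flanking CAs when
  CB is absent).

Two neighborhood summaries extend the primitives, each contributing the
element-wise min/max/mean/sum of the neighbors' full primitive blocks plus
an empty-neighborhood mask flag (4·66 + 1 values):

* **Sequence neighbors** — the ±4 window on the full sequence (window
  length 9), center excluded, truncated at termini. The window size is not
  fixed by the method description and is config-exposed.
* **Structure neighbors** — up to the 10 nearest residues with CA–CA
  distance < 10 Å, restricted to the same partner protein (cross-partner
  neighbors would leak the label and would be unavailable for unbound
  partners); exact ties break toward the lower residue index.

A residue vector is therefore 9·66 + 2 = 596 wide with all families on; a
pair vector is the receptor vector followed by the ligand vector (1192).
The four families (sequence, structure, sequence-neighbor,
structure-neighbor) are independently toggleable; ablation views are
column selections of the all-family computation, so toggles never change
the underlying values. Neighbor aggregates always summarize the full
primitive block even when a primitive family is toggled off — this keeps
neighbor-only ablations genuinely informative.

Burial-type features (ASA/RASA/DPX/CX) are computed on the bound complex
by default, since they describe the residue's interaction environment; a
`GeometryConfig(unbound=True)` switch computes each partner in isolation.

## Numerical choices in the geometry code

The Shrake–Rupley point set is a golden-spiral hemisphere plus its
antipodes (inversion-symmetric, so mirror-image configurations receive
exactly equal areas), oriented in the molecule's principal-axis frame with
axis signs fixed by third moments. Anchoring the quadrature to a
molecule-canonical frame makes ASA — and everything derived from its
accessibility threshold — invariant under rigid motions to numerical
precision rather than only to the quadrature resolution (~1/960). The
frame is ambiguous for exactly symmetric or degenerate atom clouds
(vanishing third moments, tied principal values); real and generated
structures are generic, and single atoms fall back to the lab frame.
Quadrature error: 960 vs 3840 points differ by < 2% on test fixtures.

## Dataset assembly

* **Labels** — all resolved receptor×ligand pairs, positive iff any
  heavy-atom pair is within 6.0 Å (k-d tree; verified against an
  O(atoms²) brute force in tests). Pairs with an unresolved member are
  excluded.
* **Structure-to-sequence mapping** — resolved residue letters are
  globally aligned to the chain's full-length sequence (match +1,
  mismatch −1, gap −2); identity below 0.8 over resolved residues is a
  mapping failure. Residues aligned to gaps, and mismatched residues
  beyond the configured tolerance (default 0), are left unmapped and
  treated as unresolved. The alignment is a stand-in for whatever
  database-specific reconciliation produced the original mappings.
* **Training-complex filter** — for a held-out complex, each training
  complex is scored by a Q-score-style structural similarity: chain pairs
  are matched by sequence alignment, CA traces superposed by
  least-squares (Kabsch), and Q = N_align²/((1 + (RMSD/3 Å)²)·N_a·N_b);
  the complex score is the length-weighted mean of per-chain bests, taking
  the larger direction for symmetry. Complexes scoring < 0.05 are dropped;
  if nothing survives, the filter falls back to the full pool and flags
  the run. An externally computed similarity table can override the
  internal metric.
* **Undersampling** — all positives are kept and r negatives per positive
  (default r = 3) are drawn uniformly without replacement, per training
  fold only; test-side evaluation always uses every candidate pair.

## The stacked ensemble

Four base classifiers — a decision tree (min leaf 5), Gaussian naive
Bayes, a one-hidden-layer network (100 units, early stopping, max 150
epochs), and a 200-tree random forest — feed a LightGBM meta-classifier
(≤ 500 rounds, learning rate 0.05, early stopping on a stratified 10%
holdout). Meta-training data are out-of-fold probabilities over 5
stratified folds, so the meta-learner never sees resubstitution outputs;
the base learners are refit on all training instances for inference. The
meta input concatenates the four base probabilities with the primitive
pair vector (`include_primitive_in_meta`, default on), letting the top
level exploit both the base learners' votes and the raw features. Base
probabilities (not hard labels) are used. None of the learner
hyperparameters are dictated by the method itself; all are config-exposed
package defaults.

Evaluation is leave-one-complex-out: each complex's pairs are scored by a
stack trained on the filtered, undersampled pairs of the others, and
ranked by ROC/AUROC. The ROC sweeps all distinct score thresholds with
TPR = TP/(TP+FN), FPR = FP/(FP+TN), and trapezoidal area; it equals the
pairwise ranking probability with ties counted ½ and is cross-checked
against that brute-force oracle (and scikit-learn) in tests.

## Synthetic benchmark

The generator (`synthgen`) builds what the pipeline needs and nothing
more: two chains of ideal peptide geometry (NeRF extension; helical
segments φ = −57°, ψ = −47°, extended segments φ = −139°, ψ = 135°;
segment lengths 8–15 drawn per chain with a configurable helix fraction;
N, CA, C, O, CB heavy atoms, consecutive CA–CA ≈ 3.8 Å). The second chain
is rigidly docked along random approach directions until the number of
residue pairs within 6 Å lands within ±20% of the target (default 30)
with at least 2.5 Å inter-chain clearance. Sequences are drawn with a
hydrophobic composition bias at interface positions (P(hydrophobic) 0.90
at the interface vs 0.20 elsewhere), so the sequence family carries
signal independent of geometry; the bias was set so that every feature
family is independently informative on the benchmark (each single-family
ablation scores well above chance) while the full combination remains the
best, mirroring how the families behave on real complexes. A missing-
residue fraction deletes coordinates while keeping full sequences, to
exercise the structure-to-sequence mapping.

What the benchmark does *not* emulate: real side-chain packing (side
chains are CB stubs), binding energetics, evolutionary profiles (the
pseudo-profile encodes only residue identity), inter-chain β-sheets, and
the size and diversity of crystallographic benchmarks. Passing the
synthetic acceptance therefore demonstrates that the pipeline's machinery
— featurization, filtering, sampling, stacking, evaluation — is correct
and that it recovers planted geometric/compositional signal; it does not
certify accuracy on real complexes.

Benchmark scale: the end-to-end acceptance uses 10 complexes of 60
residues per chain (~3600 candidate pairs each, ~25–30 positives), chosen
as the smallest configuration on which the leave-one-out statistics are
stable across seeds.

## Degenerate inputs and tie-breaks

Alternate locations resolve to highest occupancy, lexicographically first
identifier on ties. Only the first coordinate model is read. Modified
residues with a known parent (MSE, SEP, …) are kept and renamed; other
HETATM groups, waters, and hydrogens are dropped; unknown polymer
residues become 'X' with all-zero physicochemical values and uniform
pseudo-PSFM rows. Empty neighborhoods aggregate to zeros with the mask
flag set rather than imputed means. An all-buried (or all-accessible)
atom set has all depths 0. A fold whose training pool loses both classes,
or whose test pairs are single-class, is skipped with a warning rather
than failing the whole cross-validation.

## Known limitations

* The secondary-structure assignment collapses the 8-state vocabulary to
  3 states and implements only the core helix/bridge patterns; no exact
  agreement with DSSP's ladder bookkeeping is attempted or claimed.
* The similarity filter's Q-score needs a sequence-seeded correspondence;
  highly divergent but structurally similar chain pairs may be
  under-scored. The 0.05 threshold semantics are preserved regardless of
  which score source (internal or external table) is used.
* mmCIF input, profile database search, and probability calibration are
  out of scope.
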