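# rristack

Partner-specific residue–residue interaction (RRI) prediction for protein
complexes via stacked meta-learning.

Protein–protein interfaces are expensive to resolve experimentally.
Given a bound two-partner complex (receptor chains, ligand chains),
`rristack` classifies every (receptor residue, ligand residue) pair as
interacting or not, where two residues interact iff at least one of their
heavy-atom cross distances is ≤ 6.0 Å. It is aimed at structural
bioinformaticians who want a reproducible, fully inspectable RRI pipeline:
every feature, filter and learner is plain code over standard formats
(PDB, FASTA, PSI-BLAST ASCII profiles, TSV manifests).

## Method

Each residue *r* is described by a feature vector combining four families:

* **sequence** — 14 physicochemical scale values, PSSM/PSFM profile rows,
  and a conservation index C = 1 − H/ln 20;
* **structure** — solvent accessibility (ASA/RASA, Shrake–Rupley), depth
  index DPX, protrusion index CX, 3-state secondary structure
  (Kabsch–Sander), half-sphere exposure;
* **sequence neighbors** — min/max/mean/sum of the primitive features over
  a ±4 sequence window;
* **structure neighbors** — the same statistics over the ≤10 nearest
  same-protein residues within 10 Å (Cα–Cα).

A pair (r_i, r_j) is the concatenation ⟨f_i1…f_ip, f_j1…f_jp⟩, receptor
first. Training pairs come from complexes filtered by a Q-score-style
structural similarity to the test complex (threshold 0.05) and are
undersampled to 1:r positives:negatives (default 1:3). Four base
classifiers — decision tree, Gaussian naive Bayes, feed-forward network,
random forest — produce out-of-fold interaction probabilities that,
concatenated with the pair vector, train a LightGBM meta-classifier.
Evaluation is leave-one-complex-out AUROC with TPR = TP/(TP+FN) and
FPR = FP/(FP+TN), scoring *all* candidate pairs of the held-out complex.

A deterministic synthetic generator builds two-chain complexes from ideal
peptide geometry with a controllable interface size and a hydrophobic
interface composition bias, so the whole pipeline is testable without any
downloads. See `docs/methods.md` for the full model description and the
benchmark's scope.

## Worked example

```
rristack simulate --n 5 --residues 40 --target-pairs 20 --seed 7 --out demo/
rristack loocv --manifest demo/manifest.tsv --ratio 3 --seed 0 --out demo/run/
```

The `loocv` command prints the evaluation report, e.g. (exact numbers from
this command on this seed):

```json
{
  "mean_auroc": 0.9547311321645078,
  "per_complex": {
    "SYN000": 0.9751774367359072,
    "SYN001": 0.8947534766118838,
    "SYN002": 0.939749053030303,
    "SYN003": 0.9845328282828283,
    "SYN004": 0.9794428661616161
  },
  "warnings": []
}
```

`per_complex` holds one AUROC per held-out complex — how well the stack,
trained on the other four complexes, ranks that complex's true interface
pairs above its noninteracting pairs — and `mean_auroc` is their average.
Feature families can be ablated with `--no-sequence`,
`--no-structure`, `--no-seq-neighbor`, `--no-struct-neighbor`; the other
subcommands (`featurize`, `train`, `predict`, `evaluate`) expose the
intermediate artifacts as TSV/JSON.

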