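# plantmito

Machine-learning prediction of **plant mitochondrial proteins** from
sequence and functional-genomics features.

Most nuclear-encoded mitochondrial proteins carry a cleavable N-terminal
pre-sequence — an amphiphilic segment rich in positively charged (Arg, His,
Lys) and hydrophobic (Trp, Leu, Ala, Tyr, Ile) residues and depleted in
acidic ones (Asp, Glu) — but a substantial fraction is imported through
internal signals with no N-terminal mark at all. `plantmito` targets both
groups by combining local sequence features with whole-sequence and
co-expression evidence, for researchers who need proteome-scale candidate
lists of mitochondrially localized proteins in plants.

## Model

Each protein is encoded as a fixed-layout feature vector
`x = [x_AAFreq.NT | x_PSSM.NT | x_PSSM | x_Coexpr]` (20 + 440 + 400 + 5 =
865 values by default):

- **AAFreq.NT** — amino-acid frequencies over the first *L* = 22 residues
  (ambiguity codes excluded; the 20 entries sum to 1);
- **PSSM.NT** — the first *L* rows of the protein's position-specific
  scoring matrix, each entry scaled linearly to [-1, 1] per protein
  (20·L values, zero-padded for short chains);
- **PSSM** — the scaled profile rows averaged per residue type, a 20x20
  length-invariant "generalized composition" that needs no N-terminal
  signal;
- **Coexpr** — five K-nearest-neighbor co-expression scores. Per-dataset
  Pearson correlations r are combined across expression datasets by
  Fisher's z transform with inverse-variance weights,
  z̄ᵢⱼ = Σ_d (n_d − 3) z_d(i,j) / Σ_d (n_d − 3),  r̄ᵢⱼ = tanh z̄ᵢⱼ,
  and the score at each K ∈ {0.25, 0.5, 1, 2, 4}% is the positive fraction
  among the query's top-K% most co-expressed training genes. Unmapped
  proteins get five zeros.

Two classifiers score x: an RBF-kernel SVM (grid-searched cost/gamma) and a
feed-forward network with maxout hidden units (5 pieces), dropout 0.5 and a
2-way softmax, trained by SGD with momentum rising 0.5 → 0.7 and applied as
a 10-member ensemble (mean positive-class probability). Raw scores are
turned into calls by **specificity calibration**: the decision threshold at
an estimated specificity s is the empirical quantile of a held-out
negative set's scores, so that at most a fraction 1 − s of those negatives
score above it.

Evaluation follows standard practice: stratified 10-fold cross-validation,
ROC/precision-recall curves with trapezoidal AUC, sensitivity/specificity/
accuracy/precision/F1/MCC, and a paired bootstrap test for AUC differences.
A synthetic-data module generates sequences, profiles and block-structured
expression data with exactly these statistical signatures, so the whole
pipeline is testable without databases or external search tools.

## Worked example

```sh
python examples/simulate_and_cross_validate.py
```

```
study: 300 proteins, 150 positive
SVM    mean CV AUC = 0.952
maxout mean CV AUC = 0.827
AUC ~0.5 would mean the features carry no label information; values near 1
mean the planted mitochondrial signals are recovered.
```

The generated study plants an N-terminal composition bias in 70% of the
positives plus a shared expression factor; both classifiers recover the
labels far above chance from the 865-dimensional features. The other
scripts in `examples/` walk through co-expression KNN scoring, specificity
calibration (`calibrate_and_predict.py` prints how raising the level from
0.90 to 0.99 trades sensitivity 0.72 → 0.33 for stricter thresholds), and
metric reconstruction from printed rates.

## Command line

The same workflows are available as a thin CLI — `plantmito simulate`,
`train`, `calibrate`, `predict`, `evaluate` — reading FASTA, per-protein
PSI-BLAST ASCII PSSM files, delimited expression matrices with a YAML
manifest, and 2-column label/mapping tables. Every run writes a
`run_manifest.json` (version, seed, config hash, warnings) sufficient to
reproduce it.

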