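# epitopescan

Two-stage kernel-SVM prediction of **linear B-cell epitopes** and of
**antigenic protein regions** from sequence-derived features.

Antibodies raised against a well-chosen peptide can recognize the full
protein, which makes short linear epitopes the workhorse of peptide vaccines,
immunodiagnostics and the antibody pipelines behind genome-scale projects.
`epitopescan` is for computational immunologists and antibody-facility
bioinformaticians who need to rank candidate peptides (7–15 residues) and
larger immunization regions directly from sequence, using only
sequence-predictable properties: composition, evolutionary conservation,
secondary structure, solvent accessibility, disorder and low complexity.

## The model

**Stage 1 — peptide classifier.**  A peptide *p* of length *L* is encoded by
concatenated feature blocks

* cumulative multiset *n*-grams: each window of length *k* (*k* = 1…5) is
  canonicalized as a sorted residue multiset, counts normalized by *L*−*k*+1;
  the index space is all multisets of size ≤ 5
  (dimensions 20, 230, 1770, 10625, 53129 cumulatively);
* a 20×20 grid of identity-averaged PSSM weighted-observed percentages
  (evolutionary conservation, 400 features);
* identity-averaged 3-state secondary-structure probabilities plus H/E/C
  composition (20·3+3 = 63 features);
* identity-averaged solvent accessibility and disorder (20 features each) and
  one low-complexity fraction — 53,633 features in total.

Features are min–max scaled on the training set and fed to a soft-margin SVM
(linear, polynomial degree 2/3, RBF or sigmoid kernel).  The decision rule is
sign(f(x)): positive scores call epitopes, zero is reported as indeterminate.
Whole proteins are scanned window by window (length 15, step 1 by default).

**Stage 2 — region classifier.**  For a region of any length ≥ 15, the scan
score list is summarized by 20 empirical quantiles plus mean, max, min,
fraction of positive windows and the longest positive run; an RBF-kernel SVM
on these summaries predicts whether immunization with the region yields a
specific response.

Evaluation is stratified 5-fold cross-validation with pooled out-of-fold
confusion counts, precision/recall/F1/accuracy and rank-based AUC.  See
`docs/methods.md` for assumptions, defaults and limitations.

## Worked example

Generate a labeled synthetic peptide set with planted signal, cross-validate
the peptide classifier, then scan a synthetic protein carrying two planted
epitopes:

```python
import epitopescan as es

config = es.SyntheticConfig(n_pos=100, n_neg=100, seed=42)
records, annotations = es.generate_labeled_peptides(config)

features = es.FeatureConfig(blocks=es.BEST_FEATURE_BLOCKS)
kernel = es.KernelSpec("poly", degree=3)
cv = es.cross_validate(records, annotations, features, kernel, k=5, seed=42)
print(f"pooled 5-fold CV: accuracy={cv.report.accuracy:.3f} "
      f"F1={cv.report.f1:.3f} AUC={cv.report.auc:.3f}")

X, y, _ = es.featurize_records(records, annotations, features)
model = es.train(X, y, kernel, seed=42, feature_config=features, peptide_length=15)

proteins = es.SyntheticConfig(n_proteins=1, seed=99)
sequences, prot_annotations, truth = es.generate_proteins_with_planted_epitopes(proteins)
pid, sequence = next(iter(sequences.items()))
scan = es.scan_protein(sequence, prot_annotations[pid], model)
print(f"{pid}: {scan.n_windows} windows scanned")
for start, end, score in es.top_windows(scan, 3):
    print(f"  candidate epitope {start}-{end}  score={score:+.3f}")
print("planted at:", [(s, e) for p, s, e in truth])
```

Output:

```
pooled 5-fold CV: accuracy=0.960 F1=0.961 AUC=0.999
prot0000: 186 windows scanned
  candidate epitope 76-90  score=+0.031
  candidate epitope 25-39  score=+0.014
  candidate epitope 157-171  score=+0.013
planted at: [(75, 89), (157, 171)]
```

The classifier recovers the planted compositional/structural signal almost
perfectly in cross-validation, and the two planted 15-mers (75–89 and
157–171) are the 1st and 3rd of the 186 scanned windows after non-maximum
suppression; positive scores call candidate epitopes.

The same pipeline is available from the shell — `epitopescan simulate`,
`extract-features`, `train`, `cv`, `scan`, `score-peptide`, `train-region`,
`predict-region`, `compare-distributions`; every command writes a JSON run log
(seed, resolved parameters, config hash) next to its output.  Trained models
are versioned joblib artifacts written by `serialize_model` and checked on
load.

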