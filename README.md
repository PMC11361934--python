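# tcrh

Sequence-based prediction of T-cell receptor (TCR) : epitope binding with an
explainable, physicochemical-feature SVM — built for the setting that matters
in practice: test pairs whose epitopes and/or TCRs were **never seen during
training**.

`tcrh` is aimed at immunoinformaticians who work with curated CDR3β/epitope
binding tables (IEDB, VDJdb, McPAS-TCR, 10X assays) and want a classifier
whose inputs are interpretable peptide properties rather than learned
embeddings, together with leakage-aware evaluation and post-hoc Shapley
explanations.

## The model

Each amino-acid sequence *s* (an epitope, length < 16, or a CDR3β, length
9–23) is summarised by **96 whole-sequence physicochemical descriptors**:

* 88 family descriptors — per-residue scale tables averaged over the
  sequence, ⟨x⟩ = (1/L) Σᵢ x(sᵢ), for 14 published families: BLOSUM indices
  (10), Cruciani PP1–PP3 (3), FASGAI (6), Kidera factors (10), MS-WHIM (3),
  PCP (5), Physical (2), ProtFP (8), Sneath (4), SVGER (11), ST-scales (8),
  T-scales (5), VHSE (8), Z-scales (5);
* 8 scalar indices — Boman index, Henderson–Hasselbalch net charge at pH 7,
  maximum Eisenberg hydrophobic moment μH (helical angle 100°, window 11),
  mean Kyte–Doolittle hydrophobicity, Guruprasad instability index,
  isoelectric point (bisection on the charge curve), average molecular
  weight, and m/z at unit charge.

A binding pair contributes 192 features (epitope block + CDR3β block). The
pipeline drops zero-variance features, removes one member of every feature
pair with |Pearson r| > 0.8 on the training matrix (seeded choice), scales to
zero mean / unit variance with train-fitted parameters, and fits an RBF-kernel
SVM with the standard defaults (C = 1, γ = 1/(n_features · Var X)).

Evaluation supports four splits: **random**, **epitope-hard** (all test
epitopes unseen), **TCR-hard** (all test CDR3βs unseen) and **strict** (both
unseen; records crossing sides are discarded and counted). Metrics are
computed from explicit confusion counts — accuracy, precision, recall,
specificity, F1 — plus the rank-statistic AUC of ROC. Model predictions are
interpreted with **KernelSHAP** (implemented from the Shapley-kernel
weighted-regression definition, n_samples = 100, efficiency enforced exactly)
and summarised as mean |φ| rankings.

A synthetic-data module generates binding tables with a *known* planted
physicochemical rule (hydrophobicity complementarity, charge complementarity,
CDR3β molecular weight + Gaussian noise), so the whole pipeline — including
generalization across strict splits and SHAP's recovery of the drivers — is
testable at desk scale without any download.

## Worked example

```python
from tcrh import (SyntheticConfig, apply_filters, generate_dataset,
                  strict_split, featurize_pairs, prepare_features,
                  ModelSpec, train_classifier, evaluate, explain_model)

cfg = SyntheticConfig(n_pairs=9000, n_unique_epitopes=40, noise_sd=0.25, seed=11)
ds = apply_filters(generate_dataset(cfg))
sp = strict_split(ds, seed=11)          # doubly-unseen test set
X = featurize_pairs(ds.df.epitope, ds.df.cdr3b)          # (9000, 192)

tr, te, prune, *_ = prepare_features(
    X.iloc[sp.train_idx].reset_index(drop=True),
    X.iloc[sp.test_idx].reset_index(drop=True), threshold=0.8, seed=11)
model = train_classifier(ModelSpec("svm_rbf", seed=11), tr,
                         ds.df.label.iloc[sp.train_idx].to_numpy())
report = evaluate(model, te, ds.df.label.iloc[sp.test_idx].to_numpy())
_, summary = explain_model(model, tr, te, n_instances=40, n_background=60,
                           n_samples=100, seed=11)
```

Running this prints (via `len(sp.train_idx)`, `report`, `summary.head()`):

```
train/test/discard: 3892 1024 4084
retained: 72
AUC 0.9298 acc 0.8584 prec 0.8554 rec 0.8537 spec 0.8629 f1 0.8546
             feature  mean_abs_shap  rank
cdr_molecular_weight       0.231030     1
              cdr_T1       0.107416     2
             cdr_KF3       0.104328     3
```

What this means: of 9,000 generated pairs, 3,892 train and 1,024 test records
survive the strict split (4,084 cross sides and are discarded); pruning at
|r| > 0.8 keeps 72 of 192 features; the SVM separates binders from
non-binders on *doubly-unseen* sequences with AUC 0.93 — possible only
because the binding rule lives in physicochemical space, not in sequence
identity — and the SHAP ranking puts CDR3β molecular weight (a planted
driver) first, with the planted charge and hydrophobicity terms also in the
top 10 (directly or through retained correlated partners).

The same workflow is available from the shell:

```bash
tcrh simulate --n 5000 --epitopes 40 --noise 0.25 --seed 7 --out synth.tsv
tcrh split --input synth.tsv --kind strict --seed 7 --out-prefix run1
tcrh featurize --input run1.train.tsv --output train.csv
tcrh featurize --input run1.test.tsv --output test.csv
tcrh train --train train.csv --seed 7 --out model.bin
tcrh eval --model model.bin --test test.csv --report eval.json
tcrh explain --model model.bin --train train.csv --test test.csv \
             --n-samples 100 --top-k 50 --seed 7 --report shap.json
```

## Layout

```
src/tcrh/descriptors.py   96-descriptor census + bundled scale tables (CSV)
src/tcrh/data.py          reading, curation filters, the four splits
src/tcrh/pipeline.py      degenerate-drop, correlation pruning, scaling
src/tcrh/model_eval.py    SVM-RBF + comparators, confusion/metrics/ROC
src/tcrh/explain.py       KernelSHAP + importance summaries
src/tcrh/synthetic.py     planted-rule synthetic binding tables
src/tcrh/cli.py           `tcrh` command-line interface
docs/methods.md           modelling choices, conventions, limitations
```
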