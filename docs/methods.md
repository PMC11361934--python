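# Methods

This note records what `tcrh` computes, the conventions and defaults it
adopts where several were defensible, and what its synthetic benchmarks do
and do not demonstrate.

## Descriptors

Every sequence is validated against the 20 standard one-letter codes
(whitespace stripped, case folded; anything else — X, B, Z, U, O, gaps,
digits — is rejected with the offending character and position). The
96-descriptor census is fixed and ordered: 14 scale families contributing
88 dimensions (BLOSUM 10, Cruciani 3, FASGAI 6, Kidera 10, MS-WHIM 3, PCP 5,
Physical 2, ProtFP 8, Sneath 4, SVGER 11, ST 8, T 5, VHSE 8, Z 5), then the
8 scalar indices (`boman`, `charge`, `hydrophobic_moment`, `hydrophobicity`,
`instability_index`, `isoelectric_point`, `molecular_weight`, `mz`).

Family descriptors are plain arithmetic means of per-residue scale values,
so they are invariant under residue permutation and bounded by the table's
range; a homopolymer reproduces the residue's table row exactly. The test
suite asserts all of this, plus brute-force per-residue recomputation from
the raw CSVs at 1e-9, on 200 random sequences.

Scalar conventions, each a genuine choice the underlying definitions leave
open:

* **Charge / isoelectric point.** Henderson–Hasselbalch with the EMBOSS pKa
  set (N-terminus 8.6, C-terminus 3.6; side chains C 8.5, D 3.9, E 4.1,
  Y 10.1, H 6.5, K 10.8, R 12.5). Positive groups contribute
  1/(1+10^(pH−pKa)), negative groups −1/(1+10^(pKa−pH)). The scalar charge
  feature is evaluated at pH 7.0. The pI is found by bisection on [0, 14] to
  a bracket of 1e-4 pH units; the charge curve is strictly decreasing, so
  the zero crossing is unique. The pKa set is a configurable
  `AcidDissociationSet`.
* **Hydrophobicity.** Mean Kyte–Doolittle value by default; the scale name
  is a parameter and any bundled single-column scale can be used.
* **Hydrophobic moment.** Eisenberg consensus scale, helical angle 100°,
  μH = |Σ hᵢ e^(i·j·δ)|/N computed per window of length min(11, L), maximum
  over windows. A single residue gives |h|.
* **Instability index.** (10/L) × Σ Guruprasad dipeptide weights (DIWV
  table, taken from Biopython's `Bio.SeqUtils.ProtParamData`). A length-1
  sequence has no dipeptide and returns 0 with a warning.
* **Masses.** Average (isotope-abundance-weighted) residue masses plus one
  water (18.0153 Da); m/z = (M + z·1.00728)/z with z = 1 by default.

### Scale-table provenance

Tables ship as CSV package data with a sha256 manifest checked at load time;
each file header names its source. The widely reproduced tables — Kidera
factors, Sandberg Z-scales, VHSE, Cruciani PP1–PP3, MS-WHIM, Eisenberg,
Kyte–Doolittle, Boman contributions, residue masses, EMBOSS pKa — are
literature transcriptions. For the rarer families (BLOSUM indices, FASGAI,
PCP, Physical, ProtFP, Sneath, SVGER, ST-, T-scales) the original numeric
tables are not redistributable here; those files are **synthetic stand-ins**
(marked `.synthetic.` in the filename and in the header): standardized,
seeded mixtures of measured residue properties (hydropathy, volume, mass,
Grantham polarity, charge, flexibility, aromaticity, branching) built to
preserve each family's documented dimensionality and semantics. Every
correctness guarantee in the test suite is independent of which values the
tables hold — the oracles recompute from the same CSVs — but absolute
agreement with the original publications should not be assumed for the
stand-in families, and users who need the originals can drop replacement
CSVs into `tcrh/tables/` (regenerating the checksum manifest).

## Data curation and splits

Filters mirror the curation of public CDR3β/epitope tables: CDR3β length in
[9, 23], epitope length ≤ 15, exact duplicate (CDR3β, epitope, label) rows
collapsed to the first, and any pair observed with *both* labels removed
entirely (the most conservative resolution of contradictory assays). The
filter is idempotent and logs per-rule counts.

Splits operate on record indices and report everything needed to audit them:

* **random** — seeded permutation, |test| = round(n·t), t = 0.2 default.
* **epitope-hard / TCR-hard** — distinct group values are shuffled with the
  seed and assigned greedily to the test side until the covered record count
  first reaches t·n. All records of a group land on one side, so the
  disjointness invariant holds by construction; realized fractions are
  reported, not forced (with few, unequal groups they wobble around the
  target). A warning is raised when one group alone exceeds the train share.
* **strict** — a test epitope set and a test CDR3β set are drawn greedily
  with per-key fraction f = √t/(√t+√(1−t)) (f = 1/3 at t = 0.2), chosen so
  that the kept test share f²/(f²+(1−f)²) equals t. Test records have both
  keys on the test side, train records both keys on the train side, and
  crossing records are discarded and counted. Discarding is the only
  construction that guarantees both disjointness invariants simultaneously;
  at t = 0.2 it typically costs ~45% of records, which the split reports.

## Preprocessing

Order is fixed: drop zero-variance features (the training matrix decides),
prune correlated features, then standardize. Pruning enumerates feature
pairs in lexicographic name order and, whenever both members of a pair with
|Pearson r| > 0.8 (training data only) are still retained, removes one by a
seeded coin flip; a single ordered pass terminates with no retained pair
above threshold, which a brute-force scan re-verifies in the tests. The
scaler (per-feature mean and population SD) is fitted on the training matrix
only and applied to test — the leakage-safe reading of whole-dataset
scaling; `scale_jointly=True` reproduces the permissive reading.

## Models and metrics

The primary classifier is an RBF-kernel SVM with the standard defaults
pinned explicitly (C = 1.0, γ = "scale" = 1/(n_features·Var X)) and echoed
into the run log, because "default" drifts across library versions. Random
forest, gradient boosting and extreme gradient boosting are available as
comparators; they are configuration over established implementations, not
bespoke code. No class weighting and no hyperparameter search are applied.

Scores are the SVM decision function (threshold 0) or P(class 1) for the
probabilistic comparators (threshold 0.5). Decision values rather than
Platt-scaled probabilities feed the ROC because they are deterministic and
need no extra calibration fit. Confusion counts, accuracy, precision,
recall, specificity and F1 are computed from first principles; any 0/0
denominator yields NaN plus an explicit flag, never a silent 0. AUC is the
rank statistic (ties ½), which equals the trapezoidal area under the
threshold-swept ROC; the tests verify both identities and cross-check
against an independent implementation.

## KernelSHAP

A coalition z ∈ {0,1}^M keeps the instance's values where z = 1 and
background values elsewhere; v(z) is the mean model score over background
rows so masked. Attributions solve the Shapley-kernel-weighted least squares
with the efficiency constraint eliminated through one unknown, so
base + Σφ = f(x) holds to solver precision for every explanation. Sampling
draws n_samples = 100 coalitions from the size-aggregated kernel
distribution (subsets uniform within a size); the exhaustive mode uses all
2^M − 2 interior coalitions and reproduces exact Shapley values, verified
against subset-enumeration (M = 10) and permutation-averaging (M = 6)
oracles at 1e-8. Model-level explanation uses a seeded background subsample
of the training matrix and a seeded subsample of test instances; the
desk-scale benchmark uses 60 background rows and 40 instances, which keeps
the whole strict-split analysis under a couple of minutes on one core while
leaving the planted-driver ranking stable.

## Synthetic benchmark

The generator emulates the *structure* of curated binding data — a small
epitope pool (40 by default) reused across many TCRs, epitope lengths 8–15,
CDR3βs of length 9–23 with the canonical C…F motif, uniform interior
residues — and plants a known rule:

s = 2·H(epi)·H(cdr) + 1·C(epi)·C(cdr) + 0.5·MW(cdr)/1000 + ε,  ε ~ N(0, 0.25)

with H, C, MW the package's own hydrophobicity, net charge and molecular
weight. Labels threshold s at its sample median (balanced classes; a
quantile knob produces imbalance for stress tests). The default coefficients
make all three terms visible but unequal, so the SHAP ranking has a known
ground truth; noise_sd = 0.25 is small against the latent spread (SD ≈ 2.5),
i.e. labels are feature-determined but not trivially separable.

The benchmark demonstrates that the pipeline generalizes across hard and
strict splits *when binding truly is a function of whole-sequence
physicochemistry* — the desk-scale analogue of the method's central claim —
at ~4,000 train / ~1,000 test records (9,000 generated pairs before strict
discards). It does not emulate V(D)J recombination statistics, real
repertoire composition, epitope–MHC restriction, or label noise structure of
curated assays, so passing it says nothing about performance on real data;
the real-data replication path is documented in the README and requires the
external dataset.

## Known limitations

* Only CDR3β and epitope sequences are modelled — no CDR3α, V/J genes,
  MHC alleles, or structural features; the model is a binary classifier,
  not an affinity regressor.
* Group-greedy splits approximate the 80:20 target; with few epitope groups
  the realized test fraction can deviate by several points (it is reported).
* The strict split discards crossing records by design; at the default
  target that is a large fraction of the data.
* Stand-in scale tables (above) are semantically faithful but not
  numerically identical to the original publications.
* Unseen-but-similar sequences are not controlled for: the hard/strict
  splits enforce identity disjointness, not sequence-similarity
  disjointness.
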