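# Methods

`rnaffinity` predicts the binding affinity of protein–RNA complexes from
sequence- and structure-derived features with per-class gradient boosted
regression tree (GBRT) models. This note documents the model, the feature
catalogue, the evaluation and selection protocols, the synthetic benchmarks
the tests run on, and the numerical choices made where the design was open.

## Target variable

The regression target is the dissociation Gibbs free energy

    dG = −R · T · ln(Kd)        [kcal/mol]

with R = 1.987×10⁻³ kcal mol⁻¹ K⁻¹, Kd the dissociation constant in mol/L
and T the absolute temperature in K. The sign convention makes dG positive
for sub-molar Kd, so *larger dG = tighter binding*. Affinity tables may state
Kd, dG, or both; when both are present they must agree through the formula to
10⁻⁶ kcal/mol, and a missing temperature falls back to 298 K with a warning.

## Input data and admission rules

A complex is a PDB-format structure with at least one protein and one RNA
chain. Chains are typed by residue-alphabet majority: a chain is
protein/RNA when more than 80% of its non-water residues carry standard
amino-acid / A,U,G,C names — this tolerates occasional modified residues
(e.g. MSE), which map to `X` in sequences, count toward chain length, and are
excluded from property sums. Only the first model of multi-model files is
used and the highest-occupancy alternate location is kept; coordinates
themselves feed no feature (structural information enters through external
tool outputs, below).

Admission: every retained protein chain needs ≥ 30 residues and every
retained RNA chain ≥ 2 nucleotides; short chains are dropped with a warning
and a complex is rejected when no protein or no RNA chain survives.
Multi-chain proteins (and RNAs) are handled by concatenating the chains of
each kind; every sequence feature is additive or a percentage, so chain
order is immaterial.

## Feature catalogue

28 features, registered with name, family and units in a fixed order that
also settles all tie-breaking (`rnaffinity.registry.DEFAULT_REGISTRY`).

**Protein, sequence-based (12).** Total molecular mass (sum of per-residue
free-amino-acid average masses, e.g. Gly 75.07 Da); total hydrogen-bonding
capacity (per-residue side-chain donor+acceptor sites plus 2 backbone sites);
counts and percentages of hydrophilic, hydrophobic, aromatic-or-positive,
charged, and polar residues. The property table is a versioned YAML config
(`data/residue_properties.yaml`) so alternative hydropathy partitions or mass
conventions can be swapped in; the default sets are
hydrophobic {A,V,L,I,M,F,W,C}, hydrophilic = the other twelve,
aromatic {F,W,Y,H}, positively charged {K,R,H}, charged {D,E,K,R,H},
polar {S,T,N,Q,Y,C,H}. "Aromatic and positively charged" is a union count,
so histidine is counted once.

**Protein, structure-based (9).** From classic DSSP output: helix residue
count (8-state codes H/G/I) and sheet residue count (E/B), their summed
residue masses and percentages, helix/sheet segment counts (auxiliary), and
the total solvent-accessible surface area (sum of the DSSP ACC column, Å²).
The ACC sum is absolute; despite the field's habit of calling this quantity
"relative", no per-residue normalization is applied by default.

**RNA, sequence-based (1).** Molecular mass from base composition,

    W = 329.2·A + 306.2·U + 305.2·C + 345.2·G + 159   [Da]

applied once per RNA molecule (the 159 Da terminal term is added per chain)
and summed over chains.

**RNA, structure-based (6).** From RNAfold partition-function output: the
Boltzmann probability of the MFE structure and the ensemble diversity
(expected base-pair distance). From RNAVIEW-style annotation: the number of
cis Watson–Crick/Watson–Crick (cWW) pairs and their frequency relative to all
annotated pairs, and the number of 0BPh base-phosphate interactions and their
frequency relative to all annotated base-phosphate entries; 0/0 is defined
as 0. The core never executes DSSP/RNAfold/RNAVIEW — it parses their output
files, which keeps the pipeline testable without binaries (one integration
test does shell out to the installed RNAfold to pin the dialect).

## Complex classification

Complexes are grouped into six classes by the type of RNA bound: (I)
single-stranded RNA, (II) duplex RNA, (III) tRNA, (IV) RNA loop structures,
(V) small RNA fragments, (VI) miscellaneous. The authoritative path is an
explicit label in the manifest (class numerals or NDB-style category
strings), which always dominates. When no label exists, a configurable rule
cascade runs with fixed precedence V → II → III → IV → I → VI: total length
< 8 nt → V; ≥ 2 chains with > 50% of nucleotides in inter-chain cWW pairs →
II; a 60–100 nt single chain with ≥ 3 hairpin stem-loops → III; a single
chain with ≥ 1 hairpin and ≥ 30% paired nucleotides → IV; no annotated pairs
→ I; otherwise VI. The cascade is a reproducible stand-in for manual
database annotation, not a claim about how any curator works; only the
explicit-label path is authoritative.

## The GBRT learner

The model is the stagewise additive expansion

    F_M(x) = β₀ + Σ_{m=1..M} ν · β_m · h_m(x)

under the half squared-error loss Ψ(y, F) = (y − F)²/2, for which the
pseudo-residuals (negative loss gradients) are the ordinary residuals and β₀
is the target mean. Each weak learner h_m is a fixed-size least-squares CART
tree fit to the current pseudo-residuals; leaf values are the mean
pseudo-residual in the leaf; β_m comes from the exact line search
β = ⟨h, y−F⟩ / ⟨h, h⟩ (identically 1 under mean leaf values — computed and
stored anyway so alternative leaf-value rules keep working, with β = 0 when a
tree predicts all zeros); ν ∈ (0, 1] is the shrinkage.

Trees are grown by exact greedy search: every split minimizes the summed
within-child SSE over all (feature, midpoint-threshold) candidates, with
ties broken toward the lowest feature index, then the lowest threshold, so
training is fully deterministic — a fixed input yields a byte-identical
serialized model. Constant targets produce a single-leaf tree. Missing
feature values are rejected at fit time (the pipeline drops incomplete rows
per class with a logged count). There is no subsampling. Tree construction
and traversal run as numba-compiled kernels over a flat-array node
representation; the greedy semantics are pinned by a naive double-loop
enumeration oracle in the test suite, and staged training predictions agree
with scikit-learn's gradient boosting (identically configured) to machine
precision. Note that greedy trees are not globally optimal: the depth-2
greedy tree frequently differs from the best possible depth-2 tree, which is
expected CART behavior.

Defaults: M = 500 trees, ν = 0.1, depth 3, `min_samples_leaf` 1 — common
gradient-boosting settings for tens of training samples, all exposed in
configs and logs. The benchmark experiments shipped with the package use a
smaller ensemble (M = 20, depth 2, ν = 0.2), sized for their 8–103 samples
per fit and the many thousands of fits a leave-one-out selection run
performs. Models serialize to a versioned JSON schema (β₀, ν, per-tree
nested node records, β_m, feature names, config).

## Evaluation and feature selection

Performance is the Pearson correlation r between leave-one-out
cross-validation (LOOCV) predictions and measured dG, reported with the mean
absolute error (kcal/mol) and the coefficient of determination R². r and R²
raise on constant inputs rather than silently returning 0.

Selection is a wrapper method run independently per class: (1) each feature
is scored by the LOOCV r of a model trained on that feature alone (scoring by
LOOCV rather than training-set r is a deliberate choice — every reported
measure is LOOCV — and both modes are switchable); (2) the ten best-scoring
features form the candidate pool, ties keeping registry order; (3) starting
from the best single feature, the candidate that most improves the LOOCV r of
the refit model is added, stopping when the best gain is ≤ 10⁻⁴ (strict
improvement with a small epsilon prevents noise-driven growth). The final
model is refit on the selected set and reported by LOOCV on that set;
selection is not re-run inside each fold (nested cross-validation is out of
scope). Classes with fewer than 3 usable complexes are skipped with a
warning. Ablation mode repeats training under the feature masks all /
protein-only / RNA-only / sequence-only / structure-only.

## Synthetic benchmarks

No deposited structures are downloaded; all tests run on generated data.

The toy-complex generator emits a mutually consistent PDB file, DSSP output,
RNAfold partition-function output and RNAVIEW-style annotation from one
seed, with coordinates on a helix-like curve (no feature reads them, so
geometric realism is not attempted). It exercises parsers, the admission
boundary and the end-to-end pipeline; it does not emulate real secondary
structure statistics, B-factors, or crystallographic artifacts.

The affinity benchmark mirrors the shape of a curated 103-complex study set:
six classes sized 21/34/8/9/11/20, dG in 5–15.2 kcal/mol. In shared-signal
mode, dG is an equal-weight combination (effect size 1.4 kcal/mol per
standardized feature) of 3 planted informative features among 12 noise
features plus N(0, 1) residual noise — a noise level comparable to the
~1.1 kcal/mol LOOCV MAE regime this kind of model reaches — and values are
clipped to the stated range. In class-specific mode each class responds to
its own single feature (effect 3.0, noise sd 0.5), a construction under
which pooling classes is actively misleading. Passing benchmarks therefore
demonstrates that the machinery (selection, LOOCV, per-class training)
behaves correctly on data with the study's shape; it does not certify
accuracy on real complexes, where features are correlated, noise is not
Gaussian, and class labels are imperfect.

Two packaged experiments (`rnaffinity.experiments`) run on these benchmarks:
greedy-selection recovery over 50 seeded replicates (fraction of replicates
whose selected set contains every planted feature), and the per-class vs
pooled contrast (pooled LOOCV r should fall below every per-class r).

## Numerical choices and edge cases

- Split thresholds at midpoints between consecutive distinct sorted values;
  ties by lowest feature, then lowest threshold; stable sorts throughout.
- Degenerate inputs raise early: empty sequences, empty chains, nonpositive
  Kd or T, constant vectors in r/R², LOOCV with n < 3, arity mismatches.
- Undefined single-feature scores rank last (−∞) and are logged, not dropped.
- Relative-frequency denominators: cWW over annotated pairs, 0BPh over
  annotated base-phosphate entries, 0/0 → 0.
- Ensemble features for multi-chain RNAs default to the single folding
  output supplied per complex; per-chain folding is the caller's choice.
- All randomness flows from explicit integer seeds; replicate seeds are
  derived as `seed·1000 + replicate`.

## Known limitations

- The heuristic class cascade is a tool extension; curated labels should be
  preferred whenever available.
- The 37-feature accountings that circulate for this problem do not
  reconcile exactly with any split into sequence/structure counts; this
  package's registry names all 28 emitted features explicitly so any
  alternative accounting can be reproduced with selection masks.
- Greedy forward selection on n ≈ 10 classes is high-variance; the reported
  per-class correlations on real data of that size should be read with wide
  confidence intervals.
- mmCIF input, interface/contact features, and affinity curation from
  literature are out of scope.
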