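# rnaffinity

Protein–RNA binding affinity prediction from sequence and structure
features, with per-class gradient boosted regression tree models.

Protein–RNA interactions drive gene expression and its regulation, but
experimentally measured binding affinities for protein–RNA complexes are
scarce, and few computational predictors exist. `rnaffinity` is for
structural bioinformaticians who have complex structures (PDB files plus
standard tool outputs) and want quantitative affinity estimates, and for
methodologists who want a transparent, fully testable reference
implementation of the approach: classify complexes by the type of RNA bound,
extract a catalogue of physicochemical and structural features, and train a
boosted-tree regressor per class with greedy feature selection under
leave-one-out cross-validation (LOOCV).

## The model

The target is the dissociation free energy ΔG = −RT ln K_d (kcal/mol,
R = 1.987×10⁻³ kcal mol⁻¹ K⁻¹); larger ΔG means tighter binding. The
regressor is a gradient boosted regression tree (GBRT) ensemble

    F_M(x) = β₀ + Σ_{m=1}^{M} ν β_m h(x; Θ_m)

where each h(·; Θ_m) is a fixed-size least-squares CART tree fit to the
pseudo-residuals (negative gradients of the half squared-error loss,
ỹᵢ = yᵢ − F_{m−1}(xᵢ)), leaf values are mean pseudo-residuals, β_m is an
exact line search, and ν is the shrinkage. Features span four families:
protein sequence (masses, hydrogen-bond capacity, residue-class counts),
protein structure (DSSP helix/sheet counts, masses, percentages, summed
accessible surface), RNA sequence (base-composition mass
329.2·A + 306.2·U + 305.2·C + 345.2·G + 159 Da), and RNA structure (MFE
structure frequency, ensemble diversity, cWW and base-phosphate counts from
RNAVIEW-style annotation). Model quality is the Pearson r between LOOCV
predictions and measured ΔG, with MAE and R² reported alongside; features
are chosen per class by single-feature ranking (top 10) followed by greedy
forward selection while the LOOCV r keeps improving. See
[docs/methods.md](docs/methods.md) for the full account.

## Worked example

Scripts under `examples/` each demonstrate one capability; e.g. greedy
feature selection on the packaged study-shaped benchmark (103 synthetic
complexes in six classes, three informative features planted among twelve
noise features):

```bash
$ python examples/04_feature_selection.py
top single-feature LOOCV correlations:
  * feat_02: r = 0.487
  * feat_01: r = 0.432
  * feat_00: r = 0.369
    feat_03: r = 0.112
    feat_04: r = 0.097
greedy trajectory (feature added -> LOOCV r of the refit model):
  + feat_02 -> r = 0.487
  + feat_01 -> r = 0.738
  + feat_00 -> r = 0.869
  + feat_07 -> r = 0.871
  + feat_05 -> r = 0.872
planted features ['feat_00', 'feat_01', 'feat_02'] recovered: True
```

The three planted features (starred) rank highest individually, and the
greedy pass collects all three — the LOOCV correlation climbs from 0.49 with
one feature to 0.87 with three, after which the two noise stragglers add
essentially nothing. Other examples cover the K_d → ΔG conversion, feature
extraction from a synthetic complex with matched DSSP/RNAfold/RNAVIEW
outputs, fitting and serializing the boosted ensemble, and the per-class vs
pooled contrast (pooled r ≈ 0.33 against per-class r ≥ 0.86 when each RNA
class carries its own signal — classifying complexes by RNA type first is
what makes the problem learnable).

A thin CLI wraps the same pipeline for shell use:

```bash
rnaffinity --seed 3 make-fixtures -o demo/
rnaffinity extract-features demo/manifest.tsv --base-dir demo -o demo/features.tsv
rnaffinity train demo/features.tsv demo/affinities.tsv --pooled -o demo/models
rnaffinity predict demo/models demo/features.tsv -o demo/predictions.tsv
```

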