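# nucleotexture

Quantitative texture analysis of cell-nucleus regions of interest (ROIs)
in histology micrographs, aimed at detecting subtle chromatin
redistribution — e.g. in proximal tubule cell nuclei after mild acute
kidney injury (AKI) — that is invisible to conventional microscopic
assessment. The package extracts gray-level co-occurrence matrix (GLCM)
features and first-level Haar wavelet subband energies per nucleus,
compares the two groups nonparametrically, and trains baseline
classifiers with ROC analysis. Because such micrograph sets are rarely
deposited publicly, a seeded synthetic-nucleus generator with the same
statistical structure makes every stage testable end to end.

Intended users: image-analysis and digital-pathology researchers who
have (or simulate) per-nucleus ROI masks and want a reproducible,
scriptable alternative to GUI texture tools.

## The features

For a quantized ROI (G gray levels), the co-occurrence matrix
p(i, j) is the normalized joint distribution of gray levels at pixel
pairs separated by displacement (d, θ); only pairs with both endpoints
inside the nucleus mask are counted. Six features are computed (averaged
over θ ∈ {0°, 45°, 90°, 135°} at d = 1 by default):

    ASM  = Σᵢⱼ p(i,j)²                          uniformity
    IDM  = Σᵢⱼ p(i,j) / (1 + (i−j)²)            local homogeneity
    CON  = Σᵢⱼ (i−j)ᵏ p(i,j)ⁿ                   contrast (k = 2, n = 1)
    COR  = (Σᵢⱼ ij·p(i,j) − μₓμ_y) / (σₓσ_y)    correlation
    SA   = Σ_s s·p_{x+y}(s)                     sum average
    SVAR = Σ_s (s − SA)²·p_{x+y}(s)             sum variance

where p_{x+y}(s) = Σ_{i+j=s} p(i,j). From a level-1 orthonormal Haar
decomposition of the raw (unquantized) patch, the three detail-band
energies are

    En_b = Σ_{(x,y)∈ROI} (d_b(x,y))² / n,   b ∈ {LH, HL, HH},

with n the number of subband coefficients whose 2×2 support touches the
mask. Groups are compared feature-wise with the two-sided Mann–Whitney
U test; logistic regression, an RBF-kernel SVM and a 100-tree random
forest are trained on a stratified 80/20 split of the nine-feature
vectors and scored by held-out accuracy and trapezoidal AUC.

## Worked example

```python
import nucleotexture as nt
from nucleotexture.pipeline import RunConfig, synthetic_feature_table
from nucleotexture.compare import summarize_groups
from nucleotexture.classify import train_and_evaluate

cfg = RunConfig(synthetic=nt.SyntheticConfig(n_per_class=100, seed=7), seed=7)
table = synthetic_feature_table(cfg)          # 200 rows × 12 columns
for s in summarize_groups(table):
    print(f"{s.feature:5s} control {s.mean_ctrl:8.3f} ± {s.sd_ctrl:7.3f}   "
          f"AKI {s.mean_aki:8.3f} ± {s.sd_aki:7.3f}   p = {s.p_value:.2e}")
for rep in train_and_evaluate(table, seed=7):
    print(f"{rep.model:20s} accuracy = {rep.accuracy:.3f}  AUC = {rep.auc:.3f}")
```

prints

```
ASM   control    0.003 ±   0.001   AKI    0.002 ±   0.000   p = 7.40e-28
IDM   control    0.276 ±   0.023   AKI    0.241 ±   0.014   p = 1.29e-23
CON   control   15.972 ±   3.254   AKI   22.655 ±   3.355   p = 8.16e-26
COR   control    0.945 ±   0.013   AKI    0.937 ±   0.011   p = 1.12e-08
SA    control   56.098 ±   6.465   AKI   61.942 ±   6.432   p = 6.56e-09
SVAR  control  584.263 ± 128.084   AKI  703.675 ± 111.246   p = 4.00e-10
EnLH  control   31.540 ±   7.646   AKI  157.341 ±  25.971   p = 2.56e-34
EnHL  control   31.454 ±   7.176   AKI  158.348 ±  26.400   p = 2.56e-34
EnHH  control   14.081 ±   2.917   AKI   69.945 ±  10.333   p = 2.56e-34
logistic_regression  accuracy = 1.000  AUC = 1.000
svm                  accuracy = 1.000  AUC = 1.000
random_forest        accuracy = 1.000  AUC = 1.000
```

Uniformity (ASM) and homogeneity (IDM) drop in the injured class while
contrast, the sum statistics and all three detail energies rise — the
signature of increased chromatin structural heterogeneity. On this
synthetic population the classes are fully separable; on real
micrographs the separation is weaker, but the directions are the same.

The same pipeline runs from the shell and on real data (point
`features` at your own manifest of images + masks):

    nucleotexture run --seed 7 --out run/
    nucleotexture features --manifest data/manifest.csv --out features.csv

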