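# Methods

## Model and procedure

The package treats a multiblock table as a partition Ψ = (X, Y, D): disjoint
numeric variable blocks with roles *independent* / *dependent*, plus a
description block providing one categorical class label per sample. The
analysis asks whether two blocks induce consistent geometry on the classes,
a question that remains answerable when the sample-level regression signal
is weak.

**Preprocessing** runs in a fixed order: (1) delete every row with a missing
value in any numeric block column (description columns never trigger
deletion); (2) remove box-plot outliers — per column, quartiles by linear
interpolation of order statistics ("type 7"), Tukey fences
[Q1 − f·IQR, Q3 + f·IQR] with f = 1.5 by default, whole-row removal when any
column flags the row; (3) z-score each numeric column with the sample (n−1)
standard deviation, fit on the post-filter rows only. The outlier pass runs
exactly once; re-running it would recompute fences and remove further rows.
Fences are global by default (a per-class option exists) — with many
location classes the pooled marginal is close enough to unimodal that global
fences behave sensibly, and a single fixed choice keeps runs comparable.

**Dimension reduction** is per-block PCA by thin SVD of the centered matrix.
Because the pipeline has already z-scored every column, this is
correlation-matrix PCA. Scores are the variance-carrying UΣ (not U): the
downstream ellipsoids are covariance-based and therefore invariant to this
choice, but score plots keep the data's scale. Loading signs are fixed by
making each column's largest-magnitude element positive so repeated runs
produce identical plots. The shared retained dimension is
k = max over blocks of k_i, where k_i is the smallest component count whose
cumulative explained-variance ratio (s_j²/Σs²) reaches the threshold σ
(default 0.8). A low-rank block cannot be projected beyond its rank, so
extraction caps k at the block's own component count; the per-block minima
k_i are reported alongside the global k.

**Confidence ellipsoids.** Each class of each block's score matrix is
modelled as approximately Gaussian: center = class mean, shape = class
sample covariance, squared radius = the χ²_k quantile at the confidence
level (default 0.95). A point is inside iff its squared Mahalanobis distance
is ≤ the radius; boundary points count as inside (a measure-zero convention
fixed for determinism). The alternative reading — the smallest ellipse
literally covering 95% of the class's points — coincides with the Gaussian
region asymptotically for Gaussian data but has no closed form; the
χ²-quantile region is deterministic and is what the Gaussian modelling
assumption licenses, so it is the implemented definition. Covariances whose
condition number exceeds 1e10 (or with a non-positive eigenvalue) receive a
ridge of 1e-8·trace/k so degenerate classes cannot crash the full
|d|×|d| sweep. Classes with fewer than k + 2 members are dropped from both
rows and columns of the similarity matrix, with a warning and a record —
the index is undefined without an estimable ellipsoid.

**Similarity index.** For ordered classes (p, q) in block i,
S_{i,p,q} = (number of class-p samples inside both Θ_ip and Θ_iq) / |D_p|.
The denominator is the class size, so the matrix is asymmetric; the diagonal
S(p,p) is the own-ellipsoid coverage (≈ level for Gaussian classes). The
analysis plane defaults to the first 2 score columns — the standard score-
plot dimensionality, and the one the class-separation figures use — while
the machinery itself is dimension-agnostic up to the retained k.

**Integration.** For a block pair (a, b) and class p, the Pearson
correlation between rows S_a(p, ·) and S_b(p, ·) over the classes usable in
both blocks, excluding the self entry by default: S(p,p) measures
aggregation, not cross-class similarity, and would otherwise couple the two
profiles through a shared large diagonal. Spearman and self-inclusion are
available as options. Classes with an undefined correlation (zero-variance
profile, fewer than three paired entries) are skipped and recorded, never
imputed. Each pair is summarized by (min, mean, max) over classes.

## Regression baselines

Three conventional routes from the independent blocks to one response
column, all scored by leave-one-out R² = 1 − SSE_pred/SST (the selection or
tuning step is re-run inside every fold):

* **Forward stepwise OLS** — at each step the candidate with the largest
  partial-F enters if it exceeds the F(1, n−p−1) critical value at α = 0.05;
  forward-only (no elimination step), ties broken by column order,
  zero-variance candidates skipped. Under a pure-noise null with p
  candidates the model stays empty with probability ≈ (1−α)^p, which the
  test suite checks against simulation.
* **PLS1** — `scikit-learn`'s PLSRegression; the component count is chosen
  by a leave-one-out grid unless fixed.
* **ε-insensitive SVR** — linear kernel on standardized inputs by default
  (the primal hinge-tube formulation is linear); ε = 0.1, C = 1.

Leave-one-out at the real study's scale (≈170k rows) is quadratic and out of
reach for a desk run; baseline experiments therefore run at n ≤ ~500
(35 classes × 12 rows in the contrast experiment), which is ample for the
qualitative claim they support.

## Synthetic generator

The generator emulates the structure the method assumes, shaped like the
motivating agronomy table: 35 location classes × 100 samples, blocks of 14
(climate), 4 (altitude) and 5 (chemistry) variables.

* **Clusters.** Within each block a class is an isotropic Gaussian cluster
  (sd `within_class_sd` = 1) around a class mean.
* **Spectrum.** Class means are built from per-block latent factors whose
  standard deviations decay geometrically (`spectrum_decay` = 0.5 per
  factor), mixed into observed variables by a random rotation and scaled by
  `between_class_sd` = 3. The decay reflects real environmental tables,
  where a few dominant gradients carry most between-location variation; it
  is also a structural requirement for any low-dimensional score analysis —
  with an isotropic latent spectrum each block's leading PC plane is an
  unrelated random projection and no cross-block signal survives dimension
  reduction, for this method or any other score-plot technique.
* **Coupling.** A dependent block's shaped factor coordinates are
  ρ·M(source factors) + √(1−Σρ²)·own factors, with the Gaussian map M drawn
  once per seed and rescaled row-wise so the coupled part reproduces the
  target block's own spectrum. Coupling therefore acts purely at the
  between-class level; within-class residuals of different blocks are
  independent. Multiple sources combine with Σρ² ≤ 1 enforced.
* **Calibration.** With these defaults the per-variable population R² of a
  regression from the source block onto a dependent variable is roughly
  ρ²·σ_b²λ̄/(σ_b²λ̄+σ_w²) ≈ 0.7·ρ² — about 0.09 at the default coupling
  ρ = 0.35 and about 0.13 at ρ = 0.45, the weak-correlation regime the
  method targets. The contrast experiment uses couplings (0.45, 0.05) for
  (climate, altitude) → chemicals: regression stays below R² = 0.3 while
  the integrated correlation still ranks the pairs correctly (averaged over
  ten replicates; a single replicate's ordering is noisy at this signal
  strength).
* **Artifacts.** `inject_artifacts` blanks random numeric cells and plants
  outliers at Q3 + 10·IQR — beyond any 1.5·IQR fence whenever the column's
  IQR is positive — returning ground-truth cell lists for preprocessing
  tests.

What the generator does *not* emulate: real climate/soil covariance
structure and units, non-Gaussian or skewed class shapes, heteroscedastic
classes, spatial autocorrelation between neighboring locations, and
class-size imbalance. Passing tests therefore demonstrate correctness and
calibration of the machinery under the stated Gaussian cluster model, not
robustness to those real-data features.

## Numerical choices and degenerate inputs

* Membership uses a Cholesky solve of the class covariance, never an
  explicit inverse; a vectorized-vs-scalar-loop equivalence test pins the
  arithmetic.
* Quartiles: linear interpolation ("type 7"), recorded in the preprocessing
  report for reproducibility.
* Zero-variance columns: error in z-scoring (named column); skipped with a
  warning in stepwise selection.
* Constant responses make leave-one-out R² undefined (SST = 0): error.
* All stochastic components take a single integer seed;
  generation, the pipeline and the figures are deterministic given it.

## Problem sizes

Simulation experiments run at the generator's native scale (3,500 rows) for
the ellipsoid/integration machinery, 10,000 draws for coverage calibration,
and n = 420 for leave-one-out regression. These sizes make every experiment
a desk-scale computation while keeping binomial/estimation error well inside
the asserted tolerances (coverage tolerance ±1 percentage point at
n = 10,000 against a binomial standard error of ≈0.2pp).

## Known limitations

* The 2-D default analysis plane can miss class structure that only appears
  in higher components; raise `dims` (up to the retained k) to probe this.
* Ellipsoid coverage is calibrated for approximately Gaussian classes;
  heavy-tailed classes will under-cover and depress the diagonal.
* The integrated correlation is a descriptive index: no significance test is
  attached, and profile correlations over few usable classes are noisy.
* Global box-plot fences can over-trim when classes are strongly separated
  in raw units; use `--per-class` fences in that situation.
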