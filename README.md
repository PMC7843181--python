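# mcea — multiblock weak-correlation analysis via PCA confidence ellipsoids

`mcea` detects weak association between blocks of variables measured on the
same samples — for example climate, altitude and leaf-chemistry tables for
tobacco grown at many locations — in the regime where ordinary regression of
one block on another explains almost nothing (leave-one-out R² around 0.1).
Instead of modelling samples directly, it compares how the blocks *group the
sample classes*: per block it fits a confidence ellipse to every class in PCA
score space, counts class members falling in ellipse overlap regions to form
an asymmetric class-similarity index, and then correlates the similarity
profiles of two blocks class by class.

## Method

The sample table Ψ is partitioned into disjoint variable blocks
Ψ = (X₁, …, X_{M₁}, Y₁, …, Y_{M₂}, D): independent blocks X, dependent
blocks Y, and a description block D whose label column splits the n samples
into |d| classes. The pipeline is:

1. **Preprocess** — delete rows with missing numeric cells, remove box-plot
   outliers (Tukey fences Q1 − 1.5·IQR, Q3 + 1.5·IQR, whole-row removal),
   z-score each column: x′ = (x − μ)/σ.
2. **PCA per block** — SVD of the centered block, A = UΣVᵀ; scores T = UΣ.
   The retained dimension is k = max over blocks of the minimal component
   count whose cumulative explained variance reaches a threshold σ
   (default 0.8); extraction is capped at each block's rank.
3. **Confidence ellipsoids** — class j of block i is modelled as Gaussian in
   score space: Θ_ij = {x : (x − μ̂_ij)ᵀ Σ̂_ij⁻¹ (x − μ̂_ij) ≤ χ²_k(level)},
   with level 0.95 by default and a 2-D analysis plane following standard
   score-plot practice.
4. **Similarity index** — for an ordered class pair (p, q) in block i,

       S_{i,p,q} = ‖Θ_ip ∩ Θ_iq‖_p / ‖D_p‖,

   the fraction of class-p samples inside *both* ellipsoids. It is
   asymmetric (normalized by class p's size); S_{i,p,p} measures how tightly
   class p aggregates (≈ the confidence level for Gaussian classes).
5. **Integration** — for two blocks a, b and each class p, the Pearson
   correlation between the profile rows S_a(p, ·) and S_b(p, ·) (self-entry
   excluded), summarized by (min, mean, max) over classes. A high mean says
   the two blocks induce consistent class geometry — association at the
   class level even when sample-level regression fails.

Three regression baselines (forward stepwise OLS with partial-F entry, PLS1,
ε-insensitive SVR), each scored by leave-one-out R², quantify what the
conventional route sees on the same data. A synthetic multiblock generator
with tunable between-class coupling provides ground truth for all of it.

## Worked example

Plant a strong climate→chemicals coupling (0.9) and a weak
altitude→chemicals coupling (0.1) in the generator, then ask the integrated
analysis to rank the block pairs:

```python
from mcea import SyntheticConfig, generate, integrate_blocks
from mcea.cli_report import analyse_blocks

cfg = SyntheticConfig(seed=17, coupling={("climate", "chemicals"): 0.9,
                                         ("altitude", "chemicals"): 0.1})
bc = generate(cfg)                      # 35 classes x 100 samples, 14+4+5 vars
models, ksel, score_mats, sims = analyse_blocks(bc, sigma=0.8, level=0.95, dims=2)
print("global k:", ksel.global_k, "| per-block minimum:", ksel.per_block_k)
for res in integrate_blocks(sims):
    print(res.pair, "min/mean/max = %+.4f / %+.4f / %+.4f" % res.summary)
```

prints

```
global k: 9 | per-block minimum: {'climate': 9, 'altitude': 2, 'chemicals': 3}
('climate', 'altitude') min/mean/max = -0.3353 / -0.0253 / +0.3001
('climate', 'chemicals') min/mean/max = -0.3528 / +0.2276 / +0.6152
('altitude', 'chemicals') min/mean/max = -0.3210 / -0.0155 / +0.2382
```

The climate–chemicals pair carries the largest mean integrated correlation
(+0.23), the weakly coupled altitude–chemicals pair sits at noise level
(−0.02): the planted coupling ordering is recovered. On the same data a
regression from climate to a chemical column reaches leave-one-out R² of
only ~0.15 — the weak-correlation regime the method is built for.

The same flow is available from the shell:

```bash
mcea simulate --seed 17 --out synth.csv          # writes synth.csv + synth.yaml
mcea run synth.csv synth.yaml --out-dir results  # full pipeline + manifest
mcea report synth.csv synth.yaml --target C01 --out-dir figs
```

`mcea report` renders the ellipse score plot with marginal densities, one
similarity heatmap per block, and a radar chart of one class against all
others (radial scale inverted: 1 at the center, so similar classes plot near
the middle).

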