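# halfsam

Differential-expression testing for **heterogeneous diseases** — conditions
(colorectal cancer, acute lymphoblastic leukemia, ...) in which the case
group mixes etiological subtypes, so a gene may be overexpressed in some
patients and normal or underexpressed in others. The case group is then
over-dispersed relative to the controls, and tests that pool the two group
variances lose power.

`halfsam` implements the **half SAM score**, a moderated t-like statistic
whose denominator uses only the *control-group* standard deviation plus an
additive fudge factor, alongside its three natural comparators, with
permutation-based inference, Benjamini–Hochberg FDR control, and a Monte
Carlo engine for type-I-error/power evaluation.

## The statistics

For gene *g* with case samples (n₁, X̄₁, s₁) and control samples
(n₀, X̄₀, s₀):

| statistic | definition | null calibration |
|---|---|---|
| Student's t | tₛ = (X̄₁−X̄₀) / (sₚ·√(1/n₁+1/n₀)) | t, df = n₁+n₀−2 |
| half Student's t | tₕ = (X̄₁−X̄₀) / (s₀·√(1/n₁+1/n₀)) | t, df = n₀−1 |
| SAM | d = (X̄₁−X̄₀) / (sₚ·√(1/n₁+1/n₀) + c₀) | resampling |
| **half SAM** | dₕ = (X̄₁−X̄₀) / (s₀·√(1/n₁+1/n₀) + c₀) | resampling |

with sₚ² = ((n₁−1)s₁² + (n₀−1)s₀²)/(n₁+n₀−2) the pooled variance. The
fudge factor c₀ ≥ 0 is chosen on a percentile grid of the per-gene
denominator scatter to minimize the coefficient of variation of the
score's spread across genes (see `docs/methods.md`), stabilizing genes
with near-zero variance. The SAM-type scores do not follow a t
distribution, so significance comes from label permutations (per-gene or
pooled across genes) or, in simulation studies, from a simulated-null
critical value.

## Worked example

Synthetic 1000-gene dataset, 10 case / 10 control samples, control SD 15,
case SD inflated 1.5×, with the first 50 genes shifted upward by 30:

```python
import numpy as np
from halfsam import SimulationConfig, simulate_dataset, DifferentialExpressionModel

cfg = SimulationConfig(md=30.0, r=1.5, n_genes=1000, nonnull_fraction=0.05,
                       seed=2024)
matrix = simulate_dataset(cfg)
res = DifferentialExpressionModel(matrix, method="half_sam").fit(
    threshold_type="fdr", level=0.05, B=200, seed=7, null_mode="pooled")
print(res.summary())
```

```
Differential Expression Results
==============================================
statistic:            half_sam
genes:                1000
samples:              20 (10 case / 10 control)
permutations (B):     200
p-value null:         pooled
threshold:            fdr <= 0.05
seed:                 7
fudge factor c0:      11.6215
significant genes:    45 (4.50%)
----------------------------------------------
gene               score     pvalue       padj
g14                2.337      5e-06     0.0005
g15                2.559      5e-06     0.0005
...
```

The fit estimates c₀ ≈ 11.6 from the control-only scatter distribution,
computes dₕ per gene, and calibrates it against 200 label permutations
pooled across genes (p-value resolution 1/(1+200·1000)). Of the 45 genes
called at FDR 0.05, 40 are among the 50 planted ones. The same pipeline
runs from the shell:

```bash
halfsam test --matrix matrix.tsv --labels labels.txt \
             --method half_sam --fdr 0.05 --B 1000 --seed 7 --out results/
halfsam simulate --scenario-config grid.yaml --seed 3 --out power.tsv
```

`--method all` writes one TSV per statistic plus a JSON manifest that
makes the run replayable. The label file accepts explicit
`case`/`control` tokens or the signed-sample-id dialect used by the
classic colon-cancer expression matrix (positive id = tumor).

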