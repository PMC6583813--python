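# spdurbin

Spatial Durbin modelling of areal (county-level) health data: maximum-
likelihood estimation, decomposition of covariate effects into direct
(within-area) and indirect (between-area spillover) components, and a
"spatial profile" that partitions those effects over neighbor orders.

## Who this is for

Ecological studies in spatial epidemiology — for example, the association
between a county's social capital and its prevalence of frequent mental
distress — cannot treat areas as independent: counties share labor and
housing markets, and an attribute of one county influences outcomes in its
neighbors. The spatial Durbin model (SDM) makes that dependence explicit.
This package gives epidemiologists and social scientists a tested,
self-contained toolkit for that analysis: spatial weights handling, a
synthetic-data generator with known ground truth, exploratory spatial
statistics, the ML fit, and the effect decomposition with Monte-Carlo
inference.

## The model

For n areas with outcome y (e.g. percent of adults reporting frequent
mental distress), covariates X and a row-standardized spatial weights
matrix W:

    (I − ρW) y = α1 + Xβ + WXθ + ε,    ε ~ N(0, σ²I)

ρ captures endogenous outcome spillover, θ the effect of neighboring
areas' covariates. The marginal effect of covariate r is the n×n matrix

    ∂y/∂X_r = (I − ρW)⁻¹ (β_r I + θ_r W)

whose diagonal mean is the **direct effect**, off-diagonal mean the
**indirect (spillover) effect**, and whose geometric expansion
I + ρW + ρ²W² + … partitions both into contributions from the area itself
(W⁰), adjacent neighbors (W¹), neighbors-of-neighbors (W²), and so on.
Inference on the effects is by parametric Monte Carlo from the asymptotic
normal distribution of the ML estimates.

## Worked example

Simulate a 20×20 county-like lattice (400 areas, marginals mimicking a US
county mental-distress table), fit the SDM, and decompose the effects:

```sh
spdurbin simulate --rows 20 --cols 20 --seed 7 --out-prefix demo
spdurbin fit --table demo.csv --weights demo.gal \
    --outcome mental_distress \
    --covariates social_capital --covariates ses_index --covariates pct_female
```

```
Spatial Durbin model (ML), n = 400
log-likelihood = -555.5290   sigma2 = 0.927493
----------------------------------------------------------------
                            coef   std err        z    P>|z|
const                     0.5110    1.9222    0.266    0.790
social_capital           -0.0460    0.0438   -1.052    0.293
ses_index                -1.0575    0.0590  -17.929    0.000
pct_female                0.0871    0.0267    3.257    0.001
W.social_capital         -0.3581    0.0908   -3.944    0.000
W.ses_index              -0.5069    0.1652   -3.068    0.002
W.pct_female              0.0704    0.0472    1.493    0.136
rho                       0.3149    0.0754    4.179    0.000
----------------------------------------------------------------
```

The same from Python, with the effect decomposition:

```python
import pandas as pd, spdurbin as sd

df = pd.read_csv("demo.csv", dtype={"id": str})
w = sd.read_gal("demo.gal").row_standardize()
df = df.set_index("id").loc[w.ids].reset_index()

res = sd.fit_sdm(df, w, "mental_distress",
                 ["social_capital", "ses_index", "pct_female"])
print(res.impacts(draws=1000, seed=7).summary())
```

```
Impact decomposition (1000 Monte-Carlo draws, seed=7, rejection rate 0.0%)
variable                  direct  indirect     total
social_capital          -0.0650   -0.5250*  -0.5900*
ses_index               -1.1002*  -1.1834*  -2.2835*
pct_female               0.0920*   0.1378*   0.2299*
* significant at P < .05
```

Read: a one-unit increase in a county's social-capital index lowers its own
mental-distress prevalence by 0.065 percentage points (direct), and lowers
prevalence in the surrounding counties by 0.525 points in aggregate
(indirect) — here the spillover dominates, consistent with the ρ̂ = 0.31
outcome dependence the fit found. `res.partition_impacts(Q=4)` further
splits each effect over neighbor orders W₀…W₄ (for social capital the
indirect effect decays −0.358, −0.112, −0.038, −0.012, −0.004 from order 0
to 4), and `sd.morans_i(df["mental_distress"], w, permutations=999, seed=7)`
confirms the outcome is spatially clustered (I = 0.471, p = 0.001).

The full pipeline (descriptives → PCA indices → VIF → Moran's I → fit →
effects → partition, each artifact stamped with seed, weights checksum and
package version) runs from a YAML config: `spdurbin run --config run.yaml`.

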