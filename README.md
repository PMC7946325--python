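# iggsca

**Generalized structured component analysis for imaging genetics** —
composite-based structural equation modeling that links SNPs, brain regions
and behavioral outcomes in a single fitted model.

Imaging-genetics studies ask how genetic variation shapes brain structure,
and how both shape behavior: does a polymorphism thin a cortical region,
and does that thinning raise depression severity?  Fitting one regression
per SNP×region×outcome triple ignores the path structure and drowns in
multiplicity; factor-based SEM postulates that a gene or brain region
*causes* its SNPs or voxels, which is biologically backwards and brings
identification and convergence problems.  `iggsca` instead represents each
gene and each region of interest (ROI) as a **component** — a weighted
composite of its own observed variables — and estimates the directed paths
among components, including gene×environment interaction effects, in one
penalized model.  It is written for statistical geneticists and imaging
researchers who want hypothesis-driven path models over genome-wide scans.

## The model

With **z** the J standardized observed variables and **γ** the P components,

* weighted relation: **γ** = **W z**
* measurement: **z** = **C γ** + **ε**
* structural: **γ** = **B γ** + **ζ**

which combine, with **V** = [**I**; **W**] and **A** = [**C**; **B**], into
the single residual **Vz − AWz**.  Estimation minimizes the penalized least
squares criterion

```
phi = Σᵢ ‖V zᵢ − A W zᵢ‖²  +  λ Σ |b|^τ ,    s.t.  Σᵢ diag(γᵢγᵢ′) = N·I
```

by alternating regularized least squares: exact norm-constrained weight
updates, closed-form loadings, and ridge (τ = 2) or lasso (τ = 1) path
updates.  λ is selected by K-fold cross-validation; standard errors and 95%
intervals come from a nonparametric bootstrap.  A gene×environment
interaction component is the unit-variance-rescaled product of its parents'
scores and shares their weights.  See `docs/methods.md` for the full
account.

## Worked example

A gene with two SNPs, a traumatic-exposure score (PTE), one ROI measured on
both hemispheres, a depression score, and the PTE×gene interaction:

```python
import numpy as np, pandas as pd
from iggsca import GSCAModel, build_model

spec = build_model(
    components=[("SLC6A4", ["rs1", "rs2"]),
                ("PTE", ["pte"]),
                ("IFG", ["ifg_left", "ifg_right"]),
                ("depression", ["hads_d"])],
    interactions=[("PTE", "SLC6A4")],
    paths=[("SLC6A4", "IFG"), ("PTE", "IFG"), ("PTE x SLC6A4", "IFG"),
           ("IFG", "depression"), ("PTE", "depression")],
)
model = GSCAModel(df, spec)        # df: one row per subject
res = model.fit_cv(tau=2)          # ridge, five-fold CV for lambda
res.bootstrap(B=500, seed=1)
print(res.summary())
```

On a simulated 400-subject dataset this prints (abridged):

```
penalty:      lambda=12.6896, tau=2 (ridge)
criterion:    1107.91 after 25 iterations (converged=True)

Path coefficients
--------------------------------------------------------------
      source     target  estimate    se  ci_low  ci_high  significant
      SLC6A4        IFG     0.260 0.046   0.168    0.342         True
         PTE        IFG    -0.204 0.046  -0.295   -0.117         True
PTE x SLC6A4        IFG     0.267 0.041   0.177    0.345         True
         IFG depression    -0.309 0.044  -0.394   -0.216         True
         PTE depression     0.251 0.043   0.163    0.328         True

R^2 of dependent components
--------------------------------------------------------------
IFG          0.196
depression   0.201
average R^2: 0.199
```

Every path is reported with its bootstrap SE and percentile interval;
single-indicator components (PTE, depression) show weight and loading 1.00
with SE 0.00, as they must — a standardized single indicator *is* its
component.  Mediation and moderation follow from the same fit:

```python
res.indirect_effect("SLC6A4", "IFG", "depression")
# estimate -0.080, 95% CI [-0.119, -0.045]: the gene lowers depression
# severity through its effect on the region

res.conditional_effect("PTE", "SLC6A4", "IFG", levels=[-1.0, 1.0],
                       levels_are_standardized=True)
#    level  slope     se  ci_low  ci_high  significant
#     -1.0 -0.487  0.064  -0.606   -0.368         True
#      1.0  0.078  0.061  -0.049    0.197        False
# exposure thins the region only at low genotype scores
```

The conditional-effect slope at moderator level m is
`b_main + b_int·s·z(m)`, with s the interaction's rescaling factor.

## Command line

Each subcommand writes TSV tables with a header recording version, options
and seeds, and never overwrites without `--force`:

```sh
iggsca fit       --data data.csv --model model.yaml --lam 136 --tau 2
iggsca cv        --data data.csv --model model.yaml --lambda-grid 0,1,10,100,1000
iggsca bootstrap --data data.csv --model model.yaml --lam 136 --boot 4000
iggsca simulate  --n 1000 --seed-sim 1          # study-design preset + truth sidecar
iggsca recover   --n 250,2000 --reps 200        # parameter-recovery study
```

The model configuration is YAML: components with their indicator columns,
interactions as `"A x B"`, paths as `"source -> target"` (schema in
`docs/methods.md` and `iggsca.model`).

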