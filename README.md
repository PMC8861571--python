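# fdqsar

QSAR modelling pipeline for fullerene-derivative (FD) binding scores against
anti-diabetic protein targets.

Fullerene derivatives — C60/C70 cages decorated with substituent groups — are
candidate multi-target binders for proteins implicated in type-2 diabetes
(interleukin-1β converting enzyme, PPARγ, glycogen phosphorylase, aldose
reductase, …). Inverse-docking screens summarise each compound–protein
interaction as a dimensionless *binding score* (Bscore). This package builds
and validates the statistical models that predict those binding scores from
molecular structure, for six responses at once: the average binding score
over a large protein panel plus the scores for five diabetes-related targets
(PDB IDs 1BMQ, 1FM6, 1GPB, 1H5U, 1US0).

It is aimed at cheminformaticians who want a fully reproducible, tested
re-implementation of this modelling workflow — every stage is importable,
seeded, and runs on synthetic data with known ground truth, so no docking
computation or proprietary descriptor software is required.

## What is inside

* **`smiles_graph`** — lossless SMILES tokenizer and heavy-atom molecular
  graph parser (organic subset, bracket atoms, charges, ring closures,
  branches; aromaticity taken as written).
* **`descriptors`** — topological diameter TD (longest shortest path in bond
  steps) and the count-based drug-like descriptor panel (H-acceptors/donors,
  rotatable bonds, ring counts, amines/amides, …) under one frozen rule
  table. Descriptors requiring external models (QPpolrz polarizability
  volume, surface areas, cLogP, …) are consumed as input columns.
* **`dcw`** — the Monte Carlo *optimal descriptor*
  DCW(T, N) = Σₖ CW(attribute k): per-attribute correlation weights over
  SMILES tokens (Sk) and adjacent-token pairs (SSk), optimized by a seeded
  coordinate-wise hill-climb of r²(DCW, endpoint) with calibration-set early
  stopping, then calibrated as ŷ = C0 + C1·DCW.
* **`cpann`** — counter-propagation artificial neural network: a Kohonen
  input layer with an exactly superimposed output layer. The winner
  c = argmin‖x − wⱼ‖ is found in the input layer only; both layers update as
  wⱼ ← wⱼ + η(t)(1 − d(j,c)/(r(t)+1))(x − wⱼ) within the shrinking
  neighborhood; prediction is the winner's output weights. Includes external
  Q², leave-one-out Q²cv, weight maps and top maps.
* **`regression_stats`** — OLS with per-group R²/RMSE (headline statistic:
  squared Pearson correlation of observed vs predicted) and Pearson
  correlation matrices for the multi-target response analysis.
* **`applicability_domain`** — hat-value leverages h = x(XᵀX)⁻¹xᵀ, warning
  leverage h* = 3(p+1)/n, standardized residuals, Williams-plot data with
  structural-influence and ±3σ outlier flags.
* **`synthetic_data`** — generator of FD-like datasets: grammar-built SMILES
  around a ring-core proxy, six responses with a planted structural signal,
  one shared latent factor, and calibrated noise.
* **`pipeline` / `fdqsar` CLI** — one-command study replica producing model
  reports, correlation matrix, Williams CSVs, map exports, a binding heat
  map, and a reproducibility manifest.

The four models mirror the study design: **1a** OLS on (QPpolrz, TD),
**2a** OLS on DCW, **1b** CPANN on (QPpolrz, TD), **2b** CPANN on DCW.

## Worked example

```python
from fdqsar.pipeline import RunConfig, run_study
import pandas as pd

manifest = run_study(RunConfig(), "bundle")          # default synthetic study
print(pd.read_csv("bundle/models/model_1b_stats.csv", index_col=0).round(3))
```

prints the per-response statistics of CPANN Model 1b (14×14 neurons, 400
epochs, trained on the merged 127-compound training set):

```
           r2_train  rmse_train  q2_test  rmse_test   q2cv  rmse_cv
AvgBScore     0.979      78.531    0.899    166.824  0.922  152.170
1BMQ          0.979      77.416    0.914    156.110  0.918  153.557
1FM6          0.980      76.976    0.925    159.548  0.907  166.270
1GPB          0.983      70.886    0.878    175.679  0.925  148.895
1H5U          0.984      68.215    0.930    137.749  0.928  146.723
1US0          0.983      71.282    0.928    147.843  0.934  141.700
```

`r2_train` is the squared correlation of observed vs predicted binding
scores on the training set, `q2_test` the same on the 42 held-out
compounds, and `q2cv` the leave-one-out cross-validated value; RMSEs are in
binding-score units. The companion `bundle/correlation_matrix.csv` holds the
six-response Pearson matrix (off-diagonal ≈ 0.956–0.966 here), reflecting
the strong co-variation of average and per-target binding scores that the
generator plants. The same numbers are reachable from a shell:

```bash
fdqsar run --out bundle
fdqsar synth --n 169 --seed 3 --out compounds.csv
fdqsar cpann --in compounds.csv --inputs QPpolrz,TD --grid 14x14 \
             --epochs 400 --seed 7 --out stats.csv
```

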