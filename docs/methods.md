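# Methods

This note documents the models implemented in `fdqsar`, the defaults and
numerical conventions chosen where the workflow leaves them open, and the
limits of what the synthetic study conditions demonstrate.

## Data model and splits

A dataset is a table of compounds: an id, a SMILES string, descriptor
columns, and up to six binding-score responses (`AvgBScore` plus the five
protein targets `1BMQ, 1FM6, 1GPB, 1H5U, 1US0`). Binding scores are
dimensionless docking-derived quantities and are always *inputs* to this
package — no docking is performed.

Compounds are partitioned into four groups of near-equal size — active
training, passive training, calibration, validation — and the first three
merge into the network training set. The assignment rule is deterministic
round-robin over input order (position k → group k mod 4), which for 169
compounds forces 127 train / 42 test. A seeded random shuffle is available
(`scheme="seeded_random"`) for sensitivity checks. Round-robin was chosen as
the default because it is reproducible without any external tool and keeps
the group sizes maximally balanced; the original split rule of the source
workflow is not public.

Normalization is min–max to [0, 1], fitted on the training group only
(the conventional pre-processing for Kohonen-type networks); rows outside
the fitting group may map outside [0, 1] and are not clipped. Z-scoring is
available as an option. Constant columns are an error, never silently
passed through. Missing descriptor cells stay missing (NaN) and any model
referencing them fails fast; there is no imputation.

## SMILES handling

The tokenizer is maximal-munch and lossless (two-character `Cl`/`Br` before
single letters, `%nn` before single ring digits, bracket blocks kept whole);
concatenating the tokens always reproduces the input. The parser covers the
organic subset, aromatic lower-case atoms, bracket atoms with charges and
explicit hydrogens, branches, ring closures, bond orders and dot-separated
fragments. Implicit hydrogens follow standard valence rules (aromatic atoms
reserve one valence unit for the ring system). Two deliberate scope
decisions: aromaticity is taken as written (no perception or kekulization
— inputs are machine-written SMILES), and stereo marks (`/ \ @`) are
tokenized and recorded but structurally inert, because every implemented
descriptor is stereo-agnostic. Structural agreement with RDKit (atom, bond,
ring and hydrogen counts) is asserted in the test suite over a pool of
generated and hand-picked molecules; RDKit is used only as a test oracle,
never at run time.

## Descriptors

Topological diameter (TD) is the longest shortest path between heavy atoms
in *bond steps* (a single atom has TD 0); for multi-fragment inputs the
maximum over fragments is taken. The count descriptors follow the frozen
rule table in `descriptors.py`; the rules are simple Lipinski-style
conventions (e.g. H-acceptors = all N and O; rotatable bonds = non-ring
single bonds between non-terminal heavy atoms excluding amide C–N; sp3
atoms = non-aromatic C/N/O/S with only single bonds). Ring counts use a
minimum cycle basis (networkx) as the smallest-set-of-smallest-rings
stand-in. These rules do not attempt to reproduce any proprietary
descriptor program numerically; all tests are relative to the stated rules.
Externally computed descriptors — QPpolrz (polarizability volume, Å³),
surface areas, cLogP/cLogS, drug-likeness, stereo centers, symmetric atoms
— are consumed as input columns only.

## Optimal descriptor DCW(T, N)

Attributes are single SMILES tokens and adjacent-token pairs; a pair is
canonicalized by lexicographic order so `C→O` and `O→C` are one attribute.
Attributes present in at least T distinct active-training compounds start
with weight 1.0; rarer attributes are blocked at exactly 0 and never
perturbed. DCW of a compound is the weight-multiplicity sum over its
attribute multiset.

The optimizer is a seeded coordinate-wise Monte Carlo hill-climb: each
epoch visits the active attributes in seeded-random order, draws a step
magnitude δ·u with u ~ Uniform(0, 1], evaluates the objective — squared
Pearson correlation of DCW with the endpoint over active ∪ passive training
— at both `w + δu` and `w − δu`, and accepts the better candidate only on
strict improvement, so the accepted-move objective sequence is strictly
increasing (asserted at run time). After each epoch the calibration-set r²
is recorded and the best calibration snapshot (including the untouched
initial weights, so N = 0 degenerates to a weighted attribute count) is
returned — early stopping against overfitting the training correlation.
The prediction line C0 + C1·DCW is then fit by least squares on the active
training group, and r²/RMSE are reported for all four groups.

Defaults: T = 1, N = 20 epochs, δ = 0.1. The source workflow publishes no
optimizer internals; these values keep the optimizer fast, fully
deterministic in (T, N, δ, seed), and strong enough to recover planted
linear signals (validation r² ≈ 0.99 at 10 % noise in the test suite). A
strict-improvement rule was preferred over simulated annealing for
reproducibility; annealing is a documented extension point. Weights are
optimized per endpoint; the CPANN Model 2b uses the AvgBScore-optimized
DCW as its single input plane, since the average binding score is the
study's headline endpoint and the six responses are nearly collinear.

## Counter-propagation network

Both layers share one Nx×Ny grid; initial weights are Uniform(0, 1) from a
seeded generator. Winner selection uses Euclidean distance in the Kohonen
layer only, with ties broken toward the smallest row-major index. Updates
apply to both layers for every neuron within Chebyshev grid distance
d ≤ r(t) of the winner, scaled by a triangular kernel η(t)·(1 − d/(r(t)+1)).
Schedules decay linearly: η(t) = η_min + (η_max − η_min)(1 − t/epochs),
r(t) = round(r0(1 − t/epochs), half-up). Defaults η_max = 0.5,
η_min = 0.01, r0 = round(max(Nx, Ny)/2), planar boundary (toroidal
available). Objects are presented in dataset order — no shuffling — so
training is bit-for-bit reproducible; a seeded shuffle can be applied by
the caller. These update rules follow the classical counter-propagation
formulation; the publications the workflow relies on name the method but
not its schedule internals.

Model statistics are reported on the original (denormalized) response
scale. R², Q² and Q²cv are squared Pearson correlations of observed vs
predicted (not 1 − SSres/SStot): this matches the "squared regression
coefficient" convention of the modelling literature the package follows,
and is the headline number in all reports.

Leave-one-out cross-validation retrains from the same seeded initial
weights on each n−1 remainder, presenting the remaining objects in dataset
order. Implementation detail: all n folds are trained simultaneously as one
weight tensor with the held-out object masked per fold — update-for-update
identical to n separate retrainings (asserted against literal retraining in
the tests) — and the inner loop is JIT-compiled with numba, which brings
LOO at n = 169, 400 epochs to well under a minute on one CPU. Normalization
is fitted once on the full group passed to `loo_cv` and held fixed across
folds; Q²cv is scale-invariant to this choice, and refitting min–max bounds
per fold would change fold inputs only marginally while breaking the
batched equivalence.

## Applicability domain

Leverage is the hat-matrix diagonal h = x(XᵀX)⁻¹xᵀ with an intercept
column; query compounds get the generalized leverage against the training
design. The warning leverage defaults to h* = 3(k+1)/n with k the number
of model descriptors — the standard QSAR convention — and is overridable
(`h_star=` / `--h-star`), because the describing text also admits a
3(k+2)/n reading while the printed thresholds (0.7 and 0.47) match neither
convention at any plausible (k, n); the standard convention is the only
self-consistent choice. Standardized residuals divide raw residuals by the
training RMSE (plain convention; an internally studentized variant is
available behind `studentized=True`). Flags: structural influence at
h > h*, response outliers at |standardized residual| > 3σ.

## Synthetic study conditions

The generator emulates the shape of the real data, not its chemistry:

* **Structures.** A plain carbocycle (default cyclohexane written
  `C1CCCCC1`) stands in for the fullerene cage; each compound carries 1–8
  substituents drawn from a weighted grammar (alkyl chains of length 1–8,
  hydroxyl, carboxyl, nitro, ammonium, primary amine, benzene, naphthalene).
  The cage proxy is a per-dataset constant, and every implemented
  descriptor (counts, TD, DCW attributes) responds to the substituents, not
  to cage realism. Ring-closure digits in fragments are chosen so grammar
  output is always valid SMILES; every generated structure is parse-tested.
* **Responses.** y_t = α_t + Σ β·feature + λ·Z + ε_t, with the planted
  features NonHAtoms, TD, AromaticRings, ElectronegativeAtoms;
  β = (20, 90, 25, 20); Z ~ N(0,1) shared across the six targets of a
  compound; λ = 35 and ε-sd = 107 in binding-score units. The β mix makes
  size-like features dominate (as observed for real FDs), and λ, ε were
  calibrated once against the grammar's planted-signal sd (≈ 490) so that
  (i) pairwise response correlations land near 0.95, inside the observed
  0.88–0.96 band, and (ii) OLS on the true planted features keeps an R²
  ceiling of ≈ 0.95, which bounds what any model can reach on these data.
* **Proxies.** QPpolrz and TotalSurfaceArea are noisy linear functions of
  heavy-atom count — labelled proxies mirroring the empirical fact that
  size-like descriptors track binding, nothing more.

What passing tests therefore show: the estimators recover signals they are
supposed to recover, at the study's sample sizes and noise levels, fully
reproducibly. What they do not show: performance on real docking scores,
whose noise is neither Gaussian nor homoscedastic, whose descriptor
correlations differ, and whose cage regiochemistry the grammar ignores.
The package's printed statistics on synthetic data are therefore
benchmarks of the machinery, not claims about FD pharmacology.

## Numerical conventions and degenerate inputs

* Squared-correlation statistics raise on zero-variance vectors rather than
  returning NaN; constant LOO responses are an explicit error.
* OLS checks the design rank via QR and names the collinear columns;
  coefficient p-values use the exact t distribution.
* Normalization parameters invert exactly (round-trip identity within
  1e-12 is asserted).
* The study bundle is byte-identical across reruns of the same
  configuration; the manifest stores the config hash, seeds, library
  versions, and a SHA-256 per output file, and suffices to reproduce the
  bundle.
* Default problem sizes (169 compounds; 14×14 grids; 400/500 epochs;
  N = 20 DCW epochs) follow the study conditions; the scaled-down configs
  used in some structural tests (smaller n, grids, epochs) exercise the
  same code paths and are the package's own choice of smoke-test size.

## Known limitations

* The SMILES grammar omits isotopes-with-meaning, multi-digit ring bonds
  beyond `%nn`, and aromaticity perception; it accepts what the generator
  and common toolkits emit.
* SSSR via minimum cycle basis can differ from other SSSR definitions on
  exotic polycycles; all ring-count rules are relative to this basis.
* The DCW attribute set covers Sk and SSk only (no triples or global
  feature codes).
* `fit_cpann` trains on one ordering; ensemble-over-orderings variance is
  not estimated.
* Descriptor rules are conventions, not reproductions of any specific
  descriptor software's numbers.
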