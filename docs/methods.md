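# Methods

## Problem setting

A Pd-catalysed asymmetric Negishi coupling under Curtin–Hammett control
produces the two product enantiomers through two diastereomeric transition
states (TSs).  The enantiomeric ratio is fixed by the free-energy gap between
them,

    ΔΔG‡ = R·T·ln(major/minor),      major fraction = K/(1+K),  K = exp(ΔΔG‡/RT),

with R = 1.98720425×10⁻³ kcal·mol⁻¹·K⁻¹ and T defaulting to 298.15 K.  A
90:10 er corresponds to ~1.3 kcal/mol, so the ~1 kcal/mol error bar of
routine DFT single points translates (first order, delta method) into tens of
S-percentage points near mid-range selectivity — the quantitative motivation
for not predicting er from energies alone.  `selectivity` implements the five
interconvertible encodings (ee, er ratio, ln er, S%, R%) with exact inverses;
records are kept strictly inside (0, 100) so ratio and log metrics stay
finite.  A 100:0 input is rejected by default, with an opt-in clamp to
99.95:0.05.

er strings are read as "R:S" (so an S-selective ligand prints its minor
component first, e.g. "11:89"); both the field order and a
larger-component-is-S override are per-call options, and predictions are
printed with one decimal.

## Geometric descriptors

Descriptors are computed from explicit donor-atom indices (`DonorSet`: the
phosphine P and the two substrate carbons bound to Pd); bond perception is
deliberately out of scope for these specialised complexes.

* **Planarity** — unsigned perpendicular distance (Å) of Pd from the
  total-least-squares plane through the three donors (for exactly three
  donors the plane is exact).  Unsigned because no sign convention exists for
  "projected out of the plane".
* **Y-ness** — Pd and donors are projected onto the donor plane and the three
  donor–Pd–donor angles measured there; the descriptor is Σᵢ|θᵢ − 120°| in
  degrees (L1 chosen for interpretability), zero iff the projected complex is
  an ideal trigonal Y.
* **Projected metal angle** — the angle at Pd between the Pd→P bond and
  Pd→(foot of Pd's perpendicular on the donor plane), in degrees.  With P in
  the donor plane this angle is always acute; it is undefined (raises) when
  Pd lies in the plane to within the degeneracy tolerance.

All descriptors are invariant under rigid motion (asserted to 1e-8 under
randomised rotations/translations).  Coincident/collinear/coplanar
degeneracies are detected at 1e-6 Å (`stereonn.constants.DEGENERACY_TOL`).
Structures are exchanged as standard XYZ; the comment line may carry
`ligand=<id> role=<pro_R|pro_S>` metadata, which survives a write/parse round
trip.

## Feature engineering

Tables join three column blocks — geometric, electronic, dispersion — in that
order; assembly fails loudly, naming the ligands, when any source is
incomplete.  Min–max normalisation is fitted on an explicit row subset and
applied without clipping; inside cross-validation it is re-fitted on each
training fold so the held-out ligand cannot leak into the scaling (a
`normalize=False`/global path exists for comparison).  Zero-range features
are recorded as excluded rather than divided by zero.

Three reduction routes:

* **manual** — features ranked by |Pearson R| against a chosen selectivity
  metric (ties alphabetical; zero-variance features get R = 0 and a flag),
  top-k kept in original column order;
* **PCA** — SVD scores with signs fixed so each component's largest-|loading|
  entry is positive;
* **Sammon mapping** — minimises E = (Σd)⁻¹·Σ(d−δ)²/d with the classic
  diagonal-Hessian update (step = 0.3 · grad/|hess|, halved on stress
  increase, ≤500 iterations, relative tolerance 1e-9), initialised from the
  PCA projection so runs are deterministic; duplicate rows are nudged apart
  by a seeded jitter of 1e-9× the mean distance.  The second-order step makes
  the achieved stress independent of the input scale, which a fixed-rate
  gradient step is not.

## Network and training

The regressor is intentionally small: two hidden layers of 15 nodes
(configurable), one of six activations (ReLU default; leaky-ReLU slope 0.01;
softplus computed as logaddexp for overflow safety), a linear output.
Weights are He-initialised (sd √(2/fan-in)) from a seeded generator, biases
zero except the output bias, which is warm-started at the training-label
mean: Adam moves each parameter by roughly one learning rate per step, so
starting the only offset parameter at zero for targets on a 0–100 scale
would waste most of the epoch budget.  Training is full-batch Adam
(lr 1e-2, β = 0.9/0.999) on MSE, stopping at 2000 epochs or a relative loss
change below 1e-10; targets stay on the chosen metric's natural scale (only
features are min–max scaled).  Optional L2 is available but off by default.
Everything is plain numpy, so identical inputs give bit-identical models;
gradients are exact backpropagation and are checked against central finite
differences for every activation kind.

Leave-one-out cross-validation sorts ligands by id (row-order invariance),
derives each fold's seed as `seed + fold`, re-fits normalisation per fold,
and reports RMSE, R² (squared Pearson of predicted vs observed — the
scatter-plot usage; the coefficient of determination is logged alongside),
and the least-squares slope of predicted on observed (ideal m = 1).
Constant observed or predicted vectors are flagged degenerate with NaN
R²/slope rather than raising.

## Validation battery

* **Y-shuffling** — seeded label permutations (features untouched; label
  multiset preserved), full LOO per replicate, versus the unshuffled
  reference.
* **X/Y-randomisation** — features uniform on [0, 1] and/or labels uniform on
  a range, fresh per replicate.  For a skill-less pipeline the mean R² sits
  near zero (small-n LOO gives a residual ~0.08–0.13 from spurious and
  negative held-out correlations) and RMSE at or above the label sd
  ((hi−lo)/√12 for uniform labels).
* **Five-metric bake-off** — one model per encoding, every prediction
  converted to S% before scoring so the five RMSEs share a scale;
  out-of-domain predictions (er ratio ≤ 0 and the like) are clamped to the
  nearest valid value and counted.  Note a structural symmetry: with noise
  additive on S%, the R% encoding is an exact affine image of S% (r=100−s),
  so S- and R-models are statistically equivalent and the winner between
  them is essentially a coin flip; only the ratio/log encodings are
  systematically disadvantaged.
* **ΔΔG‡ baseline** — the conventional route, er from computed energies;
  signed gaps (positive = S major) convert through the Boltzmann relation and
  are scored against experimental S%.  Self-consistent inputs score
  perfectly; Gaussian energy noise of 0.5 then 1.0 kcal/mol strictly
  increases the S% RMSE, which operationalises the error-bar argument above.

Default replicate count is 20.

## Synthetic data

`PlantedSystem` mirrors the experimental campaign: 17 training ligands, 10 +
3 validation ligands, 15 features uniform on [0, 1], three informative
features, latent S% = clip(baseline + Σ aᵢ·gᵢ(f), 1, 99) plus Gaussian label
noise on the S% scale.  Defaults, chosen once:

* coefficients (30, −25, 20) — latent spread ≈ 13 S-points with clipping rare;
* `hinge` nonlinearity gᵢ(f) = (fᵢ−0.5) + max(0, fᵢ−0.5), a kinked-linear
  (MARS-style) hinge: monotone with genuine curvature.  A flat hinge
  max(0, f−0.5) makes the map unlearnable at n = 17 for any method we tried
  (own network, sklearn MLP/LBFGS, kernel ridge all cap near LOO R² ≈ 0.5–0.75
  even noiseless), which would defeat the generator's purpose of providing a
  recoverable favourable regime; `interaction` and `none` variants exist;
* noise sd 4 S-points — the scale of experimental er reproducibility, well
  below the ~27 S-points/kcal·mol⁻¹ that 1 kcal/mol of energy error implies
  at 80:20 (the helper `noise_sd_from_ddg_error` converts kcal/mol to an
  equivalent S% sd by the delta method);
* `baseline_s` shifts the family (75 models a uniformly S-selective series).

What the generator does *not* emulate: real electronic-population or
dispersion distributions (planted columns are abstract), correlated
features, conformer ensembles, or any chemistry in the informative-feature
names (they echo the kinds of factors that matter — C2 electronics, Pd
planarity, a ring-junction angle — purely as a naming convention).  Passing
tests therefore demonstrate that the pipeline recovers planted structure at
the stated sizes and noise, not that it would predict any particular real
ligand series.

`ToyComplexSpec` builds trigonal Pd complexes analytically (donors at
prescribed in-plane angles, Pd offset along the normal) so planarity,
Y-ness and the projected angle have closed-form ground truth
(pd_offset, Σ|aᵢ−120|, atan2(d_P, offset)); the pro-S partner is the mirror
image through the donor plane, leaving all descriptors unchanged; optional
Gaussian jitter perturbs coordinates after construction.

## Problem sizes and runtime choices

LOO at n = 17 retrains the network 17 times; randomisation suites multiply
that by the replicate count.  The test and acceptance runs therefore use
training budgets of 400–1000 epochs, which the output-bias warm start makes
equivalent to longer budgets (results stable from ~300 epochs), and 20–50
replicates.  The acceptance script's randomisation null uses 50 replicates
for a stable mean.

## Known limitations

* At n = 17 with 15 features, held-out predictions occasionally extrapolate
  badly (min–max scaling does not clip out-of-range folds); single-seed LOO
  R² on noisy tables fluctuates widely, which is intrinsic to the data size,
  so recovery claims are asserted on seed averages.
* R² of LOO predictions on pure noise is biased above zero (~0.1) by the
  usual negative-correlation artefact of leave-one-out at small n.
* The five-metric bake-off cannot structurally prefer the S% over the R%
  encoding (affine symmetry); any observed preference between them in a
  single campaign is sampling noise.
* No minibatching, early stopping, GPU paths or hyperparameter search; the
  network is deliberately the smallest thing that does the job.
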