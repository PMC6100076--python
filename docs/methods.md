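# Methods

This note documents the modeling choices behind `hsvr_qsar`: the model
and its assumptions, the defaults that matter, what the synthetic
generator does and does not emulate, numerical conventions, and the
design decisions taken where more than one reasonable option existed.

## Model

The regression target is log₁₀ of the efflux ratio (log ER). The
hierarchical SVR stack is

    ŷ(x) = g( f₁(x_{S₁}), …, f_m(x_{S_m}) ),

where each member f_i is an RBF-kernel ε- or ν-SVR restricted to its
descriptor subset S_i, and the meta model g is another RBF SVR whose
inputs are the member predictions only — no raw descriptors reach the
second level. The construction assumes the structure–activity landscape
is *locally heterogeneous*: different descriptor subsets dominate in
different regions of chemical space, so a panel of local models plus a
learned blend can outperform any single global fit. When the landscape
is globally smooth a single member suffices and the ensemble machinery
adds nothing; the selection logic (below) detects this and refuses to
pay complexity it cannot justify.

### Member training

Hyperparameters come from an exhaustive grid search scored by k-fold
cross-validated RMSE (folds from a seeded shuffle with contiguous
blocks; every sample predicted exactly once out-of-fold). Two grids are
provided: `GridSpec.default()` with the conventional log₂ ranges
(C ∈ 2⁻⁵…2¹⁵, γ ∈ 2⁻¹⁵…2³, both stepped 2²; ε ∈ {0.001, 0.01, 0.1, 0.5};
ν ∈ {0.25, 0.5, 0.75}) and `GridSpec.coarse()`
(C ∈ {1, 10, 100}, γ ∈ {0.01, 0.1, 1}, ε ∈ {0.01, 0.1}, ε-mode only) for
desk-scale runs; the pipeline defaults to the coarse grid.

The final member configuration applies the **one-standard-error rule**:
among grid points whose CV RMSE is within one standard error (over
per-fold RMSEs) of the optimum, the least flexible wins — smallest C,
then smallest γ, then the widest tube. Flexible near-optimal
configurations are the ones that partially memorize permuted responses;
the 1-SE pick costs nothing measurable in CV yet keeps the Y-scrambling
diagnostic honest. The *meta* model instead takes the plain CV optimum:
its input space is 2–4 dimensional and strongly informative, so
parsimony pressure there only shrinks the blend toward the mean. The
meta grid (`GridSpec.meta_default()`) restricts γ to {0.01, 0.1} because
narrow kernels let the blend chase individual member errors.

### Stacking convention

By default (`meta_inputs="oof"`) the meta model trains on each member's
out-of-fold predictions, generated with at least 10 folds so the columns
match test-time prediction quality. This is standard stacked
generalization: the blend sees how members generalize, not how they
memorize. The historical construction — meta trained on the members'
in-sample training predictions — is available as
`meta_inputs="insample"`. In our experiments the in-sample variant
inherits the members' partial memorization of permuted responses
(mean rs² ≈ 0.24 instead of ≈ 0) and consistently trails its best member
on held-out data, which is why it is not the default.

### Ensemble growth and selection

`grow_and_select` evaluates member combinations in increasing size
(2, then 3, then 4; pool capped at 12 candidates). A combination is
*accepted* in its size class when

1. it passes every applicable statistical criterion (below), and
2. its stack CV RMSE improves on the CV RMSE of **each of its own
   members** by more than one standard error (dominance).

If a class contains accepted combinations, the one with the largest
internal improvement wins (descriptor economy, then the objective, break
ties); otherwise the search grows to the next class. If no class
dominates, the smallest class that at least passed the criteria supplies
the winner; if nothing passes, the best-objective combination is
returned flagged `passed=False`. Screening uses the meta's own CV over
its out-of-fold input matrix as a cheap proxy for full-stack CV; classes
of three or more members are prescreened by a closed-form linear-blend
RMSE, and only the winner receives the full-fidelity stack
cross-validation (members and meta refit per fold with hyperparameters
fixed) that produces its reported q²_cv. Selection never consults the
test set; the `paper_faithful_selection` flag switches the objective to
test-set RMSE for users who explicitly want the historical, leakage-prone
practice.

## Preprocessing

- **Filtering.** Drop descriptors missing for any sample; drop
  descriptors with fewer than two distinct values or variance ≤ 1e-8;
  then repeatedly resolve the most intercorrelated surviving pair with
  r² > 0.8, keeping the descriptor more |correlated| with the response
  (earlier column when no response is supplied). The report reconstructs
  every removal; filtering is idempotent.
- **Autoscaling.** χ_ij = (x_ij − ⟨x_j⟩)/s_j with the sample (n−1)
  standard deviation. Default policy fits scaling on the training rows
  only and applies it to the test rows (no leakage); a fit-on-all flag
  exists. The Kennard–Stone split itself measures distances in a space
  scaled on all samples, since the partition precedes the train-only fit.
- **Partition.** Kennard–Stone greedy max–min on Euclidean distances:
  the first two picks are the globally most distant pair, every later
  pick maximizes its minimum distance to the selected set, ties resolve
  to the lowest row index, and the training size is
  round-half-up(fraction × n) — 63 molecules at 0.8 give 50/13. A seeded
  random split is available as an alternative. A descriptive
  `similarity_check` (range overlap, two-sample means/sds) and
  `chemical_space_stats` (PCA variance explained, nearest-neighbour
  distance statistics, sample-to-descriptor ratio) support the usual
  train/test similarity audit; neither gates anything.

## Descriptor selection

The GA explores membership bitmasks with tournament selection (size 2),
uniform crossover, per-bit mutation at rate 1/p, elitism of one, and
random add/drop repair to the configured size range (default 3–7).
Fitness is the k-fold CV RMSE of an ε-SVR with C = 32 (mid of the log₂
cost grid), γ = "scale" (dimension-scaled), ε = 0.1; fitness values are
memoized, so identical subsets always score identically. A literal
mid-grid γ (2⁻⁷ ≈ 0.008) was rejected: a near-zero width makes the
kernel effectively linear and blind to the inverted-U response shapes
this domain exhibits. RFE then removes, at each round, the descriptor
whose removal yields the lowest fitness (least contribution), recording
the fitness delta, until the floor size (default 3) is reached.
Defaults of population 30 / generations 50 are sized for desk-scale
runs; the bundled simulations and tests use smaller, documented settings
(population 10–12, generations 6–8, 5-fold fitness) that recover the
generative subsets reliably at n = 200.

Candidate member subsets for the pool are the full surviving set, the GA
winner, every RFE stage, and leave-one-out variants of the last two RFE
stages — local views of decreasing scope, mirroring how ensemble members
of different descriptor counts (for example 4/6/3 over a 7-descriptor
union) arise in practice.

## Validation statistics

All formulas are implemented directly and cross-checked in the test
suite against independent loop-based oracles to 1e-12.

- Determination coefficients are 1 − SS_res/SS_tot with SS_tot centred
  on the **observed** mean by default. The variant centred on
  the mean *predicted* value is available via `center="predicted"`; the
  observed-mean convention was chosen for internal consistency with the
  external q²_F2 definition.
- Through-origin statistics follow the Golbraikh/Tropsha convention:
  k is the least-squares slope of predicted = k·observed through the
  origin; r_o² is the coefficient of determination of the points about
  that line with SS_tot centred on the mean of the dependent axis; r'_o²
  swaps the axes.
- The rm² family defaults to the square-root variant
  rm² = r²(1 − √|r² − r_o²|); the no-root printed variant is available
  (`variant="printed"`). ⟨rm²⟩ and Δrm² are variant-independent
  combinations. The reference work's printed rm² values are not exactly
  reproducible from its rounded r²/r_o² under either variant, so no
  variant is privileged by those numbers.
- q²_F1 and q²_F3 reference the **observed** training mean; the glossed
  "average predicted training value" form is available behind a flag.
  q²_F3's denominator is the training SS divided by n_TR, as printed.
- CCC is Lin's concordance coefficient in its printed form.
- Undefined quantities (zero-variance denominators) propagate as NaN and
  surface as `not_applicable` in the criteria verdict — never as silent
  zeros or exceptions.
- The criteria checker evaluates: all coefficients ≥ 0.70 (r², q²_cv in
  training; q², q²_Fn in the external context), |r² − q²_cv| < 0.10
  (training only), (r² − r_o²)/r² < 0.10 with 0.85 ≤ k ≤ 1.15,
  |r_o² − r'_o²| < 0.30, rm² ≥ 0.65, ⟨rm²⟩ ≥ 0.65 with Δrm² < 0.20, and
  CCC ≥ 0.85 (external only). Thresholds are strict or non-strict exactly
  as printed.
- Y-scrambling permutes the response, refits the model with unchanged
  hyperparameters and descriptors (`frozen_clone`), and records the
  training-set determination coefficient rs²; the default is 25
  permutations. A near-zero ⟨rs²⟩ against a high unscrambled r² is the
  chance-correlation control.

## Synthetic data generator

The generator emulates the *statistical shape* of a small-molecule
efflux dataset, not real chemical space. Seven descriptor roles: SA
(N(450, 90²) Å²), Vm (0.75·SA plus N(0, 55²), mildly size-linked), PSA
(N(85, 30²) clipped at 5), HBD (80 % truncated Poisson(3) / 20 % uniform
0–10), nRot (Poisson(5) capped at 15), nAr (80 % Poisson(2) capped at
6 / 20 % uniform 0–6), nN+O (HBD + Poisson(3), capped at 16). Optional
collinear companions — an MW-like column tracking Vm and an HBA-like
column tracking nN+O at a target r² (default 0.98) — exercise the
intercorrelation filter.

The response is

    log ER = a_H·c_H(nRot)·exp(−(HBD−6)²/(2·2.5²))
           + a_L·c_L(nRot)·exp(−(nAr−3)²/(2·1.5²))
           + 0.3·z(Vm) + N(0, σ²),

with a_H = 1.0, a_L = 0.6 (log units), σ = 0.1 by default, and regime
coefficients c_H = ½ + s(w−½), c_L = ½ + s(½−w) where
w = sigmoid((nRot−5)/1.5) and s = 1 by default. The two Gaussian bumps
give the rise-then-fall dependence of binned log ER on HBD (peak 6) and
on the lipophilicity proxy; the sigmoid weight makes H-bonding dominate
for flexible molecules and aromatic stacking for rigid ones. That regime
structure is deliberate: it is the heterogeneous-local-landscape regime
the hierarchical ensemble exists for. At s = 0 the surface is purely
additive and a single SVR is sufficient — a useful negative control.
Amplitudes were fixed once at values giving a signal-to-noise ratio
typical of curated monolayer-assay compilations (response sd ≈ 0.4–0.5
log units against 0.1 replicate noise).

What passing tests on this generator do **not** show: robustness to
assay heterogeneity between laboratories, to non-Gaussian measurement
error, to descriptor distributions of real drug libraries, or to
activity cliffs sharper than the smooth bumps modeled here.

## Problem sizes

The bundled recovery study runs 20 replicates at n = 200, σ = 0.1 with
GA 12×8, 5-fold screening CV and 10 scrambles per replicate — about
20 s per replicate on one core. These sizes are the package's chosen
desk-scale defaults for simulation studies; the full LIBSVM-style grid
and GA 30×50 remain available for real analyses.

## Numerical conventions and degenerate inputs

- All randomized stages derive per-stage substreams deterministically
  from the single run seed; identical seeds reproduce identical runs,
  including fold assignments, GA trajectories and scramble permutations.
- Grid search is exhaustive with first-occurrence order preserved on
  ties; the Kennard–Stone tie rule is lowest row index; duplicate points
  never raise.
- Constant responses: SVR predicts within the tube of the constant
  (warning, not error); constant observed vectors make the affected
  coefficients NaN.
- Tables align by descriptor *name* everywhere; a missing name raises a
  KeyError naming it (and the member, for ensembles), and unseen names
  at scaling time are rejected rather than ignored.
- Model bundles persist via a schema-versioned joblib archive storing
  descriptor names and normalization parameters; loading a truncated or
  foreign file raises a persistence error.

## Known limitations

- Descriptor computation (quantum-chemical or otherwise) is out of
  scope; the package consumes numeric descriptor tables.
- The combination search is exhaustive only up to four members over a
  capped pool; it is a design choice for auditability, not a scalable
  subset-selection algorithm.
- The dominance rule compares CV estimates whose noise at n ≈ 200 is of
  the same order as real stacking gains; on globally smooth landscapes
  the selected ensemble can still trail its best member by a few
  thousandths of q² on a given split.
- No applicability-domain quantification beyond the descriptive
  chemical-space statistics, and no bootstrap confidence intervals.
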