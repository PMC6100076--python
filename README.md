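# hsvr-qsar

Hierarchical support vector regression (HSVR) for quantitative modeling of
P-glycoprotein (P-gp) substrate efflux.

P-gp is an ATP-driven membrane transporter that pumps xenobiotics out of
cells and across the blood–brain barrier. The strength of that efflux is
measured in monolayer assays as the efflux ratio ER =
P_app(B→A) / P_app(A→B); compounds with ER > 2 are conventionally called
P-gp substrates. Predicting log ER from molecular descriptors is hard
because efflux mixes active transport with passive permeability: the same
features (hydrogen-bond donors, lipophilicity, size) both raise and lower
the ratio over different ranges, so the structure–activity landscape is
nonlinear and locally heterogeneous. This package is for computational
chemists and ADMET modelers who want a complete, reproducible pipeline for
that regression problem — and for the statistically identical problem of
validating any small-n QSAR regression against the stringent
external-validation criteria used in the field.

## The model

HSVR is a two-level stack of RBF-kernel support vector regressions:

1. **Members.** Each member is an ε-SVR or ν-SVR trained on its own named
   descriptor subset, with cost C, kernel width γ, and tube width ε (or
   fraction ν) chosen by exhaustive grid search under k-fold
   cross-validation. Members behave like *local* models: accurate where
   their descriptors carry the signal, unreliable elsewhere.
2. **Meta level.** A second SVR is regressed on the members' predictions
   (one input per member), producing a single *global* predictor
   ŷ = g(f₁(x), …, f_m(x)). By default the meta level trains on
   out-of-fold member predictions (stacked generalization), so it learns
   how members behave on unseen data rather than on memorized fits.

Ensembles are grown under Occam's razor: all two-member combinations are
tried first, then three, then four. A combination is accepted only when it
passes the full statistical criteria battery *and* its cross-validated
RMSE improves on every one of its own members by more than one standard
error — an ensemble that cannot beat its constituents does not justify its
complexity.

Around the estimator the package implements the complete supporting
workflow:

- **Preprocessing** — descriptor filtering (missing values, low variance,
  pairwise intercorrelation r² > 0.8), autoscaling χ = (x − ⟨x⟩)/s with
  the n−1 standard deviation, and the deterministic Kennard–Stone max–min
  partition (≈4:1 train:test).
- **Descriptor selection** — a genetic algorithm over membership bitmasks
  followed by recursive feature elimination, both scored by
  cross-validated SVR RMSE.
- **Validation** — r²/q² determination coefficients, RMSE, MAE, residual statistics,
  through-origin statistics (r_o², r'_o², k), the Roy/Ojha rm² family,
  external coefficients q²_F1/F2/F3, Lin's concordance correlation
  coefficient (CCC), 10-fold cross-validation, Y-scrambling, and a
  machine-checkable verdict against the combined Golbraikh/Tropsha-style
  criteria (all coefficients ≥ 0.70, |r²−q²_cv| < 0.10,
  (r²−r_o²)/r² < 0.10 with 0.85 ≤ k ≤ 1.15, |r_o²−r'_o²| < 0.30,
  rm² ≥ 0.65, ⟨rm²⟩ ≥ 0.65 with Δrm² < 0.20, CCC ≥ 0.85).
- **Synthetic data** — a seeded generator that emulates the seven
  descriptor roles of the application domain (surface area, volume, polar
  surface area, H-bond donors, rotatable bonds, aromatic rings, N+O
  count), their collinear companions, and an inverted-U, regime-structured
  log ER response, so the whole pipeline is testable without external
  data.

Estimators follow scikit-learn conventions (`fit`/`predict`/`transform`,
`get_params`, fitted attributes with trailing underscores) and operate on
named pandas DataFrames, so prediction never depends on column order.

## Worked example

```python
from hsvr_qsar import SyntheticSpec, generate_dataset, RunConfig, run_pipeline

spec = SyntheticSpec(n_samples=200, noise_sd=0.1, seed=7)
molecules, descriptors = generate_dataset(spec)
log_er = molecules.set_index("id")["log_er"].loc[descriptors.index]

config = RunConfig(seed=7, ga_population=12, ga_generations=8,
                   folds=5, scramble_count=10)
result = run_pipeline(descriptors, log_er.to_numpy(), config)
```

Output:

```
training molecules: 160 | test molecules: 40
GA/RFE selection: ['SA', 'Vm', 'HBD', 'nRot', 'nAr', 'nNO']
ensemble members: [['SA', 'Vm', 'PSA', 'HBD', 'nRot', 'nAr', 'nNO'],
                   ['Vm', 'HBD', 'nRot', 'nAr'], ['HBD', 'nRot', 'nAr']]
training   r2=0.91  q2_cv=0.85  RMSE=0.11
test       q2=0.73  qF1=0.74  qF2=0.73  qF3=0.82  CCC=0.87  RMSE=0.15
Y-scrambling mean rs2 = -0.096
criteria passed: True
```

Reading the numbers: the Kennard–Stone design reserved 40 of 200
molecules for external testing; selection recovered a six-descriptor
subset containing every generative feature; the accepted ensemble has
three members of decreasing scope (a global 7-descriptor model plus two
local views). Training r² = 0.91 with q²_cv = 0.85 shows a well-trained
model (gap < 0.10); held-out q² = 0.73 and CCC = 0.87 clear the external
criteria; and the near-zero mean rs² under Y-scrambling shows the fit is
not a chance correlation — refitting on permuted responses destroys it.

The same run is available from a shell:

```bash
hsvr-qsar simulate --n 200 --seed 7 --out data/
hsvr-qsar train --descriptors data/descriptors.csv \
                --molecules data/molecules.csv --seed 7 --out run/
hsvr-qsar predict --model run/hsvr_model.joblib \
                  --descriptors data/descriptors.csv --out predictions.csv
```

`filter`, `split`, `select`, `validate` and `report` expose the individual
stages; all subcommands share `--seed` and a YAML `--config`, and running
them in sequence reproduces a single `run_pipeline` call exactly.

## Limitations

Quantum-chemical descriptor computation is out of scope: the package
consumes a precomputed descriptor matrix (CSV/TSV) alongside the molecule
table. SMILES strings are carried through as annotations, never
interpreted. See `docs/methods.md` for the modeling assumptions, default
parameters, and known limitations.
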