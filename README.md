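# phatg — glass transition prediction for PHA copolymers

Polyhydroxyalkanoates (PHAs) are bacterially produced biodegradable
polyesters whose thermal behaviour — above all the glass transition
temperature *T*g — is tuned by choosing two monomers and their ratio.
`phatg` is a library + CLI for predicting *T*g of PHA homo- and
copolymers directly from structure, for polymer scientists who want a
screening model that needs no hand-crafted QSPR descriptors.

## The model

A record (monomer A, monomer B, fractional composition of A in %, MW in
kg·mol⁻¹, PDI) is encoded as

```
x = [ fp_A | fp_B | frac_A | MW | PDI ]  ∈ {0,1}^{2N} × R^3,   N = 128
```

where `fp` is a binary circular (Morgan) fingerprint, and regressed
onto *T*g by a deep ReLU network (7 hidden layers × 512 neurons,
dropout 0.2, Adam with a cosine-annealed learning rate, 500 epochs,
MSE loss), evaluated by fivefold cross-validation (R², MAE, RMSE). The
monomer labelling A/B is physically arbitrary: (A, B, w) and
(B, A, 100 − w) are the same polymer. The network is made insensitive
to that labelling by **symmetry augmentation** — retraining on the
dataset plus its mirror images — which both removes the label-swap bias
and improves accuracy. The package also ships SVM and LASSO baselines
under the identical protocol, exact grouped Shapley importance of the
five input variables, input-ablation and mean/min/max missing-data
imputation experiments, Gaussian-process Bayesian hyperparameter
search, and a seeded generator of PHA-like synthetic datasets whose
ground truth is the Fox mixing rule
`1/Tg = w_A/Tg_A + (1 − w_A)/Tg_B`.

See `docs/methods.md` for assumptions, numerical choices and limits.

## Worked example

```python
from phatg import *

# a 133-record synthetic PHA-like dataset with known Fox-rule ground truth
ds, truth = generate_dataset(SyntheticConfig(seed=0))
print(describe(ds).to_dataframe().round(1))

# fivefold CV of a mid-sized network (fast; drop config= for the full-size default)
cfg = ModelConfig(n_bits=64, hidden_layers=4, width=256, dropout_rate=0.1,
                  epochs=300, batch_size=32, seed=0)
report = cross_validate(ds, config=cfg, k=5, seed=1)
print(report.summary())

# label-swap sensitivity, before and after symmetry augmentation
aug = augment_symmetric(ds)
plain_fit = TgModel.from_dataset(ds, config=cfg).fit()
aug_fit = TgModel.from_dataset(aug, config=cfg).fit()
print(f"symmetry gap, plain:     {symmetry_gap(plain_fit, ds):.2f} K")
print(f"symmetry gap, augmented: {symmetry_gap(aug_fit, ds):.2f} K")
```

prints

```
         mean      sd      max   min  median
frac_a   64.4    32.5    100.0   5.0    71.1
mw      975.4  2377.5  26331.5  47.0   418.8
pdi       2.6     1.0      6.2   1.1     2.4

  subgroup       R2      MAE     RMSE
-------------------------------------
         1    0.773    5.758    7.370
         2    0.837    6.177    8.260
         3    0.813    7.287    9.168
         4    0.786    7.916    9.952
         5    0.613    6.180    8.619
   average    0.764    6.664    8.674
  [model_kind=dnn, k=5, seed=1, pair_aware=False, feature_mask=frac_a,mw,pdi, n=133]

symmetry gap, plain:     6.74 K
symmetry gap, augmented: 0.40 K
```

The descriptive table shows the generator reproducing the structure of
published PHA compilations (composition skewed toward 100%,
right-skewed MW, PDI ≥ 1). The CV table is the standard report: one
metric triple per held-out subgroup plus their average, here explaining
~76% of the *T*g variance at this reduced network size. The symmetry
gap — mean |prediction change| when monomer labels are swapped — drops
from ~7 K to ~0.4 K once the mirror records join the training set.

Real datasets are CSVs with columns
`monomer_a_smiles, monomer_b_smiles, frac_a_pct, mw_kg_mol, pdi, tg`
(empty `monomer_b_smiles` = homopolymer), loaded with
`read_dataset(path)`.

## Command line

```bash
phatg simulate  --seed 0 --out run/            # synthetic dataset + ground truth
phatg evaluate  run/dataset.csv --out run/     # fivefold CV report + predictions
phatg symmetry  run/dataset.csv --out run/     # plain vs augmented label-swap gaps
phatg ablate    run/dataset.csv --drop frac_a --out run/
phatg impute    run/dataset.csv --features mw+pdi --statistic max --out run/
phatg importance run/dataset.csv --augment --out run/
phatg hyperopt  run/dataset.csv --n-trials 25 --out run/
phatg train     run/dataset.csv --augment --out run/   # checkpoint + sidecar
```

Every command accepts `--config <yaml>` (sections `model` / `synthetic`
mirroring the config dataclasses), `--seed`, `--out`, `--verbose`, and
writes a JSON log of the resolved configuration and library versions
next to its outputs.

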