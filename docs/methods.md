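# Methods

`phatg` predicts the glass transition temperature *T*g of
polyhydroxyalkanoate (PHA) homo- and copolymers from monomer structure,
chain composition, molecular weight and polydispersity, using a deep
feed-forward network over binary molecular fingerprints. This note
records the model, the assumptions behind the synthetic data generator,
the numerical choices, and the limits of what the test suite shows.

## Input encoding

A polymer record holds two monomer SMILES (monomer B absent for a
homopolymer), the fractional composition of A in percent, the molecular
weight MW in kg·mol⁻¹, and the polydispersity index PDI. Monomers are
taken as the free-acid monomer molecule (3-hydroxybutanoic acid, not
the in-chain ester repeat unit). Each monomer is canonicalized and
hashed to a binary circular (Morgan-type) fingerprint of length *N*
(default 128, radius 2) — the de-facto standard featurization for
QSPR; the RDKit topological fingerprint is available via
`ModelConfig.fp_family`. The feature vector is

```
[ fp_A (N) | fp_B (N) | frac_A | MW | PDI ]       length 2N + 3
```

with an all-zero block for an absent monomer and `frac_A = 100` for a
homopolymer of A. Bits are stored unscaled {0, 1}; the three numeric
slots are z-scored by statistics of the training rows only (MW spans
47–5000+ kg·mol⁻¹ and would otherwise dominate gradients). The target
is standardized internally during training and predictions are returned
on the original scale.

### Label-swap symmetry

The A/B monomer labelling is physically arbitrary: record
(A, B, frac_A) describes the same polymer as (B, A, 100 − frac_A).
`mirror()` implements that involution and `augment_symmetric()` appends
the mirror image of every record (MW, PDI, *T*g carried over), doubling
the dataset. Mirroring a homopolymer yields a record with an empty A
block and `frac_A = 0`; such records are retained. A network trained
without the augmentation is demonstrably sensitive to the labelling
(`symmetry_gap`, the mean |prediction difference| between a record and
its mirror, is several kelvin); retraining on the combined set drives
the gap down by an order of magnitude and improves CV accuracy.

## Network and training schedule

Fully connected ReLU network, `2N + 3 → 512 × 7 → 1`, dropout 0.2
after every hidden layer, MSE loss, Adam, and a half-cosine learning
rate annealed per step from its initial value to ~0 over the whole run,
no restarts; 500 training epochs. The architecture
(N = 128, 7 × 512, dropout 0.2) is the optimum of the Bayesian
hyperparameter search and ships as the default `ModelConfig`.

Training details the search does not fix were set as follows and are
all exposed in `ModelConfig`:

| parameter | default | rationale |
|---|---|---|
| batch size | 32 | small batches give the 500-epoch budget enough optimizer steps to converge on a few hundred rows |
| initial learning rate | 2e-3 | at 1e-3 the fixed epoch budget leaves the training loss visibly short of its floor (training R² ≈ 0.88 vs ≈ 0.99); 2e-3 reaches convergence without instability |
| weight init | He (fan-in) normal | standard for ReLU |
| dropout placement | after every hidden layer | uniform regularization of all hidden representations |

The network is implemented directly in NumPy (float32, flat parameter
buffer, vectorized Adam). Two numerical details matter on x86: the
second-moment accumulator is floored at 1e-30 and the first moment is
flushed to zero below 1e-30, because dead ReLU units receive
exactly-zero gradients whose decayed moments otherwise drift into the
float32 denormal range, where the hardware slows down by an order of
magnitude. Seeded training is bit-reproducible on a fixed platform;
inference has no stochastic path (dropout disabled), so repeated
predictions are identical.

## Evaluation protocol

Fivefold cross-validation: a uniform random partition into nearly
equal folds, each held out once; the input scaler and the target
standardization are fit inside each training fold; R², MAE and RMSE per
fold are averaged arithmetically. On symmetry-augmented datasets folds
are **pair-aware** by default: a record and its mirror are co-assigned,
since mirrored duplicates carry identical labels and would otherwise
leak between train and test. Non-pair-aware folding is available
(`pair_aware=False`) for comparison with protocols that ignore the
leak. R² on a constant target is an error state
(`ConstantTargetError`), not a silent NaN.

Baselines run under the identical protocol and scaling contract:
radial-kernel support-vector regression (C = 10, gamma = "scale",
epsilon = 0.1 on the standardized target) and L1-penalized linear
regression with the penalty chosen by inner cross-validation.

## Grouped Shapley importance

The importance of each input *variable* — the whole monomer-A
fingerprint block, the whole monomer-B block, frac_A, MW, PDI — is its
Shapley value with the variable treated as a single player. With at
most five players all 2⁵ coalitions are enumerated, so the attribution
is exact up to the background average: a variable absent from a
coalition is replaced by its value in a background record drawn from
the dataset (marginal masking). Reported scores are mean |attribution|
over the evaluated records. A bit-level alternative (per-column sampled
Shapley, |values| summed within blocks) is provided as a cross-check;
it is coarser and slower but produces the same ranking.

## Missing-data experiments

Two strategies are implemented. *Ablation*: remove the input neurons of
one or more numeric slots (frac_A, MW, PDI, MW+PDI) and retrain from
scratch under the standard protocol; fingerprint blocks cannot be
dropped. *Imputation*: keep the trained model untouched and replace the
"missing" slot of held-out records with the mean, minimum or maximum of
the training fold — statistics never come from test rows. Because MW
and PDI are right-skewed, the maximum lies far from the mass of the
data and max-imputation degrades accuracy much more than
min-imputation; mean-imputation of MW/PDI is nearly harmless, while any
mistreatment of frac_A is costly. Both orderings are reproduced on the
synthetic data.

## Hyperparameter search

`hyperopt.optimize` minimizes mean fivefold-CV RMSE over
{fingerprint length} × {depth} × {width} × {dropout} with a Gaussian
process surrogate (Matern-5/2 on normalized coordinates, fixed kernel
scales — with a ~25-trial budget, marginal-likelihood refitting is
noisier than it is worth) and an expected-improvement acquisition
maximized over a random candidate pool; the first third of the budget
is random exploration. Failed trials are logged and excluded from the
surrogate. The trial log (JSON lines) replays any configuration
exactly. The shipped default config is the known optimum, so running
the search is optional.

## Synthetic data generator

The generator emulates the *structure* of published PHA *T*g
compilations so that every pipeline stage is testable without
proprietary data:

- **Chemistry**: 3-/4-/5-hydroxyalkanoate free acids with H, short
  n-alkyl, branched, unsaturated and phenyl-terminated side chains
  (36 templates). Long unbranched homologues are deliberately excluded:
  beyond ~pentyl they share every radius-2 atom environment and collide
  in binary fingerprint space.
- **Composition**: ~35% homopolymers (frac_A = 100); copolymer frac_A
  uniform on [5, 95]. Together these give overall mean ≈ 67, median
  ≈ 74, SD ≈ 32 — the left-skewed shape of real compilations.
- **MW**: lognormal with median 505 and mean ≈ 1160 kg·mol⁻¹, truncated
  below at 47 kg·mol⁻¹, the smallest value such compilations contain;
  below that the −K/MW term would be oligomer physics the emulation
  does not model.
- **PDI**: 1 + Gamma(2.12, 0.76), giving mean ≈ 2.6, SD ≈ 1.1, support
  ≥ 1.
- **Ground truth**: per-monomer homopolymer *T*g drawn uniformly on
  230–300 K; copolymer *T*g from the Fox rule
  1/Tg = w_A/Tg_A + (1 − w_A)/Tg_B, which is exactly symmetric under
  the label swap — the invariance the augmentation experiments probe.
  Gordon–Taylor (tunable asymmetry) is available as an alternative. A
  weak Flory–Fox term −K/MW (K = 500 K·kg·mol⁻¹, ~1 K at the median
  MW) gives the importance analysis a true-but-small MW effect to
  detect; PDI has no true effect. Observation noise is N(0, 2 K).
- frac_A/100 is used directly as the Fox weight fraction; the
  mole-/weight-fraction distinction is ignored (known limitation).

What passing tests on this data do **not** show: real PHA *T*g surfaces
are not Fox-exact, monomer effects are not fully summarized by a
128-bit fingerprint, measurement noise is not homoscedastic Gaussian,
and literature compilations carry inter-laboratory biases. The
generator validates the machinery and the relative orderings
(augmentation helps; monomer chemistry dominates; max-imputation hurts
most), not absolute accuracy on experimental data.

## Problem sizes and runtimes

The default experiment scale is the 133-record emulation, matching the
size regime the method targets; the ground-truth recovery test uses 500
records (fivefold CV of the default network then trains on ~400 rows,
comfortably above the interpolation threshold for 12 monomers). The
comparative experiments in the test suite use a mid-sized network
(64 bits, 4 × 256, 300 epochs) whose CV behaviour tracks the full-size
default closely at a fraction of the cost; `scripts/acceptance.py` uses
the full-size default network for the headline cross-validation numbers
and the mid-sized one for the ablation block (which retrains five
models per dropped input).

## Known limitations

- Exact bit patterns depend on the fingerprint family/radius chosen;
  other choices change individual bits but not the pipeline's
  behaviour.
- The SVM/LASSO baselines use fixed sensible hyperparameters (SVR) or
  inner-CV penalty selection (LASSO); no exhaustive baseline tuning.
- Training is CPU-only and single-threaded by design; wall-clock scales
  linearly in epochs × rows.
- Checkpoints store weights (npz) plus a JSON sidecar; they are
  self-describing but not portable across incompatible package
  versions.
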