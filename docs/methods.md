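# Methods

This note documents the models and procedures `synergyloop` implements, the
assumptions behind the synthetic study generator, and the numerical and
design choices made where more than one defensible option existed.

## Synergy scoring

The Bliss independence model treats two drugs as non-interacting when the
combined viability is the product of the single-agent viabilities,
`V(c1,c2) = V(c1)V(c2)`. Writing inhibition `I = 1 − V`, the Bliss excess at
a dose pair is

    s(c1, c2) = I(c1, c2) − I(c1) − I(c2) + I(c1) I(c2).

Scores are reported on the ×100 percentage scale; all internal arithmetic is
in fractions. A block-level label is obtained by pooling the excess matrix
over nonzero-dose cells; the default is the maximum, which is far less
sensitive to the particular concentration window each laboratory chose than
the mean (synergy typically occurs in a localized dose region). Mean pooling
is provided for the average-Bliss variant of the task.

Choices:

- **Replicates** are averaged on the inhibition scale *before* scoring
  (`aggregate_replicates="before"`), because the Bliss formula is nonlinear
  in inhibition and the averaged surface is the better point estimate of the
  underlying response. Scoring each replicate and averaging the excess
  matrices (`"after"`) is exposed as an option; on noiseless data the two
  agree exactly.
- **Zero-dose margins** supply the single-agent responses and are excluded
  from pooling: their excess is identically zero under exact normalization
  and pure noise otherwise.
- **Plate normalization** anchors 0% viability at the highest-concentration
  doxorubicin well per replicate and 100% at the (0,0) control per
  combination, caps to [0, 100], and converts to fractional inhibition.
- **Quality control** rejects blocks with inhibition standard deviation
  ≤ 0.05 (rule a, assay failure), blocks smaller than 3×3 (rule b, too few
  dose pairs to pool meaningfully), and blocks whose mean inhibition lies
  outside (0.05, 0.95) (rule c, dose range missed the active window).
- **Replicate noise** η̄ is the mean over replicated (drug, drug, cell line)
  triplets of the sample (n−1) standard deviation of the pooled score —
  the sample convention because replicate counts are small and the unbiased
  variance is wanted. Note the sample *standard deviation* still carries the
  c₄(n) bias (≈ 0.89 at n = 3), which is why the recovery tests hold it to
  15% rather than to the percent level.

## The regression model

Drug features are a circular fingerprint (radius 2, 1024 bits for real
structures) concatenated with a one-hot identity encoding; either block can
be zeroed without changing dimensions, which is how feature-importance
ablations are run. The model is

1. **Single-drug encoder** `E : R^{l_D} → R^{k_D}` — an MLP (default hidden
   [1024], output 128) applied to both drugs with shared weights.
2. **Pairing** — a bilinear tensor `B ∈ R^{k_D×k_D×k}` (k = 64) whose slices
   are symmetrised at evaluation time, `z_i = e1ᵀ (W_i + W_iᵀ)/2 e2`. The
   stored tensor is unconstrained — the optimizer never has to respect the
   constraint — while every forward pass is exactly order-invariant.
3. **Head** — an MLP (default hidden [64]) mapping `z` to the scalar score.
4. **FiLM conditioning** (optional) — per hidden layer of both encoder and
   head, linear maps from cell-line features to a scale γ and shift β applied
   between the affine layer and its nonlinearity. Initialised at the neutral
   transform (γ ≡ 1, β ≡ 0), so an unconditioned model and a
   freshly-initialised conditioned one agree exactly.

Training minimises MSE with Adam (learning rate 1e−4, weight decay 1e−4 by
default — our picks from within the searched grids, since the selected
values for these two are not recoverable; both exposed in config), batch
size 128, early stopping on a 20% validation split (patience 20, max 500
epochs) with best-validation weights restored. ReLU activations throughout
(standard for this architecture family). The network core, including
backpropagation, is hand-implemented in NumPy; gradients are verified
against finite differences in the test suite's development history and the
bilinear/FiLM algebra is unit-tested directly.

Hyperparameter grids documented for reference (baselines are *not*
implemented, per scope): gradient boosting — max depth {2,5,10,**20**},
min samples split {2,5,10,**20**,50}, learning rate
{1e−4,1e−3,1e−2,**0.1**,1}, max features {all, sqrt, log2}; linear SVM —
tolerance {1e−1..1e−6}, C {1e−4,...,**0.1**,...,10}.

The DeepSynergy-style baseline (implemented) is a plain MLP on the
concatenated [drug1 | drug2 | cell] features, standardised to mean 0 / sd 1
(zero-variance columns map to 0) then tanh-transformed, with input dropout
0.2 and layer dropout 0.5, hidden layers (8182, 4096) by default; order
invariance is imposed by averaging the predictions on (d1,d2) and (d2,d1).

## Uncertainty

- **Deep ensembles** (default; size 5 in simulation, 36 for recommendation
  generation): members differ only in initialisation seed; μ̂ is the member
  mean and σ̂ the member *population* standard deviation — the ensemble is
  the whole predictive sample, not a subsample, so n (not n−1) is the right
  normaliser.
- **Direct estimation**: a frozen MSE-trained mean predictor plus an
  uncertainty predictor of the same architecture whose scalar output
  parameterises log σ̂² (floored at σ ≥ 1e−3; the NLL diverges as σ → 0),
  trained with `NLL = log(σ̂²)/2 + (y−μ̂)²/(2σ̂²)`. With σ̂ ≡ 1 this is half
  the squared error, i.e. the MSE criterion.

  Two implementation choices matter in practice. First, the residual targets
  are computed **out of fold** (5 auxiliary mean predictors trained on
  complementary folds): the bilinear architecture with one-hot features can
  interpolate per-pair noise almost perfectly in sample, so in-sample
  residuals are structureless and the uncertainty predictor would learn
  nothing — out-of-sample error is also what the predictive spread is meant
  to describe. Second, the log-variance head's bias starts at the marginal
  residual log-variance, so optimisation begins at the right scale instead
  of fighting enormous early gradients.

## Acquisition and batch design

Scores over the unlabeled pool: brute force = seeded uniform noise (random
querying), greedy = μ̂, pure exploration = σ̂, UCB = μ̂ + κσ̂ with κ = 1 by
default. Selection walks the score ranking (ties broken by a seeded random
key, so rankings are reproducible) under one of four regimes: unconstrained
top-k; drug-disjoint (each drug at most once per batch — the calibration
round's rule); diversity-first (each queried combination must involve at
least one drug absent from both the history and the current batch, batch
size 30); per-drug cap (no drug more than `cap`=5 times — interpreted per
batch, since the rule exists to avoid oversampling and stock depletion
within a round; a cumulative-history mode is available as an option).

## The SMO loop

Round 0 seeds the visible set with 30 uniformly random pairs. Each round:
re-split the visible set 80/20 (a fresh split every round, mirroring
re-splitting per iteration), train the model/ensemble *from scratch* with
early stopping — retraining avoids overfitting to early acquisitions —
score the hidden pool, select a batch of 30 under the round's constraints,
query the oracle and move the batch into the visible set. Failed oracle
queries are logged, excluded, and never retried by default. Rounds whose
strategy is brute force skip the retraining step: the scores are seeded
noise and never consult the model, so the selections are identical and the
simulation is much cheaper. Trajectories serialise to JSON with all seeds.

Recommendation mode fine-tunes each of 3 pretrained models on the
prospective data only, once per each of 12 seeds (all weights updated, no
frozen layers), giving the 36-member ensemble whose UCB scores rank the
candidates.

## Evaluation harness

- **Splits**: default 70/20/10 over combinations; one-unseen-drug holds out
  30% of drugs and tests on pairs with exactly one held-out drug;
  two-unseen-drugs tests on pairs of two held-out drugs (remaining seen-seen
  pairs split 80/20); shuffled-labels uses the default split after
  whole-row permutation of the feature matrix
  (`randomize_features(fraction=1)` — fingerprint and one-hot blocks move
  jointly, the literal reading of permuting a drug's representation).
- **Metrics**: R², Spearman (average ranks on ties), and, given
  uncertainties, explained variance weighted by w = 1/σ̂ with weighted means
  and variances throughout — the concrete estimator is a package choice and
  is isolated so it can be swapped.
- **Enrichment**: reversed cumulative density P(S ≥ s) of queried synergies
  and its ratio against random querying; thresholds where the random density
  is zero are reported missing. "Synergistic" defaults to a max-Bliss score
  above 30 (40 available as the stricter variant).
- **Noise-derived bounds**: corrupt the true scores with N(0, η²), let a
  perfect regressor fit the noisy observations exactly, and score it against
  the truth; the average over simulations bounds what any model evaluated on
  noisy labels can achieve. Exactly 1 at η = 0.

## The synthetic study generator

The generator emulates the statistical structure the pipeline assumes;
defaults are the study conditions used throughout the tests.

- **Library**: each drug gets one of 10 latent mechanisms; a mechanism has a
  deterministic signature bit pattern (128 bits by default) and a drug's
  pseudo-fingerprint is that signature with 10% independent bit flips, so
  within-mechanism Tanimoto similarity exceeds the cross-mechanism level —
  the structure/mechanism correlation that makes unseen-drug generalization
  possible at all.
- **Landscape**: synergy is a property of mechanism pairs. Four mechanism
  pairs (≈ 8% of drug pairs; the planted fraction is kept ≤ 10%) carry
  planted effects drawn from 35 + Exp(10), truncated at 62; all other pairs
  draw from N(0, 5) clipped to ±15. The result is a heavy-tailed
  distribution concentrated near zero with a small predictable positive
  tail. The planted fraction and effect scale were fixed at design time so
  that the predictable share of variance resembles a real screen (test R²
  roughly 0.3–0.5); with a vanishing planted fraction the landscape is pure
  unpredictable background and no regressor — however good — can beat the
  mean.
- **Observations**: true + iid N(0, η²), η = 5 by default (same ×100 scale);
  a per-pair η array is accepted for heteroscedastic designs.
- **Dose–response blocks**: 6×6 grids (zero dose + five concentrations in a
  1:3 dilution), single agents as four-parameter sigmoids (baseline
  inhibition 0.08–0.2, top asymptote 0.55–0.9, potency log-uniform over the
  grid span, Hill slope 0.5–2). The combination surface is the independence
  surface plus an excess field scaled so the noiseless max-pooled Bliss
  score equals the pair's true synergy: a localized Gaussian bump at a
  seeded cell with inhibition headroom for positive scores, and a *uniform*
  offset for non-positive scores — a localized negative bump is invisible to
  max pooling, which reports the least-antagonistic cell. Two consequences
  are deliberate: curve parameters are drawn per block and resampled (≤ 60
  tries) until the planted effect fits the surface's achievable excess range
  (assays re-titrate dose ranges per experiment, and without this the
  round-trip guarantee is unsatisfiable for potent drug pairs); and the
  background clip at ±15 reflects that max-pooled Bliss scores of real
  blocks are bounded below by −(minimum independence inhibition). Replicate
  noise is Gaussian with sd η/100 on the inhibition scale, clipped to [0,1].
- All randomness flows from one study seed through named substreams
  (library, landscape, noise, doses), so studies regenerate bit-identically.

What passing on this generator does and does not show: it demonstrates that
the scoring, modelling, uncertainty, acquisition and evaluation machinery is
correct and that the loop finds planted structure when structure exists; it
does not demonstrate chemistry-level generalization — pseudo-fingerprints
have none of the activity-cliff behaviour of real structure–activity
landscapes, real screens have batch effects between studies that the
generator does not model, and planted mechanism-pair synergy is cleaner than
any real mechanism of synergy.

## Problem sizes used in the checks

The bundled tests and `scripts/acceptance.py` run a scaled-down network
(hidden 64, embedding 16, bilinear 8, head 8, learning rate 1e−3) on studies
of 14–46 drugs: simulated campaigns use a 46-drug / 1,035-pair landscape
with ten rounds of 30 queries and ensembles of 3; split benchmarks use 40
drugs / 780 pairs; round-trip and noise-recovery checks use ~200 blocks and
500 replicated triplets. These sizes were chosen so the full suite completes
in minutes on a single CPU while every check still runs the complete
pipeline end to end.

## Known limitations

- The NumPy training loop is single-threaded BLAS-bound; production-default
  dimensions (1024-hidden encoder on 1024-bit fingerprints) train, but
  slowly compared to a GPU framework.
- Only Bliss synergy is implemented (no HSA/Loewe, no Hill-curve fitting);
  the max-pooled score deliberately ignores antagonism regions.
- Cell-line conditioning is implemented and tested (FiLM), but the bundled
  synthetic generator produces single-cell-line studies; multi-cell-line
  realism (mutation/expression features, cross-cell-line transfer) is out of
  scope.
- The k-medoids implementation restricts PAM swaps to within-cluster
  candidates per sweep (capped at 100 sweeps), which is the usual
  fast-PAM-style compromise rather than exhaustive swap search.
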