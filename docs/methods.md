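# Methods

`admeseq` implements a two-step pipeline for pharmacokinetics-aware
drug-likeness prediction, together with the task-dependency analysis
that motivates it, and a synthetic-data generator that makes the whole
pipeline testable at desk scale.

## The model

**Step 1 — sequential ADME multi-task learning.** A molecule is
featurized as a binary circular-substructure (Morgan/ECFP-style)
fingerprint and mapped by a shared MLP trunk to an embedding
*z* ∈ ℝ^d_z. One small MLP head per endpoint reads *z* and emits a
scalar: a sigmoid probability for classification endpoints, an
unbounded real for regression endpoints. Endpoints are grouped into the
four pharmacokinetic categories A (absorption), D (distribution), M
(metabolism), E (excretion). Each training epoch visits the categories
in a user-given order — the physiological flow A→D→M→E by default — and
trains each category's endpoints jointly on mini-batches over the union
of that category's molecules.

Losses are masked: a molecule contributes to an endpoint's loss only
where the label is observed (binary cross-entropy for classification,
squared error on the z-scored scale for regression). An endpoint's
batch loss averages over its observed entries; the total is the
unweighted mean over contributing endpoints. Regression targets are
z-scored with mean and *population* standard deviation fitted on
training molecules only, which is what makes the unweighted mixture of
BCE and MSE losses commensurable.

Within a category, each endpoint's gradient on the *shared trunk*
parameters is computed separately, and conflicts are resolved by
gradient surgery (PCGrad): for each gradient g_i, the other raw
gradients are visited in seeded random order and whenever
g_i · g_j < 0, g_i is replaced by its projection onto the normal plane
of g_j,

    g_i ← g_i − (g_i·g_j / ‖g_j‖²) g_j ,

and the combined update is the sum of the projected gradients. With no
conflicting pair this reduces exactly to the plain sum. Head parameters
only ever receive their own endpoint's gradient. One Adam optimizer
instance persists across categories and epochs. A naïve mode trains all
endpoints (or a chosen category subset) as one flat group with a summed
backward pass and no surgery.

**Step 2 — drug-likeness classification.** The trained encoder is
frozen (asserted by hashing every parameter array before and after);
molecules from a drug/non-drug table are encoded into *z* and a small
MLP (two hidden layers of width 128 by default) is trained with binary
cross-entropy under stratified k-fold cross-validation. Metrics are
MCC and F1 at the fixed 0.5 threshold and AUPRC computed as average
precision (step interpolation; tied scores share a threshold). A
degenerate MCC denominator is defined as 0.

**Task-dependency analysis.** For categories, the task improvement rate

    TIR(A|B) = (L_STL(A) − L_MTL(A|B)) / L_STL(A)

compares A's single-task held-out loss with its average held-out loss
over *all* swept subsets containing both A and B (the full subset
ABCD included). A category's loss is the unweighted mean of its
endpoints' held-out losses, averaged before the ratio. Positive TIR
means co-training with B lowers A's loss. Off-diagonal TIR cells become
a directed signed graph with edge partner→target, weight |TIR|.

## The synthetic generator

Molecules are enumerated from ~30 two-site scaffolds decorated with 18
R-groups (≈6.5k valid unique structures after canonicalization); a
seeded permutation takes the first *n*. Four latent factors form a
Markov chain: u_A is a standardized random linear functional of the
fingerprint plus Gaussian noise (`noise_sd`), and each downstream factor
is √s·u_prev + √(1−s)·(an in-sample-orthogonalized fingerprint signal)
plus noise, standardized, with s = `chain_strength`. Each endpoint is
an affine readout of its category's factor plus readout noise
(`readout_noise_sd`), thresholded at its median for classification
endpoints (balanced classes by construction). Labels are masked
independently at `missing_rate`. The drug-likeness label thresholds a
logistic score over (u_A, u_D, u_M, u_E) at its median.

Defaults (the study conditions): n=2000 molecules, 2 endpoints per
category (one classification, one regression), chain_strength=0.8,
noise_sd=0.1, readout_noise_sd=0.5, missing_rate=0.3. The two noise
dials are deliberately asymmetric: latent pharmacokinetic behaviour is
treated as mostly structure-determined (small `noise_sd`), while
individual assay readouts are noisy (larger `readout_noise_sd`) — it is
precisely that assay noise which makes cross-task transfer along the
planted chain worth having. The generator is a pure function of its
config (byte-identical output files per seed).

What the generator does *not* emulate: chemically realistic property
distributions or dataset sizes, scaffold bias between drug and non-drug
sets, inter-endpoint correlations beyond the single per-category
factor, and non-random missingness. Passing tests on this fixture show
that the machinery recovers a planted dependency structure, not that
the method improves real ADME prediction.

## Reference protocols

Three protocols (module `admeseq.experiments`) constitute the package's
synthetic-data evidence; all randomness flows from a single seed.

**Order recovery.** Forward (A→D→M→E) vs reverse (E→M→D→A) sequential
training compared on the mean held-out loss of the downstream
categories D, M, E. Block-coordinate training makes visiting order a
*transient* phenomenon: once both runs converge, the within-epoch order
has vanishing influence and the contrast is pure noise. The protocol
therefore uses a short fixed budget (4 epochs, learning rate 1e-3,
batch 128), reads the final-epoch downstream loss, and averages 5
training replicates per dataset; forward and reverse runs share
initialization and batch streams, so the comparison is paired. Under
the default generator this finds the forward order better in roughly
8–10 of 10 dataset seeds.

**Equal-budget paired sweep for TIR.** Each subset of the sweep starts
from the same trunk initialization and the same batch-stream seed and
trains for the same fixed 20-epoch budget; the category loss is read at
the end of the budget. Pairing removes initialization and stopping-time
variance from the STL-vs-MTL contrast; the equal budget makes it a
fair "same compute" comparison in which co-training's extra signal and
its regularization both count. TIR(D|A) under the default generator is
positive in ~9–10 of 10 seeds (mean ≈ +0.2).

**Drug-likeness end-to-end.** Step 1 at the convergence-oriented
preset (learning rate 5e-4, batch 128, early stopping with patience 10
on the total held-out loss), then Step 2 on the frozen embeddings with
stratified 5-fold CV. This check runs under a low-noise condition
(n=3000, noise_sd=0.01, readout_noise_sd=0.05) in which the drug label
is separable from structure; the interesting outcome is then whether
the *pipeline* preserves that separability (CV MCC ≳ 0.9). Under the
noisy default generator the same pipeline reaches MCC ≈ 0.85, which is
close to the raw-fingerprint information ceiling of that condition.

## Numerical and design choices

- **Duplicate labels** in aggregation: majority vote for
  classification (ties drop the observation), arithmetic mean for
  regression; a strict mode refuses disagreements instead.
- **Canonical keys** come from the toolkit's canonical SMILES; salts
  and stereochemistry are preserved. An opaque-key mode treats raw
  strings as keys (with hash-filled fingerprint bits) for
  chemistry-free fixtures.
- **Validation split** for convergence and all ledger losses: 10% of
  molecules by seeded key hash — stable across runs and independent of
  record order.
- **Fold assignment**: stratified k-fold (per-fold positive counts
  within one of the proportional share) on a binary label; the
  multi-endpoint ADME dataset, which has no single label, uses a
  deterministic hash split. Fold f is the test fold of CV round f.
- **Convergence rule**: stop when the total held-out loss fails to
  improve by more than 1e-4 (relative) for 5 consecutive epochs
  (patience 10 in the small preset), or at `epochs_max`.
- **PCGrad scope**: sequential mode only, within categories, matching
  the placement of conflict resolution inside the category loop; the
  flat naïve objective uses a plain sum (override available). A
  zero-norm conflicting partner is skipped; probabilities are clipped
  at 1e-7 inside BCE.
- **Determinism**: every stochastic component (molecule sampling,
  latent noise, batch order, initialization, surgery order, fold
  assignment) draws from a named substream of the run seed; two runs
  with the same config and seed produce bit-identical ledgers and
  parameters on the same hardware/BLAS build.
- **Problem sizes**: the reference experiments use the 256-bit/d_z=32
  encoder on the 2000-molecule preset, chosen so the full experiment
  battery (order recovery, sweep, end-to-end CV) completes in a few
  minutes on one CPU core.

## Known limitations

- The fingerprint+MLP encoder is the only bundled encoder; pretrained
  graph/transformer encoders are supported through the
  `MolecularEncoder` adapter contract but no weights ship.
- The order-recovery effect is an early-training phenomenon here; at
  full convergence on this generator the forward/reverse contrast
  vanishes. Whether real ADME data behaves the same way cannot be
  settled on synthetic fixtures.
- TIR is computed at category level (4×4); endpoint-level (21×21)
  dependency analysis is out of scope.
- The drug-likeness classifier is a plain MLP; no rule-based baselines
  (QED etc.), PU-learning, or threshold tuning per fold.
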