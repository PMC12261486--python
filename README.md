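# admeseq

Sequential, pharmacokinetics-ordered multi-task learning for ADME
endpoint prediction, with a data-driven task-dependency analysis and a
drug-likeness classifier on the resulting embeddings.

Early drug discovery needs fast filters that say whether a molecule
*behaves* like a drug, not just whether it looks like one. Absorption,
distribution, metabolism and excretion (ADME) endpoints carry that
behavioural signal, but they are scattered across many small, partially
overlapping assay tables, and the four stages are not independent: what
a compound does in absorption constrains what happens downstream.
`admeseq` is for computational chemists and ML practitioners who want
to (1) train one molecular encoder across many masked ADME endpoints,
(2) measure which pharmacokinetic task groups help or hurt each other,
and (3) reuse the ADME-informed embedding for drug/non-drug
classification.

## What it does

**Step 1.** A fingerprint encoder (shared MLP trunk → embedding *z*,
one MLP head per endpoint) is trained over the four categories
A → D → M → E in sequence within each epoch, any order allowed.
Missing labels are masked out of every loss. Within a category,
per-endpoint gradients on the shared trunk are combined by gradient
surgery: whenever gᵢ·gⱼ < 0,

```
gᵢ ← gᵢ − (gᵢ·gⱼ / ‖gⱼ‖²) gⱼ
```

so conflicting tasks stop fighting over the representation.

**Task dependencies.** A brute-force sweep trains every category subset
and computes the task improvement rate

```
TIR(A|B) = (L_STL(A) − L_MTL(A|B)) / L_STL(A)
```

— positive when co-training with B lowers A's held-out loss — and turns
the 4×4 matrix into a directed, signed dependency graph.

**Step 2.** The encoder is frozen and a small MLP separates approved
drugs from non-drugs on the embeddings, evaluated with MCC, F1 and
AUPRC (average precision) under stratified 5-fold cross-validation.

Input tables follow the common single-instance layout (`id, smiles,
label`, one file per endpoint, plus a YAML manifest naming each
endpoint's category and task type). A bundled synthetic generator
plants a known A→D→M→E latent chain so every claim is testable without
external data.

## Worked example

`examples/03_task_dependency.py` generates the default synthetic
dataset (2000 molecules, 8 endpoints, chain strength 0.8), trains all
15 category subsets under an equal epoch budget from a shared
initialization, and prints the TIR matrix:

```
TIR matrix (rows: target, columns: partner; positive = partner helps):
partner      A      D      M      E
target
A          NaN  0.147  0.146  0.149
D        0.254    NaN  0.215  0.197
M        0.211  0.207    NaN  0.183
E        0.244  0.230  0.230    NaN
```

Read column A: co-training with absorption improves distribution,
metabolism and excretion by 21–25% of their single-task loss — the
largest entries in the matrix — while A itself gains less from the
others (row A, ~15%). That asymmetry is the planted upstream→downstream
structure being recovered from data. `examples/04_druglikeness.py`
then runs both steps end to end and prints the cross-validated report:

```
fold    mcc     f1      auprc
0       0.9067  0.9532  0.9947
...
4       0.9434  0.9718  0.9972
mean (sd)       0.9202 (0.0159)  0.9598 (0.0083)  0.9962 (0.0010)

encoder frozen during Step 2: True
```

## Command line

```bash
admeseq generate  --preset default --seed 1 --out data/        # synthetic tables
admeseq aggregate --manifest data/manifest.yaml --out agg/     # masked wide table
admeseq train-adme --manifest data/manifest.yaml --order ADME --seed 1 --out run/
admeseq sweep-tir  --manifest data/manifest.yaml --seed 1 --out tir/
admeseq embed     --checkpoint run/encoder.npz --input data/druglikeness.csv --out z.csv
admeseq train-dl  --embeddings z.csv --labels data/druglikeness.csv --k 5 --seed 1 --out dl/
admeseq run       --config pipeline.yaml                       # all of the above
```

Every output directory gets a `run_manifest.json` (command, resolved
config, seed, input digests, version), and identical config+seed
reproduces identical metric files.

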