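"""Train the fingerprint encoder sequentially in pharmacokinetic order.

Each epoch visits the categories in the given order (absorption first),
training each category's endpoints jointly with masked losses and
resolving conflicting trunk gradients by gradient surgery.  The printed
trajectory is the total held-out loss per epoch; it should fall and then
plateau, at which point early stopping ends the run.
"""

import dataclasses

from admeseq import TrainConfig, train_sequential
from admeseq.encoders import EncoderModel
from admeseq.experiments import build_dataset
from admeseq.presets import SMALL_ENCODER, SMALL_TRAIN

dataset, _ = build_dataset(seed=0, synth=None)  # default 2000-molecule preset

cfg = dataclasses.replace(SMALL_TRAIN, mode="sequential", order=tuple("ADME"), seed=0)
model = EncoderModel(dataset.endpoints, SMALL_ENCODER, seed=0)
model, ledger = train_sequential(model, dataset, cfg)

print(f"trained {ledger.n_epochs} epochs (early-stopped), order A->D->M->E")
print("total held-out loss per epoch:")
for epoch in sorted(ledger.total_val):
    print(f"  epoch {epoch:2d}: {ledger.total_val[epoch]:.4f}")
best = ledger.best_epoch()
print(f"best epoch {best}; per-endpoint held-out losses there:")
for name, loss in sorted(ledger.val_at(best).items()):
    print(f"  {name}: {loss:.4f}")
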