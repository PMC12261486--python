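"""Named presets for desk-scale runs.

``SMALL_ENCODER`` is a 256-bit fingerprint trunk with a 32-dimensional
embedding; ``SMALL_TRAIN`` favours smooth optimization (modest learning
rate, large batches, patient early stopping) so that run-to-run noise
does not drown the order and task-dependency effects under study;
``DEFAULT_SYNTH`` is the default synthetic study condition (2000
molecules, two endpoints per category, chain strength 0.8).
"""

from admeseq.encoders import SMALL_ENCODER
from admeseq.seq_mtl import TrainConfig
from admeseq.synthetic_data import SyntheticConfig

DEFAULT_SYNTH = SyntheticConfig()

SMALL_TRAIN = TrainConfig(
    learning_rate=5e-4,
    batch_size=128,
    epochs_max=60,
    patience=10,
)

__all__ = ["SMALL_ENCODER", "SMALL_TRAIN", "DEFAULT_SYNTH"]
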