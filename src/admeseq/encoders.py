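"""Molecular encoders: fingerprint featurization, shared trunk, endpoint heads.

The reference encoder represents a molecule as a binary circular-substructure
fingerprint and maps it through an MLP trunk to an embedding ``z``; one small
MLP head per endpoint reads ``z`` and emits a scalar (a probability for
classification endpoints, an unbounded real for regression).  Pretrained
graph/transformer encoders can be plugged in through the same interface
(:class:`MolecularEncoder`).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np

from admeseq._nn import MLP, sigmoid
from admeseq.chem_data import EndpointSpec, SmilesParseError

__all__ = [
    "FingerprintConfig",
    "EncoderConfig",
    "EncoderModel",
    "MolecularEncoder",
    "featurize",
    "featurize_batch",
    "endpoint_manifest_hash",
    "params_hash",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class FingerprintConfig:
    """Circular (Morgan/ECFP-style) fingerprint settings.

    radius 2 with 2048 bits is the common ECFP4-equivalent default; the
    small presets in this package use 256 bits.
    """

    radius: int = 2
    n_bits: int = 2048
    opaque: bool = False  # hash raw strings instead of parsing (fixtures only)

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError("radius must be >= 0")
        if self.n_bits <= 0:
            raise ValueError("n_bits must be > 0")


_FP_CACHE: dict[tuple[str, int, int, bool], np.ndarray] = {}


def featurize(key: str, cfg: FingerprintConfig) -> np.ndarray:
    """Return the binary fingerprint of one molecule as a float vector.

    Deterministic: the same key always yields the identical vector.  In
    opaque mode the bits are filled from a hash of the raw string, which
    keeps featurization total on non-chemical test keys.
    """
    if not key:
        raise SmilesParseError("empty molecule key")
    cache_key = (key, cfg.radius, cfg.n_bits, cfg.opaque)
    hit = _FP_CACHE.get(cache_key)
    if hit is not None:
        return hit.copy()
    if cfg.opaque:
        digest = hashlib.sha256(key.encode()).digest()
        rng = np.random.default_rng(int.from_bytes(digest[:8], "big"))
        vec = np.zeros(cfg.n_bits)
        n_on = max(1, cfg.n_bits // 16)
        vec[rng.choice(cfg.n_bits, size=n_on, replace=False)] = 1.0
    else:
        from rdkit import Chem
        from rdkit.Chem import rdFingerprintGenerator

        mol = Chem.MolFromSmiles(key)
        if mol is None:
            raise SmilesParseError(f"unparsable SMILES: {key!r}")
        gen = rdFingerprintGenerator.GetMorganGenerator(
            radius=cfg.radius, fpSize=cfg.n_bits
        )
        fp = gen.GetFingerprint(mol)
        vec = np.zeros(cfg.n_bits)
        vec[list(fp.GetOnBits())] = 1.0
    _FP_CACHE[cache_key] = vec
    return vec.copy()


def featurize_batch(keys: Sequence[str], cfg: FingerprintConfig) -> np.ndarray:
    return np.stack([featurize(k, cfg) for k in keys]) if keys else np.zeros((0, cfg.n_bits))


@dataclass(frozen=True)
class EncoderConfig:
    """Architecture of the fingerprint encoder.

    ``trunk_hidden`` lists the widths of the trunk's hidden layers (two by
    default); ``d_z`` is the embedding width read by every head and by the
    downstream drug-likeness classifier.
    """

    fingerprint: FingerprintConfig = field(default_factory=FingerprintConfig)
    d_z: int = 128
    trunk_hidden: tuple[int, ...] = (256, 256)
    head_hidden: int = 32


SMALL_ENCODER = EncoderConfig(
    fingerprint=FingerprintConfig(radius=2, n_bits=256),
    d_z=32,
    trunk_hidden=(64, 64),
    head_hidden=16,
)


def endpoint_manifest_hash(specs: Sequence[EndpointSpec]) -> str:
    """Stable digest of the endpoint manifest (names, categories, task types)."""
    doc = [(s.name, s.category, s.task_type) for s in sorted(specs, key=lambda s: s.name)]
    return hashlib.sha256(json.dumps(doc).encode()).hexdigest()


class MolecularEncoder(Protocol):
    """Adapter contract for alternative encoders (pretrained GNNs etc.).

    An adapter must provide deterministic ``featurize_keys``, an ``encode``
    producing (batch, d_z) embeddings, ``predict`` per endpoint, and expose
    its shared (trunk) parameter arrays separately from per-endpoint head
    parameters so the sequential trainer can apply gradient surgery to the
    shared ones only.
    """

    def featurize_keys(self, keys: Sequence[str]) -> np.ndarray: ...

    def encode(self, features: np.ndarray) -> np.ndarray: ...

    def predict(self, features: np.ndarray, endpoints: Sequence[str]) -> dict[str, np.ndarray]: ...


class EncoderModel:
    """Fingerprint trunk with one scalar MLP head per endpoint.

    All heads read the same trunk output ``z``; embeddings are extracted
    from the trunk before any head, so deleting every head cannot change
    :meth:`encode`.
    """

    def __init__(
        self,
        specs: Sequence[EndpointSpec],
        cfg: EncoderConfig | None = None,
        seed: int = 0,
    ):
        self.cfg = cfg or EncoderConfig()
        self.specs = list(specs)
        self.spec_by_name = {s.name: s for s in self.specs}
        self.manifest_hash = endpoint_manifest_hash(self.specs)
        self.seed = seed
        rng = np.random.default_rng(seed)
        fp = self.cfg.fingerprint
        trunk_sizes = [fp.n_bits, *self.cfg.trunk_hidden, self.cfg.d_z]
        self.trunk = MLP(trunk_sizes, rng)
        self.heads: dict[str, MLP] = {}
        for spec in self.specs:
            self.heads[spec.name] = MLP(
                [self.cfg.d_z, self.cfg.head_hidden, 1], rng
            )

    # -- featurization -----------------------------------------------------
    def featurize_keys(self, keys: Sequence[str]) -> np.ndarray:
        return featurize_batch(keys, self.cfg.fingerprint)

    # -- forward passes ----------------------------------------------------
    def encode(self, features: np.ndarray) -> np.ndarray:
        """Map feature vectors to embeddings z of shape (batch, d_z)."""
        z, _ = self.trunk.forward(np.asarray(features, dtype=float))
        return z

    def head_raw(self, name: str, z: np.ndarray) -> np.ndarray:
        """Pre-activation head output (logit for classification heads)."""
        if name not in self.heads:
            raise KeyError(f"unknown endpoint {name!r}")
        return self.heads[name](z)[:, 0]

    def predict(
        self, features: np.ndarray, endpoints: Sequence[str] | None = None
    ) -> dict[str, np.ndarray]:
        """Predict the requested endpoints; probabilities for classification."""
        names = [s.name for s in self.specs] if endpoints is None else list(endpoints)
        unknown = [n for n in names if n not in self.heads]
        if unknown:
            raise KeyError(f"unknown endpoints: {unknown}")
        if not names:
            return {}
        z = self.encode(features)
        out = {}
        for name in names:
            raw = self.head_raw(name, z)
            if self.spec_by_name[name].task_type == "classification":
                out[name] = sigmoid(raw)
            else:
                out[name] = raw
        return out

    # -- parameter plumbing ------------------------------------------------
    def all_params(self) -> list[np.ndarray]:
        params = list(self.trunk.params)
        for name in sorted(self.heads):
            params.extend(self.heads[name].params)
        return params


def params_hash(model: EncoderModel) -> str:
    """Digest of every parameter byte; used to assert an encoder is frozen."""
    h = hashlib.sha256()
    for p in model.all_params():
        h.update(np.ascontiguousarray(p).tobytes())
    return h.hexdigest()


def save_checkpoint(model: EncoderModel, path: str | Path) -> None:
    """Serialize config, endpoint manifest and all parameters to one file."""
    meta = {
        "cfg": {
            "fingerprint": asdict(model.cfg.fingerprint),
            "d_z": model.cfg.d_z,
            "trunk_hidden": list(model.cfg.trunk_hidden),
            "head_hidden": model.cfg.head_hidden,
        },
        "specs": [asdict(s) for s in model.specs],
        "manifest_hash": model.manifest_hash,
        "seed": model.seed,
    }
    arrays = {"trunk__%d" % i: p for i, p in enumerate(model.trunk.params)}
    for name, head in model.heads.items():
        for i, p in enumerate(head.params):
            arrays[f"head__{name}__{i}"] = p
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(
    path: str | Path, expected_manifest: Sequence[EndpointSpec] | None = None
) -> EncoderModel:
    """Load a checkpoint; refuse if it disagrees with the expected manifest."""
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        cfg = EncoderConfig(
            fingerprint=FingerprintConfig(**meta["cfg"]["fingerprint"]),
            d_z=meta["cfg"]["d_z"],
            trunk_hidden=tuple(meta["cfg"]["trunk_hidden"]),
            head_hidden=meta["cfg"]["head_hidden"],
        )
        specs = [EndpointSpec(**s) for s in meta["specs"]]
        if expected_manifest is not None:
            if endpoint_manifest_hash(expected_manifest) != meta["manifest_hash"]:
                raise ValueError(
                    "checkpoint endpoint manifest does not match the expected one"
                )
        model = EncoderModel(specs, cfg, seed=meta["seed"])
        for i in range(len(model.trunk.params)):
            model.trunk.params[i][...] = data["trunk__%d" % i]
        for name, head in model.heads.items():
            for i in range(len(head.params)):
                head.params[i][...] = data[f"head__{name}__{i}"]
    return model
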