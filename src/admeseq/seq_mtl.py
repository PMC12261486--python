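"""Sequential multi-task training of the shared encoder over ADME categories.

Within a pharmacokinetic category the member endpoints are trained
jointly on mini-batches of the union of their molecules, with missing
labels masked out of every loss and (optionally) gradient surgery
resolving conflicting per-endpoint gradients on the shared trunk.
Between categories, training proceeds in a user-given order — the
pharmacokinetic flow A→D→M→E by default — once per epoch, until the
total held-out loss converges.  A naïve mode trains all endpoints as one
flat group (a single summed backward pass), and a subset mode restricts
the flat group to chosen categories, which is what the task-dependency
sweep and single-task baselines use.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from admeseq._nn import Adam, flatten_arrays, sigmoid, unflatten_like
from admeseq.chem_data import CATEGORIES, AggregatedDataset, EndpointSpec
from admeseq.encoders import EncoderModel

__all__ = [
    "TrainConfig",
    "LossLedger",
    "masked_losses",
    "pcgrad_project",
    "train_sequential",
    "train_naive",
    "validation_split",
]

_EPS_P = 1e-7  # probability clip for binary cross-entropy


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings for one training run.

    ``order`` only matters in sequential mode; ``subset_categories`` only
    in subset mode.  Convergence: training stops once the total held-out
    loss has failed to improve by more than ``convergence_tol`` (relative)
    for ``patience`` consecutive epochs, or at ``epochs_max``.
    """

    order: tuple[str, ...] = CATEGORIES
    mode: str = "sequential"  # sequential | naive | subset
    subset_categories: frozenset[str] = frozenset()
    pcgrad: bool = True
    pcgrad_in_naive: bool = False  # override: surgery also in flat modes
    epochs_max: int = 200
    batch_size: int = 64
    learning_rate: float = 1e-3
    convergence_tol: float = 1e-4
    patience: int = 5
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("sequential", "naive", "subset"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.epochs_max < 1:
            raise ValueError("epochs_max must be >= 1")
        if self.mode == "sequential" and sorted(self.order) != sorted(set(self.order)):
            raise ValueError("order must not repeat categories")
        if self.mode == "subset" and not self.subset_categories:
            raise ValueError("subset mode requires a non-empty subset_categories")


@dataclass
class LossLedger:
    """Every loss recorded during one run.

    ``train[(epoch, group, endpoint)]`` is the masked training loss of an
    endpoint over one pass of its group; ``val[(epoch, endpoint)]`` the
    held-out loss; ``total_val[epoch]`` the unweighted mean of that
    epoch's per-endpoint held-out losses.
    """

    train: dict[tuple[int, str, str], float] = field(default_factory=dict)
    val: dict[tuple[int, str], float] = field(default_factory=dict)
    total_val: dict[int, float] = field(default_factory=dict)

    @property
    def n_epochs(self) -> int:
        return len(self.total_val)

    def best_epoch(self) -> int:
        return min(self.total_val, key=lambda e: (self.total_val[e], e))

    def val_at(self, epoch: int) -> dict[str, float]:
        return {ep: v for (e, ep), v in self.val.items() if e == epoch}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LossLedger):
            return NotImplemented
        return (
            self.train == other.train
            and self.val == other.val
            and self.total_val == other.total_val
        )


def masked_losses(
    predictions: Mapping[str, np.ndarray],
    labels: Mapping[str, np.ndarray],
    masks: Mapping[str, np.ndarray],
    specs: Mapping[str, EndpointSpec] | Sequence[EndpointSpec],
) -> tuple[dict[str, float], float | None]:
    """Per-endpoint masked losses and their unweighted mean.

    Classification endpoints use binary cross-entropy on probabilities,
    regression endpoints squared error on the normalized scale; both are
    averaged over *observed* entries only.  Endpoints with no observed
    entry contribute nothing.  Returns ``(per_endpoint, total)`` with
    ``total=None`` when no endpoint has any observed entry (a flagged
    no-op, not an error).
    """
    if not isinstance(specs, Mapping):
        specs = {s.name: s for s in specs}
    per_endpoint: dict[str, float] = {}
    for name, preds in predictions.items():
        mask = np.asarray(masks[name], dtype=bool)
        if not mask.any():
            continue
        y = np.asarray(labels[name], dtype=float)[mask]
        p = np.asarray(preds, dtype=float)[mask]
        if specs[name].task_type == "classification":
            p = np.clip(p, _EPS_P, 1.0 - _EPS_P)
            loss = float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))
        else:
            loss = float(np.mean((p - y) ** 2))
        per_endpoint[name] = loss
    total = float(np.mean(list(per_endpoint.values()))) if per_endpoint else None
    return per_endpoint, total


def pcgrad_project(grads: Sequence[np.ndarray], seed: int) -> np.ndarray:
    """Combine per-task gradients by projecting away pairwise conflicts.

    For each gradient ``g_i``, the other *raw* gradients are visited in a
    seeded random order; whenever ``g_i . g_j < 0``, ``g_i`` is replaced
    by its projection onto the normal plane of ``g_j``::

        g_i <- g_i - (g_i . g_j / ||g_j||^2) g_j

    The combined gradient is the sum of the projected vectors.  With no
    conflicting pair the output equals the plain sum exactly.  A
    zero-norm partner in a conflicting pair is skipped (the projection is
    undefined).
    """
    if len(grads) == 0:
        raise ValueError("need at least one gradient")
    length = grads[0].shape[0]
    if any(g.ndim != 1 or g.shape[0] != length for g in grads):
        raise ValueError("all gradients must be 1-D of equal length")
    if len(grads) == 1:
        return grads[0].copy()
    rng = np.random.default_rng(seed)
    combined = np.zeros(length)
    n = len(grads)
    for i in range(n):
        g_i = grads[i].copy()
        others = [j for j in range(n) if j != i]
        rng.shuffle(others)
        for j in others:
            g_j = grads[j]  # raw gradient of task j
            dot = float(g_i @ g_j)
            if dot < 0.0:
                denom = float(g_j @ g_j)
                if denom == 0.0:
                    continue
                g_i = g_i - (dot / denom) * g_j
        combined += g_i
    return combined


def _key_unit_hash(key: str, seed: int) -> float:
    digest = hashlib.sha256(f"val:{seed}:{key}".encode()).digest()
    return int.from_bytes(digest[:8], "big") / 2**64


def validation_split(
    keys: Sequence[str], seed: int, val_fraction: float = 0.1
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic hash-based (train_idx, val_idx) split of the keys."""
    is_val = np.array([_key_unit_hash(k, seed) < val_fraction for k in keys])
    if is_val.all():
        raise ValueError("validation split swallowed every molecule")
    return np.flatnonzero(~is_val), np.flatnonzero(is_val)


# ---------------------------------------------------------------------------
# training internals


def _group_plan(
    cfg: TrainConfig, endpoints: Sequence[EndpointSpec]
) -> list[tuple[str, list[EndpointSpec]]]:
    """Resolve the per-epoch visit plan: (group label, member endpoints)."""
    by_cat: dict[str, list[EndpointSpec]] = {}
    for s in endpoints:
        by_cat.setdefault(s.category, []).append(s)
    if cfg.mode == "sequential":
        plan = []
        for cat in cfg.order:
            if cat in by_cat:
                plan.append((cat, by_cat[cat]))
        if not plan:
            raise ValueError("no endpoint belongs to any category in the order")
        return plan
    cats = (
        sorted(cfg.subset_categories, key=CATEGORIES.index)
        if cfg.mode == "subset"
        else [c for c in CATEGORIES if c in by_cat]
    )
    members: list[EndpointSpec] = []
    for cat in cats:
        if cat not in by_cat:
            raise ValueError(f"subset category {cat!r} has no endpoints")
        members.extend(by_cat[cat])
    return [("".join(cats), members)]


def _epoch_group_seed(seed: int, epoch: int, group_pos: int) -> int:
    digest = hashlib.sha256(f"batch:{seed}:{epoch}:{group_pos}".encode()).digest()
    return int.from_bytes(digest[:4], "big")


def _batch_grads(
    model: EncoderModel,
    x: np.ndarray,
    y: dict[str, np.ndarray],
    mask: dict[str, np.ndarray],
    members: Sequence[EndpointSpec],
    use_pcgrad: bool,
    pcgrad_seed: int,
) -> tuple[dict[str, float], dict[str, int], list[np.ndarray] | None]:
    """One batch: per-endpoint losses and the combined parameter gradients.

    Returns (losses, observed counts, grads over model.all_params()) with
    grads None when no endpoint has an observed entry in the batch.
    """
    z, trunk_cache = model.trunk.forward(x)
    trunk_grads_flat: list[np.ndarray] = []
    head_grads: dict[str, list[np.ndarray]] = {}
    losses: dict[str, float] = {}
    counts: dict[str, int] = {}
    for spec in members:
        m = mask[spec.name]
        n_obs = int(m.sum())
        if n_obs == 0:
            continue
        head = model.heads[spec.name]
        raw, head_cache = head.forward(z)
        raw = raw[:, 0]
        yv = y[spec.name]
        if spec.task_type == "classification":
            p = sigmoid(raw)
            p_c = np.clip(p, _EPS_P, 1.0 - _EPS_P)
            losses[spec.name] = float(
                -np.mean(
                    yv[m] * np.log(p_c[m]) + (1.0 - yv[m]) * np.log(1.0 - p_c[m])
                )
            )
            d_raw = np.where(m, p - np.where(m, yv, 0.0), 0.0) / n_obs
        else:
            losses[spec.name] = float(np.mean((raw[m] - yv[m]) ** 2))
            d_raw = np.where(m, 2.0 * (raw - np.where(m, yv, 0.0)), 0.0) / n_obs
        counts[spec.name] = n_obs
        hg, dz = head.backward(d_raw[:, None], head_cache)
        head_grads[spec.name] = hg
        tg, _ = model.trunk.backward(dz, trunk_cache)
        trunk_grads_flat.append(flatten_arrays(tg))
    if not losses:
        return losses, counts, None
    if use_pcgrad and len(trunk_grads_flat) > 1:
        combined_flat = pcgrad_project(trunk_grads_flat, pcgrad_seed)
    else:
        combined_flat = np.sum(trunk_grads_flat, axis=0)
    trunk_grads = unflatten_like(combined_flat, model.trunk.params)
    grads = list(trunk_grads)
    for name in sorted(model.heads):
        if name in head_grads:
            grads.extend(head_grads[name])
        else:
            grads.extend(model.heads[name].zero_grads())
    return losses, counts, grads


def _train(
    model: EncoderModel, dataset: AggregatedDataset, cfg: TrainConfig
) -> tuple[EncoderModel, LossLedger]:
    plan = _group_plan(cfg, dataset.endpoints)
    scope_names = [s.name for _, members in plan for s in members]
    scope_specs = {n: dataset.spec(n) for n in scope_names}

    keys = dataset.keys
    x_all = model.featurize_keys(keys)
    values, mask = dataset.label_arrays(scope_names)
    col = {n: j for j, n in enumerate(scope_names)}
    train_idx, val_idx = validation_split(keys, cfg.seed, cfg.val_fraction)

    # refuse to start when a requested group has no observed training data
    for label, members in plan:
        cols = [col[s.name] for s in members]
        if not mask[np.ix_(train_idx, cols)].any():
            raise ValueError(f"group {label!r} has no observed training data")

    y_filled = np.where(mask, values, 0.0)  # masked cells are never read
    optimizer = Adam(model.all_params(), lr=cfg.learning_rate)
    ledger = LossLedger()

    group_train_idx = {}
    for pos, (label, members) in enumerate(plan):
        cols = [col[s.name] for s in members]
        has_any = mask[np.ix_(train_idx, cols)].any(axis=1)
        group_train_idx[pos] = train_idx[has_any]

    use_pcgrad = cfg.pcgrad if cfg.mode == "sequential" else cfg.pcgrad_in_naive
    best_total = np.inf
    stale = 0
    for epoch in range(cfg.epochs_max):
        for pos, (label, members) in enumerate(plan):
            rng = np.random.default_rng(_epoch_group_seed(cfg.seed, epoch, pos))
            order = rng.permutation(group_train_idx[pos])
            loss_sums: dict[str, float] = {s.name: 0.0 for s in members}
            obs_sums: dict[str, int] = {s.name: 0 for s in members}
            for start in range(0, len(order), cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                yb = {s.name: y_filled[idx, col[s.name]] for s in members}
                mb = {s.name: mask[idx, col[s.name]] for s in members}
                pc_seed = _epoch_group_seed(cfg.seed ^ 0x5EED, epoch, pos) + start
                losses, counts, grads = _batch_grads(
                    model, x_all[idx], yb, mb, members, use_pcgrad, pc_seed
                )
                if grads is None:
                    continue  # no observed label in the batch: flagged no-op
                optimizer.step(grads)
                for name, loss in losses.items():
                    loss_sums[name] += loss * counts[name]
                    obs_sums[name] += counts[name]
            for s in members:
                if obs_sums[s.name] > 0:
                    ledger.train[(epoch, label, s.name)] = (
                        loss_sums[s.name] / obs_sums[s.name]
                    )
        # held-out evaluation over every endpoint in scope
        preds = model.predict(x_all[val_idx], scope_names)
        val_losses, total = masked_losses(
            preds,
            {n: y_filled[val_idx, col[n]] for n in scope_names},
            {n: mask[val_idx, col[n]] for n in scope_names},
            scope_specs,
        )
        for name, loss in val_losses.items():
            ledger.val[(epoch, name)] = loss
        if total is None:
            raise ValueError("validation split has no observed labels in scope")
        ledger.total_val[epoch] = total
        # relative-improvement early stopping
        if total < best_total * (1.0 - cfg.convergence_tol):
            best_total = total
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                break
    return model, ledger


def train_sequential(
    model: EncoderModel, dataset: AggregatedDataset, cfg: TrainConfig
) -> tuple[EncoderModel, LossLedger]:
    """Train category groups in ``cfg.order`` once per epoch (Step 1).

    Within a category, per-endpoint gradients on the shared trunk are
    combined by gradient surgery when ``cfg.pcgrad`` is set, else summed;
    each head only ever receives its own endpoint's gradient.
    """
    if cfg.mode != "sequential":
        raise ValueError("train_sequential requires cfg.mode == 'sequential'")
    return _train(model, dataset, cfg)


def train_naive(
    model: EncoderModel, dataset: AggregatedDataset, cfg: TrainConfig
) -> tuple[EncoderModel, LossLedger]:
    """Train all endpoints in scope as one flat group with a summed loss.

    ``mode="naive"`` spans every category present; ``mode="subset"``
    restricts to ``cfg.subset_categories`` (single-task baselines and the
    task-dependency sweep).
    """
    if cfg.mode not in ("naive", "subset"):
        raise ValueError("train_naive requires cfg.mode in {'naive', 'subset'}")
    return _train(model, dataset, cfg)


def single_category_config(cfg: TrainConfig, category: str) -> TrainConfig:
    """The subset-mode config equivalent to sequential training of one category."""
    return replace(
        cfg, mode="subset", subset_categories=frozenset({category}), order=(category,)
    )
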