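"""Task-dependency analysis over the four pharmacokinetic categories.

A brute-force sweep trains one naïve multi-task model per category
subset and records each member category's held-out loss.  From that loss
table the task improvement rate

    TIR(A|B) = (L_STL(A) - L_MTL(A|B)) / L_STL(A)

quantifies how co-training a target category with a partner changes the
target's loss relative to its single-task baseline: positive means
improvement, negative means interference.  L_MTL(A|B) averages the
target's loss over *all* swept subsets containing both categories.  The
off-diagonal TIR cells form a directed, signed dependency graph.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from admeseq.chem_data import CATEGORIES, AggregatedDataset
from admeseq.encoders import EncoderConfig, EncoderModel
from admeseq.seq_mtl import TrainConfig, train_naive

__all__ = [
    "TaskLossTable",
    "TIRMatrix",
    "all_subsets",
    "run_combination_sweep",
    "compute_tir",
    "compute_tir_matrix",
    "build_dependency_graph",
    "graph_edge_list",
]


@dataclass
class TaskLossTable:
    """Held-out loss of each member category under each trained subset."""

    losses: dict[frozenset[str], dict[str, float]] = field(default_factory=dict)

    def add(self, subset: Iterable[str], category_losses: dict[str, float]) -> None:
        fs = frozenset(subset)
        extra = set(category_losses) - fs
        if extra:
            raise ValueError(f"losses recorded for non-member categories: {extra}")
        self.losses[fs] = dict(category_losses)

    def stl(self, category: str) -> float:
        singleton = frozenset({category})
        if singleton not in self.losses:
            raise KeyError(f"missing singleton subset for category {category!r}")
        return self.losses[singleton][category]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for subset in sorted(self.losses, key=lambda s: (len(s), sorted(s))):
            label = "".join(c for c in CATEGORIES if c in subset)
            for cat, loss in sorted(self.losses[subset].items()):
                rows.append({"subset": label, "category": cat, "loss": loss})
        return pd.DataFrame(rows, columns=["subset", "category", "loss"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TaskLossTable":
        table = cls()
        for label, group in df.groupby("subset"):
            table.add(
                frozenset(label), dict(zip(group["category"], group["loss"]))
            )
        return table


@dataclass
class TIRMatrix:
    """Directed (target, partner) -> improvement-rate map; diagonal undefined."""

    values: dict[tuple[str, str], float] = field(default_factory=dict)
    categories: tuple[str, ...] = CATEGORIES

    def __getitem__(self, pair: tuple[str, str]) -> float:
        return self.values[pair]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(index=list(self.categories), columns=list(self.categories),
                          dtype=float)
        for (target, partner), tir in self.values.items():
            df.loc[target, partner] = tir
        df.index.name = "target"
        df.columns.name = "partner"
        return df


def all_subsets(categories: Sequence[str] = CATEGORIES) -> list[frozenset[str]]:
    """All non-empty subsets, singletons first (2^k - 1 of them)."""
    subsets = []
    for r in range(1, len(categories) + 1):
        for combo in itertools.combinations(categories, r):
            subsets.append(frozenset(combo))
    return subsets


def run_combination_sweep(
    dataset: AggregatedDataset,
    base_cfg: TrainConfig,
    encoder_cfg: EncoderConfig,
    subsets: Sequence[Iterable[str]] | None = None,
    readout: str = "best",
) -> TaskLossTable:
    """Train one naïve multi-task model per category subset.

    Defaults to all 15 non-empty subsets of the categories present.
    Every subset starts from the same seed — hence the same trunk
    initialization and batch streams — so single-task and multi-task
    losses form a paired comparison, and two sweeps with the same base
    seed produce identical tables regardless of request order.  A member
    category's entry is the unweighted mean of its endpoints' held-out
    losses at the best epoch (``readout="best"``) or at the end of the
    epoch budget (``readout="final"``, the equal-budget protocol).
    """
    if readout not in ("best", "final"):
        raise ValueError(f"unknown readout {readout!r}")
    present = [c for c in CATEGORIES if any(s.category == c for s in dataset.endpoints)]
    if subsets is None:
        chosen = all_subsets(present)
    else:
        chosen = [frozenset(s) for s in subsets]
        if len(chosen) != len(set(chosen)):
            raise ValueError("duplicate subsets in the request")
        unknown = [s for s in chosen if not s <= set(present)]
        if unknown:
            raise ValueError(f"subsets over absent categories: {unknown}")
    table = TaskLossTable()
    for subset in chosen:
        cfg = replace(base_cfg, mode="subset", subset_categories=subset)
        member_specs = [s for s in dataset.endpoints if s.category in subset]
        model = EncoderModel(member_specs, encoder_cfg, seed=cfg.seed)
        _, ledger = train_naive(model, dataset, cfg)
        epoch = ledger.best_epoch() if readout == "best" else max(ledger.total_val)
        val = ledger.val_at(epoch)
        category_losses = {}
        for cat in subset:
            member_losses = [
                val[s.name] for s in member_specs if s.category == cat and s.name in val
            ]
            if not member_losses:
                raise RuntimeError(f"no held-out losses for category {cat!r}")
            category_losses[cat] = float(sum(member_losses) / len(member_losses))
        table.add(subset, category_losses)
    return table


def compute_tir(table: TaskLossTable, target: str, partner: str) -> float:
    """Task improvement rate of ``target`` when co-trained with ``partner``."""
    if target == partner:
        raise ValueError("TIR is undefined on the diagonal")
    l_stl = table.stl(target)
    if l_stl == 0.0:
        raise ValueError(f"single-task loss of {target!r} is zero; TIR undefined")
    co = [
        losses[target]
        for subset, losses in table.losses.items()
        if target in subset and partner in subset
    ]
    if not co:
        raise ValueError(
            f"no swept subset contains both {target!r} and {partner!r}"
        )
    l_mtl = sum(co) / len(co)
    return (l_stl - l_mtl) / l_stl


def compute_tir_matrix(
    table: TaskLossTable, categories: Sequence[str] = CATEGORIES
) -> TIRMatrix:
    matrix = TIRMatrix(categories=tuple(categories))
    for target in categories:
        for partner in categories:
            if target != partner:
                matrix.values[(target, partner)] = compute_tir(table, target, partner)
    return matrix


def build_dependency_graph(tir: TIRMatrix, threshold: float = 0.0) -> nx.DiGraph:
    """Directed signed graph: edge partner -> target for each |TIR| >= threshold."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    graph = nx.DiGraph()
    graph.add_nodes_from(tir.categories)
    for (target, partner), value in tir.values.items():
        if abs(value) >= threshold:
            graph.add_edge(
                partner,
                target,
                tir=value,
                sign=1 if value >= 0 else -1,
                weight=abs(value),
            )
    return graph


def graph_edge_list(graph: nx.DiGraph) -> pd.DataFrame:
    rows = [
        {"source": u, "target": v, "tir": d["tir"]}
        for u, v, d in sorted(graph.edges(data=True))
    ]
    return pd.DataFrame(rows, columns=["source", "target", "tir"])
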