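"""Endpoint-table ingestion, molecule canonicalization and dataset aggregation.

One ADME endpoint lives in one delimited table (``id, smiles, label``).
This module merges many such tables into a single masked multi-task
dataset keyed by canonical SMILES, z-scores regression targets on the
training distribution, and assigns cross-validation folds.
"""

from __future__ import annotations

import copy
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.model_selection import StratifiedKFold

CATEGORIES = ("A", "D", "M", "E")

__all__ = [
    "CATEGORIES",
    "EndpointSpec",
    "MoleculeRecord",
    "AggregatedDataset",
    "SmilesParseError",
    "canonicalize_key",
    "aggregate_endpoints",
    "fit_and_apply_normalization",
    "stratified_kfold",
    "hash_kfold",
    "read_endpoint_table",
    "read_manifest",
    "write_dataset",
    "read_dataset",
]


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed by the chemistry toolkit."""


@dataclass
class EndpointSpec:
    """One ADME endpoint: identity, pharmacokinetic category and task type.

    ``norm_mean``/``norm_sd`` are populated only for regression endpoints
    and only once normalization has been fitted on a training split.
    """

    name: str
    category: str
    task_type: str  # "classification" | "regression"
    norm_mean: float | None = None
    norm_sd: float | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(
                f"endpoint {self.name!r}: category must be one of {CATEGORIES}, "
                f"got {self.category!r}"
            )
        if self.task_type not in ("classification", "regression"):
            raise ValueError(
                f"endpoint {self.name!r}: unknown task_type {self.task_type!r}"
            )
        if self.task_type == "classification" and (
            self.norm_mean is not None or self.norm_sd is not None
        ):
            raise ValueError(
                f"endpoint {self.name!r}: classification endpoints carry no "
                "normalization stats"
            )
        if self.norm_sd is not None and self.norm_sd <= 0:
            raise ValueError(f"endpoint {self.name!r}: norm_sd must be > 0")


@dataclass
class MoleculeRecord:
    """A molecule keyed by canonical SMILES with per-endpoint labels and masks.

    ``labels`` holds values only for observed endpoints; ``mask[e]`` is
    True iff endpoint ``e`` was observed for this molecule.  Masked-out
    endpoints carry no value at all, so nothing downstream can read one.
    """

    key: str
    labels: dict[str, float] = field(default_factory=dict)
    mask: dict[str, bool] = field(default_factory=dict)

    def observed(self, endpoint: str) -> bool:
        return bool(self.mask.get(endpoint, False))


@dataclass
class AggregatedDataset:
    """Merged multi-endpoint dataset: records, endpoint specs and folds."""

    records: list[MoleculeRecord]
    endpoints: list[EndpointSpec]
    folds: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = [r.key for r in self.records]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate molecule keys in AggregatedDataset")
        known = {e.name for e in self.endpoints}
        for r in self.records:
            extra = set(r.labels) - known
            if extra:
                raise ValueError(
                    f"record {r.key!r} labels endpoints without a spec: {sorted(extra)}"
                )

    @property
    def keys(self) -> list[str]:
        return [r.key for r in self.records]

    def spec(self, name: str) -> EndpointSpec:
        for e in self.endpoints:
            if e.name == name:
                return e
        raise KeyError(name)

    def label_arrays(
        self, endpoints: Sequence[str] | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Return (values, mask) matrices of shape (n_records, n_endpoints).

        Unobserved cells hold NaN in the value matrix and False in the mask.
        """
        names = [e.name for e in self.endpoints] if endpoints is None else list(endpoints)
        n, m = len(self.records), len(names)
        values = np.full((n, m), np.nan)
        mask = np.zeros((n, m), dtype=bool)
        for i, rec in enumerate(self.records):
            for j, name in enumerate(names):
                if rec.observed(name):
                    values[i, j] = rec.labels[name]
                    mask[i, j] = True
        return values, mask


def canonicalize_key(smiles: str, *, opaque: bool = False) -> str:
    """Map a SMILES string to a canonical key.

    Two structurally identical inputs map to the same key, and the map is
    idempotent.  Salts and stereochemistry are preserved.  With
    ``opaque=True`` the raw string itself is the key (no chemistry toolkit
    involved; intended for toolkit-free fixtures only).
    """
    if not smiles:
        raise SmilesParseError("empty SMILES string")
    if opaque:
        return smiles
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparsable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


def _consolidate(
    values: list[float], task_type: str, strict: bool
) -> tuple[float | None, bool]:
    """Resolve duplicate (key, endpoint) entries.

    Classification: majority vote, ties drop the pair.  Regression:
    arithmetic mean.  Returns (value, observed); strict mode refuses any
    disagreement instead.
    """
    if len(values) == 1:
        return values[0], True
    if strict and len(set(values)) > 1:
        return None, False  # caller raises with context
    if task_type == "classification":
        pos = sum(1 for v in values if v == 1)
        neg = len(values) - pos
        if pos == neg:
            return None, False
        return (1.0 if pos > neg else 0.0), True
    return float(np.mean(values)), True


def aggregate_endpoints(
    tables: Mapping[str, Iterable[tuple[str, float]]],
    specs: Sequence[EndpointSpec],
    *,
    duplicate_policy: str = "consolidate",
    opaque_keys: bool = False,
) -> AggregatedDataset:
    """Merge per-endpoint tables into one masked multi-task dataset.

    Overlapping compounds (same canonical key) are merged into a single
    record whose mask marks which endpoints were observed.  Duplicate
    (key, endpoint) pairs are consolidated by majority vote
    (classification; ties drop the pair) or arithmetic mean (regression);
    ``duplicate_policy="strict"`` instead raises on any disagreeing
    duplicate, listing the offending keys.
    """
    if not tables:
        raise ValueError("tables map is empty")
    if duplicate_policy not in ("consolidate", "strict"):
        raise ValueError(f"unknown duplicate_policy {duplicate_policy!r}")
    spec_by_name = {s.name: s for s in specs}
    missing = set(tables) - set(spec_by_name)
    if missing:
        raise ValueError(f"endpoints without a spec: {sorted(missing)}")

    # key -> endpoint -> list of raw values, insertion-ordered for determinism
    pending: dict[str, dict[str, list[float]]] = {}
    for name, rows in tables.items():
        for row_idx, (smiles, value) in enumerate(rows):
            try:
                key = canonicalize_key(smiles, opaque=opaque_keys)
            except SmilesParseError as err:
                raise SmilesParseError(
                    f"endpoint {name!r}, row {row_idx}: {err}"
                ) from err
            if spec_by_name[name].task_type == "classification" and value not in (0, 1):
                raise ValueError(
                    f"endpoint {name!r}, key {key!r}: classification label "
                    f"must be 0 or 1, got {value!r}"
                )
            pending.setdefault(key, {}).setdefault(name, []).append(float(value))

    strict = duplicate_policy == "strict"
    records: list[MoleculeRecord] = []
    conflicts: list[tuple[str, str]] = []
    used_specs = [s for s in specs if s.name in tables]
    for key, per_endpoint in pending.items():
        rec = MoleculeRecord(key=key)
        for spec in used_specs:
            vals = per_endpoint.get(spec.name)
            if vals is None:
                rec.mask[spec.name] = False
                continue
            value, observed = _consolidate(vals, spec.task_type, strict)
            if strict and not observed and len(set(vals)) > 1:
                conflicts.append((key, spec.name))
                continue
            rec.mask[spec.name] = observed
            if observed:
                rec.labels[spec.name] = value
        records.append(rec)
    if conflicts:
        raise ValueError(
            "conflicting duplicate labels under strict mode for (key, endpoint): "
            f"{conflicts}"
        )
    return AggregatedDataset(records=records, endpoints=list(used_specs))


def fit_and_apply_normalization(
    dataset: AggregatedDataset, train_keys: set[str]
) -> AggregatedDataset:
    """Z-score regression targets on the training distribution.

    Mean and population standard deviation (divide by n) are fitted on
    observed *training* values only, then applied to every observed value,
    train and held-out alike.  Classification labels are untouched.
    Returns a new dataset; the input is not modified.
    """
    out = copy.deepcopy(dataset)
    for spec in out.endpoints:
        if spec.task_type != "regression":
            continue
        train_vals = np.array(
            [
                r.labels[spec.name]
                for r in out.records
                if r.key in train_keys and r.observed(spec.name)
            ]
        )
        if train_vals.size < 2:
            raise ValueError(
                f"endpoint {spec.name!r}: need >= 2 observed training values "
                f"to fit normalization, got {train_vals.size}"
            )
        mean = float(np.mean(train_vals))
        sd = float(np.std(train_vals))  # population convention
        if sd == 0.0:
            raise ValueError(
                f"endpoint {spec.name!r}: zero spread in training values, "
                "cannot normalize"
            )
        spec.norm_mean = mean
        spec.norm_sd = sd
        for rec in out.records:
            if rec.observed(spec.name):
                rec.labels[spec.name] = (rec.labels[spec.name] - mean) / sd
    return out


def stratified_kfold(
    dataset: AggregatedDataset,
    k: int,
    strat_labels: str | Mapping[str, int],
    seed: int,
) -> dict[str, int]:
    """Assign each record a fold in {0..k-1}, preserving label balance.

    ``strat_labels`` is either the name of a binary endpoint observed for
    every record, or an explicit key -> label mapping (e.g. the
    drug/non-drug label).  Per-fold positive counts differ from the
    proportional share by less than one.  Fold ``f`` is the test fold of
    cross-validation round ``f``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    keys = dataset.keys
    if isinstance(strat_labels, str):
        name = strat_labels
        missing = [r.key for r in dataset.records if not r.observed(name)]
        if missing:
            raise ValueError(
                f"stratification endpoint {name!r} unobserved for "
                f"{len(missing)} records (first: {missing[0]!r})"
            )
        y = np.array([r.labels[name] for r in dataset.records])
    else:
        y = np.array([strat_labels[key] for key in keys])
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k and len(counts) > 1:
        raise ValueError(
            f"k={k} exceeds the minority-class count ({int(counts.min())})"
        )
    folds: dict[str, int] = {}
    if len(counts) == 1:
        # single-class labels: stratification is vacuous, plain shuffled k-fold
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(keys))
        for fold, chunk in enumerate(np.array_split(order, k)):
            for i in chunk:
                folds[keys[i]] = fold
        return folds
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(keys)), y)):
        for i in test_idx:
            folds[keys[i]] = fold
    return folds


def _stable_hash(text: str, seed: int) -> int:
    digest = hashlib.sha256(f"{seed}:{text}".encode()).digest()
    return int.from_bytes(digest[:8], "big")


def hash_kfold(dataset: AggregatedDataset, k: int, seed: int) -> dict[str, int]:
    """Deterministic label-free fold assignment by seeded key hash.

    Used for the multi-endpoint ADME dataset, which has no single label
    to stratify on.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    return {key: _stable_hash(key, seed) % k for key in dataset.keys}


# ---------------------------------------------------------------------------
# on-disk layout


def read_endpoint_table(path: str | Path) -> list[tuple[str, float]]:
    """Read one endpoint table (columns ``id, smiles, label``)."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    for required in ("smiles", "label"):
        if required not in cols:
            raise ValueError(f"{path}: missing column {required!r}")
    return list(zip(df[cols["smiles"]].astype(str), df[cols["label"]].astype(float)))


def read_manifest(path: str | Path) -> tuple[list[EndpointSpec], dict[str, Path]]:
    """Read an endpoint manifest mapping files to (name, category, task_type).

    Layout::

        endpoints:
          - name: caco2
            category: A
            task_type: regression
            file: caco2.csv
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    specs, files = [], {}
    for entry in doc["endpoints"]:
        spec = EndpointSpec(
            name=entry["name"],
            category=entry["category"],
            task_type=entry["task_type"],
        )
        specs.append(spec)
        files[spec.name] = path.parent / entry["file"]
    return specs, files


def _fmt(value: float) -> str:
    return "%.17g" % value


def write_dataset(dataset: AggregatedDataset, table_path: str | Path,
                  manifest_path: str | Path) -> None:
    """Write the aggregated dataset as a wide table plus a sidecar manifest.

    The table has one value column and one mask column per endpoint; the
    manifest records endpoint specs (with any fitted normalization stats)
    and fold assignments.  Floats are written with round-trip precision so
    write -> read -> write is byte-stable.
    """
    names = [e.name for e in dataset.endpoints]
    lines = ["key," + ",".join(f"{n},{n}__mask" for n in names)]
    for rec in dataset.records:
        cells = [rec.key]
        for n in names:
            if rec.observed(n):
                cells.append(_fmt(rec.labels[n]))
                cells.append("1")
            else:
                cells.append("")
                cells.append("0")
        lines.append(",".join(cells))
    Path(table_path).write_text("\n".join(lines) + "\n")

    manifest = {
        "endpoints": [
            {
                "name": e.name,
                "category": e.category,
                "task_type": e.task_type,
                **(
                    {"norm_mean": _fmt(e.norm_mean), "norm_sd": _fmt(e.norm_sd)}
                    if e.norm_mean is not None
                    else {}
                ),
            }
            for e in dataset.endpoints
        ],
        "folds": {k: int(v) for k, v in sorted(dataset.folds.items())},
    }
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def read_dataset(table_path: str | Path, manifest_path: str | Path) -> AggregatedDataset:
    """Read a dataset written by :func:`write_dataset`."""
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    endpoints = [
        EndpointSpec(
            name=e["name"],
            category=e["category"],
            task_type=e["task_type"],
            norm_mean=float(e["norm_mean"]) if "norm_mean" in e else None,
            norm_sd=float(e["norm_sd"]) if "norm_sd" in e else None,
        )
        for e in manifest["endpoints"]
    ]
    names = [e.name for e in endpoints]
    records = []
    with open(table_path) as fh:
        header = fh.readline().rstrip("\n").split(",")
        expected = ["key"] + [c for n in names for c in (n, f"{n}__mask")]
        if header != expected:
            raise ValueError(
                f"{table_path}: header does not match manifest endpoints"
            )
        for line in fh:
            cells = line.rstrip("\n").split(",")
            rec = MoleculeRecord(key=cells[0])
            for j, n in enumerate(names):
                raw, mask = cells[1 + 2 * j], cells[2 + 2 * j]
                if mask == "1":
                    rec.mask[n] = True
                    rec.labels[n] = float(raw)
                else:
                    rec.mask[n] = False
            records.append(rec)
    folds = {str(k): int(v) for k, v in (manifest.get("folds") or {}).items()}
    return AggregatedDataset(records=records, endpoints=endpoints, folds=folds)
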