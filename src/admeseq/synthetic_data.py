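"""Desk-scale synthetic stand-in for the ADME and drug-likeness datasets.

Molecules are enumerated from a small fragment vocabulary (substituted
scaffolds decorated with R-groups).  Labels come from four latent
pharmacokinetic factors u_A, u_D, u_M, u_E forming a planted Markov
chain: each downstream factor inherits ``chain_strength`` of its
variance from its predecessor and the rest from an independent
fingerprint-derived signal, plus Gaussian noise.  Every endpoint is a
noisy affine readout of its category's factor (thresholded at the median
for classification endpoints), labels are masked independently at
``missing_rate``, and the drug-likeness label thresholds a logistic
score over all four factors at its median.  Everything is a pure
function of the config, so fixtures are byte-reproducible.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from admeseq.chem_data import CATEGORIES, EndpointSpec
from admeseq.encoders import FingerprintConfig, featurize_batch

__all__ = [
    "SyntheticConfig",
    "SyntheticLabels",
    "generate_molecules",
    "generate_labels",
    "write_synthetic",
    "enumeration_space_size",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    ``chain_strength`` is the fraction of a downstream factor's variance
    inherited from its upstream neighbour; ``noise_sd`` perturbs the
    latent factors themselves (small: the latent pharmacokinetics are
    mostly structure-determined) while ``readout_noise_sd`` perturbs each
    endpoint's assay readout (larger: individual assays are noisy, which
    is what makes cross-task transfer worthwhile).
    """

    n_molecules: int = 2000
    endpoints_per_category: int = 2
    chain_strength: float = 0.8
    noise_sd: float = 0.1
    readout_noise_sd: float = 0.5
    missing_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if self.endpoints_per_category < 2:
            raise ValueError("endpoints_per_category must be >= 2")
        if not 0.0 <= self.chain_strength <= 1.0:
            raise ValueError("chain_strength must be in [0, 1]")
        if self.noise_sd < 0 or self.readout_noise_sd < 0:
            raise ValueError("noise levels must be >= 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.noise_sd == 0.0 and self.chain_strength == 1.0:
            warnings.warn(
                "degenerate config: noise_sd=0 with chain_strength=1 makes all "
                "latent factors identical",
                stacklevel=2,
            )


# -- fragment vocabulary -----------------------------------------------------
# ~30 scaffolds, each with two substitution sites, decorated combinatorially.
_SCAFFOLDS = [
    "c1cc({r1})ccc1{r2}",            # para-benzene
    "c1cc({r1})cc({r2})c1",          # meta-benzene
    "c1c({r1})cccc1{r2}",            # ortho-benzene
    "c1cc({r1})nc({r2})c1",          # pyridine
    "c1cc({r1})oc1{r2}",             # furan
    "c1cc({r1})sc1{r2}",             # thiophene
    "c1cc({r1})[nH]c1{r2}",          # pyrrole
    "C1CC({r1})CCC1{r2}",            # cyclohexane
    "C1CC({r1})CC1{r2}",             # cyclopentane
    "C1CC({r1})NCC1{r2}",            # piperidine
    "C1CC({r1})OCC1{r2}",            # tetrahydropyran
    "O=C({r1})N{r2}",                # amide
    "O=C({r1})O{r2}",                # ester
    "O=S(=O)({r1}){r2}",             # sulfone
    "{r1}C(=O)C{r2}",                # ketone chain
    "{r1}CC(O)C{r2}",                # secondary alcohol chain
    "{r1}CNC{r2}",                   # secondary amine chain
    "{r1}COC{r2}",                   # ether chain
    "{r1}C=C{r2}",                   # alkene
    "{r1}C#C{r2}",                   # alkyne
    "c1ccc2cc({r1})cc({r2})c2c1",    # naphthalene
    "c1ccc(cc1)c1cc({r1})cc({r2})c1",  # biphenyl
    "c1cc({r1})c2ccccc2n1{r2}",      # quinoline-like
    "C({r1})(F)C{r2}",               # fluorinated chain
    "c1coc({r1})c1C{r2}",            # furan with methylene arm
    "c1csc({r1})c1C{r2}",            # thiophene with methylene arm
    "N({r1})C(=O)C{r2}",             # acetamide
    "O({r1})C(=O)C{r2}",             # acetate
    "c1cc({r1})cnc1{r2}",            # pyridine, alternate sites
    "C1=CC({r1})CC({r2})C1",         # cyclohexene
]

_RGROUPS = [
    "[H]", "C", "CC", "CCC", "C(C)C", "CCO", "CO", "CN", "CCN",
    "O", "OC", "N", "F", "Cl", "Br", "C#N", "C(F)(F)F", "CC(=O)O",
]

_SPACE_CACHE: list[str] | None = None


def _enumerate_space() -> list[str]:
    """Enumerate, validate and canonicalize the full decorated-scaffold space."""
    global _SPACE_CACHE
    if _SPACE_CACHE is not None:
        return _SPACE_CACHE
    from rdkit import Chem
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.*")
    seen: set[str] = set()
    space: list[str] = []
    for scaffold in _SCAFFOLDS:
        for r1 in _RGROUPS:
            for r2 in _RGROUPS:
                smiles = scaffold.format(r1=r1, r2=r2)
                mol = Chem.MolFromSmiles(smiles)
                if mol is None:
                    continue
                canonical = Chem.MolToSmiles(mol)
                if canonical not in seen:
                    seen.add(canonical)
                    space.append(canonical)
    RDLogger.EnableLog("rdApp.*")
    _SPACE_CACHE = space
    return space


def enumeration_space_size() -> int:
    return len(_enumerate_space())


def _substream(seed: int, name: str) -> np.random.Generator:
    digest = hashlib.sha256(f"{name}:{seed}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "big"))


def generate_molecules(cfg: SyntheticConfig) -> list[str]:
    """A deterministic seeded sample of unique, valid canonical SMILES."""
    space = _enumerate_space()
    if cfg.n_molecules > len(space):
        raise ValueError(
            f"requested {cfg.n_molecules} molecules but the fragment space "
            f"only enumerates {len(space)}"
        )
    rng = _substream(cfg.seed, "molecules")
    idx = rng.permutation(len(space))[: cfg.n_molecules]
    return [space[i] for i in idx]


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        return v - v.mean()
    return (v - v.mean()) / sd


@dataclass
class SyntheticLabels:
    """Generated tables plus the ground-truth latents for oracle tests."""

    endpoint_tables: dict[str, list[tuple[str, float]]]
    specs: list[EndpointSpec]
    drug_table: list[tuple[str, int]]
    latents: dict[str, np.ndarray]
    molecules: list[str] = field(default_factory=list)


def generate_labels(molecules: list[str], cfg: SyntheticConfig) -> SyntheticLabels:
    """Plant the A→D→M→E latent chain and read out endpoint and drug labels."""
    n = len(molecules)
    fp_cfg = FingerprintConfig(radius=2, n_bits=256)
    x = featurize_batch(molecules, fp_cfg)

    # per-category fingerprint signals, orthogonalized in-sample so that
    # chain_strength alone controls the cross-category dependence
    rng_w = _substream(cfg.seed, "weights")
    signals: list[np.ndarray] = []
    for _ in CATEGORIES:
        sig = x @ rng_w.normal(size=x.shape[1])
        for prev in signals:
            sig = sig - (sig @ prev) / (prev @ prev) * prev
        signals.append(_standardize(sig))

    rng_noise = _substream(cfg.seed, "latent_noise")
    latents: dict[str, np.ndarray] = {}
    prev_u: np.ndarray | None = None
    s = cfg.chain_strength
    for cat, sig in zip(CATEGORIES, signals):
        if prev_u is None:
            base = sig
        else:
            base = np.sqrt(s) * prev_u + np.sqrt(1.0 - s) * sig
        u = _standardize(base + cfg.noise_sd * rng_noise.normal(size=n))
        latents[cat] = u
        prev_u = u

    rng_read = _substream(cfg.seed, "readout")
    rng_mask = _substream(cfg.seed, "missing")
    endpoint_tables: dict[str, list[tuple[str, float]]] = {}
    specs: list[EndpointSpec] = []
    for cat in CATEGORIES:
        for j in range(cfg.endpoints_per_category):
            name = f"{cat}{j + 1}"
            task = "classification" if j % 2 == 0 else "regression"
            readout = latents[cat] + cfg.readout_noise_sd * rng_read.normal(size=n)
            if task == "classification":
                values = (readout > np.median(readout)).astype(float)
            else:
                scale = rng_read.uniform(0.5, 2.0)
                shift = rng_read.uniform(-1.0, 1.0)
                values = scale * readout + shift
            observed = rng_mask.random(n) >= cfg.missing_rate
            specs.append(EndpointSpec(name=name, category=cat, task_type=task))
            endpoint_tables[name] = [
                (molecules[i], float(values[i])) for i in np.flatnonzero(observed)
            ]

    rng_dl = _substream(cfg.seed, "druglikeness")
    weights = rng_dl.uniform(0.5, 1.0, size=len(CATEGORIES))
    score = 1.0 / (
        1.0 + np.exp(-sum(w * latents[c] for w, c in zip(weights, CATEGORIES)))
    )
    drug_label = (score > np.median(score)).astype(int)
    latents["dl_score"] = score
    drug_table = [(m, int(l)) for m, l in zip(molecules, drug_label)]
    return SyntheticLabels(
        endpoint_tables=endpoint_tables,
        specs=specs,
        drug_table=drug_table,
        latents=latents,
        molecules=list(molecules),
    )


def write_synthetic(outdir: str | Path, cfg: SyntheticConfig) -> Path:
    """Generate a dataset and write per-endpoint tables, the drug table,
    a manifest and the latents; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    molecules = generate_molecules(cfg)
    data = generate_labels(molecules, cfg)
    entries = []
    for spec in data.specs:
        fname = f"{spec.name}.csv"
        lines = ["id,smiles,label"]
        for i, (smiles, value) in enumerate(data.endpoint_tables[spec.name]):
            lines.append(f"{spec.name}_{i},{smiles},{'%.17g' % value}")
        (outdir / fname).write_text("\n".join(lines) + "\n")
        entries.append(
            {
                "name": spec.name,
                "category": spec.category,
                "task_type": spec.task_type,
                "file": fname,
            }
        )
    lines = ["id,smiles,label"]
    for i, (smiles, label) in enumerate(data.drug_table):
        lines.append(f"dl_{i},{smiles},{label}")
    (outdir / "druglikeness.csv").write_text("\n".join(lines) + "\n")

    header = ["smiles", *CATEGORIES, "dl_score"]
    lines = [",".join(header)]
    for i, m in enumerate(data.molecules):
        cells = [m] + [
            "%.17g" % data.latents[c][i] for c in (*CATEGORIES, "dl_score")
        ]
        lines.append(",".join(cells))
    (outdir / "latents.csv").write_text("\n".join(lines) + "\n")

    manifest_path = outdir / "manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(
            {"endpoints": entries, "druglikeness": "druglikeness.csv"},
            fh,
            sort_keys=False,
        )
    return manifest_path
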