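"""Generate a synthetic ADME dataset and aggregate it into one masked table.

The generator enumerates valid molecules from a fragment vocabulary and
plants four latent pharmacokinetic factors in an A->D->M->E chain; each
endpoint is a noisy readout of its category's factor, with labels masked
at the configured missing rate.  Aggregation merges the per-endpoint
tables into one record per canonical SMILES.
"""

from admeseq import aggregate_endpoints, fit_and_apply_normalization
from admeseq.synthetic_data import SyntheticConfig, generate_labels, generate_molecules

cfg = SyntheticConfig(n_molecules=500, seed=0)
molecules = generate_molecules(cfg)
data = generate_labels(molecules, cfg)

print(f"molecules: {len(molecules)} (first three: {molecules[:3]})")
print(f"endpoints: {[s.name for s in data.specs]}")

dataset = aggregate_endpoints(data.endpoint_tables, data.specs)
observed = sum(sum(r.mask.values()) for r in dataset.records)
total = len(dataset.records) * len(dataset.endpoints)
print(f"aggregated: {len(dataset.records)} records x {len(dataset.endpoints)} "
      f"endpoints, {observed}/{total} cells observed "
      f"(~{1 - cfg.missing_rate:.0%} by construction)")

dataset = fit_and_apply_normalization(dataset, set(dataset.keys))
a2 = dataset.spec("A2")
print(f"regression endpoint A2 z-scored on the training split: "
      f"mean={a2.norm_mean:.3f}, sd={a2.norm_sd:.3f}")
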