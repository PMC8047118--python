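#!/usr/bin/env python
"""Generate the synthetic TSC-derivation study and summarize what was planted.

Five stages (TE3.5 .. TSC_Pn) x three conditions (NF, NT, SNT) x 3
replicates of expression counts, plus per-CpG methylation calls with CC and
MII donor references. Writes the planted-structure summary and the resolved
configuration; downstream drivers regenerate the same data from the seed.
"""

import pandas as pd

from common import results_dir, study_config
from tscdyn.simulate import simulate_expression, simulate_methylome

cfg = study_config()
out = results_dir()

expr, truth = simulate_expression(cfg)
meth = simulate_methylome(cfg)

expr_counts = truth.expression["cluster"].value_counts().sort_index()
meth_counts = meth.truth["category"].value_counts()

summary = pd.DataFrame(
    [
        ("genes", cfg.n_genes),
        ("TF universe", cfg.n_tf),
        ("driver TFs (clusters 1-3)", cfg.n_driver_tf),
        ("samples (expression)", expr.counts.shape[1]),
        *[(f"genes in cluster {c}", n) for c, n in expr_counts.items() if c > 0],
        ("NT-downregulated driver TFs", int(truth.expression["nt_down"].sum())),
        ("SNT-rescued driver TFs", int(truth.expression["snt_rescued"].sum())),
        ("CGIs", cfg.n_cgis),
        *[(f"CGIs: {k}", n) for k, n in meth_counts.items()],
    ],
    columns=["quantity", "count"],
)
summary.to_csv(out / "dataset_summary.tsv", sep="\t", index=False)
cfg.to_yaml(out / "study_config.yaml")

print(summary.to_string(index=False))
print(f"\nwrote {out / 'dataset_summary.tsv'} and {out / 'study_config.yaml'}")
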