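"""Simulate a small MeRIP-Seq experiment and detect DMRs with FHC.

Generates four-sample Poisson counts for 5 methylation sites of 80 bins,
runs the per-bin rescaled Fisher exact test, smooths the significance
track with the p-value-emission HMM (FHC), and merges confident bins into
differentially methylated regions.
"""

import numpy as np

from fethmm import SimConfig, StrategyConfig, call_dmrs, detect, simulate_dataset

cfg = SimConfig(n_sites=5, bins_per_site=80)
ds = simulate_dataset(cfg, seed=1)

result = detect(ds.table, cfg.sizes, StrategyConfig(strategy="fhc", seed=1))
dmrs = call_dmrs(result, cutoff=0.9)

truth = ds.labels
called = result.bins["posterior"].to_numpy() >= 0.9
agree = float(np.mean(called == truth))

print(result.bins[["site_id", "bin_index", "p_value", "fdr", "posterior"]].head(8))
print(f"\n{len(dmrs)} DMRs at posterior >= 0.9 across {cfg.n_sites} sites:")
print(dmrs[["dmr_id", "bin_first", "bin_last", "n_bins", "mean_posterior", "direction"]])
print(
    f"\nbin-level agreement with the simulated ground truth: {agree:.3f}\n"
    "posterior is P(bin is differentially methylated | all bins of its site);\n"
    "direction +1 means hypermethylated in the treated condition."
)
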