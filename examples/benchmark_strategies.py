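"""Compare the three smoothing strategies against the unsmoothed test.

Runs the increasing-site-length benchmark (7 sites of 50..350 bins,
self-transition probability 0.95) on a few simulated datasets and prints
the mean bin-level AUC of each method against the hidden ground truth.
"""

from fethmm import table1_benchmark

df = table1_benchmark(seed=1, n_datasets=3)
means = df.groupby("method", sort=False)["auc"].agg(["mean", "std"])
print(means.round(4))
print(
    "\nAUC = probability a random differentially methylated bin outranks a\n"
    "random unchanged one; 0.5 is chance. All three HMM strategies beat the\n"
    "raw per-bin exact test by exploiting the spatial coherence of DMRs."
)
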