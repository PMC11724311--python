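"""Apply the benchmark failure rules to a method x sample summary table.

Builds summaries for three hypothetical filtering methods on one sample,
standardizes the quality metrics across methods and evaluates the three
failure rules: retaining too few nuclei relative to a similar-quality
comparator, retaining implausibly many, and retaining a low-quality
population when a comparator did substantially better.
"""

import numpy as np
import pandas as pd

import qclus

matrix, truth, registry = qclus.generate_population(
    qclus.SyntheticParams(n_droplets=2000), seed=3
)
table = qclus.build_feature_table(matrix, registry)

# Three "methods": keep everything, keep true nuclei, keep a tiny subset.
rng = np.random.default_rng(0)
masks = {
    "keep_all": np.ones(len(table), dtype=bool),
    "oracle": ~truth.mask("empty"),
    "tiny": rng.uniform(size=len(table)) < 0.05,
}
summaries = pd.DataFrame(
    [qclus.summarize(mask, table, method, "sample1") for method, mask in masks.items()]
)
print(summaries[["method", "n_retained", "mean_fraction_unspliced", "median_fraction_unspliced"]]
      .round(3).to_string(index=False))

z = qclus.standardize_across_methods(summaries)
print("\nz-scored across methods (per sample):")
print(z[["method", "n_retained", "median_fraction_unspliced"]].round(2).to_string(index=False))

# Thresholds scaled to this 2000-droplet toy sample; real-data defaults are
# 3000 / 30000 nuclei.
flags = qclus.flag_failures(summaries, qclus.FailureThresholds(low_count=300, high_count=1900))
print("\nfailure flags (method, rule, witnessing comparator):")
print(flags.to_string(index=False) if len(flags) else "none")
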