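"""Preprocessing: probe-to-gene collapsing and quantile normalization.

Probe-level arrays report several probes per gene; probes annotated with
zero or multiple genes are discarded and the rest are averaged per gene.
Quantile normalization then forces every sample onto the same intensity
distribution, removing platform/batch location-scale artifacts.
"""

import numpy as np
import pandas as pd

from pathsurv import collapse_probes, quantile_normalize

probe_matrix = pd.DataFrame(
    {
        "sample_1": [1.0, 3.0, 10.0, 4.0, 2.0],
        "sample_2": [2.0, 4.0, 20.0, 8.0, 3.0],
    },
    index=["probe_a", "probe_b", "probe_c", "probe_d", "probe_e"],
)
probe_map = {
    "probe_a": ["TP53"],
    "probe_b": ["TP53"],            # second probe for the same gene -> averaged
    "probe_c": ["EGFR"],
    "probe_d": ["EGFR", "KRAS"],    # ambiguous annotation -> dropped
    "probe_e": ["MYC"],
}
genes = collapse_probes(probe_matrix, probe_map)
print("collapsed gene-level matrix (probe_d dropped, TP53 = mean of 2 probes):")
print(genes.to_string())

rng = np.random.default_rng(0)
shifted = pd.DataFrame(
    {"s1": rng.normal(0, 1, 6), "s2": rng.normal(3, 2, 6)},  # s2 on another scale
    index=[f"g{i}" for i in range(6)],
)
normed = quantile_normalize(shifted)
print("\nafter quantile normalization each sample has the same value multiset:")
print(normed.round(3).to_string())
print(f"\ncolumn means before: {shifted.mean().round(2).tolist()}, "
      f"after: {normed.mean().round(2).tolist()}")
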