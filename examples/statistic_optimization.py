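"""Optimize the reproducibility statistic on a small spike-in matrix.

Builds a 400-feature, 4-vs-4 count matrix in which the first 40 features
carry a strong group difference, runs the (alpha, k) grid optimization
and prints the selected statistic parameters and how many spiked
features land in the top 40. Four replicates per group keep the
permutation-FDR floor low (few replicates mean few distinct label
permutations, which bounds the smallest achievable FDR).
"""

import numpy as np

from rotspeaks import AlphaParams, DataMatrix, GroupDesign, RotsConfig, optimize

rng = np.random.default_rng(0)
values = np.abs(rng.normal(100, 10, (400, 8)))
values[:40, 4:] += 60  # spiked features: 6 noise-SDs of group difference

sample_ids = [f"ctrl_{i}" for i in range(1, 5)] + [
    f"treat_{i}" for i in range(1, 5)
]
data = DataMatrix(
    values=values,
    feature_ids=np.array([f"peak_{i:03d}" for i in range(400)], dtype=object),
    sample_ids=np.array(sample_ids, dtype=object),
)
design = GroupDesign(
    {s: ("ctrl" if s.startswith("ctrl") else "treat") for s in sample_ids}
)

cfg = RotsConfig(b=200, k_grid=[25, 50, 100, 200], n_perm=200, seed=1)
result = optimize(data, design, cfg)

spiked = {f"peak_{i:03d}" for i in range(40)}
recovered = len(set(result.stat.top(40)) & spiked)

print(f"optimal alpha  : ({result.alpha.alpha1}, {result.alpha.alpha2})")
print(f"optimal k      : {result.k}")
print(f"Z at optimum   : {result.z:.2f}")
print(f"R at optimum   : {result.reproducibility:.3f}")
print(f"spiked in top40: {recovered}/40")
print(f"FDR < 0.05     : {(result.fdr < 0.05).sum()} features")
# The z-score measures how much more reproducible the top list is on
# bootstrap pairs than on label-permuted pairs: large Z means the ranking
# reflects a real group difference. With a strong spike the top of the
# list should be almost exactly the spiked features.
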