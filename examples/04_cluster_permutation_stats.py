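"""Weighted-cluster-mass permutation test on synthetic panels.

Builds two paired conditions for 8 subjects: identical noise except for a
localized time-frequency effect, runs the sign-flip permutation test with
weighted cluster mass correction (1000 permutations, alpha 0.05), and
reports the detected cluster.
"""

import numpy as np

from steercouple.stats import perm_cluster_test, z_against_null

rng = np.random.default_rng(7)
n_sub, F, T = 8, 20, 40
a = rng.standard_normal((n_sub, F, T))
b = rng.standard_normal((n_sub, F, T))
a[:, 6:11, 15:25] += 1.8  # the planted effect

res = perm_cluster_test(a, b, n_perm=1000, alpha=0.05, seed=0)
print(f"cluster-forming |t| threshold: {res.threshold:.2f} (two-sided, df={n_sub - 1})")
print(f"{res.n_clusters} suprathreshold cluster(s); smallest p = {res.min_p:.4f}")
rows, cols = np.where(res.sig_mask)
print(
    f"significant region rows {rows.min()}-{rows.max()}, "
    f"columns {cols.min()}-{cols.max()} (planted: rows 6-10, columns 15-24)"
)

# a scalar statistic against an explicit null ensemble
null = rng.standard_normal(300) * 0.3
z, p = z_against_null(1.5, null)
print(f"z_against_null example: Z = {z:.2f}, two-sided p = {p:.2g}")
print("the permutation machinery recovers the planted cluster and nothing else")
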