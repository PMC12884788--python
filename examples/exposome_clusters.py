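"""Cluster exposures and pick the number of categories by the CH index.

Simulates 20 exposures in four correlated blocks (air-pollution-like,
climate-like, urbanicity-like, family-like), clusters the Spearman
correlation structure, and shows the Calinski-Harabasz profile that
selects k.
"""

import gweistools as gt

cfg = gt.SimConfig(
    n_participants=1500, n_exposures=20, n_clusters=4,
    within_cluster_rho=0.6, seed=13,
)
exposures = gt.simulate_exposome(cfg)
corr = gt.spearman_matrix(exposures)
res = gt.cluster_exposures(corr)

print("CH by candidate k:")
for k, ch in res.ch_by_k.items():
    marker = " <- chosen" if k == res.k else ""
    print(f"  k={k}: {ch:8.1f}{marker}")
print(f"chosen k = {res.k} (reliable optimum: {res.reliable})")
print("cluster sizes:", dict(zip(*__import__('numpy').unique(res.labels,
                                                             return_counts=True))))
# With four planted blocks the CH profile peaks sharply at k = 4 and the
# labels recover the generating block structure.
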