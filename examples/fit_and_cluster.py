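"""Fit the alternating solver on simulated data and inspect label recovery.

Simulates a 3-category design with 10 planted marker genes per category,
runs one alternating fit (label propagation + sparse feature selection),
and prints the adjusted Rand index between predicted and true sample
labels plus the outer objective trace.
"""

import numpy as np
from sklearn.metrics import adjusted_rand_score

import lpfs

xm, truth = lpfs.simulate_dataset(
    n_per_category=8, c=3, m=300, markers_per_category=10, effect=2.0, seed=1
)
spec = lpfs.full_labels(truth)
cfg = lpfs.LPFSConfig(delta="auto", seed=1)

fit = lpfs.lpfs_fit(xm, spec, cfg)

ari = adjusted_rand_score(truth.labels, fit.propagation.labels)
print(f"samples: {xm.n_samples}, genes: {xm.n_genes}, categories: {spec.c}")
print(f"outer rounds: {fit.trace.rounds_used} (converged={fit.trace.converged})")
print("objective trace:", np.round(fit.trace.outer_objective, 3).tolist())
print(f"adjusted Rand index vs truth: {ari:.3f}")
# ARI 1.0 means the propagated cluster labels reproduce the planted
# categories exactly; the objective trace should be non-increasing.
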