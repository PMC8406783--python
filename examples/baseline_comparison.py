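"""Compare LPFS marker recovery with fold-change and Welch t-test baselines.

All three methods score genes for 'category 1 vs the rest' on the same
simulated two-group contrast; ROC AUC against the planted markers of
category 1 measures prioritization quality.
"""

import numpy as np

import lpfs

xm, truth = lpfs.simulate_dataset(
    n_per_category=8, c=2, m=300, markers_per_category=10, effect=1.0, seed=2
)
spec = lpfs.full_labels(truth)
group_a = [s for s, l in zip(xm.sample_ids, truth.labels) if l == 1]
group_b = [s for s, l in zip(xm.sample_ids, truth.labels) if l == 2]
cat1_truth = np.array([1 if g in set(truth.markers[0]) else 0 for g in xm.gene_ids])

cfg = lpfs.LPFSConfig(
    delta="auto", removal_size=50, inner_rounds=3,
    repetitions=10, consensus_min_count=6, seed=2,
)
result = lpfs.run_protocol(xm, spec, cfg)
lpfs_scores = lpfs.gene_scores_from_consensus(result.consensus, xm.gene_ids)

fc = lpfs.fold_change_scores(xm, group_a, group_b, pseudocount=1.0)
tt = lpfs.t_test_scores(xm, group_a, group_b)

print(f"{'method':<14} AUC     AUPR")
for name, scores in [("LPFS", lpfs_scores), ("fold change", fc), ("t-test", tt)]:
    print(f"{name:<14} {lpfs.roc_auc(scores, cat1_truth):.3f}   "
          f"{lpfs.aupr(scores, cat1_truth):.3f}")
# Higher is better; at this modest effect size (1 SD) all methods rank
# most of category 1's 10 planted markers above the 280 noise genes.
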