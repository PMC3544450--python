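"""Hierarchical clustering of pre/post-surgery serum profiles.

Clusters the matched samples on the 50 most variable miRNAs with
average linkage on Pearson correlation distance, and checks whether the
two-cluster cut separates pre-surgery (disease) from post-surgery serum.
"""

from sklearn.metrics import adjusted_rand_score

from mirserum import (
    cluster_samples,
    global_mean_normalize,
    interplate_calibrate,
    simulate_paired_cohort,
    spiked_config,
    top_variable_mirnas,
)

cfg = spiked_config(n_up=10, n_down=10, shift=2.0, seed=6)
pmatrix, pmeta, _ = simulate_paired_cohort(cfg)
pnorm = global_mean_normalize(interplate_calibrate(pmatrix)[0])

reduced = top_variable_mirnas(pnorm, k=50)
tree = cluster_samples(reduced, distance="pearson")
print(f"clustered {len(tree.labels)} samples on {tree.k_mirnas} most-variable miRNAs")
print("leaf order:", " ".join(tree.leaf_order))

cut = tree.cut(2)
truth = (pmeta.loc[cut.index, "timepoint"] == "PRE").astype(int)
print(f"adjusted Rand index vs pre/post truth: {adjusted_rand_score(truth, cut):.2f}")
print("newick:", tree.to_newick()[:120], "...")
# ARI 1.0 means the tree splits cleanly by presence/absence of disease,
# not by source patient — the disease signal dominates patient identity.
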