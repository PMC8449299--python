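"""Cluster concurrent intervals by action profile; session complexity.

Raw action counts per concurrent interval are reduced with PCA, embedded in
2-D with t-SNE, and K-means clustered with the cluster count picked at the
elbow of the WSS curve. A session whose member intervals share one cluster
is a single-task collaboration; the generator builds sessions from shared
action templates, so most sessions should be single-cluster.
"""

from ehrcollab import clustering, pipeline, simulate

sim = simulate.generate(
    simulate.SimConfig(seed=0, solo_bursts_per_hcw_patient_day=0.01)
)
result = pipeline.run(sim.events, compute_intensity=False)
mats = result.matrices

emb = clustering.reduce_and_embed(mats.interval_action, variance_target=0.97, seed=0)
print(f"{mats.interval_action.shape[0]} concurrent intervals x "
      f"{mats.interval_action.shape[1]} actions")
print(f"PCA keeps {emb.n_components} components "
      f"({emb.explained_variance:.1%} of variance), then t-SNE embeds in 2-D")

grid = tuple(range(2, max(12, min(31, emb.coords.shape[0] // 2)), 2))
k, curve = clustering.choose_k(emb.coords, grid, seed=0)
print(f"Elbow-selected k = {k} (generator uses 8 action templates)")

assignments = clustering.cluster_intervals(emb.coords, k, seed=0)
cx = clustering.session_complexity(assignments, mats)
print(f"Session complexity distribution: {cx.distribution}")
print(f"Single-cluster fraction: {cx.single_cluster_fraction:.2f} — most "
      f"concurrent sessions involve HCWs doing the same kind of work.")
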