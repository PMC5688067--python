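"""Integrative clustering by collective matrix tri-factorization.

Two planted-block relation matrices (gene x substrate, gene x gene) are
jointly co-factorized with a shared gene factor; cosine distances between
reconstructed gene profiles are averaged across relations and clustered.
The planted two-block structure should be recovered exactly (ARI = 1).
"""

from sklearn.metrics import adjusted_rand_score

from nudixmap.fusion import FusionGraph, Relation, cluster_profiles, fit_fusion, normalize_relation, profile_distances
from nudixmap.simulate import GeneratorConfig, gen_fusion_collection

cfg = GeneratorConfig(seed=30, block_margin=0.6, block_noise_sd=0.05)
graph, truth = gen_fusion_collection(cfg)
graph = FusionGraph(
    graph.object_types,
    [Relation(r.name, r.type_i, r.type_j, normalize_relation(r.matrix)) for r in graph.relations],
)
print("fusion graph:", {t: len(o) for t, o in graph.object_types.items()},
      "relations:", [r.name for r in graph.relations])

system = fit_fusion(graph, ranks={"gene": 2, "substrate": 2}, seed=0, max_iter=800)
print(f"objective: {system.objective_trace[0]:.4f} -> {system.objective_trace[-1]:.4f} "
      f"over {len(system.objective_trace) - 1} sweeps (nonincreasing)")

distances = profile_distances(system, "gene")
clusters = cluster_profiles(distances, linkage="average", k=2)
labels_true = [truth.planted_blocks["gene"][g] for g in distances.labels]
labels_pred = [clusters.labels[g] for g in distances.labels]
ari = adjusted_rand_score(labels_true, labels_pred)
print(f"flat clusters at k=2 vs planted blocks: ARI = {ari:.2f} (1.0 = exact recovery)")
print("heat-map leaf order:", clusters.order)
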