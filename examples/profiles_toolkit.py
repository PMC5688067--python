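"""Activity, expression and tree-distance computations around the pipeline.

Normalizes a raw absorbance plate to its no-coupling-enzyme controls,
clusters the active enzymes, runs Welch + Benjamini-Hochberg differential
expression on a matched normal/tumor pair, and computes patristic distances
from a phylogeny over the same gene names.
"""

from nudixmap.profiles import (
    activity_similarity,
    cluster_activity,
    diff_expression,
    normalize_activity,
    patristic_distances,
)
from nudixmap.simulate import GeneratorConfig, gen_activity_and_expression, gen_tree

cfg = GeneratorConfig(seed=12, n_activity_groups=3)
raw, control_map, expression, truth = gen_activity_and_expression(cfg)

activity = normalize_activity(raw, control_map, threshold=1.5)
print(f"activity: {activity.ratios.shape[0]} enzymes x {activity.ratios.shape[1]} substrates, "
      f"{int(activity.active.to_numpy().sum())} active cells (ratio > 1.5)")

clustering = cluster_activity(activity, k=3)
print("activity clusters:", clustering.labels)

stats = diff_expression(expression, fdr_level=0.05)
hits = stats[stats.significant]
print(f"differential expression: {len(hits)} significant genes "
      f"(planted: {len(truth.planted_de_genes)}); top hit:")
print(hits.sort_values("p_adj").head(1)[["log2fc", "t", "p_adj", "direction"]])

tree = gen_tree(cfg)
distances = patristic_distances(tree)
a, b = distances.labels[0], distances.labels[1]
print(f"patristic distance {a}-{b}: {distances.distance(a, b):.3f} "
      "(sum of branch lengths on the connecting path)")

similarity = activity_similarity(activity)
print(f"activity Spearman matrix: {similarity.shape[0]}x{similarity.shape[1]}, "
      f"mean off-diagonal rho {similarity.where(~(similarity == 1)).stack().mean():.2f}")
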