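"""Profile computations around the screen pipeline.

Substrate-activity normalization to no-coupling-enzyme controls and
hierarchical clustering of active enzymes, cluster co-assignment comparison,
two-sample differential expression with Benjamini-Hochberg FDR, patristic
distances from phylogenetic trees, and activity-similarity matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ActivityMatrix",
    "ExpressionPair",
    "TreeDistances",
    "normalize_activity",
    "cluster_activity",
    "co_assignment",
    "diff_expression",
    "patristic_distances",
    "activity_similarity",
    "bubble_size",
]


@dataclass
class ActivityMatrix:
    """Enzyme-by-condition absorbance ratios relative to no-coupling controls."""

    ratios: pd.DataFrame  # enzymes x conditions
    active: pd.DataFrame  # same shape, boolean
    threshold: float

    @property
    def enzymes(self) -> list[str]:
        return list(self.ratios.index)


@dataclass
class ExpressionPair:
    """Matched log2 expression matrices (genes x samples) for two conditions."""

    normal: pd.DataFrame
    tumor: pd.DataFrame
    stats: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.normal.index.equals(self.tumor.index):
            raise ValueError("normal and tumor matrices must share the gene index")


@dataclass
class TreeDistances:
    """Patristic (branch-length path) distances between all leaf pairs."""

    labels: list[str]
    matrix: np.ndarray
    newick: str = ""

    def distance(self, a: str, b: str) -> float:
        return float(self.matrix[self.labels.index(a), self.labels.index(b)])

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)


def normalize_activity(
    raw: pd.DataFrame,
    control_map: dict[str, str],
    threshold: float = 1.5,
) -> ActivityMatrix:
    """Divide each condition column by its matched no-coupling-enzyme control.

    Cells whose control is not positive become NaN with a warning.  A cell is
    flagged active when its ratio exceeds ``threshold``.
    """
    ratios = {}
    for cond, ctrl in control_map.items():
        if ctrl not in raw.columns:
            raise ValueError(f"control column {ctrl!r} missing for condition {cond!r}")
        control = raw[ctrl].astype(float)
        bad = control <= 0
        if bad.any():
            warnings.warn(f"nonpositive control for {cond!r} in {list(raw.index[bad])}; cells set missing")
        ratios[cond] = raw[cond].astype(float) / control.where(~bad)
    ratio_df = pd.DataFrame(ratios, index=raw.index)
    return ActivityMatrix(ratios=ratio_df, active=ratio_df > threshold, threshold=threshold)


@dataclass
class ActivityClustering:
    labels: dict[str, int]
    linkage_matrix: np.ndarray
    order: list[str]
    kept_enzymes: list[str]
    kept_conditions: list[str]


def cluster_activity(
    matrix: ActivityMatrix,
    drop_inactive: bool = True,
    k: int | None = None,
    linkage: str = "average",
) -> ActivityClustering:
    """Cluster enzymes on correlation distance, excluding inactive rows/columns.

    Enzymes with no active condition and conditions with no active enzyme are
    removed first (mirroring heat maps that exclude no-activity conditions).
    """
    ratios, active = matrix.ratios, matrix.active
    if drop_inactive:
        keep_rows = active.any(axis=1)
        keep_cols = active.any(axis=0)
        ratios = ratios.loc[keep_rows, keep_cols]
    if ratios.shape[0] < 2:
        raise ValueError("nothing to cluster: fewer than 2 enzymes with activity")
    values = ratios.fillna(0.0).to_numpy()
    corr = np.corrcoef(values)
    dist = 1.0 - np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(0.5 * (dist + dist.T), 0.0, None)
    Z = hierarchy.linkage(squareform(dist, checks=False), method=linkage)
    flat = hierarchy.fcluster(Z, t=k, criterion="maxclust") if k else np.ones(len(ratios), dtype=int)
    order = [ratios.index[i] for i in hierarchy.leaves_list(Z)]
    return ActivityClustering(
        labels=dict(zip(ratios.index, map(int, flat))),
        linkage_matrix=Z,
        order=order,
        kept_enzymes=list(ratios.index),
        kept_conditions=list(ratios.columns),
    )


def co_assignment(labels_a: dict[str, int], labels_b: dict[str, int]) -> tuple[pd.DataFrame, float]:
    """Compare two clusterings pair by pair.

    Returns a matrix coding each object pair as ``both`` / ``only_a`` /
    ``only_b`` / ``neither`` co-membership, and the agreement score: the
    fraction of pairs with concordant co-membership (1 iff the labelings
    induce identical pair partitions).
    """
    objects = sorted(set(labels_a) & set(labels_b))
    if not objects:
        raise ValueError("labelings share no objects")
    n = len(objects)
    codes = pd.DataFrame("", index=objects, columns=objects)
    concordant = 0
    total = 0
    for i in range(n):
        for j in range(n):
            if i == j:
                codes.iloc[i, j] = "self"
                continue
            a = labels_a[objects[i]] == labels_a[objects[j]]
            b = labels_b[objects[i]] == labels_b[objects[j]]
            codes.iloc[i, j] = {(True, True): "both", (True, False): "only_a", (False, True): "only_b", (False, False): "neither"}[(a, b)]
            if i < j:
                total += 1
                concordant += a == b
    return codes, concordant / total


def diff_expression(pair: ExpressionPair, fdr_level: float = 0.05) -> pd.DataFrame:
    """Per-gene Welch two-sample t-tests with Benjamini-Hochberg adjustment.

    Fold change is tumor mean minus normal mean on the log2 scale; genes with
    zero variance in both groups and equal means get p = 1.  The returned
    frame also carries the result in ``pair.stats``.
    """
    if pair.normal.shape[1] < 2 or pair.tumor.shape[1] < 2:
        raise ValueError("need >= 2 samples per condition")
    normal = pair.normal.to_numpy(dtype=float)
    tumor = pair.tumor.to_numpy(dtype=float)
    log2fc = tumor.mean(axis=1) - normal.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat, p_raw = stats.ttest_ind(tumor, normal, axis=1, equal_var=False)
    degenerate = np.isnan(p_raw)
    t_stat = np.where(degenerate, 0.0, t_stat)
    p_raw = np.where(degenerate, 1.0, p_raw)
    _, p_adj, _, _ = multipletests(p_raw, method="fdr_bh")
    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "t": t_stat,
            "p": p_raw,
            "p_adj": p_adj,
            "significant": p_adj < fdr_level,
            "direction": np.where(log2fc > 0, "up", np.where(log2fc < 0, "down", "none")),
        },
        index=pair.normal.index,
    )
    pair.stats = out
    return out


def bubble_size(expression_level: np.ndarray | float) -> np.ndarray | float:
    """Bubble radius helper: proportional to the square root of expression."""
    return np.sqrt(expression_level)


def patristic_distances(newick: str) -> TreeDistances:
    """Sum of branch lengths along the unique path between every pair of leaves."""
    try:
        tree = dendropy.Tree.get(data=newick, schema="newick")
    except dendropy.utility.error.DataParseError as exc:
        if "Duplicate taxon" in str(exc) or "Multiple occurrences" in str(exc):
            raise ValueError("duplicate leaf labels in tree") from exc
        raise
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate leaf labels in tree")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node and edge.length is None:
            child = edge.head_node.taxon.label if edge.head_node.taxon else "<internal>"
            raise ValueError(f"edge above {child} has no branch length")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    labels = sorted(labels)
    n = len(labels)
    matrix = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
            matrix[i, j] = matrix[j, i] = d
    return TreeDistances(labels=labels, matrix=matrix, newick=newick)


def activity_similarity(matrix: ActivityMatrix) -> pd.DataFrame:
    """Pairwise Spearman correlation of enzyme activity profiles.

    Constant activity vectors have undefined rank correlation and are reported
    as NaN.  Needs >= 3 shared conditions.
    """
    ratios = matrix.ratios
    if ratios.shape[1] < 3:
        raise ValueError("need >= 3 conditions")
    enzymes = list(ratios.index)
    n = len(enzymes)
    out = np.eye(n)
    values = ratios.to_numpy(dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            xi, xj = values[i], values[j]
            ok = np.isfinite(xi) & np.isfinite(xj)
            if ok.sum() < 3 or np.std(xi[ok]) == 0 or np.std(xj[ok]) == 0:
                rho = np.nan
            else:
                rho = stats.spearmanr(xi[ok], xj[ok]).statistic
            out[i, j] = out[j, i] = rho
    return pd.DataFrame(out, index=enzymes, columns=enzymes)
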