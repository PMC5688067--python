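"""Integrative clustering by collective matrix tri-factorization.

Heterogeneous data sets are organized as a fusion graph: object types are
nodes and each data set is a relation matrix R_ij between two types.  Every
relation is jointly approximated as R_ij ~ G_i S_ij G_j^T with one shared
nonnegative factor matrix G_i per object type, so information flows between
data sets through the shared factors.  Reconstructed (dense, smooth)
relations touching a target type yield per-object profile vectors; cosine
distances per relation are averaged into a single matrix that drives
hierarchical clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "Relation",
    "FusionGraph",
    "LatentSystem",
    "ProfileDistances",
    "ClusterResult",
    "normalize_relation",
    "fit_fusion",
    "reconstruct",
    "profile_distances",
    "cluster_profiles",
    "select_ranks",
]

_EPS = 1e-12


@dataclass
class Relation:
    name: str
    type_i: str
    type_j: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)


@dataclass
class FusionGraph:
    """Typed object lists plus the relation matrices linking them."""

    object_types: dict[str, list[str]]
    relations: list[Relation]

    def __post_init__(self) -> None:
        names = [r.name for r in self.relations]
        if len(set(names)) != len(names):
            raise ValueError("relation names must be unique")
        for rel in self.relations:
            for t in (rel.type_i, rel.type_j):
                if t not in self.object_types:
                    raise ValueError(f"relation {rel.name!r} references unknown type {t!r}")
            expect = (len(self.object_types[rel.type_i]), len(self.object_types[rel.type_j]))
            if rel.matrix.shape != expect:
                raise ValueError(f"relation {rel.name!r} has shape {rel.matrix.shape}, expected {expect}")

    def relation(self, name: str) -> Relation:
        for rel in self.relations:
            if rel.name == name:
                return rel
        raise KeyError(f"unknown relation {name!r}")

    def relations_touching(self, type_name: str) -> list[Relation]:
        return [r for r in self.relations if type_name in (r.type_i, r.type_j)]


@dataclass
class LatentSystem:
    """Shared nonnegative factors per type and one core matrix per relation."""

    graph: FusionGraph
    factors: dict[str, np.ndarray]
    cores: dict[str, np.ndarray]
    ranks: dict[str, int]
    objective_trace: list[float] = field(default_factory=list)


def normalize_relation(matrix: np.ndarray) -> np.ndarray:
    """Two-step normalization: rows by their L2 norm, then columns of the result.

    Zero rows and columns are left untouched so object indexing is preserved.
    """
    matrix = np.asarray(matrix, dtype=float)
    if not np.all(np.isfinite(matrix)):
        raise ValueError("relation matrix must be finite")
    if np.any(matrix < 0):
        raise ValueError("normalization assumes nonnegative relations")
    out = matrix.copy()
    row_norms = np.linalg.norm(out, axis=1)
    nz = row_norms > 0
    out[nz] = out[nz] / row_norms[nz, None]
    col_norms = np.linalg.norm(out, axis=0)
    nz = col_norms > 0
    out[:, nz] = out[:, nz] / col_norms[nz]
    return out


def _objective(rels, factors, cores, masks) -> float:
    total = 0.0
    for rel in rels:
        recon = factors[rel.type_i] @ cores[rel.name] @ factors[rel.type_j].T
        diff = rel.matrix - recon
        if masks is not None and rel.name in masks:
            diff = diff * masks[rel.name]
        total += float(np.sum(diff * diff))
    return total


def fit_fusion(
    graph: FusionGraph,
    ranks: dict[str, int],
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
    masks: dict[str, np.ndarray] | None = None,
) -> LatentSystem:
    """Jointly co-factorize all relation matrices with shared nonnegative factors.

    Multiplicative updates minimize the summed squared reconstruction error;
    the objective trace is nonincreasing (a sweep that would raise it reverts
    to the previous iterate and stops).  ``masks`` (binary, per relation)
    restrict the fit to observed entries, used for held-out rank selection.
    """
    for tname, objs in graph.object_types.items():
        if tname not in ranks:
            raise ValueError(f"no rank given for type {tname!r}")
        if ranks[tname] >= len(objs):
            raise ValueError(f"rank for type {tname!r} must be < {len(objs)}")
    rels = []
    for rel in graph.relations:
        if np.any(rel.matrix < 0):
            raise ValueError(f"relation {rel.name!r} has negative entries")
        if not rel.matrix.any():
            warnings.warn(f"relation {rel.name!r} is all zero; skipped")
            continue
        rels.append(rel)
    if not rels:
        raise ValueError("no nonzero relations to factorize")

    rng = np.random.default_rng(seed)
    scale = np.sqrt(np.mean([rel.matrix.mean() for rel in rels]))
    factors = {t: rng.uniform(0.1, 1.0, size=(len(objs), ranks[t])) * scale for t, objs in graph.object_types.items()}
    cores = {rel.name: rng.uniform(0.1, 1.0, size=(ranks[rel.type_i], ranks[rel.type_j])) for rel in rels}

    def masked(rel, arr):
        if masks is not None and rel.name in masks:
            return arr * masks[rel.name]
        return arr

    trace = [_objective(rels, factors, cores, masks)]
    for _ in range(max_iter):
        prev_factors = {t: f.copy() for t, f in factors.items()}
        prev_cores = {n: c.copy() for n, c in cores.items()}

        # core updates
        for rel in rels:
            Gi, Gj, S = factors[rel.type_i], factors[rel.type_j], cores[rel.name]
            R = masked(rel, rel.matrix)
            E = masked(rel, Gi @ S @ Gj.T)
            num = Gi.T @ R @ Gj
            den = Gi.T @ E @ Gj + _EPS
            cores[rel.name] = S * num / den

        # shared factor updates, summing over every role a type plays
        for tname in factors:
            G = factors[tname]
            num = np.zeros_like(G)
            den = np.zeros_like(G)
            touched = False
            for rel in rels:
                S = cores[rel.name]
                R = masked(rel, rel.matrix)
                E = masked(rel, factors[rel.type_i] @ S @ factors[rel.type_j].T)
                if rel.type_i == tname:
                    num += R @ factors[rel.type_j] @ S.T
                    den += E @ factors[rel.type_j] @ S.T
                    touched = True
                if rel.type_j == tname:
                    num += R.T @ factors[rel.type_i] @ S
                    den += E.T @ factors[rel.type_i] @ S
                    touched = True
            if touched:
                factors[tname] = G * num / (den + _EPS)

        obj = _objective(rels, factors, cores, masks)
        if obj > trace[-1]:
            factors, cores = prev_factors, prev_cores
            break
        done = abs(trace[-1] - obj) <= tol * max(trace[-1], _EPS)
        trace.append(obj)
        if done:
            break
    return LatentSystem(graph=graph, factors=factors, cores=cores, ranks=dict(ranks), objective_trace=trace)


def reconstruct(system: LatentSystem, relation_name: str) -> np.ndarray:
    """Dense reconstruction G_i S_ij G_j^T of one relation."""
    rel = system.graph.relation(relation_name)
    if rel.name not in system.cores:
        raise KeyError(f"relation {relation_name!r} was not fitted")
    return system.factors[rel.type_i] @ system.cores[rel.name] @ system.factors[rel.type_j].T


@dataclass
class ProfileDistances:
    """Per-relation and averaged cosine distances between target-type profiles."""

    labels: list[str]
    per_relation: dict[str, np.ndarray]
    averaged: np.ndarray
    provenance: list[str] = field(default_factory=list)


def _cosine_distance_matrix(rows: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(rows, axis=1)
    zero = norms == 0
    if zero.any():
        warnings.warn("zero-vector profile; its distances are set to 1")
    safe = np.where(zero, 1.0, norms)
    sim = (rows @ rows.T) / np.outer(safe, safe)
    dist = 1.0 - np.clip(sim, -1.0, 1.0)
    dist[zero, :] = 1.0
    dist[:, zero] = 1.0
    np.fill_diagonal(dist, 0.0)
    return dist


def profile_distances(system: LatentSystem, target_type: str) -> ProfileDistances:
    """Cosine distances between target-type profile rows of each reconstruction,
    averaged (unweighted) across every relation touching the target type."""
    rels = [r for r in system.graph.relations_touching(target_type) if r.name in system.cores]
    if not rels:
        raise ValueError(f"no fitted relation touches type {target_type!r}")
    labels = list(system.graph.object_types[target_type])
    per_relation: dict[str, np.ndarray] = {}
    for rel in rels:
        recon = reconstruct(system, rel.name)
        rows = recon if rel.type_i == target_type else recon.T
        per_relation[rel.name] = _cosine_distance_matrix(rows)
    averaged = np.mean(list(per_relation.values()), axis=0)
    return ProfileDistances(labels=labels, per_relation=per_relation, averaged=averaged, provenance=[r.name for r in rels])


@dataclass
class ClusterResult:
    """Agglomerative clustering output: merge tree, flat labels, heat-map order."""

    labels: dict[str, int]
    linkage_matrix: np.ndarray
    order: list[str]


def cluster_profiles(
    distances: ProfileDistances,
    linkage: str = "average",
    k: int | None = None,
    height: float | None = None,
) -> ClusterResult:
    """Hierarchical clustering on the averaged distance matrix.

    Flat clusters are cut at ``k`` groups (or ``height``); ties break
    deterministically because objects enter in label order.
    """
    n = len(distances.labels)
    if k is not None and k > n:
        raise ValueError("k exceeds the number of objects")
    condensed = squareform(distances.averaged, checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    if k is not None:
        flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    elif height is not None:
        flat = hierarchy.fcluster(Z, t=height, criterion="distance")
    else:
        flat = np.ones(n, dtype=int)
    order = [distances.labels[i] for i in hierarchy.leaves_list(Z)]
    return ClusterResult(labels=dict(zip(distances.labels, map(int, flat))), linkage_matrix=Z, order=order)


def select_ranks(
    graph: FusionGraph,
    grid: list[int],
    seed: int = 0,
    holdout: float = 0.1,
    max_iter: int = 300,
) -> dict[str, int]:
    """Grid search over a shared rank, scored by held-out-entry reconstruction error.

    A seeded 10% entry mask is held out of every relation; the chosen rank is
    the smallest within 1% of the minimal held-out error.  Per-type ranks are
    capped at n_type - 1.
    """
    rng = np.random.default_rng(seed)
    masks = {
        rel.name: (rng.random(rel.matrix.shape) >= holdout).astype(float) for rel in graph.relations
    }
    errors: dict[int, float] = {}
    for r in sorted(grid):
        ranks = {t: min(r, len(objs) - 1) for t, objs in graph.object_types.items()}
        system = fit_fusion(graph, ranks, seed=seed, max_iter=max_iter, masks=masks)
        num = den = 0.0
        for rel in graph.relations:
            if rel.name not in system.cores:
                continue
            held = masks[rel.name] == 0
            diff = rel.matrix - reconstruct(system, rel.name)
            num += float(np.sum(diff[held] ** 2))
            den += float(np.sum(rel.matrix[held] ** 2))
        errors[r] = num / max(den, _EPS)
    best = min(errors.values())
    chosen = min(r for r, e in errors.items() if e <= best * 1.01 + 1e-12)
    return {t: min(chosen, len(objs) - 1) for t, objs in graph.object_types.items()}
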