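"""Epistasis scoring of pairwise knockdown screens under the multiplicative null.

A gene pair (a, b) is called interacting when the observed double-knockdown
viability W_ab deviates significantly from the neutral expectation
E(W_ab) = W_a * W_b.  The epistasis score is

    epsilon = mean(W_ab) - E(W_ab),

negative scores marking aggravating (synergistic) interactions and positive
scores alleviating ones.  Two callers are provided: a two-tailed Z-test on the
difference of means, and an empirical interaction-density region that flags
scores outside the central mass of all pairwise scores in a cell line.

The same multiplicative null applies per cell-cycle phase: the expected phase
fraction of a double knockdown is the control fraction scaled by the product of
the two single-knockdown fold changes, renormalized to the simplex.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

Pair = tuple[str, str]

__all__ = [
    "KnockdownPanel",
    "EpistasisResult",
    "CellCycleTable",
    "InteractionNetwork",
    "canonical_pair",
    "normalize_to_controls",
    "compute_epistasis",
    "call_interactions",
    "phase_interactions",
    "bin_scores",
    "compare_bins",
    "pairwise_spearman",
    "overlap_counts",
    "build_network",
    "export_network",
]


def canonical_pair(a: str, b: str) -> Pair:
    """Canonical unordered key for a gene pair; self-pairs are rejected."""
    if a == b:
        raise ValueError(f"self-pair ({a!r}, {b!r}) is not a valid gene pair")
    return (a, b) if a < b else (b, a)


@dataclass
class KnockdownPanel:
    """Control-normalized single and double knockdown viabilities.

    Viabilities are unitless ratios to the non-targeting control, so the
    control mean is 1 by construction.  Replicate vectors keep technical
    replicates separate; averaging happens only at scoring time.
    """

    genes: list[str]
    single_viability: dict[str, np.ndarray]
    double_viability: dict[Pair, np.ndarray]
    control_label: str = "control"
    cell_line: str = ""
    control_viability: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.single_viability = {g: np.asarray(v, dtype=float) for g, v in self.single_viability.items()}
        self.double_viability = {
            canonical_pair(*p): np.asarray(v, dtype=float) for p, v in self.double_viability.items()
        }
        if self.control_viability is not None:
            self.control_viability = np.asarray(self.control_viability, dtype=float)
        self.validate()

    def validate(self) -> None:
        for name, vec in itertools.chain(self.single_viability.items(), self.double_viability.items()):
            if np.any(np.asarray(vec) < 0):
                raise ValueError(f"negative viability for {name}")
        missing = sorted({g for p in self.double_viability for g in p} - set(self.single_viability))
        if missing:
            raise ValueError(f"pairs reference genes without single-knockdown data: {missing}")
        if self.control_viability is not None and abs(float(np.mean(self.control_viability)) - 1.0) > 1e-6:
            raise ValueError("control replicates do not average to 1; normalize to controls first")

    @property
    def pairs(self) -> list[Pair]:
        return sorted(self.double_viability)


@dataclass
class EpistasisResult:
    """Expected viabilities, epsilon scores, and (optionally) interaction calls."""

    expected: dict[Pair, float]
    epsilon: dict[Pair, float]
    z: dict[Pair, float] = field(default_factory=dict)
    p: dict[Pair, float] = field(default_factory=dict)
    call: dict[Pair, str] = field(default_factory=dict)
    alpha: float | None = None
    method: str | None = None
    density_coverage: float | None = None
    degenerate: set[Pair] = field(default_factory=set)
    cell_line: str = ""
    phase: str = "viability"

    @property
    def pairs(self) -> list[Pair]:
        return sorted(self.epsilon)

    def significant_pairs(self) -> set[Pair]:
        return {p for p, c in self.call.items() if c != "none"}

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for pair in self.pairs:
            rows.append(
                {
                    "gene_a": pair[0],
                    "gene_b": pair[1],
                    "expected": self.expected[pair],
                    "epsilon": self.epsilon[pair],
                    "z": self.z.get(pair, np.nan),
                    "p": self.p.get(pair, np.nan),
                    "call": self.call.get(pair, ""),
                }
            )
        return pd.DataFrame(rows)


@dataclass
class CellCycleTable:
    """Per-knockdown cell-cycle phase-fraction vectors.

    ``fractions`` maps the control label or a gene name (singles) or a
    canonical pair (doubles) to a vector over ``phases`` summing to 1.
    """

    phases: list[str]
    fractions: dict[str | Pair, np.ndarray]
    control_label: str = "control"
    replicate_fractions: dict[str | Pair, np.ndarray] | None = None

    def __post_init__(self) -> None:
        clean: dict[str | Pair, np.ndarray] = {}
        for key, vec in self.fractions.items():
            if isinstance(key, tuple):
                key = canonical_pair(*key)
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (len(self.phases),):
                raise ValueError(f"fraction vector for {key} has wrong length")
            if np.any(vec < 0) or abs(vec.sum() - 1.0) > 1e-6:
                raise ValueError(f"fractions for {key} are not on the simplex")
            clean[key] = vec
        self.fractions = clean

    @property
    def pairs(self) -> list[Pair]:
        return sorted(k for k in self.fractions if isinstance(k, tuple))


@dataclass
class InteractionNetwork:
    """Signed interaction network with strict/loose edge tiers."""

    nodes: list[str]
    edges: list[dict]
    phase: str = "viability"

    def to_frame(self) -> pd.DataFrame:
        cols = ["gene_a", "gene_b", "sign", "weight", "tier", "phase"]
        return pd.DataFrame(self.edges, columns=cols)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e["gene_a"], e["gene_b"], sign=e["sign"], weight=e["weight"], tier=e["tier"], phase=e["phase"])
        return g


# ---------------------------------------------------------------------------
# normalization


def normalize_to_controls(
    raw: pd.DataFrame,
    control_label: str = "control",
    cell_line: str = "",
) -> KnockdownPanel:
    """Normalize a raw plate table to its negative controls, per batch.

    ``raw`` needs columns ``gene_a``, ``gene_b`` (empty/NaN for singles and
    controls), optionally ``batch``, and one or more ``replicate_*`` columns.
    Each batch's values are divided by that batch's control mean; normalized
    replicate vectors from different batches are concatenated, never averaged.
    """
    raw = raw.copy()
    rep_cols = [c for c in raw.columns if c.startswith("replicate")]
    if not rep_cols:
        raise ValueError("no replicate_* columns in raw table")
    if "batch" not in raw.columns:
        raw["batch"] = 0
    gene_b = raw["gene_b"].fillna("") if "gene_b" in raw.columns else pd.Series("", index=raw.index)

    singles: dict[str, list[np.ndarray]] = {}
    doubles: dict[Pair, list[np.ndarray]] = {}
    controls: list[np.ndarray] = []
    for batch, chunk in raw.groupby("batch", sort=True):
        is_control = chunk["gene_a"] == control_label
        if not is_control.any():
            raise ValueError(f"batch {batch!r} has no control wells labelled {control_label!r}")
        control_mean = float(chunk.loc[is_control, rep_cols].to_numpy(dtype=float).mean())
        if control_mean <= 0:
            raise ValueError(f"batch {batch!r} control mean is not positive")
        for _, row in chunk.iterrows():
            values = row[rep_cols].to_numpy(dtype=float) / control_mean
            a, b = row["gene_a"], gene_b.loc[row.name]
            if a == control_label:
                controls.append(values)
            elif b == "":
                singles.setdefault(a, []).append(values)
            else:
                doubles.setdefault(canonical_pair(a, b), []).append(values)

    control_vec = np.concatenate(controls)
    # rescale so the pooled control mean is exactly 1 across batches
    grand = float(control_vec.mean())
    control_vec = control_vec / grand
    genes = sorted(singles)
    return KnockdownPanel(
        genes=genes,
        single_viability={g: np.concatenate(v) / grand for g, v in singles.items()},
        double_viability={p: np.concatenate(v) / grand for p, v in doubles.items()},
        control_label=control_label,
        cell_line=cell_line,
        control_viability=control_vec,
    )


# ---------------------------------------------------------------------------
# scoring


def _mean(vec: np.ndarray) -> float:
    """Replicate mean, exact for constant vectors (no roundoff from summing)."""
    if np.all(vec == vec[0]):
        return float(vec[0])
    return float(np.mean(vec))


def compute_epistasis(panel: KnockdownPanel) -> EpistasisResult:
    """Score every measured pair against the multiplicative null.

    E(W_ab) = mean(W_a) * mean(W_b);  epsilon = mean(W_ab) - E(W_ab).
    """
    expected: dict[Pair, float] = {}
    epsilon: dict[Pair, float] = {}
    for pair, w_ab in panel.double_viability.items():
        a, b = pair
        e = _mean(panel.single_viability[a]) * _mean(panel.single_viability[b])
        expected[pair] = e
        epsilon[pair] = _mean(w_ab) - e
    return EpistasisResult(expected=expected, epsilon=epsilon, cell_line=panel.cell_line)


def _pooled_noise_variance(panel: KnockdownPanel) -> float:
    """Technical-noise variance pooled over every measurement in the panel."""
    ss = 0.0
    df = 0
    vectors = list(panel.single_viability.values()) + list(panel.double_viability.values())
    if panel.control_viability is not None:
        vectors.append(panel.control_viability)
    for vec in vectors:
        if vec.size >= 2:
            ss += float(np.sum((vec - vec.mean()) ** 2))
            df += vec.size - 1
    if df == 0:
        raise ValueError("no measurement has >= 2 replicates; cannot estimate noise variance")
    return ss / df


def call_interactions(
    result: EpistasisResult,
    panel: KnockdownPanel | None = None,
    alpha: float = 0.05,
    method: str = "ztest",
    coverage: float = 0.95,
    var_mode: str = "pooled",
    reference: str = "normal",
) -> EpistasisResult:
    """Fill significance calls on an epistasis result.

    ztest
        z = epsilon / SE, two-tailed.  SE combines the double-knockdown
        standard error with the delta-method error of the product of single
        means: SE^2 = SE_ab^2 + mean(W_b)^2 SE_a^2 + mean(W_a)^2 SE_b^2.
        ``var_mode="pooled"`` (default) estimates one technical-noise variance
        from all replicate scatter in the panel, giving the reference
        distribution enough degrees of freedom to behave as standard normal;
        ``"per-pair"`` uses each measurement's own sample variance.
        ``reference="t"`` swaps the normal tail for a Student-t tail with
        Welch-Satterthwaite degrees of freedom (per-pair mode only).
    density
        A pair is significant when its epsilon lies outside the central
        empirical-probability region (symmetric percentiles, midpoint
        interpolation) of all pairwise epsilons in the cell line, at the given
        coverage (0.90 loose / 0.95 strict).

    The sign of epsilon sets the class: aggravating (< 0) or alleviating (> 0).
    """
    if method not in ("ztest", "density"):
        raise ValueError(f"unknown method {method!r}")
    res = EpistasisResult(
        expected=dict(result.expected),
        epsilon=dict(result.epsilon),
        alpha=alpha,
        method=method,
        cell_line=result.cell_line,
        phase=result.phase,
    )

    if method == "ztest":
        if panel is None:
            raise ValueError("ztest calling requires the panel for replicate scatter")
        pooled = _pooled_noise_variance(panel) if var_mode == "pooled" else None
        for pair in res.pairs:
            a, b = pair
            w_a, w_b = panel.single_viability[a], panel.single_viability[b]
            w_ab = panel.double_viability[pair]
            if var_mode == "pooled":
                var_a = var_b = var_ab = pooled
            else:
                var_a = float(np.var(w_a, ddof=1))
                var_b = float(np.var(w_b, ddof=1))
                var_ab = float(np.var(w_ab, ddof=1))
            se2 = (
                var_ab / w_ab.size
                + np.mean(w_b) ** 2 * var_a / w_a.size
                + np.mean(w_a) ** 2 * var_b / w_b.size
            )
            eps = res.epsilon[pair]
            if se2 <= 0:
                res.degenerate.add(pair)
                res.z[pair] = np.nan
                res.p[pair] = 0.0 if eps != 0 else 1.0
                sig = eps != 0
            else:
                z = eps / np.sqrt(se2)
                if reference == "t" and var_mode == "per-pair":
                    terms = np.array(
                        [
                            var_ab / w_ab.size,
                            np.mean(w_b) ** 2 * var_a / w_a.size,
                            np.mean(w_a) ** 2 * var_b / w_b.size,
                        ]
                    )
                    dfs = np.array([w_ab.size - 1, w_a.size - 1, w_b.size - 1])
                    df = se2**2 / float(np.sum(terms**2 / dfs))
                    pval = 2.0 * float(stats.t.sf(abs(z), df))
                else:
                    pval = 2.0 * float(stats.norm.sf(abs(z)))
                res.z[pair] = float(z)
                res.p[pair] = pval
                sig = pval < alpha
            res.call[pair] = ("aggravating" if eps < 0 else "alleviating") if sig and eps != 0 else "none"
    else:
        eps_values = np.array([res.epsilon[p] for p in res.pairs])
        if eps_values.size < 20:
            raise ValueError("density calling needs >= 20 pairs")
        res.density_coverage = coverage
        tail = 100.0 * (1.0 - coverage) / 2.0
        lo, hi = np.percentile(eps_values, [tail, 100.0 - tail], method="midpoint")
        for pair in res.pairs:
            eps = res.epsilon[pair]
            sig = eps < lo or eps > hi
            res.p[pair] = np.nan
            res.call[pair] = ("aggravating" if eps < 0 else "alleviating") if sig and eps != 0 else "none"
    return res


def phase_interactions(
    table: CellCycleTable,
    pairs: list[Pair] | None = None,
    alpha: float = 0.1,
    method: str = "density",
    coverage: float = 0.90,
) -> dict[str, EpistasisResult]:
    """Per-phase interaction scores under the multiplicative null on fold changes.

    For phase k with control fraction F0_k, the expected double-knockdown
    fraction is (F_a,k / F0_k) * (F_b,k / F0_k) * F0_k, renormalized across
    phases to sum 1.  The per-phase score is observed minus expected fraction;
    positive scores are increases in that phase, negative are decreases.
    Significance is assessed independently per phase with the density caller by
    default (the z-test needs replicate fractions).
    """
    f0 = table.fractions[table.control_label]
    if pairs is None:
        pairs = table.pairs
    keep = f0 > 0
    if not keep.all():
        dropped = [ph for ph, k in zip(table.phases, keep) if not k]
        warnings.warn(f"phases with zero control fraction excluded: {dropped}")

    results: dict[str, EpistasisResult] = {}
    expected_by_pair: dict[Pair, np.ndarray] = {}
    for pair in pairs:
        a, b = pair
        f_a, f_b = table.fractions[a], table.fractions[b]
        ratio = np.ones_like(f0)
        ratio[keep] = (f_a[keep] / f0[keep]) * (f_b[keep] / f0[keep])
        exp = ratio * f0
        exp = exp / exp.sum()
        expected_by_pair[pair] = exp

    for k, phase in enumerate(table.phases):
        if not keep[k]:
            continue
        expected = {p: float(expected_by_pair[p][k]) for p in pairs}
        epsilon = {p: float(table.fractions[p][k] - expected_by_pair[p][k]) for p in pairs}
        res = EpistasisResult(expected=expected, epsilon=epsilon, phase=phase)
        if method == "density" and len(pairs) >= 20:
            res = call_interactions(res, alpha=alpha, method="density", coverage=coverage)
            res.phase = phase
        results[phase] = res
    return results


# ---------------------------------------------------------------------------
# summaries


@dataclass
class BinAssignment:
    """Equal-width score bins over the observed epsilon range."""

    edges: np.ndarray
    labels: dict[Pair, int]  # 1-based bin index

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1


def bin_scores(result: EpistasisResult, n_bins: int = 5) -> BinAssignment:
    """Assign each pair to one of ``n_bins`` equal-width epsilon bins.

    Interior boundaries are right-edge inclusive: a score exactly on an edge
    falls in the lower bin; the minimum falls in bin 1.
    """
    pairs = result.pairs
    eps = np.array([result.epsilon[p] for p in pairs])
    lo, hi = float(eps.min()), float(eps.max())
    if lo == hi:
        warnings.warn("constant epsilon: single degenerate bin")
        return BinAssignment(edges=np.array([lo, hi]), labels={p: 1 for p in pairs})
    edges = np.linspace(lo, hi, n_bins + 1)
    interior = edges[1:-1]
    idx = np.searchsorted(interior, eps, side="left") + 1
    return BinAssignment(edges=edges, labels={p: int(i) for p, i in zip(pairs, idx)})


def compare_bins(bins: BinAssignment, values: dict[Pair, list[float] | float]) -> pd.DataFrame:
    """Summarize a per-pair covariate within each epsilon bin.

    ``values`` maps each binned pair to one or more covariate values (e.g. the
    log2 expression changes of both genes, a patristic distance, or an
    activity Spearman rho).  Returns per-bin median, quartiles (linear
    interpolation) and n; empty bins get n = 0 and NaN summaries.
    """
    per_bin: dict[int, list[float]] = {b: [] for b in range(1, bins.n_bins + 1)}
    for pair, vals in values.items():
        if pair not in bins.labels:
            continue
        if np.isscalar(vals):
            vals = [vals]
        per_bin[bins.labels[pair]].extend(float(v) for v in vals)
    rows = []
    for b in sorted(per_bin):
        vals = np.array(per_bin[b])
        if vals.size:
            q1, med, q3 = np.percentile(vals, [25, 50, 75], method="linear")
            rows.append({"bin": b, "n": vals.size, "q1": q1, "median": med, "q3": q3})
        else:
            rows.append({"bin": b, "n": 0, "q1": np.nan, "median": np.nan, "q3": np.nan})
    return pd.DataFrame(rows).set_index("bin")


def pairwise_spearman(results: dict[str, EpistasisResult]) -> pd.DataFrame:
    """Spearman correlation matrix of epsilon vectors across cell lines."""
    if len(results) < 2:
        raise ValueError("need >= 2 result sets")
    names = sorted(results)
    shared = set.intersection(*(set(results[n].epsilon) for n in names))
    if any(len(results[n].epsilon) != len(shared) for n in names):
        warnings.warn("pair sets differ between cell lines; intersecting")
    shared = sorted(shared)
    mat = np.ones((len(names), len(names)))
    for i, j in itertools.combinations(range(len(names)), 2):
        x = [results[names[i]].epsilon[p] for p in shared]
        y = [results[names[j]].epsilon[p] for p in shared]
        rho = stats.spearmanr(x, y).statistic
        mat[i, j] = mat[j, i] = rho
    return pd.DataFrame(mat, index=names, columns=names)


def overlap_counts(sets_by_line: dict[str, set]) -> dict[tuple[str, ...], int]:
    """Counts for every region of the Venn partition of significant-pair sets.

    Keys are sorted tuples of the set names a region belongs to exclusively;
    counts over all nonempty regions sum to the union size.
    """
    names = sorted(sets_by_line)
    universe = set().union(*sets_by_line.values())
    counts: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for members in itertools.combinations(names, r):
            region = set.intersection(*(sets_by_line[m] for m in members))
            for other in names:
                if other not in members:
                    region = region - sets_by_line[other]
            counts[members] = len(region)
    assert sum(counts.values()) == len(universe)
    return counts


# ---------------------------------------------------------------------------
# networks


def build_network(
    strict: EpistasisResult,
    loose: EpistasisResult,
    nodes: list[str] | None = None,
) -> InteractionNetwork:
    """Assemble a two-tier signed network from strict and loose call sets.

    Strict edges are those significant at the stringent result; loose edges
    are significant only at the looser one.  The strict edge set is contained
    in the loose edge set when both results come from the same scores.
    """
    strict_sig = strict.significant_pairs()
    loose_sig = loose.significant_pairs() | strict_sig
    if nodes is None:
        nodes = sorted({g for p in strict.epsilon for g in p})
    edges = []
    for pair in sorted(loose_sig):
        eps = strict.epsilon.get(pair, loose.epsilon.get(pair))
        edges.append(
            {
                "gene_a": pair[0],
                "gene_b": pair[1],
                "sign": "-" if eps < 0 else "+",
                "weight": eps,
                "tier": "strict" if pair in strict_sig else "loose",
                "phase": strict.phase,
            }
        )
    return InteractionNetwork(nodes=list(nodes), edges=edges, phase=strict.phase)


def export_network(net: InteractionNetwork, path_prefix: str) -> None:
    """Write a network as edge-list TSV and GraphML."""
    import networkx as nx

    net.to_frame().to_csv(f"{path_prefix}.tsv", sep="\t", index=False)
    nx.write_graphml(net.to_networkx(), f"{path_prefix}.graphml")
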