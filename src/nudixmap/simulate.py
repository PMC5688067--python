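"""Synthetic screen generator with known ground truth.

Emulates every input the pipeline consumes: replicate viability panels under
the multiplicative null with planted aggravating/alleviating interactions,
compositional cell-cycle phase fractions, block-structured multi-relational
matrices for data fusion, random phylogenies, and activity/expression tables.
All generators draw from per-component streams derived from one master seed,
so equal seeds give byte-identical outputs and components stay independent.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .epistasis import CellCycleTable, KnockdownPanel, Pair, canonical_pair

__all__ = [
    "GeneratorConfig",
    "TruthSet",
    "gen_knockdown_panel",
    "gen_cellcycle_table",
    "gen_fusion_collection",
    "gen_tree",
    "gen_activity_and_expression",
    "gen_null_pair_panel",
    "precision_recall",
]

_STREAMS = {"panel": 1, "cellcycle": 2, "fusion": 3, "tree": 4, "activity": 5, "expression": 6}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic study, with defaults matching the screen design
    (24 siRNA targets in technical triplicate, plate noise SD 0.05)."""

    n_genes: int = 24
    n_replicates: int = 3
    noise_sd: float = 0.05
    single_viability_range: tuple[float, float] = (0.4, 1.0)
    n_planted_aggravating: int = 0
    n_planted_alleviating: int = 0
    effect_size: float = 0.3
    phase_labels: tuple[str, ...] = ("sub-G0/G1", "G1", "S", "G2/M", ">4N")
    phase_noise_sd: float = 0.05
    phase_effect: float = 0.1
    fusion_blocks: dict = field(default_factory=lambda: {"gene": (12, 2), "substrate": (8, 2)})
    fusion_relations: tuple = (("activity", "gene", "substrate"), ("epistasis", "gene", "gene"))
    block_base: float = 0.2
    block_margin: float = 0.6
    block_noise_sd: float = 0.05
    n_tree_leaves: int = 8
    n_substrates: int = 9
    n_activity_groups: int = 3
    activity_fold: float = 4.0
    n_de_genes: int = 5
    de_log2fc: float = 2.0
    n_expression_samples: int = 6
    expression_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.single_viability_range
        if not (0 < lo < hi <= 1.2):
            raise ValueError("single_viability_range must be well-ordered within (0, 1.2]")
        for name in ("n_genes", "n_replicates", "n_tree_leaves"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.noise_sd < 0 or self.phase_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if not self.phase_labels:
            raise ValueError("phase_labels must be nonempty")

    def gene_names(self) -> list[str]:
        return [f"gene{i:02d}" for i in range(1, self.n_genes + 1)]


@dataclass
class TruthSet:
    """Planted ground truth sufficient to score any downstream caller."""

    planted_interactions: list[tuple[Pair, str, float]]
    planted_blocks: dict[str, dict[str, int]] = field(default_factory=dict)
    planted_de_genes: list[tuple[str, float]] = field(default_factory=list)
    seed: int = 0

    def validate(self, genes: list[str] | None = None) -> None:
        for pair, cls, eps in self.planted_interactions:
            if cls == "aggravating" and eps >= 0:
                raise ValueError(f"aggravating pair {pair} must have negative effect size")
            if cls == "alleviating" and eps <= 0:
                raise ValueError(f"alleviating pair {pair} must have positive effect size")
            if genes is not None and not set(pair) <= set(genes):
                raise ValueError(f"planted pair {pair} names unknown genes")

    @property
    def planted_pairs(self) -> set[Pair]:
        return {p for p, _, _ in self.planted_interactions}

    def planted_sign(self, pair: Pair) -> str:
        for p, cls, _ in self.planted_interactions:
            if p == pair:
                return cls
        raise KeyError(pair)


def _noisy(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Replicate draws, Gaussian noise truncated at 0 by resampling."""
    if sd == 0:
        return np.full(n, mean)
    out = rng.normal(mean, sd, size=n)
    while np.any(out < 0):
        bad = out < 0
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return out


def gen_knockdown_panel(cfg: GeneratorConfig) -> tuple[KnockdownPanel, TruthSet]:
    """Simulate a control-normalized single/double knockdown viability panel.

    Non-planted pair means equal the product of their single means; planted
    pairs add their signed effect size epsilon* on top of the product.
    """
    if cfg.n_genes < 3:
        raise ValueError("need >= 3 genes")
    rng = _rng(cfg.seed, "panel")
    genes = cfg.gene_names()
    lo, hi = cfg.single_viability_range
    single_means = {g: rng.uniform(lo, hi) for g in genes}

    all_pairs = [canonical_pair(a, b) for a, b in itertools.combinations(genes, 2)]
    n_planted = cfg.n_planted_aggravating + cfg.n_planted_alleviating
    # aggravating effects are only plantable where the null mean stays >= 0
    eligible = [p for p in all_pairs if single_means[p[0]] * single_means[p[1]] - cfg.effect_size >= 0]
    if cfg.n_planted_aggravating > len(eligible) or n_planted > len(all_pairs):
        raise ValueError(
            f"effect size {cfg.effect_size} would push planted pair means below 0; "
            "reduce effect_size, the planted count, or raise the single-viability range"
        )
    chosen_agg = [eligible[i] for i in rng.choice(len(eligible), size=cfg.n_planted_aggravating, replace=False)]
    remaining = [p for p in all_pairs if p not in set(chosen_agg)]
    chosen_all = [remaining[i] for i in rng.choice(len(remaining), size=cfg.n_planted_alleviating, replace=False)]
    planted: list[tuple[Pair, str, float]] = [(p, "aggravating", -cfg.effect_size) for p in chosen_agg]
    planted += [(p, "alleviating", +cfg.effect_size) for p in chosen_all]
    effects = {p: e for p, _, e in planted}

    singles = {g: _noisy(rng, single_means[g], cfg.noise_sd, cfg.n_replicates) for g in genes}
    doubles: dict[Pair, np.ndarray] = {}
    for pair in all_pairs:
        a, b = pair
        mean = single_means[a] * single_means[b] + effects.get(pair, 0.0)
        if mean < 0:
            raise ValueError(
                f"planted effect {effects[pair]} pushes pair {pair} mean below 0; "
                "reduce effect_size or raise the single-viability range"
            )
        doubles[pair] = _noisy(rng, mean, cfg.noise_sd, cfg.n_replicates)

    noise = rng.normal(0.0, cfg.noise_sd, size=cfg.n_replicates) if cfg.noise_sd > 0 else np.zeros(cfg.n_replicates)
    control = 1.0 + noise - noise.mean()  # negative-control mean fixed at 1

    truth = TruthSet(planted_interactions=planted, seed=cfg.seed)
    truth.validate(genes)
    panel = KnockdownPanel(
        genes=genes,
        single_viability=singles,
        double_viability=doubles,
        cell_line="synthetic",
        control_viability=control,
    )
    return panel, truth


def _control_point(k: int) -> np.ndarray:
    """Fixed simplex point used as the control phase distribution."""
    if k == 5:
        return np.array([0.08, 0.47, 0.15, 0.25, 0.05])
    w = np.arange(1, k + 1, dtype=float)[::-1]
    return w / w.sum()


def _perturb_simplex(rng: np.random.Generator, base: np.ndarray, sd: float) -> np.ndarray:
    """Multiplicative log-normal jitter on fold ratios, then renormalize."""
    if sd == 0:
        return base.copy()
    ratios = np.exp(rng.normal(0.0, sd, size=base.size))
    out = base * ratios
    return out / out.sum()


def gen_cellcycle_table(cfg: GeneratorConfig, truth: TruthSet) -> CellCycleTable:
    """Simulate phase-fraction vectors following the per-phase multiplicative null.

    Doubles follow the null on control-relative fold changes of the realized
    singles; pairs planted in ``truth`` get a +phase_effect deviation before
    renormalization (aggravating pairs on the first phase, the death
    compartment; alleviating pairs on the second).
    """
    rng = _rng(cfg.seed, "cellcycle")
    phases = list(cfg.phase_labels)
    k = len(phases)
    f0 = _control_point(k)
    genes = cfg.gene_names()

    fractions: dict[str | Pair, np.ndarray] = {"control": f0}
    for g in genes:
        fractions[g] = _perturb_simplex(rng, f0, cfg.phase_noise_sd)

    deviation_phase = {"aggravating": 0, "alleviating": min(1, k - 1)}
    planted = {p: cls for p, cls, _ in truth.planted_interactions}
    for a, b in itertools.combinations(genes, 2):
        pair = canonical_pair(a, b)
        ratio = (fractions[a] / f0) * (fractions[b] / f0)
        expected = ratio * f0
        expected = expected / expected.sum()
        vec = _perturb_simplex(rng, expected, cfg.phase_noise_sd)
        if pair in planted:
            vec = vec.copy()
            vec[deviation_phase[planted[pair]]] += cfg.phase_effect
        if np.any(vec < 0):
            warnings.warn(f"negative intermediate fractions for {pair}; renormalizing")
            vec = np.clip(vec, 0.0, None)
        vec = vec / vec.sum()
        fractions[pair] = vec
    return CellCycleTable(phases=phases, fractions=fractions)


def gen_fusion_collection(cfg: GeneratorConfig):
    """Simulate a fusion graph of planted block-structured relation matrices.

    Every relation matrix is block-constant (within-block entries exceed
    between-block entries by ``block_margin``) plus Gaussian noise, clipped at
    zero.  Returns (FusionGraph, TruthSet with planted block labels).
    """
    from .fusion import FusionGraph, Relation

    if len(cfg.fusion_blocks) < 2 or len(cfg.fusion_relations) < 2:
        raise ValueError("fusion spec needs >= 2 object types and >= 2 relations")
    rng = _rng(cfg.seed, "fusion")
    object_types: dict[str, list[str]] = {}
    blocks: dict[str, dict[str, int]] = {}
    for tname, (n_obj, n_blocks) in cfg.fusion_blocks.items():
        objs = [f"{tname}{i:02d}" for i in range(1, n_obj + 1)]
        object_types[tname] = objs
        blocks[tname] = {o: i % n_blocks for i, o in enumerate(objs)}

    relations = []
    for name, ti, tj in cfg.fusion_relations:
        for t in (ti, tj):
            if t not in object_types:
                raise ValueError(f"relation {name!r} names unknown object type {t!r}")
        bi = np.array([blocks[ti][o] for o in object_types[ti]])
        bj = np.array([blocks[tj][o] for o in object_types[tj]])
        mat = cfg.block_base + cfg.block_margin * (bi[:, None] == bj[None, :])
        if cfg.block_noise_sd > 0:
            mat = mat + rng.normal(0.0, cfg.block_noise_sd, size=mat.shape)
        mat = np.clip(mat, 0.0, None)
        relations.append(Relation(name=name, type_i=ti, type_j=tj, matrix=mat))

    graph = FusionGraph(object_types=object_types, relations=relations)
    truth = TruthSet(planted_interactions=[], planted_blocks=blocks, seed=cfg.seed)
    return graph, truth


def gen_tree(cfg: GeneratorConfig) -> str:
    """Random binary tree over the first ``n_tree_leaves`` panel genes, as newick.

    Built by iterative random joins with exponential branch lengths, so every
    edge has a positive length and leaf labels match panel gene names.
    """
    if cfg.n_tree_leaves < 2:
        raise ValueError("need >= 2 leaves")
    rng = _rng(cfg.seed, "tree")
    nodes = [f"{name}:{rng.exponential(0.2):.6f}" for name in cfg.gene_names()[: cfg.n_tree_leaves]]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]},{nodes[j]}):{rng.exponential(0.2):.6f}"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return f"({nodes[0]},{nodes[1]});"


def gen_activity_and_expression(cfg: GeneratorConfig):
    """Simulate a raw absorbance table and a matched normal/tumor expression pair.

    Activity: enzymes and substrates fall into matching groups; a group-matched
    (enzyme, substrate) cell reads ``activity_fold`` times its no-coupling
    control, others read near control.  Expression: tumor equals normal plus
    the planted log2 fold changes on the DE genes, with Gaussian sample noise.
    Returns (raw activity DataFrame, control-column map, ExpressionPair, TruthSet).
    """
    from .profiles import ExpressionPair

    rng = _rng(cfg.seed, "activity")
    genes = cfg.gene_names()
    enzymes = genes[: min(len(genes), 12)]
    substrates = [f"substrate{i:02d}" for i in range(1, cfg.n_substrates + 1)]
    e_group = {e: i % cfg.n_activity_groups for i, e in enumerate(enzymes)}
    s_group = {s: i % cfg.n_activity_groups for i, s in enumerate(substrates)}

    data: dict[str, np.ndarray] = {}
    control_map: dict[str, str] = {}
    for s in substrates:
        control = rng.uniform(0.2, 0.4, size=len(enzymes))
        fold = np.array([cfg.activity_fold if e_group[e] == s_group[s] else 1.0 for e in enzymes])
        signal = control * fold
        if cfg.noise_sd > 0:
            signal = np.clip(signal + rng.normal(0.0, cfg.noise_sd, size=signal.size), 0.0, None)
        data[s] = signal
        data[f"{s}_control"] = control
        control_map[s] = f"{s}_control"
    raw = pd.DataFrame(data, index=enzymes)

    rng_e = _rng(cfg.seed, "expression")
    baseline = rng_e.uniform(2.0, 8.0, size=len(genes))
    de_idx = rng_e.choice(len(genes), size=min(cfg.n_de_genes, len(genes)), replace=False)
    log2fc = np.zeros(len(genes))
    signs = np.where(rng_e.random(de_idx.size) < 0.5, -1.0, 1.0)
    log2fc[de_idx] = signs * cfg.de_log2fc
    n = cfg.n_expression_samples

    def _samples(mean_vec: np.ndarray) -> pd.DataFrame:
        noise = (
            rng_e.normal(0.0, cfg.expression_noise_sd, size=(len(genes), n))
            if cfg.expression_noise_sd > 0
            else np.zeros((len(genes), n))
        )
        return pd.DataFrame(mean_vec[:, None] + noise, index=genes, columns=[f"s{i}" for i in range(n)])

    pair = ExpressionPair(normal=_samples(baseline), tumor=_samples(baseline + log2fc))
    truth = TruthSet(
        planted_interactions=[],
        planted_de_genes=[(genes[i], float(log2fc[i])) for i in de_idx],
        seed=cfg.seed,
    )
    return raw, control_map, pair, truth


def gen_null_pair_panel(n_pairs: int, cfg: GeneratorConfig) -> KnockdownPanel:
    """Simulate ``n_pairs`` independent non-interacting gene pairs.

    Each pair gets its own two singles (means uniform in the configured
    range), a double whose mean is exactly their product, and independent
    replicate noise — so calls on different pairs are independent, matching a
    binomial calibration check.
    """
    rng = _rng(cfg.seed, "panel")
    lo, hi = cfg.single_viability_range
    singles: dict[str, np.ndarray] = {}
    doubles: dict[Pair, np.ndarray] = {}
    for i in range(n_pairs):
        a, b = f"a{i:05d}", f"b{i:05d}"
        mean_a, mean_b = rng.uniform(lo, hi, size=2)
        singles[a] = _noisy(rng, mean_a, cfg.noise_sd, cfg.n_replicates)
        singles[b] = _noisy(rng, mean_b, cfg.noise_sd, cfg.n_replicates)
        doubles[canonical_pair(a, b)] = _noisy(rng, mean_a * mean_b, cfg.noise_sd, cfg.n_replicates)
    return KnockdownPanel(
        genes=sorted(singles),
        single_viability=singles,
        double_viability=doubles,
        cell_line="null-simulation",
    )


def precision_recall(truth: TruthSet, called: set[Pair]) -> tuple[float, float]:
    """Precision and recall of a caller's significant set against the planted pairs."""
    planted = truth.planted_pairs
    if not called:
        return (float("nan"), 0.0 if planted else float("nan"))
    tp = len(called & planted)
    precision = tp / len(called)
    recall = tp / len(planted) if planted else float("nan")
    return precision, recall
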