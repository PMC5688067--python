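"""Latent-factor gene-network inference from single/double knockdown phenotypes.

Three stages: (i) factorize the double-knockdown viability matrix G through a
logistic map, Ghat = ceiling * sigmoid(steepness * (U V^T - midpoint)),
selecting the factorization rank by normalized root-mean-square error;
(ii) score, for every ordered gene pair, four pairwise relationship
hypotheses — the double phenotype matches one single (two linear-pathway
orientations), the product of singles (parallel, independent action), or an
interpolation between the nearest single and the product (partial
interdependence) — via Gaussian likelihoods on the denoised reconstruction;
(iii) build a directed network from the winning hypotheses and classify edge
stability under repeated refits on noise-perturbed copies of G (solid >= 40%
appearance, dashed 20-40%).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from scipy.special import expit

from .epistasis import KnockdownPanel, Pair

__all__ = [
    "RedInputs",
    "RedModel",
    "RelationshipProbs",
    "RedNetwork",
    "StabilityReport",
    "CLASSES",
    "fit_latent_model",
    "score_relationships",
    "infer_network",
    "stability_analysis",
    "stability_class",
]

# hypothesis slots for an ordered pair (u, v):
#   linear_first  — double matches S_u (u's knockdown phenotype masks v's)
#   linear_second — double matches S_v
#   parallel      — double matches S_u * S_v (independent action)
#   partial       — double interpolates between the nearest single and the product
CLASSES = ("linear_first", "linear_second", "parallel", "partial")


@dataclass
class RedInputs:
    """Averaged inputs: double matrix G, single vector S, expected matrix H = S S^T."""

    genes: list[str]
    G: np.ndarray  # n x n, NaN where unobserved (diagonal)
    S: np.ndarray  # n
    H: np.ndarray  # n x n
    replicate_sd: float | None = None

    def __post_init__(self) -> None:
        n = len(self.genes)
        self.G = np.asarray(self.G, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        self.H = np.asarray(self.H, dtype=float)
        if self.G.shape != (n, n) or self.S.shape != (n,) or self.H.shape != (n, n):
            raise ValueError("G, S, H dimensions do not match the gene list")
        obs = ~np.isnan(self.G)
        if not np.allclose(self.G[obs], self.G.T[obs], equal_nan=True):
            raise ValueError("G must be symmetric where observed")
        if np.nanmin(self.G) < 0 or self.S.min() < 0:
            raise ValueError("viabilities must be nonnegative")
        if not np.allclose(self.H, np.outer(self.S, self.S)):
            raise ValueError("H must equal the outer product of S with itself")

    @classmethod
    def from_panel(cls, panel: KnockdownPanel) -> "RedInputs":
        """Average a replicate panel into G/S/H, estimating noise from replicate scatter."""
        genes = sorted(panel.single_viability)
        idx = {g: i for i, g in enumerate(genes)}
        n = len(genes)
        S = np.array([np.mean(panel.single_viability[g]) for g in genes])
        G = np.full((n, n), np.nan)
        sds = []
        for (a, b), vec in panel.double_viability.items():
            G[idx[a], idx[b]] = G[idx[b], idx[a]] = float(np.mean(vec))
            if vec.size >= 2:
                sds.append(np.std(vec, ddof=1) / np.sqrt(vec.size))
        rep_sd = float(np.mean(sds)) if sds else None
        return cls(genes=genes, G=G, S=S, H=np.outer(S, S), replicate_sd=rep_sd)


@dataclass
class RedModel:
    """Fitted factorization with its logistic map and the rank-selection trace."""

    genes: list[str]
    U: np.ndarray
    V: np.ndarray
    ceiling: float
    steepness: float
    midpoint: float
    rank: int
    nrmse_by_rank: dict[int, float]
    denoised: np.ndarray
    converged: bool = True
    reconstruction_rmse: float = 0.0


def _predict(U, V, ceiling, steepness, midpoint) -> np.ndarray:
    x = U @ V.T
    p = ceiling * expit(steepness * (x - midpoint))
    return 0.5 * (p + p.T)


def _fit_at_rank(G, mask, rank, rng, init, max_iter, tol):
    """Adam minimization of the masked squared reconstruction error.

    Returns the best iterate seen, so the final objective never exceeds the
    objective at the (possibly warm-started) initialization.
    """
    n = G.shape[0]
    if init is None:
        U = rng.uniform(0.0, 1.0, size=(n, rank))
        V = rng.uniform(0.0, 1.0, size=(n, rank))
        ceiling = float(np.max(G[mask])) if mask.any() else 1.0
        steepness, midpoint = 1.0, 0.0
    else:
        U, V, ceiling, steepness, midpoint = init
    params = [U.copy(), V.copy(), np.array([ceiling]), np.array([steepness]), np.array([midpoint])]
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    lr, b1, b2, eps = 0.05, 0.9, 0.999, 1e-8

    def loss_of(ps):
        pred = _predict(ps[0], ps[1], ps[2][0], ps[3][0], ps[4][0])
        r = np.where(mask, pred - G, 0.0)
        return float(np.sum(r * r)), pred

    best_loss, _ = loss_of(params)
    best = [p.copy() for p in params]
    prev_loss = np.inf
    converged = False
    for t in range(1, max_iter + 1):
        U, V = params[0], params[1]
        L, k, x0 = params[2][0], params[3][0], params[4][0]
        X = U @ V.T
        sig = expit(k * (X - x0))
        P = L * sig
        Psym = 0.5 * (P + P.T)
        R = np.where(mask, Psym - G, 0.0)
        loss = float(np.sum(R * R))
        if loss < best_loss:
            best_loss = loss
            best = [p.copy() for p in params]
        if np.isfinite(prev_loss) and abs(prev_loss - loss) <= tol * max(prev_loss, 1e-12):
            converged = True
            break
        prev_loss = loss
        dP = R + R.T  # d/dP of sum over symmetric mask
        dsig = dP * L * sig * (1.0 - sig)
        dX = dsig * k
        grads = [
            dX @ V,
            dX.T @ U,
            np.array([np.sum(dP * sig)]),
            np.array([np.sum(dP * L * sig * (1.0 - sig) * (X - x0))]),
            np.array([-np.sum(dX)]),
        ]
        for i, g in enumerate(grads):
            m[i] = b1 * m[i] + (1 - b1) * g
            v[i] = b2 * v[i] + (1 - b2) * g * g
            mhat = m[i] / (1 - b1**t)
            vhat = v[i] / (1 - b2**t)
            params[i] = params[i] - lr * mhat / (np.sqrt(vhat) + eps)
        params[2][0] = max(params[2][0], 1e-6)  # ceiling stays positive
    return best, best_loss, converged


def fit_latent_model(
    inputs: RedInputs,
    rank_grid: list[int] | None = None,
    seed: int = 0,
    max_iter: int = 5000,
    tol: float = 1e-8,
    rank: int | None = None,
    init_model: "RedModel | None" = None,
) -> RedModel:
    """Fit the logistic latent-factor model, selecting the rank by NRMSE.

    The rank sweep warm-starts each rank from the previous fit (the extra
    factor column of V initialized to zero leaves predictions unchanged), so
    the NRMSE trace is nonincreasing in rank.  The selected rank is the
    smallest within 1% of the minimal NRMSE.  Passing ``rank`` skips the
    sweep and fits that rank from a fresh seeded initialization.
    """
    n = len(inputs.genes)
    if n < 4:
        raise ValueError("need >= 4 genes")
    G = np.where(np.isnan(inputs.G), 0.0, inputs.G)
    mask = ~np.isnan(inputs.G)
    np.fill_diagonal(mask, False)
    rng = np.random.default_rng(seed)
    spread = float(np.max(G[mask]) - np.min(G[mask])) if mask.any() else 1.0
    denom = spread if spread > 0 else 1.0
    n_obs = int(mask.sum())

    if rank is not None:
        grid = [rank]
    else:
        grid = sorted(rank_grid) if rank_grid is not None else list(range(1, min(n - 1, 8) + 1))
    if grid[0] < 1 or grid[-1] > n - 1:
        raise ValueError("rank grid must lie within [1, n-1]")

    fits: dict[int, tuple] = {}
    nrmse_by_rank: dict[int, float] = {}
    init = None
    if init_model is not None:
        if init_model.U.shape[1] != grid[0]:
            raise ValueError("init_model rank does not match the requested rank")
        init = (
            init_model.U.copy(),
            init_model.V.copy(),
            init_model.ceiling,
            init_model.steepness,
            init_model.midpoint,
        )
    for r in grid:
        if init is not None:
            U0, V0, L0, k0, x00 = init
            pad_u = rng.uniform(0.0, 1.0, size=(n, r - U0.shape[1]))
            pad_v = np.zeros((n, r - V0.shape[1]))
            init = (np.hstack([U0, pad_u]), np.hstack([V0, pad_v]), L0, k0, x00)
        best, best_loss, conv = _fit_at_rank(G, mask, r, rng, init, max_iter, tol)
        fits[r] = (best, best_loss, conv)
        nrmse_by_rank[r] = float(np.sqrt(best_loss / max(n_obs, 1)) / denom)
        init = (best[0], best[1], float(best[2][0]), float(best[3][0]), float(best[4][0]))

    min_nrmse = min(nrmse_by_rank.values())
    selected = min(r for r in grid if nrmse_by_rank[r] <= min_nrmse * 1.01 + 1e-12)
    best, best_loss, conv = fits[selected]
    U, V = best[0], best[1]
    ceiling, steepness, midpoint = float(best[2][0]), float(best[3][0]), float(best[4][0])
    denoised = _predict(U, V, ceiling, steepness, midpoint)
    rmse = float(np.sqrt(best_loss / max(n_obs, 1)))
    return RedModel(
        genes=list(inputs.genes),
        U=U,
        V=V,
        ceiling=ceiling,
        steepness=steepness,
        midpoint=midpoint,
        rank=selected,
        nrmse_by_rank=nrmse_by_rank,
        denoised=denoised,
        converged=conv,
        reconstruction_rmse=rmse,
    )


@dataclass
class RelationshipProbs:
    """Four-way relationship probabilities for every ordered gene pair."""

    genes: list[str]
    probs: dict[tuple[str, str], np.ndarray]  # ordered pair -> 4-vector over CLASSES
    sigma: float = 0.0

    def prob(self, u: str, v: str, cls: str) -> float:
        return float(self.probs[(u, v)][CLASSES.index(cls)])

    def as_frame(self):
        import pandas as pd

        rows = [
            {"gene_u": u, "gene_v": v, **{f"p_{c}": float(p[i]) for i, c in enumerate(CLASSES)}}
            for (u, v), p in sorted(self.probs.items())
        ]
        return pd.DataFrame(rows)


def score_relationships(
    model: RedModel,
    inputs: RedInputs,
    sigma: float | None = None,
    partial_penalty: float = 1.0,
    lambda_bounds: tuple[float, float] = (0.05, 0.95),
    sigma_floor: float = 1e-3,
) -> RelationshipProbs:
    """Score the four pairwise relationship hypotheses for every ordered pair.

    For ordered (u, v) with denoised double g = Ghat_uv and singles s_u, s_v:
    predictions are s_u (linear_first), s_v (linear_second), s_u*s_v
    (parallel), and the best interpolation lambda*nearest_single +
    (1-lambda)*product with lambda clamped inside (0, 1) (partial).  Residuals
    become probabilities through a Gaussian likelihood with scale sigma, the
    partial hypothesis paying a one-parameter log-likelihood penalty.  The
    noise scale is max(replicate-based estimate, model reconstruction RMSE,
    floor), so a coarse fit cannot masquerade as a strong call.
    """
    if sigma is None:
        candidates = [sigma_floor, model.reconstruction_rmse]
        if inputs.replicate_sd:
            candidates.append(inputs.replicate_sd)
        sigma = max(candidates)
    if sigma <= 0:
        sigma = sigma_floor
    idx = {g: i for i, g in enumerate(inputs.genes)}
    lam_lo, lam_hi = lambda_bounds
    probs: dict[tuple[str, str], np.ndarray] = {}
    for u in inputs.genes:
        for v in inputs.genes:
            if u == v or np.isnan(inputs.G[idx[u], idx[v]]):
                continue
            g = float(model.denoised[idx[u], idx[v]])
            s_u, s_v = float(inputs.S[idx[u]]), float(inputs.S[idx[v]])
            prod = s_u * s_v
            nearest = s_u if abs(g - s_u) <= abs(g - s_v) else s_v
            if nearest != prod:
                lam = np.clip((g - prod) / (nearest - prod), lam_lo, lam_hi)
            else:
                lam = lam_lo
            preds = np.array([s_u, s_v, prod, lam * nearest + (1.0 - lam) * prod])
            loglik = -((g - preds) ** 2) / (2.0 * sigma**2)
            loglik[3] -= partial_penalty
            loglik -= loglik.max()
            w = np.exp(loglik)
            probs[(u, v)] = w / w.sum()
    return RelationshipProbs(genes=list(inputs.genes), probs=probs, sigma=float(sigma))


@dataclass
class RedNetwork:
    """Directed pathway edges plus undirected partial-interdependence edges."""

    genes: list[str]
    directed_edges: list[tuple[str, str]] = field(default_factory=list)
    undirected_edges: list[Pair] = field(default_factory=list)

    def edge_keys(self) -> set[str]:
        keys = {f"{u}->{v}" for u, v in self.directed_edges}
        keys |= {f"{a}--{b}" for a, b in self.undirected_edges}
        return keys

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.genes)
        for u, v in self.directed_edges:
            g.add_edge(u, v, kind="linear")
        for a, b in self.undirected_edges:
            g.add_edge(a, b, kind="partial")
            g.add_edge(b, a, kind="partial")
        return g


def infer_network(probs: RelationshipProbs, edge_threshold: float = 0.5) -> RedNetwork:
    """Construct the gene network from pairwise relationship probabilities.

    A directed edge u -> v is drawn when P(linear_first) for ordered (u, v)
    exceeds the threshold (u's phenotype masks v's); an undirected edge when
    P(partial) exceeds it; a dominant parallel class draws nothing.
    """
    directed: list[tuple[str, str]] = []
    undirected: list[Pair] = []
    seen: set[Pair] = set()
    for (u, v), p in sorted(probs.probs.items()):
        key: Pair = (u, v) if u < v else (v, u)
        if key in seen:
            continue
        seen.add(key)
        if p[CLASSES.index("linear_first")] > edge_threshold:
            directed.append((u, v))
        elif p[CLASSES.index("linear_second")] > edge_threshold:
            directed.append((v, u))
        elif p[CLASSES.index("partial")] > edge_threshold:
            undirected.append(key)
    return RedNetwork(genes=list(probs.genes), directed_edges=sorted(directed), undirected_edges=sorted(undirected))


def stability_class(fraction: float) -> str:
    """Edge class from its appearance fraction: solid >= 0.40, dashed [0.20, 0.40)."""
    if fraction >= 0.40:
        return "solid"
    if fraction >= 0.20:
        return "dashed"
    return "absent"


@dataclass
class StabilityReport:
    """Per-edge appearance fractions over M noise-perturbed refits."""

    M: int
    noise_grid: list[float]
    per_level: dict[float, dict[str, float]]
    pooled: dict[str, float]

    def classes(self, level: float | None = None) -> dict[str, str]:
        frac = self.pooled if level is None else self.per_level[level]
        return {edge: stability_class(f) for edge, f in frac.items()}


def stability_analysis(
    inputs: RedInputs,
    M: int = 100,
    noise_grid: list[float] | None = None,
    seed: int = 0,
    rank: int | None = None,
    edge_threshold: float = 0.5,
    max_iter: int = 1500,
    rank_grid: list[int] | None = None,
) -> StabilityReport:
    """Re-infer the network on M noise-perturbed copies of G per noise level.

    Independent N(0, sd) noise is added to the observed entries of G
    (symmetrically, clipped at 0) with sd spanning 1e-6 to SD(G)/3 by default;
    each copy is refit at the rank selected on the unperturbed data and its
    edges recorded.  Appearance fractions are reported per level and pooled
    over all runs; classes follow the 40%/20-40% rule.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    mask = ~np.isnan(inputs.G)
    np.fill_diagonal(mask, False)
    sd_g = float(np.std(inputs.G[mask]))
    if noise_grid is None:
        noise_grid = list(np.geomspace(1e-6, max(sd_g / 3.0, 2e-6), 3))
    if min(noise_grid) < 1e-6 - 1e-15 or max(noise_grid) > sd_g / 3.0 + 1e-12:
        raise ValueError("noise grid must lie within [1e-6, SD(G)/3]")
    base = fit_latent_model(inputs, rank_grid=rank_grid, seed=seed, max_iter=max_iter, rank=rank)
    rank = base.rank
    rng = np.random.default_rng(seed)
    n = inputs.G.shape[0]

    per_level: dict[float, dict[str, float]] = {}
    pooled_counts: dict[str, int] = {}
    for sd in noise_grid:
        counts: dict[str, int] = {}
        for run in range(M):
            noise = rng.normal(0.0, sd, size=(n, n))
            noise = 0.5 * (noise + noise.T)
            G_pert = np.where(mask, np.clip(inputs.G + noise, 0.0, None), np.nan)
            pert = RedInputs(
                genes=inputs.genes, G=G_pert, S=inputs.S, H=inputs.H, replicate_sd=inputs.replicate_sd
            )
            # warm-start each refit from the base model so run-to-run variation
            # reflects the injected data noise, not optimizer randomness
            model = fit_latent_model(
                pert, seed=int(rng.integers(2**31)), max_iter=max_iter, rank=rank, init_model=base
            )
            net = infer_network(score_relationships(model, pert), edge_threshold=edge_threshold)
            for key in net.edge_keys():
                counts[key] = counts.get(key, 0) + 1
        per_level[float(sd)] = {k: c / M for k, c in counts.items()}
        for k, c in counts.items():
            pooled_counts[k] = pooled_counts.get(k, 0) + c
    pooled = {k: c / (M * len(noise_grid)) for k, c in pooled_counts.items()}
    return StabilityReport(M=M, noise_grid=[float(s) for s in noise_grid], per_level=per_level, pooled=pooled)
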