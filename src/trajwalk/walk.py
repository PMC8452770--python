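"""Lazy-teleporting random-walk operators and hitting-time pseudotime.

The pseudotime of a cluster is the expected number of steps a lazy-teleporting
random walk started at the root needs to reach it for the first time.  The
walk moves on the cluster graph with row-stochastic matrix ``P = D^-1 W``,
stays put with probability ``1 - x`` (laziness) and relocates uniformly with
probability ``1 - alpha`` (teleportation):

    Z  = x P + (1 - x) I
    Z' = alpha Z + (1 - alpha) (1/n) J

Rather than solving one absorbing linear system per target, hitting times are
obtained in closed form from the eigendecomposition of the symmetric
normalized Laplacian through a personalized-PageRank identity: with
``beta = 2 (1 - alpha) / (2 - alpha)`` and

    R = sum_m  Phi_m Phi_m^T / (beta + 2 x (1 - beta) eta_m)

the quantity ``beta (e_r - e_q)^T D^-1/2 R D^-1/2 e_r`` is, for every target
``r``, exactly proportional to the expected first-hitting step count of the
Z' chain; the proportionality constant is itself spectral, so the closed form
can be reported in expected-step units without solving any linear system
(see docs/methods.md for the derivation).  After the closed-form pass the
edges are forward-biased with a logistic function of the pseudotime
difference, and the pseudotime is refined as the first quartile of
first-visit times over simulated walks on the biased graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .config import WalkConfig
from .errors import DataError, DegenerateParameterError, GraphError, ParameterError
from .graphs import ClusterGraph


@dataclass
class TransitionOperators:
    """Row-stochastic operators P (plain), Z (lazy) and Zprime (lazy-teleporting)."""

    P: np.ndarray
    Z: np.ndarray
    Zprime: np.ndarray


def transition_operators(cg: ClusterGraph, cfg: WalkConfig) -> TransitionOperators:
    """Build P = D^-1 W, Z = xP + (1-x)I and Z' = aZ + (1-a)J/n.

    An isolated single-node component becomes an absorbing self-loop in P; a
    zero-degree node inside a multi-node component is a structural error.
    """
    n = cg.n_nodes
    d = cg.degrees.copy()
    if np.any(d <= 0):
        _, comp = cg.components()
        for i in np.flatnonzero(d <= 0):
            if (comp == comp[i]).sum() > 1:
                raise GraphError(f"node {i} has zero degree inside a multi-node component")
        d[d <= 0] = 1.0  # isolated nodes: self-absorbing rows
    P = cg.W / d[:, None]
    P[cg.degrees <= 0] = 0.0
    P[np.flatnonzero(cg.degrees <= 0), np.flatnonzero(cg.degrees <= 0)] = 1.0
    Z = cfg.x * P + (1.0 - cfg.x) * np.eye(n)
    Zp = cfg.alpha * Z + (1.0 - cfg.alpha) * np.full((n, n), 1.0 / n)
    return TransitionOperators(P, Z, Zp)


@dataclass
class SpectralCache:
    """Eigendecomposition of the normalized Laplacian plus derived operators.

    Built for one connected component of the cluster graph (node indices in
    ``nodes`` refer to the full graph).  ``R`` is the inverse beta-normalized
    Laplacian assembled from *all* eigenpairs.
    """

    nodes: np.ndarray       # component node ids in the full graph
    eta: np.ndarray         # eigenvalues of the normalized Laplacian, in [0, 2]
    Phi: np.ndarray         # eigenvectors (columns)
    beta: float
    x: float
    alpha: float
    degrees: np.ndarray
    R: np.ndarray

    def pagerank(self, seed: np.ndarray) -> np.ndarray:
        """Personalized PageRank vector for a seed distribution over the component."""
        s = np.asarray(seed, dtype=float)
        dm = self.degrees ** -0.5
        core = (self.Phi / ((1 - self.alpha) + self.alpha * self.x * self.eta)) @ self.Phi.T
        return (1 - self.alpha) * ((s * dm) @ core) / dm


def spectral_cache(cg: ClusterGraph, cfg: WalkConfig, component_of: int = 0) -> SpectralCache:
    """Eigendecomposition for the component containing node ``component_of``."""
    _, comp = cg.components()
    nodes = np.flatnonzero(comp == comp[component_of])
    sub = cg.W[np.ix_(nodes, nodes)]
    d = sub.sum(axis=1)
    if len(nodes) == 1:
        d[:] = 1.0
    dm12 = d ** -0.5
    L = np.eye(len(nodes)) - (sub * dm12[:, None]) * dm12[None, :]
    L = 0.5 * (L + L.T)
    eta, Phi = np.linalg.eigh(L)
    eta = np.clip(eta, 0.0, 2.0)
    beta = 2.0 * (1.0 - cfg.alpha) / (2.0 - cfg.alpha)
    denom = beta + 2.0 * cfg.x * (1.0 - beta) * eta
    if np.any(denom <= 1e-14):
        bad = eta[denom <= 1e-14]
        raise DegenerateParameterError(
            f"zero denominator in R for alpha={cfg.alpha}, x={cfg.x}, eta={bad}"
        )
    R = (Phi / denom) @ Phi.T
    return SpectralCache(nodes, eta, Phi, beta, cfg.x, cfg.alpha, d, R)


def closed_form_hitting_times(
    cache: SpectralCache,
    cg: ClusterGraph,
    root: int,
    scale: str = "steps",
) -> np.ndarray:
    """Hitting times from ``root`` to every node of the root's component.

    ``scale="raw"`` returns the literal spectral expression
    ``beta (e_r - e_q)^T D^-1/2 R D^-1/2 e_r``; ``scale="steps"`` (default)
    applies the exact per-target normalization that converts it into the
    expected first-hitting step count of the Z' chain (teleport arrival at
    the target counts as a hit).  Nodes outside the root's component are NaN.
    """
    if scale not in ("raw", "steps"):
        raise ParameterError(f"scale must be 'raw' or 'steps', got {scale!r}")
    if not (0 <= root < cg.n_nodes):
        raise ParameterError(f"root {root} not in graph")
    if root not in cache.nodes:
        raise ParameterError(f"root {root} is outside the cached component")
    nloc = len(cache.nodes)
    loc = {g: i for i, g in enumerate(cache.nodes)}
    r0 = loc[root]
    dm12 = cache.degrees ** -0.5
    S = (cache.R * dm12[:, None]) * dm12[None, :]
    # raw Eq-style hitting time from q to every target r: H[q, r]
    H = cache.beta * (np.diag(S)[None, :] - S)
    if scale == "steps":
        alpha, x = cache.alpha, cache.x
        if alpha >= 1.0:
            raise DegenerateParameterError("step-scale conversion requires alpha < 1")
        # G = [(1-a) I + a x L]^-1 diagonal, from the same eigenpairs
        Gdiag = (cache.Phi ** 2 / ((1 - alpha) + alpha * x * cache.eta)).sum(axis=1)
        A = H * (cache.degrees[None, :] / ((1 - alpha) ** 2 * Gdiag[None, :]))
        Sa = A.sum(axis=0)
        c = (1 - alpha) * Sa / nloc
        H = A * (1.0 + c / (1.0 - c))[None, :]
    t = np.full(cg.n_nodes, np.nan)
    t[cache.nodes] = H[r0]
    t[root] = 0.0
    return t


@dataclass
class PseudotimeVector:
    """Root-anchored pseudotime per cluster: closed form and MCMC-refined."""

    t_closed: np.ndarray
    t_refined: np.ndarray | None = None
    root: int = 0

    def best(self) -> np.ndarray:
        return self.t_refined if self.t_refined is not None else self.t_closed


@dataclass
class DirectedClusterGraph:
    """Forward-biased view of a cluster graph.

    ``multipliers[i, j]`` is the logistic factor applied to the undirected
    weight for the i -> j orientation; the two orientations of every edge sum
    to one.  ``W_directed = W * multipliers`` and ``T`` is its row-normalized
    transition matrix (dead-end rows become self-loops).
    """

    W_undirected: np.ndarray
    multipliers: np.ndarray
    t: np.ndarray
    W_directed: np.ndarray = field(init=False)
    T: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.W_directed = self.W_undirected * self.multipliers
        rowsum = self.W_directed.sum(axis=1)
        T = np.zeros_like(self.W_directed)
        ok = rowsum > 0
        T[ok] = self.W_directed[ok] / rowsum[ok, None]
        dead = np.flatnonzero(~ok)
        T[dead, dead] = 1.0
        self.T = T

    @property
    def n_nodes(self) -> int:
        return self.W_undirected.shape[0]

    def forward_view(self, threshold: float = 0.5):
        """Directed graph keeping orientations with multiplier >= threshold."""
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(range(self.n_nodes))
        src, dst = np.nonzero((self.W_undirected > 0) & (self.multipliers >= threshold))
        g.add_edges_from(zip(src.tolist(), dst.tolist()))
        return g


def forward_bias_edges(
    cg: ClusterGraph,
    t: np.ndarray | PseudotimeVector,
    cfg: WalkConfig,
    time_scale: float | None = None,
) -> DirectedClusterGraph:
    """Bias each undirected edge toward its later-pseudotime endpoint.

    The i -> j orientation receives the multiplier
    ``f = 1 / (1 + exp(-b (t_j - t_i)))`` so that edges pointing forward in
    pseudotime get more than half the undirected weight and the two
    orientations always sum to one.  ``time_scale`` optionally rescales the
    pseudotime range to ``[0, time_scale]`` before the logistic is applied
    (the pipeline uses 10 so that b = 1 gives a soft, non-saturated bias).
    """
    tv = t.best() if isinstance(t, PseudotimeVector) else np.asarray(t, dtype=float)
    if len(tv) != cg.n_nodes:
        raise DataError("pseudotime must cover every node of the graph")
    # NaN entries are tolerated only on whole untimed components: an edge
    # linking a timed and an untimed node means a genuinely missing value.
    src, dst = np.nonzero(cg.W > 0)
    half_missing = np.isnan(tv[src]) != np.isnan(tv[dst])
    if half_missing.any():
        raise DataError("pseudotime entry missing for a connected node")
    ts = tv.copy()
    if time_scale is not None:
        rng_ = np.nanmax(ts) - np.nanmin(ts)
        if rng_ > 0:
            ts = (ts - np.nanmin(ts)) * (time_scale / rng_)
    dt = ts[None, :] - ts[:, None]  # dt[i, j] = t_j - t_i
    with np.errstate(over="ignore", invalid="ignore"):
        mult = 1.0 / (1.0 + np.exp(-cfg.b * dt))
    mult = np.nan_to_num(mult, nan=0.5)
    np.fill_diagonal(mult, 0.0)
    return DirectedClusterGraph(cg.W.copy(), mult, tv)


def _simulate_walks(
    dg: DirectedClusterGraph,
    root: int,
    cfg: WalkConfig,
    rng: np.random.Generator,
    absorb_at: int | None = None,
    count_visits: bool = False,
    stop_when_all_visited: bool = False,
):
    """Vectorised lazy-teleporting walks on the biased transition matrix.

    Every walk starts at ``root`` (a visit at step 0).  Per step a walk
    teleports uniformly with probability ``1 - alpha`` (the arrival counts as
    a step and a visit), otherwise stays with probability ``1 - x``, otherwise
    moves according to ``dg.T``.  Returns ``(first_visit, visits, success)``:
    first-visit step counts (-1 if never), optional per-walk visit counts and,
    when ``absorb_at`` is set, whether each walk reached that node.
    """
    n = dg.n_nodes
    n_walks = cfg.n_mcmc
    max_steps = cfg.resolve_max_steps(n)
    cum = np.cumsum(dg.T, axis=1)
    first_visit = np.full((n_walks, n), -1, dtype=np.int64)
    first_visit[:, root] = 0
    visits = np.zeros((n_walks, n), dtype=np.int64) if count_visits else None
    if count_visits:
        visits[:, root] = 1
    state = np.full(n_walks, root, dtype=np.int64)
    active = np.ones(n_walks, dtype=bool)
    if absorb_at is not None and root == absorb_at:
        active[:] = False
    p_tele = 1.0 - cfg.alpha
    p_stay = cfg.alpha * (1.0 - cfg.x)
    for step in range(1, max_steps + 1):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        s = state[idx]
        u = rng.random(len(idx))
        new = s.copy()
        tele = u < p_tele
        if tele.any():
            new[tele] = rng.integers(0, n, size=int(tele.sum()))
        move = u >= p_tele + p_stay
        if move.any():
            mi = np.flatnonzero(move)
            r = rng.random(len(mi))
            rows = cum[s[mi]]
            new[mi] = (rows < r[:, None]).sum(axis=1).clip(max=n - 1)
        state[idx] = new
        fv = first_visit[idx, new]
        fresh = fv < 0
        if fresh.any():
            first_visit[idx[fresh], new[fresh]] = step
        if count_visits:
            visits[idx, new] += 1
        if absorb_at is not None:
            active[idx[new == absorb_at]] = False
        elif stop_when_all_visited:
            done = first_visit[idx].min(axis=1) >= 0
            active[idx[done]] = False
    success = first_visit[:, absorb_at] >= 0 if absorb_at is not None else None
    return first_visit, visits, success


def mcmc_refine_pseudotime(
    dg: DirectedClusterGraph, root: int, cfg: WalkConfig
) -> np.ndarray:
    """Refined pseudotime: first quartile of first-visit steps over n_mcmc walks.

    The quartile uses the linearly interpolated quantile definition.  Nodes
    no walk ever reached fall back to an affine rescaling of their biasing
    pseudotime onto the refined scale, with a warning.
    """
    if cfg.n_mcmc < 1:
        raise ParameterError("n_mcmc must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    first_visit, _, _ = _simulate_walks(
        dg, root, cfg, rng, stop_when_all_visited=True
    )
    n = dg.n_nodes
    t_ref = np.full(n, np.nan)
    for node in range(n):
        col = first_visit[:, node]
        hit = col[col >= 0]
        if len(hit):
            t_ref[node] = np.percentile(hit, 25.0)
    unvisited = np.isnan(t_ref)
    if unvisited.any():
        warnings.warn(
            f"{int(unvisited.sum())} node(s) never visited in {cfg.n_mcmc} walks; "
            "falling back to rescaled closed-form pseudotime",
            stacklevel=2,
        )
        src = dg.t
        vis = ~unvisited & np.isfinite(src)
        if vis.sum() >= 2 and np.ptp(src[vis]) > 0:
            A = np.vstack([src[vis], np.ones(vis.sum())]).T
            coef, *_ = np.linalg.lstsq(A, t_ref[vis], rcond=None)
            t_ref[unvisited] = coef[0] * src[unvisited] + coef[1]
        else:
            t_ref[unvisited] = np.nanmax(t_ref) if np.isfinite(t_ref).any() else 0.0
    t_ref[root] = 0.0
    return t_ref


def compute_pseudotime(
    cg: ClusterGraph,
    root: int,
    cfg: WalkConfig,
    time_scale: float | None = 10.0,
    scale: str = "steps",
) -> tuple[PseudotimeVector, DirectedClusterGraph]:
    """Closed-form hitting times, forward bias, then MCMC refinement.

    Operates on the connected component containing ``root``; other nodes keep
    NaN pseudotime (the pipeline runs each component with its own root).
    """
    cache = spectral_cache(cg, cfg, component_of=root)
    t_closed = closed_form_hitting_times(cache, cg, root, scale=scale)
    dg = forward_bias_edges(cg, t_closed, cfg, time_scale=time_scale)
    t_refined = mcmc_refine_pseudotime(dg, root, cfg)
    t_refined[np.isnan(t_closed)] = np.nan
    return PseudotimeVector(t_closed, t_refined, root), dg
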