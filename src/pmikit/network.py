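"""Co-expression graph construction and MCODE-style kernel detection.

Genes whose time-course profiles correlate strongly and positively
(default r > 0.95, p < 0.001 at n = 7) are linked into an undirected
graph; dense kernels of that graph are then extracted with the MCODE
molecular-complex-detection scheme:

1. *vertex weighting* — for each vertex, take the subgraph induced by the
   vertex and its neighbours, find its highest k-core, and set
   ``weight = k_max * density(k-core)``;
2. *greedy expansion* — seeds are visited in decreasing weight order; a
   breadth-first search adds unvisited neighbours whose weight is at
   least ``seed_weight * (1 - vwp)`` (vertex weight percentage, default
   0.2); vertices are never reused, so kernels are disjoint;
3. *post-processing* — the haircut step trims members outside the
   cluster's 2-core (default on); the fluff step optionally pads the
   cluster with dense unclaimed neighbourhoods (default off).

Correlations are computed on log2(x + pseudocount) by default: for
exponential decay or saturating-rise kinetics the log profile makes
co-regulated genes correlate regardless of their individual rate
constants. Only positive correlations form edges, so reciprocal falling
(neuronal) and rising (glial) kernels stay separate.

Cluster profiles are summarized as the weighted mean of time-0-normalized
member profiles with a weighted standard error of the mean using the
effective sample size ``n_eff = (sum w)^2 / sum w^2``.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import networkx as nx
import numpy as np
from scipy import stats

from .containers import GeneSet, TimeCourseMatrix

log = logging.getLogger(__name__)

__all__ = [
    "CorrelationGraph",
    "MCODEParams",
    "Cluster",
    "correlation_graph",
    "correlation_pvalue",
    "mcode_vertex_weights",
    "mcode_find_clusters",
    "summarize_cluster",
]

RISING = "rising"
FALLING = "falling"


@dataclass(frozen=True)
class CorrelationGraph:
    """Thresholded Pearson co-expression graph over time-course profiles."""

    graph: nx.Graph
    r_min: float = 0.95
    p_max: float = 0.001
    n_obs: int = 7

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass(frozen=True)
class MCODEParams:
    """MCODE tuning knobs (Cytoscape-plugin defaults)."""

    vwp: float = 0.2
    haircut: bool = True
    fluff: bool = False
    fluff_density: float = 0.1
    min_core: int = 2

    def validate(self) -> None:
        if not 0.0 <= self.vwp < 1.0:
            raise ValueError("vwp must be in [0, 1)")
        if not 0.0 <= self.fluff_density <= 1.0:
            raise ValueError("fluff_density must be in [0, 1]")
        if self.min_core < 1:
            raise ValueError("min_core must be >= 1")


@dataclass(frozen=True)
class Cluster:
    """A detected co-expression kernel."""

    members: frozenset[str]
    seed_gene: str
    score: float  #: density x size of the member-induced subgraph
    direction: str | None = None  #: rising | falling (filled by summarize_cluster)
    mean_profile: tuple[float, ...] | None = None
    profile_sem: tuple[float, ...] | None = None

    def __len__(self) -> int:
        return len(self.members)


def correlation_pvalue(
    r: float | np.ndarray, n_obs: int, alternative: str = "greater"
) -> float | np.ndarray:
    """P-value of a Pearson correlation via the exact t-transform.

    ``t = r * sqrt((n - 2) / (1 - r^2))`` with n - 2 degrees of freedom.
    ``alternative="greater"`` (default) tests the positive tail — the
    matched test for a graph that only links positively correlated genes,
    and the only convention under which r > 0.95 at n = 7 implies
    p < 0.001; ``"two-sided"`` doubles the tail of |t|.
    """
    if n_obs < 3:
        raise ValueError("need >= 3 observations")
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    df = n_obs - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r * r))
    if alternative == "greater":
        p = stats.t.sf(t, df)
        p = np.where(np.isclose(r, 1.0), 0.0, p)
    elif alternative == "two-sided":
        p = 2.0 * stats.t.sf(np.abs(t), df)
        p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(p) if p.ndim == 0 else p


def correlation_graph(
    tc: TimeCourseMatrix,
    candidate_genes: GeneSet | None = None,
    r_min: float = 0.95,
    p_max: float = 0.001,
    log_transform: bool = True,
    pseudocount: float = 1.0,
) -> CorrelationGraph:
    """Build the positively-thresholded Pearson co-expression graph.

    An edge (a, b) is kept iff ``r_ab > r_min`` (positive correlations
    only) and the positive-tail p-value is below ``p_max``; both
    thresholds are enforced even where one implies the other.
    Zero-variance genes cannot carry a correlation and are excluded with
    a warning.
    """
    if candidate_genes is not None:
        missing = set(candidate_genes.members) - set(tc.gene_ids)
        if missing:
            raise ValueError(f"candidate genes absent from matrix: {sorted(missing)[:5]}")
        genes = sorted(candidate_genes.members)
        sub = tc.subset(genes)
    else:
        genes = tc.gene_ids
        sub = tc
    n_obs = int(sub.timepoints_h.size)
    if n_obs < 3:
        raise ValueError("need >= 3 time points")

    x = sub.values
    if log_transform:
        x = np.log2(x + pseudocount)
    sd = x.std(axis=1)
    keep = sd > 0
    dropped = [g for g, k in zip(genes, keep) if not k]
    if dropped:
        warnings.warn(
            f"excluding {len(dropped)} zero-variance gene(s) from the correlation graph",
            stacklevel=2,
        )
    genes = [g for g, k in zip(genes, keep) if k]
    x = x[keep]

    g = nx.Graph()
    g.add_nodes_from(genes)
    if len(genes) >= 2:
        r = np.corrcoef(x)
        iu, ju = np.triu_indices(len(genes), k=1)
        rv = r[iu, ju]
        strong = rv > r_min
        iu, ju, rv = iu[strong], ju[strong], rv[strong]
        pv = correlation_pvalue(rv, n_obs)
        hit = pv < p_max
        for a, b, rr, pp in zip(iu[hit], ju[hit], rv[hit], pv[hit]):
            g.add_edge(genes[a], genes[b], r=float(rr), p=float(pp))
    return CorrelationGraph(graph=g, r_min=r_min, p_max=p_max, n_obs=n_obs)


def _as_graph(g: CorrelationGraph | nx.Graph) -> nx.Graph:
    return g.graph if isinstance(g, CorrelationGraph) else g


def _core_numbers(adj: dict) -> dict:
    """Core numbers by min-degree peeling (Batagelj-Zaversnik) on a plain
    adjacency dict; much faster than subgraph views for dense
    neighbourhoods."""
    from collections import defaultdict

    deg = {u: len(n) for u, n in adj.items()}
    buckets: dict[int, set] = defaultdict(set)
    for u, d in deg.items():
        buckets[d].add(u)
    core: dict = {}
    removed: set = set()
    cur = 0
    for _ in range(len(adj)):
        while not buckets[cur]:
            cur += 1
        u = buckets[cur].pop()
        core[u] = cur
        removed.add(u)
        for w in adj[u]:
            if w in removed:
                continue
            dw = deg[w]
            if dw > cur:
                buckets[dw].discard(w)
                deg[w] = dw - 1
                buckets[dw - 1].add(w)
    return core


def mcode_vertex_weights(g: CorrelationGraph | nx.Graph) -> dict[str, float]:
    """MCODE vertex weight: highest-k-core density of the closed neighbourhood.

    For each vertex v, the subgraph induced by {v} + neighbours(v) is
    reduced to its highest k-core; the weight is ``k_max`` times that
    core's edge density. Isolated vertices weigh 0.
    """
    graph = _as_graph(g)
    adj = {v: set(graph.neighbors(v)) for v in graph.nodes}
    weights: dict[str, float] = {}
    for v, nbrs in adj.items():
        if not nbrs:
            weights[v] = 0.0
            continue
        nodes = nbrs | {v}
        iadj = {u: adj[u] & nodes for u in nodes}
        core = _core_numbers(iadj)
        k_max = max(core.values())
        core_set = {u for u, k in core.items() if k >= k_max}
        m = len(core_set)
        possible = m * (m - 1) / 2
        edges = sum(len(iadj[u] & core_set) for u in core_set) // 2
        weights[v] = k_max * (edges / possible if possible else 0.0)
    return weights


def _cluster_score(graph: nx.Graph, members: set[str]) -> float:
    sub = graph.subgraph(members)
    m = sub.number_of_nodes()
    possible = m * (m - 1) / 2
    density = sub.number_of_edges() / possible if possible else 0.0
    return density * m


def mcode_find_clusters(
    g: CorrelationGraph | nx.Graph,
    params: MCODEParams | None = None,
    weights: dict[str, float] | None = None,
) -> list[Cluster]:
    """Greedy seeded expansion into disjoint dense kernels.

    Returns clusters sorted by score (density x size) descending, ties
    broken by smallest member gene ID. Clusters whose induced subgraph
    has no ``min_core``-core are discarded.
    """
    params = params or MCODEParams()
    params.validate()
    graph = _as_graph(g)
    if graph.number_of_nodes() == 0:
        return []
    if weights is None:
        weights = mcode_vertex_weights(graph)

    visited: set[str] = set()
    clusters: list[Cluster] = []
    seeds = sorted(graph.nodes, key=lambda v: (-weights[v], v))
    for seed in seeds:
        if seed in visited or weights[seed] <= 0:
            continue
        threshold = weights[seed] * (1.0 - params.vwp)
        members = {seed}
        visited.add(seed)
        queue = [seed]
        while queue:
            v = queue.pop(0)
            for u in sorted(graph.neighbors(v)):
                if u in visited:
                    continue
                if weights[u] >= threshold:
                    visited.add(u)
                    members.add(u)
                    queue.append(u)

        if params.haircut:
            core2 = nx.k_core(graph.subgraph(members), 2)
            members = set(core2.nodes)
        if params.fluff:
            members = _fluff(graph, members, visited, params.fluff_density)
        if not members:
            continue
        sub = graph.subgraph(members)
        if not sub.number_of_edges():
            continue
        if max(nx.core_number(sub).values()) < params.min_core:
            continue
        clusters.append(
            Cluster(
                members=frozenset(members),
                seed_gene=seed,
                score=_cluster_score(graph, members),
            )
        )
    clusters.sort(key=lambda c: (-c.score, min(c.members)))
    return clusters


def _fluff(graph: nx.Graph, members: set[str], visited: set[str],
           fluff_density: float) -> set[str]:
    """Pad a cluster with unclaimed neighbours whose neighbourhoods are dense.

    Disjointness is preserved: fluffed vertices are marked visited.
    """
    added = set()
    for v in sorted(members):
        for u in sorted(graph.neighbors(v)):
            if u in visited or u in members or u in added:
                continue
            nbh = graph.subgraph([u, *graph.neighbors(u)])
            m = nbh.number_of_nodes()
            possible = m * (m - 1) / 2
            density = nbh.number_of_edges() / possible if possible else 0.0
            if density > fluff_density:
                added.add(u)
    visited.update(added)
    return members | added


def summarize_cluster(
    tc: TimeCourseMatrix,
    cluster: Cluster,
    weights: dict[str, float] | None = None,
    weight_scheme: str = "mean_expression",
    pseudocount: float = 1.0,
) -> Cluster:
    """Fill a cluster's time profile, weighted SEM and direction label.

    Per member the profile is ``(x(t) + c) / (x(0) + c)``; the cluster
    profile is the weighted mean with weights given by ``weight_scheme``:
    ``mean_expression`` (default), ``uniform`` or ``vertex_weight`` (uses
    the supplied MCODE weights). The weighted SEM uses reliability-weight
    variance (reducing to the ordinary ddof=1 SEM for equal weights) and
    the effective sample size ``n_eff = (sum w)^2 / sum w^2``. Direction
    is ``rising`` when the Spearman correlation of the mean profile with
    time is >= 0, else ``falling``.
    """
    members = sorted(cluster.members)
    missing = [gene for gene in members if gene not in tc.data.index]
    if missing:
        raise KeyError(f"cluster members absent from matrix: {missing[:5]}")
    x = tc.data.loc[members].to_numpy(dtype=float)
    profiles = (x + pseudocount) / (x[:, [0]] + pseudocount)

    if weight_scheme == "uniform":
        w = np.ones(len(members))
    elif weight_scheme == "mean_expression":
        w = x.mean(axis=1)
    elif weight_scheme == "vertex_weight":
        if weights is None:
            raise ValueError("weight_scheme='vertex_weight' requires MCODE weights")
        w = np.array([weights.get(gene, 0.0) for gene in members], dtype=float)
    else:
        raise ValueError(f"unknown weight_scheme {weight_scheme!r}")
    if not np.all(w >= 0) or w.sum() <= 0:
        raise ValueError("cluster weights must be non-negative with positive sum")

    wsum = w.sum()
    mean = (w[:, None] * profiles).sum(axis=0) / wsum
    n_eff = wsum**2 / np.sum(w**2)
    # reliability-weight variance; equals the ddof=1 sample variance for
    # equal weights
    denom = wsum - np.sum(w**2) / wsum
    if denom > 0:
        var = (w[:, None] * (profiles - mean[None, :]) ** 2).sum(axis=0) / denom
        sem = np.sqrt(var / n_eff)
    else:
        sem = np.zeros_like(mean)

    t = tc.timepoints_h
    if np.allclose(mean, mean[0]):
        rho = 0.0
    else:
        rho = stats.spearmanr(t, mean).statistic
    direction = RISING if rho >= 0 else FALLING
    return replace(
        cluster,
        direction=direction,
        mean_profile=tuple(float(v) for v in mean),
        profile_sem=tuple(float(v) for v in sem),
    )
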