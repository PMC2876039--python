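"""P-value-thresholded similarity graphs and force-directed embeddings.

The graph keeps one undirected attraction edge per HSP whose P-value passes
the cutoff; the attraction is ``-log10(max(P, p_floor))`` normalised by the
maximum attraction in the graph, so edge weights lie in (0, 1].  The layout
is a deterministic synchronous force simulation: each edge pulls its
endpoints together with a spring force ``k_a * a_ij * d`` and every node
pair repels with ``k_r / d``; displacements are capped and cooled each
round.  That force law is the negative gradient of

    U = sum_edges k_a * a_ij * d^2 / 2  -  sum_pairs k_r * ln d

which gives a closed-form two-node equilibrium ``d* = sqrt(k_r/(k_a*a))``
used by the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pairwise_similarity import HSP

__all__ = ["SimilarityGraph", "LayoutParams", "LayoutState",
           "build_graph", "layout_step", "run_layout", "energy"]


@dataclass(frozen=True)
class SimilarityGraph:
    """Nodes, thresholded attraction edges and the cutoff that built them."""

    nodes: tuple                    # ordered node ids
    edges: np.ndarray               # (E, 2) int indices into nodes, i < j
    attractions: np.ndarray         # (E,) in (0, 1]
    pvalues: np.ndarray             # (E,) raw P-values
    p_cutoff: float
    p_floor: float

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def index(self) -> dict:
        return {n: i for i, n in enumerate(self.nodes)}

    def subgraph(self, keep_ids) -> "SimilarityGraph":
        keep = set(keep_ids)
        new_nodes = tuple(n for n in self.nodes if n in keep)
        remap = {}
        for i, n in enumerate(self.nodes):
            if n in keep:
                remap[i] = len(remap)
        sel = [k for k, (i, j) in enumerate(self.edges)
               if i in remap and j in remap]
        edges = np.array([[remap[i], remap[j]] for i, j in self.edges[sel]],
                         dtype=int).reshape(len(sel), 2)
        return SimilarityGraph(new_nodes, edges, self.attractions[sel],
                               self.pvalues[sel], self.p_cutoff, self.p_floor)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for (i, j), a, p in zip(self.edges, self.attractions, self.pvalues):
            g.add_edge(self.nodes[i], self.nodes[j], attraction=float(a),
                       pvalue=float(p))
        return g


def build_graph(
    hsps,
    p_cutoff: float,
    p_floor: float = 1e-200,
    nodes=None,
) -> SimilarityGraph:
    """Filter HSPs at a P-value cutoff and normalise attractions.

    ``nodes`` fixes the node set and order explicitly (all sequences in the
    analysis, including ones with no significant edge); if omitted, the
    node set is collected from the HSPs in first-seen order.
    """
    if not (0.0 < p_cutoff <= 1.0):
        raise ValueError("p_cutoff must lie in (0, 1]")
    if nodes is None:
        seen = []
        have = set()
        for h in hsps:
            for n in (h.query_id, h.subject_id):
                if n not in have:
                    have.add(n)
                    seen.append(n)
        nodes = tuple(seen)
    else:
        nodes = tuple(nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    epairs, pvals = [], []
    for h in hsps:
        if h.query_id == h.subject_id:
            continue
        if h.pvalue <= p_cutoff:
            i, j = idx[h.query_id], idx[h.subject_id]
            epairs.append((min(i, j), max(i, j)))
            pvals.append(h.pvalue)
    edges = np.array(epairs, dtype=int).reshape(len(epairs), 2)
    pvals = np.array(pvals, dtype=float)
    attr = -np.log10(np.maximum(pvals, p_floor))
    if len(attr):
        attr = attr / attr.max()
    return SimilarityGraph(nodes, edges, attr, pvals, p_cutoff, p_floor)


@dataclass(frozen=True)
class LayoutParams:
    """Force constants and schedule of the embedding."""

    dims: int = 2
    attract_factor: float = 1.0
    repulse_factor: float = 1.0
    max_move: float = 0.3
    cooling: float = 0.98
    rounds: int = 500
    convergence_tol: float = 1e-4
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.dims not in (2, 3):
            raise ValueError("dims must be 2 or 3")
        if self.attract_factor <= 0 or self.repulse_factor <= 0:
            raise ValueError("force factors must be positive")
        if not (0.0 < self.cooling <= 1.0):
            raise ValueError("cooling must lie in (0, 1]")


@dataclass
class LayoutState:
    """Coordinates plus bookkeeping of the running simulation."""

    coords: np.ndarray          # (n, dims)
    round: int = 0
    last_mean_displacement: float = float("inf")


def _forces(coords: np.ndarray, graph: SimilarityGraph,
            params: LayoutParams, rng: np.random.Generator) -> np.ndarray:
    n = coords.shape[0]
    f = np.zeros_like(coords)
    diff = coords[None, :, :] - coords[:, None, :]   # diff[i, j] = x_j - x_i
    d = np.linalg.norm(diff, axis=2)
    coincident = (d < 1e-12) & ~np.eye(n, dtype=bool)
    if coincident.any():
        jitter = rng.normal(size=coords.shape)
        jitter /= np.linalg.norm(jitter, axis=1, keepdims=True)
        coords = coords + 1e-6 * jitter
        diff = coords[None, :, :] - coords[:, None, :]
        d = np.linalg.norm(diff, axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        unit = diff / d[:, :, None]
    unit[np.arange(n), np.arange(n), :] = 0.0
    # repulsion k_r / d away from every other node
    rep = params.repulse_factor / np.where(d > 0, d, np.inf)
    f -= (rep[:, :, None] * unit).sum(axis=1)
    # attraction k_a * a * d along each edge
    if len(graph.edges):
        i = graph.edges[:, 0]
        j = graph.edges[:, 1]
        pull = (params.attract_factor * graph.attractions)[:, None] * (
            coords[j] - coords[i]
        )
        np.add.at(f, i, pull)
        np.add.at(f, j, -pull)
    return f


def layout_step(state: LayoutState, graph: SimilarityGraph,
                params: LayoutParams) -> LayoutState:
    """One synchronous update (forces evaluated on the old coordinates)."""
    rng = np.random.default_rng(params.rng_seed + 104729 * (state.round + 1))
    f = _forces(state.coords, graph, params, rng)
    cap = params.max_move * params.cooling ** state.round
    norms = np.linalg.norm(f, axis=1, keepdims=True)
    scale = np.where(norms > cap, cap / np.where(norms > 0, norms, 1.0), 1.0)
    move = f * scale
    coords = state.coords + move
    disp = float(np.linalg.norm(move, axis=1).mean()) if len(coords) else 0.0
    return LayoutState(coords, state.round + 1, disp)


def run_layout(graph: SimilarityGraph, params: LayoutParams) -> LayoutState:
    """Seeded initialisation + cooled iteration until convergence.

    Coordinates start uniform in the unit cube; iteration stops when the
    mean displacement drops below ``convergence_tol`` or ``rounds`` is
    exhausted.  Fully reproducible from ``rng_seed``.
    """
    if graph.n_nodes == 0:
        raise ValueError("cannot lay out an empty graph")
    rng = np.random.default_rng(params.rng_seed)
    coords = rng.uniform(0.0, 1.0, size=(graph.n_nodes, params.dims))
    state = LayoutState(coords)
    for _ in range(params.rounds):
        state = layout_step(state, graph, params)
        if state.last_mean_displacement < params.convergence_tol:
            break
    return state


def energy(state: LayoutState, graph: SimilarityGraph,
           params: LayoutParams) -> float:
    """Potential whose negative gradient is the layout force law.

    ``sum_edges k_a*a*d^2/2 - sum_pairs k_r*ln d``; coincident nodes make
    the repulsion term infinite, reported as ``inf``.
    """
    coords = state.coords
    n = coords.shape[0]
    e = 0.0
    if len(graph.edges):
        i = graph.edges[:, 0]
        j = graph.edges[:, 1]
        d = np.linalg.norm(coords[i] - coords[j], axis=1)
        e += float((params.attract_factor * graph.attractions * d ** 2 / 2.0).sum())
    if n >= 2:
        diff = coords[None, :, :] - coords[:, None, :]
        d = np.linalg.norm(diff, axis=2)
        iu = np.triu_indices(n, k=1)
        dv = d[iu]
        if (dv < 1e-300).any():
            return float("inf")
        e -= float(params.repulse_factor * np.log(dv).sum())
    return e
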