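"""Edge filtering, minimum-spanning-tree hub extraction, gene-list intersection.

Edge weights (co-expression strength) are mapped to distances
``d = 1 - w / max(w)`` so the spanning forest keeps the strongest links;
hub genes are the forest's highest-degree nodes.  MST betweenness is
available as an alternative hub score.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import networkx as nx

from .datatypes import GeneList, GeneNetwork, ValidationError

logger = logging.getLogger(__name__)


def filter_edges(net: GeneNetwork, top_frac: float) -> GeneNetwork:
    """Keep the ceil(top_frac * |E|) highest-weight edges; drop isolated nodes.

    Weight ties are broken by the lexicographic (sorted) node pair, so the
    result is deterministic.
    """
    if not 0 < top_frac <= 1:
        raise ValueError(f"top_frac must be in (0, 1] (got {top_frac})")
    if net.n_edges == 0:
        raise ValidationError("cannot filter an empty graph")
    edges = sorted(net.edge_weights(), key=lambda e: (-e[2], e[0], e[1]))
    keep = edges[: math.ceil(top_frac * len(edges))]
    g = nx.Graph()
    for u, v, w in keep:
        g.add_edge(u, v, weight=w)
    logger.info("filter_edges: kept %d/%d edges, %d/%d nodes",
                g.number_of_edges(), net.n_edges, g.number_of_nodes(), net.n_nodes)
    return GeneNetwork(g)


@dataclass
class HubResult:
    filtered_net: GeneNetwork
    mst_edges: list[tuple[str, str, float]]  # (u, v, distance), u < v, sorted
    hub_scores: dict[str, float]
    hubs: GeneList


def mst_hubs(net: GeneNetwork, n_hubs: int = 30,
             score: str = "degree") -> HubResult:
    """Minimum spanning forest on d = 1 - w/max(w); hubs = top-n by forest score.

    ``score`` is the node degree in the forest (default) or ``betweenness``
    within the forest.  Ties are broken alphabetically.
    """
    if net.n_edges == 0:
        raise ValidationError("mst_hubs needs at least one edge")
    if score not in ("degree", "betweenness"):
        raise ValueError(f"unknown hub score {score!r}")
    wmax = max(w for _, _, w in net.edge_weights())
    if wmax <= 0:
        raise ValidationError("all edge weights are zero")
    h = nx.Graph()
    h.add_nodes_from(sorted(net.graph.nodes))
    for u, v, w in net.edge_weights():  # sorted insertion -> deterministic ties
        h.add_edge(u, v, dist=1.0 - w / wmax, weight=w)
    forest = nx.minimum_spanning_tree(h, weight="dist", algorithm="kruskal")
    mst_edges = sorted(
        (min(u, v), max(u, v), float(d)) for u, v, d in forest.edges(data="dist")
    )
    if score == "degree":
        scores = {g: float(d) for g, d in forest.degree()}
    else:
        scores = {g: float(b) for g, b in
                  nx.betweenness_centrality(forest, normalized=True).items()}
    order = sorted(scores, key=lambda g: (-scores[g], g))
    if n_hubs > len(order):
        warnings.warn(
            f"n_hubs={n_hubs} exceeds node count {len(order)}; returning all nodes",
            UserWarning, stacklevel=2,
        )
        n_hubs = len(order)
    hubs = GeneList(order[:n_hubs], label=f"mst_{score}_hubs")
    return HubResult(net, mst_edges, scores, hubs)


def intersect_lists(a: GeneList, b: GeneList) -> GeneList:
    """Order-preserving (by ``a``) intersection of two gene lists."""
    in_b = set(b)
    common = [g for g in a if g in in_b]
    logger.info("intersect: %d of %d (a) x %d (b) genes shared",
                len(common), len(a), len(b))
    return GeneList(common, label=f"{a.label}&{b.label}")
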