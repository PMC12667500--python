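"""Interaction-network construction and hub-gene ranking.

The hub statistic is score = log2(degree + 1) * closeness, computed on the
unweighted simple graph.  Closeness follows the component-restricted
convention: for node v with reachable set R(v) (excluding v itself),
c(v) = |R(v)| / sum of shortest-path distances to R(v) — the reciprocal of
the mean distance to reachable nodes; isolated nodes get 0.  Hubs are
ranked within each regulation direction by descending score, ties broken
by degree then node id.
"""

from __future__ import annotations

import math

import networkx as nx
import pandas as pd

from .errors import ValidationError
from .io import EdgeList

DIRECTIONS = ("up", "down")

HUB_COLUMNS = ["node", "degree", "closeness", "score", "direction"]


def build_graph(
    edges: EdgeList | nx.Graph,
    restrict_to: set[str] | None = None,
    keep_isolated: bool = False,
) -> nx.Graph:
    """Simple undirected graph, optionally induced on ``restrict_to``.

    By default only genes that participate in at least one retained edge
    become nodes; ``keep_isolated=True`` retains every listed gene as a
    degree-0 node instead.
    """
    g = nx.Graph()
    pairs = edges.edges if isinstance(edges, EdgeList) else edges.edges()
    for a, b in pairs:
        if a == b:
            continue
        if restrict_to is None or (a in restrict_to and b in restrict_to):
            g.add_edge(a, b)
    if keep_isolated and restrict_to is not None:
        g.add_nodes_from(restrict_to)
    return g


def closeness(g: nx.Graph) -> dict[str, float]:
    """Component-restricted closeness centrality via unweighted BFS."""
    return nx.closeness_centrality(g, wf_improved=False)


def ppi_score(degree: int, closeness_value: float) -> float:
    """score = log2(degree + 1) * closeness."""
    if degree < 0 or closeness_value < 0:
        raise ValidationError("degree and closeness must be nonnegative")
    return math.log2(degree + 1) * closeness_value


def hub_table(g: nx.Graph, direction_of: dict[str, str]) -> pd.DataFrame:
    """Per-node degree, closeness, PPI score and regulation direction.

    ``direction_of`` maps gene id -> ``up``/``down`` (inherited from the
    DEG sets the network was built over).
    """
    bad = {d for d in direction_of.values() if d not in DIRECTIONS}
    if bad:
        raise ValidationError(f"unknown direction label(s): {sorted(bad)}")
    c = closeness(g)
    rows = [
        {
            "node": v,
            "degree": g.degree(v),
            "closeness": c[v],
            "score": ppi_score(g.degree(v), c[v]),
            "direction": direction_of.get(v, "none"),
        }
        for v in g.nodes
    ]
    return pd.DataFrame(rows, columns=HUB_COLUMNS)


def rank_hubs(
    records: pd.DataFrame, direction: str, top: int | None = None
) -> pd.DataFrame:
    """Rank one direction's nodes by descending PPI score.

    Ties break by higher degree, then node id.  ``top`` truncates the list.
    """
    if direction not in DIRECTIONS:
        raise ValidationError(f"unknown direction {direction!r}")
    sub = records[records["direction"] == direction].copy()
    sub = sub.sort_values(
        ["score", "degree", "node"], ascending=[False, False, True], kind="stable"
    ).reset_index(drop=True)
    return sub.head(top) if top is not None else sub
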