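"""Interaction-network filtering and hub-gene nomination.

A scored, undirected edge list is filtered by interaction confidence,
restricted to its main connected component, and summarized by node degree;
high-connectivity genes are intersected with the co-expression key genes to
nominate hubs. Graph mechanics delegate to networkx; the thresholds follow
the STRING-style conventions: edges with score < 0.4 deleted (so exactly 0.4
is retained) and connectivity >= 8 counted as high.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd


def dedupe_edges(edges: pd.DataFrame) -> pd.DataFrame:
    """Drop self-loops and collapse (A,B)/(B,A) duplicates keeping the max score."""
    df = edges.copy()
    df = df[df["geneA"] != df["geneB"]]
    key = df.apply(lambda r: tuple(sorted((r["geneA"], r["geneB"]))), axis=1)
    df = df.assign(_a=[k[0] for k in key], _b=[k[1] for k in key])
    df = (
        df.groupby(["_a", "_b"], as_index=False)["score"]
        .max()
        .rename(columns={"_a": "geneA", "_b": "geneB"})
    )
    return df[["geneA", "geneB", "score"]]


def filter_edges(edges: pd.DataFrame, min_score: float = 0.4) -> pd.DataFrame:
    """Retain edges with score >= ``min_score`` (scores below it are deleted)."""
    if ((edges["score"] < 0) | (edges["score"] > 1)).any():
        raise ValueError("scores must be in [0, 1]")
    return edges[edges["score"] >= min_score].reset_index(drop=True)


def _to_graph(edges: pd.DataFrame) -> nx.Graph:
    g = nx.Graph()
    for a, b, s in edges[["geneA", "geneB", "score"]].itertuples(index=False):
        g.add_edge(a, b, score=float(s))
    return g


def main_component(edges: pd.DataFrame) -> pd.DataFrame:
    """Edges of the largest connected component.

    Ties in component size are broken by the lexicographically smallest member.
    """
    if len(edges) == 0:
        raise ValueError("empty graph has no main component")
    g = _to_graph(edges)
    comps = list(nx.connected_components(g))
    best = max(comps, key=lambda c: (len(c), min(c)))
    mask = edges["geneA"].isin(best) & edges["geneB"].isin(best)
    return edges[mask].reset_index(drop=True)


def degrees(edges: pd.DataFrame) -> dict[str, int]:
    """Number of distinct neighbors of each gene in a deduplicated edge list."""
    g = _to_graph(edges)
    return dict(g.degree())


def high_connectivity(degree_map: dict[str, int], min_degree: int = 8) -> list[str]:
    """Genes with degree >= ``min_degree`` (inclusive), sorted by descending degree then name."""
    if min_degree < 1:
        raise ValueError("min_degree must be >= 1")
    hits = [g for g, d in degree_map.items() if d >= min_degree]
    return sorted(hits, key=lambda g: (-degree_map[g], g))


def hub_intersect(
    key_genes: list[str],
    high_conn: list[str],
    degree_map: dict[str, int] | None = None,
) -> list[str]:
    """Intersection of co-expression key genes and high-connectivity genes.

    Output is stable-sorted by descending degree (when a degree map is given)
    then by gene name.
    """
    hits = set(key_genes) & set(high_conn)
    if degree_map:
        return sorted(hits, key=lambda g: (-degree_map.get(g, 0), g))
    return sorted(hits)
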