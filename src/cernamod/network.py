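"""Interaction-network construction and Maximal Clique Centrality.

Edges enter the mRNA interaction graph only if their protein-level confidence
score exceeds 700 (STRING-score convention, 0-1000) and the two transcripts
are significantly co-expressed (Pearson p < 0.05 on normalized abundance over
all samples). Hubness is scored by Maximal Clique Centrality,

    MCC(v) = sum over maximal cliques C containing v, |C| >= 2, of (|C|-1)!

so a node whose only maximal cliques are single edges scores its degree, and
an isolated node scores 0.
"""

from __future__ import annotations

import logging
import math
import warnings

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats

logger = logging.getLogger("cernamod")


def pearson_test(x, y, alternative: str = "two-sided"):
    """Sample Pearson correlation with its t-distribution p-value (n-2 df).

    A zero-variance input makes r undefined: returns ``(nan, 1.0)`` so the
    pair is flagged non-significant rather than crashing a screen.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError(f"need n >= 3 observations, got {x.size}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = scipy.stats.pearsonr(x, y, alternative=alternative)
    r, p = float(res.statistic), float(res.pvalue)
    if not np.isfinite(r):
        return float("nan"), 1.0
    return r, p


def correlate_rows(expr: pd.DataFrame, pairs) -> pd.DataFrame:
    """Vectorized Pearson r and two-sided p for row pairs of one matrix."""
    mat = expr.to_numpy(dtype=float)
    mat = mat - mat.mean(axis=1, keepdims=True)
    norm = np.sqrt((mat**2).sum(axis=1))
    idx = {f: i for i, f in enumerate(expr.index)}
    n = expr.shape[1]
    out = []
    for a, b in pairs:
        ia, ib = idx[a], idx[b]
        denom = norm[ia] * norm[ib]
        if denom == 0:
            out.append((a, b, np.nan, 1.0))
            continue
        r = float(np.clip(mat[ia] @ mat[ib] / denom, -1.0, 1.0))
        if abs(r) == 1.0:
            p = 0.0
        else:
            t = r * math.sqrt((n - 2) / (1.0 - r * r))
            p = 2.0 * scipy.stats.t.sf(abs(t), n - 2)
        out.append((a, b, r, p))
    return pd.DataFrame(out, columns=["node_a", "node_b", "r", "p"])


def build_interaction_graph(
    edge_list: pd.DataFrame,
    expr: pd.DataFrame,
    conf_threshold: float = 700.0,
    p_threshold: float = 0.05,
) -> nx.Graph:
    """Filter an edge list by confidence and co-expression into a graph.

    ``edge_list`` needs columns node_a/node_b/confidence; ``expr`` is the
    normalized abundance matrix whose rows define the admissible universe.
    Edges with endpoints absent from ``expr`` are dropped (logged). Retained
    edges carry ``confidence``, ``r`` and ``p``; isolated nodes never enter.
    """
    df = edge_list.copy()
    df["node_a"] = df["node_a"].astype(str)
    df["node_b"] = df["node_b"].astype(str)
    df = df[df["node_a"] != df["node_b"]]
    key = [tuple(sorted(t)) for t in zip(df["node_a"], df["node_b"])]
    df = df.assign(_key=key).drop_duplicates("_key")

    known = set(expr.index)
    in_expr = df["node_a"].isin(known) & df["node_b"].isin(known)
    if (~in_expr).any():
        logger.info("dropping %d edges with endpoints missing from expression", int((~in_expr).sum()))
    df = df[in_expr & (df["confidence"] > conf_threshold)]

    graph = nx.Graph()
    if not df.empty:
        corr = correlate_rows(expr, list(zip(df["node_a"], df["node_b"])))
        keep = corr["p"].to_numpy() < p_threshold
        for (_, edge), (_, c) in zip(df[keep].iterrows(), corr[keep].iterrows()):
            graph.add_edge(
                edge["node_a"],
                edge["node_b"],
                confidence=float(edge["confidence"]),
                r=float(c["r"]),
                p=float(c["p"]),
            )
    return graph


def _sorted_nodes(nodes) -> list:
    try:
        return sorted(nodes)
    except TypeError:  # mixed node types
        return sorted(nodes, key=str)


def enumerate_maximal_cliques(graph: nx.Graph, max_nodes: int | None = 5000) -> list:
    """All maximal cliques via Bron-Kerbosch with pivoting.

    Returns sorted node tuples in deterministic order. Graphs larger than
    ``max_nodes`` are refused unless ``max_nodes=None`` (clique enumeration
    is worst-case exponential).
    """
    n = graph.number_of_nodes()
    if max_nodes is not None and n > max_nodes:
        raise ValueError(
            f"graph has {n} nodes (> {max_nodes}); pass max_nodes=None to override"
        )
    order = {v: i for i, v in enumerate(_sorted_nodes(graph.nodes))}
    adj = {v: set(graph.neighbors(v)) for v in graph.nodes}
    cliques: list = []

    def expand(r: set, p: set, x: set) -> None:
        if not p and not x:
            cliques.append(tuple(_sorted_nodes(r)))
            return
        pivot = max(p | x, key=lambda v: len(adj[v] & p))
        for v in sorted(p - adj[pivot], key=order.get):
            expand(r | {v}, p & adj[v], x & adj[v])
            p = p - {v}
            x = x | {v}

    expand(set(), set(graph.nodes), set())
    return sorted(cliques, key=lambda c: [order[v] for v in c])


def mcc_centrality(graph: nx.Graph, max_nodes: int | None = 5000) -> pd.Series:
    """Maximal Clique Centrality per node (isolated nodes score 0)."""
    mcc = {v: 0 for v in graph.nodes}
    for clique in enumerate_maximal_cliques(graph, max_nodes=max_nodes):
        if len(clique) < 2:
            continue
        weight = math.factorial(len(clique) - 1)
        for v in clique:
            mcc[v] += weight
    ordered = _sorted_nodes(mcc)
    return pd.Series([mcc[v] for v in ordered], index=ordered, name="mcc", dtype=np.int64)
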