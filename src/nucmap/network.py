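"""STRING-style protein-protein interaction analysis.

Subnetwork induction over a weighted background interactome, an empirical
permutation test for edge-count enrichment (a stand-in for STRING's
analytical network p-value, with an add-one pseudocount), degree-based hub
detection, and the merged transcription-factor x invasion network with
bridging-TF ranking.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .io import FormatError


def read_edge_list(path: str | Path, score_min: int = 400) -> nx.Graph:
    """Load a STRING-dialect edge TSV (protein1, protein2, combined_score).

    Edges below ``score_min`` are dropped; duplicate edges collapse keeping
    the maximum score; self-loops are ignored.  The default threshold 400 is
    the conventional "medium confidence" cutoff.
    """
    df = pd.read_csv(path, sep="\t")
    required = ["protein1", "protein2", "combined_score"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    scores = pd.to_numeric(df["combined_score"], errors="coerce")
    if scores.isna().any():
        bad = int(scores.isna().idxmax()) + 2  # +2: header and 0-based index
        raise FormatError(f"{path}: malformed combined_score at line {bad}")
    g = nx.Graph()
    for a, b, s in zip(df["protein1"], df["protein2"], scores):
        if a == b or s < score_min:
            continue
        a, b = str(a), str(b)
        if g.has_edge(a, b):
            g[a][b]["combined_score"] = max(g[a][b]["combined_score"], int(s))
        else:
            g.add_edge(a, b, combined_score=int(s))
    return g


def induced_subgraph(
    graph: nx.Graph, nodes: Iterable[str]
) -> tuple[nx.Graph, int, list[str]]:
    """Subgraph induced by ``nodes``; also reports connected vs isolated.

    Nodes absent from the background graph count as isolated, so the
    "interacting m of n entities" summary is over the full query set.
    """
    nodes = sorted(set(nodes))
    if not nodes:
        raise ValueError("node set must be non-empty")
    sub = graph.subgraph([n for n in nodes if n in graph]).copy()
    isolated = [n for n in nodes if n not in sub or sub.degree(n) == 0]
    return sub, sub.number_of_edges(), isolated


@dataclass(frozen=True)
class EnrichmentPvalue:
    p_value: float
    observed_edges: int
    n_perm: int
    null_mean: float


def edge_enrichment_pvalue(
    graph: nx.Graph,
    nodes: Iterable[str],
    n_perm: int = 10_000,
    seed: int | None = None,
) -> EnrichmentPvalue:
    """Empirical p-value for the edge count of an induced subnetwork.

    Each permutation draws |nodes| nodes uniformly without replacement from
    the background graph and counts induced edges; the p-value uses an
    add-one pseudocount: (1 + #{null >= observed}) / (1 + n_perm).
    """
    nodes = sorted(set(nodes))
    if len(nodes) < 2:
        raise ValueError("need at least two nodes")
    all_nodes = sorted(graph.nodes, key=str)
    if len(nodes) > len(all_nodes):
        raise ValueError("query has more nodes than the background graph")
    rng = np.random.default_rng(seed)

    index = {n: i for i, n in enumerate(all_nodes)}
    adj = np.zeros((len(all_nodes), len(all_nodes)), dtype=bool)
    for a, b in graph.edges:
        adj[index[a], index[b]] = True
        adj[index[b], index[a]] = True

    present = [index[n] for n in nodes if n in index]
    observed = int(adj[np.ix_(present, present)].sum() // 2) if present else 0

    k = len(nodes)
    null = np.empty(n_perm, dtype=np.int64)
    for i in range(n_perm):
        pick = rng.choice(len(all_nodes), size=k, replace=False)
        null[i] = adj[np.ix_(pick, pick)].sum() // 2
    p = (1 + int((null >= observed).sum())) / (1 + n_perm)
    return EnrichmentPvalue(
        p_value=float(p),
        observed_edges=observed,
        n_perm=n_perm,
        null_mean=float(null.mean()),
    )


def hub_nodes(subgraph: nx.Graph, k: int) -> list[tuple[str, int]]:
    """Top-k nodes by degree; ties broken lexicographically."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(subgraph.degree, key=lambda nd: (-nd[1], nd[0]))
    return [(n, int(d)) for n, d in ranked[:k]]


@dataclass(frozen=True)
class MergedNetwork:
    """TF x invasion merged subnetwork with a partitioned edge set.

    Edge classification: both endpoints in the TF set -> ``tf_tf``; else
    both in the invasion set -> ``invasion_invasion``; else ``cross``.
    ``cross_degree`` counts, per TF, its distinct partners over cross edges.
    """

    tf_set: frozenset[str]
    invasion_set: frozenset[str]
    subgraph: nx.Graph
    tf_tf: tuple[tuple[str, str], ...]
    invasion_invasion: tuple[tuple[str, str], ...]
    cross: tuple[tuple[str, str], ...]
    cross_degree: dict[str, int]
    overlap: frozenset[str]


def merge_tf_invasion(
    graph: nx.Graph, tf_set: Iterable[str], invasion_set: Iterable[str]
) -> MergedNetwork:
    """Induce the merged network over TF and invasion entities."""
    tfs = frozenset(tf_set)
    inv = frozenset(invasion_set)
    if not tfs or not inv:
        raise ValueError("both the TF set and the invasion set must be non-empty")
    sub, _, _ = induced_subgraph(graph, tfs | inv)
    tf_tf, inv_inv, cross = [], [], []
    for a, b in sub.edges:
        e = tuple(sorted((a, b)))
        if a in tfs and b in tfs:
            tf_tf.append(e)
        elif a in inv and b in inv:
            inv_inv.append(e)
        else:
            cross.append(e)
    cross_degree = {t: 0 for t in sorted(tfs)}
    for a, b in cross:
        if a in tfs:
            cross_degree[a] += 1
        if b in tfs:
            cross_degree[b] += 1
    return MergedNetwork(
        tf_set=tfs,
        invasion_set=inv,
        subgraph=sub,
        tf_tf=tuple(sorted(tf_tf)),
        invasion_invasion=tuple(sorted(inv_inv)),
        cross=tuple(sorted(cross)),
        cross_degree=cross_degree,
        overlap=tfs & inv,
    )


def rank_bridging_tfs(merged: MergedNetwork) -> pd.DataFrame:
    """Rank TFs by how strongly they bridge into the invasion subnetwork.

    Sort key: cross-degree descending, total degree descending, then name.
    The top TF is flagged as the candidate bridging regulator.
    """
    if not merged.tf_set:
        raise ValueError("cannot rank an empty TF set")
    rows = []
    for tf in sorted(merged.tf_set):
        total = merged.subgraph.degree(tf) if tf in merged.subgraph else 0
        rows.append(
            {"tf": tf, "cross_degree": merged.cross_degree.get(tf, 0), "total_degree": int(total)}
        )
    df = pd.DataFrame(rows)
    df = df.sort_values(
        ["cross_degree", "total_degree", "tf"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df["is_candidate_regulator"] = df["rank"] == 1
    return df
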