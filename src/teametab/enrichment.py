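"""Functional (diffusion) and structural (over-representation) enrichment.

Functional enrichment scores every node of a typed metabolic knowledge
graph (compound - reaction - enzyme - module - pathway layers, undirected)
by personalized PageRank: the stationary point of

    s = (1 - d) * r + d * W^T s

with damping d, row-normalised adjacency W and restart vector r uniform
over the seed compounds (the compounds matched to an affected feature
set).  Mass at dangling (isolated) nodes is redistributed through the
restart vector.  Significance is an empirical p-score: the add-one tail
probability of a node's observed score against scores from random
same-size compound seed sets.

Structural enrichment is classical over-representation: per consensus
class at a chosen taxonomy level, a one-sided Fisher's exact test of
cluster membership against the background, BH-corrected across classes
within the run.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse, stats

from .errors import EmptyInputError, GraphError
from .selection import bh_adjust

NODE_TYPES = ("compound", "reaction", "enzyme", "module", "pathway")


@dataclass
class EnrichmentConfig:
    seed: int
    damping: float = 0.85
    n_null: int = 1000
    p_threshold: float = 0.05
    tol: float = 1e-10
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if not 0 < self.damping < 1:
            raise ValueError("damping must be in (0, 1)")
        if self.n_null < 1:
            raise ValueError("n_null must be >= 1")


# ---------------------------------------------------------------------------
# graph I/O
# ---------------------------------------------------------------------------

def save_graph_tsv(graph: nx.Graph, path) -> None:
    """Serialise a typed graph as an edge list (node types and labels inline)."""
    rows = []
    for u, v in sorted(graph.edges()):
        rows.append(
            {
                "source": u,
                "target": v,
                "source_type": graph.nodes[u].get("type", ""),
                "target_type": graph.nodes[v].get("type", ""),
                "source_label": graph.nodes[u].get("label", u),
                "target_label": graph.nodes[v].get("label", v),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_graph_tsv(path) -> nx.Graph:
    table = pd.read_csv(path, sep="\t")
    graph = nx.Graph()
    for _, row in table.iterrows():
        graph.add_node(row["source"], type=row["source_type"], label=row["source_label"])
        graph.add_node(row["target"], type=row["target_type"], label=row["target_label"])
        graph.add_edge(row["source"], row["target"])
    return graph


def nodes_of_type(graph: nx.Graph, node_type: str) -> list:
    return sorted(n for n, d in graph.nodes(data=True) if d.get("type") == node_type)


# ---------------------------------------------------------------------------
# personalized PageRank
# ---------------------------------------------------------------------------

class _PreparedGraph:
    """Node ordering plus the transposed row-normalised adjacency."""

    def __init__(self, graph: nx.Graph):
        self.nodes = sorted(graph.nodes())
        self.index = {n: i for i, n in enumerate(self.nodes)}
        n = len(self.nodes)
        adj = nx.to_scipy_sparse_array(graph, nodelist=self.nodes, format="csr")
        degree = np.asarray(adj.sum(axis=1)).ravel()
        self.dangling = degree == 0
        inv = np.where(degree > 0, 1.0 / np.where(degree > 0, degree, 1.0), 0.0)
        W = sparse.diags(inv) @ adj
        self.Wt = sparse.csr_matrix(W.T)
        self.n = n

    def restart(self, seed_nodes) -> np.ndarray:
        r = np.zeros(self.n)
        idx = [self.index[s] for s in seed_nodes]
        r[idx] = 1.0 / len(idx)
        return r

    def pagerank(self, r: np.ndarray, damping: float, tol: float, max_iter: int) -> np.ndarray:
        s = r.copy()
        for _ in range(max_iter):
            dangling_mass = s[self.dangling].sum()
            s_new = (1 - damping) * r + damping * (self.Wt @ s + dangling_mass * r)
            if np.abs(s_new - s).sum() < tol:
                return s_new
            s = s_new
        return s


def personalized_pagerank(
    graph: nx.Graph, seed_nodes, config: EnrichmentConfig
) -> pd.Series:
    """Diffusion scores (sum 1 over the graph) from a seed-node set."""
    seeds = list(seed_nodes)
    if not seeds:
        raise EmptyInputError("seed node set is empty")
    missing = sorted(set(seeds) - set(graph.nodes()))
    if missing:
        raise GraphError(f"seed nodes absent from graph: {missing}")
    prep = _PreparedGraph(graph)
    scores = prep.pagerank(
        prep.restart(seeds), config.damping, config.tol, config.max_iter
    )
    return pd.Series(scores, index=prep.nodes)


def empirical_p_scores(
    graph: nx.Graph, seed_compounds, config: EnrichmentConfig
) -> pd.DataFrame:
    """Observed diffusion scores with add-one empirical p-scores.

    Null runs reuse the seed-set size with uniformly resampled compound
    nodes.  p = (1 + #{null score >= observed}) / (n_null + 1), so
    p-scores lie in (0, 1].
    """
    seeds = sorted(set(seed_compounds))
    compounds = nodes_of_type(graph, "compound")
    if len(compounds) < len(seeds):
        raise GraphError("fewer compound nodes than seed compounds")
    missing = sorted(set(seeds) - set(graph.nodes()))
    if missing:
        raise GraphError(f"seed nodes absent from graph: {missing}")
    prep = _PreparedGraph(graph)
    observed = prep.pagerank(
        prep.restart(seeds), config.damping, config.tol, config.max_iter
    )
    rng = np.random.default_rng(config.seed)
    exceed = np.zeros(prep.n, dtype=int)
    for _ in range(config.n_null):
        null_seeds = rng.choice(compounds, size=len(seeds), replace=False)
        null = prep.pagerank(
            prep.restart(null_seeds), config.damping, config.tol, config.max_iter
        )
        exceed += null >= observed
    p_scores = (1 + exceed) / (config.n_null + 1)
    seed_set = set(seeds)
    out = pd.DataFrame(
        {
            "node": prep.nodes,
            "type": [graph.nodes[n].get("type", "") for n in prep.nodes],
            "name": [graph.nodes[n].get("label", n) for n in prep.nodes],
            "score": observed,
            "p_score": p_scores,
            "is_seed": [n in seed_set for n in prep.nodes],
        }
    )
    return out.set_index("node")


def functional_enrichment(
    cluster_features: dict,
    feature_compounds: dict,
    graph: nx.Graph,
    config: EnrichmentConfig,
) -> pd.DataFrame:
    """Per-cluster pathway/module table in the shape (cluster, id, name, p-score).

    ``cluster_features`` maps a cluster id to its feature ids;
    ``feature_compounds`` maps a feature id to matched compound ids.  The
    seed set of a cluster is the union of its features' compounds present
    in the graph.  Pathway and module nodes with p-score <= threshold are
    reported, sorted by cluster then p-score.
    """
    import warnings

    rows = []
    graph_nodes = set(graph.nodes())
    for cluster in sorted(cluster_features, key=str):
        seeds = set()
        for fid in cluster_features[cluster]:
            seeds.update(c for c in feature_compounds.get(fid, []) if c in graph_nodes)
        if not seeds:
            warnings.warn(f"cluster {cluster}: no matched compounds in graph", stacklevel=2)
            continue
        scores = empirical_p_scores(graph, seeds, config)
        hits = scores[
            scores["type"].isin(["pathway", "module"])
            & (scores["p_score"] <= config.p_threshold)
        ]
        for node, row in hits.iterrows():
            rows.append(
                {
                    "cluster": cluster,
                    "id": node,
                    "name": row["name"],
                    "type": row["type"],
                    "p_score": row["p_score"],
                }
            )
    out = pd.DataFrame(rows, columns=["cluster", "id", "name", "type", "p_score"])
    return out.sort_values(
        ["cluster", "p_score", "id"], kind="stable", ignore_index=True
    )


# ---------------------------------------------------------------------------
# structural over-representation
# ---------------------------------------------------------------------------

def fisher_exact_one_sided(a: int, b: int, c: int, d: int) -> float:
    """Upper-tail Fisher p for the 2x2 table [[a, b], [c, d]]."""
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("counts must be non-negative")
    if a + b + c + d == 0:
        raise ValueError("all counts zero")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1])


def structural_enrichment(
    cluster_features,
    background_features,
    consensus_paths: dict,
    level: int = 2,
) -> pd.DataFrame:
    """Fisher over-representation of consensus classes in a cluster.

    Only features whose consensus reaches ``level`` enter either margin.
    For each label at that level: a 2x2 table of cluster membership vs
    class membership (cluster against the rest of the background), a
    one-sided p and a BH q across the labels of this run.
    """
    cluster = set(cluster_features)
    background = set(background_features)
    if not cluster:
        raise EmptyInputError("empty cluster")
    if not cluster <= background:
        raise ValueError("cluster must be a subset of the background")

    def label_of(fid):
        path = consensus_paths.get(fid, ())
        return path[level - 1] if len(path) >= level else None

    labelled_bg = {f: label_of(f) for f in background}
    labelled_bg = {f: lab for f, lab in labelled_bg.items() if lab is not None}
    labels = sorted({lab for lab in labelled_bg.values()})
    in_cluster = [f for f in labelled_bg if f in cluster]
    out_cluster = [f for f in labelled_bg if f not in cluster]
    rows = []
    for lab in labels:
        a = sum(1 for f in in_cluster if labelled_bg[f] == lab)
        b = len(in_cluster) - a
        c = sum(1 for f in out_cluster if labelled_bg[f] == lab)
        d = len(out_cluster) - c
        rows.append(
            {"label": lab, "a": a, "b": b, "c": c, "d": d,
             "p": fisher_exact_one_sided(a, b, c, d)}
        )
    out = pd.DataFrame(rows, columns=["label", "a", "b", "c", "d", "p"])
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
    else:
        out["q"] = []
    return out.sort_values(["p", "label"], kind="stable", ignore_index=True)
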