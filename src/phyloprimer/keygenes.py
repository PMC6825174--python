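"""Co-expression networks, centrality ranking and expression clustering.

Key biosynthetic genes are prioritized as hub–bottleneck nodes: genes high in
both degree (local connectivity) and betweenness (shortest-path traffic) of a
co-expression network built by thresholding absolute Pearson correlation.
Six centralities are reported — degree, betweenness, closeness, stress,
radiality and max-normalized eigenvector — with the distance-based measures
computed within each connected component:

  closeness(v)  = (n_c − 1) / Σ_w d(v, w)
  radiality(v)  = Σ_w (Δ_c + 1 − d(v, w)) / (n_c − 1)
  stress(v)     = number of shortest paths passing through v

where n_c and Δ_c are the node's component size and diameter.  Singleton
components get 0 for all distance-based measures (flagged in the report).
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata


def pearson_matrix(expr: pd.DataFrame, log2_transform: bool = False) -> pd.DataFrame:
    """Gene × gene Pearson correlation of expression rows.

    ``expr`` is genes × samples (non-negative).  With ``log2_transform`` rows
    are log2(x+1)-transformed first.  Zero-variance genes get NaN rows/columns
    (correlation undefined) and are excluded when building a network.
    """
    if expr.index.duplicated().any():
        raise ValueError("duplicate gene ids in expression matrix")
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples for correlation")
    x = expr.to_numpy(dtype=float)
    if log2_transform:
        x = np.log2(x + 1.0)
    sd = x.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    r[sd == 0, :] = np.nan
    r[:, sd == 0] = np.nan
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=expr.index, columns=expr.index)


def build_network(corr: pd.DataFrame, threshold: float) -> nx.Graph:
    """Undirected network with an edge wherever |r| ≥ threshold (weight |r|).

    Genes with undefined (NaN) correlations are excluded; no self-loops.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    genes = [g for g in corr.index if not corr.loc[g].drop(g).isna().all()]
    G = nx.Graph()
    G.add_nodes_from(genes)
    vals = corr.loc[genes, genes].to_numpy()
    for i, a in enumerate(genes):
        for j in range(i + 1, len(genes)):
            r = vals[i, j]
            if np.isfinite(r) and abs(r) >= threshold:
                G.add_edge(a, genes[j], weight=abs(r))
    G.graph["threshold"] = threshold
    return G


def read_edge_list(path) -> nx.Graph:
    """Edge-list TSV (gene_a, gene_b[, weight]) -> undirected network."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    G = nx.Graph()
    for row in df.itertuples(index=False):
        a, b = str(row[0]), str(row[1])
        if a == b:
            continue
        w = float(row[2]) if len(row) > 2 else 1.0
        G.add_edge(a, b, weight=w)
    return G


def _stress_and_radiality(G: nx.Graph, use_weights: bool):
    """Stress via shortest-path counting; radiality from component distances."""
    weight = "distance" if use_weights else None
    stress = {v: 0 for v in G}
    radiality = {v: 0.0 for v in G}
    for comp in nx.connected_components(G):
        nodes = sorted(comp)
        n_c = len(nodes)
        if n_c == 1:
            continue
        sub = G.subgraph(nodes)
        dist = dict(nx.all_pairs_dijkstra_path_length(sub, weight=weight)) if use_weights \
            else dict(nx.all_pairs_shortest_path_length(sub))
        # shortest-path counts σ(s, t) via BFS/Dijkstra DAG counting
        sigma = {}
        for s in nodes:
            sig = {v: 0.0 for v in nodes}
            sig[s] = 1.0
            for v in sorted(nodes, key=lambda v: dist[s][v]):
                if v == s:
                    continue
                for u in sub.neighbors(v):
                    d_uv = sub[u][v]["distance"] if use_weights else 1
                    if abs(dist[s][u] + d_uv - dist[s][v]) < 1e-12:
                        sig[v] += sig[u]
            sigma[s] = sig
        diam = max(dist[a][b] for a in nodes for b in nodes)
        for v in nodes:
            radiality[v] = sum(
                diam + 1 - dist[v][w] for w in nodes if w != v
            ) / (n_c - 1)
            tot = 0.0
            for i, s in enumerate(nodes):
                if s == v:
                    continue
                for t in nodes[i + 1 :]:
                    if t == v or s == v:
                        continue
                    if abs(dist[s][v] + dist[v][t] - dist[s][t]) < 1e-12:
                        tot += sigma[s][v] * sigma[v][t]
            stress[v] = int(round(tot)) if not use_weights else tot
    return stress, radiality


def _eigenvector_max_norm(G: nx.Graph, max_iter: int = 10000, tol: float = 1e-12):
    """Principal eigenvector of the adjacency by power iteration, max = 1."""
    nodes = sorted(G)
    n = len(nodes)
    A = nx.to_numpy_array(G, nodelist=nodes, weight=None)
    if n == 0 or A.sum() == 0:
        return {v: 0.0 for v in nodes}
    x = np.ones(n) / n
    for _ in range(max_iter):
        # shift by +I: same eigenvectors, breaks the ±λ oscillation of
        # bipartite adjacency spectra
        x_new = A @ x + x
        norm = np.max(np.abs(x_new))
        if norm == 0:
            return {v: 0.0 for v in nodes}
        x_new = x_new / norm
        if np.max(np.abs(x_new - x)) < tol:
            x = x_new
            break
        x = x_new
    return {v: float(x[i]) for i, v in enumerate(nodes)}


def centralities(G: nx.Graph, use_weights: bool = False) -> pd.DataFrame:
    """Per-node centrality report (see module docstring for formulas).

    With ``use_weights`` shortest-path distances are 1/weight; the default
    (unweighted) matches the usual screening convention for thresholded
    co-expression networks.
    """
    if use_weights:
        for a, b, d in G.edges(data=True):
            d["distance"] = 1.0 / d.get("weight", 1.0)
    weight = "distance" if use_weights else None
    nodes = sorted(G)
    degree = dict(G.degree())
    betweenness = nx.betweenness_centrality(G, normalized=False, weight=weight)
    closeness = {}
    for comp in nx.connected_components(G):
        comp_nodes = sorted(comp)
        n_c = len(comp_nodes)
        sub = G.subgraph(comp_nodes)
        if n_c == 1:
            closeness[comp_nodes[0]] = 0.0
            continue
        dist = dict(nx.all_pairs_dijkstra_path_length(sub, weight=weight)) if use_weights \
            else dict(nx.all_pairs_shortest_path_length(sub))
        for v in comp_nodes:
            closeness[v] = (n_c - 1) / sum(dist[v][w] for w in comp_nodes if w != v)
    stress, radiality = _stress_and_radiality(G, use_weights)
    eig = _eigenvector_max_norm(G)
    singleton = {v: G.degree(v) == 0 for v in nodes}
    return pd.DataFrame(
        {
            "degree": [degree[v] for v in nodes],
            "betweenness": [betweenness[v] for v in nodes],
            "closeness": [closeness[v] for v in nodes],
            "stress": [stress[v] for v in nodes],
            "radiality": [radiality[v] for v in nodes],
            "eigenvector": [eig[v] for v in nodes],
            "isolated": [singleton[v] for v in nodes],
        },
        index=pd.Index(nodes, name="gene"),
    )


def hub_bottleneck_select(
    report: pd.DataFrame,
    degree_cut: float | None = None,
    bc_cut: float | None = None,
) -> pd.DataFrame:
    """Flag hub–bottleneck genes and rank all genes.

    A gene is flagged when degree > degree_cut AND betweenness > bc_cut;
    cuts default to the network means (the usual screening convention).
    Ranking is by the product of degree and betweenness percentiles,
    descending, ties broken lexicographically by gene id.
    """
    if report.empty:
        raise ValueError("empty centrality report")
    deg = report["degree"].to_numpy(dtype=float)
    bc = report["betweenness"].to_numpy(dtype=float)
    degree_cut = float(np.mean(deg)) if degree_cut is None else degree_cut
    bc_cut = float(np.mean(bc)) if bc_cut is None else bc_cut
    n = len(report)
    deg_pct = rankdata(deg) / n
    bc_pct = rankdata(bc) / n
    out = pd.DataFrame(
        {
            "degree": report["degree"],
            "betweenness": report["betweenness"],
            "degree_percentile": deg_pct,
            "betweenness_percentile": bc_pct,
            "hub_bottleneck": (deg > degree_cut) & (bc > bc_cut),
            "rank_score": deg_pct * bc_pct,
        },
        index=report.index,
    )
    order = sorted(range(n), key=lambda i: (-out["rank_score"].iloc[i], out.index[i]))
    return out.iloc[order]


def hcluster(
    expr: pd.DataFrame,
    k: int = 2,
    log2_transform: bool = False,
) -> tuple[np.ndarray, pd.Series]:
    """Average-linkage hierarchical clustering of genes at distance 1 − r.

    Returns the scipy linkage matrix and a flat k-cluster assignment with
    canonical labels (clusters numbered by their lexicographically smallest
    member), so the partition is reproducible under input reordering.
    """
    if expr.shape[0] < k:
        raise ValueError(f"need at least {k} genes")
    order = np.argsort(expr.index.to_numpy())
    expr = expr.iloc[order]  # canonical gene order -> deterministic ties
    corr = pearson_matrix(expr, log2_transform=log2_transform).to_numpy()
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    flat = fcluster(Z, t=k, criterion="maxclust")
    labels = pd.Series(flat, index=expr.index, name="cluster")
    # canonical numbering: cluster containing the smallest gene id becomes 1
    remap = {}
    for gid in sorted(labels.index):
        c = labels[gid]
        if c not in remap:
            remap[c] = len(remap) + 1
    return Z, labels.map(remap)
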