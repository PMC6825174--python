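"""Independent brute-force oracles used to check the implementation.

Deliberately naive: quadratic/exponential enumeration with no shortcuts, so
they share no code path with the package.
"""

from __future__ import annotations

import itertools

import numpy as np


def affine_global_score(a: str, b: str, matrix, gap_open: float, gap_extend: float):
    """Three-state affine-gap global alignment score by plain DP.

    A gap of length k costs gap_open + (k-1)*gap_extend.
    """
    n, m = len(a), len(b)
    NEG = float("-inf")
    M = [[NEG] * (m + 1) for _ in range(n + 1)]  # a[i-1] aligned to b[j-1]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (a residue unmatched)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[a[i - 1], b[j - 1]]
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend,
                          Y[i - 1][j] + gap_open)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend,
                          X[i][j - 1] + gap_open)
    return max(M[n][m], X[n][m], Y[n][m])


def all_shortest_paths_stats(adj: dict):
    """Exhaustive all-pairs shortest-path statistics by simple-path enumeration.

    ``adj`` maps node -> set of neighbors (undirected).  Returns
    (dist, sigma, through) where dist[s][t] is the shortest length (None if
    unreachable), sigma[s][t] the number of shortest paths, and
    through[v][(s, t)] the number of shortest s-t paths with v strictly
    interior.
    """
    nodes = sorted(adj)
    dist = {s: {t: None for t in nodes} for s in nodes}
    sigma = {s: {t: 0 for t in nodes} for s in nodes}
    through = {v: {} for v in nodes}

    def simple_paths(s, t):
        stack = [(s, [s])]
        while stack:
            v, path = stack.pop()
            if v == t:
                yield path
                continue
            for u in sorted(adj[v]):
                if u not in path:
                    stack.append((u, path + [u]))

    for s in nodes:
        for t in nodes:
            if s == t:
                dist[s][t] = 0
                sigma[s][t] = 1
                continue
            paths = list(simple_paths(s, t))
            if not paths:
                continue
            best = min(len(p) - 1 for p in paths)
            shortest = [p for p in paths if len(p) - 1 == best]
            dist[s][t] = best
            sigma[s][t] = len(shortest)
            for v in nodes:
                if v in (s, t):
                    continue
                through[v][(s, t)] = sum(1 for p in shortest if v in p[1:-1])
    return dist, sigma, through


def centrality_oracle(adj: dict):
    """The six centralities by exhaustive enumeration (see package formulas)."""
    nodes = sorted(adj)
    dist, sigma, through = all_shortest_paths_stats(adj)
    # connected components
    comps = []
    seen = set()
    for s in nodes:
        if s in seen:
            continue
        comp = {t for t in nodes if dist[s][t] is not None}
        comps.append(sorted(comp))
        seen |= comp
    out = {}
    for v in nodes:
        comp = next(c for c in comps if v in c)
        n_c = len(comp)
        degree = len(adj[v])
        bet = sum(
            through[v].get((s, t), 0) / sigma[s][t]
            for i, s in enumerate(comp)
            for t in comp[i + 1 :]
            if s != v and t != v and sigma[s][t] > 0
        )
        stress = sum(
            through[v].get((s, t), 0)
            for i, s in enumerate(comp)
            for t in comp[i + 1 :]
            if s != v and t != v
        )
        if n_c == 1:
            clo = rad = 0.0
        else:
            tot = sum(dist[v][w] for w in comp if w != v)
            clo = (n_c - 1) / tot
            diam = max(dist[a][b] for a in comp for b in comp)
            rad = sum(diam + 1 - dist[v][w] for w in comp if w != v) / (n_c - 1)
        out[v] = {
            "degree": degree,
            "betweenness": bet,
            "stress": stress,
            "closeness": clo,
            "radiality": rad,
        }
    # eigenvector: principal eigenvector of the adjacency, max-normalized
    n = len(nodes)
    A = np.zeros((n, n))
    idx = {v: i for i, v in enumerate(nodes)}
    for v in nodes:
        for u in adj[v]:
            A[idx[v], idx[u]] = 1.0
    if A.sum() > 0:
        w, vecs = np.linalg.eigh(A)
        vec = np.abs(vecs[:, -1])
        vec = vec / vec.max()
    else:
        vec = np.zeros(n)
    for v in nodes:
        out[v]["eigenvector"] = float(vec[idx[v]])
    return out


def pearson_sum_formula(x, y) -> float:
    """Textbook Σ-formula Pearson correlation."""
    x = list(map(float, x))
    y = list(map(float, y))
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    num = n * sxy - sx * sy
    den = ((n * sxx - sx * sx) * (n * syy - sy * sy)) ** 0.5
    return num / den


def expand_oracle(iupac_string: str, code_map: dict) -> list[str]:
    """Exhaustive expansion by Cartesian product over per-position subsets."""
    pools = [sorted(code_map[c]) for c in iupac_string]
    return sorted("".join(p) for p in itertools.product(*pools))
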