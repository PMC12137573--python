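"""Independent brute-force oracles used by the test suite.

Each oracle is deliberately naive (enumeration / first-principles formulas)
and shares no code with the implementation it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def shannon_hill_oracle(counts) -> float:
    """Order-1 Hill number via scipy's entropy (independent route)."""
    from scipy.stats import entropy

    counts = np.asarray(counts, dtype=float)
    return float(np.exp(entropy(counts / counts.sum())))


def gini_mean_abs_diff_oracle(counts) -> float:
    """Gini via the O(n^2) mean-absolute-difference definition."""
    x = np.asarray(counts, dtype=float)
    n = x.size
    mad = np.abs(x[:, None] - x[None, :]).sum() / (n * n)
    return float(mad / (2.0 * x.mean()))


def dispersion_exhaustive_oracle(vectors) -> float:
    """Population variance of cosine similarity over ALL unordered pairs."""
    v = np.asarray(vectors, dtype=float)
    unit = v / np.linalg.norm(v, axis=1, keepdims=True)
    cosines = [
        float(unit[i] @ unit[j]) for i, j in itertools.combinations(range(len(v)), 2)
    ]
    cosines = np.asarray(cosines)
    return float(np.mean((cosines - cosines.mean()) ** 2))


def anova_oracle(samples) -> tuple[float, int, int]:
    """One-way ANOVA F statistic from the textbook sum-of-squares table."""
    all_vals = np.concatenate(samples)
    grand = all_vals.mean()
    ss_between = sum(len(s) * (np.mean(s) - grand) ** 2 for s in samples)
    ss_within = sum(((np.asarray(s) - np.mean(s)) ** 2).sum() for s in samples)
    df_b = len(samples) - 1
    df_w = all_vals.size - len(samples)
    return float((ss_between / df_b) / (ss_within / df_w)), df_b, df_w


# ---------------------------------------------------------------- d-separation


def _all_paths(edges: set, x, y, nodes):
    """All simple paths from x to y in the skeleton, as node sequences."""
    adjacency = {n: set() for n in nodes}
    for a, b in edges:
        adjacency[a].add(b)
        adjacency[b].add(a)
    paths = []

    def walk(path):
        last = path[-1]
        if last == y:
            paths.append(list(path))
            return
        for nxt in adjacency[last]:
            if nxt not in path:
                path.append(nxt)
                walk(path)
                path.pop()

    walk([x])
    return paths


def _descendants(edges: set, node):
    out = set()
    frontier = [node]
    while frontier:
        cur = frontier.pop()
        for a, b in edges:
            if a == cur and b not in out:
                out.add(b)
                frontier.append(b)
    return out


def d_separated_oracle(edges, x, y, z, nodes) -> bool:
    """d-separation by exhaustive path enumeration and blocking rules.

    A path is blocked given Z iff some interior node w is (a) a collider on
    the path with neither w nor any descendant of w in Z, or (b) a
    non-collider in Z.
    """
    edges = set(edges)
    z = set(z)
    for path in _all_paths(edges, x, y, set(nodes)):
        blocked = False
        for i in range(1, len(path) - 1):
            prev_node, w, nxt = path[i - 1], path[i], path[i + 1]
            collider = (prev_node, w) in edges and (nxt, w) in edges
            if collider:
                if w not in z and not (_descendants(edges, w) & z):
                    blocked = True
                    break
            elif w in z:
                blocked = True
                break
        if not blocked:
            return False
    return True


def all_dags(n_nodes: int):
    """Every labelled DAG on ``n_nodes`` nodes, as edge sets.

    Enumerates orientations of each undirected edge subset and keeps the
    acyclic ones (checked by iterative topological pruning).
    """
    nodes = list(range(n_nodes))
    for mask in range(3 ** (n_nodes * (n_nodes - 1) // 2)):
        # base-3 digit per unordered pair: absent / a->b / b->a
        edges = []
        m = mask
        for a, b in itertools.combinations(nodes, 2):
            digit = m % 3
            m //= 3
            if digit == 1:
                edges.append((a, b))
            elif digit == 2:
                edges.append((b, a))
        if _is_acyclic(edges, nodes):
            yield edges


def _is_acyclic(edges, nodes) -> bool:
    indeg = {n: 0 for n in nodes}
    for _, b in edges:
        indeg[b] += 1
    frontier = [n for n in nodes if indeg[n] == 0]
    seen = 0
    edges_by_src = {}
    for a, b in edges:
        edges_by_src.setdefault(a, []).append(b)
    while frontier:
        cur = frontier.pop()
        seen += 1
        for b in edges_by_src.get(cur, []):
            indeg[b] -= 1
            if indeg[b] == 0:
                frontier.append(b)
    return seen == len(nodes)
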