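"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own data structures and algorithms:
the breakpoint oracle enumerates adjacencies by string rotation, and the
topology oracle scores every unrooted tree shape by least-squares fit of
its path-length matrix.  They exist to cross-check the package, so keep
them dumb and obvious.
"""

from __future__ import annotations

import itertools

import numpy as np


# ---------------------------------------------------------------------------
# signed circular adjacency / breakpoint oracle

def _adjacency_strings(order):
    """Adjacency tokens of a signed circular order given as [(name, sign)].

    Each adjacency is rendered as the lexicographically smaller of its two
    strand readings 'a(s)>b(t)' vs 'b(-t)>a(-s)'.
    """
    toks = set()
    n = len(order)
    for i in range(n):
        (a, sa), (b, sb) = order[i], order[(i + 1) % n]
        fwd = f"{a}({sa})>{b}({sb})"
        rev = f"{b}({-sb})>{a}({-sa})"
        toks.add(min(fwd, rev))
    return toks


def breakpoints_oracle(order_a, order_b):
    """Breakpoint count by explicit adjacency-token set difference."""
    return len(_adjacency_strings(order_a) - _adjacency_strings(order_b))


# ---------------------------------------------------------------------------
# exhaustive-topology least-squares oracle for tree reconstruction

def all_unrooted_topologies(taxa):
    """All unrooted binary tree shapes over the taxa, as sets of splits.

    Built by stepwise addition: each new taxon is attached to every edge of
    every partial tree.  A tree is represented as a list of edges between
    node ids; tips carry taxon names.  Returns (edges, node_names) pairs.
    """
    taxa = list(taxa)
    assert len(taxa) >= 3
    # start from the 3-taxon star: internal node 0, tips 1..3
    base_edges = [(0, 1), (0, 2), (0, 3)]
    base_names = {1: taxa[0], 2: taxa[1], 3: taxa[2]}
    trees = [(base_edges, base_names, 4)]
    for taxon in taxa[3:]:
        nxt = []
        for edges, names, next_id in trees:
            for k, (u, v) in enumerate(edges):
                new_internal, new_tip = next_id, next_id + 1
                e2 = edges[:k] + edges[k + 1:]
                e2 += [(u, new_internal), (new_internal, v),
                       (new_internal, new_tip)]
                n2 = dict(names)
                n2[new_tip] = taxon
                nxt.append((e2, n2, next_id + 2))
        trees = nxt
    return [(edges, names) for edges, names, _ in trees]


def _paths(edges, names, taxa):
    """Edge-indicator matrix of tip-to-tip paths (rows follow taxon pairs)."""
    adj = {}
    for idx, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append((v, idx))
        adj.setdefault(v, []).append((u, idx))
    tip_of = {name: node for node, name in names.items()}
    rows = []
    for a, b in itertools.combinations(taxa, 2):
        # BFS path from tip a to tip b
        start, goal = tip_of[a], tip_of[b]
        prev = {start: None}
        queue = [start]
        while queue:
            node = queue.pop(0)
            if node == goal:
                break
            for nbr, eidx in adj[node]:
                if nbr not in prev:
                    prev[nbr] = (node, eidx)
                    queue.append(nbr)
        row = np.zeros(len(edges))
        node = goal
        while prev[node] is not None:
            node, eidx = prev[node]
            row[eidx] = 1
        rows.append(row)
    return np.array(rows)


def splits_of_topology(edges, names, taxa):
    """Non-trivial splits of a topology as frozensets of frozenset pairs."""
    taxa_set = frozenset(taxa)
    adj = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    splits = set()
    for u, v in edges:
        # tips reachable from u without crossing (u, v)
        seen, queue = {u, v}, [u]
        side = set()
        while queue:
            node = queue.pop()
            if node in names:
                side.add(names[node])
            for nbr in adj[node]:
                if nbr not in seen:
                    seen.add(nbr)
                    queue.append(nbr)
        side = frozenset(side)
        comp = taxa_set - side
        if len(side) >= 2 and len(comp) >= 2:
            splits.add(frozenset((side, comp)))
    return splits


def best_topology_splits(dist, taxa):
    """Splits of the least-squares-optimal topology for a distance matrix.

    ``dist``: dict keyed by frozenset({a, b}) -> distance.  Every unrooted
    shape is scored by unconstrained least squares on its path matrix; the
    minimal residual wins (ties: first found).
    """
    d_vec = np.array([dist[frozenset(p)]
                      for p in itertools.combinations(taxa, 2)])
    best, best_sse = None, np.inf
    for edges, names in all_unrooted_topologies(taxa):
        X = _paths(edges, names, taxa)
        coef, *_ = np.linalg.lstsq(X, d_vec, rcond=None)
        sse = float(((X @ coef) - d_vec) ** 2 @ np.ones(len(d_vec)))
        if sse < best_sse - 1e-12:
            best_sse = sse
            best = splits_of_topology(edges, names, taxa)
    return best


# ---------------------------------------------------------------------------
# random additive matrices from random binary trees

def random_tree_distances(taxa, rng, min_bl=0.05, max_bl=0.4):
    """A random unrooted binary tree over taxa; returns (splits, dist dict)."""
    shapes = None
    # build one random shape by stepwise addition with random edge choice
    taxa = list(taxa)
    edges = [(0, 1), (0, 2), (0, 3)]
    names = {1: taxa[0], 2: taxa[1], 3: taxa[2]}
    next_id = 4
    for taxon in taxa[3:]:
        k = rng.integers(0, len(edges))
        u, v = edges.pop(int(k))
        internal, tip = next_id, next_id + 1
        edges += [(u, internal), (internal, v), (internal, tip)]
        names[tip] = taxon
        next_id += 2
    lengths = {e: float(rng.uniform(min_bl, max_bl)) for e in edges}
    X = _paths(edges, names, taxa)
    bl = np.array([lengths[e] for e in edges])
    d_vec = X @ bl
    dist = {frozenset(p): d_vec[i]
            for i, p in enumerate(itertools.combinations(taxa, 2))}
    return splits_of_topology(edges, names, taxa), dist
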