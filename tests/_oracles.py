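"""Independent brute-force oracles used by the tests.

These deliberately avoid the code paths of the package: distances come from
a pure-Python Floyd-Warshall, path frequencies from explicit enumeration of
all shortest paths, and hypergeometric tails from exhaustive subset
enumeration.
"""

from itertools import combinations

INF = float("inf")


def fw_distances(nodes, edges, directed=False):
    """Floyd-Warshall all-pairs hop distances as a dict (a, b) -> d."""
    nodes = list(nodes)
    d = {(a, b): (0 if a == b else INF) for a in nodes for b in nodes}
    for u, v in edges:
        if u == v:
            continue
        d[(u, v)] = 1
        if not directed:
            d[(v, u)] = 1
    for k in nodes:
        for i in nodes:
            dik = d[(i, k)]
            if dik is INF:
                continue
            for j in nodes:
                alt = dik + d[(k, j)]
                if alt < d[(i, j)]:
                    d[(i, j)] = alt
    return d


def fw_mean_reachable(nodes, edges, removed=(), directed=False):
    """Mean distance over reachable unordered (ordered if directed) pairs
    after removing a node subset; None if no pair is reachable."""
    kept = [n for n in nodes if n not in set(removed)]
    keep = set(kept)
    d = fw_distances(kept, [(u, v) for u, v in edges if u in keep and v in keep],
                     directed=directed)
    if directed:
        vals = [d[(a, b)] for a in kept for b in kept if a != b and d[(a, b)] < INF]
    else:
        vals = [d[(a, b)] for a, b in combinations(kept, 2) if d[(a, b)] < INF]
    return sum(vals) / len(vals) if vals else None


def enum_shortest_paths(nodes, edges, src, dst):
    """All shortest src->dst paths by breadth-first enumeration."""
    adj = {n: set() for n in nodes}
    for u, v in edges:
        if u != v:
            adj[u].add(v)
            adj[v].add(u)
    paths = [[src]]
    best = None
    found = []
    while paths and best is None or (paths and len(paths[0]) <= best):
        nxt = []
        for p in paths:
            if p[-1] == dst:
                if best is None:
                    best = len(p)
                if len(p) == best:
                    found.append(p)
                continue
            if best is not None and len(p) >= best:
                continue
            for nb in adj[p[-1]]:
                if nb not in p:
                    nxt.append(p + [nb])
        paths = nxt
    return found


def freq_oracle(nodes, edges, cancer):
    """Per non-cancer gene: number of (cancer, non-cancer) pairs for which
    it is interior to at least one shortest path."""
    cancer = set(cancer)
    non = [n for n in nodes if n not in cancer]
    counts = {g: 0 for g in non}
    for c in sorted(cancer):
        for g in non:
            paths = enum_shortest_paths(nodes, edges, c, g)
            interior = {v for p in paths for v in p[1:-1]}
            for v in interior:
                if v in counts:
                    counts[v] += 1
    return counts


def hyper_upper_tail_enum(N, K, n, k):
    """P[X >= k] for a hypergeometric draw, by exhaustive enumeration of
    all n-subsets of an N-item population with K successes."""
    succ = set(range(K))
    hit = total = 0
    for sub in combinations(range(N), n):
        total += 1
        if sum(1 for s in sub if s in succ) >= k:
            hit += 1
    return hit / total
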