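"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's code paths: exact rational
arithmetic for the Hardy-Weinberg test and OLS, exhaustive enumeration
for betweenness, quadratic scans for interval overlap.
"""

from fractions import Fraction
from math import comb


def hwe_exact_oracle(n_aa: int, n_ab: int, n_bb: int) -> Fraction:
    """Exact two-sided HWE p by full enumeration with integer weights.

    Conditional on allele counts, P(h) is proportional to
    C(n, h) * C(n - h, (na - h)/2) * 2^h over heterozygote counts h with
    the parity of the minor-allele count.
    """
    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab
    na = min(na, 2 * n - na)
    weights = {}
    for h in range(na % 2, min(na, 2 * n - na) + 1, 2):
        weights[h] = comb(n, h) * comb(n - h, (na - h) // 2) * (2**h)
    w_obs = weights[n_ab]
    total = sum(weights.values())
    tail = sum(w for w in weights.values() if w <= w_obs)
    return Fraction(tail, total)


def betweenness_oracle(adjacency: dict) -> dict:
    """Unnormalized betweenness by enumerating every simple path.

    ``adjacency`` maps node -> iterable of neighbors (symmetric for
    undirected graphs).  For each ordered pair (s, t) all shortest paths
    are found by breadth-limited enumeration; each interior node of each
    shortest path receives sigma_st(v)/sigma_st.  Undirected graphs halve
    the ordered-pair total.
    """
    nodes = list(adjacency)
    directed = any(
        v not in adjacency.get(u, ()) for u in nodes for v in adjacency[u]
    )
    score = {v: 0.0 for v in nodes}
    for s in nodes:
        for t in nodes:
            if s == t:
                continue
            paths = _all_shortest_paths(adjacency, s, t)
            if not paths:
                continue
            for path in paths:
                for v in path[1:-1]:
                    score[v] += 1.0 / len(paths)
    if not directed:
        score = {v: x / 2.0 for v, x in score.items()}
    return score


def _all_shortest_paths(adjacency, s, t):
    # BFS layering, then backtrack all geodesics
    from collections import deque

    dist = {s: 0}
    preds = {s: []}
    q = deque([s])
    while q:
        u = q.popleft()
        for v in adjacency[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                preds[v] = [u]
                q.append(v)
            elif dist[v] == dist[u] + 1:
                preds[v].append(u)
    if t not in dist:
        return []
    out = []

    def back(v, acc):
        if v == s:
            out.append([s] + acc)
            return
        for p in preds[v]:
            back(p, [v] + acc)

    back(t, [])
    return out


def ols_exact(x_rows, y):
    """OLS coefficients by normal equations in exact rational arithmetic."""
    x = [[Fraction(v) for v in row] for row in x_rows]
    yv = [Fraction(v) for v in y]
    p = len(x[0])
    xtx = [[sum(x[i][a] * x[i][b] for i in range(len(x))) for b in range(p)]
           for a in range(p)]
    xty = [sum(x[i][a] * yv[i] for i in range(len(x))) for a in range(p)]
    return _solve_fraction(xtx, xty)


def _solve_fraction(a, b):
    n = len(a)
    a = [row[:] + [b[i]] for i, row in enumerate(a)]
    for col in range(n):
        piv = next(r for r in range(col, n) if a[r][col] != 0)
        a[col], a[piv] = a[piv], a[col]
        pv = a[col][col]
        a[col] = [v / pv for v in a[col]]
        for r in range(n):
            if r != col and a[r][col] != 0:
                f = a[r][col]
                a[r] = [rv - f * cv for rv, cv in zip(a[r], a[col])]
    return [a[r][n] for r in range(n)]


def interval_overlap_oracle(genes, variants):
    """Quadratic scan: every (variant, gene) pair with the variant inside
    the gene's closed interval on the same chromosome."""
    hits = []
    for _, g in genes.iterrows():
        for _, v in variants.iterrows():
            if v["chrom"] == g["chrom"] and g["start"] <= v["pos"] <= g["end"]:
                hits.append((v["id"], g["gene"]))
    return sorted(hits)


def greedy_clump_oracle(snps, r2, threshold):
    """Hand-executable greedy clumping on explicit pairwise r^2 values.

    ``snps``: list of (snp, chrom, pos, abs_slope); ``r2``: dict of
    frozenset pairs -> r^2.  Returns surviving snp ids in selection order.
    """
    order = sorted(snps, key=lambda s: (-s[3], s[1], s[2], s[0]))
    removed = set()
    kept = []
    for s in order:
        if s[0] in removed:
            continue
        kept.append(s[0])
        for o in order:
            if o[0] in removed or o[0] in kept or o[1] != s[1]:
                continue
            if r2.get(frozenset((s[0], o[0])), 0.0) >= threshold:
                removed.add(o[0])
    return kept
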