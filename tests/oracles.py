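"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by the most direct method available
(full dynamic programming, union-find, exhaustive enumeration, direct
ECDF sweeps) without touching the implementation paths they check.
"""

from __future__ import annotations

import math

NEG = float("-inf")


def sw_affine(a: str, b: str, match: int = 1, mismatch: int = -2,
              gap_open: int = -3, gap_extend: int = -1):
    """Optimal local alignment (Gotoh) returning (score, identities).

    Identities are counted along one optimal-score traceback path.
    """
    n, m = len(a), len(b)
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    best = 0.0
    best_cell = (0, 0, "M")
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(0.0, M[i - 1][j - 1] + s, X[i][j], Y[i][j])
            if M[i][j] > best:
                best = M[i][j]
                best_cell = (i, j, "M")
    # traceback counting identities
    i, j, state = best_cell
    ident = 0
    while i > 0 and j > 0:
        if state == "M":
            if M[i][j] == 0:
                break
            if M[i][j] == X[i][j]:
                state = "X"
                continue
            if M[i][j] == Y[i][j]:
                state = "Y"
                continue
            s = match if a[i - 1] == b[j - 1] else mismatch
            if a[i - 1] == b[j - 1] and a[i - 1] != "N":
                ident += 1
            i, j = i - 1, j - 1
            state = "M"
        elif state == "X":
            if X[i][j] == X[i - 1][j] + gap_extend:
                i, state = i - 1, "X"
            else:
                i, state = i - 1, "M"
        else:
            if Y[i][j] == Y[i][j - 1] + gap_extend:
                j, state = j - 1, "Y"
            else:
                j, state = j - 1, "M"
    return best, ident


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def brute_force_edges(reads, min_pid=25.0, min_identical=75, max_evalue=1e-20,
                      ka_lambda=None, ka_k=0.3):
    """All-pairs optimal-local-alignment thresholding (both strands)."""
    if ka_lambda is None:
        lo, hi = 1e-6, 5.0
        for _ in range(200):
            mid = (lo + hi) / 2
            val = 0.25 * math.exp(mid) + 0.75 * math.exp(-2 * mid) - 1.0
            if val > 0:
                hi = mid
            else:
                lo = mid
        ka_lambda = (lo + hi) / 2
    ids = [r[0] for r in reads]
    seqs = [r[1] for r in reads]
    db = sum(len(s) for s in seqs)
    edges = set()
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            shorter = min(len(seqs[i]), len(seqs[j]))
            best_score, best_ident = NEG, 0
            for target in (seqs[j], revcomp(seqs[j])):
                score, ident = sw_affine(seqs[i], target)
                if ident > best_ident:
                    best_score, best_ident = score, ident
            pid = 100.0 * best_ident / shorter
            ev = ka_k * shorter * db * math.exp(-ka_lambda * best_score)
            if best_ident >= min_identical and pid >= min_pid and ev <= max_evalue:
                edges.add(frozenset((ids[i], ids[j])))
    return edges


class UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, x, y):
        rx, ry = self.find(x), self.find(y)
        if rx != ry:
            self.parent[rx] = ry


def union_find_components(nodes, edges):
    """Connected components via union-find; returns frozenset of frozensets."""
    uf = UnionFind(nodes)
    for u, v in edges:
        uf.union(u, v)
    groups: dict = {}
    for node in nodes:
        groups.setdefault(uf.find(node), set()).add(node)
    return frozenset(frozenset(g) for g in groups.values())


def ks_d_direct(a, b):
    """Sup ECDF difference by direct evaluation at every pooled point."""
    pooled = sorted(set(a) | set(b))
    d = 0.0
    for x in pooled:
        fa = sum(1 for v in a if v <= x) / len(a)
        fb = sum(1 for v in b if v <= x) / len(b)
        d = max(d, abs(fa - fb))
    return d


def kolmogorov_series(x: float, terms: int = 200) -> float:
    """Two-sided asymptotic KS tail probability by direct series."""
    if x <= 0:
        return 1.0
    return max(0.0, min(1.0, 2.0 * sum(
        (-1) ** (k - 1) * math.exp(-2.0 * k * k * x * x)
        for k in range(1, terms + 1)
    )))


def max_disjoint_intervals(intervals) -> int:
    """Max pairwise-disjoint interval count by O(n^2) DP (not greedy)."""
    iv = sorted(set(intervals), key=lambda p: p[1])
    best = [0] * len(iv)
    for i, (si, ei) in enumerate(iv):
        prev = 0
        for j, (sj, ej) in enumerate(iv[:i]):
            if ej <= si:
                prev = max(prev, best[j])
        best[i] = prev + 1
    return max(best, default=0)


def monophyly_by_rerooting(tree, focal) -> bool:
    """Monophyly oracle: try every non-focal leaf as root / outgroup."""
    import dendropy

    focal = set(focal)
    newick = tree.as_string(schema="newick")
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    rest = leaves - focal
    if len(focal) <= 1 or not rest or len(rest) <= 1:
        return True
    for out_label in sorted(rest):
        t = dendropy.Tree.get(data=newick, schema="newick",
                              preserve_underscores=True)
        out_node = None
        for lf in t.leaf_node_iter():
            if lf.taxon.label == out_label:
                out_node = lf
        t.reroot_at_edge(out_node.edge, update_bipartitions=False)
        mrca = t.mrca(taxon_labels=list(focal))
        under = {lf.taxon.label for lf in mrca.leaf_iter()}
        if under == focal:
            return True
    return False
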