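"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from the problem definition, not from the
package code paths it verifies.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd


def gotoh_score(a: str, b: str, match=1.0, mismatch=-1.0,
                gap_open=-4.0, gap_extend=-1.0) -> float:
    """Optimal global affine-gap alignment score (plain DP)."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + gap_extend * (i - 1)
    for j in range(1, m + 1):
        Y[0, j] = gap_open + gap_extend * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend)
    return max(M[n, m], X[n, m], Y[n, m])


def hamming(a: str, b: str) -> int:
    assert len(a) == len(b)
    return sum(x != y for x, y in zip(a, b))


def scan_fwgxg(aa: str) -> int | None:
    """Exhaustive window scan for the first [FW]-G-X-G."""
    for i in range(len(aa) - 3):
        w = aa[i:i + 4]
        if w[0] in "FW" and w[1] == "G" and w[3] == "G":
            return i
    return None


def connected_components(names: list[str], edges: set[tuple[str, str]]
                         ) -> dict[str, str]:
    """BFS components labelled by smallest member."""
    adj = {n: set() for n in names}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    label = {}
    for start in names:
        if start in label:
            continue
        comp = {start}
        frontier = [start]
        while frontier:
            x = frontier.pop()
            for y in adj[x]:
                if y not in comp:
                    comp.add(y)
                    frontier.append(y)
        lab = min(comp)
        for x in comp:
            label[x] = lab
    return label


def p_distance_by_counting(a: str, b: str, all_seqs: list[str]) -> float:
    """Column-wise complete-deletion p-distance for one pair."""
    keep = [i for i in range(len(a))
            if all(s[i] in "ACGT" for s in all_seqs)]
    diffs = sum(a[i] != b[i] for i in keep)
    return diffs / len(keep)


def exact_d_substrings(core: str, d_seq: str, min_len: int
                       ) -> set[tuple[int, int, int, int]]:
    """All maximal exact common substrings of length >= min_len.

    Returned as (core_start, core_end, d_start, d_end), maximality per
    diagonal (the stretch cannot be extended either way).
    """
    out = set()
    for i in range(len(core)):
        for j in range(len(d_seq)):
            if core[i] != d_seq[j]:
                continue
            if i > 0 and j > 0 and core[i - 1] == d_seq[j - 1]:
                continue  # not the start of a maximal run
            k = 0
            while (i + k < len(core) and j + k < len(d_seq)
                   and core[i + k] == d_seq[j + k]):
                k += 1
            if k >= min_len:
                out.add((i, i + k, j, j + k))
    return out


def best_chain_by_enumeration(candidates, d_rank: dict[str, int]):
    """Exhaustive search over candidate subsets for the optimal D chain.

    Returns the best (weight, -segments, -start_sum) key and one chain
    achieving it, under the ordering constraints.
    """
    best_key = (0.0, 0, 0)
    best_chain: list = []
    idx = list(range(len(candidates)))
    for r in range(1, len(candidates) + 1):
        for combo in itertools.combinations(idx, r):
            hits = [candidates[i] for i in combo]
            hits.sort(key=lambda h: h.junction_interval)
            ok = all(
                hits[i].junction_interval[1] <= hits[i + 1].junction_interval[0]
                and d_rank[hits[i].d_name] < d_rank[hits[i + 1].d_name]
                for i in range(len(hits) - 1))
            if not ok:
                continue
            w = sum(h.matched_nt - len(h.mismatch_positions) for h in hits)
            key = (w, -len(hits), -sum(h.junction_interval[0] for h in hits))
            if key > best_key:
                best_key = key
                best_chain = hits
    return best_key, best_chain


def random_additive_tree(rng: np.random.Generator, n_taxa: int):
    """Random binary unrooted tree; returns (distance DataFrame, splits).

    Splits are the nontrivial bipartitions as frozensets of frozensets.
    Distances are exact path lengths, hence additive by construction.
    """
    names = [f"T{chr(65 + i)}" for i in range(n_taxa)]
    # adjacency with branch lengths; start from a 3-star
    next_internal = [0]

    def new_internal():
        next_internal[0] += 1
        return f"I{next_internal[0]}"

    adj: dict[str, dict[str, float]] = {}

    def add_edge(u, v, w):
        adj.setdefault(u, {})[v] = w
        adj.setdefault(v, {})[u] = w

    def del_edge(u, v):
        del adj[u][v]
        del adj[v][u]

    center = new_internal()
    for leaf in names[:3]:
        add_edge(center, leaf, float(rng.uniform(0.05, 1.0)))
    for leaf in names[3:]:
        edges = [(u, v) for u in adj for v in adj[u] if u < v]
        u, v = edges[rng.integers(len(edges))]
        w = adj[u][v]
        mid = new_internal()
        split = float(rng.uniform(0.2, 0.8))
        del_edge(u, v)
        add_edge(u, mid, w * split)
        add_edge(mid, v, w * (1 - split))
        add_edge(mid, leaf, float(rng.uniform(0.05, 1.0)))

    # all-pairs leaf distances by BFS/DFS accumulation
    dist = pd.DataFrame(0.0, index=names, columns=names)
    for src in names:
        seen = {src: 0.0}
        frontier = [src]
        while frontier:
            x = frontier.pop()
            for y, w in adj[x].items():
                if y not in seen:
                    seen[y] = seen[x] + w
                    frontier.append(y)
        for dst in names:
            dist.loc[src, dst] = seen[dst]

    # nontrivial splits: remove each internal edge, collect leaf sides
    splits = set()
    leafset = set(names)
    for u in list(adj):
        for v in list(adj[u]):
            if u < v and u.startswith("I") and v.startswith("I"):
                side = set()
                frontier = [v]
                seen = {u, v}
                while frontier:
                    x = frontier.pop()
                    if x in leafset:
                        side.add(x)
                    for y in adj[x]:
                        if y not in seen:
                            seen.add(y)
                            frontier.append(y)
                if 1 < len(side) < n_taxa - 1:
                    splits.add(frozenset({frozenset(side),
                                          frozenset(leafset - side)}))
    return dist, splits


def tree_splits(phylo) -> set:
    """Nontrivial bipartitions of a package PhyloTree (for comparison)."""
    leaves = phylo.leaf_names
    n = len(leaves)
    out = set()
    for node in phylo.root.traverse(include_self=False):
        if node.is_tip():
            continue
        clade = frozenset(t.name for t in node.tips())
        if 1 < len(clade) < n - 1:
            out.add(frozenset({clade, frozenset(leaves - clade)}))
    return out


def four_point_ok(d: pd.DataFrame, quartet) -> bool:
    a, b, c, e = quartet
    s1 = d.loc[a, b] + d.loc[c, e]
    s2 = d.loc[a, c] + d.loc[b, e]
    s3 = d.loc[a, e] + d.loc[b, c]
    vals = sorted([s1, s2, s3])
    return abs(vals[1] - vals[2]) < 1e-9
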