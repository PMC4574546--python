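"""V-gene subgroup and allele assignment, p-distances and NJ phylogeny.

Subgroups follow the identity rule used for TR V nomenclature: V genes
sharing more than 75 % nucleotide identity in the V-REGION belong to the
same subgroup.  Because identity is not transitive, membership is taken
as single-linkage connected components — pairs below the threshold can
still share a subgroup through intermediate members, which is exactly
the situation a monophyly check on an NJ tree is used to confirm.
Within a subgroup, sequences >=98 % identical are alleles of one gene;
below that they are distinct genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from skbio import TreeNode

from .align import MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND, pairwise_identity

SUBGROUP_THRESHOLD_PCT = 75.0
ALLELE_THRESHOLD_PCT = 98.0

_AMBIG = set("RYSWKMBDHVN-.")


def identity_matrix(seqs: dict[str, str]) -> pd.DataFrame:
    """Symmetric percent-identity matrix over all pairs (diagonal 100)."""
    names = sorted(seqs)
    mat = pd.DataFrame(100.0, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            pid = pairwise_identity(seqs[a], seqs[b])
            mat.loc[a, b] = mat.loc[b, a] = pid
    return mat


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


@dataclass(frozen=True)
class SubgroupPartition:
    """Gene name -> subgroup label (label = lexicographically smallest member)."""

    mapping: dict[str, str]
    threshold_pct: float
    linkage: str = "single"

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for name, label in self.mapping.items():
            out.setdefault(label, []).append(name)
        return {k: sorted(v) for k, v in out.items()}


def _single_linkage(seqs: dict[str, str], threshold_pct: float,
                    inclusive: bool, ident: pd.DataFrame | None = None) -> SubgroupPartition:
    if not seqs:
        raise ValueError("at least one sequence required")
    if ident is None:
        ident = identity_matrix(seqs)
    uf = _UnionFind(list(seqs))
    names = sorted(seqs)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            pid = float(ident.loc[a, b])
            if (pid >= threshold_pct) if inclusive else (pid > threshold_pct):
                uf.union(a, b)
    roots: dict[str, str] = {}
    for name in names:
        root = uf.find(name)
        roots.setdefault(root, min(n for n in names if uf.find(n) == root))
    return SubgroupPartition({n: roots[uf.find(n)] for n in names}, threshold_pct)


def assign_subgroups(seqs: dict[str, str],
                     threshold_pct: float = SUBGROUP_THRESHOLD_PCT,
                     identity: pd.DataFrame | None = None) -> SubgroupPartition:
    """Single-linkage components of the >threshold identity graph."""
    return _single_linkage(seqs, threshold_pct, inclusive=False, ident=identity)


def call_alleles(subgroup_seqs: dict[str, str],
                 threshold_pct: float = ALLELE_THRESHOLD_PCT,
                 identity: pd.DataFrame | None = None) -> SubgroupPartition:
    """Within one subgroup: >=threshold components are genes, members alleles."""
    return _single_linkage(subgroup_seqs, threshold_pct, inclusive=True, ident=identity)


def p_distance_matrix(aligned_seqs: dict[str, str]) -> pd.DataFrame:
    """p-distances (base differences per site) under complete deletion.

    Every column holding a gap or ambiguity code in ANY sequence is
    removed before counting, matching the strictest treatment of gapped
    and missing data.
    """
    names = sorted(aligned_seqs)
    seqs = [aligned_seqs[n].upper() for n in names]
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("aligned sequences must share one length")
    arr = np.array([list(s) for s in seqs])
    keep = ~np.isin(arr, sorted(_AMBIG)).any(axis=0)
    if not keep.any():
        raise ValueError("complete deletion removed every site")
    arr = arr[:, keep]
    n = len(names)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = np.mean(arr[i] != arr[j])
    return pd.DataFrame(d, index=names, columns=names)


@dataclass
class PhyloTree:
    """Unrooted tree (trifurcating root) with branch lengths >= 0."""

    root: TreeNode

    @property
    def leaf_names(self) -> set[str]:
        return {t.name for t in self.root.tips()}

    def newick(self) -> str:
        return str(self.root).strip()


def nj_tree(matrix: pd.DataFrame) -> PhyloTree:
    """Canonical neighbor-joining on a symmetric distance matrix.

    Pair choice minimises the Q criterion; ties break on the
    lexicographically smallest pair of representative leaf names, so the
    topology is deterministic.  Negative branch lengths are clamped to 0.
    """
    names = list(matrix.index)
    if len(names) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d: dict[str, dict[str, float]] = {
        a: {b: float(matrix.loc[a, b]) for b in names if b != a} for a in names}
    nodes: dict[str, TreeNode] = {n: TreeNode(name=n) for n in names}
    rep: dict[str, str] = {n: n for n in names}  # smallest leaf under node
    active = sorted(names)
    counter = 0

    while len(active) > 3:
        n = len(active)
        r = {a: sum(d[a][b] for b in active if b != a) for a in active}
        best = None
        for i, a in enumerate(active):
            for b in active[i + 1:]:
                q = (n - 2) * d[a][b] - r[a] - r[b]
                key = tuple(sorted((rep[a], rep[b])))
                if best is None or q < best[0] - 1e-12 or (abs(q - best[0]) <= 1e-12 and key < best[1]):
                    best = (q, key, a, b)
        _, _, a, b = best
        la = 0.5 * d[a][b] + (r[a] - r[b]) / (2 * (n - 2))
        lb = d[a][b] - la
        parent = TreeNode()
        nodes[a].length = max(la, 0.0)
        nodes[b].length = max(lb, 0.0)
        parent.extend([nodes[a], nodes[b]])
        uname = f"_u{counter}"
        counter += 1
        nodes[uname] = parent
        rep[uname] = min(rep[a], rep[b])
        d[uname] = {}
        for k in active:
            if k in (a, b):
                continue
            dk = 0.5 * (d[a][k] + d[b][k] - d[a][b])
            d[uname][k] = d[k][uname] = dk
        active = sorted((k for k in active if k not in (a, b)), key=lambda x: rep[x])
        active.append(uname)
        active.sort(key=lambda x: rep[x])

    a, b, c = active
    la = 0.5 * (d[a][b] + d[a][c] - d[b][c])
    lb = 0.5 * (d[a][b] + d[b][c] - d[a][c])
    lc = 0.5 * (d[a][c] + d[b][c] - d[a][b])
    root = TreeNode()
    for node, ln in ((a, la), (b, lb), (c, lc)):
        nodes[node].length = max(ln, 0.0)
        root.append(nodes[node])
    return PhyloTree(root)


def is_monophyletic(tree: PhyloTree, leafset) -> bool:
    """True iff some edge bipartition separates exactly ``leafset``."""
    leafset = set(leafset)
    all_leaves = tree.leaf_names
    unknown = leafset - all_leaves
    if unknown:
        raise ValueError(f"unknown leaves: {sorted(unknown)}")
    if leafset == all_leaves or len(leafset) == 1:
        return True
    if not leafset:
        return False
    for node in tree.root.traverse(include_self=False):
        clade = {t.name for t in node.tips()} if not node.is_tip() else {node.name}
        if clade == leafset or (all_leaves - clade) == leafset:
            return True
    return False


# --- internal progressive multiple alignment ---------------------------------

def _profile_column_score(col_a: tuple[str, ...], col_b: tuple[str, ...]) -> float:
    total = 0.0
    for x in col_a:
        for y in col_b:
            if x == "-" or y == "-":
                continue
            total += MATCH if x == y else MISMATCH
    return total / (len(col_a) * len(col_b))


def _align_profiles(pa: list[str], pb: list[str]) -> list[str]:
    """Affine-gap Gotoh alignment of two profiles (lists of gapped rows)."""
    cols_a = list(zip(*pa))
    cols_b = list(zip(*pb))
    n, m = len(cols_a), len(cols_b)
    NEG = float("-inf")
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in profile B
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in profile A
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = GAP_OPEN + GAP_EXTEND * (i - 1)
    for j in range(1, m + 1):
        Y[0][j] = GAP_OPEN + GAP_EXTEND * (j - 1)
    for i in range(n + 1):
        for j in range(m + 1):
            if i > 0 and j > 0:
                s = _profile_column_score(cols_a[i - 1], cols_b[j - 1])
                M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            if i > 0:
                X[i][j] = max(X[i][j], M[i - 1][j] + GAP_OPEN, X[i - 1][j] + GAP_EXTEND)
            if j > 0:
                Y[i][j] = max(Y[i][j], M[i][j - 1] + GAP_OPEN, Y[i][j - 1] + GAP_EXTEND)
    # traceback, preferring substitution over gaps for determinism
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    state = max(("M", "X", "Y"), key=lambda s: {"M": M, "X": X, "Y": Y}[s][i][j])
    while i > 0 or j > 0:
        if state == "M":
            s = _profile_column_score(cols_a[i - 1], cols_b[j - 1])
            prev = M[i][j] - s
            out_a.append("".join(cols_a[i - 1]))
            out_b.append("".join(cols_b[j - 1]))
            i, j = i - 1, j - 1
            for cand in ("M", "X", "Y"):
                if abs({"M": M, "X": X, "Y": Y}[cand][i][j] - prev) <= 1e-9:
                    state = cand
                    break
        elif state == "X":
            out_a.append("".join(cols_a[i - 1]))
            out_b.append("-" * len(pb))
            prev = X[i][j]
            i -= 1
            state = "M" if i >= 0 and abs(M[i][j] + GAP_OPEN - prev) <= 1e-9 else "X"
        else:
            out_a.append("-" * len(pa))
            out_b.append("".join(cols_b[j - 1]))
            prev = Y[i][j]
            j -= 1
            state = "M" if j >= 0 and abs(M[i][j] + GAP_OPEN - prev) <= 1e-9 else "Y"
    out_a.reverse()
    out_b.reverse()
    rows_a = ["".join(col[k] for col in out_a) for k in range(len(pa))]
    rows_b = ["".join(col[k] for col in out_b) for k in range(len(pb))]
    return rows_a + rows_b


def progressive_msa(seqs: dict[str, str]) -> dict[str, str]:
    """Progressive multiple alignment guided by pairwise identities.

    Average-linkage guide tree on (100 - identity), then profile-profile
    alignment with the package scoring.  Intended for closely related TR
    V sets; pre-aligned input can bypass it entirely.
    """
    names = sorted(seqs)
    if len(names) == 1:
        return {names[0]: seqs[names[0]].upper()}
    ident = identity_matrix(seqs)
    cond = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            cond.append(100.0 - float(ident.loc[a, b]))
    order = linkage(np.array(cond), method="average")
    profiles: dict[int, tuple[list[str], list[str]]] = {
        i: ([n], [seqs[n].upper()]) for i, n in enumerate(names)}
    nxt = len(names)
    for left, right, *_ in order:
        na, pa = profiles.pop(int(left))
        nb, pb = profiles.pop(int(right))
        rows = _align_profiles(pa, pb)
        profiles[nxt] = (na + nb, rows)
        nxt += 1
    (final_names, final_rows), = profiles.values()
    return dict(zip(final_names, final_rows))
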