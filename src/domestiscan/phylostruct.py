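"""Population structure: SNP p-distances, neighbor-joining trees with
bootstrap support, Newick I/O, and allele-frequency-normalized PCA.

Distances are defined on diploid allele counts (|cA - cB| / 2 averaged
over jointly non-missing variants), matching how distance tools consume
unphased VCFs.  NJ is the Saitou-Nei agglomeration with a deterministic
lexicographic tie-break; PCA uses the stratification-correction
normalization (center by mean count, scale by sqrt(p(1-p))) with
per-variant mean imputation of missing calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "p_distance",
    "neighbor_joining",
    "bootstrap_support",
    "bipartitions",
    "write_newick",
    "parse_newick",
    "pca",
]


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray  # symmetric, zero diagonal
    pair_sites: np.ndarray  # jointly non-missing site count per pair

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T) or np.isnan(v).any():
            raise ValueError("distance matrix must be symmetric and NaN-free")
        self.values = v


@dataclass
class TreeNode:
    name: str = ""
    length: float = 0.0
    support: Optional[float] = None
    children: list["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf():
            return [self]
        out = []
        for ch in self.children:
            out.extend(ch.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves()]


def p_distance(counts: np.ndarray, ids: list[str]) -> DistanceMatrix:
    """Pairwise allele-sharing distance from a (variants x samples)
    diploid count matrix with -1 for missing calls."""
    counts = np.asarray(counts)
    if counts.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    S = counts.shape[1]
    valid = counts >= 0
    D = np.zeros((S, S))
    P = np.zeros((S, S), dtype=np.int64)
    for a in range(S):
        ca = counts[:, a].astype(float)
        joint = valid[:, a][:, None] & valid[:, a + 1 :]
        diff = np.abs(ca[:, None] - counts[:, a + 1 :]) / 2.0
        diff = np.where(joint, diff, 0.0)
        n_sites = joint.sum(axis=0)
        if (n_sites == 0).any():
            bad = [ids[a + 1 + int(j)] for j in np.nonzero(n_sites == 0)[0]]
            raise ValueError(
                f"no jointly non-missing sites between {ids[a]} and {bad}"
            )
        d = diff.sum(axis=0) / n_sites
        D[a, a + 1 :] = D[a + 1 :, a] = d
        P[a, a + 1 :] = P[a + 1 :, a] = n_sites
    return DistanceMatrix(list(ids), D, P)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining.

    Ties in the Q-criterion break toward the lexicographically smallest
    (label_i, label_j) pair.  Negative branch-length estimates are
    clamped to 0 with the residual moved to the sibling branch.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("NJ requires >= 3 taxa")
    D = dm.values.copy()
    nodes: list[TreeNode] = [TreeNode(name=i) for i in dm.ids]
    # sort key per active node: smallest leaf label underneath
    keys = [nd.name for nd in nodes]

    while len(nodes) > 2:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cand = np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-12))
        best = min(
            (tuple(sorted((keys[i], keys[j]))), i, j)
            for i, j in cand
            if i < j
        )
        _, i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        if li < 0:
            lj, li = lj + li, 0.0
        if lj < 0:
            li, lj = li + lj, 0.0
            logger.info("negative NJ branch clamped; residual moved to sibling")
        ni, nj = nodes[i], nodes[j]
        ni.length, nj.length = float(li), float(lj)
        parent = TreeNode(children=[ni, nj])
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [x for x in range(m) if x not in (i, j)]
        D2 = np.empty((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = dnew[keep]
        D2[-1, -1] = 0.0
        D = D2
        new_key = min(keys[i], keys[j])
        nodes = [nodes[x] for x in keep] + [parent]
        keys = [keys[x] for x in keep] + [new_key]

    # join the last two: unrooted tree written with a basal trifurcation
    # when possible; here we attach the remaining branch to the root
    a, b = nodes
    d_ab = max(D[0, 1], 0.0)
    if a.is_leaf() and not b.is_leaf():
        a, b = b, a
    if not a.is_leaf():
        a.children.append(b)
        b.length = float(d_ab)
        root = a
    else:
        a.length = b.length = float(d_ab / 2.0)
        root = TreeNode(children=[a, b])
    return root


def bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial splits of the (unrooted) tree, each canonicalized as
    the side not containing the alphabetically first leaf."""
    all_leaves = frozenset(tree.leaf_names())
    anchor = min(all_leaves)
    splits: set[frozenset] = set()

    def walk(node: TreeNode):
        for ch in node.children:
            side = frozenset(ch.leaf_names())
            if anchor in side:
                side = all_leaves - side
            if 1 < len(side) < len(all_leaves) - 1:
                splits.add(side)
            walk(ch)

    walk(tree)
    return splits


def bootstrap_support(
    counts: np.ndarray,
    ids: list[str],
    n_reps: int = 100,
    seed: int = 0,
) -> TreeNode:
    """Point-estimate NJ tree with % bootstrap support on internal nodes.

    Variants are resampled with replacement; support for each internal
    bipartition of the point tree is the percentage of replicate trees
    containing it.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    counts = np.asarray(counts)
    tree = neighbor_joining(p_distance(counts, ids))
    rng = np.random.default_rng(seed)
    tally: dict[frozenset, int] = {}
    for _ in range(n_reps):
        idx = rng.integers(0, counts.shape[0], size=counts.shape[0])
        rep = neighbor_joining(p_distance(counts[idx], ids))
        for split in bipartitions(rep):
            tally[split] = tally.get(split, 0) + 1

    all_leaves = frozenset(ids)
    anchor = min(all_leaves)

    def annotate(node: TreeNode, is_root: bool = False):
        for ch in node.children:
            if not ch.is_leaf():
                side = frozenset(ch.leaf_names())
                if anchor in side:
                    side = all_leaves - side
                if 1 < len(side) < len(all_leaves) - 1:
                    ch.support = 100.0 * tally.get(side, 0) / n_reps
            annotate(ch)

    annotate(tree, is_root=True)
    return tree


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------


def write_newick(tree: TreeNode) -> str:
    def fmt(node: TreeNode) -> str:
        if node.is_leaf():
            return f"{node.name}:{node.length:.10g}"
        inner = ",".join(fmt(ch) for ch in node.children)
        label = "" if node.support is None else f"{node.support:.10g}"
        return f"({inner}){label}:{node.length:.10g}"

    inner = ",".join(fmt(ch) for ch in tree.children)
    label = "" if tree.support is None else f"{tree.support:.10g}"
    return f"({inner}){label};"


def parse_newick(text: str) -> TreeNode:
    """Parse Newick with branch lengths and support values in the
    internal-node label position."""
    s = text.strip()
    if not s.endswith(";"):
        raise ValueError("Newick string must end with ';'")
    s = s[:-1]
    pos = 0

    def parse_node() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_node())
                if pos < len(s) and s[pos] == ",":
                    pos += 1
                    continue
                if pos < len(s) and s[pos] == ")":
                    pos += 1
                    break
                if pos >= len(s):
                    raise ValueError("unbalanced parentheses in Newick")
        start = pos
        while pos < len(s) and s[pos] not in ",():;":
            pos += 1
        label = s[start:pos]
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in ",();":
                pos += 1
            node.length = float(s[start:pos])
        if node.children:
            if label:
                node.support = float(label)
        else:
            node.name = label
        return node

    root = parse_node()
    if pos != len(s):
        raise ValueError(f"trailing characters in Newick: {s[pos:]!r}")
    return root


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def pca(
    counts: np.ndarray,
    n_components: int = 10,
    maf: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Genotype PCA with allele-frequency normalization.

    Each variant row is centered by its mean count and scaled by
    sqrt(p(1-p)) with p the alternate-allele frequency; missing calls
    are mean-imputed.  Returns (coordinates (samples x k), explained
    variance fractions).  Component sign is fixed so the
    largest-magnitude sample coordinate is positive.
    """
    C = np.asarray(counts, dtype=float)
    if C.shape[0] < 2 or C.shape[1] < 2:
        raise ValueError("need >= 2 variants and >= 2 samples")
    missing = C < 0
    C = np.where(missing, np.nan, C)
    mean = np.nanmean(C, axis=1)
    p = mean / 2.0
    keep = (p > maf) & (p < 1 - maf) & np.isfinite(p)
    if not keep.any():
        raise ValueError("no polymorphic variants after filters")
    C = C[keep]
    mean = mean[keep]
    p = p[keep]
    C = np.where(np.isnan(C), mean[:, None], C)
    M = (C - mean[:, None]) / np.sqrt(p * (1 - p))[:, None]
    if not np.any(M):
        raise ValueError("zero-variance matrix")
    # samples x variants orientation for the sample-covariance spectrum
    X = M.T / np.sqrt(M.shape[0])
    U, sv, _ = np.linalg.svd(X, full_matrices=False)
    k = min(n_components, sv.size)
    coords = U[:, :k] * sv[:k]
    evals = sv**2
    explained = evals[:k] / evals.sum()
    for c in range(k):
        col = coords[:, c]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, c] = -col
    return coords, explained
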