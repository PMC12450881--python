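"""Accession-level distances, UPGMA dendrograms, and marker PCA.

Distances between fingerprint band profiles default to Dice (Nei & Li):
d = 1 - 2a / (2a + b + c) over shared and mismatched band presences; a
simple-matching alternative is available. UPGMA merges the closest pair at
height d/2 with size-weighted (arithmetic-mean) cluster distances, the
convention under which leaf-to-leaf patristic distance reproduces the
input distance when the matrix is ultrametric. Ties are broken by the
lexicographically smallest pair of cluster labels so trees are
reproducible.
"""

from __future__ import annotations

import numpy as np

from .io import BandMatrix, DistanceMatrix, TreeNode

__all__ = [
    "accession_distance",
    "upgma",
    "cut_tree",
    "marker_pca",
]


def accession_distance(
    bands: BandMatrix, method: str = "dice", exclude_missing: bool = False
) -> DistanceMatrix:
    """Pairwise distances between accessions from their band profiles.

    ``dice``: d = 1 - 2a/(2a+b+c) with a = shared presences, b, c =
    presences private to either accession. ``simple_matching``:
    d = (b+c)/m over all m compared slots. By default every band slot is
    compared (a 0 is informative absence); with ``exclude_missing`` the
    slots of any primer that failed to amplify — the (0,0) pair marking a
    missing genotype — are excluded pairwise, and a pair with no
    comparable slot is then an error.
    """
    if method not in ("dice", "simple_matching"):
        raise ValueError(f"unknown distance method {method!r}")
    n = bands.n_accessions
    if n < 2:
        raise ValueError("need >= 2 accessions")
    B = bands.bands
    p = len(bands.primer_names)
    primer_ok = np.ones((n, p), dtype=bool)
    if exclude_missing:
        for j in range(p):
            primer_ok[:, j] = B[:, 2 * j : 2 * j + 2].sum(axis=1) > 0
    slot_ok = np.repeat(primer_ok, 2, axis=1)
    d = np.zeros((n, n))
    for i in range(n):
        for k in range(i + 1, n):
            ok = slot_ok[i] & slot_ok[k]
            if not ok.any():
                raise ValueError(
                    f"no comparable band slots between "
                    f"{bands.accession_ids[i]!r} and {bands.accession_ids[k]!r}"
                )
            x, y = B[i, ok].astype(bool), B[k, ok].astype(bool)
            a = int((x & y).sum())
            b = int((x & ~y).sum())
            c = int((~x & y).sum())
            if method == "dice":
                denom = 2 * a + b + c
                d[i, k] = d[k, i] = 1.0 - (2 * a / denom) if denom else 0.0
            else:
                d[i, k] = d[k, i] = (b + c) / ok.sum()
    return DistanceMatrix(list(bands.accession_ids), d)


def upgma(dist: DistanceMatrix) -> TreeNode:
    """UPGMA tree from a distance matrix.

    Iteratively merges the closest pair of clusters at height d/2; the
    distance from the merged cluster to any other is the size-weighted
    mean of its members' distances. Equal-distance ties pick the
    lexicographically smallest (label_i, label_j) pair. NaNs are rejected
    by the DistanceMatrix contract.
    """
    n = len(dist.labels)
    if n < 2:
        raise ValueError("need >= 2 taxa")
    nodes: dict[str, TreeNode] = {l: TreeNode(label=l) for l in dist.labels}
    sizes = {l: 1 for l in dist.labels}
    # representative label of a cluster = its lexicographically smallest leaf
    d: dict[frozenset, float] = {}
    active = sorted(dist.labels)
    for i, a in enumerate(active):
        for b in active[i + 1 :]:
            d[frozenset((a, b))] = dist.get(a, b)
    while len(active) > 1:
        best: tuple[str, str] | None = None
        best_d = np.inf
        for i, a in enumerate(active):
            for b in active[i + 1 :]:
                v = d[frozenset((a, b))]
                if v < best_d - 1e-15 or (
                    abs(v - best_d) <= 1e-15 and (best is None or (a, b) < best)
                ):
                    best_d, best = v, (a, b)
        a, b = best  # type: ignore[misc]
        merged = TreeNode(height=best_d / 2.0, children=[nodes[a], nodes[b]])
        rep = min(a, b)
        other = max(a, b)
        na, nb = sizes[a], sizes[b]
        for c in active:
            if c in (a, b):
                continue
            dc = (na * d[frozenset((a, c))] + nb * d[frozenset((b, c))]) / (na + nb)
            d[frozenset((rep, c))] = dc
        active = sorted(set(active) - {other})
        nodes[rep] = merged
        sizes[rep] = na + nb
    return nodes[active[0]]


def _merge_heights(tree: TreeNode) -> list[tuple[float, TreeNode]]:
    out: list[tuple[float, TreeNode]] = []

    def walk(node: TreeNode) -> None:
        if not node.is_leaf:
            out.append((node.height, node))
            for c in node.children:
                walk(c)

    walk(tree)
    return out


def cut_tree(tree: TreeNode, k: int) -> dict[str, int]:
    """Group labels from cutting the k-1 highest merges of a UPGMA tree.

    Returns leaf label -> group index; groups are numbered 1..k following
    the tree's leaf order, so results are deterministic.
    """
    leaves = tree.leaf_labels()
    n = len(leaves)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    merges = sorted(_merge_heights(tree), key=lambda t: -t[0])
    cut_nodes = {id(node) for _, node in merges[: k - 1]}
    groups: dict[str, int] = {}
    counter = 0

    def walk(node: TreeNode) -> None:
        nonlocal counter
        if id(node) in cut_nodes:
            for c in node.children:
                walk(c)
        else:
            counter += 1
            for leaf in node.leaf_labels():
                groups[leaf] = counter

    walk(tree)
    return groups


def marker_pca(
    bands: BandMatrix, n_components: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """PCA of the column-centered binary band matrix.

    Returns (coordinates, explained-variance proportions) for the leading
    ``n_components`` components of the band-covariance eigenproblem. A
    constant matrix (no variance anywhere) is an error.
    """
    if bands.n_accessions < 2:
        raise ValueError("need >= 2 accessions")
    X = bands.bands.astype(float)
    X = X - X.mean(axis=0)
    if not X.any():
        raise ValueError("constant band matrix: explained proportions undefined")
    C = (X.T @ X) / (X.shape[0] - 1)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    evecs = evecs[:, order]
    explained = evals / evals.sum()
    coords = X @ evecs[:, :n_components]
    return coords, explained[:n_components]
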