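"""Hierarchical clustering with centered-Pearson distance and complete linkage.

Distance between two profiles is d = 1 - r, where r is the Pearson
correlation computed over their pairwise-complete positions (each vector
centered by its own mean on those positions), so d in [0, 2], is zero for
identical shapes, 2 for perfectly anti-correlated ones, and is invariant to
adding a constant to a vector or rescaling it by a positive factor.
Agglomeration is complete linkage (inter-cluster distance = maximum pairwise
distance, which makes merge heights monotone), with ties broken toward the
lexicographically smallest pair of cluster indices so runs are reproducible.
Trees and the clustered matrix export to Java TreeView's CDT/GTR/ATR files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data import ExpressionMatrix
from .exceptions import (
    DomainError,
    FormatError,
    InsufficientOverlapError,
    UndefinedCorrelationError,
)

__all__ = [
    "DistanceMatrix",
    "LinkageTree",
    "centered_pearson_distance",
    "complete_linkage",
    "write_treeview",
    "read_gtr",
]

MIN_SHARED = 3  # minimum pairwise-complete positions for a correlation


@dataclass
class DistanceMatrix:
    ids: list
    d: np.ndarray  # symmetric, zero diagonal
    metric: str = "centered_pearson"

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise DomainError("distance matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise DomainError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise DomainError("distance matrix diagonal not zero")


@dataclass
class LinkageTree:
    """Merge sequence of an agglomerative clustering.

    ``merges`` is a list of (node_id, left_child, right_child, height); leaf
    ids are the item ids, internal nodes are NODE1X..NODE(n-1)X in merge
    order. ``leaf_order`` is the display order: at every merge the child
    containing the smallest original item index goes left.
    """

    leaves: list
    merges: list  # [(node, left, right, height), ...]

    def __post_init__(self) -> None:
        if len(self.merges) != len(self.leaves) - 1:
            raise DomainError(
                f"{len(self.leaves)} leaves need {len(self.leaves) - 1} merges, "
                f"got {len(self.merges)}")
        heights = [h for _, _, _, h in self.merges]
        if any(b < a - 1e-12 for a, b in zip(heights, heights[1:])):
            raise DomainError("merge heights must be non-decreasing")

    @property
    def heights(self) -> list:
        return [h for _, _, _, h in self.merges]

    @property
    def root(self) -> str:
        return self.merges[-1][0]

    def leaves_under(self, node) -> list:
        """Leaves of the subtree rooted at ``node`` (a leaf id or NODE id)."""
        children = {n: (l, r) for n, l, r, _ in self.merges}
        if node not in children:
            if node not in self.leaves:
                raise DomainError(f"unknown node {node!r}")
            return [node]
        l, r = children[node]
        return self.leaves_under(l) + self.leaves_under(r)

    def top_split(self) -> tuple[list, list]:
        """The two leaf sets produced by cutting below the root merge."""
        _, l, r, _ = self.merges[-1]
        return self.leaves_under(l), self.leaves_under(r)

    def leaf_order(self) -> list:
        pos = {leaf: i for i, leaf in enumerate(self.leaves)}
        children = {node: (l, r) for node, l, r, _ in self.merges}

        def min_index(x):
            if x in pos:
                return pos[x]
            l, r = children[x]
            return min(min_index(l), min_index(r))

        def walk(x):
            if x in pos:
                return [x]
            l, r = children[x]
            if min_index(l) > min_index(r):
                l, r = r, l
            return walk(l) + walk(r)

        return walk(self.root)


def centered_pearson_distance(matrix: ExpressionMatrix,
                              axis: str = "samples") -> DistanceMatrix:
    """Pairwise 1 - Pearson distance over pairwise-complete positions.

    axis="samples" clusters the sample columns (profiles across spots);
    axis="genes" clusters the spot rows.
    """
    if axis == "samples":
        X = matrix.values.to_numpy().T
        ids = list(matrix.sample_ids)
    elif axis == "genes":
        X = matrix.values.to_numpy()
        ids = list(matrix.spot_ids)
    else:
        raise DomainError(f"axis must be 'samples' or 'genes', got {axis!r}")

    M = (~np.isnan(X)).astype(float)
    X0 = np.nan_to_num(X, nan=0.0)
    n = M @ M.T                      # shared present positions
    k = len(ids)
    off = ~np.eye(k, dtype=bool)
    too_few = (n < MIN_SHARED) & off
    if too_few.any():
        i, j = np.argwhere(too_few)[0]
        raise InsufficientOverlapError(
            f"items {ids[i]!r} and {ids[j]!r} share only {int(n[i, j])} "
            f"present values (< {MIN_SHARED})")
    Sx = X0 @ M.T                    # sum of u over positions shared with v
    Sy = Sx.T
    Sxx = (X0 * X0) @ M.T
    Syy = Sxx.T
    Sxy = X0 @ X0.T
    cov = n * Sxy - Sx * Sy
    varx = n * Sxx - Sx * Sx
    vary = n * Syy - Sy * Sy
    degen = ((varx <= 0) | (vary <= 0)) & off
    if degen.any():
        i, j = np.argwhere(degen)[0]
        raise UndefinedCorrelationError(
            f"zero variance on shared positions for pair "
            f"({ids[i]!r}, {ids[j]!r})")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / np.sqrt(varx * vary)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 2.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(ids=ids, d=d, metric="centered_pearson")


def complete_linkage(dist: DistanceMatrix) -> LinkageTree:
    """Agglomerative complete-linkage clustering of a distance matrix.

    Inter-cluster distance is the maximum pairwise distance (Lance-Williams
    update d(i+j, k) = max(d(i,k), d(j,k))); among equal minima the pair with
    the lexicographically smallest (creation-order) cluster indices merges
    first, so output is deterministic.
    """
    n = len(dist.ids)
    if n < 2:
        raise DomainError("need at least 2 items to cluster")
    # working matrix indexed by cluster creation order: leaves 0..n-1,
    # internal clusters take rows/cols of their left member
    size = 2 * n - 1
    D = np.full((size, size), np.inf)
    D[:n, :n] = dist.d
    np.fill_diagonal(D, np.inf)
    active = list(range(n))
    names = {i: dist.ids[i] for i in range(n)}
    merges = []
    next_idx = n
    for step in range(1, n):
        # lexicographically first argmin over active pairs (i < j)
        best = (np.inf, None, None)
        for ai, i in enumerate(active):
            row = D[i, active[ai + 1:]]
            if row.size == 0:
                continue
            jloc = int(np.argmin(row))
            dij = row[jloc]
            if dij < best[0]:
                best = (dij, i, active[ai + 1 + jloc])
        h, i, j = best
        node = f"NODE{step}X"
        merges.append((node, names[i], names[j], float(h)))
        # new cluster occupies index next_idx
        new_row = np.maximum(D[i, :], D[j, :])
        D[next_idx, :] = new_row
        D[:, next_idx] = new_row
        D[next_idx, next_idx] = np.inf
        D[i, :] = np.inf
        D[:, i] = np.inf
        D[j, :] = np.inf
        D[:, j] = np.inf
        active = [a for a in active if a not in (i, j)] + [next_idx]
        names[next_idx] = node
        next_idx += 1
    return LinkageTree(leaves=list(dist.ids), merges=merges)


# ---------------------------------------------------------------------------
# Java TreeView export (CDT / GTR / ATR)
# ---------------------------------------------------------------------------

def _tree_lines(tree: LinkageTree, leaf_prefix: str) -> list[str]:
    leaf_id = {leaf: f"{leaf_prefix}{i}X" for i, leaf in enumerate(tree.leaves)}

    def ref(x):
        return leaf_id.get(x, x)

    return [
        f"{node}\t{ref(l)}\t{ref(r)}\t{1.0 - h:.6g}"
        for node, l, r, h in tree.merges
    ]


def write_treeview(matrix: ExpressionMatrix,
                   gene_tree: LinkageTree | None,
                   sample_tree: LinkageTree | None,
                   out_prefix) -> list[str]:
    """Emit TreeView files: CDT always; GTR/ATR when the matching tree exists.

    CDT rows/columns follow the trees' leaf orders (input order otherwise);
    similarities in GTR/ATR are 1 - merge height. Returns the paths written.
    """
    out_prefix = str(out_prefix)
    written = []
    row_ids = list(matrix.spot_ids)
    col_ids = list(matrix.sample_ids)
    if gene_tree is not None:
        if sorted(gene_tree.leaves) != sorted(row_ids):
            raise DomainError("gene tree leaves do not match matrix rows")
        row_ids = gene_tree.leaf_order()
    if sample_tree is not None:
        if sorted(sample_tree.leaves) != sorted(col_ids):
            raise DomainError("sample tree leaves do not match matrix columns")
        col_ids = sample_tree.leaf_order()

    gid = {r: f"GENE{i}X" for i, r in enumerate(matrix.spot_ids)}
    aid = {c: f"ARRY{i}X" for i, c in enumerate(matrix.sample_ids)}
    vals = matrix.values

    def fmt(v):
        return "" if pd.isna(v) else f"{v:.6g}"

    lines = []
    header = (["GID"] if gene_tree is not None else []) + \
        ["UNIQID", "NAME", "GWEIGHT"] + col_ids
    lines.append("\t".join(header))
    lead = 4 if gene_tree is not None else 3
    if sample_tree is not None:
        lines.append("\t".join(["AID"] + [""] * (lead - 1) + [aid[c] for c in col_ids]))
    lines.append("\t".join(["EWEIGHT"] + [""] * (lead - 1) + ["1"] * len(col_ids)))
    names = matrix.gene_symbols
    for r in row_ids:
        name = str(names.loc[r]) if names is not None else str(r)
        row = ([gid[r]] if gene_tree is not None else []) + [str(r), name, "1"]
        row += [fmt(v) for v in vals.loc[r, col_ids]]
        lines.append("\t".join(row))
    cdt = out_prefix + ".cdt"
    Path(cdt).write_text("\n".join(lines) + "\n", encoding="utf-8")
    written.append(cdt)

    if gene_tree is not None:
        gtr = out_prefix + ".gtr"
        Path(gtr).write_text(
            "\n".join(_tree_lines(gene_tree, "GENE")) + "\n", encoding="utf-8")
        written.append(gtr)
    if sample_tree is not None:
        atr = out_prefix + ".atr"
        Path(atr).write_text(
            "\n".join(_tree_lines(sample_tree, "ARRY")) + "\n", encoding="utf-8")
        written.append(atr)
    return written


def read_gtr(path, leaves: list) -> LinkageTree:
    """Parse a GTR/ATR file back into a LinkageTree (writer's inverse).

    ``leaves`` supplies the original item ids in matrix order, matching the
    GENE<i>X / ARRY<i>X references by position.
    """
    text = Path(path).read_text(encoding="utf-8")
    merges = []
    for ln in text.splitlines():
        if not ln.strip():
            continue
        parts = ln.split("\t")
        if len(parts) != 4:
            raise FormatError(f"{path}: bad tree line {ln!r}")
        node, l, r, sim = parts

        def resolve(x):
            if x.startswith(("GENE", "ARRY")) and x.endswith("X"):
                return leaves[int(x[4:-1])]
            return x

        merges.append((node, resolve(l), resolve(r), 1.0 - float(sim)))
    return LinkageTree(leaves=list(leaves), merges=merges)
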