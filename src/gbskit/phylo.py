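"""Distance-based phylogenetics for dosage matrices.

The distance between two samples is the allele-sharing distance: the mean
over sites called in both of |dosage_i - dosage_j| / 2, bounded in [0, 1]
(0 for identical genotypes, 1 for opposite homozygotes everywhere). Trees
are built with Saitou-Nei neighbour joining using the Studier-Keppler
Q-criterion, which recovers the generating topology and branch lengths
exactly on additive distance matrices. Support values come from a column
(site) bootstrap: resample sites with replacement, rebuild distance + NJ,
and map bipartition frequencies onto the full-data tree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .snpmatrix import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "PhyloError",
    "pairwise_distance",
    "nj_tree",
    "bootstrap_support",
]


class PhyloError(ValueError):
    """Raised for degenerate distance input or matrices too small to use."""


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with per-pair shared-site counts."""

    ids: list[str]
    values: np.ndarray
    shared_sites: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise PhyloError(f"distance matrix shape {self.values.shape} != ({n},{n})")
        if not np.allclose(self.values, self.values.T):
            raise PhyloError("distance matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise PhyloError("distance matrix diagonal must be zero")
        if np.any(self.values < 0):
            raise PhyloError("negative distances")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = (self.ids.index(p) for p in pair)
        return float(self.values[i, j])

    def write_phylip(self, path: str) -> None:
        """Square PHYLIP distance-matrix format."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for i, name in enumerate(self.ids):
                row = " ".join(f"{v:.6f}" for v in self.values[i])
                fh.write(f"{name:<10s} {row}\n")


@dataclass
class TreeNode:
    """A node of a (generally unrooted) phylogenetic tree.

    Leaves carry ``name``; internal nodes may carry bootstrap ``support``
    (percent). ``length`` is the branch to the parent; negative NJ length
    estimates are clamped to zero at construction with the raw value kept
    in ``raw_length``.
    """

    name: str | None = None
    length: float | None = None
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)
    raw_length: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["TreeNode"]:
        yield self
        for c in self.children:
            yield from c.walk()

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.walk() if n.is_leaf]

    def set_length(self, value: float) -> None:
        self.raw_length = float(value)
        if value < 0:
            logger.info("clamping negative branch length %.3g to 0", value)
        self.length = max(0.0, float(value))

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each canonicalized to the side without the
        lexicographically smallest leaf."""
        all_leaves = frozenset(self.leaf_names())
        anchor = min(all_leaves)
        splits: set[frozenset[str]] = set()
        for node in self.walk():
            if node is self or node.is_leaf:
                continue
            side = frozenset(node.leaf_names())
            if anchor in side:
                side = all_leaves - side
            if 2 <= len(side) <= len(all_leaves) - 2:
                splits.add(side)
        return splits

    def to_newick(self, include_support: bool = True) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                label = node.name or ""
            else:
                inner = ",".join(fmt(c) for c in node.children)
                label = f"({inner})"
                if include_support and node.support is not None:
                    label += f"{node.support:g}"
            if node.length is not None:
                label += f":{node.length:g}"
            return label

        return fmt(self) + ";"


def pairwise_distance(
    matrix: GenotypeMatrix, min_shared_sites: int = 1
) -> DistanceMatrix:
    """Allele-sharing distance over pairwise-complete sites.

    d(i, j) = mean over sites called in both samples of |d_i - d_j| / 2.
    Pairs sharing fewer than ``min_shared_sites`` called sites are an error
    (all offending pairs listed), as is a sample with no called sites.
    """
    if matrix.n_samples < 2:
        raise PhyloError("need >= 2 samples for pairwise distances")
    called = matrix.called
    empty = np.flatnonzero(called.sum(axis=1) == 0)
    if empty.size:
        raise PhyloError(
            "samples with zero called sites: "
            + ", ".join(matrix.samples[i] for i in empty)
        )
    G = matrix.dosages.astype(float)
    G[~called] = np.nan
    n = matrix.n_samples
    dist = np.zeros((n, n))
    shared = np.zeros((n, n), dtype=int)
    bad_pairs = []
    for i in range(n):
        diff = np.abs(G[i] - G[i + 1:]) / 2.0  # (n-i-1, sites) with NaN at missing
        cnt = np.sum(~np.isnan(diff), axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.nansum(diff, axis=1) / np.where(cnt > 0, cnt, 1)
        for k, j in enumerate(range(i + 1, n)):
            shared[i, j] = shared[j, i] = cnt[k]
            if cnt[k] < min_shared_sites:
                bad_pairs.append((matrix.samples[i], matrix.samples[j]))
                continue
            dist[i, j] = dist[j, i] = d[k] if cnt[k] else 0.0
    if bad_pairs:
        raise PhyloError(
            f"pairs with < {min_shared_sites} shared called sites: {bad_pairs}"
        )
    np.fill_diagonal(shared, called.sum(axis=1))
    return DistanceMatrix(list(matrix.samples), dist, shared)


def nj_tree(dist: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbour joining with the Studier-Keppler Q-criterion.

    Deterministic: Q-ties are broken by the lowest (i, j) index pair in the
    current working order, which is the input taxon order. Returns an
    unrooted tree as a trifurcating root (binary elsewhere). On an additive
    matrix the generating topology and branch lengths are recovered exactly
    up to floating-point error.
    """
    n = len(dist.ids)
    if n < 3:
        raise PhyloError("neighbour joining needs >= 3 taxa")
    D = dist.values.copy()
    nodes: list[TreeNode] = [TreeNode(name=i) for i in dist.ids]
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # lowest-(i,j) tie-break: argmin of the flattened row-major matrix
        flat = np.argmin(Q)
        ai, aj = divmod(flat, m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.set_length(li)
        child_j.set_length(lj)
        new = TreeNode(children=[child_i, child_j])
        # distances from the new node to every other active node
        new_row = np.zeros(D.shape[0])
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (D[i, k] + D[j, k] - dij)
        D = np.vstack([D, new_row])
        new_col = np.append(new_row, 0.0)
        D = np.hstack([D, new_col[:, None]])
        nodes.append(new)
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    # join the last three nodes at a trifurcating root
    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for k, L in zip((a, b, c), (la, lb, lc)):
        nodes[k].set_length(L)
    return TreeNode(children=[nodes[a], nodes[b], nodes[c]])


def bootstrap_support(
    matrix: GenotypeMatrix,
    replicates: int = 1000,
    seed: int | None = None,
    min_shared_sites: int = 1,
) -> TreeNode:
    """Column-bootstrap support mapped onto the full-data NJ tree.

    Sites are resampled with replacement ``replicates`` times; each
    replicate's distance matrix and NJ tree are recomputed, and every
    internal edge of the full-data tree is annotated with the percentage of
    replicate trees containing its bipartition. Seeded and reproducible.
    """
    if replicates < 1:
        raise PhyloError("replicates must be >= 1")
    if matrix.n_sites < 2:
        raise PhyloError("bootstrap needs >= 2 sites to resample")
    rng = np.random.default_rng(seed)
    full = nj_tree(pairwise_distance(matrix, min_shared_sites))
    counts: dict[frozenset[str], int] = {bp: 0 for bp in full.bipartitions()}
    for _ in range(replicates):
        cols = np.sort(rng.integers(0, matrix.n_sites, size=matrix.n_sites))
        boot = _resample(matrix, cols)
        tree = nj_tree(pairwise_distance(boot, min_shared_sites))
        for bp in tree.bipartitions():
            if bp in counts:
                counts[bp] += 1
    all_leaves = frozenset(full.leaf_names())
    anchor = min(all_leaves)
    for node in full.walk():
        if node is full or node.is_leaf:
            continue
        side = frozenset(node.leaf_names())
        if anchor in side:
            side = all_leaves - side
        if side in counts:
            node.support = 100.0 * counts[side] / replicates
    return full


def _resample(matrix: GenotypeMatrix, cols: np.ndarray) -> GenotypeMatrix:
    """Column resample that keeps site keys unique (index-tagged copies)."""
    from .snpmatrix import SiteKey

    sites = [
        SiteKey("bs", int(k), matrix.sites[c].ref, matrix.sites[c].alt)
        for k, c in enumerate(cols)
    ]
    return GenotypeMatrix(matrix.samples, sites, matrix.dosages[:, cols])
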