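"""p-distances, neighbor-joining trees, bootstrap supports, Newick output.

The diploid p-distance between two samples is the mean over shared
non-missing variant sites of |dosage_i - dosage_j| / 2 (allele-sharing
distance, pairwise deletion). NJ follows Saitou & Nei with the standard
Q-criterion and a deterministic lowest-index tie break.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from popdiv.variant_io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


class ZeroOverlapError(ValueError):
    """A sample pair shares no non-missing variant site."""


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    d: np.ndarray
    n_shared_sites: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.sample_ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match sample_ids")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.abs(np.diag(self.d)) > 1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.d < -1e-12):
            raise ValueError("distances must be non-negative")


@dataclass
class TreeNode:
    """Node of an (unrooted, stored rooted-at-trifurcation) tree."""

    name: str | None = None
    children: list["TreeNode"] = field(default_factory=list)
    branch_length: float = 0.0  # length of the edge to the parent
    support: float | None = None  # percent, internal edges only

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [lf.name for lf in self.leaves()]


@dataclass
class PhyloTree:
    root: TreeNode
    sample_ids: list[str]

    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial bipartitions, each encoded as the side that does NOT
        contain the lexicographically smallest leaf name."""
        all_leaves = frozenset(self.leaf_names())
        ref = min(all_leaves)
        n = len(all_leaves)
        out: set[frozenset] = set()
        for node, _parent in _walk(self.root):
            if node is self.root or node.is_leaf:
                continue
            side = frozenset(node.leaf_names())
            if len(side) in (0, 1, n - 1, n):
                continue
            if ref in side:
                side = all_leaves - side
            out.add(side)
        return out

    def edge_bipartition_map(self) -> dict[frozenset, TreeNode]:
        all_leaves = frozenset(self.leaf_names())
        ref = min(all_leaves)
        n = len(all_leaves)
        out: dict[frozenset, TreeNode] = {}
        for node, _parent in _walk(self.root):
            if node is self.root or node.is_leaf:
                continue
            side = frozenset(node.leaf_names())
            if len(side) in (0, 1, n - 1, n):
                continue
            if ref in side:
                side = all_leaves - side
            out[side] = node
        return out

    def to_newick(self, include_support: bool = True) -> str:
        return _newick(self.root, include_support, top=True) + ";"

    def leaf_path_lengths(self) -> tuple[list[str], np.ndarray]:
        """Patristic distances between all leaf pairs (oracle-friendly)."""
        names = sorted(self.leaf_names())
        index = {n: i for i, n in enumerate(names)}
        n = len(names)
        dist = np.zeros((n, n))

        def descend(node: TreeNode) -> dict[str, float]:
            if node.is_leaf:
                return {node.name: 0.0}
            groups: list[dict[str, float]] = []
            for c in node.children:
                sub = descend(c)
                groups.append({k: v + c.branch_length for k, v in sub.items()})
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for a, da in groups[gi].items():
                        for b, db in groups[gj].items():
                            dist[index[a], index[b]] = da + db
                            dist[index[b], index[a]] = da + db
            merged: dict[str, float] = {}
            for g in groups:
                merged.update(g)
            return merged

        descend(self.root)
        return names, dist


def _walk(node: TreeNode, parent: TreeNode | None = None):
    yield node, parent
    for c in node.children:
        yield from _walk(c, node)


def _newick(node: TreeNode, include_support: bool, top: bool = False) -> str:
    if node.is_leaf:
        body = node.name
    else:
        inner = ",".join(_newick(c, include_support) for c in node.children)
        label = ""
        if include_support and node.support is not None:
            label = str(int(round(node.support)))
        body = f"({inner}){label}"
    if top:
        return body
    return f"{body}:{node.branch_length:.6g}"


def p_distance_matrix(
    matrix: GenotypeMatrix, samples: list[str] | None = None
) -> DistanceMatrix:
    """Allele-sharing p-distance with pairwise deletion over variant sites."""
    idx = matrix.sample_indices(samples)
    ids = [matrix.sample_ids[i] for i in idx]
    cols = np.flatnonzero(matrix.is_variant)
    dos = matrix.dosages[np.ix_(idx, cols)].astype(float)
    dos[dos == MISSING] = np.nan
    n = len(ids)
    d = np.zeros((n, n))
    shared = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~np.isnan(dos[i]) & ~np.isnan(dos[j])
            m = int(ok.sum())
            if m == 0:
                raise ZeroOverlapError(
                    f"samples {ids[i]!r} and {ids[j]!r} share no called variant site"
                )
            dij = float(np.abs(dos[i, ok] - dos[j, ok]).mean() / 2.0)
            d[i, j] = d[j, i] = dij
            shared[i, j] = shared[j, i] = m
    return DistanceMatrix(sample_ids=ids, d=d, n_shared_sites=shared)


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    """Clamp negative branch lengths, moving the deficit to the sibling."""
    if li < 0:
        lj += li
        li = 0.0
        logger.debug("negative NJ branch clamped")
    if lj < 0:
        li += lj
        lj = 0.0
        logger.debug("negative NJ branch clamped")
    return max(li, 0.0), max(lj, 0.0)


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining.

    Deterministic: ties on the Q criterion resolve to the lowest-index pair.
    Negative branch lengths are clamped to zero with the deficit moved to the
    sibling edge. Returns a tree rooted at the final trifurcation (n >= 3).
    """
    n = len(dm.sample_ids)
    if n < 3:
        raise ValueError("nj_tree requires >= 3 taxa")
    d = dm.d.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=s) for s in dm.sample_ids]

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index tie break: argmin of flattened row-major array
        flat = int(np.argmin(q))
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        li = d[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        li, lj = _clamp_pair(li, lj)
        new = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].branch_length = li
        nodes[j].branch_length = lj
        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [x for x in range(m) if x not in (i, j)]
        d2 = np.empty((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = dnew[keep]
        d2[:-1, -1] = dnew[keep]
        d2[-1, -1] = 0.0
        d = d2
        nodes = [nodes[x] for x in keep] + [new]

    # final three nodes: solve the three-point equations
    a, b, c = nodes
    la = (d[0, 1] + d[0, 2] - d[1, 2]) / 2.0
    lb = (d[0, 1] + d[1, 2] - d[0, 2]) / 2.0
    lc = (d[0, 2] + d[1, 2] - d[0, 1]) / 2.0
    a.branch_length = max(la, 0.0)
    b.branch_length = max(lb, 0.0)
    c.branch_length = max(lc, 0.0)
    root = TreeNode(children=[a, b, c])
    return PhyloTree(root=root, sample_ids=list(dm.sample_ids))


def bootstrap_supports(
    matrix: GenotypeMatrix,
    samples: list[str] | None = None,
    replicates: int = 1000,
    seed: int | None = None,
) -> PhyloTree:
    """NJ tree with bootstrap supports on internal edges.

    Variant-site columns are resampled with replacement per replicate;
    support is the percent of replicate trees containing each bipartition of
    the original tree. Replicates where some pair loses all shared sites are
    skipped with a warning.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    idx = matrix.sample_indices(samples)
    ids = [matrix.sample_ids[i] for i in idx]
    if len(ids) < 4:
        raise ValueError("bootstrap_supports requires >= 4 samples")
    tree = nj_tree(p_distance_matrix(matrix, samples=ids))
    edge_map = tree.edge_bipartition_map()
    if not edge_map:
        return tree

    cols = np.flatnonzero(matrix.is_variant)
    sub = matrix.take_sites(cols).take_samples(ids)
    rng = np.random.default_rng(seed)
    hits = {bip: 0 for bip in edge_map}
    used = 0
    for _ in range(replicates):
        resample = rng.integers(0, sub.n_sites, size=sub.n_sites)
        resample.sort()  # keep per-chrom order (duplicates collapse positions)
        boot = _resampled_matrix(sub, resample)
        try:
            bt = nj_tree(p_distance_matrix(boot))
        except ZeroOverlapError:
            logger.warning("bootstrap replicate skipped: zero-overlap pair")
            continue
        used += 1
        bips = bt.bipartitions()
        for bip in hits:
            if bip in bips:
                hits[bip] += 1
    if used == 0:
        raise ValueError("all bootstrap replicates failed")
    for bip, node in edge_map.items():
        node.support = 100.0 * hits[bip] / used
    logger.info("bootstrap: %d/%d replicates used", used, replicates)
    return tree


def _resampled_matrix(matrix: GenotypeMatrix, cols: np.ndarray) -> GenotypeMatrix:
    """Column resample that sidesteps the sorted-position invariant by
    relabelling coordinates 1..m on a single pseudo-chromosome."""
    m = len(cols)
    return GenotypeMatrix(
        sample_ids=list(matrix.sample_ids),
        chrom=np.asarray(["boot"] * m, dtype=object),
        pos=np.arange(1, m + 1, dtype=np.int64),
        is_variant=matrix.is_variant[cols],
        ref=matrix.ref[cols],
        alt=matrix.alt[cols],
        dosages=matrix.dosages[:, cols],
    )
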