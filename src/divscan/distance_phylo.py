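"""Pairwise genetic distances and distance-based trees (UPGMA, NJ).

Distances are p-distances (substitutions per site) computed from
genotype matrices; heterozygous diploid calls are compared as unordered
allele pairs (allele-sharing distance).  Trees are built by
average-linkage agglomeration (UPGMA, rooted, ultrametric) or
Saitou-Nei neighbor joining (unrooted), with deterministic tie-breaking
by label order, and serialised as Newick.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .vcf_io import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)

_NEWICK_UNSAFE = re.compile(r"[\s()\[\]{}:;,']")


@dataclass
class TreeNode:
    """A node of a rooted tree; branch ``length`` leads to the parent."""

    name: Optional[str] = None
    length: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)
    support: Optional[float] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for ch in self.children:
            out.extend(ch.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [lf.name for lf in self.leaves()]

    def depths(self) -> dict[str, float]:
        """Root-to-leaf path lengths, keyed by leaf name."""
        out: dict[str, float] = {}

        def walk(node: TreeNode, acc: float) -> None:
            acc += node.length
            if node.is_leaf:
                out[node.name] = acc
            for ch in node.children:
                walk(ch, acc)

        walk(self, -self.length)  # root's own length does not count
        return out

    def bipartitions(self) -> set[frozenset]:
        """Leaf-name sets under each internal edge (excluding root/leaves)."""
        all_leaves = frozenset(self.leaf_names())
        parts: set[frozenset] = set()

        def walk(node: TreeNode) -> frozenset:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset().union(*(walk(ch) for ch in node.children))
            if 1 < len(below) < len(all_leaves):
                parts.add(below)
            return below

        walk(self)
        return parts

    def cophenetic(self) -> "DistanceMatrix":
        """Leaf-to-leaf path-length distances through the tree."""
        labels = sorted(self.leaf_names())
        index = {l: i for i, l in enumerate(labels)}
        n = len(labels)
        d = np.zeros((n, n))

        def walk(node: TreeNode) -> dict[str, float]:
            if node.is_leaf:
                return {node.name: node.length}
            groups = [walk(ch) for ch in node.children]
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for la, da in groups[gi].items():
                        for lb, db in groups[gj].items():
                            d[index[la], index[lb]] = d[index[lb], index[la]] = da + db
            merged = {}
            for g in groups:
                for l, dist in g.items():
                    merged[l] = dist + node.length
            return merged

        walk(self)
        return DistanceMatrix(labels=labels, d=d)


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch with labels")
        if not np.allclose(self.d, self.d.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.nanmin(self.d) < 0:
            raise ValueError("distances must be non-negative")

    def get(self, a: str, b: str) -> float:
        return float(self.d[self.labels.index(a), self.labels.index(b)])

    def write_tsv(self, path: str, lower_triangle: bool = False) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for i, lab in enumerate(self.labels):
                if lower_triangle:
                    vals = [f"{self.d[i, j]:.6f}" for j in range(i)]
                else:
                    vals = [f"{self.d[i, j]:.6f}" for j in range(len(self.labels))]
                fh.write(lab + "\t" + "\t".join(vals) + "\n")


def pairwise_distance(matrix: GenotypeMatrix, mode: str = "het") -> DistanceMatrix:
    """p-distance matrix between all samples.

    ``mode="hom"`` expects the all-homozygous matrix and scores allele
    mismatches per site; ``mode="het"`` uses the allele-sharing distance
    ``1 - (shared alleles / ploidy)`` averaged over sites, comparing
    diploid genotypes as unordered pairs.  Requires a matrix without
    missing calls.
    """
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples for pairwise distances")
    if matrix.missing_mask.any():
        raise ValueError("pairwise distances require a no-missing matrix")
    if mode not in ("hom", "het"):
        raise ValueError("mode must be 'hom' or 'het'")
    calls = matrix.calls  # sites x samples x ploidy
    n_sites, n_samples, ploidy = calls.shape
    labels = list(matrix.samples)
    d = np.zeros((n_samples, n_samples))
    if n_sites == 0:
        return DistanceMatrix(labels=labels, d=d)
    for i in range(n_samples):
        gi = calls[:, i, :]
        for jdx in range(i + 1, n_samples):
            gj = calls[:, jdx, :]
            if ploidy == 1:
                dist = float((gi[:, 0] != gj[:, 0]).mean())
            else:
                # unordered allele-pair sharing per site
                ai = np.sort(gi, axis=1)
                aj = np.sort(gj, axis=1)
                direct = (ai == aj).sum(axis=1)
                crossed = (ai == aj[:, ::-1]).sum(axis=1)
                shared = np.maximum(direct, crossed)
                dist = float((1.0 - shared / ploidy).mean())
            d[i, jdx] = d[jdx, i] = dist
    return DistanceMatrix(labels=labels, d=d)


def upgma(dm: DistanceMatrix) -> TreeNode:
    """Average-linkage agglomeration; branch lengths are half the merge height.

    Ties in the minimum distance are broken by label order, so output is
    deterministic.  The result is ultrametric by construction.
    """
    if np.isnan(dm.d).any():
        raise ValueError("distance matrix contains NaN")
    clusters: list[tuple[str, TreeNode, int, float]] = [
        (lab, TreeNode(name=lab), 1, 0.0) for lab in dm.labels
    ]
    d = dm.d.copy()

    while len(clusters) > 1:
        n = len(clusters)
        best = None
        for i in range(n):
            for j in range(i + 1, n):
                key = (d[i, j], clusters[i][0], clusters[j][0])
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        height = d[i, j] / 2.0
        (lab_i, node_i, size_i, h_i) = clusters[i]
        (lab_j, node_j, size_j, h_j) = clusters[j]
        node_i.length = height - h_i
        node_j.length = height - h_j
        merged = TreeNode(children=[node_i, node_j])
        new_label = min(lab_i, lab_j)

        new_row = np.empty(n)
        for k in range(n):
            new_row[k] = (size_i * d[i, k] + size_j * d[j, k]) / (size_i + size_j)
        keep = [k for k in range(n) if k not in (i, j)]
        d = np.vstack([d[keep][:, keep], new_row[keep]])
        d = np.hstack([d, np.append(new_row[keep], 0.0)[:, None]])
        clusters = [clusters[k] for k in keep] + [
            (new_label, merged, size_i + size_j, height)
        ]
    return clusters[0][1]


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; returns an unrooted tree.

    The root of the returned structure is the final 3-way (or 2-way)
    join and carries no meaning.  Negative branch-length estimates are
    clamped to 0 with the deficit moved to the sister branch (logged).
    Q-matrix ties are broken by label order.
    """
    if len(dm.labels) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if np.isnan(dm.d).any():
        raise ValueError("distance matrix contains NaN")
    nodes: list[tuple[str, TreeNode]] = [(lab, TreeNode(name=lab)) for lab in dm.labels]
    d = dm.d.copy()

    def clamp_pair(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            log.debug("NJ: clamping negative branch %.3g, transferring to sister", li)
            lj += li
            li = 0.0
        if lj < 0:
            log.debug("NJ: clamping negative branch %.3g, transferring to sister", lj)
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(nodes) > 3:
        n = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * d[i, j] - r[i] - r[j]
                key = (q, nodes[i][0], nodes[j][0])
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = d[i, j] - li
        li, lj = clamp_pair(li, lj)
        (lab_i, node_i), (lab_j, node_j) = nodes[i], nodes[j]
        node_i.length = li
        node_j.length = lj
        merged = TreeNode(children=[node_i, node_j])

        new_row = np.empty(n)
        for k in range(n):
            new_row[k] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        d = np.vstack([d[keep][:, keep], new_row[keep]])
        d = np.hstack([d, np.append(new_row[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [(min(lab_i, lab_j), merged)]

    # terminal 3-taxon star
    (la, na), (lb, nb), (lc, nc) = nodes
    na.length = max(0.5 * (d[0, 1] + d[0, 2] - d[1, 2]), 0.0)
    nb.length = max(0.5 * (d[0, 1] + d[1, 2] - d[0, 2]), 0.0)
    nc.length = max(0.5 * (d[0, 2] + d[1, 2] - d[0, 1]), 0.0)
    return TreeNode(children=[na, nb, nc])


def _quote_label(name: str) -> str:
    if _NEWICK_UNSAFE.search(name):
        return "'" + name.replace("'", "''") + "'"
    return name


def to_newick(tree: TreeNode, precision: int = 6) -> str:
    """Newick string with branch lengths and optional support values."""

    def fmt(node: TreeNode) -> str:
        if node.is_leaf:
            return f"{_quote_label(node.name)}:{node.length:.{precision}f}"
        inner = ",".join(fmt(ch) for ch in node.children)
        sup = "" if node.support is None else f"{node.support:g}"
        return f"({inner}){sup}:{node.length:.{precision}f}"

    inner = ",".join(fmt(ch) for ch in tree.children)
    sup = "" if tree.support is None else f"{tree.support:g}"
    return f"({inner}){sup};"


def write_newick(tree: TreeNode, path: str, precision: int = 6) -> None:
    with open(path, "w") as fh:
        fh.write(to_newick(tree, precision=precision) + "\n")


def bootstrap_support(
    matrix: GenotypeMatrix,
    mode: str = "het",
    method: str = "upgma",
    n_replicates: int = 100,
    seed: int = 0,
) -> TreeNode:
    """Site-resampling bootstrap; supports annotated on the full-data tree.

    Each replicate resamples sites with replacement, rebuilds the tree,
    and counts recovered bipartitions; internal nodes of the full-data
    tree get the percentage of replicates containing their bipartition.
    """
    build = upgma if method == "upgma" else neighbor_joining
    ref = build(pairwise_distance(matrix, mode=mode))
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {bp: 0 for bp in ref.bipartitions()}
    n_sites = matrix.n_sites
    for _ in range(n_replicates):
        idx = rng.integers(0, n_sites, size=n_sites)
        rep = build(pairwise_distance(matrix.take_sites(idx), mode=mode))
        for bp in rep.bipartitions():
            if bp in counts:
                counts[bp] += 1

    def annotate(node: TreeNode) -> frozenset:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(annotate(ch) for ch in node.children))
        if below in counts:
            node.support = 100.0 * counts[below] / n_replicates
        return below

    annotate(ref)
    return ref
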