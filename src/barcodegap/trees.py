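"""Distance-based tree construction and monophyly-based species recovery.

Implements Saitou–Nei neighbor joining and UPGMA on K2P distance matrices,
nonparametric bootstrap over alignment columns, strict and majority-rule
consensus by bipartition counting, and scoring of per-species monophyly
("species recovery") — the standard criterion for whether a barcode locus
resolves species as exclusive clades.

Both tree builders use a deterministic tie-break (lexicographically smallest
pair of cluster representatives, where a cluster's representative is its
smallest leaf label), so results are exactly reproducible.  Trees are
scikit-bio ``TreeNode`` objects; NJ output is unrooted, represented with a
trifurcating root.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from skbio import TreeNode

from .distances import DistanceMatrix, pairwise_matrix, complete_deletion
from .seqdata import LocusAlignment, SpeciesMap

__all__ = [
    "RecoveryReport",
    "nj_tree",
    "upgma_tree",
    "bootstrap_trees",
    "consensus",
    "bipartition_support",
    "is_species_monophyletic",
    "species_recovery",
    "write_newick",
    "read_newick",
]


def _check_defined(dm: DistanceMatrix) -> None:
    if dm.n_undefined_pairs:
        raise ValueError(
            f"{dm.n_undefined_pairs} undefined distance(s); impute or drop "
            "the affected accessions before tree building"
        )


def _tip(name: str, length: float) -> TreeNode:
    return TreeNode(name=name, length=max(0.0, length))


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining.

    Exact on additive matrices.  Negative branch-length estimates are
    clamped to zero with the deficit transferred to the sibling edge
    (Kuhner–Felsenstein convention), which changes lengths only, never
    topology.  Returns an unrooted tree as a trifurcating-root ``TreeNode``.
    """
    _check_defined(dm)
    n = dm.n
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    D = dm.values.copy()
    # Active nodes: (representative label for tie-breaks, TreeNode, pending length)
    reps = list(dm.labels)
    nodes: list[TreeNode] = [TreeNode(name=l) for l in dm.labels]

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        ties = np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-12))
        i, j = min(
            (tuple(sorted((int(a), int(b)))) for a, b in ties),
            key=lambda ij: tuple(sorted((reps[ij[0]], reps[ij[1]]))),
        )
        d_ij = D[i, j]
        bi = 0.5 * d_ij + (r[i] - r[j]) / (2.0 * (m - 2))
        bj = d_ij - bi
        if bi < 0:
            bj -= bi
            bi = 0.0
        if bj < 0:
            bi -= bj
            bj = 0.0
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = max(0.0, bi)
        child_j.length = max(0.0, bj)
        new = TreeNode(children=[child_i, child_j])
        d_new = 0.5 * (D[i] + D[j] - d_ij)
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.zeros((len(keep) + 1, len(keep) + 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = d_new[keep]
        D2[:-1, -1] = d_new[keep]
        nodes = [nodes[k] for k in keep] + [new]
        reps = [reps[k] for k in keep] + [min(reps[i], reps[j])]
        D = D2

    # Three-point resolution of the final trifurcation.
    (x, y, z) = nodes
    dxy, dxz, dyz = D[0, 1], D[0, 2], D[1, 2]
    x.length = max(0.0, 0.5 * (dxy + dxz - dyz))
    y.length = max(0.0, 0.5 * (dxy + dyz - dxz))
    z.length = max(0.0, 0.5 * (dxz + dyz - dxy))
    return TreeNode(children=[x, y, z])


def upgma_tree(dm: DistanceMatrix) -> TreeNode:
    """UPGMA (average-linkage) clustering into a rooted ultrametric tree.

    Merge order follows the minimum average inter-cluster distance; a node's
    height is half that distance.  On ultrametric input the tree's
    cophenetic distances reproduce the input exactly.
    """
    _check_defined(dm)
    n = dm.n
    if n < 2:
        raise ValueError("UPGMA needs >= 2 taxa")
    D = dm.values.copy().astype(float)
    reps = list(dm.labels)
    sizes = [1] * n
    heights = [0.0] * n
    nodes: list[TreeNode] = [TreeNode(name=l) for l in dm.labels]

    while len(nodes) > 1:
        m = len(nodes)
        M = D.copy()
        np.fill_diagonal(M, np.inf)
        dmin = M.min()
        ties = np.argwhere(np.isclose(M, dmin, rtol=0, atol=1e-12))
        i, j = min(
            (tuple(sorted((int(a), int(b)))) for a, b in ties),
            key=lambda ij: tuple(sorted((reps[ij[0]], reps[ij[1]]))),
        )
        h = D[i, j] / 2.0
        ci, cj = nodes[i], nodes[j]
        ci.length = max(0.0, h - heights[i])
        cj.length = max(0.0, h - heights[j])
        new = TreeNode(children=[ci, cj])
        ni, nj = sizes[i], sizes[j]
        d_new = (ni * D[i] + nj * D[j]) / (ni + nj)
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.zeros((len(keep) + 1, len(keep) + 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = d_new[keep]
        D2[:-1, -1] = d_new[keep]
        nodes = [nodes[k] for k in keep] + [new]
        reps = [reps[k] for k in keep] + [min(reps[i], reps[j])]
        sizes = [sizes[k] for k in keep] + [ni + nj]
        heights = [heights[k] for k in keep] + [h]
        D = D2
    root = nodes[0]
    root.length = None
    return root


_BUILDERS = {"nj": nj_tree, "upgma": upgma_tree}


def build_tree(dm: DistanceMatrix, method: str) -> TreeNode:
    try:
        return _BUILDERS[method.lower()](dm)
    except KeyError:
        raise ValueError(f"unknown tree method {method!r}") from None


def bootstrap_trees(
    aln: LocusAlignment,
    method: str = "nj",
    n_replicates: int = 500,
    seed: int | None = None,
) -> tuple[list[TreeNode], int]:
    """Column-resampling bootstrap.

    Complete deletion is applied once, then each replicate resamples that
    alignment's columns with replacement (same length), recomputes the K2P
    matrix and rebuilds the tree.  Replicates whose resampled matrix has
    undefined entries are skipped and counted.

    Returns ``(trees, n_skipped)``.
    """
    aln = complete_deletion(aln)
    rng = np.random.default_rng(seed)
    trees: list[TreeNode] = []
    skipped = 0
    for _ in range(n_replicates):
        cols = rng.integers(0, aln.length, size=aln.length)
        sub = aln.select_columns([int(c) for c in cols])
        dm = pairwise_matrix(sub, deletion="none")
        if dm.n_undefined_pairs:
            skipped += 1
            continue
        trees.append(build_tree(dm, method))
    return trees, skipped


def _tipset(tree: TreeNode) -> frozenset[str]:
    return frozenset(t.name for t in tree.tips())


def _bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions as the side not containing the reference
    taxon (the lexicographically smallest leaf)."""
    taxa = _tipset(tree)
    ref = min(taxa)
    n = len(taxa)
    out: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = taxa - side
        if 2 <= len(side) <= n - 2:
            out.add(side)
    return out


def consensus(trees: Sequence[TreeNode], rule: str = "majority50") -> TreeNode:
    """Strict or >50% majority-rule consensus by bipartition counting.

    ``rule="strict"`` keeps bipartitions present in every tree;
    ``rule="majority50"`` keeps those in more than half.  Internal nodes of
    the result carry ``support`` = bipartition frequency × 100.  The
    consensus is a topology-only tree (no branch lengths).
    """
    if not trees:
        raise ValueError("no trees given")
    taxa = _tipset(trees[0])
    for t in trees[1:]:
        if _tipset(t) != taxa:
            raise ValueError("trees have differing leaf sets")
    counts: Counter[frozenset[str]] = Counter()
    for t in trees:
        counts.update(_bipartitions(t))
    n = len(trees)
    if rule == "strict":
        selected = [bp for bp, c in counts.items() if c == n]
    elif rule == "majority50":
        selected = [bp for bp, c in counts.items() if c > n / 2]
    else:
        raise ValueError(f"unknown consensus rule {rule!r}")

    ref = min(taxa)
    # Nest selected clades (all exclude ref; >50% rule guarantees pairwise
    # compatibility) by containment, largest first.
    selected.sort(key=lambda s: (-len(s), sorted(s)))
    clade_nodes: list[tuple[frozenset[str], TreeNode]] = []
    root = TreeNode()
    for clade in selected:
        node = TreeNode()
        node.support = 100.0 * counts[clade] / n
        parent = root
        for cl, nd in clade_nodes:
            if clade < cl:
                parent = nd  # clades sorted big->small: last container wins
        parent.append(node)
        clade_nodes.append((clade, node))
    for taxon in sorted(taxa):
        parent = root
        for cl, nd in clade_nodes:
            if taxon in cl:
                parent = nd
        parent.append(TreeNode(name=taxon))
    return root


def bipartition_support(tree: TreeNode, replicates: Sequence[TreeNode]) -> TreeNode:
    """Annotate each internal node of ``tree`` with the percentage of
    ``replicates`` containing its bipartition (bootstrap support)."""
    taxa = _tipset(tree)
    ref = min(taxa)
    counts: Counter[frozenset[str]] = Counter()
    for t in replicates:
        counts.update(_bipartitions(t))
    n = len(replicates)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = taxa - side
        if 2 <= len(side) <= len(taxa) - 2:
            node.support = 100.0 * counts.get(side, 0) / max(1, n)
    return tree


def is_species_monophyletic(
    tree: TreeNode, species_name: str, species: SpeciesMap
) -> bool:
    """Whether a species' accessions form an exclusive group in the tree.

    Evaluated in the unrooted sense: true iff some bipartition of the tree
    separates exactly that species' leaves from all others, i.e. some node's
    tip set equals the species set or its complement.  Single-accession
    species are trivially monophyletic.  A collapsed polytomy mixing species
    yields no such node and scores False.
    """
    taxa = _tipset(tree)
    target = frozenset(t for t in taxa if species.species_of(t) == species_name)
    if not target:
        raise ValueError(f"species {species_name!r} has no leaves in tree")
    if len(target) == 1 or len(target) == len(taxa):
        return True
    rest = taxa - target
    for node in tree.non_tips(include_self=True):
        side = frozenset(t.name for t in node.tips())
        if side == target or side == rest:
            return True
    return False


@dataclass(frozen=True)
class RecoveryReport:
    """Monophyly-based species recovery for one tree."""

    method: str
    monophyly: dict[str, bool]

    @property
    def n_species_evaluated(self) -> int:
        return len(self.monophyly)

    @property
    def n_recovered(self) -> int:
        return sum(self.monophyly.values())

    @property
    def pct_recovered(self) -> float:
        """Percentage of evaluated species recovered, to one decimal."""
        return round(100.0 * self.n_recovered / self.n_species_evaluated, 1)


def species_recovery(
    tree: TreeNode, species: SpeciesMap, method: str = ""
) -> RecoveryReport:
    """Score every species with leaves in the tree for monophyly."""
    taxa = sorted(_tipset(tree))
    names = species.species_names(taxa)
    if len(names) < 2:
        raise ValueError("species recovery needs >= 2 species in the tree")
    flags = {
        sp: is_species_monophyletic(tree, sp, species) for sp in names
    }
    return RecoveryReport(method=method, monophyly=flags)


def write_newick(tree: TreeNode, path) -> None:
    """Write newick; internal-node ``support`` values become node labels
    (scikit-bio serialises the ``support`` attribute natively)."""
    tree.write(str(path), format="newick")


def read_newick(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")
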