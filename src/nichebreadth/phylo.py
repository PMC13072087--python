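"""Phylogeny handling: Newick I/O, pruning, and phylogenetic covariance matrices.

The phylogenetic variance-covariance (VCV) matrix is the workhorse of
phylogenetic generalized least squares: under a Brownian-motion model of trait
evolution, the covariance between the trait values of two tips is proportional
to the depth (root-to-node path length) of their most recent common ancestor,
and the variance of a tip is its root-to-tip distance.  Pagel's lambda rescales
the shared-history (off-diagonal) part of this matrix.

Trees are stored as thin wrappers around :class:`dendropy.Tree`.  Trees need
not be ultrametric, polytomies are accepted as-is, and branch lengths are
mandatory on every non-root edge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "PhyloCovariance",
    "PhylogenyError",
    "parse_newick",
    "write_newick",
    "prune",
    "vcv",
    "lambda_transform",
    "normalize_label",
]


class PhylogenyError(ValueError):
    """Raised for malformed trees or invalid tree operations."""


def normalize_label(label: str) -> str:
    """Normalize a tip label: strip whitespace, spaces -> underscores.

    This is the Newick convention and is applied consistently to tree tips and
    to species names in data tables so the two always match by exact string
    comparison.
    """
    return label.strip().replace(" ", "_")


@dataclass(frozen=True)
class Phylogeny:
    """A rooted phylogeny with branch lengths.

    Attributes
    ----------
    tree:
        The underlying dendropy tree.  Treat as immutable; operations return
        new :class:`Phylogeny` objects.
    """

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        labels = self.tip_labels
        if len(labels) < 2:
            raise PhylogenyError(
                f"tree must have at least 2 tips, got {len(labels)}"
            )
        if len(set(labels)) != len(labels):
            seen: set[str] = set()
            dups = sorted({l for l in labels if l in seen or seen.add(l)})
            raise PhylogenyError(f"duplicate tip labels: {dups}")
        if any(not l for l in labels):
            raise PhylogenyError("empty tip label")
        root = self.tree.seed_node
        n_zero_terminal = 0
        for node in self.tree.preorder_node_iter():
            if node is root:
                continue
            if node.edge.length is None:
                name = node.taxon.label if node.taxon else f"internal node {id(node)}"
                raise PhylogenyError(f"missing branch length on edge above {name!r}")
            if node.edge.length < 0:
                name = node.taxon.label if node.taxon else "an internal node"
                raise PhylogenyError(
                    f"negative branch length {node.edge.length} above {name!r}"
                )
            if node.is_leaf() and node.edge.length == 0:
                n_zero_terminal += 1
        if n_zero_terminal:
            warnings.warn(
                f"{n_zero_terminal} zero-length terminal branch(es); the "
                "phylogenetic covariance matrix may be singular if two tips "
                "become identical rows",
                stacklevel=3,
            )

    @property
    def tip_labels(self) -> list[str]:
        """Tip labels in tree traversal order."""
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tree.leaf_nodes())

    def __len__(self) -> int:
        return self.n_tips


def parse_newick(text: str) -> Phylogeny:
    """Parse a Newick string into a :class:`Phylogeny`.

    Branch lengths are required on all non-root edges; tip labels are
    normalized (stripped, spaces replaced by underscores).

    Raises
    ------
    PhylogenyError
        If the string is malformed (message includes the parser's position
        information), a branch length is missing, or fewer than 2 tips.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises DataError subclasses
        raise PhylogenyError(f"malformed Newick: {exc}") from exc
    for taxon in tree.taxon_namespace:
        taxon.label = normalize_label(taxon.label)
    return Phylogeny(tree)


def write_newick(phy: Phylogeny) -> str:
    """Serialize to a Newick string (terminated by ';' and newline-free)."""
    return (
        phy.tree.as_string(schema="newick", suppress_rooting=True)
        .strip()
    )


def read_newick_file(path: str) -> Phylogeny:
    with open(path) as fh:
        return parse_newick(fh.read())


def prune(phy: Phylogeny, keep: set[str]) -> Phylogeny:
    """Induced subtree on ``keep``, preserving root-to-tip path lengths.

    Degree-2 internal nodes created by the pruning are suppressed with their
    branch lengths summed, so all pairwise MRCA depths among kept tips are
    unchanged.

    Raises
    ------
    PhylogenyError
        If any label in ``keep`` is absent (message lists all missing labels)
        or fewer than 2 labels are kept.
    """
    keep = {normalize_label(k) for k in keep}
    have = set(phy.tip_labels)
    missing = sorted(keep - have)
    if missing:
        raise PhylogenyError(f"labels not in tree: {missing}")
    if len(keep) < 2:
        raise PhylogenyError(f"need at least 2 tips to keep, got {len(keep)}")
    sub = phy.tree.extract_tree_with_taxa_labels(
        labels=keep, suppress_unifurcations=True
    )
    # If the original root becomes a unifurcation its length is pushed onto
    # the new root's own edge; vcv() counts that edge so depths are preserved.
    return Phylogeny(sub)


@dataclass(frozen=True)
class PhyloCovariance:
    """Phylogenetic variance-covariance matrix for an ordered set of taxa.

    ``matrix[i, j]`` is the root depth of the MRCA of taxa i and j;
    ``matrix[i, i]`` is the root-to-tip distance of taxon i.
    """

    taxa: tuple[str, ...]
    matrix: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        V = self.matrix
        if V.shape != (len(self.taxa), len(self.taxa)):
            raise PhylogenyError("covariance matrix shape does not match taxa")
        if not np.allclose(V, V.T):
            raise PhylogenyError("covariance matrix not symmetric")
        if np.any(np.diag(V) <= 0):
            raise PhylogenyError("zero root-to-tip distance: tip at the root")

    @property
    def n(self) -> int:
        return len(self.taxa)

    def reorder(self, taxa: list[str]) -> "PhyloCovariance":
        """Rows/columns subset and reordered to ``taxa``."""
        index = {t: i for i, t in enumerate(self.taxa)}
        missing = [t for t in taxa if t not in index]
        if missing:
            raise PhylogenyError(f"taxa not in covariance matrix: {missing}")
        idx = np.array([index[t] for t in taxa])
        return PhyloCovariance(tuple(taxa), self.matrix[np.ix_(idx, idx)])


def vcv(phy: Phylogeny) -> PhyloCovariance:
    """Phylogenetic variance-covariance matrix of a tree.

    One O(n^2) pass: node depths by preorder accumulation, then for every
    internal node the tip pairs split across its children share that node as
    MRCA (deeper nodes overwrite shallower ones in postorder order of
    visiting, but since we fill each pair exactly once at its true MRCA no
    overwriting occurs).
    """
    tree = phy.tree
    tips = list(tree.leaf_node_iter())
    order = {id(t): i for i, t in enumerate(tips)}
    n = len(tips)
    root_edge = tree.seed_node.edge.length or 0.0
    depth: dict[int, float] = {id(tree.seed_node): root_edge}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        depth[id(node)] = depth[id(node.parent_node)] + node.edge.length

    V = np.zeros((n, n))
    # postorder: collect tip index lists; cross-child pairs get this node's depth
    tips_below: dict[int, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = order[id(node)]
            V[i, i] = depth[id(node)]
            tips_below[id(node)] = [i]
        else:
            groups = [tips_below.pop(id(c)) for c in node.child_nodes()]
            d = depth[id(node)]
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    ia = np.array(groups[a])
                    ib = np.array(groups[b])
                    V[np.ix_(ia, ib)] = d
                    V[np.ix_(ib, ia)] = d
            tips_below[id(node)] = [i for g in groups for i in g]
    return PhyloCovariance(tuple(t.taxon.label for t in tips), V)


def lambda_transform(cov: PhyloCovariance, lam: float) -> PhyloCovariance:
    """Pagel's lambda transform: multiply off-diagonal entries by ``lam``.

    ``lam = 1`` leaves the matrix unchanged (Brownian motion); ``lam = 0``
    removes all shared history (star phylogeny).  For ``lam`` in [0, 1] the
    result is a convex combination of V and diag(V), hence stays positive
    semi-definite.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    V = cov.matrix
    out = lam * V + (1.0 - lam) * np.diag(np.diag(V))
    return PhyloCovariance(cov.taxa, out)
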