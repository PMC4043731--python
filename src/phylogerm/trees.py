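"""Phylogeny utilities: newick I/O, Yule simulation, tree covariance.

Trees are plain :class:`dendropy.Tree` objects throughout the package. A
valid phylogeny here is rooted, has >= 2 uniquely-named tips and nonnegative
branch lengths. The among-species covariance used by the trait model is the
standard Brownian-motion tree covariance: ``C[i, i]`` is the root-to-tip
distance of tip *i* and ``C[i, j]`` the root-to-MRCA path length shared by
tips *i* and *j*.
"""

from __future__ import annotations

import zlib

import dendropy
import numpy as np

__all__ = [
    "read_newick",
    "write_newick",
    "simulate_tree",
    "tip_labels",
    "tip_depths",
    "tree_covariance",
    "unit_branch_variant",
    "basal_clade_partition",
    "prune_to_taxa",
    "stage_rng",
]


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Named RNG substream: one global seed, one independent stream per stage.

    Streams are keyed by ``(seed, crc32(stage))`` so adding a new pipeline
    stage never perturbs the draws of existing stages.
    """
    return np.random.default_rng([int(seed), zlib.crc32(stage.encode("utf8"))])


def read_newick(path_or_string: str, *, lenient: bool = False) -> dendropy.Tree:
    """Read a rooted newick tree from a file path or literal string.

    Missing branch lengths raise a parse error unless ``lenient`` is set, in
    which case they default to 1.
    """
    text = path_or_string
    if not text.lstrip().startswith("("):
        with open(path_or_string) as fh:
            text = fh.read()
    tree = dendropy.Tree.get(
        data=text, schema="newick", rooting="force-rooted",
        suppress_internal_node_taxa=True,
    )
    missing = [e for e in tree.preorder_edge_iter()
               if e.head_node.parent_node is not None and e.length is None]
    if missing:
        if not lenient:
            raise ValueError(
                f"{len(missing)} branch(es) lack a length; "
                "pass lenient=True to default them to 1"
            )
        for e in missing:
            e.length = 1.0
    if len(tree.leaf_nodes()) < 2:
        raise ValueError("phylogeny must have at least 2 tips")
    labels = tip_labels(tree)
    if len(set(labels)) != len(labels):
        raise ValueError("tip names must be unique")
    return tree


def write_newick(tree: dendropy.Tree, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(newick_string(tree) + "\n")


def newick_string(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def simulate_tree(n_tips: int, rng_seed: int) -> dendropy.Tree:
    """Simulate a rooted ultrametric Yule (pure-birth) tree.

    Lineages split at unit rate; after the ``n_tips``-th birth one further
    exponential interval is appended so terminal branches have positive
    length. Root-to-tip depth is rescaled to exactly 1, making the BM rate
    sigma2 interpretable as per-total-tree-depth variance. Tips are named
    ``sp0001..spNNNN`` in ladder order; identical seeds give byte-identical
    newick output.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    rng = stage_rng(rng_seed, "tree")

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    birth_time = {root: 0.0}
    active = [root]
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        idx = int(rng.integers(len(active)))
        node = active.pop(idx)
        node.edge.length = t - birth_time[node]
        for _ in range(2):
            child = node.new_child()
            birth_time[child] = t
            active.append(child)
    t += rng.exponential(1.0 / len(active))
    for node in active:
        node.edge.length = t - birth_time[node]
    root.edge.length = None

    # rescale root-to-tip depth (identical for all tips) to exactly 1; the
    # waiting time before the root's own split carries no edge, so the
    # realised depth is less than the final simulation clock t
    depth = 0.0
    node = active[0]
    while node.parent_node is not None:
        depth += node.edge.length
        node = node.parent_node
    for e in tree.preorder_edge_iter():
        if e.length is not None:
            e.length /= depth

    width = max(4, len(str(n_tips)))
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon = taxa.new_taxon(f"sp{i:0{width}d}")
    return tree


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def _node_depths(tree: dendropy.Tree) -> dict:
    depths = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depths[node] = 0.0
        else:
            depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
    return depths


def tip_depths(tree: dendropy.Tree) -> dict[str, float]:
    depths = _node_depths(tree)
    return {leaf.taxon.label: depths[leaf] for leaf in tree.leaf_node_iter()}


def tree_covariance(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Brownian-motion covariance matrix and the tip order it uses.

    O(n^2); dense algebra is ample at the ~10^2-tip scale this package
    targets.
    """
    depths = _node_depths(tree)
    leaves = list(tree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    index = {lf: i for i, lf in enumerate(leaves)}
    n = len(leaves)
    C = np.zeros((n, n))
    for lf in leaves:
        C[index[lf], index[lf]] = depths[lf]
    tipsets: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            tipsets[node] = [index[node]]
            continue
        children = [tipsets.pop(ch) for ch in node.child_nodes()]
        for a in range(len(children)):
            for b in range(a + 1, len(children)):
                for i in children[a]:
                    for j in children[b]:
                        C[i, j] = C[j, i] = depths[node]
        merged = [i for ch in children for i in ch]
        tipsets[node] = merged
    return labels, C


def unit_branch_variant(tree: dendropy.Tree) -> dendropy.Tree:
    """Same topology with every branch length set to 1 (robustness check)."""
    clone = tree.clone(depth=1)
    for e in clone.preorder_edge_iter():
        if e.head_node.parent_node is not None:
            e.length = 1.0
    return clone


def basal_clade_partition(tree: dendropy.Tree, n_groups: int) -> dict[str, int]:
    """Partition tips into ``n_groups`` clades by cutting the earliest splits.

    The first ``n_groups - 1`` internal nodes in depth order are dissolved,
    leaving the n most basal clades; cutting deeper strictly refines a
    shallower cut, so e.g. taxonomic families produced by a deeper cut nest
    inside orders from a shallower one.
    """
    n_tips = len(tree.leaf_nodes())
    if not 2 <= n_groups <= n_tips:
        raise ValueError("n_groups must be in [2, n_tips]")
    depths = _node_depths(tree)
    internal = sorted(
        (nd for nd in tree.preorder_node_iter() if not nd.is_leaf()),
        key=lambda nd: depths[nd],
    )
    cut = internal[: n_groups - 1]
    dissolved = set(cut)
    out: dict[str, int] = {}
    group = 0
    for node in cut:
        for child in node.child_nodes():
            if child in dissolved:
                continue
            for leaf in child.leaf_iter():
                out[leaf.taxon.label] = group
            group += 1
    return out


def prune_to_taxa(tree: dendropy.Tree, keep: set[str]) -> dendropy.Tree:
    """Return a copy of the tree restricted to the given tip labels."""
    clone = tree.clone(depth=1)
    clone.retain_taxa_with_labels(sorted(keep))
    return clone
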