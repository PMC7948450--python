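"""Phylogeny handling: Newick I/O, deterministic internal-node labels, and
MRCA lookup.  Trees are dendropy objects throughout; branch lengths are in
expected substitutions per site.
"""

from __future__ import annotations

import dendropy


def read_newick(source: str, *, is_path: bool | None = None) -> dendropy.Tree:
    """Read a Newick tree (from a path or a literal string) as rooted.

    Internal nodes without labels receive deterministic preorder labels
    ``N1, N2, ...`` so nodes can be addressed stably across runs.
    """
    if is_path is None:
        is_path = "(" not in source
    if is_path:
        tree = dendropy.Tree.get(path=str(source), schema="newick",
                                 preserve_underscores=True)
    else:
        tree = dendropy.Tree.get(data=source, schema="newick",
                                 preserve_underscores=True)
    tree.is_rooted = True
    label_internal_nodes(tree)
    return tree


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True,
               unquoted_underscores=True,
               suppress_internal_node_labels=False)


def label_internal_nodes(tree: dendropy.Tree) -> None:
    """Assign ``N<i>`` labels (preorder) to unlabelled internal nodes."""
    i = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        i += 1
        if node.label is None:
            node.label = f"N{i}"


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def node_label(node: dendropy.Node) -> str:
    if node.is_leaf():
        return node.taxon.label
    return node.label


def find_node(tree: dendropy.Tree, label: str) -> dendropy.Node:
    for node in tree.preorder_node_iter():
        if node_label(node) == label:
            return node
    raise KeyError(f"no node labelled {label!r} in tree")


def mrca_node(tree: dendropy.Tree, taxa) -> dendropy.Node:
    """Most recent common ancestor of a set of leaf labels."""
    taxa = list(taxa)
    present = set(leaf_labels(tree))
    missing = [t for t in taxa if t not in present]
    if missing:
        raise ValueError(f"taxa not in tree: {missing}")
    node = tree.mrca(taxon_labels=taxa)
    if node is None:
        raise ValueError(f"no MRCA found for {taxa}")
    return node


def check_leaves_match(tree: dendropy.Tree, alignment_ids) -> None:
    """Require the tree leaf set to equal the alignment id set."""
    tree_set = set(leaf_labels(tree))
    aln_set = set(alignment_ids)
    only_tree = sorted(tree_set - aln_set)
    only_aln = sorted(aln_set - tree_set)
    if only_tree or only_aln:
        raise ValueError(
            "tree/alignment mismatch: "
            f"only in tree {only_tree}; only in alignment {only_aln}"
        )
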