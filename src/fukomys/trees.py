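"""Newick tree I/O and chronogram utilities (thin layer over dendropy)."""

from __future__ import annotations

import dendropy

from .errors import TreeError


def read_newick(source, preserve_underscores: bool = True) -> dendropy.Tree:
    """Parse a Newick file (or string starting with '(') into a dendropy Tree.

    Support values stored as internal node labels are preserved.
    """
    src = str(source)
    try:
        if src.lstrip().startswith("("):
            return dendropy.Tree.get(
                data=src, schema="newick", preserve_underscores=preserve_underscores
            )
        return dendropy.Tree.get(
            path=src, schema="newick", preserve_underscores=preserve_underscores
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"could not parse Newick input {source!r}: {exc}") from exc


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick", unquoted_underscores=True, suppress_rooting=True
    ).strip()


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def node_ages(tree: dendropy.Tree) -> dict:
    """Ages (time before present) for every node of an ultrametric tree."""
    tree.calc_node_ages(ultrametricity_precision=1e-5)
    return {nd: nd.age for nd in tree}


def root_age(tree: dendropy.Tree) -> float:
    tree.calc_node_ages(ultrametricity_precision=1e-5)
    return float(tree.seed_node.age)


def assert_ultrametric(tree: dendropy.Tree, tol: float = 1e-6) -> None:
    depths = []
    for leaf in tree.leaf_node_iter():
        depth = 0.0
        nd = leaf
        while nd.parent_node is not None:
            depth += nd.edge.length or 0.0
            nd = nd.parent_node
        depths.append(depth)
    if max(depths) - min(depths) > tol * max(max(depths), 1.0):
        raise TreeError(
            f"tree is not ultrametric: tip depths span "
            f"[{min(depths):.6g}, {max(depths):.6g}]"
        )
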