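"""Perfect-phylogeny checking and gene-tree construction.

Infinite-sites data compatible with an all-zero root has a unique *gene
tree*: a rooted tree whose edges carry mutation (site) labels and whose
leaves are the haplotypes with their multiplicities.  Gene trees carry no
branch lengths — they are not coalescent trees.

Compatibility is checked with the rooted three-gamete condition (no column
pair may show all of the gametes 01, 10 and 11; the known all-zero root
supplies 00), or optionally the classical unrooted four-gamete test.
Construction follows Gusfield's radix-sort algorithm: columns are sorted by
decreasing multiplicity-weighted carrier count and each haplotype's sorted
mutation list is inserted as a root-to-leaf path in a trie.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import K69Dataset, ValidationReport
from .errors import DataValidationError

__all__ = ["GeneTreeNode", "GeneTree", "four_gamete_test", "build_gene_tree", "export_tree"]


@dataclass
class GeneTreeNode:
    """Tree node; ``edge_mutations`` labels the edge from the parent."""

    edge_mutations: tuple[str, ...] = ()
    allele: str | None = None         # leaf payload: allele name
    count: int = 0                    # leaf payload: multiplicity
    children: list["GeneTreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class GeneTree:
    root: GeneTreeNode
    name: str = ""

    def leaves(self) -> list[GeneTreeNode]:
        out: list[GeneTreeNode] = []

        def walk(node):
            if node.allele is not None:
                out.append(node)
            for ch in node.children:
                walk(ch)

        walk(self.root)
        return out

    def edge_labels(self) -> list[str]:
        out: list[str] = []

        def walk(node):
            out.extend(node.edge_mutations)
            for ch in node.children:
                walk(ch)

        walk(self.root)
        return out

    def haplotypes(self) -> dict[str, tuple[frozenset, int]]:
        """Map allele name -> (set of mutation labels on its root path, count)."""
        out: dict[str, tuple[frozenset, int]] = {}

        def walk(node, acc):
            acc = acc | set(node.edge_mutations)
            if node.allele is not None:
                out[node.allele] = (frozenset(acc), node.count)
            for ch in node.children:
                walk(ch, acc)

        walk(self.root, set())
        return out


def four_gamete_test(d: K69Dataset, rooted: bool = True) -> ValidationReport:
    """Compatibility test for a perfect phylogeny.

    With ``rooted=True`` (the default; the root is known to be all-zero) a
    column pair fails when the three gametes 01, 10 and 11 all occur among
    sampled rows.  ``rooted=False`` runs the classical four-gamete variant,
    which additionally requires the gamete 00 for a failure.
    """
    X = d.X.astype(bool)
    s = d.num_sites
    for j in range(s):
        for k in range(j + 1, s):
            a, b = X[:, j], X[:, k]
            has11 = bool((a & b).any())
            has10 = bool((a & ~b).any())
            has01 = bool((~a & b).any())
            has00 = bool((~a & ~b).any()) or rooted
            if has11 and has10 and has01 and has00:
                return ValidationReport(
                    ok=False,
                    violations=(("incompatible site pair",
                                 f"columns {j + 1} and {k + 1}"),),
                )
    return ValidationReport(ok=True)


def build_gene_tree(d: K69Dataset, allele_names: list[str] | None = None) -> GeneTree:
    """Construct the unique gene tree of a compatible dataset.

    Raises :class:`DataValidationError` when the (rooted) gamete test
    fails, citing the offending column pair.  Alleles are named
    ``a1..aK`` in row order unless ``allele_names`` is given.
    """
    report = four_gamete_test(d)
    if not report.ok:
        rule, loc = report.violations[0]
        raise DataValidationError(f"no perfect phylogeny: {rule} at {loc}")
    if allele_names is None:
        allele_names = [f"a{i + 1}" for i in range(d.num_haplotypes)]

    carriers = d.X.astype(np.int64).T @ d.nu
    order = sorted(range(d.num_sites), key=lambda j: (-int(carriers[j]), j))

    root = GeneTreeNode()
    # trie over sorted mutation sequences; one node per mutation, then
    # unary chains are collapsed into multi-label edges
    index: dict[tuple, GeneTreeNode] = {(): root}
    for i in range(d.num_haplotypes):
        path = tuple(j for j in order if d.X[i, j])
        for k in range(1, len(path) + 1):
            prefix = path[:k]
            if prefix not in index:
                node = GeneTreeNode(edge_mutations=(d.site_labels[prefix[-1]],))
                index[prefix[:-1]].children.append(node)
                index[prefix] = node
        leaf_parent = index[path]
        leaf_parent.allele = allele_names[i]
        leaf_parent.count = int(d.nu[i])

    _collapse_unary(root)
    return GeneTree(root=root, name=d.name)


def _collapse_unary(node: GeneTreeNode) -> None:
    for i, ch in enumerate(node.children):
        while len(ch.children) == 1 and ch.allele is None:
            only = ch.children[0]
            ch = GeneTreeNode(
                edge_mutations=ch.edge_mutations + only.edge_mutations,
                allele=only.allele, count=only.count, children=only.children,
            )
            node.children[i] = ch
        _collapse_unary(ch)


# ---------------------------------------------------------------------------
# export


def export_tree(t: GeneTree, format: str = "text") -> str:
    """Render a gene tree as ``dot``, ``newick`` or indented ``text``.

    Output is deterministic for a given tree.
    """
    if format == "dot":
        return _to_dot(t)
    if format == "newick":
        return _to_newick(t)
    if format == "text":
        return _to_text(t)
    raise ValueError(f"unknown format {format!r} (expected dot, newick or text)")


def _node_label(node: GeneTreeNode, idx: int) -> str:
    if node.allele is not None:
        return f"{node.allele}:{node.count}"
    return f"n{idx}"


def _to_dot(t: GeneTree) -> str:
    lines = ["digraph genetree {", '  node [shape=box];']
    counter = [0]

    def walk(node) -> str:
        my = counter[0]
        counter[0] += 1
        label = _node_label(node, my)
        shape = "" if node.allele is None else ' style=filled'
        lines.append(f'  N{my} [label="{label}"{shape}];')
        for ch in node.children:
            cid = walk(ch)
            elabel = ",".join(ch.edge_mutations)
            lines.append(f'  N{my} -> {cid} [label="{elabel}"];')
        return f"N{my}"

    walk(t.root)
    lines.append("}")
    return "\n".join(lines) + "\n"


def _to_newick(t: GeneTree) -> str:
    def walk(node) -> str:
        label = "" if node.allele is None else f"{node.allele}"
        comment = ""
        if node.allele is not None:
            comment = f"[&count={node.count}]"
        if node.edge_mutations:
            comment += "[&mutations=" + "|".join(node.edge_mutations) + "]"
        if node.children:
            inner = ",".join(walk(ch) for ch in node.children)
            sub = f"({inner}){label}{comment}"
            # a leaf payload on an internal node becomes an extra child
            return sub
        return f"{label}{comment}"

    root = t.root
    if root.allele is not None and not root.children:
        return f"{root.allele}[&count={root.count}];"
    return walk(root) + ";"


def _to_text(t: GeneTree) -> str:
    lines: list[str] = []

    def walk(node, depth):
        edge = ("-[" + ",".join(node.edge_mutations) + "]-> ") if node.edge_mutations else ""
        payload = f"{node.allele}:{node.count}" if node.allele is not None else "*"
        lines.append("  " * depth + edge + payload)
        for ch in node.children:
            walk(ch, depth + 1)

    walk(t.root, 0)
    return "\n".join(lines) + "\n"
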