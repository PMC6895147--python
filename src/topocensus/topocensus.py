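"""Gene-tree topology census for closely related species groups.

Given a collection of gene-family trees (one rooted or outgroup-rootable
Newick tree per orthologous group) and a taxon map assigning tips to
species and species to groups, this module

1. roots each family tree on a ranked outgroup,
2. extracts the smallest clade spanning a focal species group, applying
   explicit sampling/duplication rules (single-copy, one-species-missing,
   within-species monophyletic duplicates collapsed, everything else
   rejected with a reason),
3. classifies each extracted clade among all (2n-3)!! possible rooted
   binary topologies on the focal taxa via the rooted Robinson-Foulds
   distance (distance 0 = identical topology),
4. aggregates topology counts/proportions, a majority-rule consensus tree
   with percent gene-tree support, and per-topology branch-length
   summaries.

A multispecies-coalescent simulator generates synthetic gene families
(focal clade under incomplete lineage sorting, embedded in an outgroup
scaffold, with dropout/duplication/paralog perturbations) so the whole
pipeline is testable without transcriptome-derived trees.

The module is laid out in the order the pipeline runs: configuration and
errors; the rooted-tree model and Newick I/O; topology catalogues and RF
distance; clade extraction; the census; the coalescent simulator; file
I/O; the command-line interface.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import sys
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import click
import numpy as np
from scipy import stats as _scipy_stats

__all__ = [
    "TreeNode",
    "RootedTree",
    "TaxonMap",
    "TopologyCatalog",
    "ExtractionRecord",
    "CensusOptions",
    "CensusResult",
    "SpeciesTreeModel",
    "SimulatedFamily",
    "FocalClade",
    "NewickError",
    "TreeError",
    "UnrootableError",
    "CrossSpeciesDuplicationError",
    "parse_newick",
    "write_newick",
    "clade_set",
    "reroot_by_outgroup",
    "enumerate_rooted_topologies",
    "rf_distance",
    "find_focal_clade",
    "collapse_species_duplicates",
    "collapse_short_branches",
    "classify_topology",
    "subtree_mean_branch_length",
    "majority_consensus",
    "run_census",
    "simulate_gene_trees",
    "apply_perturbations",
    "expected_triplet_frequencies",
    "frequency_agreement_test",
    "extract_family",
    "default_model",
    "simulator_taxon_map",
    "read_trees",
    "read_taxon_map",
    "write_taxon_map",
    "write_records_tsv",
    "write_truth_tsv",
    "census_summary_text",
    "cli",
]

# --------------------------------------------------------------------------
# Configuration & errors
# --------------------------------------------------------------------------

logger = logging.getLogger("topocensus")

#: categories a gene family can land in
CATEGORIES = ("complete", "one_missing", "duplicated_collapsed", "rejected")

#: rejection reasons, in the order they are evaluated
REJECT_REASONS = (
    "unrootable",
    "too_few_species",
    "cross_species_duplication",
    "paraphyletic_focal_group",
    "unresolved_polytomy",
)

#: default number of significant digits for serialized branch lengths
DEFAULT_PRECISION = 6

#: terminal branch length given to duplicate cherries by the simulator
#: (coalescent units) -- small but nonzero so trees stay strictly binary
DUPLICATE_CHERRY_LENGTH = 0.01

#: guard for topology enumeration: (2n-3)!! explodes beyond n = 8
MAX_CATALOG_TAXA = 8


class TreeError(ValueError):
    """Invalid tree operation (leaf-set mismatch, too few leaves, ...)."""


class NewickError(TreeError):
    """Malformed Newick input; ``offset`` is the 0-based character offset."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at character {offset})")
        self.offset = offset


class UnrootableError(TreeError):
    """No outgroup tip present; the family cannot be rooted."""


class CrossSpeciesDuplicationError(TreeError):
    """A species' duplicate tips do not form a single-species clade."""


# --------------------------------------------------------------------------
# Rooted-tree model and Newick I/O
# --------------------------------------------------------------------------


class TreeNode:
    """Node of a rooted tree.

    ``label`` is required (and unique) for leaves, optional for internal
    nodes where it typically holds a support value.  ``length`` is the
    length of the edge to the parent (``None`` when absent, always ``None``
    on the root).
    """

    __slots__ = ("label", "length", "children", "parent", "support")

    def __init__(self, label: str | None = None, length: float | None = None):
        self.label = label
        self.length = length
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None
        self.support: float | None = None  # consensus clade frequency

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<TreeNode {kind} label={self.label!r} length={self.length!r}>"


class RootedTree:
    """A rooted, leaf-labelled tree with optional branch lengths.

    Invariants (checked on construction): exactly one root, every non-root
    node has one parent, leaf labels are unique, the node structure is a
    tree (acyclic, connected).
    """

    def __init__(self, root: TreeNode):
        self.root = root
        self._validate()

    # -- structure ---------------------------------------------------------

    def _validate(self) -> None:
        if self.root.parent is not None:
            raise TreeError("root must not have a parent")
        seen: set[int] = set()
        labels: set[str] = set()
        for node in self.preorder():
            if id(node) in seen:
                raise TreeError("node reachable twice: tree is not acyclic")
            seen.add(id(node))
            for child in node.children:
                if child.parent is not node:
                    raise TreeError("child/parent links inconsistent")
            if node.is_leaf:
                if not node.label:
                    raise TreeError("leaf without label")
                if node.label in labels:
                    raise TreeError(f"duplicate leaf label {node.label!r}")
                labels.add(node.label)

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[TreeNode]:
        out: list[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_labels(self) -> frozenset[str]:
        return frozenset(n.label for n in self.leaves())  # type: ignore[misc]

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self.leaves())

    def is_binary(self) -> bool:
        """True iff every internal node has exactly two children."""
        return all(len(n.children) == 2 for n in self.preorder() if not n.is_leaf)

    def find_leaf(self, label: str) -> TreeNode:
        for n in self.leaves():
            if n.label == label:
                return n
        raise TreeError(f"no leaf labelled {label!r}")

    def copy(self) -> "RootedTree":
        def _copy(node: TreeNode) -> TreeNode:
            new = TreeNode(node.label, node.length)
            new.support = node.support
            for c in node.children:
                new.add_child(_copy(c))
            return new

        return RootedTree(_copy(self.root))

    # -- derived quantities ------------------------------------------------

    def depths(self) -> dict[int, float]:
        """Sum of branch lengths from the root, keyed by ``id(node)``.

        Missing lengths count as 0 (the root's absent edge always does).
        """
        out = {id(self.root): 0.0}
        for node in self.preorder():
            for c in node.children:
                out[id(c)] = out[id(node)] + (c.length or 0.0)
        return out

    def mrca(self, nodes: Sequence[TreeNode]) -> TreeNode:
        """Most recent common ancestor of ``nodes`` (non-empty)."""
        if not nodes:
            raise TreeError("mrca of empty node set")
        paths = []
        for n in nodes:
            path = []
            cur: TreeNode | None = n
            while cur is not None:
                path.append(cur)
                cur = cur.parent
            paths.append(list(reversed(path)))
        anc = paths[0][0]
        for depth in range(min(len(p) for p in paths)):
            candidate = paths[0][depth]
            if all(p[depth] is candidate for p in paths):
                anc = candidate
            else:
                break
        return anc

    def path_length(self, a: str, b: str) -> float:
        """Sum of branch lengths along the path between two leaves."""
        na, nb = self.find_leaf(a), self.find_leaf(b)
        anc = self.mrca([na, nb])
        total = 0.0
        for n in (na, nb):
            cur = n
            while cur is not anc:
                total += cur.length or 0.0
                cur = cur.parent  # type: ignore[assignment]
        return total

    def canonical_newick(self, precision: int = DEFAULT_PRECISION,
                         lengths: bool = True) -> str:
        return write_newick(self, precision=precision, lengths=lengths)

    def __repr__(self) -> str:  # pragma: no cover
        return f"RootedTree({self.canonical_newick(lengths=False)!r})"


def _strip_comments(text: str) -> tuple[str, int]:
    """Remove square-bracket comment blocks (outside quotes); return count."""
    out = []
    i, n, removed = 0, len(text), 0
    while i < n:
        c = text[i]
        if c == "'":
            j = i + 1
            while j < n:
                if text[j] == "'" and j + 1 < n and text[j + 1] == "'":
                    j += 2
                elif text[j] == "'":
                    break
                else:
                    j += 1
            out.append(text[i:j + 1])
            i = j + 1
        elif c == "[":
            depth = 1
            j = i + 1
            while j < n and depth:
                if text[j] == "[":
                    depth += 1
                elif text[j] == "]":
                    depth -= 1
                j += 1
            if depth:
                raise NewickError("unterminated '[' comment", i)
            removed += 1
            i = j
        else:
            out.append(c)
            i += 1
    return "".join(out), removed


_UNQUOTED_TERMINATORS = set("(),:;[]'\t\n\r ")


def parse_newick(text: str) -> RootedTree:
    """Parse a single ``;``-terminated Newick statement into a RootedTree.

    Quoted labels, branch lengths and internal (support) labels are
    accepted; ``[...]`` comment blocks are stripped with a warning.
    Malformed input (unbalanced parentheses, duplicate leaf labels, empty
    input, trailing garbage) raises :class:`NewickError` naming the
    character offset.
    """
    if text is None or not text.strip():
        raise NewickError("empty Newick string", 0)
    text, n_comments = _strip_comments(text)
    if n_comments:
        logger.warning("stripped %d [...] comment block(s) from Newick input",
                       n_comments)
    pos = 0
    n = len(text)

    def skip_ws() -> None:
        nonlocal pos
        while pos < n and text[pos] in " \t\n\r":
            pos += 1

    def parse_label() -> str | None:
        nonlocal pos
        skip_ws()
        if pos < n and text[pos] == "'":
            start = pos
            pos += 1
            chunks = []
            while pos < n:
                if text[pos] == "'" and pos + 1 < n and text[pos + 1] == "'":
                    chunks.append("'")
                    pos += 2
                elif text[pos] == "'":
                    pos += 1
                    return "".join(chunks)
                else:
                    chunks.append(text[pos])
                    pos += 1
            raise NewickError("unterminated quoted label", start)
        start = pos
        while pos < n and text[pos] not in _UNQUOTED_TERMINATORS:
            pos += 1
        return text[start:pos] if pos > start else None

    def parse_length() -> float | None:
        nonlocal pos
        skip_ws()
        if pos < n and text[pos] == ":":
            pos += 1
            skip_ws()
            start = pos
            while pos < n and (text[pos].isdigit() or text[pos] in "+-.eE"):
                pos += 1
            try:
                return float(text[start:pos])
            except ValueError:
                raise NewickError("invalid branch length", start) from None
        return None

    def parse_subtree() -> TreeNode:
        nonlocal pos
        skip_ws()
        if pos >= n:
            raise NewickError("unexpected end of input", pos)
        if text[pos] == "(":
            open_pos = pos
            pos += 1
            node = TreeNode()
            node.add_child(parse_subtree())
            skip_ws()
            while pos < n and text[pos] == ",":
                pos += 1
                node.add_child(parse_subtree())
                skip_ws()
            if pos >= n or text[pos] != ")":
                raise NewickError("unbalanced parentheses: '(' never closed",
                                  open_pos)
            pos += 1
            node.label = parse_label()
            node.length = parse_length()
            return node
        label = parse_label()
        if label is None:
            raise NewickError(f"expected a label, found {text[pos]!r}", pos)
        node = TreeNode(label)
        node.length = parse_length()
        return node

    root = parse_subtree()
    skip_ws()
    if pos >= n or text[pos] != ";":
        raise NewickError("missing ';' terminator", pos)
    terminator = pos
    pos += 1
    skip_ws()
    if pos < n:
        raise NewickError("trailing characters after ';'", pos)

    try:
        return RootedTree(root)
    except TreeError as exc:
        if "duplicate leaf label" in str(exc):
            raise NewickError(str(exc), terminator) from None
        raise


def _needs_quotes(label: str) -> bool:
    return any(c in _UNQUOTED_TERMINATORS for c in label)


def _format_label(label: str) -> str:
    if _needs_quotes(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: RootedTree, precision: int = DEFAULT_PRECISION,
                 lengths: bool = True) -> str:
    """Serialize to canonical Newick.

    Children are ordered lexicographically by each child's smallest
    descendant leaf label, so two topologically identical trees produce
    identical strings when ``lengths=False``.  Branch lengths are written
    with ``precision`` significant digits.
    """

    def min_leaf(node: TreeNode) -> str:
        if node.is_leaf:
            return node.label  # type: ignore[return-value]
        return min(min_leaf(c) for c in node.children)

    def fmt(node: TreeNode, is_root: bool) -> str:
        if node.is_leaf:
            s = _format_label(node.label)  # type: ignore[arg-type]
        else:
            kids = sorted(node.children, key=min_leaf)
            s = "(" + ",".join(fmt(c, False) for c in kids) + ")"
            if node.label:
                s += _format_label(node.label)
        if lengths and not is_root and node.length is not None:
            s += ":" + f"{node.length:.{precision}g}"
        return s

    return fmt(tree.root, True) + ";"


def clade_set(tree: RootedTree) -> frozenset[frozenset[str]]:
    """Non-trivial rooted clades: one leaf-label set per internal node,
    excluding singletons and the full leaf set.

    For a rooted binary tree on n leaves this has exactly n - 2 members.
    """
    leaves = tree.leaf_labels()
    if len(leaves) < 2:
        raise TreeError("clade_set requires a tree with at least 2 leaves")
    label_sets: dict[int, frozenset[str]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            label_sets[id(node)] = frozenset([node.label])  # type: ignore[list-item]
        else:
            label_sets[id(node)] = frozenset().union(
                *(label_sets[id(c)] for c in node.children))
    out = set()
    for node in tree.preorder():
        if node.is_leaf:
            continue
        s = label_sets[id(node)]
        if 1 < len(s) < len(leaves):
            out.add(s)
    return frozenset(out)


def _suppress_unary(node: TreeNode) -> None:
    """Merge a degree-2 node into its single child (summing lengths)."""
    (child,) = node.children
    parent = node.parent
    if node.length is None or child.length is None:
        merged = child.length if node.length is None else node.length
        if node.length is not None and child.length is not None:
            merged = node.length + child.length
    else:
        merged = node.length + child.length
    child.length = merged
    child.parent = parent
    if parent is not None:
        parent.children[parent.children.index(node)] = child
    node.children = []
    node.parent = None


def _detach_leaf(tree: RootedTree, leaf: TreeNode) -> RootedTree:
    """Remove a leaf, suppressing the resulting degree-2 node; returns a
    (possibly re-rooted) tree sharing the remaining nodes."""
    parent = leaf.parent
    if parent is None:
        raise TreeError("cannot remove the only node of a tree")
    parent.children.remove(leaf)
    leaf.parent = None
    root = tree.root
    if len(parent.children) == 1:
        if parent is root:
            new_root = parent.children[0]
            new_root.parent = None
            new_root.length = None
            parent.children = []
            root = new_root
        else:
            _suppress_unary(parent)
    return RootedTree(root)


def reroot_by_outgroup(tree: RootedTree, taxon_map: "TaxonMap") -> RootedTree:
    """Root on the edge subtending the smallest clade containing all tips
    of the highest-priority outgroup species present.

    The split edge's length is divided equally between the two new root
    children.  If the tree is already rooted with that clade as a direct
    child of a two-child root, it is returned unchanged (idempotence).
    Raises :class:`UnrootableError` when no outgroup tip is present.
    """
    by_species: dict[str, list[TreeNode]] = {}
    tree = tree.copy()
    for leaf in tree.leaves():
        sp = taxon_map.species_of(leaf.label)  # type: ignore[arg-type]
        by_species.setdefault(sp, []).append(leaf)
    target: list[TreeNode] | None = None
    for sp in taxon_map.outgroup_priority:
        if sp in by_species:
            target = by_species[sp]
            break
    if target is None:
        raise UnrootableError(
            "no tip of any outgroup-priority species present")
    mrca = tree.mrca(target)
    if mrca is tree.root:
        # outgroup tips span the present root: no edge above them; the
        # current rooting already separates them maximally
        return tree
    if mrca.parent is tree.root and len(tree.root.children) == 2:
        return tree  # already rooted here

    # re-hang on the edge above mrca: reverse parent pointers along the
    # path mrca -> old root
    path: list[TreeNode] = []
    cur: TreeNode | None = mrca
    while cur is not None:
        path.append(cur)
        cur = cur.parent
    # edge lengths along the path, edge_len[i] = length(path[i] -> path[i+1])
    edge_len = [p.length for p in path[:-1]]

    new_root = TreeNode()
    half = None if edge_len[0] is None else edge_len[0] / 2.0
    for p in path:
        p.parent = None
    path[1].children.remove(mrca)
    new_root.add_child(mrca)
    mrca.length = half
    new_root.add_child(path[1])
    path[1].length = half
    for i in range(1, len(path) - 1):
        parent_on_path = path[i]
        next_up = path[i + 1]
        next_up.children.remove(parent_on_path)
        parent_on_path.add_child(next_up)
        next_up.length = edge_len[i]
    old_root = path[-1]
    if len(old_root.children) == 1:
        _suppress_unary(old_root)
    return RootedTree(new_root)


# --------------------------------------------------------------------------
# Taxon map
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TaxonMap:
    """Tip-label -> species and species -> group assignments, plus the
    ranked list of outgroup species usable for rooting."""

    tip_to_species: Mapping[str, str]
    species_to_group: Mapping[str, str]
    outgroup_priority: tuple[str, ...] = ()

    def __post_init__(self):
        missing = {s for s in self.tip_to_species.values()
                   if s not in self.species_to_group}
        if missing:
            raise ValueError(
                f"species without group assignment: {sorted(missing)}")
        for sp in self.outgroup_priority:
            if sp not in self.species_to_group:
                raise ValueError(f"unknown outgroup species {sp!r}")

    def species_of(self, tip: str) -> str:
        try:
            return self.tip_to_species[tip]
        except KeyError:
            if tip in self.species_to_group:
                return tip  # tip already labelled with a species id
            raise TreeError(f"tip {tip!r} not covered by the taxon map") from None

    def group_of_tip(self, tip: str) -> str:
        return self.species_to_group[self.species_of(tip)]

    def species_in_group(self, group: str) -> frozenset[str]:
        return frozenset(s for s, g in self.species_to_group.items()
                         if g == group)

    def validate_focal_group(self, group: str) -> None:
        focal = self.species_in_group(group)
        if not focal:
            raise ValueError(f"no species assigned to group {group!r}")
        overlap = focal & set(self.outgroup_priority)
        if overlap:
            raise ValueError(
                f"outgroup species inside focal group: {sorted(overlap)}")


# --------------------------------------------------------------------------
# Topology catalogue & Robinson-Foulds distance
# --------------------------------------------------------------------------


def _double_factorial(k: int) -> int:
    out = 1
    while k > 1:
        out *= k
        k -= 2
    return out


@dataclass(frozen=True)
class TopologyCatalog:
    """All (2n-3)!! rooted binary leaf-labelled topologies on a taxon set,
    deterministically ordered by canonical Newick, ids starting at 1."""

    taxa: tuple[str, ...]
    topologies: tuple[RootedTree, ...]

    @property
    def size(self) -> int:
        return len(self.topologies)

    def tree(self, topology_id: int) -> RootedTree:
        return self.topologies[topology_id - 1]

    def newick(self, topology_id: int) -> str:
        return self.tree(topology_id).canonical_newick(lengths=False)

    def ids(self) -> range:
        return range(1, self.size + 1)

    def clade_sets(self) -> tuple[frozenset[frozenset[str]], ...]:
        return tuple(clade_set(t) if len(self.taxa) > 1 else frozenset()
                     for t in self.topologies)


def enumerate_rooted_topologies(taxon_set: Iterable[str]) -> TopologyCatalog:
    """Enumerate every rooted binary leaf-labelled topology on the taxa.

    Built by sequential tip insertion: a rooted binary tree on k leaves
    offers 2k-1 attachment positions (every edge plus above the root), so
    the count is the double factorial (2n-3)!! — 15 for four taxa.
    """
    taxa = tuple(sorted(set(taxon_set)))
    n = len(taxa)
    if not 2 <= n <= MAX_CATALOG_TAXA:
        raise ValueError(
            f"taxon set size must be in [2, {MAX_CATALOG_TAXA}], got {n}")

    def cherry(a: str, b: str) -> TreeNode:
        node = TreeNode()
        node.add_child(TreeNode(a))
        node.add_child(TreeNode(b))
        return node

    shapes: list[TreeNode] = [cherry(taxa[0], taxa[1])]
    for new_taxon in taxa[2:]:
        grown: list[TreeNode] = []
        for shape in shapes:
            nodes = list(RootedTree(shape).preorder())
            for idx in range(len(nodes)):
                t = RootedTree(shape).copy()
                target = list(t.preorder())[idx]
                joint = TreeNode()
                parent = target.parent
                if parent is None:
                    t_root = joint
                else:
                    parent.children[parent.children.index(target)] = joint
                    joint.parent = parent
                    t_root = t.root
                target.parent = None
                joint.add_child(target)
                joint.add_child(TreeNode(new_taxon))
                joint.parent = parent
                grown.append(t_root)
        shapes = grown

    trees = [RootedTree(s) for s in shapes]
    trees.sort(key=lambda t: t.canonical_newick(lengths=False))
    expected = _double_factorial(2 * n - 3)
    assert len(trees) == expected, "enumeration does not match (2n-3)!!"
    return TopologyCatalog(taxa=taxa, topologies=tuple(trees))


def rf_distance(a: RootedTree, b: RootedTree) -> int:
    """Rooted Robinson-Foulds distance: size of the symmetric difference of
    the two trees' non-trivial clade sets.  0 iff identical rooted topology.
    """
    la, lb = a.leaf_labels(), b.leaf_labels()
    if la != lb:
        only_a, only_b = sorted(la - lb), sorted(lb - la)
        raise TreeError(
            f"leaf sets differ: only in first {only_a}, only in second {only_b}")
    return len(clade_set(a) ^ clade_set(b))


def classify_topology(subtree: RootedTree,
                      catalog: TopologyCatalog) -> int | None:
    """Return the unique catalogue id at RF distance 0, or ``None``
    ("unresolved") when the subtree is non-binary so no binary catalogue
    entry matches."""
    labels = subtree.leaf_labels()
    if labels != frozenset(catalog.taxa):
        raise TreeError(
            f"subtree leaves {sorted(labels)} do not match catalogue taxa "
            f"{list(catalog.taxa)}")
    cs = clade_set(subtree) if len(labels) > 1 else frozenset()
    for tid, ref_cs in zip(catalog.ids(), catalog.clade_sets()):
        if cs == ref_cs:
            return tid
    return None


# --------------------------------------------------------------------------
# Focal-clade extraction
# --------------------------------------------------------------------------


@dataclass
class FocalClade:
    """Result of locating the focal group inside a rooted family tree."""

    subtree: RootedTree          # rooted at the MRCA, original branch lengths
    monophyletic: bool
    species_present: frozenset[str]
    tips_per_species: dict[str, int]


def find_focal_clade(tree: RootedTree, taxon_map: TaxonMap,
                     focal_group: str) -> FocalClade:
    """Locate the smallest clade containing every focal-group tip.

    The clade is monophyletic iff it contains no non-focal tip.  The
    returned subtree is a copy rooted at the MRCA (root edge length
    dropped), keeping original branch lengths and tip labels.
    Raises :class:`TreeError` when the tree has no focal tips.
    """
    focal_tips = [leaf for leaf in tree.leaves()
                  if taxon_map.group_of_tip(leaf.label) == focal_group]  # type: ignore[arg-type]
    if not focal_tips:
        raise TreeError(f"no tips of focal group {focal_group!r} in tree")
    mrca = tree.mrca(focal_tips)

    def _copy(node: TreeNode) -> TreeNode:
        new = TreeNode(node.label, node.length)
        for c in node.children:
            new.add_child(_copy(c))
        return new

    sub_root = _copy(mrca)
    sub_root.length = None
    subtree = RootedTree(sub_root)
    mono = all(taxon_map.group_of_tip(l) == focal_group
               for l in subtree.leaf_labels())
    counts = Counter(taxon_map.species_of(t.label) for t in focal_tips)  # type: ignore[arg-type]
    return FocalClade(subtree=subtree, monophyletic=mono,
                      species_present=frozenset(counts),
                      tips_per_species=dict(counts))


def collapse_species_duplicates(subtree: RootedTree,
                                taxon_map: TaxonMap) -> tuple[RootedTree, bool]:
    """Reduce a focal clade to one tip per species.

    For every species with k >= 2 tips the tips must form a monophyletic
    group inside the subtree; all but the tip with the shortest terminal
    branch (ties broken lexicographically by label) are dropped, degree-2
    nodes suppressed with branch lengths summed, and the survivor is
    relabelled with the species id.  Single-tip species are relabelled too.

    Returns ``(collapsed_tree, any_collapsed)``.  Raises
    :class:`CrossSpeciesDuplicationError` when a multi-tip species is not
    monophyletic.
    """
    tree = subtree.copy()
    by_species: dict[str, list[TreeNode]] = {}
    for leaf in tree.leaves():
        by_species.setdefault(taxon_map.species_of(leaf.label), []).append(leaf)  # type: ignore[arg-type]

    any_collapsed = False
    for sp in sorted(by_species):
        tips = by_species[sp]
        if len(tips) < 2:
            continue
        mrca = tree.mrca(tips)
        clade_leaves = [n for n in RootedTree.preorder(_subtree_view(mrca))
                        if n.is_leaf]
        if len(clade_leaves) != len(tips):
            raise CrossSpeciesDuplicationError(
                f"tips of species {sp!r} are not monophyletic")
        survivor = min(
            tips, key=lambda t: (t.length if t.length is not None else math.inf,
                                 t.label))
        for tip in tips:
            if tip is survivor:
                continue
            tree = _detach_leaf(tree, tip)
        any_collapsed = True
    for leaf in tree.leaves():
        leaf.label = taxon_map.species_of(leaf.label)  # type: ignore[arg-type]
    return RootedTree(tree.root), any_collapsed


class _subtree_view:
    """Light wrapper so RootedTree.preorder can walk from any node."""

    def __init__(self, node: TreeNode):
        self.root = node


def collapse_short_branches(tree: RootedTree, epsilon: float) -> RootedTree:
    """Contract internal edges shorter than ``epsilon`` into polytomies.

    Terminal edges are never contracted (that would delete leaves).  Off by
    default in the census; near-zero maximum-likelihood branches are kept
    as resolved bifurcations unless the caller opts in.
    """
    tree = tree.copy()
    changed = True
    while changed:
        changed = False
        for node in list(tree.preorder()):
            if node.is_leaf or node.parent is None:
                continue
            if node.length is not None and node.length < epsilon:
                parent = node.parent
                idx = parent.children.index(node)
                parent.children.pop(idx)
                for c in node.children:
                    c.parent = parent
                parent.children[idx:idx] = node.children
                node.children = []
                node.parent = None
                changed = True
                break
    return RootedTree(tree.root)


def subtree_mean_branch_length(subtree: RootedTree) -> float | None:
    """Arithmetic mean over all edges of the subtree (terminal and
    internal), excluding the root's absent parent edge.  Returns ``None``
    when any edge length is missing (family excluded from the
    branch-length summary only)."""
    lengths = [n.length for n in subtree.preorder() if n.parent is not None]
    if not lengths or any(l is None for l in lengths):
        return None
    return float(np.mean([l for l in lengths if l is not None]))


# --------------------------------------------------------------------------
# Census
# --------------------------------------------------------------------------


@dataclass
class ExtractionRecord:
    """One row of the census: what happened to one gene family."""

    family_id: str
    category: str                          # complete | one_missing | duplicated_collapsed | rejected
    reject_reason: str | None = None
    clade: RootedTree | None = None        # on species ids, post-collapse
    topology_id: int | None = None
    topology_newick: str | None = None     # canonical, no branch lengths
    taxa: tuple[str, ...] | None = None    # taxa the topology id refers to
    mean_branch_length: float | None = None
    kept_duplicate_tips: bool = False

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if (self.category == "rejected") != (self.reject_reason is not None):
            raise ValueError("reject_reason present iff category == rejected")
        if (self.category == "rejected") != (self.clade is None):
            raise ValueError("clade absent iff category == rejected")


@dataclass
class CensusOptions:
    """Tunable census behaviour."""

    one_missing_enabled: bool = True
    consensus_scope: str = "complete_plus_collapsed"  # or "complete_only"
    polytomy_epsilon: float | None = None             # off by default

    def __post_init__(self):
        if self.consensus_scope not in ("complete_plus_collapsed",
                                        "complete_only"):
            raise ValueError(f"bad consensus_scope {self.consensus_scope!r}")


@dataclass
class CensusResult:
    """Aggregated topology census over a set of gene families."""

    n_input: int
    n_rejected: int
    counts: dict[str, Counter]             # category -> {key -> count}
    proportions: dict[str, dict]           # category -> {key -> fraction}
    pooled_full_proportions: dict[int, float]  # complete + collapsed pooled
    rejection_reasons: Counter
    consensus: RootedTree | None
    consensus_support: dict[frozenset[str], float]   # clade -> fraction
    branch_length_summary: dict[int, float]
    catalog: TopologyCatalog
    one_missing_catalogs: dict[frozenset[str], TopologyCatalog]

    def to_json_dict(self) -> dict:
        def cat_counts(cat: str) -> dict:
            return {str(k): int(v) for k, v in sorted(self.counts[cat].items(),
                                                      key=lambda kv: str(kv[0]))}

        out = {
            "n_input": self.n_input,
            "n_rejected": self.n_rejected,
            "counts": {c: cat_counts(c) for c in self.counts},
            "rejection_reasons": dict(self.rejection_reasons),
            "proportions": {c: {str(k): v for k, v in p.items()}
                            for c, p in self.proportions.items()},
            "pooled_full_proportions": {str(k): v for k, v in
                                        self.pooled_full_proportions.items()},
            "branch_length_summary": {str(k): v for k, v in
                                      self.branch_length_summary.items()},
            "topologies": {str(i): self.catalog.newick(i)
                           for i in self.catalog.ids()},
            "consensus_newick": (self.consensus.canonical_newick(lengths=False)
                                 if self.consensus else None),
            "consensus_support_pct": {
                "|".join(sorted(cl)): round(100.0 * f, 6)
                for cl, f in sorted(self.consensus_support.items(),
                                    key=lambda kv: sorted(kv[0]))},
        }
        return out


def majority_consensus(
        subtrees: Sequence[RootedTree],
) -> tuple[RootedTree, dict[frozenset[str], float]]:
    """Majority-rule consensus of rooted trees on one leaf set.

    Returns the tree containing exactly the clades present in strictly more
    than half of the inputs (ties at exactly 50% excluded), plus a mapping
    clade -> support fraction.  Internal node labels carry the percentage
    rounded to the nearest integer; the exact fraction is kept on the
    node's ``support`` attribute.
    """
    if not subtrees:
        raise TreeError("consensus of zero trees")
    leaves = subtrees[0].leaf_labels()
    for t in subtrees[1:]:
        if t.leaf_labels() != leaves:
            raise TreeError("consensus inputs must share one leaf set")
    n = len(subtrees)
    freq: Counter = Counter()
    for t in subtrees:
        if len(leaves) >= 2:
            freq.update(clade_set(t))
    support = {cl: c / n for cl, c in freq.items()}
    kept = [cl for cl, f in support.items() if f > 0.5]
    kept.sort(key=len, reverse=True)

    root = TreeNode()
    node_of: dict[frozenset[str], TreeNode] = {frozenset(leaves): root}
    for cl in kept:
        # parent = smallest already-placed clade strictly containing cl
        parent_clade = min((c for c in node_of if cl < c), key=len)
        node = TreeNode()
        node.support = support[cl]
        node.label = str(round(100.0 * support[cl]))
        node_of[parent_clade].add_child(node)
        node_of[cl] = node
    for label in sorted(leaves):
        singleton = frozenset([label])
        parent_clade = min((c for c in node_of if singleton < c), key=len)
        node_of[parent_clade].add_child(TreeNode(label))
    tree = RootedTree(root)
    return tree, {cl: support[cl] for cl in kept}


def _required_min_species(n_focal: int, options: CensusOptions) -> int:
    if options.one_missing_enabled and n_focal >= 4:
        return n_focal - 1
    return n_focal


def extract_family(family_id: str, tree: RootedTree, taxon_map: TaxonMap,
                   focal_group: str, options: CensusOptions,
                   catalog: TopologyCatalog,
                   one_missing_catalogs: dict[frozenset[str], TopologyCatalog],
                   ) -> ExtractionRecord:
    """Run one gene family through reroot -> extract -> collapse -> classify.

    Rejection reasons are evaluated in a fixed order — unrootable,
    too_few_species, cross_species_duplication, paraphyletic_focal_group,
    unresolved_polytomy — and only the first applicable one is reported.
    """
    focal_species = taxon_map.species_in_group(focal_group)
    n_focal = len(focal_species)

    def reject(reason: str) -> ExtractionRecord:
        logger.info("family %s rejected: %s", family_id, reason)
        return ExtractionRecord(family_id=family_id, category="rejected",
                                reject_reason=reason)

    try:
        rooted = reroot_by_outgroup(tree, taxon_map)
    except UnrootableError:
        return reject("unrootable")

    try:
        focal = find_focal_clade(rooted, taxon_map, focal_group)
    except TreeError:
        return reject("too_few_species")
    if len(focal.species_present) < _required_min_species(n_focal, options):
        return reject("too_few_species")

    # a species whose copies are scattered across the tree is a duplication
    # artifact (cross-species paralogy), reported before focal paraphyly
    multi = [sp for sp, k in focal.tips_per_species.items() if k >= 2]
    if multi:
        tips_by_sp: dict[str, list[TreeNode]] = {sp: [] for sp in multi}
        for leaf in rooted.leaves():
            sp = taxon_map.species_of(leaf.label)  # type: ignore[arg-type]
            if sp in tips_by_sp:
                tips_by_sp[sp].append(leaf)
        for sp in sorted(multi):
            mrca = rooted.mrca(tips_by_sp[sp])
            n_under = sum(1 for x in RootedTree.preorder(_subtree_view(mrca))
                          if x.is_leaf)
            if n_under != len(tips_by_sp[sp]):
                return reject("cross_species_duplication")

    if not focal.monophyletic:
        return reject("paraphyletic_focal_group")

    subtree = focal.subtree
    if options.polytomy_epsilon is not None:
        subtree = collapse_short_branches(subtree, options.polytomy_epsilon)
    try:
        collapsed, any_collapsed = collapse_species_duplicates(subtree,
                                                               taxon_map)
    except CrossSpeciesDuplicationError:
        return reject("cross_species_duplication")

    if not collapsed.is_binary():
        return reject("unresolved_polytomy")

    present = frozenset(focal.species_present)
    if present == focal_species:
        category = "duplicated_collapsed" if any_collapsed else "complete"
        use_catalog = catalog
    else:  # exactly one species missing (guaranteed by the min-species gate)
        category = "one_missing"
        if present not in one_missing_catalogs:
            one_missing_catalogs[present] = enumerate_rooted_topologies(present)
        use_catalog = one_missing_catalogs[present]

    if len(present) >= 2:
        tid = classify_topology(collapsed, use_catalog)
    else:  # pragma: no cover - needs focal groups of size 1, gated earlier
        tid = None
    if tid is None:
        return reject("unresolved_polytomy")

    return ExtractionRecord(
        family_id=family_id,
        category=category,
        clade=collapsed,
        topology_id=tid,
        topology_newick=use_catalog.newick(tid),
        taxa=use_catalog.taxa,
        mean_branch_length=subtree_mean_branch_length(collapsed),
        kept_duplicate_tips=any_collapsed,
    )


def run_census(trees: Sequence[tuple[str, RootedTree]], taxon_map: TaxonMap,
               focal_group: str, options: CensusOptions | None = None,
               ) -> tuple[list[ExtractionRecord], CensusResult]:
    """Run the full topology census over a collection of gene families.

    Each family yields exactly one :class:`ExtractionRecord`.  Complete and
    duplicated-collapsed families are classified against the full focal
    catalogue; one-missing families against the catalogue on their reduced
    taxon set and tallied separately.  Proportions are computed per
    category; the majority-rule consensus is built from the complete
    (plus collapsed, by default) subtrees.
    """
    if not trees:
        raise ValueError("empty input: no gene families")
    options = options or CensusOptions()
    taxon_map.validate_focal_group(focal_group)
    focal_species = taxon_map.species_in_group(focal_group)
    catalog = enumerate_rooted_topologies(focal_species)
    one_missing_catalogs: dict[frozenset[str], TopologyCatalog] = {}

    records = [extract_family(fid, t, taxon_map, focal_group, options,
                              catalog, one_missing_catalogs)
               for fid, t in trees]

    counts: dict[str, Counter] = {c: Counter() for c in
                                  ("complete", "one_missing",
                                   "duplicated_collapsed")}
    rejection_reasons: Counter = Counter()
    bl_by_topology: dict[int, list[float]] = {}
    consensus_pool: list[RootedTree] = []
    for rec in records:
        if rec.category == "rejected":
            rejection_reasons[rec.reject_reason] += 1
            continue
        if rec.category == "one_missing":
            counts["one_missing"][rec.topology_newick] += 1
        else:
            counts[rec.category][rec.topology_id] += 1
            if rec.mean_branch_length is not None:
                bl_by_topology.setdefault(rec.topology_id, []).append(
                    rec.mean_branch_length)
            if (rec.category == "complete"
                    or options.consensus_scope == "complete_plus_collapsed"):
                consensus_pool.append(rec.clade)  # type: ignore[arg-type]

    proportions: dict[str, dict] = {}
    for cat, counter in counts.items():
        total = sum(counter.values())
        proportions[cat] = ({k: v / total for k, v in counter.items()}
                            if total else {})
    pooled = Counter(counts["complete"]) + Counter(counts["duplicated_collapsed"])
    pooled_total = sum(pooled.values())
    pooled_props = ({k: v / pooled_total for k, v in pooled.items()}
                    if pooled_total else {})

    consensus = None
    consensus_support: dict[frozenset[str], float] = {}
    if consensus_pool:
        consensus, consensus_support = majority_consensus(consensus_pool)

    result = CensusResult(
        n_input=len(records),
        n_rejected=sum(rejection_reasons.values()),
        counts=counts,
        proportions=proportions,
        pooled_full_proportions=dict(sorted(pooled_props.items())),
        rejection_reasons=rejection_reasons,
        consensus=consensus,
        consensus_support=consensus_support,
        branch_length_summary={tid: float(np.mean(v))
                               for tid, v in sorted(bl_by_topology.items())},
        catalog=catalog,
        one_missing_catalogs=one_missing_catalogs,
    )
    return records, result


# --------------------------------------------------------------------------
# Multispecies-coalescent simulator
# --------------------------------------------------------------------------


@dataclass
class SpeciesTreeModel:
    """Generating model for synthetic gene families.

    The focal species tree carries branch lengths in coalescent units and
    must be ultrametric (constant effective population size, so coalescent
    units form a global clock).  One haploid lineage is sampled per focal
    species.  Scaffold (outgroup) species attach basally at fixed depths —
    they exist only to exercise rooting and extraction, without coalescent
    variance of their own.

    Perturbation probabilities apply independently per family and focal
    species: ``p_dropout`` deletes the species' tip, ``p_duplicate``
    replaces it by a within-species cherry, ``p_paralog`` additionally
    grafts a stray copy into the scaffold (a cross-species paralog that
    downstream analysis must reject).
    """

    species_tree: RootedTree
    scaffold_species: tuple[str, ...] = ("OG1", "OG2", "OG3", "OG4")
    scaffold_depths: tuple[float, ...] | None = None
    p_dropout: float = 0.1
    p_duplicate: float = 0.1
    p_paralog: float = 0.05
    seed: int = 0
    scaffold_spacing: float = 3.0

    def __post_init__(self):
        for name in ("p_dropout", "p_duplicate", "p_paralog"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        focal = self.focal_species()
        if set(self.scaffold_species) & set(focal):
            raise ValueError("scaffold species overlap focal species")
        for node in self.species_tree.preorder():
            if node.parent is not None and (node.length is None
                                            or node.length < 0):
                raise ValueError("species tree needs non-negative branch "
                                 "lengths on every edge")
        self._check_ultrametric()
        if self.scaffold_depths is not None:
            if len(self.scaffold_depths) != len(self.scaffold_species):
                raise ValueError("scaffold_depths must match scaffold_species")
            if list(self.scaffold_depths) != sorted(self.scaffold_depths):
                raise ValueError("scaffold_depths must be non-decreasing")

    def focal_species(self) -> tuple[str, ...]:
        return tuple(sorted(self.species_tree.leaf_labels()))

    def _check_ultrametric(self, tol: float = 1e-6) -> None:
        depths = self.species_tree.depths()
        tip_depths = [depths[id(l)] for l in self.species_tree.leaves()]
        if max(tip_depths) - min(tip_depths) > tol:
            raise ValueError("species tree must be ultrametric in "
                             "coalescent units (constant population size)")

    @property
    def height(self) -> float:
        return max(self.species_tree.depths()[id(l)]
                   for l in self.species_tree.leaves())

    def effective_scaffold_depths(self) -> tuple[float, ...]:
        if self.scaffold_depths is not None:
            return self.scaffold_depths
        h = self.height
        s = self.scaffold_spacing
        return tuple(h + s * (i + 1) for i in range(len(self.scaffold_species)))

    # -- config round-trip -------------------------------------------------

    def to_config(self) -> dict:
        return {
            "species_tree": self.species_tree.canonical_newick(),
            "scaffold_species": list(self.scaffold_species),
            "scaffold_depths": (list(self.scaffold_depths)
                                if self.scaffold_depths else None),
            "p_dropout": self.p_dropout,
            "p_duplicate": self.p_duplicate,
            "p_paralog": self.p_paralog,
            "seed": self.seed,
            "scaffold_spacing": self.scaffold_spacing,
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "SpeciesTreeModel":
        tree = parse_newick(cfg["species_tree"])
        kwargs = {k: cfg[k] for k in ("p_dropout", "p_duplicate", "p_paralog",
                                      "seed", "scaffold_spacing") if k in cfg}
        depths = cfg.get("scaffold_depths")
        return cls(species_tree=tree,
                   scaffold_species=tuple(cfg.get("scaffold_species", ())),
                   scaffold_depths=tuple(depths) if depths else None,
                   **kwargs)


def default_model(seed: int = 0) -> SpeciesTreeModel:
    """Study conditions used throughout: an asymmetric ultrametric 4-taxon
    species tree with 2-coalescent-unit internal branches (moderate
    incomplete lineage sorting), a 4-species outgroup scaffold, and mild
    dropout/duplication/paralog rates."""
    return SpeciesTreeModel(
        species_tree=parse_newick("(((A:6,B:6):2,C:8):2,D:10);"),
        scaffold_species=("OG1", "OG2", "OG3", "OG4"),
        p_dropout=0.1, p_duplicate=0.1, p_paralog=0.05,
        seed=seed,
    )


@dataclass
class SimulatedFamily:
    """One simulated gene family plus the generating truth."""

    family_id: str
    tree: RootedTree
    true_focal_topology: int                # id in the focal catalogue
    expected_category: str                  # what a correct census reports
    expected_reject_reason: str | None
    perturbations_applied: tuple[str, ...] = ()
    locus_index: int = 0


def _locus_rng(seed: int, locus: int, stream: int) -> np.random.Generator:
    # fixed per-locus substreams: changing n_loci never reshuffles earlier loci
    return np.random.default_rng([seed & 0x7FFFFFFF, locus, stream])


def _coalesce(lineages: list[tuple[TreeNode, float]], t0: float, t1: float,
              rng: np.random.Generator) -> list[tuple[TreeNode, float]]:
    """Coalesce lineages in one population between times t0 and t1
    (coalescent units; t1 may be inf).  Waiting times are exponential at
    rate k(k-1)/2 for k extant lineages."""
    lineages = list(lineages)
    t = t0
    while len(lineages) >= 2:
        k = len(lineages)
        t = t + rng.exponential(2.0 / (k * (k - 1)))
        if t >= t1:
            break
        i, j = rng.choice(k, size=2, replace=False)
        (ni, hi), (nj, hj) = lineages[i], lineages[j]
        parent = TreeNode()
        ni.length = t - hi
        nj.length = t - hj
        parent.add_child(ni)
        parent.add_child(nj)
        keep = [lineages[x] for x in range(k) if x not in (i, j)]
        keep.append((parent, t))
        lineages = keep
    return lineages


def _simulate_focal_gene_tree(model: SpeciesTreeModel,
                              rng: np.random.Generator,
                              ) -> tuple[TreeNode, float]:
    """One multispecies-coalescent gene tree on the focal species.

    Returns the gene-tree root node (tips labelled with species ids) and
    its height in coalescent units.
    """
    sp = model.species_tree
    depths = sp.depths()
    height = model.height
    time_of = {id(n): height - depths[id(n)] for n in sp.preorder()}

    pools: dict[int, list[tuple[TreeNode, float]]] = {}
    for leaf in sp.leaves():
        pools[id(leaf)] = [(TreeNode(leaf.label), time_of[id(leaf)])]

    # postorder guarantees children are processed before their parent even
    # when zero-length branches make node times tie
    for node in (n for n in sp.postorder() if not n.is_leaf):
        merged: list[tuple[TreeNode, float]] = []
        for child in node.children:
            merged.extend(_coalesce(pools[id(child)], time_of[id(child)],
                                    time_of[id(node)], rng))
        pools[id(node)] = merged
    final = _coalesce(pools[id(sp.root)], time_of[id(sp.root)], math.inf, rng)
    (root, root_h), = final
    return root, root_h


def _embed_in_scaffold(gene_root: TreeNode, root_height: float,
                       model: SpeciesTreeModel) -> RootedTree:
    """Attach scaffold species basally at fixed depths; each depth is bumped
    above the realized gene-root height if a deep coalescence overshoots."""
    for leaf in RootedTree.preorder(_subtree_view(gene_root)):
        if leaf.is_leaf:
            leaf.label = f"{leaf.label}_1"
    cur, cur_h = gene_root, root_height
    for species, depth in zip(model.scaffold_species,
                              model.effective_scaffold_depths()):
        d = max(depth, cur_h + 1.0)
        joint = TreeNode()
        cur.length = d - cur_h
        joint.add_child(cur)
        joint.add_child(TreeNode(species, length=d))
        cur, cur_h = joint, d
    cur.length = None
    return RootedTree(cur)


def simulate_gene_trees(model: SpeciesTreeModel,
                        n_loci: int) -> list[SimulatedFamily]:
    """Simulate unperturbed gene families under the multispecies coalescent.

    Per locus, lineages (one per focal species) coalesce within species-tree
    branches with exponential waiting times at rate k(k-1)/2, merging
    populations at each ancestral node.  The resulting gene tree is binary
    with strictly positive branch lengths, classified against the focal
    topology catalogue (``true_focal_topology``), then embedded under the
    outgroup scaffold with focal tips relabelled ``<species>_1``.

    The RNG is fully determined by ``model.seed`` plus the locus index.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    focal = model.focal_species()
    catalog = enumerate_rooted_topologies(focal) if len(focal) >= 2 else None
    families = []
    for i in range(n_loci):
        rng = _locus_rng(model.seed, i, 0)
        gene_root, h = _simulate_focal_gene_tree(model, rng)
        if catalog is not None:
            tid = classify_topology(RootedTree(gene_root).copy(), catalog)
            assert tid is not None  # coalescent trees are binary
        else:  # pragma: no cover
            tid = 1
        tree = (_embed_in_scaffold(gene_root, h, model)
                if model.scaffold_species
                else _relabel_focal(RootedTree(gene_root)))
        families.append(SimulatedFamily(
            family_id=str(i + 1), tree=tree, true_focal_topology=tid,
            expected_category="complete", expected_reject_reason=None,
            locus_index=i))
    return families


def _relabel_focal(tree: RootedTree) -> RootedTree:
    for leaf in tree.leaves():
        leaf.label = f"{leaf.label}_1"
    return tree


def expected_triplet_frequencies(T: float) -> tuple[float, float, float]:
    """Closed-form rooted-triplet topology probabilities under the
    coalescent for a 3-taxon species tree ((A,B),C) with internal branch
    ``T`` coalescent units: the concordant topology has probability
    1 - (2/3)e^{-T}; each discordant one (1/3)e^{-T}."""
    if T < 0:
        raise ValueError("internal branch length must be >= 0")
    d = math.exp(-T) / 3.0
    return (1.0 - 2.0 * d, d, d)


def apply_perturbations(families: Sequence[SimulatedFamily],
                        model: SpeciesTreeModel) -> list[SimulatedFamily]:
    """Inject dropout / within-species duplication / stray-paralog noise.

    Independently per family and focal species: with ``p_dropout`` the tip
    is deleted; otherwise with ``p_duplicate`` it becomes a two-tip cherry
    (terminal branches 0.01 coalescent units); with ``p_paralog`` an extra
    copy is grafted onto a random scaffold tip edge.  ``expected_category``
    and ``expected_reject_reason`` are updated to what a correct census
    must report."""
    focal = model.focal_species()
    n_focal = len(focal)
    out = []
    for fam in families:
        rng = _locus_rng(model.seed, fam.locus_index, 1)
        tree = fam.tree.copy()
        tags: list[str] = []
        dropped: set[str] = set()
        any_dup = False
        any_paralog = False
        for sp in focal:
            u_drop, u_dup, u_par = rng.random(3)
            tip_label = f"{sp}_1"
            if u_drop < model.p_dropout:
                if tree.n_leaves > 2:
                    tree = _detach_leaf(tree, tree.find_leaf(tip_label))
                    dropped.add(sp)
                    tags.append(f"dropout:{sp}")
                continue
            if u_dup < model.p_duplicate:
                tip = tree.find_leaf(tip_label)
                eps = min(DUPLICATE_CHERRY_LENGTH,
                          (tip.length or DUPLICATE_CHERRY_LENGTH) / 2.0)
                inner = TreeNode(length=(tip.length or 0.0) - eps)
                parent = tip.parent
                parent.children[parent.children.index(tip)] = inner  # type: ignore[union-attr]
                inner.parent = parent
                tip.parent = None
                inner.add_child(TreeNode(f"{sp}_1", length=eps))
                inner.add_child(TreeNode(f"{sp}_2", length=eps))
                any_dup = True
                tags.append(f"duplicate:{sp}")
            if u_par < model.p_paralog and model.scaffold_species:
                scaffold_tips = [l for l in tree.leaves()
                                 if l.label in model.scaffold_species]
                if scaffold_tips:
                    host = scaffold_tips[rng.integers(len(scaffold_tips))]
                    d = host.length or 1.0
                    a = float(d * rng.uniform(0.3, 0.7))
                    joint = TreeNode(length=d - a)
                    parent = host.parent
                    parent.children[parent.children.index(host)] = joint  # type: ignore[union-attr]
                    joint.parent = parent
                    host.parent = None
                    joint.add_child(host)
                    host.length = a
                    copy_no = 3 if f"{sp}_2" in tree.leaf_labels() else 2
                    joint.add_child(TreeNode(f"{sp}_{copy_no}", length=a))
                    any_paralog = True
                    tags.append(f"paralog:{sp}")
        n_present = n_focal - len(dropped)
        min_required = n_focal - 1 if n_focal >= 4 else n_focal
        if n_present < min_required:
            category, reason = "rejected", "too_few_species"
        elif any_paralog:
            category, reason = "rejected", "cross_species_duplication"
        elif n_present == n_focal:
            category = "duplicated_collapsed" if any_dup else "complete"
            reason = None
        else:
            category, reason = "one_missing", None
        out.append(dataclasses.replace(
            fam, tree=RootedTree(tree.root), perturbations_applied=tuple(tags),
            expected_category=category, expected_reject_reason=reason))
    return out


def frequency_agreement_test(observed_counts: Sequence[int],
                             expected_freqs: Sequence[float],
                             ) -> tuple[float, float]:
    """Chi-square goodness of fit of observed topology counts against
    expected frequencies, with categories of expected count < 5 pooled
    (smallest merged together).  Returns (statistic, p_value) with k-1
    degrees of freedom after pooling."""
    obs = np.asarray(observed_counts, dtype=float)
    freqs = np.asarray(expected_freqs, dtype=float)
    if obs.shape != freqs.shape:
        raise ValueError("observed and expected must have the same length")
    if len(obs) < 2:
        raise ValueError("degenerate test: need at least 2 categories")
    if not math.isclose(freqs.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("expected frequencies must sum to 1")
    n = obs.sum()
    if n < 1:
        raise ValueError("need at least one observation")
    exp = freqs * n
    order = np.argsort(exp)
    obs, exp = obs[order], exp[order]
    while len(exp) > 2 and exp[0] < 5.0:
        obs = np.concatenate([[obs[0] + obs[1]], obs[2:]])
        exp = np.concatenate([[exp[0] + exp[1]], exp[2:]])
        order = np.argsort(exp)
        obs, exp = obs[order], exp[order]
    if len(exp) < 2:
        raise ValueError("degenerate test after pooling")
    stat = float(((obs - exp) ** 2 / exp).sum())
    p = float(_scipy_stats.chi2.sf(stat, df=len(exp) - 1))
    return stat, p


# --------------------------------------------------------------------------
# File I/O
# --------------------------------------------------------------------------


TREE_SUFFIXES = (".nwk", ".newick", ".tree", ".tre")


def read_trees(path: str | Path) -> list[tuple[str, RootedTree]]:
    """Read gene family trees from a multi-tree Newick file (one per line,
    family id = 1-based line number) or from a directory of per-family
    Newick files (family id = file stem)."""
    path = Path(path)
    out: list[tuple[str, RootedTree]] = []
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in TREE_SUFFIXES)
        if not files:
            raise FileNotFoundError(f"no Newick files in directory {path}")
        for p in files:
            out.append((p.stem, parse_newick(p.read_text())))
        return out
    lines = [l for l in path.read_text().splitlines()]
    idx = 0
    for line in lines:
        if not line.strip():
            continue
        idx += 1
        out.append((str(idx), parse_newick(line)))
    if not out:
        raise ValueError(f"no trees found in {path}")
    return out


def read_taxon_map(path: str | Path) -> TaxonMap:
    """Read a taxon map TSV with a ``# tips`` section (tip TAB species) and
    a ``# species`` section (species TAB group [TAB outgroup_rank])."""
    tip_to_species: dict[str, str] = {}
    species_to_group: dict[str, str] = {}
    ranked: list[tuple[int, str]] = []
    section = "tips"
    for ln, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            token = line.lstrip("#").strip().lower()
            if token in ("tips", "species"):
                section = token
            continue
        cols = line.split("\t")
        if section == "tips":
            if len(cols) != 2:
                raise ValueError(f"{path}:{ln}: tip rows need 2 columns")
            tip_to_species[cols[0]] = cols[1]
        else:
            if len(cols) not in (2, 3):
                raise ValueError(f"{path}:{ln}: species rows need 2-3 columns")
            species_to_group[cols[0]] = cols[1]
            if len(cols) == 3 and cols[2]:
                ranked.append((int(cols[2]), cols[0]))
    ranked.sort()
    return TaxonMap(tip_to_species=tip_to_species,
                    species_to_group=species_to_group,
                    outgroup_priority=tuple(sp for _, sp in ranked))


def write_taxon_map(taxon_map: TaxonMap, path: str | Path) -> None:
    lines = ["# tips"]
    for tip, sp in sorted(taxon_map.tip_to_species.items()):
        lines.append(f"{tip}\t{sp}")
    lines.append("# species")
    rank = {sp: i + 1 for i, sp in enumerate(taxon_map.outgroup_priority)}
    for sp, grp in sorted(taxon_map.species_to_group.items()):
        if sp in rank:
            lines.append(f"{sp}\t{grp}\t{rank[sp]}")
        else:
            lines.append(f"{sp}\t{grp}")
    Path(path).write_text("\n".join(lines) + "\n")


def simulator_taxon_map(model: SpeciesTreeModel,
                        focal_group: str = "focal",
                        max_copies: int = 3) -> TaxonMap:
    """Taxon map covering every tip label the simulator can emit."""
    tip_to_species = {}
    species_to_group = {}
    for sp in model.focal_species():
        species_to_group[sp] = focal_group
        for k in range(1, max_copies + 1):
            tip_to_species[f"{sp}_{k}"] = sp
    for sp in model.scaffold_species:
        species_to_group[sp] = "outgroup"
        tip_to_species[sp] = sp
    return TaxonMap(tip_to_species=tip_to_species,
                    species_to_group=species_to_group,
                    outgroup_priority=tuple(reversed(model.scaffold_species)))


def write_records_tsv(records: Sequence[ExtractionRecord],
                      path: str | Path) -> None:
    header = ["family_id", "category", "reject_reason", "topology_id",
              "canonical_topology_newick", "mean_branch_length"]
    rows = ["\t".join(header)]
    for r in records:
        rows.append("\t".join([
            r.family_id, r.category, r.reject_reason or "",
            "" if r.topology_id is None else str(r.topology_id),
            r.topology_newick or "",
            "" if r.mean_branch_length is None
            else f"{r.mean_branch_length:.6g}",
        ]))
    Path(path).write_text("\n".join(rows) + "\n")


def write_truth_tsv(families: Sequence[SimulatedFamily],
                    path: str | Path) -> None:
    header = ["family_id", "true_focal_topology", "expected_category",
              "expected_reject_reason", "perturbations"]
    rows = ["\t".join(header)]
    for f in families:
        rows.append("\t".join([
            f.family_id, str(f.true_focal_topology), f.expected_category,
            f.expected_reject_reason or "",
            ",".join(f.perturbations_applied)]))
    Path(path).write_text("\n".join(rows) + "\n")


def census_summary_text(result: CensusResult,
                        precision: int = 2) -> str:
    """Human-readable census summary: counts per category, topology
    proportions (percentages rounded to integers), consensus support."""
    lines = []
    n_classified = result.n_input - result.n_rejected
    lines.append(f"gene families analysed: {result.n_input}")
    lines.append(f"  complete (all species, single-copy): "
                 f"{sum(result.counts['complete'].values())}")
    lines.append(f"  one species missing:                 "
                 f"{sum(result.counts['one_missing'].values())}")
    lines.append(f"  duplicates collapsed:                "
                 f"{sum(result.counts['duplicated_collapsed'].values())}")
    lines.append(f"  rejected:                            {result.n_rejected}")
    for reason, k in sorted(result.rejection_reasons.items()):
        lines.append(f"    {reason}: {k}")
    lines.append(f"  classified total:                    {n_classified}")
    for cat in ("complete", "duplicated_collapsed"):
        props = result.proportions[cat]
        if not props:
            continue
        lines.append(f"topology proportions ({cat}):")
        for tid, p in sorted(props.items(), key=lambda kv: -kv[1]):
            lines.append(f"  topology {tid} {result.catalog.newick(tid)}: "
                         f"{100 * p:.0f}%  ({p:.{precision}f})")
    if result.proportions["one_missing"]:
        lines.append("topology proportions (one species missing):")
        for nwk, p in sorted(result.proportions["one_missing"].items(),
                             key=lambda kv: -kv[1]):
            lines.append(f"  {nwk}: {100 * p:.0f}%  ({p:.{precision}f})")
    if result.consensus is not None:
        lines.append("majority-rule consensus (support %): "
                     + result.consensus.canonical_newick(lengths=False))
    if result.branch_length_summary:
        lines.append("mean branch length per topology (mean of per-family means):")
        for tid, m in result.branch_length_summary.items():
            lines.append(f"  topology {tid}: {m:.4f}")
    return "\n".join(lines)


# --------------------------------------------------------------------------
# Command-line interface
# --------------------------------------------------------------------------


@click.group()
@click.option("-v", "--verbose", is_flag=True, help="Log at DEBUG level.")
def cli(verbose: bool) -> None:
    """Gene-tree topology census and multispecies-coalescent simulator."""
    logging.basicConfig(stream=sys.stderr,
                        level=logging.DEBUG if verbose else logging.INFO,
                        format="%(levelname)s %(name)s: %(message)s")


@cli.command("enumerate")
@click.argument("n", type=int)
def cmd_enumerate(n: int) -> None:
    """Print all rooted binary topologies on N generic taxa (t1..tN)."""
    if not 2 <= n <= MAX_CATALOG_TAXA:
        raise click.ClickException(
            f"n must be in [2, {MAX_CATALOG_TAXA}], got {n}")
    catalog = enumerate_rooted_topologies(f"t{i}" for i in range(1, n + 1))
    for tid in catalog.ids():
        click.echo(f"{tid}\t{catalog.newick(tid)}")
    click.echo(f"count\t{catalog.size}")


@cli.command("simulate")
@click.option("--model", "model_path", type=click.Path(exists=True),
              help="Model config JSON; defaults to the built-in 4-taxon model.")
@click.option("--n-loci", type=int, required=True)
@click.option("--out", "out_dir", type=click.Path(), required=True)
@click.option("--seed", type=int, default=None,
              help="Overrides the seed in the model config.")
def cmd_simulate(model_path: str | None, n_loci: int, out_dir: str,
                 seed: int | None) -> None:
    """Simulate gene families; write trees.nwk, truth.tsv, taxon_map.tsv."""
    if n_loci < 1:
        raise click.ClickException("--n-loci must be >= 1")
    try:
        if model_path:
            model = SpeciesTreeModel.from_config(
                json.loads(Path(model_path).read_text()))
        else:
            model = default_model()
        if seed is not None:
            model = dataclasses.replace(model, seed=seed)
    except (ValueError, KeyError, NewickError) as exc:
        raise click.ClickException(f"invalid model config: {exc}")
    families = apply_perturbations(simulate_gene_trees(model, n_loci), model)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "trees.nwk", "w") as fh:
        for fam in families:
            fh.write(fam.tree.canonical_newick() + "\n")
    write_truth_tsv(families, out / "truth.tsv")
    write_taxon_map(simulator_taxon_map(model), out / "taxon_map.tsv")
    (out / "model.json").write_text(json.dumps(model.to_config(), indent=2)
                                    + "\n")
    logger.info("wrote %d families to %s", len(families), out)


@cli.command("census")
@click.option("--trees", "trees_path", type=click.Path(exists=True),
              required=True, help="Multi-tree Newick file or directory.")
@click.option("--taxon-map", "taxon_map_path", type=click.Path(exists=True),
              required=True)
@click.option("--focal-group", default="focal", show_default=True)
@click.option("--out", "out_dir", type=click.Path(), required=True)
@click.option("--one-missing/--no-one-missing", default=True,
              show_default=True,
              help="Admit families with exactly one focal species missing.")
@click.option("--consensus-scope",
              type=click.Choice(["complete_plus_collapsed", "complete_only"]),
              default="complete_plus_collapsed", show_default=True)
@click.option("--polytomy-epsilon", type=float, default=None,
              help="Collapse internal branches shorter than this into "
                   "polytomies before classification (off by default).")
@click.option("--stdout", "to_stdout", is_flag=True,
              help="Also print the human-readable summary to stdout.")
def cmd_census(trees_path: str, taxon_map_path: str, focal_group: str,
               out_dir: str, one_missing: bool, consensus_scope: str,
               polytomy_epsilon: float | None, to_stdout: bool) -> None:
    """Run the topology census; write records.tsv, census.json,
    consensus.nwk and summary.txt."""
    try:
        trees = read_trees(trees_path)
        taxon_map = read_taxon_map(taxon_map_path)
    except (OSError, ValueError) as exc:
        raise click.ClickException(str(exc))
    options = CensusOptions(one_missing_enabled=one_missing,
                            consensus_scope=consensus_scope,
                            polytomy_epsilon=polytomy_epsilon)
    try:
        records, result = run_census(trees, taxon_map, focal_group, options)
    except (ValueError, TreeError) as exc:
        raise click.ClickException(str(exc))
    if result.n_input == result.n_rejected:
        raise click.ClickException("empty census: every family was rejected")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_records_tsv(records, out / "records.tsv")
    (out / "census.json").write_text(
        json.dumps(result.to_json_dict(), indent=2) + "\n")
    if result.consensus is not None:
        (out / "consensus.nwk").write_text(
            result.consensus.canonical_newick(lengths=False) + "\n")
    summary = census_summary_text(result)
    (out / "summary.txt").write_text(summary + "\n")
    logger.info("census written to %s", out)
    if to_stdout:
        click.echo(summary)


if __name__ == "__main__":  # pragma: no cover
    cli()
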