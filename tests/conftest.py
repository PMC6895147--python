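import numpy as np
import pytest

from topocensus import RootedTree, TaxonMap, TreeNode, parse_newick


def random_rooted_tree(rng: np.random.Generator, n_leaves: int,
                       with_lengths: bool = True) -> RootedTree:
    """Random rooted binary tree built by sequential random attachment;
    branch lengths (when present) are positive and pre-rounded to 6
    significant digits so serialization round-trips exactly."""
    labels = [f"L{i}" for i in range(n_leaves)]

    def leaf(lab):
        node = TreeNode(lab)
        if with_lengths:
            node.length = float(f"{rng.uniform(0.01, 5.0):.6g}")
        return node

    if n_leaves == 1:
        root = TreeNode()
        root.add_child(leaf(labels[0]))
        return RootedTree(root)
    root = TreeNode()
    root.add_child(leaf(labels[0]))
    root.add_child(leaf(labels[1]))
    tree = RootedTree(root)
    for lab in labels[2:]:
        nodes = [n for n in tree.preorder()]
        target = nodes[rng.integers(len(nodes))]
        joint = TreeNode()
        if with_lengths:
            joint.length = float(f"{rng.uniform(0.01, 5.0):.6g}")
        parent = target.parent
        if parent is None:
            joint.length = None
            joint.add_child(target)
            joint.add_child(leaf(lab))
            tree = RootedTree(joint)
        else:
            parent.children[parent.children.index(target)] = joint
            joint.parent = parent
            target.parent = None
            joint.add_child(target)
            joint.add_child(leaf(lab))
            tree = RootedTree(tree.root)
    return tree


@pytest.fixture
def fixture_taxon_map() -> TaxonMap:
    """Four focal species x/y/z/w (up to three tips each) plus two ranked
    outgroups, for hand-written extraction fixtures."""
    tip_to_species = {}
    for sp in "xyzw":
        for k in (1, 2, 3):
            tip_to_species[f"{sp}{k}"] = sp
    tip_to_species["og1"] = "OGA"
    tip_to_species["og2"] = "OGB"
    species_to_group = {sp: "focal" for sp in "xyzw"}
    species_to_group.update({"OGA": "outgroup", "OGB": "outgroup"})
    return TaxonMap(tip_to_species=tip_to_species,
                    species_to_group=species_to_group,
                    outgroup_priority=("OGB", "OGA"))


@pytest.fixture
def tree():
    """Convenience parser for terse fixtures."""
    return parse_newick
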