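"""Presence/absence profiling and Dollo gain/loss reconstruction.

Given per-record family assignments and a rooted species tree, this module
builds the species × family count matrix and explains each family's
presence pattern under Dollo parsimony: the family is gained exactly once,
on the edge above the most recent common ancestor of all species that have
it, and lost on the minimal set of edges below the gain whose removal
accounts for every absence.  Species present in the tree but missing from
the matrix are treated as "no data", not as absences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import pandas as pd

from .records import FAMILIES
from .classify import FamilyAssignment


# ---------------------------------------------------------------------------
# Species tree wrapper
# ---------------------------------------------------------------------------

class SpeciesTree:
    """A rooted species tree with deterministic labels on every node.

    Unnamed internal nodes receive preorder labels ``n1, n2, ...`` so that
    events can be reported as (family, child-node label, gain|loss).
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        counter = 0
        for node in tree.preorder_node_iter():
            if node.taxon is not None and node.taxon.label:
                node._wf_label = node.taxon.label
            elif node.label:
                node._wf_label = node.label
            else:
                counter += 1
                node._wf_label = f"n{counter}"
        labels = [n._wf_label for n in tree.preorder_node_iter()]
        if len(labels) != len(set(labels)):
            raise ValueError("tree node labels are not unique")

    @classmethod
    def read(cls, source: str, outgroup: str | None = None) -> "SpeciesTree":
        """Read a newick tree from a path or a newick string.

        The tree is used as rooted at its seed node; if ``outgroup`` is
        given the tree is rerooted on the edge above that leaf first.
        """
        import os
        kwargs = dict(schema="newick", preserve_underscores=True)
        if os.path.exists(source):
            tree = dendropy.Tree.get(path=source, **kwargs)
        else:
            tree = dendropy.Tree.get(data=source, **kwargs)
        if outgroup is not None:
            node = next((leaf for leaf in tree.leaf_node_iter()
                         if leaf.taxon and leaf.taxon.label == outgroup), None)
            if node is None:
                raise ValueError(f"outgroup {outgroup!r} is not a leaf")
            tree.to_outgroup_position(node, update_bipartitions=False)
        return cls(tree)

    @property
    def root(self):
        return self._tree.seed_node

    def nodes(self):
        return list(self._tree.preorder_node_iter())

    def leaves(self):
        return [n for n in self._tree.leaf_node_iter()]

    def leaf_labels(self) -> list[str]:
        return [n._wf_label for n in self.leaves()]

    def node(self, label: str):
        for n in self._tree.preorder_node_iter():
            if n._wf_label == label:
                return n
        raise KeyError(label)

    @staticmethod
    def label(node) -> str:
        return node._wf_label

    def mrca(self, labels: set[str]):
        want = set(labels)
        best = None
        for node in self._tree.postorder_node_iter():
            below = {l._wf_label for l in node.leaf_iter()}
            if want <= below:
                best = node
                break
        if best is None:
            raise ValueError(f"labels {sorted(want)} not all in tree")
        return best


# ---------------------------------------------------------------------------
# Presence matrix
# ---------------------------------------------------------------------------

def build_matrix(assignments: list[FamilyAssignment],
                 species_map: dict[str, tuple[str, tuple[str, ...]]],
                 include_pseudogenes: bool = False,
                 all_species: list[str] | None = None) -> pd.DataFrame:
    """Species × family count matrix from classified records.

    Unclassified records are excluded; pseudogene-flagged records are
    excluded unless ``include_pseudogenes``.  ``all_species`` may add rows
    for surveyed species that contributed no record (their absences are
    then explicit zeros rather than missing data).
    """
    missing = [a.record_id for a in assignments
               if not a.species and a.record_id not in species_map]
    if missing:
        raise ValueError("records without a species mapping: "
                         + ", ".join(sorted(missing)))
    species = sorted({a.species or species_map[a.record_id][0]
                      for a in assignments} | set(all_species or ()))
    matrix = pd.DataFrame(0, index=species, columns=list(FAMILIES), dtype=int)
    for a in assignments:
        if a.family == "unclassified":
            continue
        if a.pseudogene and not include_pseudogenes:
            continue
        sp = a.species or species_map[a.record_id][0]
        matrix.loc[sp, a.family] += 1
    return matrix


# ---------------------------------------------------------------------------
# Dollo reconstruction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FamilyEvents:
    """Single-gain reconstruction for one family."""

    family: str
    gain: str | None                   # child-node label of the gain edge
    losses: tuple[str, ...]            # child-node labels of loss edges
    states: dict = field(default_factory=dict)  # node label -> bool
    note: str = ""


@dataclass(frozen=True)
class GainLossEvents:
    per_family: dict

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for fam, ev in self.per_family.items():
            if ev.gain is not None:
                rows.append((fam, ev.gain, "gain"))
            for loss in ev.losses:
                rows.append((fam, loss, "loss"))
        return pd.DataFrame(rows, columns=["family", "edge", "event"])


def dollo_reconstruct(tree: SpeciesTree, matrix: pd.DataFrame,
                      families: list[str] | None = None) -> GainLossEvents:
    """Dollo parsimony per family: one gain above the MRCA of all presence
    leaves; losses on the highest edges below the gain whose entire subtree
    lacks the family (ignoring no-data leaves)."""
    leaf_set = set(tree.leaf_labels())
    unknown = set(matrix.index) - leaf_set
    if unknown:
        raise ValueError("species absent from the tree: "
                         + ", ".join(sorted(unknown)))
    per_family = {}
    for fam in (families or list(matrix.columns)):
        present = {sp for sp in matrix.index if matrix.loc[sp, fam] >= 1}
        absent = {sp for sp in matrix.index if matrix.loc[sp, fam] == 0}
        if not present:
            per_family[fam] = FamilyEvents(fam, None, (),
                                           note="absent from all species")
            continue
        gain_node = tree.mrca(present)
        losses: list[str] = []

        def has_present(node) -> bool:
            return any(l._wf_label in present for l in node.leaf_iter())

        def has_absent(node) -> bool:
            return any(l._wf_label in absent for l in node.leaf_iter())

        def walk(node) -> None:
            for child in node.child_nodes():
                if has_present(child):
                    walk(child)
                elif has_absent(child):
                    losses.append(SpeciesTree.label(child))
                # all-no-data subtrees: no event inferred

        walk(gain_node)

        lost_under = {l for l in losses}
        states: dict[str, bool] = {}

        def paint(node, state: bool) -> None:
            lbl = SpeciesTree.label(node)
            if lbl in lost_under:
                state = False
            states[lbl] = state
            for child in node.child_nodes():
                paint(child, state)

        # everything outside the gain clade is absent
        paint(tree.root, False)
        paint(gain_node, True)
        per_family[fam] = FamilyEvents(fam, SpeciesTree.label(gain_node),
                                       tuple(sorted(losses)), states)
    return GainLossEvents(per_family)


def summarize_inventory(matrix: pd.DataFrame, tree: SpeciesTree,
                        events: GainLossEvents | None = None) -> pd.DataFrame:
    """Collapse clades with a uniform family inventory into single rows.

    A clade is reported once when every leaf below it is in the matrix and
    shares the same presence/absence vector; remaining leaves are reported
    individually.  Columns: clade, n_species, then one 0/1 per family.
    """
    presence = (matrix >= 1).astype(int)
    rows = []

    def uniform(node):
        leaves = [l._wf_label for l in node.leaf_iter()]
        if any(l not in presence.index for l in leaves):
            return None
        vecs = presence.loc[leaves]
        if (vecs.nunique(axis=0) == 1).all():
            return leaves, vecs.iloc[0]
        return None

    def walk(node):
        res = uniform(node)
        if res is not None:
            leaves, vec = res
            label = leaves[0] if len(leaves) == 1 else SpeciesTree.label(node)
            rows.append((label, len(leaves), *vec.tolist()))
            return
        if node.is_leaf():
            rows.append((SpeciesTree.label(node), 1,
                         *([0] * presence.shape[1])))
            return
        for child in node.child_nodes():
            walk(child)

    walk(tree.root)
    return pd.DataFrame(rows, columns=["clade", "n_species",
                                       *presence.columns.tolist()])
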