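"""Rooted phylogenies: Newick I/O, patristic distances, megatree grafting.

The :class:`Phylogeny` wraps a :class:`dendropy.Tree` and adds the cached
array views (edge/tip incidence, root-path depths) that the diversity
metrics need.  Trees are treated as immutable: editing operations such as
:func:`graft_species` return a new object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = ["NewickError", "PhylogenyError", "Phylogeny", "graft_species", "GraftReport"]


class NewickError(ValueError):
    """Raised when a Newick string cannot be parsed into a valid tree."""


class PhylogenyError(ValueError):
    """Raised when an operation's structural preconditions are violated."""


def _format_length(x: float) -> str:
    return format(float(x), ".12g")


@dataclass
class _TreeIndex:
    """Array views of a tree, in a fixed leaf order.

    ``edge_tips`` is a boolean (n_edges, n_tips) incidence matrix: entry
    (e, t) is True iff tip t lies below edge e.  The root carries no edge.
    """

    tip_labels: list
    tip_index: dict
    branch_lengths: np.ndarray        # (n_edges,)
    edge_tips: np.ndarray             # (n_edges, n_tips) bool
    tip_depths: np.ndarray            # (n_tips,) root-to-tip path lengths
    node_ids: dict = field(default_factory=dict)   # dendropy node -> stable id
    _dist: np.ndarray | None = None

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def distance_matrix(self) -> np.ndarray:
        if self._dist is None:
            # shared root-path length S[i,j] = sum of branch lengths common
            # to the root paths of tips i and j; S[i,i] is the tip depth.
            E = self.edge_tips.astype(float)
            S = E.T @ (E * self.branch_lengths[:, None])
            d = np.diag(S)
            self._dist = d[:, None] + d[None, :] - 2.0 * S
            np.fill_diagonal(self._dist, 0.0)
        return self._dist


class Phylogeny:
    """A rooted tree with branch lengths and uniquely labelled tips."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._tree.is_rooted = True   # trees are rooted by contract
        self._validate()
        self._idx: _TreeIndex | None = None

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        """Parse a single rooted Newick string.

        Every non-root edge must carry a finite, non-negative branch
        length; parse failures raise :class:`NewickError` with the
        line/column position reported by the reader.
        """
        try:
            tree = dendropy.Tree.get(
                data=text, schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several reader errors
            raise NewickError(f"Newick parse failure: {exc}") from exc
        return cls(tree)

    def to_newick(self) -> str:
        """Serialize to a normalized Newick string (child order preserved,
        branch lengths formatted with 12 significant digits)."""

        def render(node) -> str:
            if node.is_leaf():
                core = node.taxon.label.replace(" ", "_")
            else:
                core = "(" + ",".join(render(c) for c in node.child_nodes()) + ")"
            if node.parent_node is not None:
                core += ":" + _format_length(node.edge.length)
            return core

        return render(self._tree.seed_node) + ";"

    # ------------------------------------------------------ basic structure

    def _validate(self) -> None:
        seen = set()
        n_tips = 0
        for leaf in self._tree.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise NewickError("unlabelled tip")
            if leaf.taxon.label in seen:
                raise NewickError(f"duplicate tip label {leaf.taxon.label!r}")
            seen.add(leaf.taxon.label)
            n_tips += 1
        if n_tips == 0:
            raise NewickError("tree has no tips")
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            length = node.edge.length
            if length is None:
                raise NewickError(
                    f"missing branch length on edge above "
                    f"{node.taxon.label if node.taxon else 'an internal node'}"
                )
            if not np.isfinite(length) or length < 0:
                raise NewickError(f"invalid branch length {length!r}")

    def _index(self) -> _TreeIndex:
        if self._idx is None:
            leaves = list(self._tree.leaf_node_iter())
            labels = [lf.taxon.label for lf in leaves]
            tip_index = {lab: i for i, lab in enumerate(labels)}
            edges, lengths = [], []
            node_ids = {}
            for k, node in enumerate(self._tree.preorder_node_iter()):
                node_ids[node] = (
                    node.taxon.label if node.is_leaf() else f"node{k}"
                )
                if node.parent_node is not None:
                    edges.append(node)
                    lengths.append(float(node.edge.length))
            E = np.zeros((len(edges), len(labels)), dtype=bool)
            for e, node in enumerate(edges):
                for lf in node.leaf_iter():
                    E[e, tip_index[lf.taxon.label]] = True
            bl = np.asarray(lengths, dtype=float)
            depths = (E * bl[:, None]).sum(axis=0)
            self._idx = _TreeIndex(labels, tip_index, bl, E, depths, node_ids)
        return self._idx

    @property
    def tip_labels(self) -> list:
        return list(self._index().tip_labels)

    @property
    def n_tips(self) -> int:
        return self._index().n_tips

    @property
    def total_length(self) -> float:
        return float(self._index().branch_lengths.sum())

    @property
    def depth(self) -> float:
        """Maximum root-to-tip path length."""
        return float(self._index().tip_depths.max())

    def copy(self) -> "Phylogeny":
        return Phylogeny(self._tree.clone(depth=1))

    def __contains__(self, label: str) -> bool:
        return label in self._index().tip_index

    # ------------------------------------------------------------ distances

    def patristic_distance(self, a: str, b: str) -> float:
        """Branch-length distance between tips ``a`` and ``b`` via their MRCA."""
        idx = self._index()
        for lab in (a, b):
            if lab not in idx.tip_index:
                raise PhylogenyError(f"unknown tip label {lab!r}")
        return float(idx.distance_matrix()[idx.tip_index[a], idx.tip_index[b]])

    def distance_matrix(self) -> tuple[np.ndarray, list]:
        """Full patristic distance matrix and the matching tip-label order."""
        idx = self._index()
        return idx.distance_matrix().copy(), list(idx.tip_labels)

    # --------------------------------------------------------- ultrametry

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        d = self._index().tip_depths
        return bool(d.max() - d.min() <= rel_tol * max(d.max(), 1e-300))

    def node_age(self, node) -> float:
        """Age of a node = longest path from the node down to any of its
        descendant tips (equals tip height on ultrametric trees)."""

        def deepest(n) -> float:
            if n.is_leaf():
                return 0.0
            return max(float(c.edge.length) + deepest(c) for c in n.child_nodes())

        return deepest(node)


@dataclass
class GraftReport:
    """Outcome of a grafting run: one row per requested species."""

    table: pd.DataFrame  # columns: species, action in {attached, skipped}, node_id

    @property
    def n_attached(self) -> int:
        return int((self.table["action"] == "attached").sum())

    @property
    def skipped(self) -> list:
        return self.table.loc[self.table["action"] == "skipped", "species"].tolist()


def _genus_of(label: str) -> str:
    for sep in (" ", "_"):
        if sep in label:
            return label.split(sep, 1)[0]
    return label


def graft_species(
    backbone: Phylogeny,
    new_species: list,
    genus_of_tip: dict | None = None,
    rel_tol: float = 1e-6,
) -> tuple[Phylogeny, GraftReport]:
    """Attach species to an ultrametric backbone at their genus's basal node.

    Each new species whose genus already has tips in the backbone is added
    as a new tip hanging from the most basal node of that genus — the MRCA
    of its congeneric tips, or the parent node of the single tip for a
    monotypic genus — with pendant branch length equal to that node's age,
    so the grafted tree stays ultrametric.  Species whose genus is absent
    are reported as skipped and the topology is otherwise untouched.
    Polytomies may arise and are never resolved.
    """
    if not backbone.is_ultrametric(rel_tol=rel_tol):
        raise PhylogenyError("backbone must be ultrametric for grafting")
    existing = set(backbone.tip_labels)
    if len(set(new_species)) != len(new_species):
        raise PhylogenyError("duplicate labels in new_species")
    dup = existing.intersection(new_species)
    if dup:
        raise PhylogenyError(f"labels already present in backbone: {sorted(dup)}")

    if genus_of_tip is None:
        genus_of_tip = {lab: _genus_of(lab) for lab in backbone.tip_labels}
    missing = [lab for lab in backbone.tip_labels if lab not in genus_of_tip]
    if missing:
        raise PhylogenyError(f"genus mapping missing for tips: {missing[:5]}")

    grafted = backbone.copy()
    tree = grafted._tree
    idx = grafted._index()   # ids refer to the pre-graft traversal
    genus_tips: dict = {}
    for leaf in tree.leaf_node_iter():
        genus_tips.setdefault(genus_of_tip[leaf.taxon.label], []).append(leaf)

    rows = []
    for species in new_species:
        genus = _genus_of(species)
        tips = genus_tips.get(genus)
        if not tips:
            rows.append((species, "skipped", ""))
            continue
        if len(tips) == 1:
            target = tips[0].parent_node
            if target is None:  # single-tip tree: attach at the root
                target = tree.seed_node
        else:
            target = tree.mrca(taxa=[t.taxon for t in tips])
        age = grafted.node_age(target)
        taxon = tree.taxon_namespace.new_taxon(label=species)
        child = target.new_child(taxon=taxon, edge_length=age)
        rows.append((species, "attached", idx.node_ids.get(target, "node?")))
        genus_tips[genus].append(child)

    grafted._idx = None  # structure changed; rebuild lazily
    report = GraftReport(pd.DataFrame(rows, columns=["species", "action", "node_id"]))
    return Phylogeny(grafted._tree), report
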