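"""Time-calibrated trees: reading, validation, ages, and species joins.

Trees are rooted, binary, ultrametric chronograms with branch lengths in Myr
(so node ages are in Ma).  Parsing and serialization stand on dendropy; this
module adds the validation contracts the DEC engine relies on: no duplicate
tip labels, no polytomies (unless resolution is requested), non-negative
branch lengths, and ultrametricity within a tolerance that defaults to
``1e-3 x tree height`` to absorb the rounding noise of published chronograms.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping

import dendropy

from .errors import DataError

DEFAULT_ULTRAMETRIC_RTOL = 1e-3


@dataclass
class JoinReport:
    """Outcome of matching tree tips against a species-keyed table."""

    matched: list[str]
    tree_only: list[str]
    table_only: list[str]

    @property
    def ok(self) -> bool:
        return not self.tree_only and not self.table_only


class TimeTree:
    """A rooted binary ultrametric tree with branch lengths in Myr."""

    def __init__(self, tree: dendropy.Tree, resolve_polytomies: bool = False):
        self._tree = tree
        self._validate(resolve_polytomies)
        self._assign_ids()
        self._ages: dict | None = None

    # -- construction ---------------------------------------------------

    @classmethod
    def from_newick(cls, source: str, resolve_polytomies: bool = False) -> "TimeTree":
        """Parse a newick tree from a string or a file path."""
        text = source
        if "(" not in source:  # looks like a path, not newick
            with open(source) as fh:
                text = fh.read()
        try:
            tree = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise DataError(f"newick parse error: {exc}") from exc
        return cls(tree, resolve_polytomies=resolve_polytomies)

    def _validate(self, resolve_polytomies: bool) -> None:
        t = self._tree
        labels = [leaf.taxon.label for leaf in t.leaf_node_iter()]
        if any(lbl is None for lbl in labels):
            raise DataError("tree has unlabeled tips")
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        if dupes:
            raise DataError(f"duplicate tip labels: {dupes}")
        if len(labels) < 2:
            raise DataError("tree must have at least 2 tips")
        for node in t.preorder_node_iter():
            if node.parent_node is not None and node.edge.length is None:
                raise DataError(f"missing branch length above node {_describe(node)}")
            if node.parent_node is not None and node.edge.length < 0:
                raise DataError(f"negative branch length above node {_describe(node)}")
            nch = len(node.child_nodes())
            if nch > 2:
                if resolve_polytomies:
                    pass  # handled below in one pass
                else:
                    raise DataError(
                        f"polytomy ({nch} children) at node {_describe(node)}; "
                        "pass resolve_polytomies=True to bifurcate with zero-length edges"
                    )
            elif nch == 1:
                raise DataError(f"unifurcation at node {_describe(node)}")
        if resolve_polytomies:
            t.resolve_polytomies(limit=2, update_bipartitions=False)
            for node in t.preorder_node_iter():
                if node.parent_node is not None and node.edge.length is None:
                    node.edge.length = 0.0

    def _assign_ids(self) -> None:
        """Stable ids: tips keep their label, internal nodes get 'nd<k>' in
        preorder (root is nd0)."""
        k = 0
        for node in self._tree.preorder_node_iter():
            if node.is_leaf():
                node.riverscape_id = node.taxon.label
            else:
                node.riverscape_id = f"nd{k}"
                k += 1

    # -- basic accessors ------------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self._tree.leaf_nodes())

    @property
    def root(self):
        return self._tree.seed_node

    def postorder(self):
        return self._tree.postorder_node_iter()

    def preorder(self):
        return self._tree.preorder_node_iter()

    @property
    def height(self) -> float:
        return max(
            leaf.distance_from_root() for leaf in self._tree.leaf_node_iter()
        )

    @property
    def root_age(self) -> float:
        return self.node_ages()[self.root.riverscape_id]

    # -- ages -----------------------------------------------------------

    def node_ages(self, rtol: float = DEFAULT_ULTRAMETRIC_RTOL) -> dict[str, float]:
        """Ages in Ma for every node (keyed by node id); tips sit at 0.

        Raises :class:`DataError` if any tip's root-to-tip distance deviates
        from the tree height by more than ``rtol x height``.
        """
        if self._ages is not None:
            return self._ages
        import statistics

        height = self.height
        tol = rtol * height
        depths = {
            leaf.taxon.label: leaf.distance_from_root()
            for leaf in self._tree.leaf_node_iter()
        }
        # deviation is judged against the median tip depth so the reported
        # "worst tip" is the aberrant one, not the majority
        ref = statistics.median(depths.values())
        worst_tip = max(depths, key=lambda l: abs(depths[l] - ref))
        worst_dev = abs(depths[worst_tip] - ref)
        if worst_dev > tol:
            raise DataError(
                f"tree is not ultrametric: tip {worst_tip!r} deviates from the "
                f"median root-to-tip distance by {worst_dev:.6g} Myr "
                f"(tolerance {tol:.6g})"
            )
        ages = {}
        for node in self._tree.preorder_node_iter():
            age = height - node.distance_from_root()
            if node.is_leaf():
                age = 0.0
            ages[node.riverscape_id] = age
        self._ages = ages
        return ages

    # -- joins ----------------------------------------------------------

    def join_tip_data(
        self,
        table: Mapping[str, object],
        strict: bool = False,
        normalize_names: bool = False,
    ) -> JoinReport:
        """Match tip labels against the keys of a species-keyed mapping.

        With ``normalize_names`` both sides are compared after trimming
        whitespace, lower-casing, and treating underscores as spaces (the
        original names are reported).  ``strict`` raises on any mismatch.
        """
        def norm(s: str) -> str:
            return s.strip().lower().replace("_", " ") if normalize_names else s

        tips = {norm(l): l for l in self.tip_labels}
        keys = {norm(k): k for k in table}
        matched = sorted(tips[n] for n in tips.keys() & keys.keys())
        tree_only = sorted(tips[n] for n in tips.keys() - keys.keys())
        table_only = sorted(keys[n] for n in keys.keys() - tips.keys())
        report = JoinReport(matched=matched, tree_only=tree_only, table_only=table_only)
        if strict and not report.ok:
            raise DataError(
                f"tip/table mismatch: tree-only={report.tree_only}, "
                f"table-only={report.table_only}"
            )
        return report

    # -- output ---------------------------------------------------------

    def to_newick(self, path=None) -> str:
        text = self._tree.as_string(schema="newick", suppress_rooting=True).strip()
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def cherries(self) -> list[tuple[str, str]]:
        """All terminal sister pairs: internal nodes whose two children are tips."""
        out = []
        for node in self._tree.preorder_node_iter():
            ch = node.child_nodes()
            if len(ch) == 2 and all(c.is_leaf() for c in ch):
                out.append((ch[0].taxon.label, ch[1].taxon.label))
        return out


def _describe(node) -> str:
    if node.is_leaf():
        return repr(node.taxon.label)
    tips = [l.taxon.label for l in node.leaf_iter()]
    return f"MRCA of {tips[:3]}{'...' if len(tips) > 3 else ''}"


def read_newick(source: str, resolve_polytomies: bool = False) -> TimeTree:
    """Module-level convenience wrapper around :meth:`TimeTree.from_newick`."""
    return TimeTree.from_newick(source, resolve_polytomies=resolve_polytomies)
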