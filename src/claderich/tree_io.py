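"""Time-calibrated tree input/output and structural utilities.

Trees are rooted, with branch lengths in millions of years (Myr), and are
expected to be ultrametric (all extant tips contemporaneous) for age-based
analyses.  Parsing, writing and pruning are delegated to :mod:`dendropy`;
this module adds deterministic integer node ids, node-age computation,
artifact detection (polytomies, zero-length branches) and the construction
of reduced one-tip-per-clade trees used as the PGLS covariance substrate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

#: Tolerance (Myr) within which root-to-tip path lengths must agree for a
#: tree to count as ultrametric.  Real supertrees carry rounding noise.
ULTRAMETRIC_TOL = 1e-6

#: Branch lengths at or below this value (Myr) are treated as zero.
ZERO_BRANCH_TOL = 1e-9


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed."""


class TreeStructureError(ValueError):
    """Raised when a tree violates a structural precondition."""


class TimeTree:
    """A rooted time-calibrated tree with stable integer node ids.

    Node ids are assigned by deterministic post-order traversal at
    construction, so the same Newick string always yields the same ids and
    seeded sampling is reproducible across runs.
    """

    def __init__(self, dtree: dendropy.Tree):
        self._dtree = dtree
        self._nodes: list[dendropy.Node] = []
        for i, nd in enumerate(dtree.postorder_node_iter()):
            nd.cr_id = i
            self._nodes.append(nd)
        self._depths: dict[int, float] | None = None

    # -- basic accessors ---------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def root_id(self) -> int:
        return self._dtree.seed_node.cr_id

    @property
    def tip_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self._dtree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self._dtree.leaf_node_iter())

    def node(self, node_id: int) -> dendropy.Node:
        try:
            return self._nodes[node_id]
        except IndexError:
            raise TreeStructureError(f"unknown node id {node_id}") from None

    def is_tip(self, node_id: int) -> bool:
        return self.node(node_id).is_leaf()

    def internal_node_ids(self, exclude_root: bool = False) -> list[int]:
        ids = [nd.cr_id for nd in self._nodes if not nd.is_leaf()]
        if exclude_root:
            ids = [i for i in ids if i != self.root_id]
        return ids

    def parent_id(self, node_id: int) -> int | None:
        parent = self.node(node_id).parent_node
        return None if parent is None else parent.cr_id

    def is_ancestor(self, ancestor_id: int, descendant_id: int) -> bool:
        """True iff ``ancestor_id`` lies on the root path of ``descendant_id``
        (strict: a node is not its own ancestor)."""
        nd = self.node(descendant_id).parent_node
        while nd is not None:
            if nd.cr_id == ancestor_id:
                return True
            nd = nd.parent_node
        return False

    def mrca_id(self, tip_labels: list[str]) -> int:
        """Most recent common ancestor of the given tips, by post-order scan."""
        targets = set(tip_labels)
        if not targets:
            raise TreeStructureError("mrca_id requires at least one tip label")
        count: dict[int, int] = {}
        for nd in self._dtree.postorder_node_iter():
            if nd.is_leaf():
                count[nd.cr_id] = 1 if nd.taxon.label in targets else 0
            else:
                count[nd.cr_id] = sum(count[ch.cr_id] for ch in nd.child_nodes())
            if count[nd.cr_id] == len(targets):
                return nd.cr_id
        raise TreeStructureError(f"tips not found in tree: {sorted(targets)!r}")

    # -- ages --------------------------------------------------------------

    def node_depths(self) -> dict[int, float]:
        """Depth of each node = max path length to a descendant tip.

        On an ultrametric tree this is the node's age in Myr.
        """
        if self._depths is None:
            depths: dict[int, float] = {}
            for nd in self._dtree.postorder_node_iter():
                if nd.is_leaf():
                    depths[nd.cr_id] = 0.0
                else:
                    depths[nd.cr_id] = max(
                        depths[ch.cr_id] + (ch.edge.length or 0.0)
                        for ch in nd.child_nodes()
                    )
            self._depths = depths
        return self._depths

    def root_to_tip_distances(self) -> dict[str, float]:
        dist: dict[dendropy.Node, float] = {self._dtree.seed_node: 0.0}
        out: dict[str, float] = {}
        for nd in self._dtree.preorder_node_iter():
            if nd.parent_node is not None:
                dist[nd] = dist[nd.parent_node] + (nd.edge.length or 0.0)
            if nd.is_leaf():
                out[nd.taxon.label] = dist[nd]
        return out

    def check_ultrametric(self, tol: float = ULTRAMETRIC_TOL) -> None:
        """Raise :class:`TreeStructureError` naming the worst-offending tip
        pair if root-to-tip path lengths disagree beyond ``tol``."""
        d = self.root_to_tip_distances()
        lo = min(d, key=d.get)
        hi = max(d, key=d.get)
        if d[hi] - d[lo] > tol:
            raise TreeStructureError(
                f"tree is not ultrametric within {tol:g} Myr: tip {hi!r} has "
                f"depth {d[hi]:.9g} but tip {lo!r} has depth {d[lo]:.9g}"
            )

    def is_ultrametric(self, tol: float = ULTRAMETRIC_TOL) -> bool:
        d = list(self.root_to_tip_distances().values())
        return (max(d) - min(d)) <= tol


@dataclass
class NodeAges:
    """Crown and stem ages (Myr) for every node of an ultrametric tree.

    crown_age: node depth = age of the oldest split among the clade's
        extant members (0 for tips).
    stem_age: the crown age of the node's parent, i.e. when the clade
        split from its sister lineage.  Undefined for the root.
    """

    crown: dict[int, float] = field(default_factory=dict)
    stem: dict[int, float] = field(default_factory=dict)

    def crown_age(self, node_id: int) -> float:
        return self.crown[node_id]

    def stem_age(self, node_id: int) -> float:
        return self.stem[node_id]


@dataclass(frozen=True)
class ArtifactFlags:
    in_polytomy: bool
    has_zero_branch: bool


def parse_newick(text: str) -> TimeTree:
    """Parse a Newick string into a :class:`TimeTree`.

    All non-root edges must carry branch lengths; a missing length raises an
    error naming the offending node.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    root = dtree.seed_node
    for nd in dtree.postorder_node_iter():
        if nd is root:
            continue
        if nd.edge.length is None:
            name = nd.taxon.label if nd.is_leaf() else _describe_internal(nd)
            raise NewickParseError(f"missing branch length on node {name}")
        if nd.edge.length < 0:
            name = nd.taxon.label if nd.is_leaf() else _describe_internal(nd)
            raise NewickParseError(f"negative branch length on node {name}")
    labels = [lf.taxon.label for lf in dtree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise NewickParseError(f"duplicate tip labels: {dupes}")
    return TimeTree(dtree)


def _describe_internal(nd: dendropy.Node) -> str:
    tips = [lf.taxon.label for lf in nd.leaf_iter()]
    shown = ",".join(sorted(tips)[:3])
    return f"internal node above ({shown}{',...' if len(tips) > 3 else ''})"


def write_newick(tree: TimeTree, precision: int = 12) -> str:
    """Serialize to Newick with ``precision`` significant digits.

    12 significant digits by default: on trees hundreds of Myr deep, fewer
    digits let root-to-tip sums drift past the ultrametricity tolerance.
    """
    s = tree._dtree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=f".{precision}g",
        unquoted_underscores=True,
    )
    return s.strip()


def node_ages(tree: TimeTree, tol: float = ULTRAMETRIC_TOL) -> NodeAges:
    """Crown and stem ages for all nodes of an ultrametric tree."""
    tree.check_ultrametric(tol)
    depths = tree.node_depths()
    ages = NodeAges()
    for node_id, depth in depths.items():
        ages.crown[node_id] = depth
        parent = tree.parent_id(node_id)
        if parent is not None:
            ages.stem[node_id] = depths[parent]
    return ages


def clade_tips(tree: TimeTree, node_id: int) -> set[str]:
    """Tip labels descending from ``node_id`` (the clade's sampled species).

    For a tip node this is the singleton set of its own label; the set size
    is the clade's species richness in the tree.
    """
    nd = tree.node(node_id)
    if nd.is_leaf():
        return {nd.taxon.label}
    return {lf.taxon.label for lf in nd.leaf_iter()}


def detect_artifacts(
    tree: TimeTree,
    polytomy_scope: str = "subtree",
    zero_tol: float = ZERO_BRANCH_TOL,
) -> dict[int, ArtifactFlags]:
    """Per-node structural artifact flags.

    ``in_polytomy``: with ``polytomy_scope="subtree"`` (default) true iff
    the node or any internal node inside its subtree has more than two
    children; with ``"crown"`` only the node itself is examined.
    ``has_zero_branch``: true iff any branch inside the clade subtree has
    length <= ``zero_tol``.
    """
    if polytomy_scope not in ("subtree", "crown"):
        raise ValueError("polytomy_scope must be 'subtree' or 'crown'")
    poly_below: dict[int, bool] = {}
    zero_below: dict[int, bool] = {}
    flags: dict[int, ArtifactFlags] = {}
    for nd in tree._dtree.postorder_node_iter():
        children = nd.child_nodes()
        is_multi = len(children) > 2
        sub_poly = is_multi or any(poly_below[ch.cr_id] for ch in children)
        sub_zero = any(
            (ch.edge.length or 0.0) <= zero_tol or zero_below[ch.cr_id]
            for ch in children
        )
        poly_below[nd.cr_id] = sub_poly
        zero_below[nd.cr_id] = sub_zero
        flags[nd.cr_id] = ArtifactFlags(
            in_polytomy=sub_poly if polytomy_scope == "subtree" else is_multi,
            has_zero_branch=sub_zero,
        )
    return flags


def reduced_tree(
    tree: TimeTree, clade_node_ids: list[int]
) -> tuple[TimeTree, list[str]]:
    """Tree with exactly one representative tip per clade.

    The representative is the lexicographically smallest tip label of each
    clade (on an ultrametric tree the choice does not affect pairwise path
    lengths).  Returns the reduced tree and the representative labels
    aligned with ``clade_node_ids``.  Clades must be mutually non-nested.
    """
    if len(clade_node_ids) < 2:
        raise TreeStructureError("need at least two clades to build a reduced tree")
    for i, a in enumerate(clade_node_ids):
        for b in clade_node_ids[i + 1:]:
            if tree.is_ancestor(a, b) or tree.is_ancestor(b, a) or a == b:
                raise TreeStructureError(
                    f"clades {a} and {b} are nested; resolve nesting first"
                )
    reps = [min(clade_tips(tree, nid)) for nid in clade_node_ids]
    sub = tree._dtree.extract_tree_with_taxa_labels(
        reps, suppress_unifurcations=True
    )
    return TimeTree(sub), reps


def drop_tips(tree: TimeTree, keep_fraction: float, seed: int) -> TimeTree:
    """Retain ``floor(N * keep_fraction)`` tips chosen uniformly at random.

    Emulates incomplete taxon sampling.  Degree-2 internal nodes left by
    pruning are suppressed with branch lengths summed.
    """
    if not (0 < keep_fraction <= 1):
        raise ValueError("keep_fraction must be in (0, 1]")
    labels = sorted(tree.tip_labels)
    n_keep = int(np.floor(len(labels) * keep_fraction))
    if n_keep < 2:
        raise TreeStructureError(
            f"keep_fraction={keep_fraction} would retain {n_keep} tips (<2)"
        )
    if n_keep == len(labels):
        return TimeTree(tree._dtree.clone(depth=1))
    rng = np.random.default_rng(seed)
    keep = [labels[i] for i in rng.choice(len(labels), size=n_keep, replace=False)]
    sub = tree._dtree.extract_tree_with_taxa_labels(
        keep, suppress_unifurcations=True
    )
    return TimeTree(sub)
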