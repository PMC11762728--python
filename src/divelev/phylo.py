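"""Time-calibrated phylogeny handling: reading, validation, pruning, stem ages.

A :class:`Chronogram` wraps a rooted, ultrametric (within tolerance)
``dendropy.Tree`` whose tips are genus names and whose branch lengths are in
millions of years (Myr).  Node *depths* are expressed in Ma before present:
tips sit at depth 0 (up to dating error) and the root at the crown age.

The stem age of a genus tip — the time since it split from its sister
lineage — is the depth of the tip's parent node, which is the quantity the
Magallón–Sanderson rate estimator consumes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import dendropy

__all__ = [
    "Chronogram",
    "TaxonMatchReport",
    "ChronogramError",
    "read_newick",
    "write_newick",
    "prune_to_taxa",
    "stem_age",
]

#: relative tolerance on tip-depth spread below which a tree counts as ultrametric
ULTRAMETRIC_RTOL = 1e-6


class ChronogramError(ValueError):
    """Raised when a tree violates the chronogram contract."""


def _normalize_name(name: str) -> str:
    return re.sub(r"\s+", " ", name.strip()).casefold()


@dataclass
class TaxonMatchReport:
    """Audit trail of a prune: which query names hit a tip and which did not."""

    matched: list[str]
    unmatched: list[str]
    substitutions: dict[str, str] = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        rows = [(g, "matched", self.substitutions.get(g, "")) for g in self.matched]
        rows += [(g, "unmatched", self.substitutions.get(g, "")) for g in self.unmatched]
        return pd.DataFrame(rows, columns=["genus", "status", "substituted_to"])


class Chronogram:
    """Rooted tree with branch lengths in Myr and depths in Ma before present.

    Parameters
    ----------
    tree
        A rooted ``dendropy.Tree`` with strictly positive branch lengths and
        unique tip labels.
    ultrametric_rtol
        Tip depths may differ by at most this fraction of the root depth
        before the tree is flagged non-ultrametric.  The flag is advisory:
        dated trees from ML pipelines carry rounding error, so a failing
        tree remains usable.
    """

    def __init__(self, tree: dendropy.Tree, ultrametric_rtol: float = ULTRAMETRIC_RTOL):
        self._tree = tree
        self._validate()
        self._compute_depths()
        heights = [self._root_dist[lf] for lf in tree.leaf_node_iter()]
        self.root_depth = max(heights)
        spread = max(heights) - min(heights)
        self.is_ultrametric = spread <= ultrametric_rtol * max(self.root_depth, 1e-300)
        self._tip_index = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
        self._norm_index = {_normalize_name(k): k for k in self._tip_index}

    # -- construction helpers -------------------------------------------------

    def _validate(self) -> None:
        labels = []
        for leaf in self._tree.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise ChronogramError("tree has an unlabeled tip")
            labels.append(leaf.taxon.label)
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ChronogramError(f"duplicate tip labels: {dupes}")
        if len(labels) < 2:
            raise ChronogramError("chronogram needs at least 2 tips")
        root = self._tree.seed_node
        for node in self._tree.preorder_node_iter():
            if node is root:
                continue
            bl = node.edge.length
            if bl is None or bl <= 0:
                raise ChronogramError(
                    f"non-positive or missing branch length above node "
                    f"{node.taxon.label if node.taxon else '<internal>'!s}"
                )

    def _compute_depths(self) -> None:
        # depth = max path time from the node down to any descendant tip
        self._depth: dict[dendropy.Node, float] = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                self._depth[node] = 0.0
            else:
                self._depth[node] = max(
                    self._depth[ch] + ch.edge.length for ch in node.child_nodes()
                )
        self._root_dist: dict[dendropy.Node, float] = {}
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None:
                self._root_dist[node] = 0.0
            else:
                self._root_dist[node] = self._root_dist[node.parent_node] + node.edge.length

    # -- queries ---------------------------------------------------------------

    @property
    def tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_labels(self) -> list[str]:
        return sorted(self._tip_index)

    @property
    def n_tips(self) -> int:
        return len(self._tip_index)

    def depth(self, node: dendropy.Node) -> float:
        return self._depth[node]

    def has_tip(self, name: str) -> bool:
        return _normalize_name(name) in self._norm_index

    def resolve_tip(self, name: str) -> str:
        """Map a query name to the tip label it matches (exact after
        whitespace/case normalization)."""
        key = _normalize_name(name)
        if key not in self._norm_index:
            raise KeyError(f"no tip matching {name!r}")
        return self._norm_index[key]

    def stem_age(self, tip: str) -> float:
        """Depth (Ma) of the tip's parent node: the split from its sister lineage."""
        leaf = self._tip_index[self.resolve_tip(tip)]
        parent = leaf.parent_node
        if parent is None:
            raise ChronogramError(f"tip {tip!r} is the root")
        return self._depth[parent]

    def stem_ages(self) -> dict[str, float]:
        return {label: self.stem_age(label) for label in self.tip_labels}

    def write_newick(self, path=None) -> str:
        s = self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            real_value_format_specifier=".17g",
        ).strip() + "\n"
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def read_newick(path, ultrametric_rtol: float = ULTRAMETRIC_RTOL) -> Chronogram:
    """Read one rooted Newick tree with branch lengths.

    Raises a parse error (with position information from the parser) on
    malformed input and :class:`ChronogramError` on zero/negative branch
    lengths.  A tree whose tip depths disagree beyond ``ultrametric_rtol`` is
    returned with ``is_ultrametric=False`` rather than rejected.
    """
    tree = dendropy.Tree.get(
        path=str(path),
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    return Chronogram(tree, ultrametric_rtol=ultrametric_rtol)


def read_newick_string(s: str, ultrametric_rtol: float = ULTRAMETRIC_RTOL) -> Chronogram:
    tree = dendropy.Tree.get(
        data=s,
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    return Chronogram(tree, ultrametric_rtol=ultrametric_rtol)


def write_newick(tree: Chronogram, path) -> None:
    tree.write_newick(path)


def stem_age(tree: Chronogram, tip: str) -> float:
    return tree.stem_age(tip)


def prune_to_taxa(
    tree: Chronogram,
    names: Iterable[str],
    synonyms: Mapping[str, str] | None = None,
) -> tuple[Chronogram, TaxonMatchReport]:
    """Prune the chronogram to the tips matching ``names``.

    ``synonyms`` maps query names onto tree tip names (e.g. records of
    *Lophocolea* assigned to a *Chiloscyphus* tip) and is applied before
    exact matching; a synonym whose target is absent from the tree leaves the
    query unmatched.  Degree-2 nodes created by pruning are suppressed with
    their branch lengths summed, so retained divergence times are unchanged.
    """
    names = list(names)
    if not names:
        raise ValueError("names must be non-empty")
    synonyms = dict(synonyms or {})
    norm_syn = {_normalize_name(k): v for k, v in synonyms.items()}

    matched: list[str] = []
    unmatched: list[str] = []
    subs: dict[str, str] = {}
    keep_labels: set[str] = set()
    for name in names:
        query = name
        key = _normalize_name(name)
        if key in norm_syn:
            query = norm_syn[key]
            subs[name] = query
        if tree.has_tip(query):
            matched.append(name)
            keep_labels.add(tree.resolve_tip(query))
        else:
            unmatched.append(name)
    if not keep_labels:
        raise ChronogramError("no query name matched any tree tip")

    pruned = tree.tree.extract_tree()  # deep copy, preserves lengths
    pruned.retain_taxa_with_labels(sorted(keep_labels))
    pruned.purge_taxon_namespace()
    report = TaxonMatchReport(matched=matched, unmatched=unmatched, substitutions=subs)
    return Chronogram(pruned), report


def read_synonym_csv(path) -> dict[str, str]:
    """Two-column CSV ``from_name,to_name`` → synonym map."""
    import pandas as pd

    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("synonym CSV needs columns from_name,to_name")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
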