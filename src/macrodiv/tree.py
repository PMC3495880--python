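"""Ultrametric time-tree container, Newick I/O, and tree surgery.

The central object is :class:`TimeTree`, a rooted, strictly bifurcating,
ultrametric chronogram with branch durations in units of time (My by
convention).  Everything downstream (the gamma statistic, birth-death
likelihoods, rate-shift search, BiSSE, ancestral states) consumes either a
``TimeTree`` or the branching-time / internode-interval vectors derived from
it here.

Parsing and serialisation are delegated to :mod:`dendropy`; this module adds
the validation layer (bifurcating, ultrametric within tolerance, unique tip
labels) and the derived quantities.
"""

from __future__ import annotations

import io
from typing import Iterable, Mapping

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "TimeTree",
    "TreeError",
    "read_newick",
    "branching_times",
    "internode_intervals",
    "ages_from_intervals",
    "prune_to_tips",
    "collapse_to_backbone",
    "read_tip_annotations",
    "read_clade_richness",
]

#: default relative ultrametricity tolerance (fraction of tree depth)
DEFAULT_ULTRAMETRIC_RTOL = 1e-6


class TreeError(ValueError):
    """Invalid tree input (polytomy, non-ultrametric, bad labels...)."""


class TimeTree:
    """Rooted binary ultrametric chronogram.

    Parameters
    ----------
    tree
        A ``dendropy.Tree``.  Ownership is taken; callers should not mutate
        the instance afterwards.
    ultrametric_rtol
        Relative tolerance (fraction of tree depth) for the ultrametricity
        check.  Trees within tolerance are re-normalised by extending tip
        branches to the mean root-to-tip depth; trees outside it are
        rejected.
    validate
        Internal switch used by simulators whose output is ultrametric by
        construction.

    Attributes
    ----------
    richness : dict[str, int] | None
        Optional per-tip species richness (set by
        :meth:`collapse_to_backbone`).
    """

    def __init__(self, tree: dendropy.Tree, *,
                 ultrametric_rtol: float = DEFAULT_ULTRAMETRIC_RTOL,
                 validate: bool = True,
                 richness: dict[str, int] | None = None):
        self._tree = tree
        self._tree.is_rooted = True
        self.richness = richness
        if validate:
            self._validate(ultrametric_rtol)
        self._index()

    # ------------------------------------------------------------------ io

    @classmethod
    def from_newick(cls, source: str, **kwargs) -> "TimeTree":
        """Parse a Newick string (or path ending in a common tree suffix)."""
        text = source
        if not source.lstrip().startswith("(") :
            with open(source) as fh:
                text = fh.read()
        try:
            dtree = dendropy.Tree.get(data=text, schema="newick",
                                      suppress_internal_node_taxa=True,
                                      preserve_underscores=True)
        except Exception as exc:  # dendropy raises several error types
            raise TreeError(f"Newick parse error: {exc}") from exc
        return cls(dtree, **kwargs)

    def to_newick(self, precision: int = 12) -> str:
        s = self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            real_value_format_specifier=f".{precision}g",
        )
        return s.strip() + ("\n" if not s.endswith("\n") else "")

    # ----------------------------------------------------------- validation

    def _validate(self, rtol: float) -> None:
        tree = self._tree
        leaves = list(tree.leaf_node_iter())
        if len(leaves) < 2:
            raise TreeError("tree must have at least 2 tips")
        labels = [lf.taxon.label if lf.taxon else None for lf in leaves]
        if any(l is None or l == "" for l in labels):
            raise TreeError("every tip must carry a non-empty label")
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeError(f"duplicate tip labels: {dup}")
        for nd in tree.preorder_node_iter():
            nch = len(nd.child_nodes())
            if nch not in (0, 2):
                raise TreeError(
                    f"polytomy or unifurcation (node with {nch} children); "
                    "only strictly bifurcating trees are supported")
            if nd is not tree.seed_node and nd.edge.length is None:
                raise TreeError("missing branch length on a non-root edge")
            if nd is not tree.seed_node and nd.edge.length < 0:
                raise TreeError("negative branch length")
        # ultrametricity: all root-to-tip depths equal within rtol * depth
        depths = {}
        for nd in tree.preorder_node_iter():
            if nd is tree.seed_node:
                depths[nd] = 0.0
            else:
                depths[nd] = depths[nd.parent_node] + nd.edge.length
        tip_depths = np.array([depths[lf] for lf in leaves])
        depth = tip_depths.mean()
        if depth <= 0:
            raise TreeError("tree has zero depth")
        if np.max(np.abs(tip_depths - depth)) > rtol * depth:
            raise TreeError(
                "tree is not ultrametric: root-to-tip depths range "
                f"[{tip_depths.min():.6g}, {tip_depths.max():.6g}]")
        # normalise: extend tip branches so that every depth equals the mean
        for lf, d in zip(leaves, tip_depths):
            lf.edge.length += depth - d

    def _index(self) -> None:
        tree = self._tree
        self._depth_of = {}
        for nd in tree.preorder_node_iter():
            p = nd.parent_node
            self._depth_of[nd] = 0.0 if p is None else (
                self._depth_of[p] + nd.edge.length)
        leaves = list(tree.leaf_node_iter())
        self._crown_age = float(np.mean([self._depth_of[lf] for lf in leaves]))
        self._tips = {lf.taxon.label: lf for lf in leaves}

    # ------------------------------------------------------------ accessors

    @property
    def n_tips(self) -> int:
        return len(self._tips)

    @property
    def tip_labels(self) -> list[str]:
        return sorted(self._tips)

    @property
    def crown_age(self) -> float:
        """Tree depth = age of the root split, time before present."""
        return self._crown_age

    def node_age(self, node) -> float:
        """Age (time before present) of a dendropy node of this tree."""
        return max(self._crown_age - self._depth_of[node], 0.0)

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    def copy(self) -> "TimeTree":
        return TimeTree(self._tree.clone(depth=1), validate=False,
                        richness=dict(self.richness) if self.richness else None)

    def scale(self, factor: float) -> "TimeTree":
        """Return a copy with every branch duration multiplied by ``factor``."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        t = self._tree.clone(depth=1)
        for e in t.preorder_edge_iter():
            if e.length is not None:
                e.length *= factor
        return TimeTree(t, validate=False,
                        richness=dict(self.richness) if self.richness else None)

    # ------------------------------------------------------- derived vectors

    def branching_times(self) -> np.ndarray:
        """Internal-node ages x_2 > x_3 > ... > x_n (time before present).

        The oldest entry equals the crown age; length is ``n_tips - 1``.
        Requires at least 3 tips.
        """
        if self.n_tips < 3:
            raise TreeError("branching times require n >= 3 tips")
        ages = [self.node_age(nd) for nd in self._tree.preorder_node_iter()
                if nd.child_nodes()]
        return np.sort(np.asarray(ages))[::-1]

    def internode_intervals(self) -> np.ndarray:
        return internode_intervals(self.branching_times())

    # --------------------------------------------------------- tree surgery

    def mrca(self, labels: Iterable[str]):
        labels = list(labels)
        unknown = [l for l in labels if l not in self._tips]
        if unknown:
            raise TreeError(f"unknown tip labels: {unknown}")
        taxa = [self._tips[l].taxon for l in labels]
        if len(taxa) == 1:
            return self._tips[labels[0]]
        return self._tree.mrca(taxa=taxa)

    def prune_to_tips(self, keep: Iterable[str]) -> "TimeTree":
        """Induced subtree on ``keep``, re-rooted at their MRCA.

        Degree-2 nodes are suppressed with branch durations summed, so the
        result is ultrametric and every retained internal node keeps the age
        it had in the full tree.
        """
        keep = set(keep)
        unknown = sorted(keep - set(self._tips))
        if unknown:
            raise TreeError(f"unknown tip labels: {unknown}")
        if len(keep) < 2:
            raise TreeError("need at least 2 tips to prune to")
        if len(keep) == self.n_tips:
            return self.copy()
        sub = self._tree.extract_tree_with_taxa_labels(
            labels=keep, suppress_unifurcations=True)
        # drop any stem path above the MRCA of the retained tips
        while len(sub.seed_node.child_nodes()) == 1:
            child = sub.seed_node.child_nodes()[0]
            child.parent_node = None
            sub.seed_node = child
        sub.seed_node.edge.length = None
        return TimeTree(sub, validate=False)

    def collapse_to_backbone(self, clades: Mapping[str, Iterable[str]],
                             richness: Mapping[str, int]) -> "TimeTree":
        """Collapse monophyletic clades to single richness-bearing terminals.

        Each clade becomes one terminal whose branch spans from the clade's
        stem age to the present; the clade's extant species richness is
        attached to the terminal.  Clades must be disjoint, jointly cover all
        tips, and each be monophyletic.
        """
        clades = {k: set(v) for k, v in clades.items()}
        allt = set()
        for lab, tips in clades.items():
            if allt & tips:
                raise TreeError(f"clades are not disjoint (at {lab!r})")
            allt |= tips
        if allt != set(self._tips):
            raise TreeError("clades must jointly cover all tips")
        reps = {}
        for lab, tips in clades.items():
            node = self.mrca(tips)
            under = ({node.taxon.label} if not node.child_nodes() else
                     {lf.taxon.label for lf in node.leaf_iter()})
            if under != tips:
                raise TreeError(f"clade {lab!r} is not monophyletic "
                                f"(MRCA spans {len(under)} tips)")
            if lab not in richness:
                raise TreeError(f"missing richness entry for clade {lab!r}")
            if int(richness[lab]) < len(tips):
                raise TreeError(
                    f"richness for clade {lab!r} ({richness[lab]}) is below "
                    f"its sampled tip count ({len(tips)})")
            reps[lab] = sorted(tips)[0]
        if len(reps) < 2:
            raise TreeError("need at least 2 clades for a backbone")
        backbone = self.prune_to_tips(reps.values())
        rep_to_clade = {v: k for k, v in reps.items()}
        for lf in backbone._tree.leaf_node_iter():
            lf.taxon.label = rep_to_clade[lf.taxon.label]
        backbone._index()
        backbone.richness = {lab: int(richness[lab]) for lab in clades}
        return backbone


# --------------------------------------------------------------- functions

def read_newick(source: str, **kwargs) -> TimeTree:
    """Read a single ultrametric binary tree from a Newick string or file."""
    return TimeTree.from_newick(source, **kwargs)


def read_newick_list(path: str, **kwargs) -> list[TimeTree]:
    """Read one tree per line (e.g. a posterior sample) from a Newick file."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(TimeTree.from_newick(line, **kwargs))
    return out


def branching_times(tree: TimeTree) -> np.ndarray:
    return tree.branching_times()


def internode_intervals(bt: np.ndarray) -> np.ndarray:
    """Internode intervals g_2..g_n from branching times x_2 > ... > x_n.

    g_k is the duration during which the reconstructed tree has exactly k
    lineages; the final interval g_n runs from the youngest node to the
    present, so that ``sum(g) == crown age``.
    """
    x = np.asarray(bt, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise TreeError("need at least 2 branching times (n >= 3)")
    if np.any(np.diff(x) > 0) or np.any(x <= 0):
        raise TreeError("branching times must be positive and descending")
    return np.concatenate([-np.diff(x), x[-1:]])


def ages_from_intervals(g: np.ndarray) -> np.ndarray:
    """Inverse of :func:`internode_intervals`."""
    g = np.asarray(g, dtype=float)
    return np.cumsum(g[::-1])[::-1]


def prune_to_tips(tree: TimeTree, keep: Iterable[str]) -> TimeTree:
    return tree.prune_to_tips(keep)


def collapse_to_backbone(tree: TimeTree, clades: Mapping[str, Iterable[str]],
                         richness: Mapping[str, int]) -> TimeTree:
    return tree.collapse_to_backbone(clades, richness)


# ------------------------------------------------------------ table readers

def read_tip_annotations(source, n_states: int | None = None) -> dict[str, int]:
    """Read a species -> discrete-state CSV (columns ``species,state``).

    States must be non-negative integers; if ``n_states`` is given they must
    lie in ``[0, n_states)`` (at most 7 states are meaningful downstream).
    """
    df = pd.read_csv(source) if not isinstance(source, pd.DataFrame) else source
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    if "species" not in cols or "state" not in cols:
        raise ValueError("annotation table needs columns 'species' and 'state'")
    states = df["state"].astype(int)
    if (states < 0).any():
        raise ValueError("state codes must be non-negative")
    if n_states is not None and (states >= n_states).any():
        bad = df.loc[states >= n_states, "species"].tolist()
        raise ValueError(f"state code outside declared alphabet for {bad}")
    return dict(zip(df["species"].astype(str), states))


def read_clade_richness(source) -> dict[str, int]:
    """Read a clade -> extant-species-count CSV (columns ``clade,richness``)."""
    df = pd.read_csv(source) if not isinstance(source, pd.DataFrame) else source
    df.columns = [c.strip().lower() for c in df.columns]
    if "clade" not in df.columns or "richness" not in df.columns:
        raise ValueError("richness table needs columns 'clade' and 'richness'")
    rich = df["richness"].astype(int)
    if (rich < 1).any():
        raise ValueError("richness counts must be >= 1")
    return dict(zip(df["clade"].astype(str), rich))


def validate_annotations(tree: TimeTree, annot: Mapping[str, int]) -> None:
    """Check that every tip of ``tree`` has a state in ``annot``."""
    missing = [l for l in tree.tip_labels if l not in annot]
    if missing:
        raise ValueError(f"tips without state annotation: {missing[:10]}")
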