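"""Chronogram I/O, validation, and lineage-accumulation utilities.

A chronogram is a rooted, ultrametric, strictly bifurcating tree whose branch
lengths are in Myr, so every node carries an *age* measured before the present
(tips at age 0, root at the crown age).  Everything downstream of this module
consumes either a :class:`Chronogram` or its sufficient statistic for
birth-death likelihoods, the vector of :class:`BranchingTimes`.

Trees are carried by dendropy; this module adds the age bookkeeping, the
ultrametricity contract, truncation of the analysis at a time horizon (with
re-basing of ages onto the pseudo-present), and lineage-through-time curves.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = [
    "Chronogram",
    "BranchingTimes",
    "LTTCurve",
    "TreeParseError",
    "UltrametricityError",
    "UltrametricityReport",
    "read_trees",
    "write_trees",
    "check_ultrametric",
    "branching_times",
    "truncate_at",
    "ltt_curve",
    "median_ltt",
    "write_ltt_tsv",
]

#: default relative tolerance on tip-depth deviation from tree height
DEFAULT_TOL_ULTRA = 1e-6


class TreeParseError(ValueError):
    """A tree file could not be parsed; carries the index of the offending tree."""

    def __init__(self, message: str, tree_index: int | None = None):
        self.tree_index = tree_index
        if tree_index is not None:
            message = f"tree #{tree_index}: {message}"
        super().__init__(message)


class UltrametricityError(ValueError):
    """Tip depths deviate from the tree height beyond tolerance."""


@dataclass(frozen=True)
class UltrametricityReport:
    passed: bool
    height: float
    max_deviation: float
    tol: float
    violating_tips: tuple[str, ...] = ()


class Chronogram:
    """Rooted ultrametric tree with node ages in Myr before present.

    Parameters
    ----------
    tree:
        A rooted dendropy tree with branch lengths in Myr.  Branch lengths are
        mandatory on all non-root edges.
    resolve_polytomies:
        Polytomies are rejected by default (the birth-death likelihood assumes
        binary trees).  When True, they are resolved arbitrarily with
        zero-length internal edges, aged ``epsilon`` below the parent.
    extend_tips:
        When True, terminal branches of a nearly-ultrametric tree are extended
        to the maximum tip depth instead of rejecting the tree.
    """

    def __init__(
        self,
        tree: dendropy.Tree,
        *,
        tol_ultra: float = DEFAULT_TOL_ULTRA,
        resolve_polytomies: bool = False,
        extend_tips: bool = False,
    ):
        tree = tree.clone(depth=1)
        tree.suppress_unifurcations()
        n_tips = sum(1 for _ in tree.leaf_node_iter())
        if n_tips < 2:
            raise ValueError(f"a chronogram needs >= 2 tips, got {n_tips}")
        for node in tree.preorder_node_iter():
            if node.parent_node is not None and node.edge.length is None:
                raise TreeParseError("missing branch length", None)
            n_children = len(node.child_nodes())
            if n_children > 2:
                if not resolve_polytomies:
                    raise ValueError(
                        "polytomy encountered; pass resolve_polytomies=True "
                        "to resolve arbitrarily with zero-length edges"
                    )
        if resolve_polytomies:
            tree.resolve_polytomies(limit=2, update_bipartitions=False)
            for node in tree.preorder_node_iter():
                if node.parent_node is not None and node.edge.length is None:
                    node.edge.length = 0.0
        self._tree = tree
        self.tol_ultra = tol_ultra
        self._assign_ages(extend_tips=extend_tips)

    def _assign_ages(self, *, extend_tips: bool) -> None:
        tree = self._tree
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                node.depth = 0.0
            else:
                node.depth = node.parent_node.depth + node.edge.length
        height = max(leaf.depth for leaf in tree.leaf_node_iter())
        if extend_tips:
            for leaf in tree.leaf_node_iter():
                leaf.edge.length += height - leaf.depth
                leaf.depth = height
        for node in tree.preorder_node_iter():
            node.age = height - node.depth
        for leaf in tree.leaf_node_iter():
            leaf.age = max(leaf.age, 0.0)
        self._height = height

    # -- basic accessors ---------------------------------------------------

    @property
    def tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    @property
    def crown_age(self) -> float:
        return self._height

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    def internal_ages(self) -> np.ndarray:
        """Ages of internal nodes (including the root), unsorted."""
        return np.array(
            [nd.age for nd in self._tree.preorder_internal_node_iter()], dtype=float
        )

    def newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    def __repr__(self) -> str:  # pragma: no cover
        return f"Chronogram(n_tips={self.n_tips}, crown_age={self.crown_age:.4g})"


@dataclass(frozen=True)
class BranchingTimes:
    """Descending internal-node ages of a (possibly truncated) chronogram.

    ``ages[0]`` is the crown age of the analyzed tree; the number of lineages
    represented at the (re-based) present is ``n = len(ages) + 1``.  ``t_cut``
    records the re-base offset in Myr (0 for untruncated trees).
    """

    ages: np.ndarray
    t_cut: float = 0.0

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=float)
        if ages.ndim != 1 or ages.size == 0:
            raise ValueError("need at least one branching time")
        ages = np.sort(ages, kind="stable")[::-1]
        if ages[-1] <= 0:
            raise ValueError("branching times must be strictly positive")
        object.__setattr__(self, "ages", ages)

    @property
    def n(self) -> int:
        return self.ages.size + 1

    @property
    def crown_age(self) -> float:
        return float(self.ages[0])


def read_trees(
    path: str | Path,
    format: str = "newick",
    *,
    tol_ultra: float = DEFAULT_TOL_ULTRA,
    resolve_polytomies: bool = False,
    extend_tips: bool = False,
) -> list[Chronogram]:
    """Read all trees in a newick or NEXUS file, in file order.

    NEXUS translate tables are resolved to full tip labels; branch lengths are
    interpreted as Myr.  A parse failure raises :class:`TreeParseError` naming
    the offending tree index; no partial tree is returned.
    """
    if format not in ("newick", "nexus"):
        raise ValueError(f"unknown tree format {format!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        tree_list = dendropy.TreeList.get(
            path=str(path),
            schema=format,
            rooting="force-rooted",
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeParseError(str(exc), tree_index=0) from exc
    if len(tree_list) == 0:
        raise TreeParseError("file contains no trees", tree_index=0)
    chronos = []
    for i, tree in enumerate(tree_list):
        try:
            chronos.append(
                Chronogram(
                    tree,
                    tol_ultra=tol_ultra,
                    resolve_polytomies=resolve_polytomies,
                    extend_tips=extend_tips,
                )
            )
        except ValueError as exc:
            raise TreeParseError(str(exc), tree_index=i) from exc
    return chronos


def write_trees(chronograms: Iterable[Chronogram], path: str | Path) -> None:
    """Write chronograms as one newick string per line."""
    with open(path, "w") as fh:
        for c in chronograms:
            fh.write(c.newick() + "\n")


def check_ultrametric(
    chrono: Chronogram, tol: float | None = None
) -> UltrametricityReport:
    """Report whether every tip depth matches the tree height within ``tol``.

    ``tol`` is relative to the tree height; pass iff
    ``max |tip depth - height| <= tol * height``.
    """
    if tol is None:
        tol = chrono.tol_ultra
    height = chrono.crown_age
    violators = []
    max_dev = 0.0
    for leaf in chrono.tree.leaf_node_iter():
        dev = abs(leaf.depth - height)
        max_dev = max(max_dev, dev)
        if dev > tol * height:
            violators.append(leaf.taxon.label)
    return UltrametricityReport(
        passed=not violators,
        height=height,
        max_deviation=max_dev,
        tol=tol,
        violating_tips=tuple(violators),
    )


def branching_times(chrono: Chronogram, tol: float | None = None) -> BranchingTimes:
    """Extract descending internal-node ages; rejects non-ultrametric input."""
    report = check_ultrametric(chrono, tol)
    if not report.passed:
        raise UltrametricityError(
            f"tree is not ultrametric within tolerance {report.tol:g} "
            f"(max tip-depth deviation {report.max_deviation:g} on height "
            f"{report.height:g}); violating tips: {report.violating_tips[:5]}"
        )
    return BranchingTimes(ages=chrono.internal_ages(), t_cut=0.0)


def truncate_at(bt: BranchingTimes, t_cut: float) -> BranchingTimes:
    """Restrict the analysis to events older than ``t_cut`` and re-base ages.

    Keeps branching events with age > t_cut, subtracts t_cut from each, and
    accumulates the offset.  The lineage count at the new pseudo-present is the
    number of lineages crossing t_cut, i.e. 1 + number of retained events for
    a crown-rooted tree.
    """
    if t_cut < 0:
        raise ValueError("t_cut must be >= 0")
    if t_cut == 0:
        return bt
    if t_cut >= bt.crown_age:
        raise ValueError(
            f"t_cut={t_cut:g} >= crown age {bt.crown_age:g}: fewer than 2 "
            "lineages would remain"
        )
    kept = bt.ages[bt.ages > t_cut] - t_cut
    return BranchingTimes(ages=kept, t_cut=bt.t_cut + t_cut)


@dataclass(frozen=True)
class LTTCurve:
    """Right-closed step curve of reconstructed lineage count against age.

    The count is ``1 + #{branching times >= age}``: 1 above the crown age,
    2 at the crown age and just below it, ``n`` at age 0.  ``counts[k]`` is
    the value of the curve at ``knot_ages[k]``.
    """

    knot_ages: np.ndarray  # ascending, starting at 0
    counts: np.ndarray

    def __post_init__(self):
        ka = np.asarray(self.knot_ages, dtype=float)
        ct = np.asarray(self.counts, dtype=float)
        if ka.shape != ct.shape or ka.ndim != 1:
            raise ValueError("knot_ages and counts must be 1-D and equal length")
        object.__setattr__(self, "knot_ages", ka)
        object.__setattr__(self, "counts", ct)

    def count_at(self, ages) -> np.ndarray:
        """Evaluate the step curve at arbitrary ages (vectorized)."""
        ages = np.asarray(ages, dtype=float)
        # the curve is constant on each left-open, right-closed inter-knot
        # interval (knot_k, knot_{k+1}] where it takes counts[k+1]
        idx = np.searchsorted(self.knot_ages, ages, side="left")
        idx = np.clip(idx, 0, self.knot_ages.size - 1)
        return self.counts[idx]


def ltt_curve(data: Chronogram | BranchingTimes) -> LTTCurve:
    """Lineage-through-time step curve of one chronogram."""
    bt = data if isinstance(data, BranchingTimes) else branching_times(data)
    asc = bt.ages[::-1]  # ascending branching times
    n = bt.n
    # knots: age 0 (count n), each branching time (count just at/below it),
    # then one knot above the crown where the count is 1.
    knots = [0.0]
    counts = [float(n)]
    for a in asc:
        c = 1 + np.sum(bt.ages >= a)
        knots.append(float(a))
        counts.append(float(c))
    knots.append(float(bt.crown_age) * (1 + 1e-12) + 1e-12)
    counts.append(1.0)
    return LTTCurve(np.array(knots), np.array(counts))


def median_ltt(curves: Sequence[LTTCurve], ages: np.ndarray) -> LTTCurve:
    """Pointwise median of several LTT curves on a common age grid."""
    if len(curves) == 0:
        raise ValueError("need at least one LTT curve")
    ages = np.asarray(ages, dtype=float)
    mat = np.vstack([c.count_at(ages) for c in curves])
    return LTTCurve(knot_ages=ages, counts=np.median(mat, axis=0))


def write_ltt_tsv(curve: LTTCurve, path: str | Path) -> None:
    """Write a curve as TSV with columns age, count, log10_count."""
    with open(path, "w") as fh:
        fh.write("age\tcount\tlog10_count\n")
        for a, c in zip(curve.knot_ages, curve.counts):
            log10c = np.log10(c) if c > 0 else float("nan")
            fh.write(f"{a:.6f}\t{c:.6f}\t{log10c:.6f}\n")
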