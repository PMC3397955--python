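"""Clade partitions on ultrametric trees and comparative statistics.

Species are pooled into the largest clades whose most recent common ancestor
is younger than an age cutoff; Moran's I with row-normalized binary
within-clade weights then measures whether species in the same clade carry
more similar (log) coverage than expected under the null E(I) = -1/(n-1).
Wilcoxon rank-sum and Spearman rank statistics back the group and GC%
comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
from scipy import stats

ULTRAMETRIC_RTOL = 1e-6


class TreeValidationError(ValueError):
    """Raised when a tree is not ultrametric within tolerance."""


class UndefinedStatisticError(ValueError):
    """Raised when a statistic has no defined value (no weights, zero variance)."""


def load_tree(source, schema: str = "newick") -> dendropy.Tree:
    """Read a rooted tree with branch lengths (path or newick string)."""
    import os

    if isinstance(source, (str, os.PathLike)) and os.path.exists(source):
        tree = dendropy.Tree.get(path=str(source), schema=schema,
                                 preserve_underscores=True)
    else:
        tree = dendropy.Tree.get(data=str(source), schema=schema,
                                 preserve_underscores=True)
    return tree


def _leaf_label(leaf: dendropy.Node) -> str:
    if leaf.taxon is not None and leaf.taxon.label is not None:
        return leaf.taxon.label
    if leaf.label is not None:
        return leaf.label
    raise TreeValidationError("unlabeled leaf in tree")


def node_ages(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    """Age of every node (distance to its leaves) on a validated ultrametric tree."""
    depth: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        edge = node.edge.length or 0.0
        depth[node] = edge if node.parent_node is None else depth[node.parent_node] + edge
    leaf_depths = [depth[leaf] for leaf in tree.leaf_node_iter()]
    height = max(leaf_depths)
    if height <= 0:
        raise TreeValidationError("tree has zero height")
    if (height - min(leaf_depths)) > ULTRAMETRIC_RTOL * height:
        raise TreeValidationError(
            f"tree is not ultrametric: leaf depths span "
            f"[{min(leaf_depths):g}, {height:g}]"
        )
    return {node: max(height - d, 0.0) for node, d in depth.items()}


@dataclass(frozen=True)
class CladePartition:
    """Assignment of leaves to the largest clades younger than a cutoff age."""

    cutoff_mya: float
    clade_of: Mapping[str, int]
    n_clades: int

    def clades(self) -> list[list[str]]:
        out: list[list[str]] = [[] for _ in range(self.n_clades)]
        for species, idx in self.clade_of.items():
            out[idx].append(species)
        return out


def clades_at_cutoff(tree: dendropy.Tree, cutoff_mya: float) -> CladePartition:
    """Partition leaves into maximal clades whose MRCA age is strictly below cutoff.

    Every leaf (age 0) is reachable, so the clades partition the leaf set; a
    leaf whose parent is older than the cutoff forms a singleton clade.
    """
    if cutoff_mya <= 0:
        raise ValueError("cutoff must be positive")
    ages = node_ages(tree)
    clade_of: dict[str, int] = {}
    n_clades = 0
    stack = [tree.seed_node]
    while stack:
        node = stack.pop()
        if ages[node] < cutoff_mya:
            for leaf in node.leaf_iter():
                label = _leaf_label(leaf)
                if label in clade_of:
                    raise TreeValidationError(f"duplicate leaf label {label!r}")
                clade_of[label] = n_clades
            n_clades += 1
        else:
            # preserve left-to-right order despite LIFO traversal
            stack.extend(reversed(node.child_nodes()))
    return CladePartition(cutoff_mya=cutoff_mya, clade_of=clade_of, n_clades=n_clades)


@dataclass(frozen=True)
class CorrelogramPoint:
    """Moran's I at one clade-age cutoff, with its Gaussian null moments."""

    cutoff_mya: float
    I: float
    expected_I: float
    sd_I: float
    p_value: float
    n_species: int
    n_clades: int

    @property
    def is_defined(self) -> bool:
        return not math.isnan(self.I)


def partition_weights(part: CladePartition, order: Sequence[str]) -> np.ndarray:
    """Row-normalized binary within-clade weight matrix over ``order``."""
    n = len(order)
    clade = np.array([part.clade_of[s] for s in order])
    w = (clade[:, None] == clade[None, :]).astype(float)
    np.fill_diagonal(w, 0.0)
    row_sums = w.sum(axis=1)
    nonzero = row_sums > 0
    w[nonzero] /= row_sums[nonzero, None]
    return w


def morans_i_from_weights(x: np.ndarray, w: np.ndarray) -> tuple[float, float, float, float]:
    """Moran's I, E(I), sd(I) and two-sided p for values ``x`` and weights ``w``.

    The null standard deviation uses the randomization (kurtosis-corrected)
    moments; the p-value is Gaussian.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 3:
        raise UndefinedStatisticError("Moran's I needs at least 3 observations")
    w0 = float(w.sum())
    if w0 == 0:
        raise UndefinedStatisticError("all weights are zero (only singleton clades)")
    z = x - x.mean()
    m2 = float(z @ z)
    if m2 == 0:
        raise UndefinedStatisticError("zero variance in values")
    obs = (n / w0) * float(z @ w @ z) / m2
    expected = -1.0 / (n - 1)

    s1 = 0.5 * float(((w + w.T) ** 2).sum())
    s2 = float(((w.sum(axis=1) + w.sum(axis=0)) ** 2).sum())
    s0_sq = w0 * w0
    b2 = n * float((z**4).sum()) / (m2 * m2)
    var = (
        n * ((n * n - 3 * n + 3) * s1 - n * s2 + 3 * s0_sq)
        - b2 * ((n * n - n) * s1 - 2 * n * s2 + 6 * s0_sq)
    ) / ((n - 1) * (n - 2) * (n - 3) * s0_sq) - expected**2
    sd = math.sqrt(max(var, 0.0))
    if sd < 1e-12:
        # complete within-clade graph: I is permutation-invariant and equals E
        return obs, expected, 0.0, 1.0
    p = float(2.0 * stats.norm.sf(abs(obs - expected) / sd))
    return obs, expected, sd, min(p, 1.0)


def morans_i(values: Mapping[str, float], part: CladePartition) -> CorrelogramPoint:
    """Moran's I of ``values`` under the clade partition's within-clade weights.

    Callers apply any transform (e.g. natural log of coverage) beforehand.
    """
    missing = set(part.clade_of) - set(values)
    if missing:
        raise UndefinedStatisticError(f"values missing for species: {sorted(missing)}")
    order = sorted(part.clade_of)
    x = np.array([values[s] for s in order], dtype=float)
    w = partition_weights(part, order)
    obs, expected, sd, p = morans_i_from_weights(x, w)
    return CorrelogramPoint(
        cutoff_mya=part.cutoff_mya,
        I=obs,
        expected_I=expected,
        sd_I=sd,
        p_value=p,
        n_species=len(order),
        n_clades=part.n_clades,
    )


def default_cutoffs(root_age: float) -> list[float]:
    """50 Mya, then multiples of 100 Mya up to the first strictly above the root.

    "Younger than" is strict, so only a cutoff exceeding the root age pools
    the whole tree into a single clade; the sequence ends at that cutoff.
    """
    cutoffs = [50.0]
    c = 100.0
    while True:
        cutoffs.append(c)
        if c > root_age:
            return cutoffs
        c += 100.0


def correlogram(
    tree: dendropy.Tree,
    values: Mapping[str, float],
    cutoffs: Sequence[float] | None = None,
) -> list[CorrelogramPoint]:
    """Moran's I across clade-age cutoffs; undefined points carry NaN, not dropped."""
    if cutoffs is None:
        root_age = max(node_ages(tree).values())
        cutoffs = default_cutoffs(root_age)
    points: list[CorrelogramPoint] = []
    for cutoff in cutoffs:
        part = clades_at_cutoff(tree, cutoff)
        n = len(part.clade_of)
        try:
            points.append(morans_i(values, part))
        except UndefinedStatisticError:
            points.append(
                CorrelogramPoint(
                    cutoff_mya=cutoff,
                    I=math.nan,
                    expected_I=-1.0 / (n - 1) if n > 1 else math.nan,
                    sd_I=math.nan,
                    p_value=math.nan,
                    n_species=n,
                    n_clades=part.n_clades,
                )
            )
    return points


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sample Wilcoxon statistic W and two-sided p.

    W counts pairs where x exceeds y, with half-credit for ties (the
    Mann-Whitney U of the first sample), so 0 <= W <= len(x)*len(y).  The
    p-value is exact for small untied samples and a tie- and
    continuity-corrected normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if not has_ties and max(x.size, y.size) < 50 else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Mid-rank Spearman correlation and two-sided p (t approximation)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("samples must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise UndefinedStatisticError("zero rank variance")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)
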