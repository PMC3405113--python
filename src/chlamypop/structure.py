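"""Population structure: distances, neighbor joining, PCA, fixed differences.

The pairwise distance between two strains is the fraction of jointly
called SNPs at which they differ.  The neighbor-joining tree is built
by the Saitou-Nei agglomeration with deterministic (lowest index pair)
tie-breaking; PCA operates on per-site-centred 0/1 genotypes.  A SNP is
a fixed difference (F_ST = 1) when its alleles sort completely between
the two subpopulations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

from .datatypes import MISSING, FixedDifferenceSummary, GenotypeMatrix

__all__ = ["DistanceMatrix", "distance_matrix", "neighbor_joining",
           "pca", "fixed_difference_fraction", "flag_near_duplicates",
           "groups_are_clades"]


@dataclass
class DistanceMatrix:
    """Symmetric strain-by-strain Hamming fractions over co-called SNPs."""

    ids: list[str]
    values: np.ndarray
    pair_counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def distance_matrix(matrix: GenotypeMatrix) -> DistanceMatrix:
    """Fraction of jointly-called SNPs that differ, per strain pair.

    A pair sharing no called sites gets a NaN distance and a warning.
    """
    if matrix.n_strains < 2:
        raise ValueError("need at least two strains")
    calls = matrix.calls
    n = matrix.n_strains
    values = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            both = (calls[i] != MISSING) & (calls[j] != MISSING)
            m = int(both.sum())
            counts[i, j] = counts[j, i] = m
            if m == 0:
                warnings.warn(
                    f"strains {matrix.strain_ids[i]} and "
                    f"{matrix.strain_ids[j]} share no called SNPs")
                values[i, j] = values[j, i] = float("nan")
                continue
            d = float((calls[i, both] != calls[j, both]).mean())
            values[i, j] = values[j, i] = d
    return DistanceMatrix(ids=list(matrix.strain_ids), values=values,
                          pair_counts=counts)


def neighbor_joining(d: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    The Q-matrix minimiser is chosen as the lexicographically smallest
    (i, j) among ties; negative branch lengths are clamped to zero with
    a warning.  The returned tree is unrooted, represented with a
    trifurcating root.
    """
    D = np.array(d.values, dtype=float)
    if not np.isfinite(D).all():
        raise ValueError("distance matrix contains non-finite entries")
    nodes = [TreeNode(name=name) for name in d.ids]
    if len(nodes) < 3:
        raise ValueError("neighbor joining needs at least three strains")

    def clamp(x: float) -> float:
        if x < 0:
            warnings.warn("negative NJ branch length clamped to 0")
            return 0.0
        return float(x)

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        best = np.unravel_index(np.argmin(Q), Q.shape)  # row-major => lowest
        i, j = (int(best[0]), int(best[1]))
        if i > j:
            i, j = j, i
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length = clamp(li)
        nodes[j].length = clamp(lj)
        new_row = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D = np.vstack([D[np.ix_(keep, keep)],
                       new_row[keep][None, :]])
        D = np.hstack([D, np.append(new_row[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]

    # close the unrooted tree on the last three nodes
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    lengths = [0.5 * (d01 + d02 - d12),
               0.5 * (d01 + d12 - d02),
               0.5 * (d02 + d12 - d01)]
    for node, length in zip(nodes, lengths):
        node.length = clamp(length)
    return TreeNode(children=nodes)


def groups_are_clades(tree: TreeNode, groups: dict[str, str]) -> bool:
    """True when the two group labels form the two sides of one split."""
    labels = set(groups.values())
    if len(labels) != 2:
        raise ValueError("need exactly two group labels")
    tips = {t.name for t in tree.tips()}
    by_group = {g: frozenset(s for s in tips if groups.get(s) == g)
                for g in labels}
    splits = set()
    for node in tree.non_tips(include_self=False):
        splits.add(frozenset(t.name for t in node.tips()))
    # at a trifurcating root one group can also sit as two of the three
    # root children; testing both groups covers that arrangement
    return any(by_group[g] in splits
               or frozenset(tips - by_group[g]) in splits
               for g in labels)


def pca(matrix: GenotypeMatrix, n_components: int = 3,
        scale: bool = False, max_sites: int | None = None,
        seed: int | None = None) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal component scores of the strains from 0/1 genotypes.

    Sites with missing calls are dropped (strict mode) and each site is
    mean-centred; with ``scale`` the sites are also variance-scaled.
    Component signs are fixed so the largest-magnitude score on each
    axis is positive.  ``max_sites`` optionally downsamples SNPs with
    the given seed.  Returns (scores frame, per-component variance).
    """
    keep = matrix.complete_sites() & matrix.segregating_sites()
    X = matrix.calls[:, keep].astype(float)
    if X.shape[1] < 1:
        raise ValueError("no complete polymorphic sites for PCA")
    if max_sites is not None and X.shape[1] > max_sites:
        rng = np.random.default_rng(seed)
        cols = np.sort(rng.choice(X.shape[1], size=max_sites, replace=False))
        X = X[:, cols]
    X = X - X.mean(axis=0, keepdims=True)
    if scale:
        sd = X.std(axis=0, ddof=0, keepdims=True)
        X = X / np.where(sd > 0, sd, 1.0)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    scores = U * s
    for k in range(scores.shape[1]):
        if scores[np.argmax(np.abs(scores[:, k])), k] < 0:
            scores[:, k] = -scores[:, k]
    explained = s ** 2 / X.shape[1]
    k = min(n_components, scores.shape[1])
    frame = pd.DataFrame(
        scores[:, :k], index=matrix.strain_ids,
        columns=[f"PC{i + 1}" for i in range(k)])
    return frame, explained[:k]


def fixed_difference_fraction(matrix: GenotypeMatrix,
                              groups: dict[str, str]
                              ) -> FixedDifferenceSummary:
    """Fraction of fully-called SNPs with alleles sorted between groups."""
    labels = sorted(set(groups[s] for s in matrix.strain_ids))
    if len(labels) != 2:
        raise ValueError("need exactly two groups")
    idx1 = [i for i, s in enumerate(matrix.strain_ids)
            if groups[s] == labels[0]]
    idx2 = [i for i, s in enumerate(matrix.strain_ids)
            if groups[s] == labels[1]]
    if not idx1 or not idx2:
        raise ValueError("each group needs at least one strain")
    complete = matrix.complete_sites()
    g1 = matrix.calls[np.ix_(idx1, np.flatnonzero(complete))]
    g2 = matrix.calls[np.ix_(idx2, np.flatnonzero(complete))]
    n_total = g1.shape[1]
    mono1 = (g1 == g1[0:1, :]).all(axis=0)
    mono2 = (g2 == g2[0:1, :]).all(axis=0)
    fixed = mono1 & mono2 & (g1[0, :] != g2[0, :])
    return FixedDifferenceSummary(n_fixed=int(fixed.sum()), n_total=n_total)


def flag_near_duplicates(d: DistanceMatrix, threshold: float = 0.01
                         ) -> tuple[list[tuple[str, str]], list[str]]:
    """Strain pairs closer than ``threshold``, and which member to drop.

    For every flagged pair the later-sorting strain label is marked for
    exclusion, so a chain A~B, B~C drops B and C and keeps A.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    pairs = []
    excluded: list[str] = []
    n = len(d.ids)
    for i in range(n):
        for j in range(i + 1, n):
            if np.isfinite(d.values[i, j]) and d.values[i, j] < threshold:
                a, b = sorted((d.ids[i], d.ids[j]))
                pairs.append((a, b))
                if b not in excluded:
                    excluded.append(b)
    return pairs, excluded
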