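"""Multiple agglomerative hierarchical clustering (MAHC) imputation.

The environments are clustered on the J x (I*K) wide rearrangement of
the standardized array with Ward's incremental-sum-of-squares linkage on
a missing-aware squared-Euclidean dissimilarity.  A missing value
(i, j, k) is estimated by the mean observed value of attribute k for
genotype i in the environment group that environment j first merges
with, walking up the dendrogram until a donor is found.  Each imputation
h builds two trees — one from all K attributes and one from a random
subset of K_h ~ Uniform{1, ..., K-1} attributes — and averages the two
donor estimates when both exist; the H imputations are averaged into the
final estimate.

Unlike the model-based imputers, every MAHC estimate is an average of
actually observed values, so it can never leave the observed range of
its attribute slice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .base import BaseMETImputer, spawn_rngs
from .core import MissingPattern, StandardizedMET

__all__ = ["MergeTree", "MAHCImputer", "environment_distance", "ward_cluster", "donor_estimate", "mahc_impute"]


@dataclass
class MergeTree:
    """Agglomeration sequence over J environment leaves.

    ``merges`` lists (left, right, height) with scipy cluster numbering:
    leaves are 0..J-1 and merge t creates cluster J+t.  Heights are the
    incremental-sum-of-squares merge costs on the squared-distance
    scale, nondecreasing.
    """

    merges: list[tuple[int, int, float]]
    n_leaves: int
    _members: list[list[int]] = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.merges) != self.n_leaves - 1:
            raise ValueError("a tree over J leaves has exactly J-1 merges")
        members = [[i] for i in range(self.n_leaves)]
        for left, right, _ in self.merges:
            members.append(members[left] + members[right])
        self._members = members

    def members(self, cluster: int) -> list[int]:
        """Leaf indices contained in a (leaf or internal) cluster."""
        return self._members[cluster]

    def sibling_path(self, leaf: int) -> list[list[int]]:
        """Sibling leaf-sets met on the walk from ``leaf`` to the root.

        The first entry is the environment (group) that ``leaf`` first
        merges with — the primary donor group; later entries continue
        the walk up for fallback donors.
        """
        path: list[list[int]] = []
        current = leaf
        for t, (left, right, _) in enumerate(self.merges):
            if left == current or right == current:
                sibling = right if left == current else left
                path.append(self._members[sibling])
                current = self.n_leaves + t
        return path


def environment_distance(std: StandardizedMET, attrs=None) -> np.ndarray:
    """Missing-aware squared-Euclidean dissimilarity between environments.

    Environments are compared over the genotype-attribute coordinates of
    the selected attributes.  Sums of squared differences run over
    jointly observed coordinates and are rescaled by
    (total coordinates / shared coordinates) so sparsity does not shrink
    distances.

    Raises if two environments share no observed coordinate.
    """
    I, J, K = std.shape
    if attrs is None:
        attrs = np.arange(K)
    attrs = np.asarray(sorted(attrs), dtype=int)
    if attrs.size == 0:
        raise ValueError("attrs must be nonempty")
    # J x (I * |attrs|) wide slice, genotypes nested within attributes
    X = std.values[:, :, attrs].transpose(1, 2, 0).reshape(J, -1)
    O = np.isfinite(X)
    X0 = np.where(O, X, 0.0)
    Of = O.astype(float)
    shared = Of @ Of.T
    cross = X0 @ X0.T
    sq = (X0**2) @ Of.T
    if np.any(shared == 0):
        a, b = np.argwhere(shared == 0)[0]
        raise ValueError(
            f"environments {a} and {b} share no observed coordinate over the selected attributes"
        )
    m = X.shape[1]
    d = (sq + sq.T - 2.0 * cross) * (m / shared)
    np.fill_diagonal(d, 0.0)
    d = np.maximum(d, 0.0)
    return (d + d.T) / 2.0


def ward_cluster(dist: np.ndarray) -> MergeTree:
    """Agglomerate under Ward's incremental-sum-of-squares criterion.

    ``dist`` is a J x J matrix of squared dissimilarities.  The linkage
    is computed on their square roots (the Lance-Williams Ward update on
    squared distances is equivalent); merge heights are reported back on
    the squared scale.
    """
    dist = np.asarray(dist, dtype=float)
    J = dist.shape[0]
    if J < 2:
        raise ValueError("need at least two environments to cluster")
    Z = linkage(np.sqrt(squareform(dist, checks=False)), method="ward")
    merges = [(int(a), int(b), float(h) ** 2) for a, b, h, _ in Z]
    return MergeTree(merges=merges, n_leaves=J)


def donor_estimate(tree: MergeTree, std: StandardizedMET, target: tuple[int, int, int]) -> float:
    """Estimate one missing cell from the dendrogram's donor groups.

    Walks up from environment j's leaf; at each merge, takes the mean of
    the observed values of attribute k for genotype i over the sibling
    environment group.  Returns NaN when no environment has the value
    observed anywhere in the tree.
    """
    i, j, k = target
    for sibling in tree.sibling_path(j):
        vals = std.values[i, sibling, k]
        vals = vals[np.isfinite(vals)]
        if vals.size:
            return float(vals.mean())
    return float("nan")


def _column_estimates(tree: MergeTree, std: StandardizedMET, rows: np.ndarray, j: int, k: int) -> np.ndarray:
    """Vectorized donor_estimate over the missing rows of one column."""
    out = np.full(rows.size, np.nan)
    todo = np.ones(rows.size, dtype=bool)
    for sibling in tree.sibling_path(j):
        if not todo.any():
            break
        block = std.values[np.ix_(rows[todo], sibling)][:, :, k]
        obs = np.isfinite(block)
        cnt = obs.sum(axis=1)
        sums = np.where(obs, block, 0.0).sum(axis=1)
        means = np.where(cnt > 0, sums / np.maximum(cnt, 1), np.nan)
        found = np.isfinite(means)
        idx = np.flatnonzero(todo)
        out[idx[found]] = means[found]
        todo[idx[found]] = False
    return out


class MAHCImputer(BaseMETImputer):
    """Multiple agglomerative hierarchical clustering imputer.

    Parameters
    ----------
    n_imputations : int, default 100
        Number of imputations H.  Each draws a fresh attribute subset.
    random_state : int or None
        Master seed; per-imputation streams are spawned from it, so
        imputations are order-independent.
    """

    def __init__(self, n_imputations: int = 100, random_state: int | None = None):
        self.n_imputations = n_imputations
        self.random_state = random_state

    def _impute_all(self, std: StandardizedMET, pattern: MissingPattern, missing, random_state):
        I, J, K = std.shape
        if self.n_imputations < 1:
            raise ValueError("n_imputations must be >= 1")
        rngs = spawn_rngs(random_state, self.n_imputations)
        # group missing triples by column for vectorized donor search
        by_col: dict[tuple[int, int], list[int]] = {}
        for m, (i, j, k) in enumerate(missing):
            by_col.setdefault((j, k), []).append(m)
        rows_by_col = {
            (j, k): np.array([missing[m][0] for m in ms], dtype=int)
            for (j, k), ms in by_col.items()
        }
        full_dist = environment_distance(std)
        full_tree = ward_cluster(full_dist)
        out = np.empty((self.n_imputations, len(missing)))
        for h, rng in enumerate(rngs):
            trees = [full_tree]
            if K >= 2:
                # a subset can leave an environment with no observed
                # coordinate (e.g. the subset is exactly a wholly missing
                # column's attribute); redraw, else use the full tree only
                for _ in range(10):
                    k_h = int(rng.integers(1, K))  # Uniform{1, ..., K-1}
                    attrs = rng.choice(K, size=k_h, replace=False)
                    try:
                        trees.append(ward_cluster(environment_distance(std, attrs)))
                        break
                    except ValueError:
                        continue
            est_h = np.full(len(missing), np.nan)
            for (j, k), ms in by_col.items():
                rows = rows_by_col[(j, k)]
                cands = np.stack(
                    [_column_estimates(t, std, rows, j, k) for t in trees], axis=0
                )
                fin = np.isfinite(cands)
                cnt = fin.sum(axis=0)
                sums = np.where(fin, cands, 0.0).sum(axis=0)
                est_h[ms] = np.where(cnt > 0, sums / np.maximum(cnt, 1), np.nan)
            out[h] = est_h
        dead = np.all(np.isnan(out), axis=0)
        if dead.any():
            bad = [tuple(missing[m]) for m in np.flatnonzero(dead)]
            raise ValueError(f"cells inestimable in every imputation: {bad}")
        # a cell inestimable under one subset tree falls back to the
        # imputations where an estimate exists
        return np.where(np.isnan(out), np.nanmean(out, axis=0), out)


def mahc_impute(X, n_imputations: int = 100, random_state: int | None = None) -> np.ndarray:
    """Functional wrapper: completed array from MAHC imputation."""
    return MAHCImputer(n_imputations=n_imputations, random_state=random_state).fit_transform(X)
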