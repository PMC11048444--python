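"""The treelet transform: iterated two-variable local PCAs.

Starting from ``V`` variables (voxel score vectors), the algorithm repeatedly
finds the pair of active variables with the highest signed Pearson
correlation, replaces the pair by the standardized sum variable ``x_s`` (the
leading principal component of the two standardized inputs whenever their
correlation is positive) and records the difference variable ``x_d`` and the
eigenvalue pair ``(1+|r|, 1-|r|)`` of the local 2x2 correlation matrix.
``V - 1`` merges produce a full hierarchy whose merge sequence is a
dendrogram over the original variables.

Variable identifiers follow the scipy linkage convention: leaves are
``0..V-1`` and the variable created at level ``l`` has id ``V - 1 + l``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["TreeletNode", "TreeletTree", "similarity", "local_pca2", "build_tree"]

_DEGENERATE_TOL = 1e-12


def similarity(x: np.ndarray, y: np.ndarray) -> float:
    """Signed Pearson correlation between two score vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("inputs must be equal-length 1-D vectors of length >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    nx, ny = np.linalg.norm(xc), np.linalg.norm(yc)
    if nx == 0 or ny == 0:
        raise ValueError("similarity undefined for zero-variance input")
    return float(np.clip(xc @ yc / (nx * ny), -1.0, 1.0))


def _standardize(x: np.ndarray) -> np.ndarray:
    xc = x - x.mean()
    return xc / xc.std()


@dataclass
class TreeletNode:
    """One merge of the hierarchy.

    ``sum_scores``/``diff_scores`` are the standardized sum and difference
    variables; a degenerate variable (zero variance before standardization,
    from r = -1 or r = +1 exactly) is stored as zeros and flagged.
    """

    level: int
    merged: tuple[int, int]
    sum_scores: np.ndarray = field(repr=False)
    diff_scores: np.ndarray = field(repr=False)
    eigenvalues: tuple[float, float]
    merge_similarity: float
    sum_degenerate: bool = False
    diff_degenerate: bool = False

    @property
    def lambda1(self) -> float:
        return self.eigenvalues[0]

    @property
    def lambda2(self) -> float:
        return self.eigenvalues[1]


def local_pca2(
    x: np.ndarray, y: np.ndarray, level: int = 0, merged: tuple[int, int] = (0, 1)
) -> TreeletNode:
    """Local PCA of a variable pair on the correlation scale.

    Both inputs are standardized to zero mean, unit variance; the 2x2
    correlation matrix ``[[1, r], [r, 1]]`` has eigenvalues ``1 + |r|`` and
    ``1 - |r|``.  The sum variable is the normalised positive combination
    ``(x~ + y~)/sqrt(2(1+r))`` - the leading eigenvector combination whenever
    r > 0, which is every merge the max-similarity rule selects in practice -
    and the difference variable is ``(x~ - y~)/sqrt(2(1-r))``.  Both carry a
    positive loading on ``x``; the pair is exactly uncorrelated for any r.
    """
    r = similarity(x, y)
    xs_raw = _standardize(x) + _standardize(y)
    xd_raw = _standardize(x) - _standardize(y)
    out = []
    degenerate = []
    for raw in (xs_raw, xd_raw):
        sd = raw.std()
        if sd <= _DEGENERATE_TOL:
            out.append(np.zeros_like(raw))
            degenerate.append(True)
        else:
            out.append((raw - raw.mean()) / sd)
            degenerate.append(False)
    return TreeletNode(
        level=level,
        merged=merged,
        sum_scores=out[0],
        diff_scores=out[1],
        eigenvalues=(1.0 + abs(r), 1.0 - abs(r)),
        merge_similarity=r,
        sum_degenerate=degenerate[0],
        diff_degenerate=degenerate[1],
    )


@dataclass
class TreeletTree:
    """Full merge hierarchy over ``n_leaves`` variables."""

    n_leaves: int
    nodes: list[TreeletNode]
    leaf_scores: np.ndarray = field(repr=False)

    @property
    def n_levels(self) -> int:
        return len(self.nodes)

    @property
    def n_dims(self) -> int:
        return self.leaf_scores.shape[1]

    def node(self, level: int) -> TreeletNode:
        """Node created at 1-based level ``level``."""
        if not 1 <= level <= len(self.nodes):
            raise IndexError(f"level must be in [1, {len(self.nodes)}]")
        return self.nodes[level - 1]

    def active_at(self, level: int) -> list[int]:
        """Sorted ids of variables active after ``level`` merges (0 = none)."""
        if not 0 <= level <= len(self.nodes):
            raise IndexError(f"level must be in [0, {len(self.nodes)}]")
        active = set(range(self.n_leaves))
        for node in self.nodes[:level]:
            active.difference_update(node.merged)
            active.add(self.n_leaves - 1 + node.level)
        return sorted(active)

    def scores(self, var_id: int) -> np.ndarray:
        """Standardized score vector of any variable (leaf or sum)."""
        if var_id < self.n_leaves:
            return _standardize(self.leaf_scores[var_id])
        return self.nodes[var_id - self.n_leaves].sum_scores

    def leaf_set(self, var_id: int) -> frozenset[int]:
        """Original variables underlying ``var_id`` (memoised)."""
        cache = self.__dict__.setdefault("_leafset_cache", {})
        if var_id in cache:
            return cache[var_id]
        if var_id < self.n_leaves:
            result = frozenset((var_id,))
        else:
            a, b = self.nodes[var_id - self.n_leaves].merged
            result = self.leaf_set(a) | self.leaf_set(b)
        cache[var_id] = result
        return result

    def dendrogram(self) -> np.ndarray:
        """Merge table with rows (child_a, child_b, 1 - r, cluster size)."""
        rows = np.empty((len(self.nodes), 4))
        for k, node in enumerate(self.nodes):
            a, b = node.merged
            rows[k] = (a, b, 1.0 - node.merge_similarity, len(self.leaf_set(self.n_leaves + k)))
        return rows

    def to_linkage(self) -> np.ndarray:
        """scipy-compatible linkage matrix (monotone non-negative heights)."""
        Z = self.dendrogram().copy()
        Z[:, 2] = np.maximum.accumulate(np.maximum(Z[:, 2], 0.0))
        return Z

    def to_newick(self) -> str:
        """Newick string with branch lengths derived from merge similarity."""
        height = {i: 0.0 for i in range(self.n_leaves)}
        label = {i: f"v{i}" for i in range(self.n_leaves)}
        for k, node in enumerate(self.nodes):
            a, b = node.merged
            h = max(1.0 - node.merge_similarity, 0.0)
            h = max(h, height[a], height[b])
            la = f"{label[a]}:{h - height[a]:.6g}"
            lb = f"{label[b]}:{h - height[b]:.6g}"
            new = self.n_leaves + k
            label[new] = f"({la},{lb})"
            height[new] = h
        roots = self.active_at(self.n_levels)
        if len(roots) == 1:
            return label[roots[0]] + ";"
        inner = ",".join(f"{label[r]}:0" for r in roots)
        return f"({inner});"


def build_tree(X: np.ndarray, n_levels: int | str = "full") -> TreeletTree:
    """Construct the treelet hierarchy of the rows of ``X`` (V x K).

    At each level the active pair with maximal signed correlation is merged
    (ties broken by the lexicographically smallest index pair); the sum
    variable replaces the pair in the active set, and only the row and column
    of the new variable in the similarity matrix are recomputed.  A
    degenerate (zero-variance) sum variable is recorded but excluded from
    further merging.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be 2-D with at least two rows")
    V, K = X.shape
    if K < 3:
        raise ValueError("need at least 3 observations per variable")
    sd = X.std(axis=1)
    if (sd == 0).any():
        raise ValueError(
            f"zero-variance input rows: {np.flatnonzero(sd == 0).tolist()[:10]}"
        )
    max_levels = V - 1 if n_levels == "full" else int(n_levels)
    if not 1 <= max_levels <= V - 1:
        raise ValueError(f"n_levels must be in [1, {V - 1}] or 'full'")

    work = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    scores = work.copy()  # slot s holds the current variable living in slot s
    ids = np.arange(V)  # variable id occupying each slot

    corr = np.clip((work @ work.T) / K, -1.0, 1.0)
    np.fill_diagonal(corr, -np.inf)

    nodes: list[TreeletNode] = []
    n_active = V
    for level in range(1, max_levels + 1):
        flat = int(np.argmax(corr))
        i, j = divmod(flat, V)
        if i > j:
            i, j = j, i
        if not np.isfinite(corr[i, j]):
            warnings.warn(
                f"no mergeable pair left at level {level}; stopping early",
                RuntimeWarning,
                stacklevel=2,
            )
            break
        if ids[i] > ids[j]:  # report merges ordered by variable id
            i, j = j, i
        node = local_pca2(
            scores[i], scores[j], level=level, merged=(int(ids[i]), int(ids[j]))
        )
        nodes.append(node)
        n_active -= 1
        assert n_active == V - level

        # retire slot j entirely; slot i now hosts the sum variable
        corr[j, :] = -np.inf
        corr[:, j] = -np.inf
        scores[i] = node.sum_scores
        ids[i] = V - 1 + level
        if node.sum_degenerate:
            corr[i, :] = -np.inf
            corr[:, i] = -np.inf
        else:
            live = np.isfinite(corr[i, :]) | np.isfinite(corr[:, i])
            live[i] = False
            idx = np.flatnonzero(live)
            if idx.size:
                row = np.clip((scores[idx] @ node.sum_scores) / K, -1.0, 1.0)
                corr[i, idx] = row
                corr[idx, i] = row
            corr[i, i] = -np.inf
    return TreeletTree(n_leaves=V, nodes=nodes, leaf_scores=X)
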