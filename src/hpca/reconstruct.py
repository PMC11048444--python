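"""Subject-level back-reconstruction of treelet levels.

A level's group score vector ``h`` (its sum variable, length K) is projected
into each subject's time domain via the compression inverses, optionally
after *tree-independent orthogonalization*: regressing ``h`` on every
base-level basis variable that is **not** a dendrogram descendant of the
level.  The subject map is then the seed-style Pearson correlation of the
back-projected series with every voxel's raw time series, z-scored across
voxels; the group map is the subject mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .compress import CompressionModel
from .tree import TreeletTree

__all__ = [
    "DependencySet",
    "LevelMaps",
    "tree_dependencies",
    "orthogonalize",
    "reconstruct_level",
    "reconstruct_variable",
]


@dataclass(frozen=True)
class DependencySet:
    """Partition of the base-level basis relative to one level's subtree."""

    level: int
    dependent_basis: tuple[int, ...]
    independent_basis: tuple[int, ...]


@dataclass
class LevelMaps:
    """Back-reconstructed time series and z-scored spatial maps for a level."""

    level: int
    subject_timeseries: np.ndarray  # M x N
    subject_maps: np.ndarray  # M x V, z-scored per subject
    group_map: np.ndarray  # length V
    raw_map_sd: np.ndarray  # per-subject SD of the correlation map before z-scoring
    excluded_subjects: list[int] = field(default_factory=list)


def tree_dependencies(
    tree: TreeletTree, level: int, base_level: int
) -> DependencySet:
    """Split the base-level basis into descendants and non-descendants.

    A basis variable is *dependent* if its leaf set intersects the leaf set
    of the level's sum variable; the rest are tree-independent of the level.
    Levels at or below the base are already summarised by the basis and are
    out of range.
    """
    if not base_level < level <= tree.n_levels:
        raise ValueError(
            f"level must lie in ({base_level}, {tree.n_levels}] for this basis"
        )
    basis = tree.active_at(base_level)
    target = tree.leaf_set(tree.n_leaves - 1 + level)
    dependent = tuple(b for b in basis if tree.leaf_set(b) & target)
    independent = tuple(b for b in basis if not (tree.leaf_set(b) & target))
    return DependencySet(
        level=level, dependent_basis=dependent, independent_basis=independent
    )


def orthogonalize(
    h: np.ndarray, basis: dict[int, np.ndarray], deps: DependencySet
) -> np.ndarray:
    """Residual of ``h`` after regressing out its tree-independent basis.

    With an empty independent set (e.g. the tree root) the series is
    returned unchanged.  Ordinary least squares via lstsq (pseudo-inverse
    behaviour on collinear regressors).
    """
    h = np.asarray(h, dtype=float)
    if not deps.independent_basis:
        return h.copy()
    A = np.column_stack([basis[b] for b in deps.independent_basis])
    coef, *_ = np.linalg.lstsq(A, h, rcond=None)
    return h - A @ coef


def reconstruct_level(
    tree: TreeletTree,
    level: int,
    compression: CompressionModel,
    subjects: list[np.ndarray],
    orthogonalize_flag: bool = True,
    base_level: int | None = None,
) -> LevelMaps:
    """Back-reconstruct one level for every subject.

    ``subjects`` are the uncompressed voxel-by-time matrices (seed maps are
    computed against raw voxel time series).  Orthogonalization operates on
    compressed (length-K) score vectors before back-projection and requires
    ``base_level``.  Subjects whose reconstructed series has zero variance
    are excluded from the group map with a warning.
    """
    node = tree.node(level)
    h = node.sum_scores
    if node.sum_degenerate:
        warnings.warn(
            f"level {level} has a degenerate sum variable; maps will be "
            "noise-level",
            RuntimeWarning,
            stacklevel=2,
        )
    if orthogonalize_flag:
        if base_level is None:
            raise ValueError("orthogonalization requires base_level")
        deps = tree_dependencies(tree, level, base_level)
        basis = {b: tree.scores(b) for b in deps.independent_basis}
        h = orthogonalize(h, basis, deps)
    return _backreconstruct(h, level, compression, subjects)


def reconstruct_variable(
    tree: TreeletTree,
    var_id: int,
    compression: CompressionModel,
    subjects: list[np.ndarray],
    orthogonalize_flag: bool = False,
    base_level: int | None = None,
) -> LevelMaps:
    """Back-reconstruct any tree variable (leaf or sum) by its id.

    Useful for the base-level basis variables themselves, which summarise
    the redundant prefix; with ``orthogonalize_flag`` each basis variable is
    regressed on every *other* basis variable.
    """
    h = tree.scores(var_id)
    if orthogonalize_flag:
        if base_level is None:
            raise ValueError("orthogonalization requires base_level")
        basis_ids = [b for b in tree.active_at(base_level) if b != var_id]
        deps = DependencySet(
            level=max(var_id - tree.n_leaves + 1, 0),
            dependent_basis=(var_id,),
            independent_basis=tuple(basis_ids),
        )
        h = orthogonalize(h, {b: tree.scores(b) for b in basis_ids}, deps)
    level = var_id - tree.n_leaves + 1 if var_id >= tree.n_leaves else 0
    return _backreconstruct(h, level, compression, subjects)


def _backreconstruct(
    h: np.ndarray,
    level: int,
    compression: CompressionModel,
    subjects: list[np.ndarray],
) -> LevelMaps:
    M = compression.n_subjects
    if len(subjects) != M:
        raise ValueError(f"expected {M} subjects, got {len(subjects)}")
    V = compression.n_voxels
    series = np.empty((M, compression.n_timepoints))
    maps = np.zeros((M, V))
    raw_sd = np.zeros(M)
    excluded: list[int] = []
    for i, Z in enumerate(subjects):
        Z = np.asarray(getattr(Z, "data", Z), dtype=float)
        h_i = h @ compression.backprojector(i)
        series[i] = h_i
        sd = h_i.std()
        if sd == 0:
            excluded.append(i)
            continue
        hc = h_i - h_i.mean()
        hc /= np.linalg.norm(hc)
        Zc = Z - Z.mean(axis=1, keepdims=True)
        vn = np.linalg.norm(Zc, axis=1)
        vn[vn == 0] = np.inf
        corr = (Zc @ hc) / vn
        raw_sd[i] = corr.std()
        if raw_sd[i] == 0:
            excluded.append(i)
            continue
        maps[i] = (corr - corr.mean()) / raw_sd[i]
    if excluded:
        warnings.warn(
            f"excluded zero-variance subjects {excluded} from the group map",
            RuntimeWarning,
            stacklevel=2,
        )
    kept = [i for i in range(M) if i not in excluded]
    group = maps[kept].mean(axis=0) if kept else np.zeros(V)
    return LevelMaps(
        level=level,
        subject_timeseries=series,
        subject_maps=maps,
        group_map=group,
        raw_map_sd=raw_sd,
        excluded_subjects=excluded,
    )
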