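"""Two-stage PCA compression with temporal concatenation, and its inverses.

Subject stage: each voxel-by-time matrix ``Z_i`` is centred over time and
reduced to ``Y_i = Z_i F_i`` where ``F_i`` (time x C) holds the top right
singular vectors.  Group stage: the horizontally concatenated
``Y = [Y_1 ... Y_M]`` is reduced again to ``X = Y G`` with ``G`` partitioned
row-wise into per-subject blocks ``G_i``.  Back-projection of any group-level
score vector ``h`` (length K) into subject ``i``'s time domain is
``h_i = h G_i^+ F_i^T`` (GICA3-style), with ``^+`` the pseudo-inverse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg

__all__ = [
    "CompressionModel",
    "CompressedGroupData",
    "RankDeficiencyError",
    "subject_pca",
    "group_pca",
    "compress_subjects",
    "backproject_timeseries",
]


class RankDeficiencyError(ValueError):
    """Requested more components than the data can supply."""


def _fix_signs(basis: np.ndarray, scores: np.ndarray) -> None:
    """Flip basis/score column pairs so the largest-|loading| entry of each
    basis column is positive.  Makes repeated runs bit-comparable."""
    flip = np.sign(basis[np.abs(basis).argmax(axis=0), np.arange(basis.shape[1])])
    flip[flip == 0] = 1.0
    basis *= flip
    scores *= flip


def _pca_reduce(Z: np.ndarray, n_keep: int):
    """Centred thin-SVD reduction shared by both stages.

    Returns scores (rows x n_keep), basis (cols x n_keep) and the removed
    row means.  Deterministic LAPACK SVD; no randomised solver.
    """
    Z = np.asarray(Z, dtype=float)
    rows, cols = Z.shape
    attainable = min(rows, cols)
    if not 1 <= n_keep <= attainable:
        raise RankDeficiencyError(
            f"cannot keep {n_keep} components; attainable rank is {attainable} "
            f"for a {rows}x{cols} matrix"
        )
    means = Z.mean(axis=1)
    Zc = Z - means[:, None]
    U, s, Vt = linalg.svd(Zc, full_matrices=False)
    basis = Vt[:n_keep].T.copy()
    scores = U[:, :n_keep] * s[:n_keep]
    _fix_signs(basis, scores)
    return scores, basis, means


def subject_pca(Z: np.ndarray, n_keep: int):
    """Reduce one subject's voxel-by-time matrix.

    Returns ``(Y_i, F_i, means)`` with ``Y_i = (Z - means) F_i`` the V x C
    scores and ``F_i`` the N x C orthonormal temporal basis ordered by
    decreasing singular value.
    """
    return _pca_reduce(Z, n_keep)


def group_pca(Y: np.ndarray, n_keep: int, n_subjects: int | None = None):
    """Reduce the concatenated group matrix.

    Returns ``(X, G, means)``; when ``n_subjects`` is given, also the list of
    per-subject row blocks ``G_i`` as a fourth element.
    """
    X, G, means = _pca_reduce(Y, n_keep)
    if n_subjects is None:
        return X, G, means
    if G.shape[0] % n_subjects:
        raise ValueError("rows of G not divisible into equal subject blocks")
    C = G.shape[0] // n_subjects
    parts = [G[i * C : (i + 1) * C] for i in range(n_subjects)]
    return X, G, means, parts


@dataclass
class CompressionModel:
    """Fitted two-stage compression: per-subject bases plus the group basis."""

    subject_bases: list[np.ndarray]  # each N x C, orthonormal columns
    subject_means: list[np.ndarray]  # each length V
    group_basis: np.ndarray  # (C*M) x K
    group_means: np.ndarray  # length V, removed before the group PCA
    n_voxels: int
    n_timepoints: int
    n_subject_pcs: int
    n_group_pcs: int
    n_subjects: int

    @property
    def dims(self) -> dict[str, int]:
        return {
            "V": self.n_voxels,
            "N": self.n_timepoints,
            "C": self.n_subject_pcs,
            "K": self.n_group_pcs,
            "M": self.n_subjects,
        }

    @property
    def group_partitions(self) -> list[np.ndarray]:
        """Per-subject C x K row blocks of the group basis."""
        C = self.n_subject_pcs
        return [
            self.group_basis[i * C : (i + 1) * C] for i in range(self.n_subjects)
        ]

    def backproject(self, h: np.ndarray, subject: int) -> np.ndarray:
        """Subject-specific time series for a group-level score vector."""
        return h @ self.backprojector(subject)

    def backprojector(self, subject: int) -> np.ndarray:
        """Cached K x N back-projection matrix for one subject.

        The generalized inverse of the orthonormal group basis is its
        transpose, so the subject-i block of ``G^+`` is ``G_i^T`` and the
        projector is ``G_i^T F_i^T``.
        """
        cache = self.__dict__.setdefault("_projector_cache", {})
        if subject not in cache:
            C = self.n_subject_pcs
            G_i = self.group_basis[subject * C : (subject + 1) * C]
            cache[subject] = G_i.T @ self.subject_bases[subject].T
        return cache[subject]


@dataclass
class CompressedGroupData:
    """The V x K compressed matrix together with its provenance."""

    X: np.ndarray
    provenance: CompressionModel

    @property
    def n_voxels(self) -> int:
        return self.X.shape[0]

    @property
    def n_dims(self) -> int:
        return self.X.shape[1]


def compress_subjects(
    subjects: list[np.ndarray],
    n_subject_pcs: int,
    n_group_pcs: int,
) -> CompressedGroupData:
    """Run both PCA stages over a list of voxel-by-time matrices."""
    if len(subjects) == 0:
        raise ValueError("need at least one subject")
    mats = [np.asarray(getattr(s, "data", s), dtype=float) for s in subjects]
    V, N = mats[0].shape
    if any(m.shape != (V, N) for m in mats):
        raise ValueError("all subjects must share the same shape")
    C, K, M = n_subject_pcs, n_group_pcs, len(mats)
    if K > C * M:
        raise RankDeficiencyError(f"K={K} exceeds C*M={C * M}")

    bases, means_list, blocks = [], [], []
    for Z in mats:
        Y_i, F_i, mu = subject_pca(Z, C)
        bases.append(F_i)
        means_list.append(mu)
        blocks.append(Y_i)
    Y = np.hstack(blocks)
    X, G, gmeans = group_pca(Y, K)
    model = CompressionModel(
        subject_bases=bases,
        subject_means=means_list,
        group_basis=G,
        group_means=gmeans,
        n_voxels=V,
        n_timepoints=N,
        n_subject_pcs=C,
        n_group_pcs=K,
        n_subjects=M,
    )
    return CompressedGroupData(X=X, provenance=model)


def backproject_timeseries(
    h: np.ndarray, G_i: np.ndarray, F_i: np.ndarray
) -> np.ndarray:
    """Map a length-K group score vector to a length-N subject time series.

    Computes ``h (G^+)_i F_i^T`` where ``(G^+)_i`` is the subject-i block of
    the generalized inverse of the full group basis.  Because ``G`` has
    orthonormal columns, ``G^+ = G^T`` and the block reduces to ``G_i^T`` -
    inverting the subject block *in isolation* instead would amplify the
    small singular values each subject contributes to the shared basis and
    destroy the reconstruction.  A warning is raised when ``G_i`` carries a
    degenerate share of the group basis (all-zero block).
    """
    h = np.asarray(h, dtype=float)
    G_i = np.asarray(G_i, dtype=float)
    F_i = np.asarray(F_i, dtype=float)
    if h.shape[-1] != G_i.shape[1]:
        raise ValueError(f"h has length {h.shape[-1]}, expected K={G_i.shape[1]}")
    if not np.any(G_i):
        warnings.warn(
            "subject block of the group basis is identically zero; "
            "back-projection is degenerate",
            RuntimeWarning,
            stacklevel=2,
        )
    return h @ G_i.T @ F_i.T
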