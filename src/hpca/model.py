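"""Model / Results interface for multiresolution hierarchical PCA.

:class:`HierarchicalPCA` is constructed from multi-subject voxel-by-time
data (or from an already compressed matrix) and ``fit()`` returns a
:class:`TreeletResults` carrying the full merge hierarchy, the statistical
level filter, and methods for subject-level back-reconstruction, tabular
reporting and dendrogram plotting.

Example
-------
>>> from hpca import simulate, HierarchicalPCA
>>> spec = simulate.HierarchySpec(n_levels=3, branching=2, n_voxels=64, seed=0)
>>> _, subjects = simulate.simulate_experiment(spec, n_subjects=5, n_timepoints=120)
>>> res = HierarchicalPCA(subjects, subject_pcs=40, group_pcs=60).fit()
>>> res.base_level <= res.tree.n_levels
True
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import compress as _compress
from . import levelstats as _levelstats
from . import reconstruct as _reconstruct
from . import tree as _tree

__all__ = ["HierarchicalPCA", "TreeletResults"]


class HierarchicalPCA:
    """Treelet hierarchical PCA of multi-subject voxel-by-time data.

    Parameters
    ----------
    data : list of array-like
        One voxel-by-time matrix (or :class:`~hpca.simulate.SubjectDataset`)
        per subject.
    subject_pcs, group_pcs : int
        Components retained by the subject-level and group-level PCA
        compression stages (C and K).
    gamma : float
        Smallest-eigenvalue cutoff of the redundancy test, on the
        correlation scale where eigenvalue pairs sum to 2.
    alpha_fwe : float
        Family-wise error rate shared by the two level tests, Bonferroni
        corrected over ``2 (V - 1)`` tests.
    n_levels : int or "full"
        Height of the constructed hierarchy.
    """

    def __init__(
        self,
        data,
        *,
        subject_pcs: int = 295,
        group_pcs: int = 300,
        gamma: float = 0.4,
        alpha_fwe: float = 0.001,
        n_levels: int | str = "full",
    ):
        self.subjects = [np.asarray(getattr(s, "data", s), dtype=float) for s in data]
        if not self.subjects:
            raise ValueError("need at least one subject")
        self.subject_pcs = subject_pcs
        self.group_pcs = group_pcs
        self.gamma = gamma
        self.alpha_fwe = alpha_fwe
        self.n_levels = n_levels
        self._compressed: _compress.CompressedGroupData | None = None

    @classmethod
    def from_compressed(
        cls,
        X,
        *,
        gamma: float = 0.4,
        alpha_fwe: float = 0.001,
        n_levels: int | str = "full",
    ) -> "HierarchicalPCA":
        """Build the model from an existing V x K compressed matrix.

        ``X`` may be a plain array or a
        :class:`~hpca.compress.CompressedGroupData`; back-reconstruction is
        only available in the latter case.
        """
        obj = cls.__new__(cls)
        if isinstance(X, _compress.CompressedGroupData):
            obj._compressed = X
            obj.subjects = None
        else:
            obj._compressed = _compress.CompressedGroupData(
                X=np.asarray(X, dtype=float), provenance=None
            )
            obj.subjects = None
        obj.subject_pcs = None
        obj.group_pcs = obj._compressed.X.shape[1]
        obj.gamma = gamma
        obj.alpha_fwe = alpha_fwe
        obj.n_levels = n_levels
        return obj

    def fit(self) -> "TreeletResults":
        """Compress (if needed), build the hierarchy and filter its levels."""
        if self._compressed is None:
            self._compressed = _compress.compress_subjects(
                self.subjects, self.subject_pcs, self.group_pcs
            )
        tree = _tree.build_tree(self._compressed.X, self.n_levels)
        report = _levelstats.filter_levels(tree, self.gamma, self.alpha_fwe)
        return TreeletResults(
            model=self,
            tree=tree,
            compressed=self._compressed,
            report=report,
        )


@dataclass
class TreeletResults:
    """Fitted hierarchy plus level filter; returned by ``HierarchicalPCA.fit``."""

    model: HierarchicalPCA
    tree: _tree.TreeletTree
    compressed: _compress.CompressedGroupData
    report: _levelstats.LevelFilterReport
    _maps_cache: dict = field(default_factory=dict, repr=False)

    # -- headline quantities -------------------------------------------------
    @property
    def base_level(self) -> int:
        return self.report.base_level

    @property
    def n_active(self) -> int:
        return self.tree.n_leaves - self.report.base_level

    @property
    def significant_levels(self) -> list[int]:
        return self.report.significant_levels

    @property
    def unrelated_levels(self) -> list[int]:
        return self.report.unrelated_levels

    @property
    def basis_variables(self) -> list[int]:
        """Ids of the active variables at the base level (analysis basis)."""
        return self.tree.active_at(self.report.base_level)

    def level_table(self) -> pd.DataFrame:
        """Tidy per-level table (level, r, lambda2, p_set, p_corr, flag)."""
        return self.report.table.copy()

    # -- reconstruction ------------------------------------------------------
    def reconstruct_level(
        self, level: int, orthogonalize: bool = True, subjects=None
    ) -> _reconstruct.LevelMaps:
        """Subject time series and z-scored seed maps for one level."""
        if self.compressed.provenance is None:
            raise ValueError("no compression model attached; cannot back-project")
        subjects = self.model.subjects if subjects is None else subjects
        if subjects is None:
            raise ValueError("raw subject matrices are required for seed maps")
        key = (level, orthogonalize)
        if key not in self._maps_cache:
            self._maps_cache[key] = _reconstruct.reconstruct_level(
                self.tree,
                level,
                self.compressed.provenance,
                subjects,
                orthogonalize_flag=orthogonalize,
                base_level=self.report.base_level,
            )
        return self._maps_cache[key]

    def reconstruct_variable(
        self, var_id: int, orthogonalize: bool = False, subjects=None
    ) -> _reconstruct.LevelMaps:
        """Back-reconstruct any tree variable (e.g. a base-level basis sum)."""
        if self.compressed.provenance is None:
            raise ValueError("no compression model attached; cannot back-project")
        subjects = self.model.subjects if subjects is None else subjects
        return _reconstruct.reconstruct_variable(
            self.tree,
            var_id,
            self.compressed.provenance,
            subjects,
            orthogonalize_flag=orthogonalize,
            base_level=self.report.base_level,
        )

    # -- presentation --------------------------------------------------------
    def summary(self) -> str:
        """Human-readable fit summary in the style of a regression report."""
        rep = self.report
        V = self.tree.n_leaves
        dims = (
            self.compressed.provenance.dims
            if self.compressed.provenance is not None
            else {"V": V, "K": self.tree.n_dims}
        )
        lines = [
            "Hierarchical PCA (treelets) results",
            "=" * 56,
            f"variables (voxels)        {V}",
            f"tree levels               {self.tree.n_levels}",
            f"observations K            {rep.K}",
        ]
        if "M" in dims:
            lines += [
                f"subjects M                {dims['M']}",
                f"subject PCs C             {dims['C']}",
            ]
        lines += [
            f"gamma (SET cutoff)        {rep.gamma}",
            f"alpha FWE / per test      {rep.alpha_fwe} / {rep.alpha_per_test:.3g}",
            "-" * 56,
            f"base level (SET prefix)   {rep.base_level}",
            f"active variables at base  {V - rep.base_level}",
            f"significant levels        {len(rep.significant_levels)}",
            f"unrelated levels          {len(rep.unrelated_levels)}"
            + (
                f"  (top: {rep.unrelated_levels[-3:]})"
                if rep.unrelated_levels
                else ""
            ),
            "-" * 56,
        ]
        tail = self.report.table.tail(3)
        lines.append("last merges (level, r, lambda2, flag):")
        for _, row in tail.iterrows():
            lines.append(
                f"  {int(row['level']):>6}  r={row['r']:+.3f}  "
                f"lambda2={row['lambda2']:.3f}  {row['flag']}"
            )
        return "\n".join(lines)

    def plot_dendrogram(self, ax=None, truncate_to: int | None = 40, **kwargs):
        """Plot the merge dendrogram (1 - r heights) via scipy/matplotlib."""
        import matplotlib.pyplot as plt
        from scipy.cluster.hierarchy import dendrogram

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        Z = self.tree.to_linkage()
        opts = dict(no_labels=True, color_threshold=None)
        if truncate_to is not None:
            opts.update(truncate_mode="lastp", p=truncate_to)
        opts.update(kwargs)
        dendrogram(Z, ax=ax, **opts)
        ax.set_xlabel("merged variables")
        ax.set_ylabel("merge height (1 - r)")
        return ax
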