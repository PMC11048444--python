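"""Parametric filtering of treelet levels.

Two tests are applied to every merge of the hierarchy, each at a Bonferroni
per-test level ``alpha_fwe / (2 (V-1))``:

* the Smallest Eigenvalue Test (SET) flags *redundant* mergers - merges whose
  trailing local-PCA eigenvalue ``lambda2`` is significantly below a cutoff
  ``gamma``, meaning the difference between the merged variables is
  noise-level.  H0: ``lambda2 >= gamma``; reject when
  ``lambda2 < gamma - z_alpha * lambda2 * sqrt(2 / (K - 1))`` (the classical
  asymptotic with Var(lambda_hat) ~ 2 lambda^2 / (K - 1)), where ``K`` is the
  number of observations (the compressed, concatenated time dimension);

* a one-tailed correlation t-test flags *unrelated* mergers - merges whose
  similarity is not significantly positive (H0: rho <= 0), using
  ``t = sqrt(K-2) r / sqrt(1 - r^2)`` with ``K - 2`` degrees of freedom.

The *base level* is the last level of the maximal contiguous prefix of SET
rejections; its active variables summarise all earlier redundant mergers and
form the analysis basis.  Levels above the base that pass the SET (are not
redundant) and whose similarity is significantly positive are the
*significant* levels kept for back-reconstruction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .tree import TreeletTree

__all__ = [
    "SetTestResult",
    "CorrTestResult",
    "LevelFilterReport",
    "bonferroni_alpha",
    "set_test",
    "corr_test",
    "select_base_level",
    "filter_levels",
]

#: Probabilities below this are reported as 0 and flagged as underflowed.
P_FLOOR = 1e-300


def bonferroni_alpha(alpha_fwe: float, n_tests: int) -> float:
    """Per-test significance level controlling the family-wise error rate."""
    if not 0.0 < alpha_fwe < 1.0:
        raise ValueError("alpha_fwe must lie in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha_fwe / n_tests


@dataclass
class SetTestResult:
    level: int
    lambda2: float
    gamma: float
    K: int
    z_alpha: float
    p_value: float
    reject_H0: bool
    underflow: bool = False


@dataclass
class CorrTestResult:
    level: int
    r: float
    t_stat: float
    df: int
    p_value: float
    significant: bool
    underflow: bool = False


def set_test(
    lambda2: float, gamma: float, K: int, alpha: float, level: int = 0
) -> SetTestResult:
    """Smallest Eigenvalue Test for one merge.

    Rejecting H0 (``lambda2 >= gamma``) declares the merge redundant: the
    leading component carries essentially all the shared variance.
    """
    if lambda2 < 0:
        raise ValueError("lambda2 must be non-negative")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if K < 3:
        raise ValueError("need at least 3 observations")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if lambda2 == 0.0:
        z = -np.inf
    else:
        with np.errstate(over="ignore", divide="ignore"):
            z = (lambda2 - gamma) / (lambda2 * np.sqrt(2.0 / (K - 1)))
    p = float(stats.norm.cdf(z))
    underflow = 0.0 < p < P_FLOOR or z == -np.inf
    if p < P_FLOOR:
        p = 0.0
    return SetTestResult(
        level=level,
        lambda2=float(lambda2),
        gamma=float(gamma),
        K=int(K),
        z_alpha=float(stats.norm.isf(alpha)),
        p_value=p,
        reject_H0=p < alpha,
        underflow=underflow,
    )


def corr_test(r: float, K: int, alpha: float, level: int = 0) -> CorrTestResult:
    """One-tailed test of a merge similarity against H0: rho <= 0."""
    if not -1.0 <= r <= 1.0:
        raise ValueError("r must lie in [-1, 1]")
    if K < 3:
        raise ValueError("need at least 3 observations")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    df = K - 2
    if r == 1.0:
        t, p = np.inf, 0.0
    elif r == -1.0:
        t, p = -np.inf, 1.0
    else:
        t = float(np.sqrt(df) * r / np.sqrt(1.0 - r * r))
        p = float(stats.t.sf(t, df))
    underflow = 0.0 < p < P_FLOOR or t == np.inf
    if p < P_FLOOR:
        p = 0.0
    return CorrTestResult(
        level=level,
        r=float(r),
        t_stat=t,
        df=df,
        p_value=p,
        significant=p < alpha,
        underflow=underflow,
    )


def select_base_level(tree: TreeletTree, gamma: float, alpha: float) -> int:
    """Last level of the contiguous prefix of SET rejections.

    Isolated SET rejections beyond the prefix do not move the base level.
    Returns 0 (the all-voxel basis) with a warning if the first level is
    already accepted.
    """
    K = tree.n_dims
    base = 0
    for node in tree.nodes:
        if set_test(node.lambda2, gamma, K, alpha, level=node.level).reject_H0:
            base = node.level
        else:
            break
    if base == 0:
        warnings.warn(
            "no redundant prefix found; base level 0 keeps every variable",
            RuntimeWarning,
            stacklevel=2,
        )
    return base


@dataclass
class LevelFilterReport:
    """Joint outcome of SET and correlation filtering for a whole tree."""

    base_level: int
    redundant_levels: range
    unrelated_levels: list[int]
    significant_levels: list[int]
    alpha_fwe: float
    alpha_per_test: float
    n_tests: int
    gamma: float
    K: int
    table: pd.DataFrame = field(repr=False)

    @property
    def n_active(self) -> int:
        """Active variables at the base level (V - base_level)."""
        return int(self.table.attrs["n_leaves"]) - self.base_level


def filter_levels(
    tree: TreeletTree, gamma: float = 0.4, alpha_fwe: float = 0.001
) -> LevelFilterReport:
    """Apply both tests to every level and classify the hierarchy."""
    V = tree.n_leaves
    K = tree.n_dims
    n_tests = 2 * (V - 1)
    alpha = bonferroni_alpha(alpha_fwe, n_tests)

    rows = []
    for node in tree.nodes:
        s = set_test(node.lambda2, gamma, K, alpha, level=node.level)
        c = corr_test(node.merge_similarity, K, alpha, level=node.level)
        rows.append(
            {
                "level": node.level,
                "r": node.merge_similarity,
                "lambda2": node.lambda2,
                "p_set": s.p_value,
                "p_corr": c.p_value,
                "set_reject": s.reject_H0,
                "corr_significant": c.significant,
            }
        )
    table = pd.DataFrame(rows)

    base = 0
    for rej in table["set_reject"]:
        if not rej:
            break
        base += 1
    if base == 0:
        warnings.warn(
            "no redundant prefix found; base level 0 keeps every variable",
            RuntimeWarning,
            stacklevel=2,
        )

    above = table[table["level"] > base]
    unrelated = above.loc[~above["corr_significant"], "level"].tolist()
    significant = above.loc[
        above["corr_significant"] & ~above["set_reject"], "level"
    ].tolist()

    flags = np.where(
        table["level"] <= base,
        "redundant",
        np.where(
            ~table["corr_significant"],
            "unrelated",
            np.where(table["set_reject"], "redundant_isolated", "significant"),
        ),
    )
    table["flag"] = flags
    table.attrs["n_leaves"] = V
    return LevelFilterReport(
        base_level=base,
        redundant_levels=range(1, base + 1),
        unrelated_levels=unrelated,
        significant_levels=significant,
        alpha_fwe=alpha_fwe,
        alpha_per_test=alpha,
        n_tests=n_tests,
        gamma=gamma,
        K=K,
        table=table,
    )
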