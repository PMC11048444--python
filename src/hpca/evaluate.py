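"""Accuracy measurement against ground truth and the FastICA baseline.

Back-reconstruction accuracy follows the classic validation recipe for group
ICA: for every ground-truth component (per subject, separately in the
spatial and temporal domains) the best match is the estimated vector with
the highest absolute Pearson correlation.  Matching is deliberately not
injective - a single estimated component may be the best match of several
true components, which is exactly what exposes a method that only captures
one scale of a hierarchy.  Methods are compared with paired t-tests on the
per-(subject, component) absolute correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .compress import CompressedGroupData

__all__ = [
    "best_match",
    "compare_methods",
    "run_ica_baseline",
    "ICAResult",
    "PairedComparison",
]


def _row_standardize(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    A = np.asarray(A, dtype=float)
    Ac = A - A.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Ac, axis=1)
    ok = norms > 0
    Ac[ok] /= norms[ok, None]
    return Ac, ok


def best_match(
    true_set: np.ndarray,
    est_set: np.ndarray,
    method: str = "",
    subject: int | None = None,
    domain: str = "",
) -> pd.DataFrame:
    """Best absolute-correlation match for every true component.

    Rows of both matrices are components (over voxels or over time).  Ties
    break to the lowest estimate index; zero-variance estimates are excluded
    with a warning, and zero-variance true components are dropped.
    """
    T, t_ok = _row_standardize(true_set)
    E, e_ok = _row_standardize(est_set)
    if T.shape[1] != E.shape[1]:
        raise ValueError("true and estimated sets differ in dimension")
    if not t_ok.all():
        warnings.warn(
            f"dropping zero-variance true components {np.flatnonzero(~t_ok).tolist()}",
            RuntimeWarning,
            stacklevel=2,
        )
    if not e_ok.all():
        warnings.warn(
            f"excluding zero-variance estimates {np.flatnonzero(~e_ok).tolist()}",
            RuntimeWarning,
            stacklevel=2,
        )
    if not e_ok.any():
        raise ValueError("no usable estimated components")
    C = np.abs(T[t_ok] @ E[e_ok].T)
    est_ids = np.flatnonzero(e_ok)
    picks = C.argmax(axis=1)
    rows = pd.DataFrame(
        {
            "true_id": np.flatnonzero(t_ok),
            "best_match_id": est_ids[picks],
            "abs_correlation": C[np.arange(C.shape[0]), picks],
        }
    )
    rows["method"] = method
    if subject is not None:
        rows["subject"] = subject
    if domain:
        rows["domain"] = domain
    return rows


@dataclass
class PairedComparison:
    """Paired t-test on per-key absolute correlations of two methods."""

    method_a: str
    method_b: str
    mean_a: float
    mean_b: float
    mean_diff: float  # a - b
    t_stat: float
    df: int
    p_value: float
    n_pairs: int
    long: pd.DataFrame = field(repr=False)


def compare_methods(table_a: pd.DataFrame, table_b: pd.DataFrame) -> PairedComparison:
    """Paired comparison of two match tables on shared (subject, component) keys."""
    keys = [k for k in ("subject", "true_id", "domain") if k in table_a.columns]
    if not keys or any(k not in table_b.columns for k in keys):
        raise ValueError("tables lack shared alignment keys")
    merged = table_a.merge(table_b, on=keys, suffixes=("_a", "_b"), validate="1:1")
    if len(merged) != len(table_a) or len(merged) != len(table_b):
        raise ValueError("tables do not align on (subject, component) keys")
    a = merged["abs_correlation_a"].to_numpy()
    b = merged["abs_correlation_b"].to_numpy()
    d = a - b
    n = len(d)
    if np.allclose(d, 0.0):
        t, p = 0.0, 1.0
    elif np.ptp(d) == 0.0:  # exactly constant non-zero difference
        t, p = np.sign(d[0]) * np.inf, 0.0
    else:
        t, p = stats.ttest_rel(a, b)
    long = pd.concat(
        [
            table_a.assign(method=table_a.get("method", "a")),
            table_b.assign(method=table_b.get("method", "b")),
        ],
        ignore_index=True,
    )
    name_a = str(table_a["method"].iloc[0]) if "method" in table_a else "a"
    name_b = str(table_b["method"].iloc[0]) if "method" in table_b else "b"
    return PairedComparison(
        method_a=name_a,
        method_b=name_b,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        mean_diff=float(d.mean()),
        t_stat=float(t),
        df=n - 1,
        p_value=float(p),
        n_pairs=n,
        long=long,
    )


@dataclass
class ICAResult:
    """Spatial FastICA decomposition of the compressed group data."""

    maps: np.ndarray  # n_components x V, z-scored across voxels
    mixing: np.ndarray  # n_components x K (rows of the mixing matrix A)
    subject_timeseries: list[np.ndarray]  # each n_components x N
    n_restarts: int
    failed_restarts: int
    chosen_restart: int


def _zscore_rows(A: np.ndarray) -> np.ndarray:
    Ac = A - A.mean(axis=1, keepdims=True)
    sd = Ac.std(axis=1)
    sd[sd == 0] = 1.0
    return Ac / sd[:, None]


def run_ica_baseline(
    X: CompressedGroupData | np.ndarray,
    n_components: int,
    seed: int = 0,
    n_restarts: int = 5,
    max_iter: int = 1000,
    tol: float = 1e-4,
) -> ICAResult:
    """Single-scale spatial ICA baseline with multi-restart stabilisation.

    FastICA is run ``n_restarts`` times from distinct seeds; the kept run is
    the centrotype - the run whose components agree best, by mean matched
    absolute correlation, with all other runs.  Subject time series come
    from GICA3 back-projection of the mixing rows (``R_i = A G_i^+ F_i^T``),
    available when ``X`` carries compression provenance.
    """
    data = X.X if isinstance(X, CompressedGroupData) else np.asarray(X, dtype=float)
    if n_components > data.shape[1]:
        raise ValueError("n_components cannot exceed the compressed dimension")
    seeds = np.random.SeedSequence(seed).generate_state(n_restarts) % (2**31 - 1)
    runs = []
    failed = 0
    for s in seeds:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            ica = FastICA(
                n_components=n_components,
                random_state=int(s),
                max_iter=max_iter,
                tol=tol,
                whiten="unit-variance",
            )
            sources = ica.fit_transform(data)  # V x n_components
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            failed += 1
        runs.append((sources, ica.mixing_))
    # centrotype selection: mean best-|r| agreement with every other run
    if n_restarts > 1:
        std_runs = [_row_standardize(s.T)[0] for s, _ in runs]
        agreement = np.zeros(n_restarts)
        for i in range(n_restarts):
            for j in range(n_restarts):
                if i == j:
                    continue
                agreement[i] += np.abs(std_runs[i] @ std_runs[j].T).max(axis=1).mean()
        chosen = int(agreement.argmax())
    else:
        chosen = 0
    sources, mixing = runs[chosen]
    maps = _zscore_rows(sources.T)  # n_components x V
    A = mixing.T  # n_components x K

    subject_series: list[np.ndarray] = []
    if isinstance(X, CompressedGroupData):
        model = X.provenance
        for i in range(model.n_subjects):
            subject_series.append(A @ model.backprojector(i))
    return ICAResult(
        maps=maps,
        mixing=A,
        subject_timeseries=subject_series,
        n_restarts=n_restarts,
        failed_restarts=failed,
        chosen_restart=chosen,
    )
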