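"""Descriptor pre-filtering and cluster-based test-set selection.

Three elimination passes run before model selection, mirroring the usual
QSAR feature-selection workflow: columns with missing entries are dropped,
columns with too few non-zero entries are dropped, and of every pair of
columns correlated above an R-squared threshold the later one is dropped.
Each pass is a scikit-learn transformer so the whole chain composes with
``sklearn.pipeline.Pipeline``; module-level functions wrap them for one-shot
use and return a :class:`FilterReport`.

Test-set selection clusters the standardized (descriptors + activity) rows
by single-linkage hierarchical clustering on Euclidean distance, cuts the
tree into ``n_test`` clusters, and takes the medoid of each cluster as a
test compound.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "FilterReport",
    "MissingValueFilter",
    "ZeroFractionFilter",
    "CorrelationPruner",
    "missing_values_test",
    "zero_test",
    "correlation_prune",
    "select_test_set",
]


@dataclass
class FilterReport:
    """Record of every removal, with its reason."""

    removed_by_missing: list[str] = field(default_factory=list)
    removed_by_zero: list[tuple[str, float]] = field(default_factory=list)
    removed_by_constant: list[str] = field(default_factory=list)
    removed_by_correlation: list[tuple[str, str, float]] = field(default_factory=list)
    surviving: list[str] = field(default_factory=list)

    def merge(self, other: "FilterReport") -> "FilterReport":
        return FilterReport(
            removed_by_missing=self.removed_by_missing + other.removed_by_missing,
            removed_by_zero=self.removed_by_zero + other.removed_by_zero,
            removed_by_constant=self.removed_by_constant + other.removed_by_constant,
            removed_by_correlation=self.removed_by_correlation
            + other.removed_by_correlation,
            surviving=other.surviving,
        )

    def to_dict(self) -> dict:
        return {
            "removed_by_missing": self.removed_by_missing,
            "removed_by_zero": [
                {"name": n, "nonzero_fraction": f} for n, f in self.removed_by_zero
            ],
            "removed_by_constant": self.removed_by_constant,
            "removed_by_correlation": [
                {"kept": k, "dropped": d, "r2": r}
                for k, d, r in self.removed_by_correlation
            ],
            "surviving": self.surviving,
        }


def _column_names(X) -> list[str]:
    if isinstance(X, pd.DataFrame):
        return [str(c) for c in X.columns]
    return [f"x{i}" for i in range(np.asarray(X).shape[1])]


class _NamedFilter(BaseEstimator, TransformerMixin):
    """Shared plumbing: fit stores support_ and report_, transform selects."""

    def transform(self, X):
        check_is_fitted(self, "support_")
        if isinstance(X, pd.DataFrame):
            return X.loc[:, X.columns[self.support_]]
        return np.asarray(X)[:, self.support_]

    def get_support(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_.copy()


class MissingValueFilter(_NamedFilter):
    """Drops every column containing any missing value."""

    def fit(self, X, y=None):
        values = np.asarray(X, dtype=float)
        names = _column_names(X)
        self.support_ = ~np.any(np.isnan(values), axis=0)
        self.report_ = FilterReport(
            removed_by_missing=[n for n, k in zip(names, self.support_) if not k],
            surviving=[n for n, k in zip(names, self.support_) if k],
        )
        return self


class ZeroFractionFilter(_NamedFilter):
    """Drops columns whose fraction of non-zero entries is below threshold."""

    def __init__(self, min_nonzero_fraction: float = 0.1):
        self.min_nonzero_fraction = min_nonzero_fraction

    def fit(self, X, y=None):
        if not 0 < self.min_nonzero_fraction <= 1:
            raise ValueError("min_nonzero_fraction must be in (0, 1]")
        values = np.asarray(X, dtype=float)
        names = _column_names(X)
        frac = np.mean(values != 0, axis=0)
        self.support_ = frac >= self.min_nonzero_fraction
        self.report_ = FilterReport(
            removed_by_zero=[
                (n, float(f)) for n, f, k in zip(names, frac, self.support_) if not k
            ],
            surviving=[n for n, k in zip(names, self.support_) if k],
        )
        return self


class CorrelationPruner(_NamedFilter):
    """Greedy pairwise-correlation pruning in fixed column order.

    Zero-variance columns are dropped first. Then, scanning columns left to
    right, a column is dropped if its squared Pearson correlation with any
    earlier surviving column exceeds the threshold; the earlier column is
    kept. The surviving set therefore has all pairwise R-squared at or below
    the threshold, and the result does not depend on column scaling.
    """

    def __init__(self, r2_threshold: float = 0.7):
        self.r2_threshold = r2_threshold

    def fit(self, X, y=None):
        values = np.asarray(X, dtype=float)
        names = _column_names(X)
        n_cols = values.shape[1]
        if n_cols < 2:
            raise ValueError("correlation pruning needs at least 2 columns")
        sd = values.std(axis=0)
        support = sd > 0
        report = FilterReport(
            removed_by_constant=[n for n, k in zip(names, support) if not k]
        )
        live = np.flatnonzero(support)
        if len(live) >= 2:
            corr = np.corrcoef(values[:, live], rowvar=False) ** 2
            kept: list[int] = []
            for pos, col in enumerate(live):
                clash = next(
                    (kpos for kpos in kept if corr[pos, kpos] > self.r2_threshold),
                    None,
                )
                if clash is None:
                    kept.append(pos)
                else:
                    support[col] = False
                    report.removed_by_correlation.append(
                        (names[live[clash]], names[col], float(corr[pos, clash]))
                    )
        report.surviving = [n for n, k in zip(names, support) if k]
        self.support_ = support
        self.report_ = report
        return self


def missing_values_test(matrix) -> FilterReport:
    return MissingValueFilter().fit(matrix).report_


def zero_test(matrix, min_nonzero_fraction: float = 0.1) -> FilterReport:
    return ZeroFractionFilter(min_nonzero_fraction).fit(matrix).report_


def correlation_prune(matrix, r2_threshold: float = 0.7) -> FilterReport:
    return CorrelationPruner(r2_threshold).fit(matrix).report_


def select_test_set(
    matrix,
    activity,
    n_test: int,
    linkage_rule: str = "single",
) -> np.ndarray:
    """Indices of ``n_test`` cluster-representative test compounds.

    Descriptors and activity are z-scored column-wise, clustered by
    hierarchical clustering (Euclidean distance, single linkage by default),
    and the tree is cut into ``n_test`` clusters; the medoid of each cluster
    (lowest row index on ties) is returned, sorted ascending.
    """
    X = np.asarray(matrix, dtype=float)
    y = np.asarray(activity, dtype=float).reshape(-1, 1)
    n = X.shape[0]
    if not 1 <= n_test < n:
        raise ValueError(f"n_test must be in [1, {n - 1}], got {n_test}")
    Z = np.hstack([X, y])
    sd = Z.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (Z - Z.mean(axis=0)) / sd
    if linkage_rule not in ("single", "complete"):
        raise ValueError("linkage_rule must be 'single' or 'complete'")
    labels = fcluster(linkage(Z, method=linkage_rule), t=n_test, criterion="maxclust")
    picks = []
    for lab in np.unique(labels):
        members = np.flatnonzero(labels == lab)
        sub = Z[members]
        d = np.linalg.norm(sub[:, None, :] - sub[None, :, :], axis=-1)
        total = d.sum(axis=1)
        # argmin takes the first minimum, i.e. the lowest index on ties
        picks.append(int(members[np.argmin(total)]))
    return np.array(sorted(picks), dtype=int)
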