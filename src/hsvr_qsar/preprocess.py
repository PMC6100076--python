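"""Descriptor filtering, autoscaling, Kennard-Stone partitioning, and
chemical-space diagnostics.

The filtering and scaling steps are scikit-learn transformers operating on
named pandas DataFrames; the Kennard-Stone split is a deterministic design
function returning an auditable pick sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "FilterReport",
    "PartitionResult",
    "DescriptorFilter",
    "Autoscaler",
    "kennard_stone_split",
    "random_split",
    "chemical_space_stats",
    "similarity_check",
]


class EmptyFeatureSpaceError(ValueError):
    """Raised when filtering removes every descriptor."""


@dataclass
class FilterReport:
    """Audit trail of every descriptor-removal decision."""

    dropped_missing: list[str] = field(default_factory=list)
    dropped_low_variance: list[str] = field(default_factory=list)
    dropped_intercorrelated: list[tuple[str, str, float]] = field(default_factory=list)
    surviving: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "dropped_missing": self.dropped_missing,
            "dropped_low_variance": self.dropped_low_variance,
            "dropped_intercorrelated": [
                {"kept": k, "dropped": d, "r2": r2}
                for k, d, r2 in self.dropped_intercorrelated
            ],
            "surviving": self.surviving,
        }


class DescriptorFilter(TransformerMixin, BaseEstimator):
    """Remove uninformative and redundant descriptors.

    Three passes, each recorded in ``report_``:

    1. descriptors missing for at least one sample;
    2. descriptors with little or no discrimination (fewer than two
       distinct values, or variance at or below ``variance_floor``);
    3. of every pair with squared Pearson intercorrelation above
       ``r2_threshold``, only one is kept — the one more correlated in
       absolute value with the response when a response is supplied at
       fit time, otherwise the earlier column.

    Filtering an already-filtered table is a no-op (idempotent).
    """

    def __init__(self, r2_threshold: float = 0.8, variance_floor: float = 1e-8):
        self.r2_threshold = r2_threshold
        self.variance_floor = variance_floor

    def fit(self, X: pd.DataFrame, y: Sequence[float] | None = None) -> "DescriptorFilter":
        if X.shape[1] == 0 or X.shape[0] == 0:
            raise ValueError("empty descriptor table")
        if X.columns.duplicated().any():
            dupes = X.columns[X.columns.duplicated()].tolist()
            raise ValueError(f"duplicate descriptor names: {dupes}")
        report = FilterReport()
        yv = None if y is None else np.asarray(y, dtype=float).ravel()

        keep: list[str] = []
        for name in X.columns:
            col = X[name]
            if col.isna().any():
                report.dropped_missing.append(name)
            elif col.nunique() < 2 or float(col.var(ddof=1)) <= self.variance_floor:
                report.dropped_low_variance.append(name)
            else:
                keep.append(name)

        # intercorrelation pruning: repeatedly resolve the most correlated
        # surviving pair above threshold (deterministic order)
        def resp_corr(name: str) -> float:
            if yv is None or np.std(yv) == 0:
                return 0.0
            c = np.corrcoef(X[name].to_numpy(dtype=float), yv)[0, 1]
            return abs(float(c)) if np.isfinite(c) else 0.0

        while len(keep) > 1:
            vals = X.loc[:, keep].to_numpy(dtype=float)
            corr = np.corrcoef(vals, rowvar=False)
            r2 = corr**2
            np.fill_diagonal(r2, 0.0)
            i, j = divmod(int(np.argmax(r2)), r2.shape[1])
            if r2[i, j] <= self.r2_threshold:
                break
            if i > j:
                i, j = j, i
            a, b = keep[i], keep[j]
            ca, cb = resp_corr(a), resp_corr(b)
            kept, dropped = (a, b) if ca >= cb else (b, a)
            report.dropped_intercorrelated.append((kept, dropped, float(r2[i, j])))
            keep.remove(dropped)

        if not keep:
            raise EmptyFeatureSpaceError("all descriptors removed by filtering")
        report.surviving = list(keep)
        self.report_ = report
        self.surviving_ = list(keep)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "surviving_")
        missing = [n for n in self.surviving_ if n not in X.columns]
        if missing:
            raise KeyError(f"descriptor(s) missing from input table: {missing}")
        return X.loc[:, self.surviving_].copy()


class Autoscaler(TransformerMixin, BaseEstimator):
    """Autoscaling to zero mean and unit sample standard deviation.

    Each descriptor j is transformed as (x_ij - <x_j>) / s_j with s_j the
    sample standard deviation (n-1 denominator) estimated at fit time.
    Transformation aligns columns by name; zero-variance columns must be
    filtered beforehand and raise here.
    """

    def fit(self, X: pd.DataFrame, y=None) -> "Autoscaler":
        self.feature_names_in_ = [str(c) for c in X.columns]
        vals = X.to_numpy(dtype=float)
        self.mean_ = vals.mean(axis=0)
        self.scale_ = vals.std(axis=0, ddof=1)
        if np.any(self.scale_ <= 0) or np.any(~np.isfinite(self.scale_)):
            bad = [n for n, s in zip(self.feature_names_in_, self.scale_) if not s > 0]
            raise ValueError(f"zero-variance descriptor(s), filter first: {bad}")
        return self

    def _align(self, X: pd.DataFrame) -> pd.DataFrame:
        missing = [n for n in self.feature_names_in_ if n not in X.columns]
        if missing:
            raise KeyError(f"descriptor(s) missing from input table: {missing}")
        extra = [n for n in X.columns if n not in self.feature_names_in_]
        if extra:
            raise KeyError(f"unseen descriptor name(s) at apply time: {extra}")
        return X.loc[:, self.feature_names_in_]

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "mean_")
        aligned = self._align(X)
        out = (aligned.to_numpy(dtype=float) - self.mean_) / self.scale_
        return pd.DataFrame(out, index=X.index, columns=self.feature_names_in_)

    def inverse_transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "mean_")
        aligned = self._align(X)
        out = aligned.to_numpy(dtype=float) * self.scale_ + self.mean_
        return pd.DataFrame(out, index=X.index, columns=self.feature_names_in_)


@dataclass
class PartitionResult:
    """Train/test assignment with the Kennard-Stone pick sequence."""

    train_ids: list[str]
    test_ids: list[str]
    selection_order: list[str]
    distance_metric: str = "euclidean"

    def to_frame(self) -> pd.DataFrame:
        rows = [{"id": i, "set": "train"} for i in self.train_ids]
        rows += [{"id": i, "set": "test"} for i in self.test_ids]
        return pd.DataFrame(rows)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def kennard_stone_split(
    X: pd.DataFrame, train_fraction: float = 0.8
) -> PartitionResult:
    """Deterministic max-min Kennard-Stone train/test partition.

    Distances are Euclidean in the (already normalized) descriptor space.
    The first two picks are the globally most distant pair; each further
    pick maximizes its minimum distance to the selected set.  Ties always
    resolve to the lowest row index, so the partition is fully
    deterministic.  Training size is round-half-up(train_fraction * n).
    """
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples to partition")
    if not 0.0 < train_fraction <= 1.0:
        raise ValueError("train_fraction must be in (0, 1]")
    ids = [str(i) for i in X.index]
    n_train = min(n, max(2, _round_half_up(train_fraction * n)))
    dist = squareform(pdist(X.to_numpy(dtype=float), metric="euclidean"))

    # the first pair: globally most distant, lexicographically first on ties
    iu = np.triu_indices(n, k=1)
    flat = dist[iu]
    best = int(np.argmax(flat))
    first, second = int(iu[0][best]), int(iu[1][best])
    selected = [first, second]
    remaining = [i for i in range(n) if i not in selected]

    while len(selected) < n_train and remaining:
        min_d = dist[np.ix_(remaining, selected)].min(axis=1)
        pick = remaining[int(np.argmax(min_d))]  # argmax takes first max: lowest index
        selected.append(pick)
        remaining.remove(pick)

    order = [ids[i] for i in selected]
    test_ids = [ids[i] for i in range(n) if i not in selected]
    return PartitionResult(
        train_ids=[ids[i] for i in sorted(selected)],
        test_ids=test_ids,
        selection_order=order,
    )


def random_split(
    X: pd.DataFrame, train_fraction: float = 0.8, seed: int = 0
) -> PartitionResult:
    """Seeded random partition (alternative to Kennard-Stone)."""
    n = X.shape[0]
    ids = [str(i) for i in X.index]
    n_train = min(n, max(2, _round_half_up(train_fraction * n)))
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    chosen = sorted(int(i) for i in order[:n_train])
    return PartitionResult(
        train_ids=[ids[i] for i in chosen],
        test_ids=[ids[i] for i in range(n) if i not in chosen],
        selection_order=[ids[int(i)] for i in order[:n_train]],
        distance_metric="random",
    )


def chemical_space_stats(X: pd.DataFrame, n_components: int = 3) -> dict:
    """Descriptive chemical-space diagnostics.

    Returns the leading principal-component variance-explained fractions,
    the mean and sample sd of each sample's nearest-neighbor distance, and
    the maximum pairwise distance.
    """
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least 3 samples")
    k = min(n_components, min(n - 1, p))
    if k < n_components:
        warnings.warn(
            f"only {k} principal components available; truncating from {n_components}",
            UserWarning,
            stacklevel=2,
        )
    pca = PCA(n_components=k)
    pca.fit(X.to_numpy(dtype=float))
    dist = squareform(pdist(X.to_numpy(dtype=float)))
    np.fill_diagonal(dist, np.inf)
    nn = dist.min(axis=1)
    finite = dist[np.isfinite(dist)]
    return {
        "explained_variance_ratio": [float(v) for v in pca.explained_variance_ratio_],
        "total_explained": float(np.sum(pca.explained_variance_ratio_)),
        "nn_distance_mean": float(nn.mean()),
        "nn_distance_sd": float(np.std(nn, ddof=1)),
        "max_distance": float(finite.max()),
        "n_samples": n,
        "n_descriptors": p,
        "sample_to_descriptor_ratio": float(n / p),
    }


def _interval_overlap(lo1, hi1, lo2, hi2) -> float:
    """Jaccard overlap of two closed intervals; 1.0 for identical points."""
    inter = max(0.0, min(hi1, hi2) - max(lo1, lo2))
    union = max(hi1, hi2) - min(lo1, lo2)
    if union == 0.0:
        return 1.0 if (lo1 == lo2) else 0.0
    # count touching identical degenerate intervals as overlapping
    if inter == 0.0 and min(hi1, hi2) >= max(lo1, lo2):
        return 0.0 if union > 0 else 1.0
    return inter / union


def similarity_check(
    train: pd.DataFrame,
    test: pd.DataFrame,
    train_response: Sequence[float] | None = None,
    test_response: Sequence[float] | None = None,
) -> dict:
    """Distributional train/test similarity report (descriptive only).

    For every shared feature (and the response when supplied) reports the
    range-overlap fraction and two-sample means/sds.  No pass/fail.
    """
    shared = [c for c in train.columns if c in test.columns]
    out: dict[str, dict] = {}

    def summarize(a: np.ndarray, b: np.ndarray) -> dict:
        return {
            "overlap": _interval_overlap(a.min(), a.max(), b.min(), b.max()),
            "train_mean": float(a.mean()),
            "train_sd": float(np.std(a, ddof=1)) if a.size > 1 else 0.0,
            "test_mean": float(b.mean()),
            "test_sd": float(np.std(b, ddof=1)) if b.size > 1 else 0.0,
        }

    for name in shared:
        out[name] = summarize(
            train[name].to_numpy(dtype=float), test[name].to_numpy(dtype=float)
        )
    if train_response is not None and test_response is not None:
        out["__response__"] = summarize(
            np.asarray(train_response, dtype=float),
            np.asarray(test_response, dtype=float),
        )
    return out
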