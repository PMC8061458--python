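"""Feature-hashing projection and PCA for large Beta matrices.

Array-wide PCA over ~half a million probes is made tractable by first
hashing probe ids into a d-dimensional intermediate space (the "hashing
trick"): each probe maps deterministically to a bucket and a sign, and a
sample's hashed vector is the signed sum of its Beta-values per bucket.
Signed hashing keeps inner products unbiased, so the PCA geometry of the
projected data is trustworthy; embeddings at d = 1000 and d = 10000 agree
closely in practice.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "HashedProjection",
    "SignedFeatureHasher",
    "hash_project",
    "HashedPCA",
    "pca_embed",
    "group_variance_ratio",
]


@dataclass(frozen=True)
class HashedProjection:
    """Deterministic probe-id -> (bucket, sign) mapping contract."""

    d: int = 1000
    seed: int = 0
    signed: bool = True

    def mapping(self, probe_ids) -> tuple[np.ndarray, np.ndarray]:
        buckets = np.empty(len(probe_ids), dtype=np.int64)
        signs = np.empty(len(probe_ids), dtype=np.int8)
        for i, pid in enumerate(probe_ids):
            digest = hashlib.blake2b(
                f"{self.seed}:{pid}".encode(), digest_size=8
            ).digest()
            value = int.from_bytes(digest, "little")
            buckets[i] = (value >> 1) % self.d
            signs[i] = 1 if (self.signed and value & 1 == 0) or not self.signed else -1
        return buckets, signs


class SignedFeatureHasher(BaseEstimator, TransformerMixin):
    """Project samples x probes data into d hashed buckets.

    The mapping depends only on (probe id, seed), so it is stable across
    cohorts; the transform is linear: h(x + y) = h(x) + h(y).
    """

    def __init__(self, d: int = 1000, seed: int = 0, signed: bool = True):
        self.d = d
        self.seed = seed
        self.signed = signed

    def fit(self, X: pd.DataFrame, y=None):
        proj = HashedProjection(d=self.d, seed=self.seed, signed=self.signed)
        buckets, signs = proj.mapping(list(X.columns))
        n_probes = X.shape[1]
        self.projection_ = proj
        self.matrix_ = sparse.csr_matrix(
            (signs.astype(float), (np.arange(n_probes), buckets)),
            shape=(n_probes, self.d),
        )
        self.feature_names_in_ = np.asarray(X.columns)
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "matrix_")
        arr = np.asarray(X, dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError(
                "missing values in input: impute (per-sample median) before hashing"
            )
        return np.asarray(self.matrix_.T.dot(arr.T)).T


def hash_project(beta: pd.DataFrame, proj: HashedProjection) -> pd.DataFrame:
    """Hash a probes x samples Beta matrix into samples x d (thin wrapper)."""
    hasher = SignedFeatureHasher(d=proj.d, seed=proj.seed, signed=proj.signed)
    out = hasher.fit(beta.T).transform(beta.T)
    return pd.DataFrame(out, index=beta.columns)


class HashedPCA(BaseEstimator, TransformerMixin):
    """Centered PCA of hashed data with a fixed sign convention.

    Components are oriented so the largest-magnitude loading is positive,
    making scores reproducible across SVD implementations. ``k`` is truncated
    (with a warning) when it exceeds the matrix rank.
    """

    def __init__(self, k: int = 2):
        self.k = k

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.shape[0] < 2:
            raise ValueError("need >= 2 samples")
        rank = min(X.shape[0] - 1, X.shape[1])
        k = self.k
        if k > rank:
            warnings.warn(f"k={k} exceeds rank {rank}; truncated", RuntimeWarning)
            k = rank
        self.pca_ = PCA(n_components=k, svd_solver="full")
        scores = self.pca_.fit_transform(X)
        flips = np.ones(k)
        for j in range(k):
            loading = self.pca_.components_[j]
            if loading[np.argmax(np.abs(loading))] < 0:
                flips[j] = -1.0
        self.flips_ = flips
        self.k_ = k
        self.scores_ = scores * flips
        total_var = np.asarray(X).var(axis=0, ddof=1).sum()
        self.variance_fractions_ = (
            self.pca_.explained_variance_ / total_var if total_var > 0 else
            np.zeros(k)
        )
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "pca_")
        return self.pca_.transform(np.asarray(X, dtype=float)) * self.flips_


def pca_embed(hashed: pd.DataFrame | np.ndarray, k: int = 2):
    """Scores and per-component variance fractions (thin wrapper)."""
    est = HashedPCA(k=k).fit(np.asarray(hashed, dtype=float))
    index = hashed.index if isinstance(hashed, pd.DataFrame) else None
    scores = pd.DataFrame(
        est.scores_, index=index, columns=[f"PC{i+1}" for i in range(est.k_)]
    )
    return scores, est.variance_fractions_


def group_variance_ratio(
    scores: pd.DataFrame, groups: pd.Series, group_a: str, group_b: str,
    component: str = "PC1",
) -> dict:
    """Variance ratio of two groups along one component with an F-test.

    Two-sided p with (nA - 1, nB - 1) degrees of freedom.
    """
    groups = groups.reindex(scores.index)
    a = scores.loc[groups == group_a, component].to_numpy(dtype=float)
    b = scores.loc[groups == group_b, component].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need >= 2 samples")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 or vb == 0:
        raise ValueError("degenerate group variance 0")
    ratio = va / vb
    dfa, dfb = len(a) - 1, len(b) - 1
    cdf = stats.f.cdf(ratio, dfa, dfb)
    p = 2 * min(cdf, 1 - cdf)
    return {"ratio": float(ratio), "p_value": float(min(p, 1.0)),
            "df": (dfa, dfb)}
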