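"""Feature normalization and Z-score fusion of the LBP and ORB blocks.

LBP histogram counts are first scaled into [0, 1] by dividing by the
vector maximum (L = l / max l).  Each feature block (LBP, then ORB) is
then standardized independently over its own entries,

    f_hat_j = K * (f_j - mu) / sigma + C

with mu the block mean and sigma the *population* standard deviation of
the block, and the standardized blocks are concatenated LBP-first.  K
(default 100) sets the common spread of the fused vector and C (default
0) its offset, putting the two heterogeneous feature families on one
scale before the SVM.  A zero-variance block maps to the constant C.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

DEFAULT_K = 100.0
DEFAULT_C = 0.0


def max_normalize(v: np.ndarray) -> np.ndarray:
    """Scale a nonnegative vector into [0, 1] by its maximum.

    The all-zero vector maps to itself; negative entries are a domain
    error (LBP histogram counts are nonnegative by construction).
    """
    arr = np.asarray(v, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot normalize an empty vector")
    if np.any(arr < 0):
        raise ValueError("max-normalization is defined for nonnegative vectors")
    m = arr.max()
    return arr / m if m > 0 else arr.copy()


def zscore_block(block: np.ndarray, K: float = DEFAULT_K, C: float = DEFAULT_C) -> np.ndarray:
    """Standardize one block to mean C and population SD K."""
    arr = np.asarray(block, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot standardize an empty block")
    mu = arr.mean()
    sigma = arr.std()  # population SD
    if sigma == 0:
        return np.full_like(arr, C)
    return K * (arr - mu) / sigma + C


@dataclass(frozen=True)
class FusedFeature:
    """Z-score fused feature vector with block provenance."""

    values: np.ndarray
    lbp_len: int
    K: float = DEFAULT_K
    C: float = DEFAULT_C

    @property
    def lbp_block(self) -> np.ndarray:
        return self.values[: self.lbp_len]

    @property
    def orb_block(self) -> np.ndarray:
        return self.values[self.lbp_len :]

    def __len__(self) -> int:
        return self.values.size


def zscore_fuse(
    lbp: np.ndarray,
    orb: np.ndarray,
    K: float = DEFAULT_K,
    C: float = DEFAULT_C,
) -> FusedFeature:
    """Fuse an LBP vector and an ORB bit vector into one standardized vector.

    Each block is standardized over its own entries (per-vector scope) and
    the results concatenated LBP-first.  Standardization is scale-free, so
    whether the LBP block was max-normalized beforehand does not change
    the result; the normalization step is kept in the pipeline for
    fidelity to the feature-preparation flow.
    """
    lbp_z = zscore_block(lbp, K, C)
    orb_z = zscore_block(orb, K, C)
    return FusedFeature(
        values=np.concatenate([lbp_z, orb_z]), lbp_len=lbp_z.size, K=K, C=C
    )


class BlockZScoreFuser(BaseEstimator, TransformerMixin):
    """Transformer standardizing row-wise feature blocks and concatenating.

    X is the horizontally stacked (n_samples, d_lbp + d_orb) matrix;
    `lbp_len` marks the block boundary (None or 0 treats the whole row as
    one block, the single-family ablation mode).  `scope="vector"`
    standardizes each sample's blocks over their own entries (the default
    per-vector reading); `scope="dataset"` standardizes each column over
    the fitted training set instead.
    """

    def __init__(self, lbp_len: int | None = None, K: float = DEFAULT_K,
                 C: float = DEFAULT_C, scope: str = "vector"):
        self.lbp_len = lbp_len
        self.K = K
        self.C = C
        self.scope = scope

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if self.scope not in ("vector", "dataset"):
            raise ValueError(f"unknown scope {self.scope!r}")
        self.n_features_in_ = X.shape[1]
        if self.scope == "dataset":
            self.mean_ = X.mean(axis=0)
            self.scale_ = X.std(axis=0)
            self.scale_[self.scale_ == 0] = 1.0
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if self.scope == "dataset":
            return self.K * (X - self.mean_) / self.scale_ + self.C
        boundary = self.lbp_len or X.shape[1]
        out = np.empty_like(X)
        for i, row in enumerate(X):
            out[i, :boundary] = zscore_block(row[:boundary], self.K, self.C)
            if boundary < X.shape[1]:
                out[i, boundary:] = zscore_block(row[boundary:], self.K, self.C)
        return out
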