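"""Uniform-pattern local binary patterns and patch-histogram features.

The LBP code of a pixel thresholds its 8 neighbors at the center value:

    LBP(x_c, y_c) = sum_{n=0..7} 2^n * s(i_n - i_c),   s(u) = 1 if u >= 0

so only the *signs* of local intensity differences matter, which makes the
code invariant to monotone illumination changes.  A code is *uniform* when
its circular bit string has at most one 0->1 and one 1->0 transition;
exactly 58 of the 256 codes are uniform, and pooling all non-uniform codes
into a single bin yields a 59-bin histogram per image patch.

On the 130x130 face, codes are computed at every interior pixel giving a
128x128 code map, which is tiled into 16x16-pixel patches (an 8x8 grid);
concatenating the 64 per-patch 59-bin histograms gives the
64 * 59 = 3776-dimensional LBP feature vector.

Neighbor bit order (n = 0..7) is fixed clockwise from the top-left of the
3x3 neighborhood: (-1,-1), (-1,0), (-1,+1), (0,+1), (+1,+1), (+1,0),
(+1,-1), (0,-1), as (row, col) offsets.  Any fixed order permutes bits
without changing uniform-pattern membership.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

# (row, col) neighbor offsets for bits n = 0..7, clockwise from top-left.
NEIGHBOR_OFFSETS = (
    (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1),
)

N_BINS = 59  # 58 uniform codes + 1 pooled non-uniform bin


def circular_transitions(code: int) -> int:
    """Number of 0<->1 transitions in the circular 8-bit string of `code`."""
    bits = [(code >> n) & 1 for n in range(8)]
    return sum(bits[n] != bits[(n + 1) % 8] for n in range(8))


def is_uniform(code: int) -> bool:
    """A code is uniform when its circular bit string has <= 2 transitions."""
    return circular_transitions(code) <= 2


def uniform_bin_map() -> np.ndarray:
    """Lookup table (256,) sending each code to its histogram bin.

    The 58 uniform codes map, in ascending code order, to bins 0..57;
    every non-uniform code maps to the pooled bin 58.
    """
    table = np.full(256, N_BINS - 1, dtype=np.int64)
    rank = 0
    for code in range(256):
        if is_uniform(code):
            table[code] = rank
            rank += 1
    assert rank == 58
    return table


_UNIFORM_TABLE = uniform_bin_map()


def uniform_bin(code: int) -> int:
    """Histogram bin (0..58) of an LBP code (0..255)."""
    if not 0 <= code <= 255:
        raise ValueError(f"LBP code must be in [0, 255], got {code}")
    return int(_UNIFORM_TABLE[code])


def lbp_code(neighborhood: np.ndarray) -> int:
    """LBP code of a single 3x3 intensity patch (center = element [1, 1])."""
    patch = np.asarray(neighborhood, dtype=float)
    if patch.shape != (3, 3):
        raise ValueError(f"expected a 3x3 patch, got shape {patch.shape}")
    center = patch[1, 1]
    code = 0
    for n, (dr, dc) in enumerate(NEIGHBOR_OFFSETS):
        if patch[1 + dr, 1 + dc] - center >= 0:
            code |= 1 << n
    return code


def lbp_face(face: np.ndarray) -> np.ndarray:
    """Code map over all interior pixels of a 130x130 face -> 128x128.

    Border pixels serve only as neighbors.  Vectorized: for each of the 8
    offsets, one shifted comparison against the interior contributes one
    bit plane.
    """
    img = np.asarray(face, dtype=np.int64)
    if img.ndim != 2 or img.shape[0] < 3 or img.shape[1] < 3:
        raise ValueError(f"expected a 2-D image of at least 3x3, got shape {img.shape}")
    center = img[1:-1, 1:-1]
    codes = np.zeros_like(center)
    for n, (dr, dc) in enumerate(NEIGHBOR_OFFSETS):
        neighbor = img[1 + dr : img.shape[0] - 1 + dr, 1 + dc : img.shape[1] - 1 + dc]
        codes |= ((neighbor - center) >= 0).astype(np.int64) << n
    return codes


def lbp_features(
    code_map: np.ndarray,
    patch_size: int = 16,
    bin_map: np.ndarray | None = None,
) -> np.ndarray:
    """Concatenated per-patch uniform-pattern histograms of a code map.

    Patches are enumerated row-major over a (H/patch, W/patch) grid; each
    contributes a 59-bin histogram of its binned codes (raw counts, each
    block summing to patch_size**2).

    Returns
    -------
    ndarray of shape ((H/patch)*(W/patch)*59,), dtype float64.
    """
    codes = np.asarray(code_map)
    h, w = codes.shape
    if h % patch_size or w % patch_size:
        raise ValueError(
            f"patch_size {patch_size} must divide code-map shape {codes.shape}"
        )
    table = _UNIFORM_TABLE if bin_map is None else np.asarray(bin_map)
    binned = table[codes]
    gh, gw = h // patch_size, w // patch_size
    blocks = binned.reshape(gh, patch_size, gw, patch_size).transpose(0, 2, 1, 3)
    hists = [
        np.bincount(blocks[i, j].ravel(), minlength=N_BINS)
        for i in range(gh)
        for j in range(gw)
    ]
    return np.concatenate(hists).astype(float)


class LBPFeaturizer(BaseEstimator, TransformerMixin):
    """Transformer: (n, 130, 130) face stack -> (n, n_patches*59) LBP features.

    Parameters
    ----------
    patch_size : int
        Side of the square histogram patches on the 128x128 code map.
        16 (the default) gives an 8x8 patch grid and 3776 features.
    """

    def __init__(self, patch_size: int = 16):
        self.patch_size = patch_size

    def fit(self, X, y=None):
        X = np.asarray(X)
        self.n_features_in_ = X.shape[1] * X.shape[2] if X.ndim == 3 else None
        map_side = X.shape[1] - 2
        self.n_patches_ = (map_side // self.patch_size) ** 2
        return self

    def transform(self, X):
        X = np.asarray(X)
        return np.stack([lbp_features(lbp_face(face), self.patch_size) for face in X])
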