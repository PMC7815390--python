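"""Region-balanced ORB: FAST corners, intensity-centroid orientation,
and orientation-steered 256-bit BRIEF descriptors.

The FAST segment test declares pixel p a corner when at least 12
contiguous pixels on the 16-pixel Bresenham circle around p are all
brighter than I_p + t or all darker than I_p - t.  Surviving corners are
scored by

    score = max( sum_{x in S_bright} (I_x - I_p - t),
                 sum_{x in S_dark}   (I_p - I_x - t) )

and thinned by non-maximal suppression (strict 3x3 local maximum of the
score, ties broken by row-major position).

Plain FAST concentrates keypoints wherever texture is densest.  To spread
them, the image is divided evenly into an M x N grid with a per-region
budget T = floor(n / (M*N)); regions that fall short have their threshold
halved (down to 1) and are re-scanned.  The budget remainder goes
one-each to the regions with the strongest surplus candidates, and any
residual deficit is filled from leftover candidates image-wide so the
total is exactly n whenever enough corners exist at the minimum
threshold.

Each kept corner gets an orientation from the intensity centroid of its
circular patch (theta = atan2(m01, m10)) and a 256-bit BRIEF descriptor:
pairwise comparisons of 5x5-box-smoothed intensities at Gaussian-placed
offsets inside a 31x31 window, the offsets rotated by theta ("steered")
so descriptors of a rotated face stay comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator, TransformerMixin

# 16-pixel Bresenham circle of radius 3, (row, col) offsets, clockwise
# from the top pixel — the standard segment-test ring.
FAST_CIRCLE = (
    (-3, 0), (-3, 1), (-2, 2), (-1, 3), (0, 3), (1, 3), (2, 2), (3, 1),
    (3, 0), (3, -1), (2, -2), (1, -3), (0, -3), (-1, -3), (-2, -2), (-3, -1),
)
FAST_ARC = 12          # required contiguous run length
CIRCLE_RADIUS = 3

BRIEF_BITS = 256
BRIEF_WINDOW = 31      # effective window after boundary removal
BRIEF_SUBIMAGE = 35    # raw subimage before the 5x5 smoothing margin
SMOOTH_SIZE = 5
DESCRIPTOR_MARGIN = (BRIEF_SUBIMAGE - 1) // 2  # 17: keep the full window inside

DEFAULT_PATTERN_SEED = 20210112


class BorderError(ValueError):
    """Raised when a point is too close to the image border for an operator."""


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class Corner:
    """A retained FAST keypoint."""

    row: int
    col: int
    score: float
    theta: float = 0.0
    region_index: int = 0


@dataclass(frozen=True)
class RegionGrid:
    """Even M x N division of the image with a total keypoint budget n."""

    M: int = 4
    N: int = 4
    n: int = 160

    def __post_init__(self):
        if self.M < 1 or self.N < 1 or self.n < 1:
            raise ConfigurationError("M, N and n must all be >= 1")
        if self.M * self.N > self.n:
            raise ConfigurationError(
                f"number of regions {self.M * self.N} exceeds keypoint budget {self.n}"
            )

    @property
    def per_region(self) -> int:
        """Base per-region budget T = floor(n / (M*N))."""
        return self.n // (self.M * self.N)


@dataclass(frozen=True)
class SamplingPattern:
    """The 256 Gaussian-placed BRIEF comparison pairs.

    Offsets (r1, c1, r2, c2) are relative to the keypoint, drawn i.i.d.
    from Gaussian(0, S^2/25) with S the 31-pixel window, clipped to the
    window, and frozen by seed so every run of the library produces the
    identical descriptor layout.
    """

    pairs: np.ndarray = field(repr=False)
    patch_size: int = BRIEF_WINDOW
    seed: int = DEFAULT_PATTERN_SEED

    @classmethod
    def generate(
        cls,
        seed: int = DEFAULT_PATTERN_SEED,
        n_pairs: int = BRIEF_BITS,
        patch_size: int = BRIEF_WINDOW,
    ) -> "SamplingPattern":
        rng = np.random.default_rng(seed)
        half = (patch_size - 1) // 2
        sd = patch_size / 5.0  # variance S^2 / 25
        coords = rng.normal(0.0, sd, size=(n_pairs, 4))
        pairs = np.clip(np.rint(coords), -half, half).astype(np.int64)
        return cls(pairs=pairs, patch_size=patch_size, seed=seed)


def _circle_values(image: np.ndarray, row: int, col: int) -> np.ndarray:
    return np.array([image[row + dr, col + dc] for dr, dc in FAST_CIRCLE], dtype=float)


def _check_circle_fits(image: np.ndarray, row: int, col: int) -> None:
    h, w = image.shape
    r = CIRCLE_RADIUS
    if not (r <= row < h - r and r <= col < w - r):
        raise BorderError(
            f"point ({row}, {col}) closer than {r} pixels to the border of {image.shape}"
        )


def fast_is_corner(image: np.ndarray, p: tuple[int, int], t: float) -> bool:
    """Segment test at a single pixel: 12 contiguous circle pixels all
    >= I_p + t (bright) or all <= I_p - t (dark)."""
    img = np.asarray(image, dtype=float)
    row, col = p
    _check_circle_fits(img, row, col)
    center = img[row, col]
    vals = _circle_values(img, row, col)
    for mask in ((vals >= center + t), (vals <= center - t)):
        ext = np.concatenate([mask, mask[: FAST_ARC - 1]])
        run = 0
        for m in ext:
            run = run + 1 if m else 0
            if run >= FAST_ARC:
                return True
    return False


def fast_score(image: np.ndarray, p: tuple[int, int], t: float) -> float:
    """Score of a candidate corner: larger of the summed bright / dark
    excesses beyond the +-t band around I_p (0 when both sets are empty)."""
    img = np.asarray(image, dtype=float)
    row, col = p
    _check_circle_fits(img, row, col)
    center = img[row, col]
    vals = _circle_values(img, row, col)
    bright = vals[vals >= center + t] - center - t
    dark = center - vals[vals <= center - t] - t
    return float(max(bright.sum() if bright.size else 0.0,
                     dark.sum() if dark.size else 0.0))


def _fast_response(image: np.ndarray, t: float) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized segment test + score over all circle-fitting pixels.

    Returns (corner_mask, score) full-size arrays; entries within 3 px of
    the border are always False / 0.
    """
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    r = CIRCLE_RADIUS
    ih, iw = h - 2 * r, w - 2 * r
    corner = np.zeros((h, w), dtype=bool)
    score = np.zeros((h, w), dtype=float)
    if ih <= 0 or iw <= 0:
        return corner, score
    center = img[r : h - r, r : w - r]
    ring = np.empty((16, ih, iw))
    for k, (dr, dc) in enumerate(FAST_CIRCLE):
        ring[k] = img[r + dr : r + dr + ih, r + dc : r + dc + iw]
    bright = ring >= center + t
    dark = ring <= center - t
    hit = np.zeros((ih, iw), dtype=bool)
    for mask in (bright, dark):
        ext = np.concatenate([mask, mask[: FAST_ARC - 1]], axis=0).astype(np.int8)
        cs = np.cumsum(ext, axis=0)
        for s in range(16):
            top = cs[s + FAST_ARC - 1] - (cs[s - 1] if s else 0)
            hit |= top == FAST_ARC
    bright_sum = np.where(bright, ring - center - t, 0.0).sum(axis=0)
    dark_sum = np.where(dark, center - ring - t, 0.0).sum(axis=0)
    corner[r : h - r, r : w - r] = hit
    score[r : h - r, r : w - r] = np.where(hit, np.maximum(bright_sum, dark_sum), 0.0)
    return corner, score


def _nms(corner: np.ndarray, score: np.ndarray) -> np.ndarray:
    """3x3 non-maximal suppression: keep a corner only if its score is the
    strict local maximum among corners; ties go to the earlier row-major
    position."""
    h, w = corner.shape
    s = np.where(corner, score, -np.inf)
    idx = np.arange(h * w).reshape(h, w)
    keep = corner.copy()
    pad_s = np.pad(s, 1, constant_values=-np.inf)
    pad_i = np.pad(idx, 1, constant_values=h * w)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            ns = pad_s[1 + dr : 1 + dr + h, 1 + dc : 1 + dc + w]
            ni = pad_i[1 + dr : 1 + dr + h, 1 + dc : 1 + dc + w]
            keep &= (s > ns) | ((s == ns) & (idx < ni))
    return keep


def _region_edges(size: int, parts: int) -> np.ndarray:
    return np.linspace(0, size, parts + 1).astype(int)


def detect_region_balanced(
    image: np.ndarray,
    grid: RegionGrid = RegionGrid(),
    t0: float = 30,
    border: int = DESCRIPTOR_MARGIN,
) -> list[Corner]:
    """Detect up to grid.n FAST corners spread over an even M x N tiling.

    Per region the segment test runs at threshold t0; while a region holds
    fewer than T = floor(n/(M*N)) NMS-surviving corners the threshold is
    halved (floor, never below 1) and the region re-scanned.  The budget
    remainder n - T*M*N goes one-each to the regions whose best surplus
    candidate scores highest; any residual deficit is filled from leftover
    candidates image-wide by descending score, so exactly n corners are
    returned whenever that many exist at threshold 1.

    Candidates are restricted to pixels at least `border` (default 17)
    pixels from every edge so the full 35x35 descriptor subimage fits.

    Returns corners sorted by (region_index, descending score, row, col).
    """
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    if t0 < 1:
        raise ConfigurationError("initial threshold t0 must be >= 1")
    if h < 7 * grid.M or w < 7 * grid.N:
        raise ValueError(
            f"image {img.shape} too small for a {grid.M}x{grid.N} division "
            "(need at least 7x7 pixels per region)"
        )
    band = np.zeros((h, w), dtype=bool)
    if h > 2 * border and w > 2 * border:
        band[border : h - border, border : w - border] = True

    r_edges = _region_edges(h, grid.M)
    c_edges = _region_edges(w, grid.N)
    T = grid.per_region
    remainder = grid.n - T * grid.M * grid.N

    cache: dict[float, tuple[np.ndarray, np.ndarray]] = {}

    def response(t: float):
        if t not in cache:
            cache[t] = _fast_response(img, t)
        return cache[t]

    per_region: list[list[Corner]] = []
    for i in range(grid.M):
        for j in range(grid.N):
            rmask = np.zeros((h, w), dtype=bool)
            rmask[r_edges[i] : r_edges[i + 1], c_edges[j] : c_edges[j + 1]] = True
            rmask &= band
            t = float(t0)
            while True:
                corner, score = response(t)
                local = corner & rmask
                keep = _nms(local, score)
                rows, cols = np.nonzero(keep)
                if len(rows) >= T or t <= 1:
                    break
                t = max(1.0, np.floor(t / 2.0))
            order = np.lexsort((cols, rows, -score[rows, cols]))
            per_region.append(
                [
                    Corner(int(rows[k]), int(cols[k]), float(score[rows[k], cols[k]]),
                           region_index=i * grid.N + j)
                    for k in order
                ]
            )

    take = [min(T, len(c)) for c in per_region]
    # remainder: one extra slot to the regions with the best surplus candidate
    surplus = sorted(
        (r for r in range(len(per_region)) if len(per_region[r]) > take[r]),
        key=lambda r: -per_region[r][take[r]].score,
    )
    for r in surplus[:remainder]:
        take[r] += 1
    selected = [c for r, cands in enumerate(per_region) for c in cands[: take[r]]]
    deficit = grid.n - len(selected)
    if deficit > 0:
        leftovers = sorted(
            (c for r, cands in enumerate(per_region) for c in cands[take[r]:]),
            key=lambda c: (-c.score, c.row, c.col),
        )
        selected.extend(leftovers[:deficit])
    if len(selected) < grid.n:
        warnings.warn(
            f"only {len(selected)} of {grid.n} requested keypoints found; "
            "descriptor vector will be zero-padded",
            stacklevel=2,
        )
    selected.sort(key=lambda c: (c.region_index, -c.score, c.row, c.col))
    return selected


_DISC_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _disc_offsets(radius: int) -> tuple[np.ndarray, np.ndarray]:
    if radius not in _DISC_CACHE:
        rr, cc = np.mgrid[-radius : radius + 1, -radius : radius + 1]
        m = rr**2 + cc**2 <= radius**2
        _DISC_CACHE[radius] = (rr[m], cc[m])
    return _DISC_CACHE[radius]


def orientation(image: np.ndarray, corner, radius: int = 15) -> float:
    """Intensity-centroid orientation of the circular patch at a corner.

    theta = atan2(m01, m10) with moments m_pq = sum x^p y^q I(x, y) over
    the disc (x = column offset, y = row offset); 0.0 when both first
    moments vanish (radially symmetric patch).
    """
    img = np.asarray(image, dtype=float)
    row, col = (corner.row, corner.col) if isinstance(corner, Corner) else corner
    h, w = img.shape
    if not (radius <= row < h - radius and radius <= col < w - radius):
        raise BorderError(
            f"orientation patch of radius {radius} at ({row}, {col}) "
            f"exits image of shape {img.shape}"
        )
    dr, dc = _disc_offsets(radius)
    vals = img[row + dr, col + dc]
    m10 = float(np.sum(dc * vals))  # x moment
    m01 = float(np.sum(dr * vals))  # y moment
    if m10 == 0.0 and m01 == 0.0:
        return 0.0
    return float(np.arctan2(m01, m10))


def smooth(image: np.ndarray) -> np.ndarray:
    """5x5 box smoothing used before every BRIEF intensity comparison."""
    return ndimage.uniform_filter(np.asarray(image, dtype=float), size=SMOOTH_SIZE,
                                  mode="nearest")


def brief_descriptor(
    image: np.ndarray,
    corner,
    pattern: SamplingPattern,
    steered: bool = True,
    smoothed: np.ndarray | None = None,
) -> np.ndarray:
    """256-bit BRIEF descriptor at a corner.

    Each bit compares the 5x5-smoothed intensity at two pattern offsets
    (rotated by the corner's theta when `steered`): bit = 1 iff
    I(r1, c1) < I(r2, c2).  Pass a precomputed `smoothed` image to avoid
    re-filtering per keypoint.
    """
    img = np.asarray(image, dtype=float)
    if isinstance(corner, Corner):
        row, col, theta = corner.row, corner.col, corner.theta
    else:
        row, col = corner
        theta = 0.0
    h, w = img.shape
    m = DESCRIPTOR_MARGIN
    if not (m <= row < h - m and m <= col < w - m):
        raise BorderError(
            f"descriptor window at ({row}, {col}) exits image of shape {img.shape}"
        )
    if smoothed is None:
        smoothed = smooth(img)
    pairs = pattern.pairs
    half = (pattern.patch_size - 1) // 2
    if steered and theta != 0.0:
        cos_t, sin_t = np.cos(theta), np.sin(theta)
        y = pairs[:, [0, 2]].astype(float)  # row offsets
        x = pairs[:, [1, 3]].astype(float)  # col offsets
        xr = x * cos_t - y * sin_t
        yr = x * sin_t + y * cos_t
        r_off = np.clip(np.rint(yr), -half, half).astype(int)
        c_off = np.clip(np.rint(xr), -half, half).astype(int)
    else:
        r_off = pairs[:, [0, 2]]
        c_off = pairs[:, [1, 3]]
    v1 = smoothed[row + r_off[:, 0], col + c_off[:, 0]]
    v2 = smoothed[row + r_off[:, 1], col + c_off[:, 1]]
    return (v1 < v2).astype(np.uint8)


@dataclass(frozen=True)
class OrbFeature:
    """Fixed-length concatenation of per-keypoint descriptors.

    bits has length n * 256 (region-scan order: region row-major, within a
    region by descending score); valid[k] is False for zero-padded slots
    where fewer than n corners were found.
    """

    bits: np.ndarray
    valid: np.ndarray
    corners: tuple = ()

    def __len__(self) -> int:
        return self.bits.size


def orb_feature(
    image: np.ndarray,
    grid: RegionGrid = RegionGrid(),
    pattern: SamplingPattern | None = None,
    t0: float = 30,
    orientation_radius: int = 15,
    steered: bool = True,
) -> OrbFeature:
    """Full region-balanced ORB feature of one face image.

    detect -> orient -> describe, assembled into a fixed n*256-bit vector
    with zero padding (and a False validity flag) for missing keypoints.
    Deterministic for fixed inputs and pattern.
    """
    img = np.asarray(image, dtype=float)
    if pattern is None:
        pattern = SamplingPattern.generate()
    corners = detect_region_balanced(img, grid, t0=t0)
    smoothed = smooth(img)
    oriented = [
        Corner(c.row, c.col, c.score,
               orientation(img, c, orientation_radius), c.region_index)
        for c in corners
    ]
    bits = np.zeros(grid.n * BRIEF_BITS, dtype=np.uint8)
    valid = np.zeros(grid.n, dtype=bool)
    for k, c in enumerate(oriented):
        bits[k * BRIEF_BITS : (k + 1) * BRIEF_BITS] = brief_descriptor(
            img, c, pattern, steered=steered, smoothed=smoothed
        )
        valid[k] = True
    return OrbFeature(bits=bits, valid=valid, corners=tuple(oriented))


class RegionOrbFeaturizer(BaseEstimator, TransformerMixin):
    """Transformer: (n_samples, H, W) face stack -> (n_samples, n*256) bits.

    Parameters mirror the detection/description stages: total keypoint
    budget `n_keypoints` spread over a `grid_m` x `grid_n` division,
    initial FAST threshold `t0`, intensity-centroid `orientation_radius`,
    and the frozen BRIEF `pattern_seed`.
    """

    def __init__(
        self,
        n_keypoints: int = 160,
        grid_m: int = 4,
        grid_n: int = 4,
        t0: float = 30,
        orientation_radius: int = 15,
        pattern_seed: int = DEFAULT_PATTERN_SEED,
        steered: bool = True,
    ):
        self.n_keypoints = n_keypoints
        self.grid_m = grid_m
        self.grid_n = grid_n
        self.t0 = t0
        self.orientation_radius = orientation_radius
        self.pattern_seed = pattern_seed
        self.steered = steered

    def fit(self, X, y=None):
        self.pattern_ = SamplingPattern.generate(self.pattern_seed)
        self.grid_ = RegionGrid(self.grid_m, self.grid_n, self.n_keypoints)
        return self

    def transform(self, X):
        if not hasattr(self, "pattern_"):
            self.fit(X)
        feats = [
            orb_feature(
                face, self.grid_, self.pattern_,
                t0=self.t0, orientation_radius=self.orientation_radius,
                steered=self.steered,
            ).bits
            for face in np.asarray(X)
        ]
        return np.stack(feats).astype(float)
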