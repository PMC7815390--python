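"""68-point facial landmark sets and their sidecar file format.

Landmarks follow the standard 68-point annotation scheme: jaw 1-17,
left eyebrow 18-22, right eyebrow 23-27, nose 28-36, eyes 37-48,
lips 49-68 (1-based, matching the convention used in the annotation
literature).  Internally coordinates are stored as an (68, 2) float
array of (x, y) pixel positions; sub-pixel coordinates are allowed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

N_LANDMARKS = 68

# 1-based index ranges of the named point groups.
GROUPS = {
    "jaw": (1, 17),
    "left_eyebrow": (18, 22),
    "right_eyebrow": (23, 27),
    "nose": (28, 36),
    "left_eye": (37, 42),
    "right_eye": (43, 48),
    "outer_lip": (49, 60),
    "inner_lip": (61, 68),
}


class InvalidLandmarksError(ValueError):
    """Raised when a landmark set does not contain exactly 68 finite points."""


@dataclass(frozen=True)
class LandmarkSet:
    """Ordered set of 68 (x, y) facial landmark coordinates.

    Parameters
    ----------
    points : ndarray of shape (68, 2)
        (x, y) pixel coordinates, x = column, y = row.  May be fractional.
    """

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (N_LANDMARKS, 2):
            raise InvalidLandmarksError(
                f"expected {N_LANDMARKS} (x, y) points, got array of shape {pts.shape}"
            )
        if not np.all(np.isfinite(pts)):
            raise InvalidLandmarksError("landmark coordinates must be finite")
        object.__setattr__(self, "points", pts)

    def point(self, index: int) -> np.ndarray:
        """Return landmark `index` using the 1-based public numbering."""
        if not 1 <= index <= N_LANDMARKS:
            raise IndexError(f"landmark index must be in 1..{N_LANDMARKS}, got {index}")
        return self.points[index - 1]

    def group(self, name: str) -> np.ndarray:
        """Return the (k, 2) coordinates of a named point group."""
        lo, hi = GROUPS[name]
        return self.points[lo - 1 : hi]

    def face_points(self) -> np.ndarray:
        """Points 1-27 (jaw plus both eyebrows): the face-region support."""
        return self.points[:27]

    def translated(self, dx: float, dy: float) -> "LandmarkSet":
        return LandmarkSet(self.points + np.array([dx, dy]))


def read_sidecar(path: str | Path) -> LandmarkSet:
    """Read a landmark sidecar: 68 whitespace-delimited "x y" lines."""
    pts = np.loadtxt(path, dtype=float)
    if pts.ndim == 1:  # a single 136-number row
        pts = pts.reshape(-1, 2)
    return LandmarkSet(pts)


def write_sidecar(landmarks: LandmarkSet, path: str | Path) -> None:
    np.savetxt(path, landmarks.points, fmt="%.4f")


def from_flat(values) -> LandmarkSet:
    """Build a LandmarkSet from 136 interleaved numbers x1,y1,...,x68,y68."""
    arr = np.asarray(values, dtype=float).reshape(-1)
    if arr.size != 2 * N_LANDMARKS:
        raise InvalidLandmarksError(
            f"expected {2 * N_LANDMARKS} numbers, got {arr.size}"
        )
    return LandmarkSet(arr.reshape(N_LANDMARKS, 2))
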