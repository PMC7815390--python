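"""Face-region extraction: landmark-guided crop to the 130x130 working size.

The face region is the axis-aligned bounding box of landmark points 1-27
(jaw line plus both eyebrows) — the part of the face that carries
expression, excluding forehead and ears.  The crop is converted to
grayscale if needed and resized to a fixed 130x130 so every downstream
texture and keypoint operator sees the same geometry.
"""

from __future__ import annotations

import numpy as np
from PIL import Image
from skimage.transform import resize
from sklearn.base import BaseEstimator, TransformerMixin

from .landmarks import LandmarkSet

FACE_SIZE = 130

# ITU-R BT.601 luminance weights for RGB -> gray.
_LUMA = np.array([0.299, 0.587, 0.114])


class DegenerateRegionError(ValueError):
    """Raised when the landmark bounding box has zero width or height."""


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Convert an (H, W) or (H, W, 3/4) uint8-like image to (H, W) grayscale.

    Uses BT.601 luminance weighting rounded to nearest integer; a
    single-channel image passes through unchanged.
    """
    img = np.asarray(image)
    if img.ndim == 2:
        return img
    if img.ndim == 3 and img.shape[2] in (3, 4):
        gray = img[..., :3].astype(float) @ _LUMA
        return np.rint(gray).astype(np.uint8)
    raise ValueError(f"expected 2-D or 3-D (RGB/RGBA) image, got shape {img.shape}")


def crop_face(
    image: np.ndarray,
    landmarks: LandmarkSet,
    size: int = FACE_SIZE,
) -> np.ndarray:
    """Extract the standardized grayscale face region from an image.

    The region is the axis-aligned bounding box of landmark points 1-27,
    clamped to the image, resized with bilinear interpolation to
    (size, size) and quantized back to uint8.

    Parameters
    ----------
    image : ndarray
        Grayscale (H, W) or color (H, W, 3/4) pixel array.
    landmarks : LandmarkSet
        68-point landmark set in the image's pixel coordinates.
    size : int
        Output side length; 130 by default.

    Returns
    -------
    ndarray of shape (size, size), dtype uint8.
    """
    gray = to_grayscale(image)
    if gray.size == 0:
        raise ValueError("empty image")
    pts = landmarks.face_points()
    h, w = gray.shape
    x0 = int(np.floor(np.clip(pts[:, 0].min(), 0, w - 1)))
    x1 = int(np.ceil(np.clip(pts[:, 0].max(), 0, w - 1)))
    y0 = int(np.floor(np.clip(pts[:, 1].min(), 0, h - 1)))
    y1 = int(np.ceil(np.clip(pts[:, 1].max(), 0, h - 1)))
    if x1 <= x0 or y1 <= y0:
        raise DegenerateRegionError(
            f"face bounding box [{y0}:{y1}, {x0}:{x1}] has zero area"
        )
    patch = gray[y0 : y1 + 1, x0 : x1 + 1].astype(float)
    out = resize(patch, (size, size), order=1, mode="edge",
                 anti_aliasing=False, preserve_range=True)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def load_image(path) -> np.ndarray:
    """Read a PNG/JPEG/PGM image file into a numpy array."""
    with Image.open(path) as im:
        return np.asarray(im)


class FaceCropper(BaseEstimator, TransformerMixin):
    """Transformer mapping (image, landmarks) pairs to 130x130 face arrays.

    X is a sequence of (image, LandmarkSet) tuples; transform returns an
    (n, size, size) uint8 array.  Stateless (fit is a no-op), provided so
    the crop stage composes in sklearn pipelines.
    """

    def __init__(self, size: int = FACE_SIZE):
        self.size = size

    def fit(self, X, y=None):
        self.n_features_in_ = 1
        return self

    def transform(self, X):
        return np.stack([crop_face(img, lm, self.size) for img, lm in X])
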