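"""Synthetic face-image generator with known landmarks and ground truth.

Real expression corpora are built from posed photographs of consenting
subjects and cannot ship with a library, so every pipeline stage here is
exercised on generated data that mimics the *structure* such corpora
give the method: a face-shaped region whose position is described by a
68-point landmark set, an expression class signal carried by both
texture (oriented sinusoidal gratings, which drive LBP statistics) and
geometry (class-specific constellations of small bright corner blobs,
which drive FAST/BRIEF), and subject-specific nuisance variation
(a global brightness offset plus a mild similarity warp of the whole
face) that makes subject-independent evaluation genuinely harder than
subject-dependent evaluation.

Everything is deterministic given the spec seed: subject nuisance
parameters, class constellations and per-replicate noise are drawn from
disjoint child seed sequences, so the same (subject, class, replicate)
triple always renders the identical image.

The default spec — 10 subjects x 7 expressions x 3 replicates = 210
images — matches the scale of the classic 10-subject, 213-image posed
expression corpus the evaluation protocols were designed around.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .cv import EXPRESSIONS
from .landmarks import LandmarkSet, write_sidecar


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the generated corpus.

    Intensities are 8-bit gray levels.  `texture_contrast` is the grating
    amplitude, `blob_amplitude` the brightness step of planted corner
    blobs, `noise_sd` the additive Gaussian pixel noise.  Subject
    nuisance: brightness offset up to +-25 levels and a similarity warp
    of +-5% scale, +-3 degrees rotation, +-2 px translation.
    """

    n_subjects: int = 10
    n_classes: int = 7
    replicates: int = 3
    image_size: int = 200
    texture_contrast: float = 28.0
    blob_amplitude: float = 95.0
    n_blobs: int = 12
    noise_sd: float = 8.0
    brightness_range: float = 25.0
    scale_jitter: float = 0.05
    rotation_jitter_deg: float = 3.0
    translation_jitter: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if not 1 <= self.n_classes <= len(EXPRESSIONS):
            raise ValueError(f"n_classes must be in 1..{len(EXPRESSIONS)}")
        if self.n_subjects < 1 or self.replicates < 1:
            raise ValueError("n_subjects and replicates must be >= 1")

    @property
    def labels(self) -> tuple:
        return EXPRESSIONS[: self.n_classes]


def _landmark_template() -> np.ndarray:
    """Canonical 68-point layout in unit face coordinates.

    x in [-1, 1] spans the face width; y runs downward from about -0.65
    (brow line) to 1.0 (chin).  Groups follow the standard numbering:
    jaw 1-17, brows 18-27, nose 28-36, eyes 37-48, lips 49-68.
    """
    pts = []
    # jaw: left temple -> chin -> right temple
    psi = np.linspace(-np.pi / 2, np.pi / 2, 17)
    pts += [(np.sin(p), -0.1 + 1.1 * np.cos(p)) for p in psi]
    # eyebrows, arched
    u = np.linspace(0, 1, 5)
    pts += [(-0.75 + 0.5 * t, -0.55 - 0.08 * np.sin(np.pi * t)) for t in u]
    pts += [(0.25 + 0.5 * t, -0.55 - 0.08 * np.sin(np.pi * (1 - t))) for t in u]
    # nose bridge (28-31) and base (32-36)
    pts += [(0.0, -0.45 + 0.18 * i) for i in range(4)]
    pts += [(-0.18 + 0.09 * i, 0.2) for i in range(5)]
    # eyes: hexagons around (-0.5, -0.35) and (0.5, -0.35)
    for cx in (-0.5, 0.5):
        ang = np.linspace(np.pi, -np.pi, 7)[:-1]  # 6 points, from outer corner
        pts += [(cx + 0.15 * np.cos(a), -0.35 - 0.08 * np.sin(a)) for a in ang]
    # outer lip: 12 points on an ellipse around (0, 0.55)
    ang = np.linspace(np.pi, -np.pi, 13)[:-1]
    pts += [(0.35 * np.cos(a), 0.55 - 0.12 * np.sin(a)) for a in ang]
    # inner lip: 8 points
    ang = np.linspace(np.pi, -np.pi, 9)[:-1]
    pts += [(0.25 * np.cos(a), 0.55 - 0.05 * np.sin(a)) for a in ang]
    arr = np.array(pts, dtype=float)
    assert arr.shape == (68, 2)
    return arr


_TEMPLATE = _landmark_template()


def _subject_params(spec: SyntheticSpec, subject_id: int) -> dict:
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=(1, subject_id))
    )
    return {
        "brightness": rng.uniform(-spec.brightness_range, spec.brightness_range),
        "scale": 1.0 + rng.uniform(-spec.scale_jitter, spec.scale_jitter),
        "rot": np.deg2rad(rng.uniform(-spec.rotation_jitter_deg, spec.rotation_jitter_deg)),
        "tx": rng.uniform(-spec.translation_jitter, spec.translation_jitter),
        "ty": rng.uniform(-spec.translation_jitter, spec.translation_jitter),
    }


def _class_params(spec: SyntheticSpec, class_id: int) -> dict:
    """Pairwise-distinct class signal: grating orientation/frequency plus a
    fixed constellation of corner-blob positions in face coordinates."""
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=(3, class_id))
    )
    blobs = np.column_stack(
        [rng.uniform(-0.55, 0.55, spec.n_blobs), rng.uniform(-0.4, 0.85, spec.n_blobs)]
    )
    return {
        "orientation": np.pi * class_id / max(spec.n_classes, 1),
        "omega": 34.0 + 7.0 * (class_id % 3),  # angular frequency in face units
        "blobs": blobs,
    }


def _crop_box(landmarks: LandmarkSet, shape: tuple[int, int]) -> tuple[int, int, int, int]:
    """(y0, y1, x0, x1) inclusive bounds of the point-1..27 bounding box,
    clamped to the image — the same geometry the face cropper applies."""
    pts = landmarks.face_points()
    h, w = shape
    x0 = int(np.floor(np.clip(pts[:, 0].min(), 0, w - 1)))
    x1 = int(np.ceil(np.clip(pts[:, 0].max(), 0, w - 1)))
    y0 = int(np.floor(np.clip(pts[:, 1].min(), 0, h - 1)))
    y1 = int(np.ceil(np.clip(pts[:, 1].max(), 0, h - 1)))
    return y0, y1, x0, x1


def generate_face(
    spec: SyntheticSpec,
    subject_id: int,
    class_id: int,
    replicate: int,
) -> tuple[np.ndarray, LandmarkSet, dict]:
    """Render one synthetic face.

    Returns (image, landmarks, ground_truth) where ground_truth records
    the crop box implied by landmark points 1-27, the raw (unresized)
    face patch inside it, and the planted corner-blob centers both in
    image coordinates and mapped into the 130x130 crop frame.
    """
    if not 0 <= subject_id < spec.n_subjects:
        raise ValueError(f"subject_id {subject_id} out of range")
    if not 0 <= class_id < spec.n_classes:
        raise ValueError(f"class_id {class_id} out of range")
    if not 0 <= replicate < spec.replicates:
        raise ValueError(f"replicate {replicate} out of range")

    sp = _subject_params(spec, subject_id)
    cp = _class_params(spec, class_id)
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed,
                               spawn_key=(2, subject_id, class_id, replicate))
    )
    size = spec.image_size
    center = size / 2.0
    s0 = 0.31 * size * sp["scale"]  # face half-width in pixels
    rot = sp["rot"]
    # replicate-level micro-jitter: the same pose re-photographed
    tx = sp["tx"] + rng.uniform(-1.0, 1.0)
    ty = sp["ty"] + rng.uniform(-1.0, 1.0)

    cos_r, sin_r = np.cos(rot), np.sin(rot)
    A = s0 * np.array([[cos_r, -sin_r], [sin_r, cos_r]])  # template -> pixel

    def fwd(uv: np.ndarray) -> np.ndarray:
        xy = uv @ A.T
        return xy + np.array([center + tx, center + ty])

    lm_xy = fwd(_TEMPLATE)
    landmarks = LandmarkSet(lm_xy)

    # inverse map: template coordinates of every pixel
    cols, rows = np.meshgrid(np.arange(size, dtype=float), np.arange(size, dtype=float))
    px = np.stack([cols - (center + tx), rows - (center + ty)], axis=-1)
    Ainv = np.linalg.inv(A)
    uv = px @ Ainv.T
    U, V = uv[..., 0], uv[..., 1]

    img = np.full((size, size), 70.0)
    oval = (U / 1.15) ** 2 + ((V - 0.2) / 1.05) ** 2 <= 1.0
    img[oval] = 150.0 + sp["brightness"]
    # class texture: oriented grating in face coordinates
    alpha, omega = cp["orientation"], cp["omega"]
    grating = spec.texture_contrast * np.sin(
        omega * (U * np.cos(alpha) + V * np.sin(alpha))
    )
    img[oval] += grating[oval]
    # facial features (dark): brows, eyes, nose, mouth
    for cx in (-0.5, 0.5):
        brow = ((U - cx) / 0.30) ** 2 + ((V + 0.59) / 0.06) ** 2 <= 1.0
        img[brow] -= 50.0
        eye = ((U - cx) / 0.16) ** 2 + ((V + 0.35) / 0.09) ** 2 <= 1.0
        img[eye] -= 65.0
    nose = (np.abs(U) <= 0.045) & (V >= -0.45) & (V <= 0.15)
    img[nose] -= 35.0
    base = (U / 0.19) ** 2 + ((V - 0.2) / 0.05) ** 2 <= 1.0
    img[base] -= 35.0
    mouth = (U / 0.35) ** 2 + ((V - 0.55) / 0.12) ** 2 <= 1.0
    img[mouth] -= 45.0

    # planted corner blobs (3x3 bright squares) at the class constellation
    blob_xy = fwd(cp["blobs"])
    blob_centers = []
    for x, y in blob_xy:
        r, c = int(round(y)), int(round(x))
        if 2 <= r < size - 2 and 2 <= c < size - 2:
            img[r - 1 : r + 2, c - 1 : c + 2] += spec.blob_amplitude
            blob_centers.append((r, c))

    img += rng.normal(0.0, spec.noise_sd, img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    y0, y1, x0, x1 = _crop_box(landmarks, img.shape)
    sy = 130.0 / (y1 - y0 + 1)
    sx = 130.0 / (x1 - x0 + 1)
    blobs_crop = [((r - y0 + 0.5) * sy - 0.5, (c - x0 + 0.5) * sx - 0.5)
                  for r, c in blob_centers]
    truth = {
        "subject_id": subject_id,
        "class_id": class_id,
        "replicate": replicate,
        "label": spec.labels[class_id],
        "crop_box": (y0, y1, x0, x1),
        "face_patch": img[y0 : y1 + 1, x0 : x1 + 1].copy(),
        "blob_centers": blob_centers,
        "blob_centers_crop": blobs_crop,
    }
    return img, landmarks, truth


def generate_dataset(
    spec: SyntheticSpec,
    out_dir: str | Path | None = None,
) -> tuple[list[np.ndarray], list[LandmarkSet], pd.DataFrame, list[dict]]:
    """Full factorial corpus: subjects x classes x replicates.

    Returns (images, landmark_sets, manifest, ground_truth) with manifest
    rows in deterministic (subject, class, replicate) order and columns
    path, label, subject.  When out_dir is given, PNG images, landmark
    sidecars (<stem>.pts.txt) and manifest.csv are also written there.
    """
    images, lms, truths, rows = [], [], [], []
    for s in range(spec.n_subjects):
        for c in range(spec.n_classes):
            for r in range(spec.replicates):
                img, lm, truth = generate_face(spec, s, c, r)
                stem = f"s{s:02d}_{spec.labels[c]}_r{r}"
                images.append(img)
                lms.append(lm)
                truths.append(truth)
                rows.append(
                    {"path": stem + ".png", "label": spec.labels[c],
                     "subject": f"subj{s:02d}"}
                )
    manifest = pd.DataFrame(rows, columns=["path", "label", "subject"])
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for img, lm, row in zip(images, lms, manifest.itertuples()):
            Image.fromarray(img).save(out / row.path)
            write_sidecar(lm, out / (Path(row.path).stem + ".pts.txt"))
        manifest.to_csv(out / "manifest.csv", index=False)
    return images, lms, manifest, truths


def make_corner_grid_image(
    size: int = 192,
    grid_shape: tuple[int, int] = (4, 4),
    per_region: int = 12,
    seed: int = 0,
    amplitude: float = 100.0,
    background: float = 60.0,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Corner-rich test image: >= per_region isolated 3x3 bright blobs in
    the detectable band of every grid region.  Returns (image, planted
    blob centers)."""
    rng = np.random.default_rng(seed)
    img = np.full((size, size), background)
    centers = []
    m_rows, n_cols = grid_shape
    r_edges = np.linspace(0, size, m_rows + 1).astype(int)
    c_edges = np.linspace(0, size, n_cols + 1).astype(int)
    band = 18  # keep blobs fully inside the descriptor-safe band
    for i in range(m_rows):
        for j in range(n_cols):
            r_lo = max(r_edges[i], band)
            r_hi = min(r_edges[i + 1], size - band)
            c_lo = max(c_edges[j], band)
            c_hi = min(c_edges[j + 1], size - band)
            placed = 0
            # jittered lattice, spacing >= 7 px so blobs stay isolated
            rr = np.arange(r_lo + 2, r_hi - 2, 7)
            cc = np.arange(c_lo + 2, c_hi - 2, 7)
            sites = [(r, c) for r in rr for c in cc]
            rng.shuffle(sites)
            for r, c in sites:
                if placed >= per_region:
                    break
                a = amplitude * rng.uniform(0.7, 1.0)
                img[r - 1 : r + 2, c - 1 : c + 2] = background + a
                centers.append((int(r), int(c)))
                placed += 1
    return np.clip(img, 0, 255).astype(np.uint8), centers


def make_clustered_corner_image(
    size: int = 192,
    grid_shape: tuple[int, int] = (4, 4),
    per_region: int = 12,
    seed: int = 0,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Texture-rich image whose *strongest* corners cluster in one area —
    the situation region balancing exists to handle.

    Every grid region carries `per_region` weak blobs (so a balanced
    detector can always fill its local budget), and a dense lattice of
    much stronger blobs is overlaid on the upper-left quarter, which is
    where a global top-n detector concentrates."""
    img, centers = make_corner_grid_image(
        size=size, grid_shape=grid_shape, per_region=per_region,
        seed=seed, amplitude=45.0,
    )
    img = img.astype(float)
    rng = np.random.default_rng(seed + 1)
    for r in range(24, size // 2 - 6, 7):  # dense strong cluster
        for c in range(24, size // 2 - 6, 7):
            img[r - 1 : r + 2, c - 1 : c + 2] = 60.0 + 150.0 + rng.uniform(0, 20)
            centers.append((r, c))
    return np.clip(img, 0, 255).astype(np.uint8), centers
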