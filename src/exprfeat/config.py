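"""Single configuration surface and the end-to-end pipeline runner.

PipelineConfig is the one source of truth for every constant the stages
use (face size, LBP patch size, FAST/BRIEF parameters, fusion K and C,
CV protocol sizes); it validates on construction and round-trips through
JSON.  run_pipeline composes crop -> LBP -> region-ORB -> normalize ->
Z-score fuse -> SVM cross-validation, optionally caching extracted
features keyed by a content hash of (config, inputs) so the
LBP-only / ORB-only / fused ablation reuses one extraction pass.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as efio
from .cv import CVResult, SVMConfig, run_cv
from .face import crop_face
from .fusion import BlockZScoreFuser, max_normalize
from .lbp import LBPFeaturizer
from .orb import DEFAULT_PATTERN_SEED, RegionOrbFeaturizer

logger = logging.getLogger("exprfeat")

FEATURE_SETS = ("lbp", "orb", "fused")


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable constant of the pipeline, validated at load time."""

    face_size: int = 130
    lbp_patch_size: int = 16
    fast_t0: float = 30.0
    fast_arc: int = 12
    circle_size: int = 16
    grid_m: int = 4
    grid_n: int = 4
    n_keypoints: int = 160
    brief_bits: int = 256
    smoothing_window: int = 5
    brief_window: int = 31
    orientation_radius: int = 15
    pattern_seed: int = DEFAULT_PATTERN_SEED
    fusion_k: float = 100.0
    fusion_c: float = 0.0
    svm_c_grid: tuple = SVMConfig.C_grid
    svm_gamma_grid: tuple = SVMConfig.gamma_grid
    svm_inner_k: int = 3
    cv_k: int = 10
    repeats: int = 10
    seed: int = 0
    version: int = 1

    def __post_init__(self):
        checks = {
            "face_size": self.face_size >= 35,
            "lbp_patch_size": (self.face_size - 2) % self.lbp_patch_size == 0,
            "fast_t0": self.fast_t0 >= 1,
            "fast_arc": 1 <= self.fast_arc <= self.circle_size,
            "circle_size": self.circle_size == 16,
            "grid": self.grid_m >= 1 and self.grid_n >= 1
                    and self.grid_m * self.grid_n <= self.n_keypoints,
            "brief_bits": self.brief_bits >= 1,
            "smoothing_window": self.smoothing_window % 2 == 1,
            "brief_window": self.brief_window
                            == self.brief_window // 2 * 2 + 1,
            "fusion_k": self.fusion_k > 0,
            "cv_k": self.cv_k >= 2,
            "repeats": self.repeats >= 1,
        }
        bad = [k for k, ok in checks.items() if not ok]
        if bad:
            raise ValueError(f"invalid configuration field(s): {bad}")

    def to_json(self, path: str | Path | None = None) -> str:
        d = asdict(self)
        d["svm_c_grid"] = list(self.svm_c_grid)
        d["svm_gamma_grid"] = list(self.svm_gamma_grid)
        text = json.dumps(d, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PipelineConfig":
        text = str(source)
        if not text.lstrip().startswith("{"):  # a path, not JSON text
            text = Path(source).read_text()
        d = json.loads(text)
        d["svm_c_grid"] = tuple(d.get("svm_c_grid", SVMConfig.C_grid))
        d["svm_gamma_grid"] = tuple(d.get("svm_gamma_grid", SVMConfig.gamma_grid))
        return cls(**d)

    def svm_config(self) -> SVMConfig:
        return SVMConfig(
            C_grid=tuple(self.svm_c_grid),
            gamma_grid=tuple(self.svm_gamma_grid),
            inner_k=self.svm_inner_k,
        )


def extract_features(
    images,
    landmark_sets,
    config: PipelineConfig = PipelineConfig(),
) -> tuple[np.ndarray, np.ndarray]:
    """Crop every image and compute raw LBP counts and ORB bits.

    Returns (lbp_matrix, orb_bit_matrix) with one row per image.
    """
    faces = np.stack(
        [crop_face(img, lm, config.face_size) for img, lm in zip(images, landmark_sets)]
    )
    logger.info("extracting features from %d faces (%dx%d)",
                len(faces), config.face_size, config.face_size)
    lbp = LBPFeaturizer(patch_size=config.lbp_patch_size).fit(faces).transform(faces)
    orb = RegionOrbFeaturizer(
        n_keypoints=config.n_keypoints, grid_m=config.grid_m, grid_n=config.grid_n,
        t0=config.fast_t0, orientation_radius=config.orientation_radius,
        pattern_seed=config.pattern_seed,
    ).fit(faces).transform(faces)
    return lbp, orb


def fuse_feature_set(
    lbp: np.ndarray,
    orb: np.ndarray,
    feature_set: str,
    config: PipelineConfig = PipelineConfig(),
) -> np.ndarray:
    """Assemble the SVM input for one ablation arm.

    LBP counts are max-normalized into [0, 1] per vector, then each block
    is Z-score standardized to mean C / SD K; "fused" concatenates the
    standardized LBP and ORB blocks, "lbp"/"orb" keep a single block.
    """
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"feature_set must be one of {FEATURE_SETS}")
    fuser = BlockZScoreFuser(K=config.fusion_k, C=config.fusion_c)
    if feature_set == "lbp":
        norm = np.stack([max_normalize(row) for row in lbp])
        return fuser.fit(norm).transform(norm)
    if feature_set == "orb":
        return fuser.fit(orb).transform(orb)
    norm = np.stack([max_normalize(row) for row in lbp])
    stacked = np.hstack([norm, orb])
    fuser = BlockZScoreFuser(lbp_len=lbp.shape[1], K=config.fusion_k, C=config.fusion_c)
    return fuser.fit(stacked).transform(stacked)


def _cache_key(config: PipelineConfig, manifest: pd.DataFrame, images) -> str:
    h = hashlib.sha256()
    h.update(config.to_json().encode())
    h.update(pd.util.hash_pandas_object(manifest[["path", "label", "subject"]]).values.tobytes())
    for img in images:
        h.update(np.ascontiguousarray(img).tobytes())
    return h.hexdigest()[:16]


def run_pipeline(
    config: PipelineConfig,
    images,
    landmark_sets,
    manifest: pd.DataFrame,
    feature_sets=FEATURE_SETS,
    protocols=("SD", "SI"),
    cache_dir: str | Path | None = None,
) -> dict:
    """Full pipeline on an in-memory dataset.

    Returns ``{"features": {...}, "results": {feature_set: {protocol:
    CVResult}}}``; identical config + seed + inputs give identical
    results.  With cache_dir, extraction is keyed by a content hash of
    (config, inputs) and reused across ablation arms and reruns.
    """
    lbp = orb = None
    if cache_dir is not None:
        key = _cache_key(config, manifest, images)
        cache_path = Path(cache_dir) / f"features-{key}.npz"
        if cache_path.exists():
            logger.info("reusing cached features %s", cache_path)
            lbp, orb, _, _ = efio.load_feature_cache(cache_path)
    if lbp is None:
        lbp, orb = extract_features(images, landmark_sets, config)
        if cache_dir is not None:
            Path(cache_dir).mkdir(parents=True, exist_ok=True)
            efio.save_feature_cache(
                cache_path, lbp, orb, manifest,
                {"K": config.fusion_k, "C": config.fusion_c,
                 "lbp_len": lbp.shape[1], "pattern_seed": config.pattern_seed},
            )
    results: dict[str, dict[str, CVResult]] = {}
    for fs in feature_sets:
        X = fuse_feature_set(lbp, orb, fs, config)
        results[fs] = {}
        for proto in protocols:
            logger.info("cross-validating %s features under %s", fs, proto)
            results[fs][proto] = run_cv(
                X, manifest, protocol=proto, k=config.cv_k,
                repeats=config.repeats, seed=config.seed,
                svm_config=config.svm_config(),
            )
    return {"features": {"lbp": lbp, "orb": orb}, "results": results}


def format_report(results: dict) -> str:
    """Human-readable accuracy table (feature set x protocol)."""
    protos = sorted({p for d in results.values() for p in d})
    lines = ["Feature set      " + "".join(f"{p:>12}" for p in protos)]
    for fs, d in results.items():
        cells = "".join(
            f"{100 * d[p].mean_accuracy:>11.1f}%" if p in d else f"{'—':>12}"
            for p in protos
        )
        lines.append(f"{fs:<17}{cells}")
    return "\n".join(lines)
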