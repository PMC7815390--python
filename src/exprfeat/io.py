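"""Feature-matrix and manifest file formats.

Manifests are delimited text with header ``path,label,subject``.  Feature
matrices travel either as TSV (one row per image; label and subject
columns first, then the feature values) or as a compressed ``.npz``
columnar cache holding the raw LBP counts and ORB bits separately plus
the metadata needed to reproduce the fusion (K, C, block boundary,
pattern seed).  Both round-trip exactly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"path", "label", "subject"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if df["subject"].isna().any() or (df["subject"].astype(str) == "").any():
        raise ValueError("every manifest record needs a nonempty subject id")
    return df


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest[["path", "label", "subject"]].to_csv(path, index=False)


def write_feature_tsv(
    features: np.ndarray, manifest: pd.DataFrame, path: str | Path
) -> None:
    """One row per image: label, subject, then the feature values."""
    df = pd.DataFrame(features)
    df.insert(0, "subject", manifest["subject"].to_numpy())
    df.insert(0, "label", manifest["label"].to_numpy())
    df.to_csv(path, sep="\t", index=False)


def read_feature_tsv(path: str | Path) -> tuple[np.ndarray, pd.DataFrame]:
    df = pd.read_csv(path, sep="\t")
    meta = pd.DataFrame(
        {"path": [f"row{i}" for i in range(len(df))],
         "label": df["label"], "subject": df["subject"]}
    )
    feats = df.drop(columns=["label", "subject"]).to_numpy(dtype=float)
    return feats, meta


def save_feature_cache(
    path: str | Path,
    lbp: np.ndarray,
    orb_bits: np.ndarray,
    manifest: pd.DataFrame,
    meta: dict,
) -> None:
    """Binary columnar cache of raw per-stage features (ORB bits packed
    32 per word, little-endian bit order within each uint8 byte)."""
    packed = np.packbits(orb_bits.astype(np.uint8), axis=1, bitorder="little")
    np.savez_compressed(
        path,
        lbp=lbp.astype(np.float64),
        orb_packed=packed,
        orb_len=np.int64(orb_bits.shape[1]),
        paths=manifest["path"].to_numpy(dtype=object).astype(str),
        labels=manifest["label"].to_numpy(dtype=object).astype(str),
        subjects=manifest["subject"].to_numpy(dtype=object).astype(str),
        meta_keys=np.array(sorted(meta), dtype=object).astype(str),
        meta_vals=np.array([str(meta[k]) for k in sorted(meta)], dtype=object).astype(str),
    )


def load_feature_cache(path: str | Path) -> tuple[np.ndarray, np.ndarray, pd.DataFrame, dict]:
    with np.load(path, allow_pickle=False) as z:
        lbp = z["lbp"]
        orb = np.unpackbits(z["orb_packed"], axis=1, bitorder="little")[
            :, : int(z["orb_len"])
        ].astype(np.uint8)
        manifest = pd.DataFrame(
            {"path": z["paths"], "label": z["labels"], "subject": z["subjects"]}
        )
        meta = dict(zip(z["meta_keys"].tolist(), z["meta_vals"].tolist()))
    return lbp, orb, manifest, meta
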