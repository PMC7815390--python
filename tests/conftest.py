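"""Shared fixtures: small synthetic corpora and independent oracles.

Oracles here are deliberately naive (per-pixel loops over plain Python
ints) so they stay independent of the vectorized implementation paths
they check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from exprfeat import SVMConfig, SyntheticSpec, generate_dataset
from exprfeat.orb import FAST_CIRCLE


# ---------------------------------------------------------------- oracles

def oracle_lbp_code(patch3x3, offsets) -> int:
    """Bit-by-bit evaluation of the LBP sum with plain Python ints."""
    center = patch3x3[1][1]
    code = 0
    for n, (dr, dc) in enumerate(offsets):
        if patch3x3[1 + dr][1 + dc] - center >= 0:
            code += 2**n
    return code


def oracle_lbp_face(image) -> np.ndarray:
    """Naive double loop over every interior pixel."""
    img = [[int(v) for v in row] for row in np.asarray(image)]
    h, w = len(img), len(img[0])
    from exprfeat.lbp import NEIGHBOR_OFFSETS

    out = np.zeros((h - 2, w - 2), dtype=np.int64)
    for r in range(1, h - 1):
        row = np.empty(w - 2, dtype=np.int64)
        for c in range(1, w - 1):
            patch = [img[r - 1][c - 1 : c + 2], img[r][c - 1 : c + 2],
                     img[r + 1][c - 1 : c + 2]]
            row[c - 1] = oracle_lbp_code(patch, NEIGHBOR_OFFSETS)
        out[r - 1] = row
    return out


def oracle_uniform_rank() -> dict[int, int]:
    """Enumerate all 256 codes, count circular transitions on the bit
    string, and rank the uniform ones in ascending code order."""
    def transitions(code):
        bits = [(code >> n) & 1 for n in range(8)]
        return sum(bits[n] != bits[(n + 1) % 8] for n in range(8))

    uniform = [c for c in range(256) if transitions(c) <= 2]
    table = {c: 58 for c in range(256)}
    for rank, c in enumerate(uniform):
        table[c] = rank
    return table


def oracle_fast_is_corner(image, row, col, t) -> bool:
    """Explicit 16-offset circular scan for a run of >= 12."""
    img = np.asarray(image, dtype=float)
    center = img[row, col]
    flags_b = [img[row + dr, col + dc] >= center + t for dr, dc in FAST_CIRCLE]
    flags_d = [img[row + dr, col + dc] <= center - t for dr, dc in FAST_CIRCLE]
    for flags in (flags_b, flags_d):
        doubled = flags + flags
        run = 0
        for f in doubled:
            run = run + 1 if f else 0
            if run >= 12:
                return True
    return False


def oracle_brief(smoothed, row, col, pairs) -> np.ndarray:
    """Literal two-loop evaluation of the pairwise comparisons."""
    bits = []
    for r1, c1, r2, c2 in pairs:
        v1 = smoothed[row + r1, col + c1]
        v2 = smoothed[row + r2, col + c2]
        bits.append(1 if v1 < v2 else 0)
    return np.array(bits, dtype=np.uint8)


# --------------------------------------------------------------- fixtures

#: coarse grid so unit-level CV runs stay fast; acceptance uses defaults
FAST_SVM = SVMConfig(C_grid=(1.0, 64.0), gamma_grid=(1.0,), inner_k=2)


@pytest.fixture(scope="session")
def small_corpus():
    """4 subjects x 3 classes x 2 replicates = 24 images, for unit tests."""
    spec = SyntheticSpec(n_subjects=4, n_classes=3, replicates=2, seed=7)
    images, lms, manifest, truths = generate_dataset(spec)
    return spec, images, lms, manifest, truths


@pytest.fixture(scope="session")
def balanced_manifest():
    """Label-balanced 7-class manifest of 210 records over 10 subjects."""
    from exprfeat.cv import EXPRESSIONS

    rows = [
        {"path": f"s{s:02d}_{lab}_r{r}.png", "label": lab, "subject": f"subj{s:02d}"}
        for s in range(10)
        for lab in EXPRESSIONS
        for r in range(3)
    ]
    return pd.DataFrame(rows)
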