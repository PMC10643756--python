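"""Grey-level co-occurrence matrices and Haralick-style texture features.

For one 8-bit image and an ROI mask, ordered grey-pair counts are accumulated
for a directed pixel offset (angle, distance), normalized to a probability
matrix, and summarized by five classical features:

    ASM  = sum p^2                      angular second moment (uniformity)
    CON  = sum (i-j)^2 p                contrast (local heterogeneity)
    CORR = sum (i-mu_i)(j-mu_j) p / (sigma_i sigma_j)   correlation
    IDM  = sum p / (1 + (i-j)^2)        inverse difference moment (homogeneity)
    ENT  = -sum p log2 p                entropy (randomness), 0*log 0 = 0

Matrices are directed (non-symmetrized), one per orientation, over the full
256-level range with no requantization.  Opposite orientations give transposed
matrices, and all five features are transpose-invariant, so 0/180 and 90/270
always agree exactly.  Pairs are counted only when both pixels lie inside the
mask, so background never contaminates the statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class GlcmError(ValueError):
    """Raised for invalid GLCM inputs (no valid pairs, bad config...)."""


# Directed pixel offsets (row, col) per unit distance. Image convention is
# row-major with origin at top-left, so 90 deg points up (negative row).
ANGLE_OFFSETS = {0: (0, 1), 90: (-1, 0), 180: (0, -1), 270: (1, 0)}


@dataclass(frozen=True)
class GlcmConfig:
    """Angles, distances and conventions for co-occurrence analysis."""

    levels: int = 256
    angles: tuple[int, ...] = (0, 90, 180, 270)
    distances: tuple[int, ...] = (1, 2, 3)
    entropy_log_base: float = 2.0

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise GlcmError("levels must be >= 2")
        if any(a not in ANGLE_OFFSETS for a in self.angles):
            raise GlcmError(f"angles must be among {sorted(ANGLE_OFFSETS)}")
        if any(d < 1 for d in self.distances):
            raise GlcmError("distances must be >= 1")
        if self.entropy_log_base <= 1:
            raise GlcmError("entropy log base must exceed 1")


def glcm(image, mask=None, angle: int = 0, distance: int = 1, levels: int = 256) -> np.ndarray:
    """Normalized directed co-occurrence matrix for one (angle, distance).

    Counts ordered pairs (grey at p, grey at p + offset) over all pixel
    positions p where both endpoints fall inside the mask (whole frame if
    ``mask`` is None), then divides by the pair count.

    Raises
    ------
    GlcmError
        If the offset yields no valid pair (mask or image too small).
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise GlcmError("image must be 2-D")
    if img.dtype != np.uint8 and (img.min() < 0 or img.max() > levels - 1):
        raise GlcmError(f"grey values must lie in [0, {levels - 1}]")
    img = img.astype(np.intp)
    if angle not in ANGLE_OFFSETS:
        raise GlcmError(f"unsupported angle {angle}")
    if distance < 1:
        raise GlcmError("distance must be >= 1")
    dr, dc = (o * distance for o in ANGLE_OFFSETS[angle])

    h, w = img.shape
    if mask is None:
        m = np.ones((h, w), dtype=bool)
    else:
        m = np.asarray(getattr(mask, "array", mask), dtype=bool)
        if m.shape != img.shape:
            raise GlcmError("mask shape must match image shape")

    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    if r0 >= r1 or c0 >= c1:
        raise GlcmError("offset larger than image; no valid pairs")
    src = img[r0:r1, c0:c1]
    dst = img[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    valid = m[r0:r1, c0:c1] & m[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    n_pairs = int(valid.sum())
    if n_pairs == 0:
        raise GlcmError("no pixel pair has both endpoints inside the mask")

    idx = src[valid] * levels + dst[valid]
    counts = np.bincount(idx, minlength=levels * levels).reshape(levels, levels)
    return counts.astype(np.float64) / n_pairs


@dataclass(frozen=True)
class HaralickFeatures:
    asm: float
    con: float
    corr: float
    idm: float
    ent: float

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.asm, self.con, self.corr, self.idm, self.ent)


def haralick_features(matrix, entropy_log_base: float = 2.0) -> HaralickFeatures:
    """The five texture features of one normalized co-occurrence matrix.

    CORR is returned as NaN (explicitly undefined) when either marginal has
    zero variance, e.g. for a constant image.
    """
    p = np.asarray(matrix, dtype=np.float64)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise GlcmError("matrix must be square")
    if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise GlcmError("matrix must be normalized (entries >= 0, sum 1)")

    n = p.shape[0]
    levels = np.arange(n, dtype=np.float64)
    pi = p.sum(axis=1)  # marginal of the first pixel
    pj = p.sum(axis=0)

    asm = float(np.sum(p * p))

    diff2 = (levels[:, None] - levels[None, :]) ** 2
    con = float(np.sum(diff2 * p))
    idm = float(np.sum(p / (1.0 + diff2)))

    nz = p[p > 0]
    ent = float(-np.sum(nz * np.log(nz) / np.log(entropy_log_base)))

    mu_i = float(np.sum(levels * pi))
    mu_j = float(np.sum(levels * pj))
    var_i = float(np.sum((levels - mu_i) ** 2 * pi))
    var_j = float(np.sum((levels - mu_j) ** 2 * pj))
    if var_i <= 0 or var_j <= 0:
        corr = float("nan")
    else:
        corr = float(
            np.sum((levels[:, None] - mu_i) * (levels[None, :] - mu_j) * p)
            / np.sqrt(var_i * var_j)
        )
    return HaralickFeatures(asm=asm, con=con, corr=corr, idm=idm, ent=ent)


@dataclass(frozen=True)
class GlcmFeatures:
    """Per-combination feature table plus the flat average over combinations."""

    asm: float
    con: float
    corr: float
    idm: float
    ent: float
    per_combination: pd.DataFrame = field(repr=False, compare=False)


def averaged_features(image, mask=None, config: GlcmConfig | None = None) -> GlcmFeatures:
    """Features averaged over every (angle, distance) combination.

    One matrix is built per combination (default 4 angles x 3 distances = 12);
    each feature's reported value is the arithmetic mean across combinations.
    The per-combination table is retained for QC, e.g. angle-dependence tests.
    """
    cfg = config or GlcmConfig()
    rows = []
    for d in cfg.distances:
        for a in cfg.angles:
            m = glcm(image, mask, angle=a, distance=d, levels=cfg.levels)
            f = haralick_features(m, entropy_log_base=cfg.entropy_log_base)
            rows.append({"angle": a, "distance": d, "asm": f.asm, "con": f.con,
                         "corr": f.corr, "idm": f.idm, "ent": f.ent})
    table = pd.DataFrame(rows)
    means = table[["asm", "con", "corr", "idm", "ent"]].mean(skipna=False)
    return GlcmFeatures(asm=float(means["asm"]), con=float(means["con"]),
                        corr=float(means["corr"]), idm=float(means["idm"]),
                        ent=float(means["ent"]), per_combination=table)
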