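"""Per-oocyte optical-density features: ROI mean OD, concentric ring ODs, GRAD.

The ooplasm ROI is a single connected pixel region.  Its centroid and
equivalent-area radius R = sqrt(area/pi) define four concentric rings C1..C4
at quarter-radius steps of normalized distance r/R:

    C1: [0, 0.25)   C2: [0.25, 0.5)   C3: [0.5, 0.75)   C4: [0.75, ...]

Ring OD is the mean calibrated OD over the annulus pixel set, equivalently
the integrated density difference between the outer and inner circle divided
by their area difference.  Mask pixels beyond R (non-circular ROIs) join C4,
so the rings always partition the mask.  The radial gradient statistic is

    GRAD = 100 * (mean(OD_C1, OD_C2) - mean(OD_C3, OD_C4)) / OD

a signed percentage contrasting the inner half of the ooplasm against the
outer half, normalized by the overall mean OD.

Pixel-to-ring assignment uses pixel-centre distance with half-open bins and
0-based row/col coordinates (origin top-left).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .calibration import CalibrationCurve, grey_to_od
from .texture import GlcmConfig, averaged_features

RING_EDGES = (0.0, 0.25, 0.5, 0.75, 1.0)
FEATURE_COLUMNS = ("od", "od_c1", "od_c2", "od_c3", "od_c4",
                   "grad", "asm", "con", "corr", "idm", "ent")


class RoiError(ValueError):
    """Raised for invalid ROI masks or degenerate ring decompositions."""


@dataclass(frozen=True)
class RoiMask:
    """Boolean ooplasm mask with derived centre and equivalent-area radius."""

    array: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.array, dtype=bool)
        if arr.ndim != 2:
            raise RoiError("mask must be 2-D")
        if not arr.any():
            raise RoiError("mask is empty")
        _, n_components = ndimage.label(arr)
        if n_components != 1:
            raise RoiError(f"mask must be a single connected component, found {n_components}")
        object.__setattr__(self, "array", arr)

    @property
    def area(self) -> int:
        return int(self.array.sum())

    @property
    def centroid(self) -> tuple[float, float]:
        rows, cols = np.nonzero(self.array)
        return float(rows.mean()), float(cols.mean())

    @property
    def radius(self) -> float:
        """Equivalent-area radius sqrt(area/pi), in pixels."""
        return float(np.sqrt(self.area / np.pi))


def _as_mask(mask) -> RoiMask:
    return mask if isinstance(mask, RoiMask) else RoiMask(np.asarray(mask))


def ring_labels(mask) -> np.ndarray:
    """Integer ring label per pixel: 1..4 inside the mask, 0 outside.

    Normalized pixel-centre distance r/R from the mask centroid is binned at
    quarter-radius edges; mask pixels with r/R >= 1 are assigned to C4.
    """
    roi = _as_mask(mask)
    cr, cc = roi.centroid
    radius = roi.radius
    rows, cols = np.indices(roi.array.shape)
    rnorm = np.hypot(rows - cr, cols - cc) / radius
    labels = np.zeros(roi.array.shape, dtype=np.int8)
    for k in range(4):
        lo, hi = RING_EDGES[k], RING_EDGES[k + 1]
        if k < 3:
            sel = (rnorm >= lo) & (rnorm < hi)
        else:
            sel = rnorm >= lo  # outermost ring absorbs r/R >= 1
        labels[sel & roi.array] = k + 1
    return labels


def measure_od(od_image, mask) -> float:
    """Arithmetic mean OD over the mask pixels of a calibrated OD image."""
    roi = _as_mask(mask)
    od = np.asarray(od_image, dtype=float)
    if od.shape != roi.array.shape:
        raise RoiError("OD image and mask shapes differ")
    return float(od[roi.array].mean())


def ring_od(od_image, mask) -> np.ndarray:
    """Mean OD of each concentric ring C1..C4 (length-4 array).

    Equivalent to (integrated density inside the outer circle minus inside
    the inner circle) divided by the corresponding pixel-count difference.

    Raises
    ------
    RoiError
        If any ring is empty (ROI too small for a quarter-radius annulus).
    """
    roi = _as_mask(mask)
    od = np.asarray(od_image, dtype=float)
    if od.shape != roi.array.shape:
        raise RoiError("OD image and mask shapes differ")
    labels = ring_labels(roi)
    out = np.empty(4, dtype=float)
    for k in range(1, 5):
        sel = labels == k
        if not sel.any():
            raise RoiError(f"ring C{k} contains no pixels; ROI too small")
        out[k - 1] = od[sel].mean()
    return out


def gradient(ring_ods, overall_od: float) -> float:
    """Radial gradient GRAD, in percent.

    100 * (mean of inner rings C1,C2 - mean of outer rings C3,C4) / overall OD.
    Positive when the centre is optically denser than the periphery.
    """
    c1, c2, c3, c4 = (float(v) for v in ring_ods)
    if overall_od <= 0:
        raise RoiError("GRAD undefined for non-positive overall OD")
    return 100.0 * ((c1 + c2) / 2.0 - (c3 + c4) / 2.0) / overall_od


@dataclass(frozen=True)
class FeatureVector:
    """All imaging parameters for one oocyte."""

    od: float
    od_rings: tuple[float, float, float, float]
    grad: float
    asm: float
    con: float
    corr: float
    idm: float
    ent: float
    oocyte_id: str | None = field(default=None, compare=False)

    def to_series(self) -> pd.Series:
        vals = {"od": self.od,
                "od_c1": self.od_rings[0], "od_c2": self.od_rings[1],
                "od_c3": self.od_rings[2], "od_c4": self.od_rings[3],
                "grad": self.grad, "asm": self.asm, "con": self.con,
                "corr": self.corr, "idm": self.idm, "ent": self.ent}
        return pd.Series(vals, name=self.oocyte_id)


def extract_features(image, mask, curve: CalibrationCurve,
                     glcm_config: GlcmConfig | None = None,
                     oocyte_id: str | None = None) -> FeatureVector:
    """Full feature vector for one oocyte image.

    OD features are computed on the calibrated OD image; texture features are
    computed on the raw 8-bit grey image restricted to the mask.
    """
    roi = _as_mask(mask)
    img = np.asarray(image)
    if img.shape != roi.array.shape:
        raise RoiError("image and mask shapes differ")
    od_img = grey_to_od(curve, img)
    od = measure_od(od_img, roi)
    rings = ring_od(od_img, roi)
    grad = gradient(rings, od)
    tex = averaged_features(img, roi, glcm_config)
    return FeatureVector(od=od, od_rings=tuple(rings), grad=grad,
                         asm=tex.asm, con=tex.con, corr=tex.corr,
                         idm=tex.idm, ent=tex.ent, oocyte_id=oocyte_id)


def features_table(vectors) -> pd.DataFrame:
    """Stack FeatureVectors into a cohort table (one row per oocyte)."""
    df = pd.DataFrame([v.to_series() for v in vectors])
    df.index.name = "oocyte_id"
    return df.reset_index()
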