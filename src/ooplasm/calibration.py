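"""Grey-value to optical-density calibration from a neutral-density step-filter series.

A transmission microscope is calibrated per session by imaging a variable
neutral-density filter whose steps have known optical densities (OD), plus a
clear-glass frame that anchors 0.0 OD.  The mean grey value of each step image
and its known OD define the knots of a monotone piecewise-linear map from 8-bit
grey value to OD, which is then applied pixelwise to specimen images.

Grey values fall as OD rises (denser filter transmits less light), so the knot
greys must be strictly decreasing in OD; a violation signals unstable
illumination and is rejected rather than silently reordered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class CalibrationError(ValueError):
    """Raised when a step series cannot define a valid grey->OD map."""


@dataclass(frozen=True)
class CalibrationCurve:
    """Monotone piecewise-linear map from 8-bit grey value to optical density.

    Parameters
    ----------
    step_greys
        Mean grey value of each calibration step, ordered by increasing OD
        (hence strictly decreasing grey).
    step_ods
        Optical density of each step, strictly increasing, dimensionless.

    The curve passes exactly through every ``(grey, od)`` knot.  Queries
    outside the measured grey range are clamped to the boundary OD: greys
    brighter than clear glass map to 0.0 OD and greys darker than the densest
    step map to the maximum calibrated OD, because OD outside the measured
    range is not physically calibrated.
    """

    step_greys: tuple[float, ...]
    step_ods: tuple[float, ...]

    def __post_init__(self) -> None:
        greys = np.asarray(self.step_greys, dtype=float)
        ods = np.asarray(self.step_ods, dtype=float)
        if greys.size != ods.size:
            raise CalibrationError("step_greys and step_ods differ in length")
        if greys.size < 2:
            raise CalibrationError("need at least two calibration steps")
        if not np.all(np.isfinite(greys)) or not np.all(np.isfinite(ods)):
            raise CalibrationError("non-finite calibration values")
        if np.any(np.diff(ods) <= 0):
            raise CalibrationError("step ODs must be strictly increasing")
        if np.any(np.diff(greys) >= 0):
            raise CalibrationError(
                "mean grey must strictly decrease with OD; "
                "non-monotone steps indicate unstable illumination"
            )
        object.__setattr__(self, "step_greys", tuple(greys))
        object.__setattr__(self, "step_ods", tuple(ods))

    def __call__(self, grey):
        return grey_to_od(self, grey)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"grey": self.step_greys, "od": self.step_ods})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CalibrationCurve":
        df = pd.read_csv(path)
        return cls(tuple(df["grey"]), tuple(df["od"]))


def fit_calibration(calibration_images) -> CalibrationCurve:
    """Fit the grey->OD curve from ``(image, od)`` pairs.

    Each image is a spatially uniform view of one filter step; its mean grey
    over the full frame becomes the knot grey for that step's OD.  Requires at
    least three steps including the 0.0 OD clear-glass frame.

    Raises
    ------
    CalibrationError
        Fewer than 3 steps, missing 0.0 OD anchor, duplicate grey values, or
        mean greys not strictly decreasing with OD.
    """
    pairs = []
    for image, od in calibration_images:
        arr = np.asarray(image)
        if arr.ndim != 2:
            raise CalibrationError("calibration images must be single-channel")
        pairs.append((float(np.mean(arr, dtype=np.float64)), float(od)))
    if len(pairs) < 3:
        raise CalibrationError("need at least 3 calibration steps")
    ods = [od for _, od in pairs]
    if not np.any(np.isclose(ods, 0.0)):
        raise CalibrationError("calibration series must include a 0.0 OD clear-glass image")
    pairs.sort(key=lambda p: p[1])
    greys = [g for g, _ in pairs]
    if len(set(greys)) != len(greys):
        raise CalibrationError("duplicate mean grey values across steps")
    return CalibrationCurve(tuple(greys), tuple(o for _, o in pairs))


def grey_to_od(curve: CalibrationCurve, grey):
    """Convert grey values (scalar or array) to OD via the calibration curve.

    Piecewise-linear interpolation between knots; out-of-range greys are
    clamped to the boundary OD.  Returns a float scalar for scalar input,
    else a float array of the same shape.
    """
    if not isinstance(curve, CalibrationCurve):
        raise CalibrationError("grey_to_od requires a fitted CalibrationCurve")
    # np.interp needs ascending x: greys ascend when ODs are reversed
    xs = np.asarray(curve.step_greys, dtype=float)[::-1]
    ys = np.asarray(curve.step_ods, dtype=float)[::-1]
    g = np.asarray(grey, dtype=float)
    od = np.interp(g, xs, ys)
    if np.isscalar(grey) or g.ndim == 0:
        return float(od)
    return od
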