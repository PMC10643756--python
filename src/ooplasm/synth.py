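"""Synthetic calibration stacks, textured oocyte images and simulated cohorts.

No oocyte micrographs were deposited with the study this package models, so
every downstream stage is exercised on synthetic data with known ground
truth:

* calibration stacks — one constant-intensity frame per neutral-density
  step (default: a 10-step 0.1-4.0 OD filter plus a clear-glass 0.0 OD
  frame) with optional i.i.d. Gaussian noise;
* oocyte images — a disk-shaped ooplasm on a bright background whose grey
  level is linear in normalized radius (a controllable radial gradient)
  plus Gaussian-blurred noise whose correlation length tunes texture
  homogeneity: longer correlation raises IDM and lowers ENT;
* cohorts — per-oocyte feature draws with binary outcomes following a
  logistic model on in-optimal-range indicators with planted log odds
  ratios, nested hierarchically (blastulation only for fertilised oocytes,
  implantation only for a transferred subset).

All generators take explicit integer seeds and never touch global random
state; identical specs and seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .calibration import CalibrationCurve

# Step densities of a 10-step variable neutral-density filter wheel spanning
# 0.1-4.0 OD, with the clear-glass 0.0 OD anchor prepended.
DEFAULT_STEP_ODS = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 1.0, 2.0, 3.0, 4.0)
# Camera grey per step: transmission-shaped (grey ~ 10^-OD) with a dark
# offset, hand-adjusted to stay strictly decreasing after 8-bit rounding.
DEFAULT_STEP_GREYS = (230, 183, 146, 117, 94, 76, 61, 34, 14, 8, 5)


class SynthError(ValueError):
    """Raised for invalid synthetic-data specifications."""


# ------------------------------------------------------ calibration stack

@dataclass(frozen=True)
class CalibrationStack:
    images: tuple  # uint8 arrays, one per step, ordered by OD
    truth: pd.DataFrame = field(repr=False)  # columns: od, grey

    def pairs(self):
        """(image, od) pairs ready for ``calibration.fit_calibration``."""
        return list(zip(self.images, self.truth["od"]))


def make_calibration_stack(step_ods=DEFAULT_STEP_ODS, step_greys=DEFAULT_STEP_GREYS,
                           noise_sd: float = 0.0, seed: int = 0,
                           shape: tuple[int, int] = (64, 64)) -> CalibrationStack:
    """Constant-intensity frame per ND step plus i.i.d. Gaussian noise.

    Frames are rounded and clipped to the 8-bit range.  Step greys must be
    strictly decreasing with increasing OD (denser filter, darker frame) and
    a 0.0 OD clear-glass entry must be present.

    Raises
    ------
    SynthError
        Mismatched lengths, missing 0.0 OD step, or non-monotone design.
    """
    ods = np.asarray(step_ods, dtype=float)
    greys = np.asarray(step_greys, dtype=float)
    if ods.size != greys.size:
        raise SynthError("step_ods and step_greys differ in length")
    if not np.any(np.isclose(ods, 0.0)):
        raise SynthError("design must include a 0.0 OD clear-glass step")
    order = np.argsort(ods)
    ods, greys = ods[order], greys[order]
    if np.any(np.diff(ods) <= 0) or np.any(np.diff(greys) >= 0):
        raise SynthError("calibration design error: grey must strictly "
                         "decrease with strictly increasing OD")
    if noise_sd < 0:
        raise SynthError("noise_sd must be >= 0")

    rng = np.random.default_rng(seed)
    images = []
    for g in greys:
        frame = np.full(shape, g, dtype=float)
        if noise_sd > 0:
            frame = frame + rng.normal(0.0, noise_sd, size=shape)
        images.append(np.clip(np.rint(frame), 0, 255).astype(np.uint8))
    truth = pd.DataFrame({"od": ods, "grey": greys})
    return CalibrationStack(images=tuple(images), truth=truth)


# --------------------------------------------------------- oocyte images

@dataclass(frozen=True)
class SyntheticImageSpec:
    """Geometry, radial profile and texture of one synthetic oocyte image.

    ``radial_slope`` is in grey units per unit normalized radius; positive
    values make the centre darker than the periphery.  ``texture_sigma`` is
    the noise amplitude in grey units after smoothing; ``texture_corr_len``
    is the Gaussian-blur length (pixels) controlling homogeneity.
    """

    width: int = 96
    height: int = 96
    disk_center: tuple[float, float] = (48.0, 48.0)  # (row, col)
    disk_radius: float = 36.0
    base_grey: float = 120.0
    radial_slope: float = 0.0
    texture_sigma: float = 0.0
    texture_corr_len: float = 0.0
    background_grey: float = 235.0
    seed: int = 0

    def __post_init__(self) -> None:
        cr, cc = self.disk_center
        if not (0 <= self.base_grey <= 255):
            raise SynthError("base_grey must lie in [0, 255]")
        if self.disk_radius <= 0:
            raise SynthError("disk_radius must be positive")
        if self.texture_corr_len < 0 or self.texture_sigma < 0:
            raise SynthError("texture parameters must be >= 0")
        if (cr - self.disk_radius < 0 or cr + self.disk_radius > self.height - 1
                or cc - self.disk_radius < 0 or cc + self.disk_radius > self.width - 1):
            raise SynthError("disk must fit fully inside the frame")


@dataclass(frozen=True)
class OocyteSample:
    """A rendered oocyte image with its mask and noise-free ground truth."""

    image: np.ndarray  # uint8
    mask: np.ndarray  # bool
    truth: dict = field(repr=False)


_RING_EDGES = (0.0, 0.25, 0.5, 0.75)


def _noiseless_disk(spec: SyntheticImageSpec):
    rows, cols = np.indices((spec.height, spec.width), dtype=float)
    cr, cc = spec.disk_center
    rnorm = np.hypot(rows - cr, cols - cc) / spec.disk_radius
    inside = rnorm <= 1.0
    profile = np.full((spec.height, spec.width), spec.background_grey, dtype=float)
    # positive slope = darker centre: grey rises from base_grey at the centre
    # to base_grey + slope at the rim
    profile[inside] = spec.base_grey + spec.radial_slope * rnorm[inside]
    return profile, inside, rnorm


def make_oocyte_image(spec: SyntheticImageSpec,
                      curve: CalibrationCurve | None = None) -> OocyteSample:
    """Render a textured oocyte disk with analytic ring/GRAD ground truth.

    The noise field is white Gaussian noise convolved with a Gaussian kernel
    of width ``texture_corr_len`` and rescaled back to ``texture_sigma``,
    applied inside the disk only.  Ground truth (per-ring mean grey, and ring
    ODs/GRAD when a calibration curve is supplied) is evaluated on the
    noise-free unquantized profile, so extraction on the rendered image
    agrees with it up to grey-level quantization and noise.
    """
    profile, inside, rnorm = _noiseless_disk(spec)

    img = profile.copy()
    if spec.texture_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        noise = rng.normal(0.0, 1.0, size=profile.shape)
        if spec.texture_corr_len > 0:
            noise = ndimage.gaussian_filter(noise, spec.texture_corr_len)
            sd = noise.std()
            if sd > 0:
                noise = noise / sd
        img[inside] += spec.texture_sigma * noise[inside]
    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    truth: dict = {}
    ring_greys = np.empty(4)
    edges = (*_RING_EDGES, np.inf)
    for k in range(4):
        sel = inside & (rnorm >= edges[k]) & (rnorm < edges[k + 1])
        ring_greys[k] = profile[sel].mean()
    truth["mean_grey"] = float(profile[inside].mean())
    truth["ring_greys"] = ring_greys
    if curve is not None:
        od_img = curve(profile)
        ring_ods = np.empty(4)
        for k in range(4):
            sel = inside & (rnorm >= edges[k]) & (rnorm < edges[k + 1])
            ring_ods[k] = od_img[sel].mean()
        od = float(od_img[inside].mean())
        truth["ring_ods"] = ring_ods
        truth["od"] = od
        truth["grad"] = (100.0 * ((ring_ods[0] + ring_ods[1]) / 2
                                  - (ring_ods[2] + ring_ods[3]) / 2) / od
                         if od > 0 else float("nan"))
    return OocyteSample(image=image, mask=inside, truth=truth)


# -------------------------------------------------------------- cohorts

def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def solve_intercept(coefs, in_probs, target_rate: float) -> float:
    """Intercept making the marginal outcome rate hit ``target_rate``.

    ``coefs`` maps feature -> planted log odds ratio and ``in_probs`` maps
    feature -> P(indicator = 1); indicators are assumed independent, so the
    marginal rate is the mixture of logistic probabilities over the 2^k
    indicator cells.  Solved deterministically by bracketing.
    """
    feats = sorted(coefs)
    k = len(feats)

    def rate(a: float) -> float:
        total = 0.0
        for cell in range(2**k):
            bits = [(cell >> j) & 1 for j in range(k)]
            w = np.prod([in_probs[f] if b else 1 - in_probs[f]
                         for f, b in zip(feats, bits)])
            total += w * _sigmoid(a + sum(coefs[f] * b for f, b in zip(feats, bits)))
        return total

    if not 0 < target_rate < 1:
        raise SynthError("target rate must lie in (0, 1)")
    return float(optimize.brentq(lambda a: rate(a) - target_rate, -30.0, 30.0))


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Feature distributions and planted outcome models for a cohort.

    ``planted_log_odds`` maps outcome name -> {"intercept": a, "coefs":
    {feature: log odds ratio}}; the success probability of an oocyte is
    logistic(a + sum coef * indicator).  ``optimal_ranges`` gives the
    continuous (low, high] bounds defining each in-range indicator.
    Outcomes named ``blastulation``/``implantation`` follow the clinical
    hierarchy: blastulation is drawn only for fertilised oocytes selected
    for extended culture, implantation only for a transferred subset of
    blastocysts.
    """

    n_oocytes: int
    feature_means: dict
    feature_sds: dict
    optimal_ranges: dict
    planted_log_odds: dict
    seed: int = 0
    cultured_frac: float = 1.0
    transfer_frac: float = 1.0
    failure_probs: dict | None = None  # category -> prob among unfertilised
    feature_corr: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_oocytes < 8:
            raise SynthError("n_oocytes must be >= 8 so quartiles are populated")
        feats = set(self.feature_means)
        if feats != set(self.feature_sds) or not feats >= set(self.optimal_ranges):
            raise SynthError("feature parameter dictionaries are inconsistent")
        for out, spec in self.planted_log_odds.items():
            if not np.isfinite(spec["intercept"]):
                raise SynthError(f"non-finite intercept for outcome {out!r}")
            unknown = set(spec["coefs"]) - set(self.optimal_ranges)
            if unknown:
                raise SynthError(f"outcome {out!r} references features without "
                                 f"optimal ranges: {sorted(unknown)}")
        if not (0 < self.cultured_frac <= 1 and 0 < self.transfer_frac <= 1):
            raise SynthError("cultured_frac and transfer_frac must lie in (0, 1]")


def simulate_cohort(spec: SyntheticCohortSpec) -> pd.DataFrame:
    """Draw a cohort table: features, indicators and hierarchical outcomes.

    Returns one row per oocyte with the continuous features, the planted
    in-range indicator per feature with an optimal range, and binary outcome
    columns (NaN where the outcome is undefined for that oocyte).
    """
    rng = np.random.default_rng(spec.seed)
    feats = sorted(spec.feature_means)
    n = spec.n_oocytes

    sds = np.array([spec.feature_sds[f] for f in feats])
    means = np.array([spec.feature_means[f] for f in feats])
    if spec.feature_corr is not None:
        corr = np.asarray(spec.feature_corr, dtype=float)
        cov = corr * np.outer(sds, sds)
        draws = rng.multivariate_normal(means, cov, size=n)
    else:
        draws = means + sds * rng.standard_normal((n, len(feats)))
    df = pd.DataFrame(draws, columns=feats)
    df.insert(0, "oocyte_id", [f"oo{i:04d}" for i in range(n)])

    indicators = {}
    for f, (lo, hi) in spec.optimal_ranges.items():
        ind = ((df[f] > lo) & (df[f] <= hi)).astype(int)
        indicators[f] = ind.to_numpy()
        df[f"{f}_in_range"] = ind

    def outcome_probs(name: str) -> np.ndarray:
        planted = spec.planted_log_odds[name]
        eta = np.full(n, planted["intercept"], dtype=float)
        for f, b in planted["coefs"].items():
            eta += b * indicators[f]
        return _sigmoid(eta)

    fert = None
    if "fertilised" in spec.planted_log_odds:
        fert = (rng.random(n) < outcome_probs("fertilised")).astype(float)
        df["fertilised"] = fert
        if spec.failure_probs:
            cats = list(spec.failure_probs)
            probs = np.array([spec.failure_probs[c] for c in cats], dtype=float)
            probs = probs / probs.sum()
            fail = pd.array([None] * n, dtype="object")
            idx = np.nonzero(fert == 0)[0]
            fail[idx] = rng.choice(cats, size=idx.size, p=probs)
            df["failure_category"] = fail

    if "blastulation" in spec.planted_log_odds:
        if fert is None:
            raise SynthError("blastulation requires a fertilisation model")
        cultured = (fert == 1) & (rng.random(n) < spec.cultured_frac)
        blast = np.full(n, np.nan)
        blast[cultured] = (rng.random(cultured.sum())
                           < outcome_probs("blastulation")[cultured]).astype(float)
        df["blastulation"] = blast

        if "implantation" in spec.planted_log_odds:
            transferred = (blast == 1) & (rng.random(n) < spec.transfer_frac)
            df["transferred"] = transferred.astype(float)
            impl = np.full(n, np.nan)
            impl[transferred] = (rng.random(transferred.sum())
                                 < outcome_probs("implantation")[transferred]).astype(float)
            df["implantation"] = impl

    return df


def clinical_cohort_spec(n_oocytes: int = 957, seed: int = 0,
                           target_rates: dict | None = None) -> SyntheticCohortSpec:
    """Cohort spec with planted odds ratios at the published point estimates.

    Features OD, GRAD, IDM and ENT are independent normals with defaults in
    the range plausible for calibrated ooplasm measurements; each optimal
    range is the central 50% of its feature's distribution, so every
    indicator is Bernoulli(1/2).  Planted odds ratios: fertilisation OD 4.71,
    GRAD 2.31, IDM 2.01; blastulation OD 2.756, GRAD 2.686, IDM 0.572,
    ENT 0.330; implantation OD 7.756, GRAD 0.087, ENT 0.019.  Intercepts are
    solved so marginal outcome rates match the published cohort (73.0%
    fertilisation, 67.9% blastulation among cultured, 50.9% implantation).
    """
    means = {"od": 0.55, "grad": 4.0, "idm": 0.90, "ent": 4.8}
    sds = {"od": 0.12, "grad": 6.0, "idm": 0.04, "ent": 0.9}
    z = 0.6744897501960817  # central 50% of a normal
    ranges = {f: (means[f] - z * sds[f], means[f] + z * sds[f]) for f in means}

    coefs = {
        "fertilised": {"od": np.log(4.71), "grad": np.log(2.31), "idm": np.log(2.01)},
        "blastulation": {"od": np.log(2.756), "grad": np.log(2.686),
                         "idm": np.log(0.572), "ent": np.log(0.330)},
        "implantation": {"od": np.log(7.756), "grad": np.log(0.087),
                         "ent": np.log(0.019)},
    }
    rates = {"fertilised": 0.730, "blastulation": 0.679, "implantation": 0.509}
    if target_rates:
        rates.update(target_rates)
    # Intercepts are solved hierarchically: conditioning on the previous
    # outcome re-weights the indicator cells (fertilised oocytes are more
    # often in-range), so each stage's marginal rate is matched within the
    # subcohort that stage is actually drawn on.
    feats_all = sorted(means)
    cells = [tuple((c >> j) & 1 for j in range(len(feats_all)))
             for c in range(2 ** len(feats_all))]
    weights = np.full(len(cells), 1.0 / len(cells))

    def cell_prob(intercept, cf):
        etas = np.array([intercept + sum(cf.get(f, 0.0) * b
                                         for f, b in zip(feats_all, cell))
                         for cell in cells])
        return 1.0 / (1.0 + np.exp(-etas))

    planted = {}
    for out in ("fertilised", "blastulation", "implantation"):
        cf = coefs[out]
        w = weights

        def gap(a, cf=cf, w=w, target=rates[out]):
            return float(w @ cell_prob(a, cf)) - target

        a = float(optimize.brentq(gap, -30.0, 30.0))
        planted[out] = {"intercept": a, "coefs": cf}
        p = cell_prob(a, cf)
        weights = weights * p / float(weights @ p)
    failure = {"0PN": 129 / 258, "1PN": 24 / 258, "3PN": 25 / 258,
               "degenerated": 80 / 258}
    return SyntheticCohortSpec(n_oocytes=n_oocytes, feature_means=means,
                               feature_sds=sds, optimal_ranges=ranges,
                               planted_log_odds=planted, seed=seed,
                               cultured_frac=645 / 699, transfer_frac=114 / 438,
                               failure_probs=failure)


# ------------------------------------------- set-up experiment simulators

def simulate_repeated_od(n_oocytes: int = 50, od_mean: float = 0.55,
                         od_sd: float = 0.12, noise_sd: float = 0.01,
                         seed: int = 0) -> np.ndarray:
    """Two independent noisy OD measurements per oocyte, shape (n, 2).

    Emulates re-measuring the same oocytes after re-preparing the optics:
    both sessions see the oocyte's true OD plus independent measurement
    noise.  Small ``noise_sd`` relative to ``od_sd`` gives high r^2 and a
    non-significant paired shift.
    """
    rng = np.random.default_rng(seed)
    true = rng.normal(od_mean, od_sd, size=n_oocytes)
    return np.stack([true + rng.normal(0, noise_sd, n_oocytes) for _ in range(2)],
                    axis=1)


def simulate_focal_planes(n_oocytes: int = 10, n_planes: int = 11,
                          od_mean: float = 0.55, od_sd: float = 0.12,
                          defocus_slope_sd: float = 0.004,
                          noise_sd: float = 0.005, seed: int = 0) -> np.ndarray:
    """Per-oocyte OD across focal planes under a linear defocus model.

    Each oocyte's OD varies linearly with plane offset from the equatorial
    plane (the middle index), with a per-oocyte random slope, plus
    measurement noise.  With planes symmetric about the equator the plane
    mean equals the equatorial OD up to noise, so the mean-vs-equatorial
    r^2 is high.  Shape: (n_oocytes, n_planes); equatorial index
    ``n_planes // 2``.
    """
    rng = np.random.default_rng(seed)
    true = rng.normal(od_mean, od_sd, size=n_oocytes)
    slopes = rng.normal(0.0, defocus_slope_sd, size=n_oocytes)
    offsets = np.arange(n_planes) - n_planes // 2
    planes = true[:, None] + slopes[:, None] * offsets[None, :]
    planes += rng.normal(0.0, noise_sd, size=planes.shape)
    return planes
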