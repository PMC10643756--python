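"""Evaluation statistics: repeatability, focal-plane and angle checks,
Mann-Whitney comparisons, and classifier confusion metrics.

Conventions used throughout: two-sided p-values; Wilcoxon signed-rank drops
zero differences and uses the tie-corrected normal approximation; the
Mann-Whitney U test switches from exact enumeration to the tie-corrected
normal approximation above a combined sample size of 12.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps


class StatsError(ValueError):
    """Raised for degenerate statistical inputs (constant vectors etc.)."""


# ---------------------------------------------------------------- helpers

def pearson_r2(x, y) -> float:
    """Squared Pearson correlation; errors on constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise StatsError("need >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise StatsError("correlation undefined for a constant vector")
    r, _ = sps.pearsonr(x, y)
    return float(r * r)


def wilcoxon_signed_rank(first, second) -> tuple[float, float]:
    """Tie-corrected normal-approximation Wilcoxon signed-rank test.

    Zero differences are dropped (Wilcoxon's original convention).  The z
    statistic is signed so that z > 0 means the second measurement tends to
    exceed the first; swapping the inputs negates z.  Returns ``(z, p)``;
    if every difference is zero the degenerate contract (0.0, 1.0) applies.
    """
    d = np.asarray(second, dtype=float) - np.asarray(first, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0, 1.0
    ranks = sps.rankdata(np.abs(d))
    t_plus = float(ranks[d > 0].sum())
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(ranks, return_counts=True)
    var -= np.sum(counts**3 - counts) / 48.0
    if var <= 0:
        return 0.0, 1.0
    z = (t_plus - mean) / math.sqrt(var)
    p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return float(z), float(p)


# ------------------------------------------------- set-up experiment stats

@dataclass(frozen=True)
class RepeatabilityResult:
    r2: float
    wilcoxon_z: float
    p: float


def repeatability(pairs) -> RepeatabilityResult:
    """Agreement between two repeated measurements of the same oocytes.

    ``pairs`` is a sequence of (measurement1, measurement2).  Returns the
    squared Pearson correlation between the two measurement vectors and the
    Wilcoxon signed-rank z/p for a systematic shift between sessions.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise StatsError("need >= 3 (m1, m2) pairs")
    if not np.all(np.isfinite(arr)):
        raise StatsError("non-finite measurements")
    m1, m2 = arr[:, 0], arr[:, 1]
    if np.ptp(m1) == 0 and np.ptp(m2) == 0 and np.all(m1 == m2):
        r2 = 1.0  # identical constant repeats: perfect agreement by contract
    else:
        r2 = pearson_r2(m1, m2)
    z, p = wilcoxon_signed_rank(m1, m2)
    return RepeatabilityResult(r2=r2, wilcoxon_z=z, p=p)


def focal_plane_check(plane_ods, equatorial_index: int) -> float:
    """r^2 between per-oocyte mean OD over focal planes and the equatorial OD.

    ``plane_ods`` is an (n_oocytes, n_planes) array; every oocyte must have
    the same plane count.  A high r^2 supports measuring at the equatorial
    plane only.
    """
    arr = np.asarray(plane_ods, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3:
        raise StatsError("need >= 3 oocytes with equal plane counts")
    if not 0 <= equatorial_index < arr.shape[1]:
        raise StatsError("equatorial_index out of range")
    means = arr.mean(axis=1)
    equatorial = arr[:, equatorial_index]
    if np.allclose(means, equatorial):
        return 1.0
    return pearson_r2(means, equatorial)


def kruskal_wallis(groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H across groups, p from chi-square.

    When every observation is identical the test degenerates to H = 0, p = 1
    (no between-group variation by construction).
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(g.size == 0 for g in gs):
        raise StatsError("need >= 2 non-empty groups")
    pooled = np.concatenate(gs)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = sps.kruskal(*gs)
    return float(h), float(p)


def angle_dependence(feature_table: pd.DataFrame,
                     feature_cols=("asm", "con", "corr", "idm", "ent")) -> pd.DataFrame:
    """Kruskal-Wallis across orientations, per feature and distance.

    ``feature_table`` is a tidy per-oocyte per-combination table with
    ``angle`` and ``distance`` columns plus one column per feature (the
    concatenation of texture per-combination tables over oocytes).  Each
    feature/distance cell compares the four angle groups; a non-significant
    result means no orientation preference.
    """
    required = {"angle", "distance"}
    if not required <= set(feature_table.columns):
        raise StatsError("feature_table needs 'angle' and 'distance' columns")
    rows = []
    for (dist,), sub in feature_table.groupby(["distance"]):
        angles = sorted(sub["angle"].unique())
        if len(angles) < 2:
            raise StatsError("need >= 2 angle groups per distance")
        for feat in feature_cols:
            groups = [sub.loc[sub["angle"] == a, feat].dropna().to_numpy() for a in angles]
            if any(g.size < 2 for g in groups):
                raise StatsError(f"angle group with <2 observations for {feat}@d={dist}")
            h, p = kruskal_wallis(groups)
            rows.append({"feature": feat, "distance": dist, "H": h, "p": p})
    return pd.DataFrame(rows)


# ------------------------------------------------------------ Mann-Whitney

@dataclass(frozen=True)
class GroupComparison:
    """Mann-Whitney U comparison of a feature between two independent groups."""

    feature: str
    median_a: float
    iqr_a: tuple[float, float]
    median_b: float
    iqr_b: tuple[float, float]
    u: float
    p: float
    method: str  # "exact" or "normal"


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for group a via midranks (ties count one half)."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    r_a = ranks[: a.size].sum()
    return float(r_a - a.size * (a.size + 1) / 2.0)


def _exact_two_sided_p(a: np.ndarray, b: np.ndarray, u_obs: float) -> float:
    """Exact two-sided p by enumerating every group-a subset of the pooled values."""
    pooled = np.concatenate([a, b])
    n, n1 = pooled.size, a.size
    us = []
    for idx in combinations(range(n), n1):
        sel = np.zeros(n, dtype=bool)
        sel[list(idx)] = True
        us.append(_u_statistic(pooled[sel], pooled[~sel]))
    us = np.asarray(us)
    mean_u = a.size * b.size / 2.0
    dev = abs(u_obs - mean_u)
    # two-sided: all assignments at least as extreme (either tail), tie-safe
    p = np.mean(np.abs(us - mean_u) >= dev - 1e-12)
    return float(min(1.0, p))


def mann_whitney(group_a, group_b, feature: str = "", exact_max_n: int = 12) -> GroupComparison:
    """Two-sided Mann-Whitney U test between independent groups.

    Exact enumeration of all C(n, n1) group assignments when the combined
    sample size is <= ``exact_max_n``; tie-corrected normal approximation
    (no continuity correction) otherwise.  Identical pooled values give the
    degenerate contract p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise StatsError("both groups must be non-empty")
    u = _u_statistic(a, b)
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        p, method = 1.0, "degenerate"
    elif a.size + b.size <= exact_max_n:
        p, method = _exact_two_sided_p(a, b, u), "exact"
    else:
        n1, n2, n = a.size, b.size, a.size + b.size
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            p, method = 1.0, "degenerate"
        else:
            # continuity correction: U is discrete on a half-integer lattice
            z = max(abs(u - n1 * n2 / 2.0) - 0.5, 0.0) / math.sqrt(var)
            p, method = min(1.0, 2.0 * sps.norm.sf(z)), "normal"

    q1a, med_a, q3a = np.percentile(a, [25, 50, 75])
    q1b, med_b, q3b = np.percentile(b, [25, 50, 75])
    return GroupComparison(feature=feature, median_a=float(med_a),
                           iqr_a=(float(q1a), float(q3a)), median_b=float(med_b),
                           iqr_b=(float(q1b), float(q3b)), u=u, p=float(p),
                           method=method)


def compare_groups(table: pd.DataFrame, outcome_col: str, feature_cols) -> pd.DataFrame:
    """Mann-Whitney comparison of each feature between outcome 1 and 0 rows.

    Emits one tidy row per feature (medians, IQRs, U, p), mirroring a
    per-outcome comparison table.  Rows with missing outcome are dropped.
    """
    sub = table.dropna(subset=[outcome_col])
    pos = sub[sub[outcome_col] == 1]
    neg = sub[sub[outcome_col] == 0]
    rows = []
    for feat in feature_cols:
        c = mann_whitney(pos[feat].to_numpy(), neg[feat].to_numpy(), feature=feat)
        rows.append({"feature": feat,
                     "median_pos": c.median_a, "iqr_pos_low": c.iqr_a[0],
                     "iqr_pos_high": c.iqr_a[1], "median_neg": c.median_b,
                     "iqr_neg_low": c.iqr_b[0], "iqr_neg_high": c.iqr_b[1],
                     "U": c.u, "p": c.p})
    return pd.DataFrame(rows)


# ------------------------------------------------------- normality gates

def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk normality gate (descriptive only; gates reporting)."""
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise StatsError("Shapiro-Wilk needs >= 3 observations")
    w, p = sps.shapiro(v)
    return float(w), float(p)


def brown_forsythe(*groups) -> tuple[float, float]:
    """Brown-Forsythe (median-centred Levene) equality-of-variance gate."""
    if len(groups) < 2:
        raise StatsError("need >= 2 groups")
    stat, p = sps.levene(*[np.asarray(g, dtype=float) for g in groups], center="median")
    return float(stat), float(p)


# ------------------------------------------------------ confusion metrics

def _pct(num: int, den: int) -> float:
    return 100.0 * num / den if den > 0 else float("nan")


@dataclass(frozen=True)
class ConfusionMetrics:
    """2x2 classification counts with percentage metrics.

    Metrics with a zero denominator are NaN (explicitly undefined), never 0.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def accuracy(self) -> float:
        return _pct(self.tp + self.tn, self.total)

    @property
    def ppv(self) -> float:
        return _pct(self.tp, self.tp + self.fp)

    @property
    def sensitivity(self) -> float:
        return _pct(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return _pct(self.tn, self.tn + self.fp)

    def to_series(self) -> pd.Series:
        return pd.Series({"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
                          "accuracy": self.accuracy, "ppv": self.ppv,
                          "sensitivity": self.sensitivity,
                          "specificity": self.specificity})


def confusion_metrics(predicted, actual) -> ConfusionMetrics:
    """Counts and percentage metrics from binary predictions vs outcomes."""
    pred = np.asarray(predicted).astype(bool)
    act = np.asarray(actual).astype(bool)
    if pred.shape != act.shape:
        raise StatsError("predicted and actual lengths differ")
    return ConfusionMetrics(tp=int(np.sum(pred & act)), fp=int(np.sum(pred & ~act)),
                            fn=int(np.sum(~pred & act)), tn=int(np.sum(~pred & ~act)))
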