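"""Set-up experiment statistics, Mann-Whitney contracts, confusion metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from ooplasm.stats import (StatsError, angle_dependence, brown_forsythe,
                           confusion_metrics, focal_plane_check, kruskal_wallis,
                           mann_whitney, pearson_r2, repeatability, shapiro_wilk,
                           wilcoxon_signed_rank)


# ------------------------------------------------------------ repeatability

def test_identical_pairs_perfect_agreement():
    pairs = [(0.4, 0.4), (0.5, 0.5), (0.61, 0.61), (0.7, 0.7)]
    res = repeatability(pairs)
    assert res.r2 == 1.0 and res.wilcoxon_z == 0.0 and res.p == 1.0


def test_swapping_measurements_negates_z_preserves_r2():
    rng = np.random.default_rng(2)
    m1 = rng.normal(0.5, 0.1, 30)
    m2 = m1 + rng.normal(0.003, 0.01, 30)
    a = repeatability(np.stack([m1, m2], axis=1))
    b = repeatability(np.stack([m2, m1], axis=1))
    assert a.r2 == pytest.approx(b.r2)
    assert a.wilcoxon_z == pytest.approx(-b.wilcoxon_z)


def test_small_noise_repeats_high_r2_non_significant_shift():
    """Repeated OD with small measurement noise: the published pattern of a
    high coefficient of determination and a non-significant Wilcoxon."""
    rng = np.random.default_rng(5)
    true = rng.normal(0.55, 0.12, 50)
    pairs = np.stack([true + rng.normal(0, 0.01, 50),
                      true + rng.normal(0, 0.01, 50)], axis=1)
    res = repeatability(pairs)
    assert res.r2 > 0.95
    assert res.p > 0.05


def test_constant_vector_correlation_error():
    with pytest.raises(StatsError, match="constant"):
        pearson_r2([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


# ------------------------------------------------------------ focal planes

def test_equal_planes_give_r2_one():
    planes = np.tile(np.array([[0.4], [0.5], [0.6]]), (1, 11))
    assert focal_plane_check(planes, 5) == 1.0


def test_constant_plane_offset_leaves_r2_unchanged():
    rng = np.random.default_rng(7)
    planes = rng.normal(0.5, 0.1, (10, 11))
    base = focal_plane_check(planes, 5)
    shifted = focal_plane_check(planes + 0.2, 5)
    assert shifted == pytest.approx(base)


def test_focal_plane_contracts():
    with pytest.raises(StatsError):
        focal_plane_check(np.ones((2, 11)), 5)
    with pytest.raises(StatsError):
        focal_plane_check(np.ones((5, 11)), 11)


# ----------------------------------------------------------- Kruskal-Wallis

def test_identical_values_degenerate_h_zero():
    assert kruskal_wallis([[1.0, 1.0], [1.0, 1.0]]) == (0.0, 1.0)


def test_kruskal_matches_rank_formula_on_worked_instance():
    groups = [[1, 2], [3, 4], [5, 6], [7, 8]]
    # direct rank-sum evaluation: H = 12/(N(N+1)) * sum n_i (rbar_i - (N+1)/2)^2
    mean_ranks = [1.5, 3.5, 5.5, 7.5]
    h_manual = 12.0 / (8 * 9) * sum(2 * (rb - 4.5) ** 2 for rb in mean_ranks)
    h, p = kruskal_wallis(groups)
    assert h == pytest.approx(h_manual)
    assert p == pytest.approx(1 - sps.chi2.cdf(h_manual, df=3))


def test_angle_dependence_non_significant_for_duplicated_groups():
    """Opposite orientations give identical features, so angle groups are
    pairwise duplicated and the Kruskal-Wallis test must be non-significant."""
    rng = np.random.default_rng(9)
    rows = []
    for oocyte in range(10):
        for d in (1, 2, 3):
            v0 = rng.normal(0.5, 0.1)
            v90 = v0 + rng.normal(0, 0.02)
            for angle, v in ((0, v0), (180, v0), (90, v90), (270, v90)):
                rows.append({"angle": angle, "distance": d, "asm": v,
                             "con": v * 2, "corr": v - 0.5, "idm": v,
                             "ent": 1 - v})
    res = angle_dependence(pd.DataFrame(rows))
    assert len(res) == 15  # 5 features x 3 distances
    assert (res["p"] > 0.05).all()


# ------------------------------------------------------------ Mann-Whitney

def test_separated_groups_exact_enumeration():
    c = mann_whitney([1, 2, 3], [4, 5, 6])
    assert c.u == 0.0
    assert c.p == pytest.approx(0.1)  # 2 of C(6,3)=20 assignments as extreme
    assert c.method == "exact"


def test_group_swap_symmetry():
    a, b = [1.0, 2.5, 3.0, 7.0], [2.0, 4.0, 6.0]
    ca, cb = mann_whitney(a, b), mann_whitney(b, a)
    assert ca.u + cb.u == len(a) * len(b)
    assert ca.p == pytest.approx(cb.p)


def test_identical_groups_degenerate_p():
    assert mann_whitney([2.0, 2.0], [2.0, 2.0, 2.0]).p == 1.0


def test_exact_matches_scipy_enumeration_without_ties():
    rng = np.random.default_rng(13)
    for _ in range(10):
        a = rng.normal(size=5)
        b = rng.normal(size=6)
        ours = mann_whitney(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert ours.method == "exact"
        assert ours.u == pytest.approx(ref.statistic)
        assert ours.p == pytest.approx(ref.pvalue)


def test_exact_and_normal_agree_within_002_at_n12():
    rng = np.random.default_rng(21)
    for _ in range(20):
        a = rng.normal(size=6)
        b = rng.normal(size=6)
        exact = mann_whitney(a, b).p
        approx = mann_whitney(a, b, exact_max_n=0).p
        assert abs(exact - approx) <= 0.02


def test_empty_group_error():
    with pytest.raises(StatsError):
        mann_whitney([], [1.0])


# --------------------------------------------------------- Wilcoxon + gates

def test_wilcoxon_all_zero_differences_degenerate():
    assert wilcoxon_signed_rank([1, 2, 3], [1, 2, 3]) == (0.0, 1.0)


def test_wilcoxon_sign_convention():
    first = np.zeros(10)
    second = np.arange(1.0, 11.0)  # second uniformly larger -> z > 0
    z, p = wilcoxon_signed_rank(first, second)
    assert z > 0 and p < 0.05


def test_normality_and_variance_gates_pass_through():
    rng = np.random.default_rng(17)
    x = rng.normal(size=40)
    w, p = shapiro_wilk(x)
    assert 0 < w <= 1 and 0 < p <= 1
    stat, p2 = brown_forsythe(x, rng.normal(size=35))
    assert stat >= 0 and 0 < p2 <= 1


# -------------------------------------------------------- confusion metrics

def test_symmetric_confusion_table():
    pred = [1] * 8 + [1] * 2 + [0] * 2 + [0] * 8
    act = [1] * 8 + [0] * 2 + [1] * 2 + [0] * 8
    m = confusion_metrics(pred, act)
    assert (m.tp, m.fp, m.fn, m.tn) == (8, 2, 2, 8)
    assert m.accuracy == m.ppv == m.sensitivity == m.specificity == 80.0


def test_perfect_and_degenerate_classifiers():
    perfect = confusion_metrics([1, 0, 1, 0], [1, 0, 1, 0])
    assert perfect.accuracy == perfect.ppv == 100.0
    assert perfect.sensitivity == perfect.specificity == 100.0
    all_pos = confusion_metrics([1, 1, 1, 1], [1, 1, 0, 0])
    assert all_pos.sensitivity == 100.0 and all_pos.specificity == 0.0
    assert all_pos.ppv == 50.0


def test_zero_denominator_metrics_are_nan_not_zero():
    m = confusion_metrics([0, 0], [0, 0])  # no predicted or actual positives
    assert np.isnan(m.ppv) and np.isnan(m.sensitivity)
    assert m.specificity == 100.0


@settings(derandomize=True, max_examples=50)
@given(st.integers(0, 20), st.integers(0, 20), st.integers(0, 20), st.integers(0, 20))
def test_metrics_match_closed_forms(tp, fp, fn, tn):
    if tp + fp + fn + tn == 0:
        return
    pred = [1] * tp + [1] * fp + [0] * fn + [0] * tn
    act = [1] * tp + [0] * fp + [1] * fn + [0] * tn
    m = confusion_metrics(pred, act)
    assert m.accuracy == pytest.approx(100 * (tp + tn) / (tp + fp + fn + tn))
    if tp + fp:
        assert m.ppv == pytest.approx(100 * tp / (tp + fp))
    if tp + fn:
        assert m.sensitivity == pytest.approx(100 * tp / (tp + fn))
    if tn + fp:
        assert m.specificity == pytest.approx(100 * tn / (tn + fp))
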