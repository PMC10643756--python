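"""Quartile recoding, optimal ranges, logistic fits and ROC/AUC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ooplasm.model import (ModelError, SeparationError, assign_quartiles, classify,
                           fit_logistic, fit_outcome_model, optimal_range,
                           quartile_of, quartile_rate_table, roc_auc)
from ooplasm.stats import mann_whitney
from ooplasm.synth import clinical_cohort_spec, simulate_cohort


# --------------------------------------------------------------- quartiles

def test_values_one_to_eight_split_two_per_quartile():
    scheme = assign_quartiles(np.arange(1, 9))
    assert list(scheme.labels) == [1, 1, 2, 2, 3, 3, 4, 4]
    assert scheme.counts().tolist() == [2, 2, 2, 2]


def test_value_on_median_cut_goes_to_lower_quartile():
    scheme = assign_quartiles([1.0, 2.0, 2.0, 3.0])  # q50 = 2.0
    assert scheme.cuts[1] == 2.0
    assert quartile_of(2.0, scheme.cuts) == 2  # tie at q50 -> Q2


def test_label_order_invariance():
    v = np.array([5.0, 1.0, 9.0, 3.0, 7.0, 2.0, 8.0, 4.0])
    base = assign_quartiles(v)
    perm = np.random.default_rng(0).permutation(len(v))
    permuted = assign_quartiles(v[perm])
    assert np.array_equal(permuted.labels, base.labels[perm])


@settings(derandomize=True, max_examples=40)
@given(st.lists(st.integers(-500, 500), min_size=6, max_size=30, unique=True))
def test_labels_invariant_under_monotone_transform(values):
    v = np.asarray(values, dtype=float) / 10.0
    base = assign_quartiles(v)
    transformed = assign_quartiles(np.exp(v / 25.0))
    assert np.array_equal(base.labels, transformed.labels)


def test_degenerate_quartiles_error():
    with pytest.raises(ModelError, match="identical"):
        assign_quartiles([3.0, 3.0, 3.0, 3.0])


# ------------------------------------------------------------ optimal range

def _rates_cohort(rates_pct, per_quartile=10):
    """Cohort with `per_quartile` oocytes per quartile at given success %."""
    n = 4 * per_quartile
    scheme = assign_quartiles(np.arange(1, n + 1, dtype=float))
    y = np.concatenate([
        np.r_[np.ones(round(per_quartile * r / 100)),
              np.zeros(per_quartile - round(per_quartile * r / 100))]
        for r in rates_pct])
    return scheme, y


def test_top_two_quartiles_define_contiguous_optimal_range():
    scheme, y = _rates_cohort([50, 80, 70, 40])
    rng = optimal_range(scheme, y, feature="od", outcome_name="fertilised")
    assert rng.quartile_rates == (50.0, 80.0, 70.0, 40.0)
    assert rng.selected == (2, 3) and rng.contiguous
    assert rng.bounds == (scheme.cuts[0], scheme.cuts[2])  # (q25, q75]


def test_outer_quartile_winners_flagged_non_contiguous():
    scheme, y = _rates_cohort([80, 40, 40, 80])
    rng = optimal_range(scheme, y)
    assert rng.selected == (1, 4) and not rng.contiguous
    assert rng.bounds == (-np.inf, np.inf)


def test_all_rates_equal_tie_rule_selects_q1_q2():
    scheme = assign_quartiles(np.arange(1, 9, dtype=float))
    y = np.array([1, 0, 1, 0, 1, 0, 1, 0], dtype=float)  # all 50%
    rng = optimal_range(scheme, y)
    assert rng.selected == (1, 2)


def test_contains_reproduces_training_selection():
    rng_ = np.random.default_rng(3)
    v = rng_.normal(size=40)
    y = (rng_.random(40) < 0.6).astype(float)
    scheme = assign_quartiles(v)
    rng = optimal_range(scheme, y)
    assert np.array_equal(rng.contains(v), np.isin(scheme.labels, rng.selected))


def test_quartile_without_eligible_oocyte_errors():
    scheme = assign_quartiles(np.arange(1, 9, dtype=float))
    y = np.array([1, 0, 1, 0, 1, 0, np.nan, np.nan])  # Q4 fully ineligible
    with pytest.raises(ModelError, match="Q4"):
        optimal_range(scheme, y, outcome_name="implantation")


# ------------------------------------------------------------ logistic fit

def test_two_by_two_table_closed_form_or():
    x = np.r_[np.ones(50), np.zeros(50)]
    y = np.r_[np.ones(40), np.zeros(10), np.ones(20), np.zeros(30)]
    model = fit_logistic(x, y, predictor_names=["in_range"])
    assert model.report.loc[0, "or"] == pytest.approx(6.0, rel=1e-6)
    # Wald CI reproduces exp(coef +/- 1.96 se)
    row = model.report.loc[0]
    assert row["ci_low"] == pytest.approx(np.exp(row["coef"] - 1.959964 * row["se"]), rel=1e-4)


def test_constant_predictor_rejected():
    with pytest.raises(ModelError, match="constant"):
        fit_logistic(np.ones(20), np.r_[np.ones(10), np.zeros(10)])


def test_complete_separation_raises():
    x = np.r_[np.ones(15), np.zeros(15)]
    with pytest.raises(SeparationError):
        fit_logistic(x, x.copy())


def test_null_model_ci_covers_one():
    rng = np.random.default_rng(8)
    cover = 0
    for rep in range(50):
        x = (rng.random(400) < 0.5).astype(float)
        y = (rng.random(400) < 0.6).astype(float)  # independent of x
        rep_ = fit_logistic(x, y).report.loc[0]
        cover += rep_["ci_low"] <= 1.0 <= rep_["ci_high"]
    assert cover >= 44  # ~95% coverage, binomial slack


# ----------------------------------------------------------------- ROC/AUC

def test_auc_trivial_and_pairwise_cases():
    assert roc_auc([0.9, 0.8, 0.4, 0.3], [1, 1, 0, 0]).auc == 1.0
    assert roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0]).auc == 0.5
    # swap the labels of one positive/negative pair: 3 of 4 pairs concordant
    assert roc_auc([0.9, 0.8, 0.4, 0.3], [1, 0, 1, 0]).auc == 0.75


def test_auc_equals_mannwhitney_u_identity():
    rng = np.random.default_rng(12)
    scores = rng.random(60)
    y = (rng.random(60) < 0.5).astype(int)
    pos, neg = scores[y == 1], scores[y == 0]
    auc = roc_auc(scores, y).auc
    u = mann_whitney(pos, neg).u
    assert auc == pytest.approx(u / (pos.size * neg.size))


def test_auc_matches_sklearn():
    sk = pytest.importorskip("sklearn.metrics")
    rng = np.random.default_rng(15)
    scores = rng.random(80).round(1)  # force ties
    y = (rng.random(80) < 0.4).astype(int)
    assert roc_auc(scores, y).auc == pytest.approx(sk.roc_auc_score(y, scores))


def test_one_class_auc_error():
    with pytest.raises(ModelError, match="classes"):
        roc_auc([0.2, 0.8], [1, 1])


# ------------------------------------------------------------ classification

def test_confident_correct_predictions_full_accuracy():
    x = np.r_[np.ones(30), np.zeros(30)]
    y = np.r_[np.ones(28), np.zeros(2), np.ones(5), np.zeros(25)]
    model = fit_logistic(x, y)
    preds, metrics = classify(model, np.ones(10), np.ones(10))
    assert preds.all() and metrics.accuracy == 100.0


def test_raising_threshold_never_increases_sensitivity():
    rng = np.random.default_rng(19)
    x = (rng.random(300) < 0.5).astype(float)
    y = (rng.random(300) < 0.3 + 0.4 * x).astype(float)
    model = fit_logistic(x, y)
    sens = []
    for thr in (0.2, 0.4, 0.6, 0.8):
        _, m = classify(model, x, y, threshold=thr)
        sens.append(m.sensitivity if np.isfinite(m.sensitivity) else 0.0)
    assert all(a >= b for a, b in zip(sens, sens[1:]))


# ------------------------------------------------------------- end-to-end

def test_outcome_model_pipeline_on_planted_cohort():
    """Joint quartile/range/logistic pipeline on a planted-effect cohort
    reproduces the qualitative pattern: moderate AUC, high sensitivity,
    limited specificity."""
    df = simulate_cohort(clinical_cohort_spec(n_oocytes=957, seed=42))
    om = fit_outcome_model(df, df["fertilised"], ("od", "grad", "idm"),
                           outcome_name="fertilised")
    ors = om.model.report.set_index("predictor")["or"]
    assert ors["od_in_range"] > ors["grad_in_range"]  # OD carries the top OR
    assert 0.6 < om.auc.auc < 0.85
    assert om.metrics.sensitivity > 80.0
    assert om.metrics.specificity < 50.0
    table = quartile_rate_table(df, df, ("od", "grad"), ("fertilised",))
    assert len(table) == 8
    assert table.groupby("feature")["fertilised_optimal"].sum().eq(2).all()
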