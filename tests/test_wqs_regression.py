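import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from ecmnet import scid_scales
from ecmnet.wqs_regression import (
    WQSError,
    average_bilateral,
    fit_wqs,
    quartile_matrix,
    quartile_rank,
    wqs_index,
    wqs_report,
)


# ---------------------------------------------------------------------------
# quartile_rank

def test_ranks_of_one_to_eight():
    out = quartile_rank(np.arange(1.0, 9.0))
    assert list(out) == [0, 0, 1, 1, 2, 2, 3, 3]


def test_constant_column_all_zero(caplog):
    with caplog.at_level(logging.WARNING):
        out = quartile_rank(np.full(12, 7.0))
    assert (out == 0).all()
    assert "distinct" in caplog.text


def test_boundary_values_assigned_to_lower_quartile():
    x = np.array([1.0, 1, 2, 2, 3, 3, 4, 4])
    cuts = np.quantile(x, [0.25, 0.5, 0.75])
    out = quartile_rank(x)
    for xi, r in zip(x, out):
        assert r == (xi > cuts).sum()


@given(st.lists(
    st.integers(-5000, 5000).map(lambda v: v / 100.0),
    min_size=8, max_size=40, unique=True,
))
def test_monotone_transform_invariance(values):
    # well-separated values so the transforms stay injective in float64
    x = np.asarray(values)
    assert np.array_equal(quartile_rank(x), quartile_rank(3 * x + 2))
    assert np.array_equal(quartile_rank(x), quartile_rank(np.exp(x / 50)))


def test_too_few_values_rejected():
    with pytest.raises(WQSError, match="at least 8"):
        quartile_rank(np.arange(5.0))


def test_missing_rejected():
    x = np.arange(10.0)
    x[3] = np.nan
    with pytest.raises(WQSError, match="missing"):
        quartile_rank(x)


# ---------------------------------------------------------------------------
# wqs_index

def test_index_upper_bound():
    Q = np.full((3, 4), 3.0)
    out = wqs_index([0.25] * 4, Q)
    assert np.allclose(out, 3.0)


def test_degenerate_weighting_selects_component(rng):
    Q = rng.integers(0, 4, size=(10, 4)).astype(float)
    out = wqs_index([1.0, 0, 0, 0], Q)
    assert np.array_equal(out, Q[:, 0])


def test_index_matches_double_loop_oracle(rng):
    Q = rng.integers(0, 4, size=(15, 4)).astype(float)
    w = np.array([0.4, 0.3, 0.2, 0.1])
    out = wqs_index(w, Q)
    for j in range(15):
        manual = sum(w[i] * Q[j, i] for i in range(4))
        assert abs(out[j] - manual) < 1e-12


def test_index_dimension_mismatch(rng):
    with pytest.raises(WQSError, match="match"):
        wqs_index([0.5, 0.5], rng.integers(0, 4, size=(5, 4)))


def test_index_requires_simplex_weights(rng):
    Q = rng.integers(0, 4, size=(10, 4)).astype(float)
    with pytest.raises(WQSError, match="sum to 1"):
        wqs_index([0.5, 0.5, 0.5, 0.5], Q)
    with pytest.raises(WQSError, match="non-negative"):
        wqs_index([1.5, -0.5, 0, 0], Q)


@given(st.integers(0, 3), st.integers(0, 2))
def test_index_monotone_in_ranks(rank_value, comp):
    Q = np.ones((4, 3)) * rank_value
    Q2 = Q.copy()
    Q2[:, comp] = min(rank_value + 1, 3)
    w = np.array([0.2, 0.3, 0.5])
    assert (wqs_index(w, Q2) >= wqs_index(w, Q)).all()


# ---------------------------------------------------------------------------
# fit_wqs

def _mixture_data(rng, n=45, beta=-0.004, weights=(0.65, 0.15, 0.10, 0.10),
                  rho=0.4):
    shared = rng.standard_normal(n)
    scales = pd.DataFrame(
        {
            name: 20 + 4 * (rho * shared
                            + (1 - rho) * rng.standard_normal(n))
            for name in scid_scales.SUBSCALES
        }
    )
    Q = quartile_matrix(scales).to_numpy(dtype=float)
    idx = Q @ np.asarray(weights)
    y = 0.09 + beta * idx + 0.002 * rng.standard_normal(n)
    cov = pd.DataFrame({"mdd": rng.binomial(1, 0.3, n),
                        "psychotropic": rng.binomial(1, 0.3, n),
                        "opioid": rng.binomial(1, 0.05, n)})
    return y, scales, cov


def test_weights_on_simplex(rng):
    y, scales, cov = _mixture_data(rng)
    fit = fit_wqs(y, scales, cov, n_boot=50, seed=1)
    assert fit.weights.min() >= 0
    assert fit.weights.sum() == pytest.approx(1.0, abs=1e-9)
    assert fit.contributions_pct.sum() == pytest.approx(100.0, abs=1e-6)


def test_dominant_weight_recovered(rng):
    y, scales, cov = _mixture_data(rng)
    fit = fit_wqs(y, scales, cov, n_boot=200, seed=2)
    assert fit.weights.idxmax() == "re_experiencing"
    assert fit.beta < 0
    assert fit.p < 0.05


def test_deterministic_given_seed(rng):
    y, scales, cov = _mixture_data(rng)
    a = fit_wqs(y, scales, cov, n_boot=25, seed=7)
    b = fit_wqs(y, scales, cov, n_boot=25, seed=7)
    assert np.array_equal(a.weights.to_numpy(), b.weights.to_numpy())
    assert a.beta == b.beta and a.p == b.p


def test_single_bootstrap_deterministic(rng):
    y, scales, cov = _mixture_data(rng)
    a = fit_wqs(y, scales, cov, n_boot=1, seed=3)
    b = fit_wqs(y, scales, cov, n_boot=1, seed=3)
    assert a.beta == b.beta
    assert np.array_equal(a.weights.to_numpy(), b.weights.to_numpy())


def test_single_component_equals_plain_regression(rng):
    import statsmodels.api as sm

    y, scales, cov = _mixture_data(rng)
    one = scales[["avoidance"]]
    fit = fit_wqs(y, one, cov, n_boot=10, seed=4, direction="negative")
    assert fit.weights.iloc[0] == pytest.approx(1.0)
    q = quartile_rank(one["avoidance"].to_numpy())
    X = pd.DataFrame({"const": 1.0, "q": q.astype(float)})
    for c in cov.columns:
        X[c] = cov[c].astype(float)
    ols = sm.OLS(y, X).fit()
    assert fit.beta == pytest.approx(ols.params["q"], rel=1e-10)
    assert fit.se == pytest.approx(ols.bse["q"], rel=1e-10)


def test_positive_direction(rng):
    y, scales, cov = _mixture_data(rng, beta=0.004)
    fit = fit_wqs(y, scales, cov, n_boot=100, seed=5, direction="positive")
    assert fit.beta > 0
    assert fit.direction == "positive"


def test_direction_validation(rng):
    y, scales, cov = _mixture_data(rng)
    with pytest.raises(WQSError, match="direction"):
        fit_wqs(y, scales, cov, n_boot=10, direction="both")


def test_too_few_subjects(rng):
    y, scales, cov = _mixture_data(rng, n=15)
    with pytest.raises(WQSError, match="at least 20"):
        fit_wqs(y, scales, cov, n_boot=10)


def test_length_mismatch(rng):
    y, scales, cov = _mixture_data(rng)
    with pytest.raises(WQSError, match="subject count"):
        fit_wqs(y[:-1], scales, cov, n_boot=10)


def test_mean_aggregation_flag(rng):
    y, scales, cov = _mixture_data(rng)
    fit = fit_wqs(y, scales, cov, n_boot=60, seed=6, aggregation="mean")
    assert fit.n_used == fit.n_boot - fit.n_dropped
    assert fit.weights.sum() == pytest.approx(1.0, abs=1e-9)


def test_planted_cohort_recovery(planted_run):
    table, pheno, cfg = planted_run
    merged = table.merge(pheno, on="subject_id")
    case = merged[merged["ptsd"] == 1].reset_index(drop=True)
    fit = fit_wqs(
        case["roi_65"],
        case[list(scid_scales.SUBSCALES)],
        case[["mdd", "psychotropic", "opioid"]],
        n_boot=300, seed=8, direction="negative",
    )
    planted = pd.Series(cfg.symptom_weights,
                        index=list(scid_scales.SUBSCALES))
    assert fit.weights.idxmax() == planted.idxmax()
    assert fit.beta < 0


# ---------------------------------------------------------------------------
# average_bilateral

def test_average_of_pair():
    ec = pd.DataFrame({"subject_id": ["a"], "roi_0": [0.08],
                       "roi_1": [0.10], "roi_2": [0.05]})
    out = average_bilateral(ec, [(0, 1)])
    assert out["roi_0+1"].iloc[0] == pytest.approx(0.09)
    assert "roi_0" not in out.columns and "roi_1" not in out.columns
    assert list(out.columns) == ["subject_id", "roi_0+1", "roi_2"]


def test_nine_hub_columns_reduce_to_eight(planted_run):
    table, _, cfg = planted_run
    hubs = [f"roi_{i}" for i in cfg.hub_rois]
    out = average_bilateral(table, [(13, 61)])
    merged_hubs = [c for c in hubs if c not in ("roi_13", "roi_61")]
    merged_hubs.append("roi_13+61")
    assert len(merged_hubs) == 8
    assert all(c in out.columns for c in merged_hubs)


def test_empty_pairs_identity(planted_run):
    table, _, _ = planted_run
    out = average_bilateral(table, [])
    pd.testing.assert_frame_equal(out, table)


def test_unknown_roi_rejected():
    ec = pd.DataFrame({"roi_0": [0.1]})
    with pytest.raises(WQSError, match="no column"):
        average_bilateral(ec, [(0, 5)])


def test_wqs_report_adjusts(rng):
    y, scales, cov = _mixture_data(rng)
    fits = {
        "roi_a": fit_wqs(y, scales, cov, n_boot=20, seed=1),
        "roi_b": fit_wqs(y + rng.standard_normal(45) * 0.01, scales, cov,
                         n_boot=20, seed=2),
    }
    report = wqs_report(fits)
    assert list(report.columns) == ["roi", "beta", "se", "p", "n_obs",
                                    "p_adjusted"]
    assert (report["p_adjusted"] >= report["p"] - 1e-12).all()
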