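"""Link function, design matrices, ML fitting and rate prediction."""

import numpy as np
import pandas as pd
import pytest

from cpgmut.glm import (
    MODELS,
    FitResult,
    build_design_matrix,
    d_inverse_link,
    fit_glm,
    fit_from_json,
    fit_to_json,
    inverse_link,
    link,
    model_scores,
    predict_scaled_rates,
)
from cpgmut.simulate import MethylationMixture, SyntheticTruth, default_truth, simulate_site_table


# ---------------------------------------------------------------------------
# link function
# ---------------------------------------------------------------------------

def test_link_closed_forms():
    assert inverse_link(0.0) == 0.0
    assert inverse_link(-1.0) == pytest.approx(1 - np.exp(-1), abs=1e-9)
    assert float(inverse_link(-1.0)) == pytest.approx(0.632121, abs=1e-6)
    assert d_inverse_link(0.0) == -1.0
    with pytest.raises(ValueError):
        link(0.0)
    with pytest.raises(ValueError):
        link(1.0)


def test_link_inverse_round_trip_is_tight():
    # through p the round-trip error grows like eps * e^(-eta) as p -> 1,
    # so the 1e-12 bound is checked where double precision can deliver it
    eta = -np.logspace(np.log10(1e-8), np.log10(8), 200)
    assert np.max(np.abs(link(inverse_link(eta)) - eta)) < 1e-12
    deep = -np.logspace(np.log10(8), np.log10(20), 50)
    err = np.abs(link(inverse_link(deep)) - deep)
    assert np.all(err <= 8 * np.finfo(float).eps * np.exp(-deep))


def test_small_rate_limit_first_order():
    """For muT <= 1e-3 the saturation correction is a sub-muT effect."""
    mu = np.logspace(-6, -3, 50)
    p = inverse_link(-mu)
    assert np.all(np.abs(p - mu) / mu <= mu)


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "model,expected_p",
    [
        ("up1_down1", 14),
        ("4mer", 32),
        ("up21_down12", 62),
        ("6mer", 512),
        ("additive_positions", 26),
        ("context_only_4mer", 16),
        ("context_only_up1_down1", 7),
    ],
)
def test_design_matrix_parameter_counts(sites_k6, model, expected_p):
    dm = build_design_matrix(sites_k6, model)
    assert dm.p == expected_p
    assert len(dm.columns) == expected_p
    # full column rank when every level is present
    X = np.asarray(dm.X.todense())
    assert np.linalg.matrix_rank(X) == expected_p


def test_design_matrix_requires_context_column(sites_small):
    with pytest.raises(ValueError):
        build_design_matrix(sites_small.assign(context4=pd.NA), "4mer")


# ---------------------------------------------------------------------------
# fitting: closed forms and invariants
# ---------------------------------------------------------------------------

def test_intercept_only_matches_closed_form():
    rng = np.random.default_rng(0)
    y = (rng.random(1000) < 0.1).astype(int)
    df = pd.DataFrame({"context4": "ACGA", "m": 0.0, "y": y})
    fit = fit_glm(build_design_matrix(df, "context_only_4mer"))
    assert -fit.theta[0] == pytest.approx(-np.log1p(-y.mean()), abs=1e-9)


def test_stratum_closed_form_with_binary_methylation():
    truth = default_truth(5, n_per_context=4000, m_kind="binary")
    df = simulate_site_table(truth)
    fit = fit_glm(build_design_matrix(df, "4mer"))
    for x in (0, 1):
        for e in predict_scaled_rates(fit, x):
            cell = df[(df["context4"] == e.context) & (df["m"] == float(x))]
            assert e.muT == pytest.approx(-np.log1p(-cell["y"].mean()), abs=1e-6)


def test_null_methylation_effect_is_not_detected(sites_small):
    truth = default_truth(9, n_per_context=5000, beta_zero=True)
    df = simulate_site_table(truth)
    fit = fit_glm(build_design_matrix(df, "4mer"))
    r0 = {e.context: e for e in predict_scaled_rates(fit, 0)}
    r1 = {e.context: e for e in predict_scaled_rates(fit, 1)}
    for c in r0:
        se_diff = np.hypot(r0[c].se, r1[c].se)
        assert abs(r1[c].muT - r0[c].muT) < 3.5 * se_diff


def test_fit_diagnostics_and_information_criteria(fit_4mer_small):
    fit = fit_4mer_small
    assert fit.converged and fit.n_clipped == 0
    assert fit.residual_deviance <= fit.null_deviance
    assert fit.aic == pytest.approx(2 * fit.n_params - 2 * fit.loglik)
    assert fit.bic == pytest.approx(fit.n_params * np.log(fit.n_obs) - 2 * fit.loglik)
    # fitted rates strictly interior: eta < 0 everywhere
    assert fit.eta is not None and float(fit.eta.max()) < 0


def test_model_scores_arithmetic():
    fit = FitResult(
        spec=MODELS["4mer"], columns=[], levels={}, theta=np.zeros(32),
        cov=np.eye(32), loglik=-50_000.0, null_deviance=100.0,
        residual_deviance=75.0, aic=2 * 32 - 2 * -50_000.0,
        bic=0.0, n_obs=10, n_iter=1, converged=True, n_clipped=0,
    )
    scores = model_scores(fit)
    assert scores["variance_explained"] == pytest.approx(0.25)
    assert scores["AIC"] == pytest.approx(100_064.0)


def test_variance_explained_monotone_under_nesting(sites_small):
    ve = {
        name: model_scores(fit_glm(build_design_matrix(sites_small, name), keep_eta=False))[
            "variance_explained"
        ]
        for name in ("up1_down1", "4mer")
    }
    assert 0 <= ve["up1_down1"] <= ve["4mer"] <= 1


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def test_predictions_recover_truth_within_ci(truth_small, fit_4mer_small, sites_small):
    misses = 0
    for x in (0, 1):
        for e in predict_scaled_rates(fit_4mer_small, x):
            t = truth_small.muT(e.context, x)
            misses += not (e.ci_low <= t <= e.ci_high)
    assert misses <= 4  # ~5% of 32 cells expected to miss


def test_prediction_rejects_extrapolation_and_unseen_levels(fit_4mer_small):
    with pytest.raises(ValueError):
        predict_scaled_rates(fit_4mer_small, 2)
    with pytest.raises(ValueError, match="not a valid"):
        predict_scaled_rates(fit_4mer_small, 0, contexts=["AAAA"])


def test_duplicated_context_labels_get_identical_estimates():
    rng = np.random.default_rng(3)
    n = 8000
    m = rng.random(n)
    y = (rng.random(n) < -np.expm1(-(0.03 + 0.3 * m))).astype(int)
    half = pd.DataFrame({"context4": "ACGA", "m": m, "y": y})
    other = half.assign(context4="TCGT")  # same data under a second label
    fit = fit_glm(build_design_matrix(pd.concat([half, other]), "4mer"))
    for x in (0, 1):
        ests = {e.context: e.muT for e in predict_scaled_rates(fit, x)}
        assert ests["ACGA"] == pytest.approx(ests["TCGT"], abs=1e-8)


def test_predictions_invariant_to_level_relabeling(sites_small):
    """A bijective renaming of contexts permutes estimates but not values."""
    mapping = {c: c for c in sites_small["context4"].unique()}
    # swap two labels so the lexicographic reference level changes
    mapping["ACGA"], mapping["TCGT"] = "TCGT", "ACGA"
    renamed = sites_small.assign(context4=sites_small["context4"].map(mapping))
    fit_a = fit_glm(build_design_matrix(sites_small, "4mer"))
    fit_b = fit_glm(build_design_matrix(renamed, "4mer"))
    for x in (0, 1):
        a = {e.context: e.muT for e in predict_scaled_rates(fit_a, x)}
        b = {e.context: e.muT for e in predict_scaled_rates(fit_b, x)}
        for c in a:
            assert a[c] == pytest.approx(b[mapping[c]], abs=1e-7)


def test_se_shrinks_with_sample_size():
    small = simulate_site_table(default_truth(13, n_per_context=1_000))
    large = simulate_site_table(default_truth(13, n_per_context=100_000))
    se_small = np.mean([e.se for e in predict_scaled_rates(
        fit_glm(build_design_matrix(small, "4mer")), 1)])
    se_large = np.mean([e.se for e in predict_scaled_rates(
        fit_glm(build_design_matrix(large, "4mer")), 1)])
    assert 8 <= se_small / se_large <= 12


def test_context_only_model_has_single_state(sites_small):
    fit = fit_glm(build_design_matrix(sites_small, "context_only_4mer"))
    assert len(predict_scaled_rates(fit, 0)) == 16
    with pytest.raises(ValueError):
        predict_scaled_rates(fit, 1)


# ---------------------------------------------------------------------------
# independent reference implementation
# ---------------------------------------------------------------------------

def test_matches_statsmodels_logc_glm(sites_small):
    sm = pytest.importorskip("statsmodels.api")
    import statsmodels.genmod.families.links as links
    import warnings

    dm = build_design_matrix(sites_small, "up1_down1")
    fit = fit_glm(dm)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(
            dm.y, np.asarray(dm.X.todense()),
            family=sm.families.Binomial(link=links.LogC()),
        ).fit(maxiter=200, tol=1e-10)
    assert np.abs(fit.theta - res.params).max() < 1e-5
    assert fit.loglik == pytest.approx(res.llf, abs=1e-4)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def test_fit_round_trips_through_json(tmp_path, fit_4mer_small):
    p = tmp_path / "fit.json"
    fit_to_json(fit_4mer_small, p)
    back = fit_from_json(p)
    for x in (0, 1):
        a = predict_scaled_rates(fit_4mer_small, x)
        b = predict_scaled_rates(back, x)
        assert [e.muT for e in a] == pytest.approx([e.muT for e in b])
        assert [e.se for e in a] == pytest.approx([e.se for e in b])
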