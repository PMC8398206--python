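"""OLS fitting, backward reduction and prediction."""

import numpy as np
import pandas as pd
import pytest

from dftbench.regression import (
    INTERCEPT,
    CollinearityError,
    fit_full,
    fit_reduced,
    predict,
    reduce,
    significance_stars,
)
from dftbench.synthetic import PropertyErrorModel, SyntheticConfig, generate_errors

AEA_COEF = {"LR": 0.012, "zeta": 2.416, "D": -7.203}
AIP_COEF = {"SR": 0.031, "MR": 0.100, "LR": 0.087, "zeta": -1.696, "D": 3.605, "intercept": -11.393}


def _grid_response(features, coef, noise_sd=0.0, seed=0):
    rng = np.random.default_rng(seed)
    y = np.full(len(features), coef.get("intercept", 0.0))
    for term, c in coef.items():
        if term != "intercept":
            y = y + c * features[term].to_numpy()
    if noise_sd:
        y = y + rng.normal(0, noise_sd, len(y))
    return y


def test_noiseless_recovery_exact(features):
    X = features[["SR", "MR", "LR", "NBF", "zeta", "D"]]
    y = _grid_response(features, AIP_COEF)
    model = fit_full(X, y, "aip")
    for term, c in AIP_COEF.items():
        assert model.coef[term] == pytest.approx(c, abs=1e-8)
    assert model.r_squared == pytest.approx(1.0)


def test_constant_response(features):
    X = features[["SR", "MR", "LR", "NBF", "zeta", "D"]]
    model = fit_full(X, np.full(len(X), 5.0), "const")
    assert model.r_squared == pytest.approx(0.0, abs=1e-12)
    for t in model.terms:
        if t != INTERCEPT:
            assert model.pvalue[t] > 0.9


def test_row_duplication_invariance(features):
    X = features[["SR", "MR", "LR", "NBF", "zeta", "D"]]
    y = _grid_response(features, AIP_COEF, noise_sd=1.9, seed=4)
    m1 = fit_full(X, y, "aip")
    m2 = fit_full(pd.concat([X, X], ignore_index=True), np.concatenate([y, y]), "aip")
    for t in m1.terms:
        assert m2.coef[t] == pytest.approx(m1.coef[t], abs=1e-10)
    assert m2.n_observations == 2 * m1.n_observations


def test_collinear_design_rejected(features):
    X = features[["SR", "MR", "LR", "NBF", "zeta", "D"]].copy()
    X["LR"] = 2.0 * X["SR"] + X["MR"]
    with pytest.raises(CollinearityError):
        fit_full(X, _grid_response(features, {"SR": 1.0}), "y")


def test_zero_variance_column_dropped_with_warning(features):
    X = features[["SR", "MR", "LR", "NBF", "zeta", "D"]].copy()
    X["D"] = 1.0
    with pytest.warns(UserWarning, match="zero-variance"):
        model = fit_full(X, _grid_response(features, {"SR": 1.0, "intercept": 2.0}), "y")
    assert "D" not in model.terms


def test_reduce_drops_only_inactive_term(features):
    """One inert feature with noise elsewhere is eliminated first and alone."""
    X = features[["SR", "MR", "LR", "NBF", "zeta", "D"]]
    coef = {"SR": 0.5, "MR": 0.3, "LR": 0.2, "zeta": 4.0, "D": -6.0, "intercept": -10.0}
    y = _grid_response(features, coef, noise_sd=0.5, seed=7)
    reduced = reduce(fit_full(X, y, "y"), alpha=0.05)
    dropped = [t for t, _ in reduced.reduction_trail]
    assert dropped == ["NBF"]
    assert set(reduced.terms) == {"SR", "MR", "LR", "zeta", "D", INTERCEPT}


def test_reduce_fixed_point_when_all_significant(features):
    X = features[["SR", "MR", "LR", "NBF", "zeta", "D"]]
    y = _grid_response(features, {"SR": 1.0, "MR": 1.0, "LR": 1.0, "NBF": 0.1, "zeta": 5.0, "D": 5.0, "intercept": 3.0})
    full = fit_full(X, y + np.random.default_rng(0).normal(0, 1e-6, len(y)), "y")
    reduced = reduce(full, alpha=0.05)
    assert reduced.terms == full.terms
    assert reduced.reduction_trail == ()


def test_reduce_recovers_electron_affinity_structure(features):
    """Errors built from {LR, zeta, D} plus small noise reduce to exactly that set."""
    cfg = SyntheticConfig(seed=5, models={"aea": PropertyErrorModel(AEA_COEF, noise_sd=0.5)})
    errs = generate_errors(cfg)
    sub = errs.merge(features, on=["functional", "basis"])
    reduced = fit_reduced(sub[["SR", "MR", "LR", "NBF", "zeta", "D"]], sub["epsilon"].to_numpy(), "aea")
    assert set(reduced.terms) == {"LR", "zeta", "D"}
    assert INTERCEPT in dict(reduced.reduction_trail) or INTERCEPT not in reduced.terms
    assert reduced.f_pvalue < 0.05


def test_reduced_r2_not_above_full(features, noisy_errors):
    sub = noisy_errors[noisy_errors["property"] == "aip"].merge(features, on=["functional", "basis"])
    full = fit_full(sub[["SR", "MR", "LR", "NBF", "zeta", "D"]], sub["epsilon"].to_numpy(), "aip")
    reduced = reduce(full)
    assert reduced.r_squared <= full.r_squared + 1e-12


def test_residuals_orthogonal_to_design(features):
    X = features[["SR", "MR", "LR", "NBF", "zeta", "D"]]
    y = _grid_response(features, AIP_COEF, noise_sd=1.9, seed=2)
    model = fit_full(X, y, "aip")
    fitted = np.array([predict(model, row) for _, row in X.iterrows()])
    resid = y - fitted
    design = np.column_stack([np.ones(len(X)), X.to_numpy()])
    assert np.max(np.abs(design.T @ resid)) / len(y) < 1e-7


@pytest.mark.parametrize(
    "coef, feats, expected",
    [
        # worked predictors on published-scale coefficient tables
        (AIP_COEF, {"SR": 19, "MR": 0, "LR": 65, "NBF": 334, "zeta": 0, "D": 1}, -1.544),
        (AEA_COEF, {"SR": 0, "MR": 0, "LR": 0, "NBF": 222, "zeta": 1, "D": 0}, 2.416),
        ({"intercept": 3.5}, {}, 3.5),
    ],
)
def test_predict_from_coefficient_table(coef, feats, expected):
    assert predict(coef, feats) == pytest.approx(expected, abs=1e-9)


def test_predict_missing_feature_errors():
    with pytest.raises(KeyError, match="LR"):
        predict(AEA_COEF, {"zeta": 1, "D": 0})


def test_parameter_recovery_within_three_se(features):
    """Estimates stay within 3 classical SEs of truth in >=99% of replicates."""
    X = features[["SR", "MR", "LR", "NBF", "zeta", "D"]]
    n_reps, hits, total = 50, 0, 0
    for rep in range(n_reps):
        y = _grid_response(features, AIP_COEF, noise_sd=1.924, seed=1000 + rep)
        m = fit_full(X, y, "aip")
        for term, truth in AIP_COEF.items():
            total += 1
            if abs(m.coef[term] - truth) <= 3 * m.stderr[term]:
                hits += 1
    assert hits / total >= 0.99


def test_significance_stars_thresholds():
    assert significance_stars(0.0005) == "***"
    assert significance_stars(0.005) == "**"
    assert significance_stars(0.03) == "*"
    assert significance_stars(0.2) == ""
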