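"""Regression families, their algebraic equivalences, metrics, and the
published CARS-MLR reference predictors."""
import numpy as np
import pytest

import hsifruit as hf
from hsifruit.errors import ContractError, DomainError
from hsifruit.models import RegressionModel


@pytest.fixture()
def tall_linear(rng):
    """Full-rank 20 x 5 design with an exact linear response."""
    X = rng.normal(size=(20, 5))
    beta = np.array([1.5, -2.0, 0.5, 3.0, -1.0])
    y = X @ beta + 0.7
    return X, y


def test_mlr_recovers_slope_and_intercept(rng):
    x = rng.random((30, 1))
    y = 2.0 * x[:, 0] + 1.0
    model = hf.fit("MLR", x, y)
    assert model.estimator.coef_[0] == pytest.approx(2.0, abs=1e-8)
    assert model.estimator.intercept_ == pytest.approx(1.0, abs=1e-8)


def test_mlr_needs_enough_samples(rng):
    with pytest.raises(DomainError, match="fewer bands"):
        hf.fit("MLR", rng.random((5, 6)), rng.random(5))


def test_mlr_rank_deficiency_detected(rng):
    x = rng.random((20, 2))
    X = np.column_stack([x, x[:, 0]])  # duplicated band
    with pytest.raises(DomainError, match="collinear"):
        hf.fit("MLR", X, rng.random(20))


def test_plsr_exact_on_rank_one(rng):
    v = rng.random(8)
    t = rng.normal(size=20)
    X = np.outer(t, v)
    y = 2.0 * t + 1.0
    model = hf.PLSRRegressor(n_components=1).fit(X, y)
    rmsec = np.sqrt(np.mean((y - model.predict(X)) ** 2))
    assert rmsec < 1e-6


def test_plsr_equals_mlr_at_full_rank(tall_linear):
    """With LVs = rank(X), PLSR reproduces the least-squares predictions."""
    X, y = tall_linear
    pls = hf.PLSRRegressor(n_components=5).fit(X, y)
    mlr = hf.MLRRegressor().fit(X, y)
    np.testing.assert_allclose(pls.predict(X), mlr.predict(X), atol=1e-6)


def test_pcr_equals_mlr_with_all_components(tall_linear):
    X, y = tall_linear
    pcr = hf.PCRRegressor(n_components=5).fit(X, y)
    mlr = hf.MLRRegressor().fit(X, y)
    np.testing.assert_allclose(pcr.predict(X), mlr.predict(X), atol=1e-6)


def test_elm_linear_identity_reduces_to_least_squares(tall_linear):
    X, y = tall_linear
    elm = hf.ELMRegressor(activation="linear", hidden_weights=np.eye(5),
                          hidden_bias=np.zeros(5)).fit(X, y)
    mlr = hf.MLRRegressor().fit(X, y)
    np.testing.assert_allclose(elm.predict(X), mlr.predict(X), atol=1e-6)


def test_elm_deterministic_under_seed(rng):
    X = rng.random((40, 10))
    y = rng.random(40)
    p1 = hf.ELMRegressor(random_state=3).fit(X, y).predict(X)
    p2 = hf.ELMRegressor(random_state=3).fit(X, y).predict(X)
    np.testing.assert_array_equal(p1, p2)


def test_bp_learns_linear_map(rng):
    X = rng.random((120, 3))
    y = X @ [1.0, -2.0, 0.5] + 0.3
    model = hf.BPRegressor(random_state=0).fit(X, y)
    r = y - model.predict(X)
    assert 1 - (r**2).sum() / ((y - y.mean()) ** 2).sum() > 0.9


def test_predict_reproduces_fitted_values_and_band_binding(rng):
    X = rng.random((30, 12))
    y = rng.random(30)
    bands = np.array([1, 4, 7])
    model = hf.fit("MLR", X, y, band_indices=bands)
    np.testing.assert_allclose(model.predict(X),
                               model.estimator.predict(X[:, bands]))
    with pytest.raises(ContractError):
        model.predict(X[:, :3])  # bands no longer resolvable


def test_linear_predictions_affine_in_rows(tall_linear):
    X, y = tall_linear
    model = hf.fit("MLR", X, y)
    lam = 0.3
    mix = lam * X[0] + (1 - lam) * X[1]
    p = model.predict(np.vstack([X[0], X[1], mix]))
    assert p[2] == pytest.approx(lam * p[0] + (1 - lam) * p[1], rel=1e-10)


@pytest.mark.parametrize("family", ["MLR", "PLSR", "PCR", "ELM", "BP"])
def test_serialisation_roundtrip(rng, family, tmp_path):
    X = rng.random((40, 8))
    y = rng.random(40)
    hp = {"n_components": 3} if family in ("PLSR", "PCR") else {}
    model = hf.fit(family, X, y, hyperparams=hp, seed=1)
    path = tmp_path / "model.json"
    model.to_json(path)
    back = RegressionModel.from_json(path)
    expected = model.predict(X)
    got = back.predict(X)
    if family in ("MLR", "PLSR"):
        np.testing.assert_array_equal(got, expected)  # bit-exact, linear
    else:
        # PCR folds PCA + OLS into one linear map on load; ELM/BP re-walk
        # the same float path
        np.testing.assert_allclose(got, expected, rtol=1e-9, atol=1e-12)


def test_evaluate_offset_and_translation_invariance(rng):
    y_cal = rng.random(20)
    y_pred = rng.random(10)
    d = 0.37
    rep = hf.evaluate(y_cal, y_cal, y_pred, y_pred + d)
    assert rep.rmsep == pytest.approx(d, rel=1e-12)
    assert rep.rpd == pytest.approx(rep.sd_pred / rep.rmsep, rel=1e-12)
    shift = 5.0
    rep2 = hf.evaluate(y_cal + shift, y_cal + shift, y_pred + shift,
                       y_pred + d + shift)
    assert rep2.r2_p == pytest.approx(rep.r2_p, rel=1e-9)
    assert rep2.rmsep == pytest.approx(rep.rmsep, rel=1e-9)
    assert rep2.rpd == pytest.approx(rep.rpd, rel=1e-9)


def test_evaluate_perfect_predictions_rpd_undefined(rng):
    y_cal, y_pred = rng.random(10), rng.random(10)
    with pytest.raises(DomainError, match="RPD"):
        hf.evaluate(y_cal, y_cal, y_pred, y_pred)


def test_evaluate_zero_variance_rejected():
    with pytest.raises(DomainError, match="variance"):
        hf.evaluate([1.0, 1.0, 1.0], [1.0, 1.1, 0.9], [2.0, 3.0], [2.1, 2.9])


@pytest.mark.parametrize("rpd, tier", [
    (1.2, "poor"), (1.5, "moderate"), (1.99, "moderate"),
    (2.0, "good"), (2.5, "good"), (2.81, "excellent"),
])
def test_rpd_tiers(rpd, tier):
    assert hf.rpd_tier(rpd) == tier


@pytest.mark.parametrize("target, n_bands, intercept", [
    ("colour_e", 20, 22.89), ("firmness", 29, 13.36), ("ssc", 18, 36.33),
])
def test_published_model_intercepts(target, n_bands, intercept):
    """At all-zero reflectance the published models return their intercepts."""
    assert hf.predict_published(target, np.zeros(n_bands)) == pytest.approx(
        intercept, abs=1e-12
    )


def test_published_model_is_exact_linear_form():
    model = hf.load_published_model("colour_e")
    rng = np.random.default_rng(5)
    x = rng.random(20)
    expected = model.intercept + float(x @ model.coefficients)
    assert hf.predict_published("colour_e", x) == pytest.approx(expected, rel=1e-15)
    # first and last coefficient by wavelength, from the printed formula
    assert model.wavelengths[0] == 397.0 and model.coefficients[0] == -8.82
    assert model.wavelengths[-1] == 993.0 and model.coefficients[-1] == -18.62


def test_published_model_length_contract():
    with pytest.raises(ContractError, match="ssc"):
        hf.predict_published("ssc", np.zeros(5))
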