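"""Regression model families for spectral calibration and their evaluation.

Five families: PLSR and PCR on the full spectrum (latent-variable /
principal-component count chosen by 5-fold cross-validated RMSE), and MLR,
ELM and BP on selected feature bands.  Evaluation reports the calibration
and prediction determination coefficients and RMSEs plus the residual
predictive deviation RPD = SD / RMSEP (SD of the measured prediction-set
values, n-1 denominator) with the usual interpretation tiers: < 1.5 poor,
1.5-2 moderate, 2-2.5 good, > 2.5 excellent.
"""
from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPRegressor

from .errors import ContractError, DomainError

FAMILIES = ("PLSR", "PCR", "MLR", "ELM", "BP")


# ------------------------------------------------------------ CV helper


def _rmsecv_curve(make_model, X, y, max_k: int, cv_folds: int, seed: int):
    """Per-component-count CV RMSE and fold-SE for one-SE model selection."""
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    folds = list(kf.split(X))
    rmse = np.zeros(max_k)
    fold_mse = np.zeros((max_k, len(folds)))
    for k in range(1, max_k + 1):
        sse = 0.0
        for f, (tr, te) in enumerate(folds):
            model = make_model(min(k, len(tr) - 1))
            model.fit(X[tr], y[tr])
            err = y[te] - np.asarray(model.predict(X[te])).ravel()
            fold_mse[k - 1, f] = float(np.mean(err**2))
            sse += float((err**2).sum())
        rmse[k - 1] = np.sqrt(sse / len(y))
    return rmse, fold_mse


def _one_se_pick(rmse: np.ndarray, fold_mse: np.ndarray) -> int:
    """Smallest component count whose CV RMSE is within one SE of the best."""
    best = int(np.argmin(rmse))
    se = fold_mse[best].std(ddof=1) / np.sqrt(fold_mse.shape[1])
    threshold = np.sqrt(rmse[best] ** 2 + se)
    return int(np.nonzero(rmse <= threshold)[0][0]) + 1


class PLSRRegressor(RegressorMixin, BaseEstimator):
    """PLS regression (NIPALS) with CV-selected latent-variable count.

    ``n_components=None`` selects by 5-fold RMSECV (cap ``max_components``,
    default 20) with a one-standard-error preference for fewer components;
    an explicit ``n_components`` skips selection.
    """

    def __init__(self, n_components=None, max_components: int = 20,
                 cv_folds: int = 5, random_state: int = 0):
        self.n_components = n_components
        self.max_components = max_components
        self.cv_folds = cv_folds
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y, float).ravel()
        cap = max(1, min(self.max_components, X.shape[1], X.shape[0] - 2))
        if self.n_components is not None:
            k = int(self.n_components)
        else:
            rmse, fold_mse = _rmsecv_curve(
                lambda k: PLSRegression(n_components=k, scale=False),
                X, y, cap, self.cv_folds, self.random_state,
            )
            k = _one_se_pick(rmse, fold_mse)
            self.rmsecv_curve_ = rmse
        self.n_components_ = k
        self.pls_ = PLSRegression(n_components=k, scale=False).fit(X, y)
        return self

    def predict(self, X):
        return np.asarray(self.pls_.predict(np.asarray(X, float))).ravel()


class PCRRegressor(RegressorMixin, BaseEstimator):
    """Principal-component regression with CV-selected component count (cap 30)."""

    def __init__(self, n_components=None, max_components: int = 30,
                 cv_folds: int = 5, random_state: int = 0):
        self.n_components = n_components
        self.max_components = max_components
        self.cv_folds = cv_folds
        self.random_state = random_state

    @staticmethod
    def _make(k):
        from sklearn.pipeline import Pipeline

        return Pipeline([("pca", PCA(n_components=k)), ("ols", LinearRegression())])

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y, float).ravel()
        cap = max(1, min(self.max_components, X.shape[1], X.shape[0] - 2))
        if self.n_components is not None:
            k = int(self.n_components)
        else:
            rmse, fold_mse = _rmsecv_curve(
                self._make, X, y, cap, self.cv_folds, self.random_state
            )
            k = _one_se_pick(rmse, fold_mse)
            self.rmsecv_curve_ = rmse
        self.n_components_ = k
        self.pipeline_ = self._make(k).fit(X, y)
        return self

    def predict(self, X):
        return np.asarray(self.pipeline_.predict(np.asarray(X, float))).ravel()


class MLRRegressor(RegressorMixin, BaseEstimator):
    """Ordinary least-squares multiple linear regression on selected bands."""

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y, float).ravel()
        if X.shape[0] <= X.shape[1] + 1:
            raise DomainError(
                f"MLR needs n > bands + 1 (got n={X.shape[0]}, bands={X.shape[1]}); "
                "select fewer bands"
            )
        A = np.column_stack([np.ones(X.shape[0]), X])
        if np.linalg.matrix_rank(A) < A.shape[1]:
            raise DomainError(
                "rank-deficient design matrix: bands are collinear, select fewer bands"
            )
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        self.intercept_ = float(coef[0])
        self.coef_ = coef[1:]
        return self

    def predict(self, X):
        return self.intercept_ + np.asarray(X, float) @ self.coef_


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


class ELMRegressor(RegressorMixin, BaseEstimator):
    """Extreme learning machine: random fixed hidden layer, analytic output.

    Inputs are scaled per band to [-1, 1] (sigmoid saturation control);
    hidden weights/biases are uniform on [-1, 1] unless given explicitly,
    and output weights come from the least-squares pseudo-inverse.
    ``activation='linear'`` makes the network an affine map, in which case
    predictions coincide with ordinary least squares.
    """

    def __init__(self, n_hidden: int = 40, activation: str = "sigmoid",
                 random_state: int = 0, hidden_weights=None, hidden_bias=None):
        self.n_hidden = n_hidden
        self.activation = activation
        self.random_state = random_state
        self.hidden_weights = hidden_weights
        self.hidden_bias = hidden_bias

    def _scale(self, X):
        span = self.x_max_ - self.x_min_
        span = np.where(span == 0, 1.0, span)
        return 2.0 * (X - self.x_min_) / span - 1.0

    def _hidden(self, X):
        Z = self._scale(X) @ self.W_ + self.b_
        return Z if self.activation == "linear" else _sigmoid(Z)

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y, float).ravel()
        self.x_min_ = X.min(axis=0)
        self.x_max_ = X.max(axis=0)
        rng = np.random.default_rng(self.random_state)
        if self.hidden_weights is not None:
            self.W_ = np.asarray(self.hidden_weights, float)
            nh = self.W_.shape[1]
        else:
            nh = self.n_hidden
            self.W_ = rng.uniform(-1, 1, size=(X.shape[1], nh))
        self.b_ = (np.asarray(self.hidden_bias, float)
                   if self.hidden_bias is not None else rng.uniform(-1, 1, nh))
        H = np.column_stack([np.ones(X.shape[0]), self._hidden(X)])
        self.beta_ = np.linalg.pinv(H) @ y
        return self

    def predict(self, X):
        X = np.asarray(X, float)
        H = np.column_stack([np.ones(X.shape[0]), self._hidden(X)])
        return H @ self.beta_


class BPRegressor(RegressorMixin, BaseEstimator):
    """Back-propagation network: one sigmoid hidden layer, linear output.

    Trained by stochastic gradient descent with early stopping on an inner
    validation split; inputs scaled to [-1, 1] per band and the target
    standardised internally.  Deterministic under ``random_state``.
    """

    def __init__(self, n_hidden: int = 10, random_state: int = 0,
                 max_iter: int = 3000, learning_rate_init: float = 0.05,
                 validation_fraction: float = 0.15):
        self.n_hidden = n_hidden
        self.random_state = random_state
        self.max_iter = max_iter
        self.learning_rate_init = learning_rate_init
        self.validation_fraction = validation_fraction

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y, float).ravel()
        self.x_min_ = X.min(axis=0)
        self.x_max_ = X.max(axis=0)
        self.y_mean_ = float(y.mean())
        self.y_sd_ = float(y.std(ddof=1)) or 1.0
        self.net_ = MLPRegressor(
            hidden_layer_sizes=(self.n_hidden,),
            activation="logistic",
            solver="sgd",
            learning_rate="adaptive",
            learning_rate_init=self.learning_rate_init,
            max_iter=self.max_iter,
            early_stopping=True,
            validation_fraction=self.validation_fraction,
            n_iter_no_change=25,
            tol=1e-6,
            random_state=self.random_state,
        )
        self.net_.fit(self._scale(X), (y - self.y_mean_) / self.y_sd_)
        return self

    def _scale(self, X):
        span = self.x_max_ - self.x_min_
        span = np.where(span == 0, 1.0, span)
        return 2.0 * (X - self.x_min_) / span - 1.0

    def predict(self, X):
        z = self.net_.predict(self._scale(np.asarray(X, float)))
        return self.y_mean_ + self.y_sd_ * z


# ------------------------------------------------- the fitted-model wrapper


@dataclass
class RegressionModel:
    """A fitted family bound to a band subset and preprocessing recipe."""

    family: str
    estimator: object
    band_indices: np.ndarray
    preprocessing_tag: str = "snv"
    seed: int | None = None
    wavelengths: np.ndarray | None = None

    def predict(self, X_full) -> np.ndarray:
        X_full = np.asarray(X_full, float)
        if X_full.ndim != 2:
            raise ContractError("expected a 2-D spectrum matrix")
        if self.band_indices.max(initial=-1) >= X_full.shape[1]:
            raise ContractError(
                f"band indices up to {int(self.band_indices.max())} do not fit a "
                f"matrix with {X_full.shape[1]} bands"
            )
        out = np.asarray(self.estimator.predict(X_full[:, self.band_indices])).ravel()
        if not np.all(np.isfinite(out)):
            raise DomainError("model produced non-finite predictions")
        return out

    # JSON serialisation: linear families round-trip predictions bit-exactly
    def to_json(self, path=None) -> str:
        est = self.estimator
        params: dict = {}
        if self.family in ("MLR",):
            params = {"coef": est.coef_.tolist(), "intercept": est.intercept_}
        elif self.family == "PLSR":
            params = {
                "coef": np.asarray(est.pls_.coef_).reshape(-1).tolist(),
                "x_mean": est.pls_._x_mean.tolist(),
                "y_mean": float(np.asarray(est.pls_._y_mean).ravel()[0]),
                "n_components": est.n_components_,
            }
        elif self.family == "PCR":
            ols = est.pipeline_.named_steps["ols"]
            pca = est.pipeline_.named_steps["pca"]
            params = {
                "components": pca.components_.tolist(),
                "pca_mean": pca.mean_.tolist(),
                "coef": ols.coef_.tolist(),
                "intercept": float(ols.intercept_),
                "n_components": est.n_components_,
            }
        elif self.family == "ELM":
            params = {
                "W": est.W_.tolist(), "b": est.b_.tolist(),
                "beta": est.beta_.tolist(), "x_min": est.x_min_.tolist(),
                "x_max": est.x_max_.tolist(), "activation": est.activation,
            }
        elif self.family == "BP":
            params = {
                "coefs": [w.tolist() for w in est.net_.coefs_],
                "intercepts": [b.tolist() for b in est.net_.intercepts_],
                "x_min": est.x_min_.tolist(), "x_max": est.x_max_.tolist(),
                "y_mean": est.y_mean_, "y_sd": est.y_sd_,
            }
        payload = {
            "family": self.family,
            "band_indices": self.band_indices.tolist(),
            "wavelengths": None if self.wavelengths is None else list(self.wavelengths),
            "preprocessing_tag": self.preprocessing_tag,
            "seed": self.seed,
            "parameters": params,
        }
        text = json.dumps(payload)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "RegressionModel":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        family, params = payload["family"], payload["parameters"]
        if family == "MLR":
            est = MLRRegressor()
            est.coef_ = np.array(params["coef"], float)
            est.intercept_ = float(params["intercept"])
        elif family == "PLSR":
            est = _DeserialisedLinear(
                np.array(params["coef"], float),
                x_mean=np.array(params["x_mean"], float),
                y_mean=float(params["y_mean"]),
            )
        elif family == "PCR":
            comp = np.array(params["components"], float)
            coef_pc = np.array(params["coef"], float)
            beta = comp.T @ coef_pc
            mean = np.array(params["pca_mean"], float)
            est = _DeserialisedLinear(beta, x_mean=mean, y_mean=float(params["intercept"]))
        elif family == "ELM":
            est = ELMRegressor(activation=params["activation"])
            est.W_ = np.array(params["W"], float)
            est.b_ = np.array(params["b"], float)
            est.beta_ = np.array(params["beta"], float)
            est.x_min_ = np.array(params["x_min"], float)
            est.x_max_ = np.array(params["x_max"], float)
        elif family == "BP":
            est = BPRegressor()
            net = MLPRegressor(hidden_layer_sizes=(len(params["intercepts"][0]),),
                               activation="logistic")
            net.coefs_ = [np.array(w, float) for w in params["coefs"]]
            net.intercepts_ = [np.array(b, float) for b in params["intercepts"]]
            net.n_layers_ = len(net.coefs_) + 1
            net.out_activation_ = "identity"
            est.net_ = net
            est.x_min_ = np.array(params["x_min"], float)
            est.x_max_ = np.array(params["x_max"], float)
            est.y_mean_ = float(params["y_mean"])
            est.y_sd_ = float(params["y_sd"])
        else:
            raise ContractError(f"unknown family {family!r}")
        return cls(
            family=family,
            estimator=est,
            band_indices=np.array(payload["band_indices"], int),
            preprocessing_tag=payload["preprocessing_tag"],
            seed=payload.get("seed"),
            wavelengths=(None if payload.get("wavelengths") is None
                         else np.array(payload["wavelengths"], float)),
        )


class _DeserialisedLinear:
    """Centred linear predictor reconstructed from serialised PLSR/PCR."""

    def __init__(self, beta: np.ndarray, x_mean: np.ndarray, y_mean: float):
        self.beta, self.x_mean, self.y_mean = beta, x_mean, y_mean

    def predict(self, X):
        return self.y_mean + (np.asarray(X, float) - self.x_mean) @ self.beta


def _make_estimator(family: str, hyperparams: dict, seed: int):
    hyperparams = dict(hyperparams or {})
    if family == "PLSR":
        return PLSRRegressor(random_state=seed, **hyperparams)
    if family == "PCR":
        return PCRRegressor(random_state=seed, **hyperparams)
    if family == "MLR":
        return MLRRegressor(**hyperparams)
    if family == "ELM":
        return ELMRegressor(random_state=seed, **hyperparams)
    if family == "BP":
        return BPRegressor(random_state=seed, **hyperparams)
    raise ContractError(f"unknown family {family!r}; expected one of {FAMILIES}")


def fit(
    family: str,
    X_cal,
    y_cal,
    band_indices=None,
    hyperparams: dict | None = None,
    seed: int = 0,
    preprocessing_tag: str = "snv",
    wavelengths=None,
) -> RegressionModel:
    """Fit one regression family on (a band subset of) calibration spectra."""
    X_cal = np.asarray(X_cal, float)
    y_cal = np.asarray(y_cal, float).ravel()
    if not (np.all(np.isfinite(X_cal)) and np.all(np.isfinite(y_cal))):
        raise DomainError("non-finite values in calibration data")
    idx = (np.arange(X_cal.shape[1]) if band_indices is None
           else np.asarray(band_indices, int))
    est = _make_estimator(family, hyperparams or {}, seed)
    est.fit(X_cal[:, idx], y_cal)
    return RegressionModel(
        family=family, estimator=est, band_indices=idx,
        preprocessing_tag=preprocessing_tag, seed=seed,
        wavelengths=None if wavelengths is None else np.asarray(wavelengths, float),
    )


def predict(model: RegressionModel, X) -> np.ndarray:
    return model.predict(X)


# ----------------------------------------------------------- evaluation


RPD_TIERS = ((1.5, "poor"), (2.0, "moderate"), (2.5, "good"))


def rpd_tier(rpd: float) -> str:
    """RPD interpretation tier: < 1.5 poor, 1.5-2 moderate, 2-2.5 good
    (boundary 2.5 inclusive), > 2.5 excellent."""
    if rpd < 1.5:
        return "poor"
    if rpd < 2.0:
        return "moderate"
    if rpd <= 2.5:
        return "good"
    return "excellent"


@dataclass(frozen=True)
class EvaluationReport:
    """Calibration/prediction metrics of one fitted model."""

    r2_c: float
    rmsec: float
    r2_p: float
    rmsep: float
    rpd: float
    n_c: int
    n_p: int
    sd_pred: float
    tier: str

    def to_row(self) -> dict:
        """Row in the conventional report column order."""
        return {
            "R2_C": self.r2_c, "RMSEC": self.rmsec,
            "R2_P": self.r2_p, "RMSEP": self.rmsep, "RPD": self.rpd,
        }


def _r2_rmse(y_act: np.ndarray, y_hat: np.ndarray) -> tuple[float, float]:
    sst = float(((y_act - y_act.mean()) ** 2).sum())
    if sst == 0:
        raise DomainError("zero variance in measured values: R^2 undefined")
    sse = float(((y_act - y_hat) ** 2).sum())
    return 1.0 - sse / sst, float(np.sqrt(sse / len(y_act)))


def evaluate(y_act_cal, y_cal_hat, y_act_pred, y_pred_hat) -> EvaluationReport:
    """Compute R2/RMSE on both sets plus RPD = SD / RMSEP and its tier.

    SD is the n-1 standard deviation of the measured prediction-set values.
    Raises :class:`DomainError` on zero measured variance or on a perfect
    prediction set (RMSEP = 0), where RPD is undefined.
    """
    yc, yc_hat = np.asarray(y_act_cal, float), np.asarray(y_cal_hat, float)
    yp, yp_hat = np.asarray(y_act_pred, float), np.asarray(y_pred_hat, float)
    if yc.size != yc_hat.size or yp.size != yp_hat.size:
        raise ContractError("measured/predicted length mismatch")
    if yc.size < 2 or yp.size < 2:
        raise DomainError("need at least 2 samples per set")
    r2_c, rmsec = _r2_rmse(yc, yc_hat)
    r2_p, rmsep = _r2_rmse(yp, yp_hat)
    if rmsep == 0:
        raise DomainError("RMSEP is zero: RPD undefined")
    sd_pred = float(yp.std(ddof=1))
    rpd = sd_pred / rmsep
    return EvaluationReport(
        r2_c=r2_c, rmsec=rmsec, r2_p=r2_p, rmsep=rmsep, rpd=rpd,
        n_c=int(yc.size), n_p=int(yp.size), sd_pred=sd_pred, tier=rpd_tier(rpd),
    )
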