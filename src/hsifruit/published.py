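"""Published CARS-MLR loquat quality models and band-subset fixtures.

The optimal CARS-MLR prediction equations for colour e value, firmness and
SSC are shipped as transcribed linear forms (intercept plus a coefficient
per feature wavelength): 20 bands for colour e, 29 for firmness, 18 for SSC
out of the 256-band full spectrum.  They act as fixed reference predictors,
e.g. for pixel-wise quality maps.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .errors import ContractError, DomainError

TARGET_UNITS = {"colour_e": "colour e value", "firmness": "kg/cm^2", "ssc": "Brix"}

_EXPECTED_N_BANDS = {"colour_e": 20, "firmness": 29, "ssc": 18}


def _load_json(name: str) -> dict:
    with resources.files("hsifruit.data").joinpath(name).open() as fh:
        return json.load(fh)


@dataclass(frozen=True)
class LinearBandModel:
    """Linear predictor on reflectance at specific wavelengths.

    ``predict`` computes ``intercept + coefficients . x`` for each row of a
    reflectance matrix whose columns are the model's wavelengths, in order.
    """

    wavelengths: np.ndarray
    coefficients: np.ndarray
    intercept: float
    target: str | None = None
    preprocessing_tag: str = "raw"

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        co = np.asarray(self.coefficients, dtype=float)
        if wl.size != co.size:
            raise DomainError("one coefficient per wavelength required")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "coefficients", co)

    @property
    def n_bands(self) -> int:
        return int(self.wavelengths.size)

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_bands:
            raise ContractError(
                f"model {self.target or 'linear'} expects {self.n_bands} "
                f"reflectances, got {X.shape[1]}"
            )
        return self.intercept + X @ self.coefficients


def load_published_model(target: str) -> LinearBandModel:
    """The published CARS-MLR model for ``colour_e``, ``firmness`` or ``ssc``."""
    models = _load_json("published_models.json")
    if target not in models:
        raise ContractError(f"unknown target {target!r}; expected one of {list(models)}")
    entry = models[target]
    wl = np.array([float(w) for w in entry["terms"]])
    coef = np.array(list(entry["terms"].values()), dtype=float)
    order = np.argsort(wl)
    model = LinearBandModel(
        wavelengths=wl[order],
        coefficients=coef[order],
        intercept=float(entry["intercept"]),
        target=target,
    )
    if model.n_bands != _EXPECTED_N_BANDS[target]:
        raise DomainError(
            f"{target}: fixture has {model.n_bands} bands, expected "
            f"{_EXPECTED_N_BANDS[target]}"
        )
    return model


def predict_published(target: str, reflectances) -> np.ndarray | float:
    """Evaluate the published CARS-MLR model for ``target``.

    ``reflectances`` is a vector (or matrix of rows) of reflectance values
    at the model's feature wavelengths, sorted by wavelength.
    """
    model = load_published_model(target)
    x = np.asarray(reflectances, dtype=float)
    out = model.predict(x)
    return float(out[0]) if x.ndim == 1 else out


def load_selected_bands(target: str, method: str) -> np.ndarray:
    """Published feature wavelengths (nm) for a (target, method) pair."""
    table = _load_json("selected_bands.json")
    if target not in table or method not in table[target]:
        raise ContractError(f"no published subset for ({target!r}, {method!r})")
    return np.asarray(table[target][method], dtype=float)


def full_spectrum_band_count() -> int:
    """Number of bands in the instrument's full spectrum (256)."""
    return int(_load_json("selected_bands.json")["n_full_spectrum_bands"])


def subset_percentage(target: str, method: str) -> float:
    """A published subset's size as a percentage of the full spectrum."""
    n = load_selected_bands(target, method).size
    return round(100.0 * n / full_spectrum_band_count(), 2)
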