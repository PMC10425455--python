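"""Spectral preprocessing (SNV) and deterministic calibration/prediction
set splitting (SPXY for regression, Kennard-Stone for classification).

SNV (standard normal variate) centres and scales each spectrum to mean 0,
SD 1, removing per-sample multiplicative gain and additive offset — exactly
the scatter model ``a*x + b``.  Both splitters are deterministic
farthest-point algorithms: Kennard-Stone works on X-distances alone, SPXY on
the sum of max-normalised X- and y-distance matrices so the calibration set
covers both the spectral and the response range.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, TransformerMixin

from .cube import WavelengthGrid
from .errors import DomainError


@dataclass
class SpectrumMatrix:
    """n samples x p bands of reflectance on a shared wavelength grid."""

    values: np.ndarray
    grid: WavelengthGrid
    sample_ids: list[str]
    preprocessing_tag: str = "raw"  # {"raw", "snv"}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] < 1:
            raise DomainError("spectrum matrix must be 2-D with >= 1 row")
        if self.values.shape[1] != len(self.grid):
            raise DomainError("band count does not match wavelength grid")
        if len(self.sample_ids) != self.values.shape[0]:
            raise DomainError("one sample_id per row required")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DomainError("sample_ids must be unique")
        if self.preprocessing_tag not in ("raw", "snv"):
            raise DomainError(f"unknown preprocessing_tag {self.preprocessing_tag!r}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def subset(self, indices) -> "SpectrumMatrix":
        indices = np.asarray(indices, dtype=int)
        return SpectrumMatrix(
            self.values[indices],
            self.grid,
            [self.sample_ids[i] for i in indices],
            self.preprocessing_tag,
        )


def snv_rows(X: np.ndarray) -> np.ndarray:
    """Row-wise SNV with the n-1 SD denominator; raises on a constant row."""
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise DomainError(f"constant spectrum at row {int(np.nonzero(sd.ravel() == 0)[0][0])}")
    return (X - X.mean(axis=1, keepdims=True)) / sd


class SNV(TransformerMixin, BaseEstimator):
    """Standard normal variate transformer (stateless, row-wise).

    Each spectrum is independently centred to mean 0 and scaled to SD 1
    (n-1 denominator).  Idempotent, and invariant to ``a*x + b`` scatter
    with ``a > 0``.
    """

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return snv_rows(X)


def snv(matrix: SpectrumMatrix) -> SpectrumMatrix:
    """SNV-transform a :class:`SpectrumMatrix`, retagging it ``snv``."""
    X = matrix.values
    sd = X.std(axis=1, ddof=1)
    if np.any(sd == 0):
        bad = matrix.sample_ids[int(np.nonzero(sd == 0)[0][0])]
        raise DomainError(f"constant spectrum for sample {bad!r}: SNV undefined")
    return SpectrumMatrix(
        snv_rows(X), matrix.grid, list(matrix.sample_ids), preprocessing_tag="snv"
    )


@dataclass(frozen=True)
class SplitResult:
    """Calibration/prediction index sets from a deterministic splitter."""

    cal_indices: np.ndarray
    pred_indices: np.ndarray
    method: str  # {"SPXY", "KS"}
    ratio: tuple[int, int]

    def __post_init__(self) -> None:
        cal = np.asarray(self.cal_indices, dtype=int)
        pred = np.asarray(self.pred_indices, dtype=int)
        object.__setattr__(self, "cal_indices", cal)
        object.__setattr__(self, "pred_indices", pred)
        if cal.size == 0 or pred.size == 0:
            raise DomainError("both calibration and prediction sets must be non-empty")
        if np.intersect1d(cal, pred).size:
            raise DomainError("calibration and prediction sets must be disjoint")

    @property
    def n_cal(self) -> int:
        return int(self.cal_indices.size)

    @property
    def n_pred(self) -> int:
        return int(self.pred_indices.size)

    def to_frame(self, sample_ids=None) -> pd.DataFrame:
        n = self.n_cal + self.n_pred
        ids = sample_ids if sample_ids is not None else [str(i) for i in range(n)]
        assignment = np.empty(n, dtype=object)
        assignment[self.cal_indices] = "cal"
        assignment[self.pred_indices] = "pred"
        return pd.DataFrame({"sample_id": ids, "set": assignment})

    def to_csv(self, path, sample_ids=None) -> None:
        self.to_frame(sample_ids).to_csv(path, index=False)


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5))


def _ks_select(D: np.ndarray, n_select: int) -> np.ndarray:
    """Kennard-Stone farthest-point selection on a distance matrix.

    Seeds with the pair at maximal distance (lowest indices on ties), then
    greedily adds the point with the largest minimum distance to the
    selected set.  Returns selected indices in selection order.
    """
    n = D.shape[0]
    if n_select < 2:
        raise DomainError("Kennard-Stone needs to select at least 2 samples")
    i, j = np.unravel_index(np.argmax(D), D.shape)  # argmax is first-max: lowest index tie-break
    selected = [int(min(i, j)), int(max(i, j))]
    remaining = np.ones(n, dtype=bool)
    remaining[selected] = False
    min_dist = np.minimum(D[selected[0]], D[selected[1]])
    while len(selected) < n_select:
        cand = np.where(remaining, min_dist, -np.inf)
        nxt = int(np.argmax(cand))
        selected.append(nxt)
        remaining[nxt] = False
        min_dist = np.minimum(min_dist, D[nxt])
    return np.array(selected, dtype=int)


def kennard_stone_split(
    X: np.ndarray,
    cal_fraction: float = 2.0 / 3.0,
    stratify_labels=None,
) -> SplitResult:
    """Kennard-Stone calibration/prediction split on X-distances.

    With ``stratify_labels``, farthest-point selection runs within each
    class; per-class calibration sizes are ``round(cal_fraction * class
    size)`` (half away from zero), repaired by +/-1 on the classes with the
    largest rounding remainders so the total matches
    ``round(cal_fraction * n)``.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise DomainError("need at least 3 samples to split")
    if not 0.0 < cal_fraction < 1.0:
        raise DomainError("cal_fraction must be in (0, 1)")

    if stratify_labels is None:
        n_cal = min(max(_round_half_away(cal_fraction * n), 2), n - 1)
        D = cdist(X, X)
        cal = np.sort(_ks_select(D, n_cal))
        pred = np.setdiff1d(np.arange(n), cal)
        return SplitResult(cal, pred, "KS", _ratio_of(cal_fraction))

    labels = np.asarray(stratify_labels)
    classes = [c for c in pd.unique(labels)]
    sizes = {c: int((labels == c).sum()) for c in classes}
    for c, sz in sizes.items():
        if sz < 2:
            raise DomainError(f"class {c!r} has fewer than 2 members")
    target_total = _round_half_away(cal_fraction * n)
    per_class = {c: _round_half_away(cal_fraction * sizes[c]) for c in classes}
    per_class = {c: min(max(k, 1), sizes[c] - 1) for c, k in per_class.items()}
    # repair so the class sizes sum to the global rounding
    remainders = {c: cal_fraction * sizes[c] - per_class[c] for c in classes}
    while sum(per_class.values()) < target_total:
        c = max(classes, key=lambda c: (remainders[c], -classes.index(c)))
        per_class[c] += 1
        remainders[c] -= 1
    while sum(per_class.values()) > target_total:
        c = min(classes, key=lambda c: (remainders[c], classes.index(c)))
        per_class[c] -= 1
        remainders[c] += 1

    cal_parts = []
    for c in classes:
        idx = np.nonzero(labels == c)[0]
        if per_class[c] >= 2:
            D = cdist(X[idx], X[idx])
            chosen = _ks_select(D, per_class[c])
        else:
            chosen = np.array([0])
        cal_parts.append(idx[chosen])
    cal = np.sort(np.concatenate(cal_parts))
    pred = np.setdiff1d(np.arange(n), cal)
    return SplitResult(cal, pred, "KS", _ratio_of(cal_fraction))


def spxy_split(X: np.ndarray, y: np.ndarray, cal_fraction: float = 0.75) -> SplitResult:
    """SPXY split: Kennard-Stone on joint X-y distances.

    The X and y Euclidean distance matrices are each normalised by their
    maximum and summed, so the calibration set covers both the spectral and
    the response space.  y is standardised first.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).reshape(len(X), -1)
    if not np.all(np.isfinite(y)):
        raise DomainError("y must be finite")
    n = X.shape[0]
    if n < 4:
        raise DomainError("need at least 4 samples for SPXY")
    if not 0.0 < cal_fraction < 1.0:
        raise DomainError("cal_fraction must be in (0, 1)")
    y_sd = y.std(axis=0, ddof=1)
    y_std = (y - y.mean(axis=0)) / np.where(y_sd == 0, 1.0, y_sd)
    Dx = cdist(X, X)
    Dy = cdist(y_std, y_std)
    D = Dx / Dx.max() + (Dy / Dy.max() if Dy.max() > 0 else 0.0)
    n_cal = min(max(_round_half_away(cal_fraction * n), 2), n - 1)
    cal = np.sort(_ks_select(D, n_cal))
    pred = np.setdiff1d(np.arange(n), cal)
    return SplitResult(cal, pred, "SPXY", _ratio_of(cal_fraction))


def _ratio_of(cal_fraction: float) -> tuple[int, int]:
    """Express a calibration fraction as a small cal:pred integer ratio."""
    from fractions import Fraction

    f = Fraction(cal_fraction).limit_denominator(100)
    return (f.numerator, f.denominator - f.numerator)
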