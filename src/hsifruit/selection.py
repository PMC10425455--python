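"""Feature-wavelength selection: CARS, GA and SPA.

All three selectors are scikit-learn style (``fit(X, y)`` then
``get_support()`` / ``transform``) and record their run in a
:class:`SelectionResult`.

* CARS (competitive adaptive reweighted sampling): Monte-Carlo loop in which
  bands compete through the absolute PLS regression coefficients; an
  exponentially decaying schedule forces the retained fraction from 1 down
  to 2/p, adaptive reweighted sampling removes further low-weight bands, and
  the subset with minimal cross-validated RMSE wins.
* GA: binary chromosomes over bands, tournament selection, single-point
  crossover, bitwise mutation, elitism of one; fitness is -RMSECV of a PLS
  model on the encoded subset.
* SPA (successive projections algorithm): forward chains that repeatedly add
  the band with the largest norm orthogonal to the span of those already
  chosen, scored by validation RMSE of an ordinary least-squares model.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.cross_decomposition import PLSRegression
from sklearn.feature_selection import SelectorMixin
from sklearn.model_selection import KFold

from .errors import DomainError
from .preprocess import spxy_split

import logging

logger = logging.getLogger(__name__)


@dataclass
class SelectionResult:
    """Outcome of one wavelength-selection run."""

    method: str  # {"CARS", "GA", "SPA"}
    selected_band_indices: np.ndarray
    selected_wavelengths: np.ndarray
    rmsecv_trace: np.ndarray
    winning_iteration: int
    seed: int | None = None

    def __post_init__(self) -> None:
        idx = np.asarray(self.selected_band_indices, dtype=int)
        if idx.size == 0:
            raise DomainError("selection produced an empty band subset")
        if np.unique(idx).size != idx.size or np.any(np.diff(idx) < 0):
            raise DomainError("selected band indices must be unique and sorted")
        object.__setattr__(self, "selected_band_indices", idx)
        object.__setattr__(
            self, "selected_wavelengths", np.asarray(self.selected_wavelengths, float)
        )
        object.__setattr__(self, "rmsecv_trace", np.asarray(self.rmsecv_trace, float))

    @property
    def n_selected(self) -> int:
        return int(self.selected_band_indices.size)

    def to_json(self, path=None) -> str:
        payload = {
            "method": self.method,
            "selected_band_indices": self.selected_band_indices.tolist(),
            "selected_wavelengths": self.selected_wavelengths.tolist(),
            "rmsecv_trace": self.rmsecv_trace.tolist(),
            "winning_iteration": int(self.winning_iteration),
            "seed": self.seed,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "SelectionResult":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(
            method=payload["method"],
            selected_band_indices=np.array(payload["selected_band_indices"], int),
            selected_wavelengths=np.array(payload["selected_wavelengths"], float),
            rmsecv_trace=np.array(payload["rmsecv_trace"], float),
            winning_iteration=int(payload["winning_iteration"]),
            seed=payload.get("seed"),
        )


# ---------------------------------------------------------------- helpers


def _canonical_order(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Sample ordering that is invariant to input permutation.

    Sorts primarily by y, then by the first spectral bands; makes the
    seeded Monte-Carlo selectors permutation-invariant.
    """
    keys = [X[:, j] for j in range(min(X.shape[1], 3) - 1, -1, -1)] + [y]
    return np.lexsort(tuple(keys))


def _check_xy(X, y, cv_folds: int):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if not np.all(np.isfinite(y)):
        raise DomainError("y must be finite")
    if X.shape[0] != y.size:
        raise DomainError("X and y length mismatch")
    if X.shape[0] < cv_folds + 2:
        raise DomainError(f"need at least cv_folds + 2 = {cv_folds + 2} samples")
    return X, y


def _pls_rmsecv(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    cv_folds: int,
    seed: int,
) -> float:
    """5-fold (by default) cross-validated RMSE of a PLS model."""
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    sse = 0.0
    for train, test in kf.split(X):
        nc = max(1, min(n_components, X.shape[1], len(train) - 1))
        pls = PLSRegression(n_components=nc, scale=False)
        pls.fit(X[train], y[train])
        pred = pls.predict(X[test]).ravel()
        sse += float(((y[test] - pred) ** 2).sum())
    return float(np.sqrt(sse / len(y)))


def choose_pls_components(
    X: np.ndarray,
    y: np.ndarray,
    max_components: int = 10,
    cv_folds: int = 5,
    seed: int = 0,
) -> int:
    """Latent-variable count minimising cross-validated RMSE (cap 10)."""
    cap = max(1, min(max_components, X.shape[1], X.shape[0] - 2))
    scores = [
        _pls_rmsecv(X, y, nc, cv_folds, seed) for nc in range(1, cap + 1)
    ]
    return int(np.argmin(scores)) + 1


def _wavelengths(grid, indices: np.ndarray) -> np.ndarray:
    if grid is None:
        return np.asarray(indices, dtype=float)
    return np.asarray(grid.wavelengths)[indices]


class _BandSelector(SelectorMixin, BaseEstimator):
    """Shared plumbing: support mask + SelectionResult exposure."""

    def _get_support_mask(self):
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "support_")
        return self.support_

    def _finalise(self, p, indices, trace, winning, method, seed, grid):
        indices = np.sort(np.unique(np.asarray(indices, int)))
        self.support_ = np.zeros(p, dtype=bool)
        self.support_[indices] = True
        self.selected_idx_ = indices
        self.rmsecv_trace_ = np.asarray(trace, float)
        self.winning_iteration_ = int(winning)
        self.result_ = SelectionResult(
            method=method,
            selected_band_indices=indices,
            selected_wavelengths=_wavelengths(grid, indices),
            rmsecv_trace=self.rmsecv_trace_,
            winning_iteration=int(winning),
            seed=seed,
        )
        self.n_features_in_ = p
        return self


class CARSSelector(_BandSelector):
    """Competitive adaptive reweighted sampling wavelength selector.

    Parameters
    ----------
    n_runs : Monte-Carlo sampling runs (50, the published setting).
    cv_folds : folds of the RMSECV that scores each surviving subset (5).
    mc_sample_fraction : fraction of calibration samples drawn per run.
    max_components : cap on the inner PLS latent-variable count; the count
        itself is chosen once by RMSECV on the full spectrum.
    random_state : seed for Monte-Carlo sampling and CV fold shuffling.
    """

    def __init__(
        self,
        n_runs: int = 50,
        cv_folds: int = 5,
        mc_sample_fraction: float = 0.8,
        max_components: int = 10,
        random_state: int | None = 0,
        grid=None,
    ):
        self.n_runs = n_runs
        self.cv_folds = cv_folds
        self.mc_sample_fraction = mc_sample_fraction
        self.max_components = max_components
        self.random_state = random_state
        self.grid = grid

    def fit(self, X, y):
        if self.n_runs < 2:
            raise DomainError("n_runs must be >= 2")
        X, y = _check_xy(X, y, self.cv_folds)
        order = _canonical_order(X, y)
        X, y = X[order], y[order]
        n, p = X.shape
        seed = 0 if self.random_state is None else int(self.random_state)
        rng = np.random.default_rng(seed)
        n_comp = choose_pls_components(
            X, y, self.max_components, self.cv_folds, seed
        )

        # exponential retention schedule r_i = a * exp(-k i): r_1 = 1, r_N = 2/p
        N = self.n_runs
        a = (p / 2.0) ** (1.0 / (N - 1))
        k = np.log(p / 2.0) / (N - 1)

        subset = np.arange(p)
        trace, subsets = [], []
        m = max(2, int(round(self.mc_sample_fraction * n)))
        for i in range(1, N + 1):
            if subset.size == 0:
                logger.warning("CARS eliminated all bands at iteration %d", i)
                break
            samp = rng.choice(n, size=m, replace=False)
            nc = max(1, min(n_comp, subset.size, m - 1))
            pls = PLSRegression(n_components=nc, scale=False)
            pls.fit(X[np.ix_(samp, subset)], y[samp])
            w = np.abs(np.asarray(pls.coef_).reshape(-1))

            ratio = a * np.exp(-k * i)
            n_keep = min(max(2, int(round(ratio * p))), subset.size)
            top = np.argsort(-w, kind="stable")[:n_keep]
            top_bands, top_w = subset[top], w[top]
            # adaptive reweighted sampling: n_keep weighted draws, keep uniques
            if top_w.sum() > 0:
                probs = top_w / top_w.sum()
                draws = rng.choice(n_keep, size=n_keep, replace=True, p=probs)
                subset = np.sort(np.unique(top_bands[draws]))
            else:
                subset = np.sort(top_bands)
            trace.append(
                _pls_rmsecv(
                    X[:, subset],
                    y,
                    max(1, min(n_comp, subset.size)),
                    self.cv_folds,
                    seed,
                )
            )
            subsets.append(subset)
        if not subsets:
            raise DomainError("CARS failed before any subset was evaluated")
        best = int(np.argmin(trace))
        return self._finalise(
            p, subsets[best], trace, best, "CARS", seed, self.grid
        )


class GASelector(_BandSelector):
    """Genetic-algorithm wavelength selector.

    Published settings: population 30, crossover probability 0.5, mutation
    probability 0.01, 100 generations.  Fitness is -RMSECV of a PLS model on
    the encoded subset; tournament selection (size 2), single-point
    crossover, bitwise mutation, elitism of one.  Deterministic under
    ``random_state``.
    """

    def __init__(
        self,
        population: int = 30,
        crossover_p: float = 0.5,
        mutation_p: float = 0.01,
        generations: int = 100,
        cv_folds: int = 5,
        max_components: int = 10,
        init_prob: float = 0.3,
        random_state: int | None = 0,
        grid=None,
    ):
        self.population = population
        self.crossover_p = crossover_p
        self.mutation_p = mutation_p
        self.generations = generations
        self.cv_folds = cv_folds
        self.max_components = max_components
        self.init_prob = init_prob
        self.random_state = random_state
        self.grid = grid

    def fit(self, X, y):
        if self.population < 4 or self.population % 2:
            raise DomainError("population must be even and >= 4")
        if not (0 <= self.crossover_p <= 1 and 0 <= self.mutation_p <= 1):
            raise DomainError("probabilities must be in [0, 1]")
        X, y = _check_xy(X, y, self.cv_folds)
        order = _canonical_order(X, y)
        X, y = X[order], y[order]
        n, p = X.shape
        seed = 0 if self.random_state is None else int(self.random_state)
        rng = np.random.default_rng(seed)
        n_comp = choose_pls_components(X, y, self.max_components, self.cv_folds, seed)

        cache: dict[bytes, float] = {}

        def fitness(chrom: np.ndarray) -> float:
            key = chrom.tobytes()
            if key not in cache:
                idx = np.nonzero(chrom)[0]
                if idx.size == 0:
                    cache[key] = -np.inf  # all-zero chromosome: worst, never fitted
                else:
                    cache[key] = -_pls_rmsecv(
                        X[:, idx], y, max(1, min(n_comp, idx.size)),
                        self.cv_folds, seed,
                    )
            return cache[key]

        pop = (rng.random((self.population, p)) < self.init_prob).astype(np.uint8)
        fits = np.array([fitness(c) for c in pop])
        best_i = int(np.argmax(fits))
        best_chrom, best_fit = pop[best_i].copy(), float(fits[best_i])
        best_trace = [best_fit]

        for _ in range(self.generations):
            children = []
            while len(children) < self.population:
                parents = []
                for _ in range(2):  # tournament of 2
                    i, j = rng.integers(self.population, size=2)
                    parents.append(pop[i] if fits[i] >= fits[j] else pop[j])
                c1, c2 = parents[0].copy(), parents[1].copy()
                if rng.random() < self.crossover_p and p > 1:
                    cut = int(rng.integers(1, p))
                    c1[cut:], c2[cut:] = parents[1][cut:], parents[0][cut:]
                for c in (c1, c2):
                    flip = rng.random(p) < self.mutation_p
                    c[flip] ^= 1
                children.extend([c1, c2])
            pop = np.array(children[: self.population])
            pop[0] = best_chrom  # elitism of one
            fits = np.array([fitness(c) for c in pop])
            gen_best = int(np.argmax(fits))
            if fits[gen_best] > best_fit:
                best_fit = float(fits[gen_best])
                best_chrom = pop[gen_best].copy()
            best_trace.append(best_fit)

        indices = np.nonzero(best_chrom)[0]
        trace = -np.asarray(best_trace)  # RMSECV scale
        self.best_fitness_trace_ = np.asarray(best_trace)
        return self._finalise(
            p, indices, trace, int(np.argmin(trace)), "GA", seed, self.grid
        )


class SPASelector(_BandSelector):
    """Successive projections algorithm wavelength selector.

    For every candidate start band a chain is grown by repeatedly picking
    the band with maximal projection norm orthogonal to the span of the
    chain so far; every (start, length) chain is scored by the validation
    RMSE of an OLS model on an SPXY 3:1 sub-split of the calibration data,
    and the global minimiser is returned.  Fully deterministic.
    """

    def __init__(
        self,
        min_vars: int = 1,
        max_vars: int = 30,
        validation_fraction: float = 0.25,
        grid=None,
    ):
        self.min_vars = min_vars
        self.max_vars = max_vars
        self.validation_fraction = validation_fraction
        self.grid = grid

    @staticmethod
    def chain_from(X: np.ndarray, start: int, max_len: int) -> list[int]:
        """Projection chain from one start band (exposed for oracle tests)."""
        n, p = X.shape
        R = np.array(X, dtype=float, copy=True)
        chain = [int(start)]
        alive = np.ones(p, dtype=bool)
        alive[start] = False
        tol = 1e-10 * max(np.linalg.norm(X, axis=0).max(), 1.0)
        for _ in range(min(max_len, p) - 1):
            q = R[:, chain[-1]]
            nq = np.linalg.norm(q)
            if nq <= tol:
                break
            q = q / nq
            R = R - np.outer(q, q @ R)
            norms = np.where(alive, np.linalg.norm(R, axis=0), -1.0)
            nxt = int(np.argmax(norms))
            if norms[nxt] <= tol:
                logger.info("SPA chain from band %d truncated: collinear exhaustion", start)
                break
            chain.append(nxt)
            alive[nxt] = False
        return chain

    def fit(self, X, y):
        X, y = _check_xy(X, y, 2)
        n, p = X.shape
        if not 1 <= self.min_vars <= self.max_vars <= p:
            raise DomainError("need 1 <= min_vars <= max_vars <= n_bands")
        split = spxy_split(X, y, 1.0 - self.validation_fraction)
        Xt, yt = X[split.cal_indices], y[split.cal_indices]
        Xv, yv = X[split.pred_indices], y[split.pred_indices]
        max_len = min(self.max_vars, Xt.shape[0] - 1, p)

        best = (np.inf, None)
        trace = []
        for start in range(p):
            chain = self.chain_from(Xt, start, max_len)
            for m in range(self.min_vars, len(chain) + 1):
                idx = np.array(sorted(chain[:m]), dtype=int)
                A = np.column_stack([np.ones(len(Xt)), Xt[:, idx]])
                coef, *_ = np.linalg.lstsq(A, yt, rcond=None)
                pred = np.column_stack([np.ones(len(Xv)), Xv[:, idx]]) @ coef
                rmse = float(np.sqrt(np.mean((yv - pred) ** 2)))
                trace.append(rmse)
                if rmse < best[0] - 1e-15:
                    best = (rmse, idx)
        if best[1] is None:
            raise DomainError("SPA found no valid chain")
        trace = np.asarray(trace)
        return self._finalise(
            p, best[1], trace, int(np.argmin(trace)), "SPA", None, self.grid
        )


# thin functional wrappers (the spec-level operation surface)


def cars_select(X, y, config: dict | None = None, grid=None) -> SelectionResult:
    sel = CARSSelector(grid=grid, **(config or {}))
    return sel.fit(X, y).result_


def ga_select(X, y, config: dict | None = None, grid=None) -> SelectionResult:
    sel = GASelector(grid=grid, **(config or {}))
    return sel.fit(X, y).result_


def spa_select(X, y, config: dict | None = None, grid=None) -> SelectionResult:
    sel = SPASelector(grid=grid, **(config or {}))
    return sel.fit(X, y).result_
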