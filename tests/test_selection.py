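"""CARS, GA and SPA wavelength selection."""
import numpy as np
import pytest

import hsifruit as hf
from hsifruit.errors import DomainError
from hsifruit.published import full_spectrum_band_count, load_selected_bands
from hsifruit.selection import SelectionResult, SPASelector


@pytest.fixture(scope="module")
def sparse_task(request):
    """200-sample synthetic task whose SSC target loads on 5 known bands."""
    params = hf.SynthSpectraParams(noise_sd=0.005)
    table = hf.simulate_quality_table(200, seed=1)
    matrix = hf.snv(hf.simulate_spectra(table, params, seed=3))
    return matrix.values, table.column("ssc"), params.true_bands("ssc")


def test_cars_trace_length_and_monotone_subsets(sparse_task):
    X, y, _ = sparse_task
    sel = hf.CARSSelector(n_runs=50, random_state=0).fit(X, y)
    assert sel.rmsecv_trace_.size == 50
    assert sel.winning_iteration_ == int(np.argmin(sel.rmsecv_trace_))
    assert sel.result_.n_selected < X.shape[1]


def test_cars_deterministic_and_permutation_invariant(sparse_task, rng):
    X, y, _ = sparse_task
    a = hf.CARSSelector(n_runs=20, random_state=3).fit(X, y).selected_idx_
    b = hf.CARSSelector(n_runs=20, random_state=3).fit(X, y).selected_idx_
    np.testing.assert_array_equal(a, b)
    perm = rng.permutation(len(y))
    c = hf.CARSSelector(n_runs=20, random_state=3).fit(X[perm], y[perm]).selected_idx_
    np.testing.assert_array_equal(a, c)


def test_cars_recovers_informative_bands(sparse_task):
    """Winning subsets contain >= 4 of the 5 true bands in >= 4/5 seeds."""
    X, y, true = sparse_task
    hits = 0
    for seed in range(5):
        sel = hf.CARSSelector(random_state=seed).fit(X, y)
        hits += len(set(true) & set(sel.selected_idx_)) >= 4
    assert hits >= 4


def test_cars_rejects_nonfinite_y(sparse_task):
    X, y, _ = sparse_task
    bad = y.copy()
    bad[0] = np.nan
    with pytest.raises(DomainError):
        hf.CARSSelector().fit(X, bad)


@pytest.fixture(scope="module")
def small_task(sparse_task):
    """Down-projected task (informative + noise bands) for the slower GA."""
    X, y, true = sparse_task
    keep = np.concatenate([true, np.arange(0, 256, 18)[:15]])
    keep = np.unique(keep)
    new_true = np.searchsorted(keep, true)
    return X[:, keep], y, new_true


def test_ga_deterministic_under_seed(small_task):
    X, y, _ = small_task
    cfg = dict(population=12, generations=8, random_state=5)
    r1 = hf.GASelector(**cfg).fit(X, y).result_
    r2 = hf.GASelector(**cfg).fit(X, y).result_
    np.testing.assert_array_equal(r1.selected_band_indices, r2.selected_band_indices)
    np.testing.assert_allclose(r1.rmsecv_trace, r2.rmsecv_trace)


def test_ga_best_fitness_nondecreasing(small_task):
    X, y, _ = small_task
    sel = hf.GASelector(population=12, generations=10, random_state=1).fit(X, y)
    assert np.all(np.diff(sel.best_fitness_trace_) >= 0)  # elitism


def test_ga_subset_beats_full_spectrum(small_task):
    """The GA-selected subset's RMSECV is no worse than the full spectrum's."""
    from hsifruit.selection import _pls_rmsecv, choose_pls_components

    X, y, _ = small_task
    sel = hf.GASelector(population=12, generations=12, random_state=2).fit(X, y)
    nc = choose_pls_components(X, y, seed=2)
    full = _pls_rmsecv(X, y, nc, 5, 2)
    subset_rmsecv = -sel.best_fitness_trace_[-1]
    assert subset_rmsecv <= full + 1e-12
    assert 0 < sel.result_.n_selected < X.shape[1]


def test_ga_parameter_validation(small_task):
    X, y, _ = small_task
    with pytest.raises(DomainError):
        hf.GASelector(population=7).fit(X, y)
    with pytest.raises(DomainError):
        hf.GASelector(mutation_p=1.5).fit(X, y)


def test_spa_chain_on_orthonormal_columns():
    """Start at column j picks j first, then the largest-norm remaining one."""
    Q = np.eye(6)
    Q[:, 3] *= 2.0  # make column 3 the largest
    chain = SPASelector.chain_from(Q, start=0, max_len=3)
    assert chain[0] == 0
    assert chain[1] == 3


def test_spa_never_coselects_duplicated_column():
    rng = np.random.default_rng(0)
    X = rng.random((30, 5))
    X = np.column_stack([X, X[:, 2]])  # column 5 duplicates column 2
    chain = SPASelector.chain_from(X, start=2, max_len=6)
    assert not ({2, 5} <= set(chain))


def test_spa_chain_matches_bruteforce_projection(rng):
    """Greedy chain equals explicit argmax of orthogonal-projection norms."""
    X = rng.normal(size=(15, 6))
    start = 1
    chain = SPASelector.chain_from(X, start, max_len=4)
    picked = [start]
    for _ in range(3):
        B = X[:, picked]
        P = B @ np.linalg.pinv(B)
        norms = [
            -1.0 if j in picked else np.linalg.norm(X[:, j] - P @ X[:, j])
            for j in range(6)
        ]
        picked.append(int(np.argmax(norms)))
    assert chain == picked


def test_spa_selects_minimum_validation_rmse(small_task):
    X, y, true = small_task
    sel = hf.SPASelector(min_vars=1, max_vars=8).fit(X, y)
    res = sel.result_
    assert res.method == "SPA"
    assert 1 <= res.n_selected <= 8
    assert res.rmsecv_trace.min() == res.rmsecv_trace[res.winning_iteration]
    # SPA should pick up at least some truly informative bands
    assert len(set(true) & set(res.selected_band_indices)) >= 2


def test_selection_result_roundtrip(tmp_path, small_task):
    X, y, _ = small_task
    res = hf.SPASelector(max_vars=5).fit(X, y).result_
    path = tmp_path / "sel.json"
    res.to_json(path)
    back = SelectionResult.from_json(path)
    np.testing.assert_array_equal(back.selected_band_indices,
                                  res.selected_band_indices)
    np.testing.assert_allclose(back.rmsecv_trace, res.rmsecv_trace)


def test_selection_result_invariants():
    with pytest.raises(DomainError):
        SelectionResult("CARS", np.array([3, 3]), np.array([500.0, 500.0]),
                        np.array([1.0]), 0)


@pytest.mark.parametrize("target, method, count", [
    ("colour_e", "CARS", 20), ("colour_e", "GA", 29), ("colour_e", "SPA", 3),
    ("firmness", "CARS", 29), ("firmness", "GA", 22), ("firmness", "SPA", 27),
    ("ssc", "CARS", 18), ("ssc", "GA", 23), ("ssc", "SPA", 16),
])
def test_published_band_subsets(target, method, count):
    wl = load_selected_bands(target, method)
    assert wl.size == count
    assert np.all((wl >= 390) & (wl <= 1030))


def test_published_subsets_resolve_on_instrument_grid():
    """Every published wavelength maps onto the 256-band 390-1030 nm grid."""
    grid = hf.SynthSpectraParams().grid
    assert full_spectrum_band_count() == 256
    for target in ("colour_e", "firmness", "ssc"):
        wl = load_selected_bands(target, "CARS")
        idx = grid.indices_for(wl)
        # printed wavelengths sit within half a band spacing of the uniform
        # grid; a couple of adjacent pairs (e.g. 705/707 nm) share a band
        assert np.unique(idx).size >= wl.size - 2
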