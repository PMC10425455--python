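"""SNV preprocessing and SPXY / Kennard-Stone splitting."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.spatial.distance import cdist

import hsifruit as hf
from hsifruit.cube import WavelengthGrid
from hsifruit.errors import DomainError
from hsifruit.preprocess import SpectrumMatrix, snv_rows


def _matrix(X, tag="raw"):
    grid = WavelengthGrid(np.linspace(400, 1000, X.shape[1]))
    return SpectrumMatrix(X, grid, [f"s{i}" for i in range(X.shape[0])], tag)


def test_snv_simple_row():
    np.testing.assert_allclose(snv_rows(np.array([[1.0, 2.0, 3.0]])),
                               [[-1.0, 0.0, 1.0]])


def test_snv_idempotent(rng):
    X = rng.random((10, 30))
    once = snv_rows(X)
    np.testing.assert_allclose(snv_rows(once), once, atol=1e-12)


@given(
    a=st.floats(0.1, 10), b=st.floats(-5, 5),
    row=arrays(np.float64, 20, elements=st.floats(0, 1, width=32)),
)
@settings(max_examples=50, deadline=None, derandomize=True)
def test_snv_removes_multiplicative_and_additive_scatter(a, b, row):
    """snv(a x + b) == snv(x) for a > 0 — the property SNV exists for."""
    if np.std(row, ddof=1) < 1e-6:
        return
    base = snv_rows(row[None, :])
    scattered = snv_rows((a * row + b)[None, :])
    np.testing.assert_allclose(scattered, base, atol=1e-7)


def test_snv_constant_row_names_sample():
    X = np.vstack([np.arange(5.0), np.full(5, 2.0)])
    with pytest.raises(DomainError, match="s1"):
        hf.snv(_matrix(X))


def test_snv_retags_matrix(spectra200):
    out = hf.snv(spectra200)
    assert out.preprocessing_tag == "snv"
    assert spectra200.preprocessing_tag == "raw"  # input untouched


@pytest.mark.parametrize("n, expected_cal, expected_pred", [(140, 105, 35), (120, 90, 30)])
def test_spxy_three_to_one_sizes(rng, n, expected_cal, expected_pred):
    X = rng.random((n, 20))
    y = rng.random(n)
    split = hf.spxy_split(X, y, 0.75)
    assert (split.n_cal, split.n_pred) == (expected_cal, expected_pred)
    assert np.array_equal(np.sort(np.concatenate([split.cal_indices,
                                                  split.pred_indices])),
                          np.arange(n))


def test_spxy_seeds_with_max_joint_distance_pair(rng):
    X = rng.random((30, 8))
    y = rng.random(30)
    split = hf.spxy_split(X, y, 0.5)
    Dx = cdist(X, X)
    ys = (y - y.mean()) / y.std(ddof=1)
    Dy = cdist(ys[:, None], ys[:, None])
    D = Dx / Dx.max() + Dy / Dy.max()
    i, j = np.unravel_index(np.argmax(D), D.shape)
    assert i in split.cal_indices and j in split.cal_indices


def test_spxy_covers_response_range(table200, snv200):
    """Extremes of y land in the calibration set (wider calibration range)."""
    y = table200.column("ssc")
    split = hf.spxy_split(snv200.values, y, 0.75)
    assert np.argmin(y) in split.cal_indices
    assert np.argmax(y) in split.cal_indices
    assert y[split.cal_indices].min() <= y[split.pred_indices].min()
    assert y[split.cal_indices].max() >= y[split.pred_indices].max()


def test_spxy_deterministic(rng):
    X = rng.random((40, 10))
    y = rng.random(40)
    s1 = hf.spxy_split(X, y, 0.75)
    s2 = hf.spxy_split(X, y, 0.75)
    np.testing.assert_array_equal(s1.cal_indices, s2.cal_indices)


@pytest.mark.parametrize("bad", [0.0, 1.0, -0.5, 1.5])
def test_split_fraction_validation(rng, bad):
    X = rng.random((10, 4))
    with pytest.raises(DomainError):
        hf.spxy_split(X, rng.random(10), bad)
    with pytest.raises(DomainError):
        hf.kennard_stone_split(X, bad)


def test_kennard_stone_stratified_published_sizes(rng):
    """Stage sizes 60/150/39 at 2:1 give 166 calibration / 83 prediction."""
    labels = np.array(["I"] * 60 + ["II"] * 150 + ["III"] * 39)
    X = rng.random((249, 16))
    split = hf.kennard_stone_split(X, 2 / 3, stratify_labels=labels)
    assert (split.n_cal, split.n_pred) == (166, 83)
    # the split is stratified: each class is represented in both sets
    for c in ("I", "II", "III"):
        assert (labels[split.cal_indices] == c).any()
        assert (labels[split.pred_indices] == c).any()


def test_kennard_stone_tiny():
    X = np.array([[0.0], [1.0], [10.0]])
    split = hf.kennard_stone_split(X, 2 / 3)
    assert (split.n_cal, split.n_pred) == (2, 1)
    # the two farthest points (0 and 10) are the calibration set
    assert set(split.cal_indices) == {0, 2}


def test_kennard_stone_calibration_spans_data():
    """On 1-D points, the calibration hull contains the prediction hull
    (checked exhaustively on 10 points)."""
    X = np.linspace(0, 1, 10)[:, None] ** 2
    split = hf.kennard_stone_split(X, 0.6)
    cal, pred = X[split.cal_indices, 0], X[split.pred_indices, 0]
    assert cal.min() <= pred.min() and cal.max() >= pred.max()


def test_kennard_stone_small_class_rejected(rng):
    labels = np.array(["I"] * 5 + ["II"])
    with pytest.raises(DomainError, match="II"):
        hf.kennard_stone_split(rng.random((6, 3)), 2 / 3, stratify_labels=labels)


def test_split_serialisation(tmp_path, rng):
    X = rng.random((12, 4))
    split = hf.kennard_stone_split(X, 2 / 3)
    path = tmp_path / "split.csv"
    split.to_csv(path, sample_ids=[f"s{i}" for i in range(12)])
    import pandas as pd

    df = pd.read_csv(path)
    assert set(df["set"]) == {"cal", "pred"}
    assert (df["set"] == "cal").sum() == split.n_cal
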