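"""Deviation compression, pixel-wise prediction maps and rendering."""
import json

import numpy as np
import pytest
from PIL import Image

import hsifruit as hf
from hsifruit.errors import ContractError, DomainError
from hsifruit.published import LinearBandModel
from hsifruit.synthetic import clean_spectrum
from hsifruit.quality import MaturityStage


@pytest.fixture(scope="module")
def corrected_scene():
    params = hf.SynthSpectraParams()
    table = hf.simulate_quality_table(5, seed=2)
    record = table.records[0]
    raw, white, dark, mask = hf.simulate_scene(record, 40, 40, seed=4, params=params)
    return record, hf.correct_reflectance(raw, white, dark), mask, params


def _truth_model(params, target, table):
    """Linear model on the generator's true bands, fitted on clean spectra."""
    idx = params.true_bands(target)
    X = np.vstack([clean_spectrum(r, params) for r in table])[:, idx]
    y = table.column(target)
    A = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return LinearBandModel(
        wavelengths=params.wavelengths[idx], coefficients=coef[1:],
        intercept=float(coef[0]), target=target, preprocessing_tag="raw",
    )


@pytest.mark.parametrize("c", [0.0, 0.5, 1.0])
def test_compression_preserves_mean_spectrum(corrected_scene, c):
    _, cube, mask, _ = corrected_scene
    out = hf.compress_pixels(cube, mask, c)
    np.testing.assert_allclose(
        hf.mean_spectrum(out, mask), hf.mean_spectrum(cube, mask), atol=1e-12
    )


def test_compression_identity_and_collapse(corrected_scene):
    _, cube, mask, _ = corrected_scene
    ident = hf.compress_pixels(cube, mask, 1.0)
    np.testing.assert_array_equal(ident.values, cube.values)
    collapsed = hf.compress_pixels(cube, mask, 0.0)
    m = hf.mean_spectrum(cube, mask)
    np.testing.assert_allclose(collapsed.values[mask.values],
                               np.tile(m, (mask.pixel_count, 1)), atol=1e-12)
    # background untouched
    np.testing.assert_array_equal(collapsed.values[~mask.values],
                                  cube.values[~mask.values])


def test_compression_factor_validated(corrected_scene):
    _, cube, mask, _ = corrected_scene
    with pytest.raises(DomainError):
        hf.compress_pixels(cube, mask, 1.2)


def test_map_variance_monotone_in_compression(corrected_scene):
    table = hf.simulate_quality_table(50, seed=3)
    record, cube, mask, params = corrected_scene
    model = _truth_model(params, "ssc", table)
    variances = [
        np.var(hf.predict_map(cube, mask, model, c=c).fruit_values)
        for c in (0.1, 0.5, 1.0)
    ]
    assert variances[0] <= variances[1] <= variances[2]


def test_map_c0_is_uniform_mean_prediction(corrected_scene):
    table = hf.simulate_quality_table(50, seed=3)
    record, cube, mask, params = corrected_scene
    model = _truth_model(params, "ssc", table)
    pmap = hf.predict_map(cube, mask, model, c=0.0)
    m = hf.mean_spectrum(cube, mask)
    expected = model.predict(m[None, cube.grid.indices_for(model.wavelengths)])[0]
    np.testing.assert_allclose(pmap.fruit_values, expected, atol=1e-9)


def test_map_linearity_identity(corrected_scene):
    """For a linear model at c=1, the mean pixel prediction equals the
    prediction of the mean spectrum."""
    table = hf.simulate_quality_table(50, seed=3)
    record, cube, mask, params = corrected_scene
    model = _truth_model(params, "ssc", table)
    pmap = hf.predict_map(cube, mask, model, c=1.0)
    m = hf.mean_spectrum(cube, mask)
    mean_pred = model.predict(m[None, cube.grid.indices_for(model.wavelengths)])[0]
    assert pmap.fruit_values.mean() == pytest.approx(mean_pred, abs=1e-8)


def test_map_recovers_generator_truth(corrected_scene):
    """Per-pixel predictions from the generator-truth model stay within
    model-propagated noise of the record's actual quality value."""
    table = hf.simulate_quality_table(50, seed=3)
    record, cube, mask, params = corrected_scene
    model = _truth_model(params, "ssc", table)
    pmap = hf.predict_map(cube, mask, model, c=0.0)
    tol = 3 * params.noise_sd * np.abs(model.coefficients).sum()
    assert abs(pmap.fruit_values.mean() - record.ssc) <= max(tol, 0.3)


def test_map_stage_ordering_follows_ripening():
    """Across stages, mean map values rise for colour e and SSC and fall
    for firmness."""
    params = hf.SynthSpectraParams()
    table = hf.simulate_quality_table(60, (1 / 3, 1 / 3, 1 / 3), seed=9)
    models = {t: _truth_model(params, t, table)
              for t in ("colour_e", "firmness", "ssc")}
    by_stage = {}
    for stage in (MaturityStage.I, MaturityStage.II, MaturityStage.III):
        records = [r for r in table if r.stage == stage][:5]
        sums = {t: 0.0 for t in models}
        for record in records:
            raw, white, dark, mask = hf.simulate_scene(record, 32, 32, seed=10,
                                                       params=params)
            cube = hf.correct_reflectance(raw, white, dark)
            for t, model in models.items():
                sums[t] += hf.predict_map(cube, mask, model,
                                          c=0.5).fruit_values.mean()
        by_stage[stage] = {t: v / len(records) for t, v in sums.items()}
    s1, s2, s3 = (by_stage[s] for s in (MaturityStage.I, MaturityStage.II,
                                        MaturityStage.III))
    assert s1["colour_e"] < s2["colour_e"] < s3["colour_e"]
    assert s1["ssc"] < s2["ssc"] < s3["ssc"]
    assert s1["firmness"] > s2["firmness"] > s3["firmness"]


def test_map_unresolvable_wavelengths_reported(corrected_scene):
    _, cube, mask, params = corrected_scene
    model = LinearBandModel(wavelengths=[1100.0], coefficients=[1.0],
                            intercept=0.0, target="ssc")
    with pytest.raises(ContractError, match="1100"):
        hf.predict_map(cube, mask, model, c=0.5)


def test_render_roundtrip_preserves_silhouette(tmp_path, corrected_scene):
    table = hf.simulate_quality_table(50, seed=3)
    record, cube, mask, params = corrected_scene
    model = _truth_model(params, "ssc", table)
    pmap = hf.predict_map(cube, mask, model, c=0.5)
    out = tmp_path / "map.png"
    hf.render_pseudocolour(pmap, out_path=out, background=(180, 180, 180))
    img = np.asarray(Image.open(out))
    is_background = np.all(img == 180, axis=2)
    np.testing.assert_array_equal(~is_background, mask.values)
    sidecar = json.loads((tmp_path / "map.png.json").read_text())
    assert sidecar["target"] == "ssc"
    assert sidecar["n_fruit_pixels"] == mask.pixel_count


def test_render_uniform_map_single_colour(corrected_scene, tmp_path):
    _, cube, mask, _ = corrected_scene
    values = np.full(mask.shape, np.nan)
    values[mask.values] = 5.0
    pmap = hf.PredictionMap(values, mask, "ssc", (0.0, 10.0))
    img = np.asarray(hf.render_pseudocolour(pmap, out_path=None))
    fruit_px = img[mask.values]
    assert (fruit_px == fruit_px[0]).all()
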