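"""Pixel-wise quality prediction maps with deviation compression.

Because a near-spherical fruit shades its own surface, per-pixel spectra
within one fruit vary strongly with curvature.  For visualisation the
deviation of each pixel spectrum from the fruit's mean spectrum is
compressed by a factor ``c`` in [0, 1] (``p' = m + c (p - m)``) before the
linear quality model is applied per pixel, and the resulting map is
rendered as a pseudo-colour image over the fruit mask.
"""
from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps
from PIL import Image

from .cube import FruitMask, SpectralCube, mean_spectrum
from .errors import ContractError, DomainError
from .preprocess import snv_rows


@dataclass
class PredictionMap:
    """Per-pixel predicted quality over a fruit mask (NaN outside)."""

    values: np.ndarray
    mask: FruitMask
    target: str
    colour_scale: tuple[float, float]

    def __post_init__(self) -> None:
        if self.values.shape != self.mask.shape:
            raise ContractError("map and mask shapes differ")
        if not np.all(np.isfinite(self.values[self.mask.values])):
            raise DomainError("non-finite prediction inside the fruit mask")
        lo, hi = self.colour_scale
        if not lo < hi:
            raise DomainError("colour_scale min must be < max")

    @property
    def fruit_values(self) -> np.ndarray:
        return self.values[self.mask.values]


def compress_pixels(cube: SpectralCube, mask: FruitMask, c: float) -> SpectralCube:
    """Shrink fruit-pixel spectra toward the mask-mean spectrum by factor c.

    ``c = 1`` is the identity, ``c = 0`` replaces every fruit pixel with the
    mean spectrum; the background is untouched and the mask-mean spectrum is
    preserved for every ``c``.
    """
    if not 0.0 <= c <= 1.0:
        raise DomainError(f"compression factor must be in [0, 1], got {c}")
    if cube.kind != "reflectance":
        raise ContractError("compress_pixels requires a reflectance cube")
    m = mean_spectrum(cube, mask)
    out = cube.values.copy().astype(float)
    out[mask.values] = m + c * (out[mask.values] - m)
    return SpectralCube(out, cube.grid, kind="reflectance")


def predict_map(
    cube: SpectralCube,
    mask: FruitMask,
    model,
    c: float = 0.5,
    colour_scale: tuple[float, float] | None = None,
) -> PredictionMap:
    """Apply a linear band model to every fruit pixel after compression.

    ``model`` must expose ``predict`` plus either ``wavelengths`` (nm,
    resolved on the cube's grid) or ``band_indices``; if its
    ``preprocessing_tag`` is ``snv``, each pixel spectrum is SNV-treated
    over the full grid before band extraction.
    """
    compressed = compress_pixels(cube, mask, c)
    pixels = compressed.values[mask.values]  # n_fruit x bands
    if getattr(model, "preprocessing_tag", "raw") == "snv":
        pixels = snv_rows(pixels)
    wavelengths = getattr(model, "wavelengths", None)
    if wavelengths is not None:
        idx = cube.grid.indices_for(wavelengths)
    else:
        idx = np.asarray(model.band_indices, int)
    preds = np.asarray(model.predict(pixels[:, idx])).ravel()

    values = np.full(mask.shape, np.nan)
    values[mask.values] = preds
    if colour_scale is None:
        lo, hi = float(preds.min()), float(preds.max())
        if lo == hi:
            lo, hi = lo - 0.5, hi + 0.5
        colour_scale = (lo, hi)
    target = getattr(model, "target", None) or "quality"
    return PredictionMap(values=values, mask=mask, target=target,
                         colour_scale=colour_scale)


def render_pseudocolour(
    pmap: PredictionMap,
    palette: str = "viridis",
    out_path=None,
    background=(180, 180, 180),
):
    """Render a prediction map to an RGB PNG plus a sidecar JSON.

    Fruit pixels are mapped linearly from ``colour_scale`` to the palette;
    the background is a neutral grey.  The sidecar records target, scale and
    palette so the image is interpretable on its own.
    """
    lo, hi = pmap.colour_scale
    if not lo < hi:
        raise DomainError("degenerate colour scale")
    cmap = colormaps[palette]
    norm = np.clip((pmap.values - lo) / (hi - lo), 0.0, 1.0)
    rgb = np.empty(pmap.values.shape + (3,), dtype=np.uint8)
    rgb[...] = np.asarray(background, dtype=np.uint8)
    fruit = pmap.mask.values
    rgb[fruit] = (np.asarray(cmap(norm[fruit]))[:, :3] * 255).round().astype(np.uint8)
    img = Image.fromarray(rgb, mode="RGB")
    if out_path is not None:
        img.save(out_path)
        sidecar = {
            "target": pmap.target,
            "colour_scale": [lo, hi],
            "palette": palette,
            "n_fruit_pixels": pmap.mask.pixel_count,
        }
        with open(str(out_path) + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=1)
    return img
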