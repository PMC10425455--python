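"""Hyperspectral cube containers, black/white reflectance correction,
fruit segmentation and spectrum extraction.

A cube is stored as a ``(rows, cols, bands)`` array with an explicit
wavelength grid; wavelengths are never inferred from band index.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import ContractError, DomainError, SegmentationError

logger = logging.getLogger(__name__)

CUBE_KINDS = ("raw", "white_ref", "dark_ref", "reflectance")


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing wavelengths in nm shared by a cube's bands."""

    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        if wl.ndim != 1 or wl.size < 1:
            raise DomainError("wavelength grid must be a 1-D, non-empty array")
        if np.any(np.diff(wl) <= 0):
            raise DomainError("wavelengths must be strictly increasing")
        if wl[0] < 300.0 or wl[-1] > 1200.0:
            raise DomainError("wavelengths outside [300, 1200] nm sanity bounds")

    def __len__(self) -> int:
        return int(self.wavelengths.size)

    def __eq__(self, other) -> bool:
        return isinstance(other, WavelengthGrid) and np.allclose(
            self.wavelengths, other.wavelengths
        )

    @property
    def spacing(self) -> float:
        """Median band spacing in nm."""
        return float(np.median(np.diff(self.wavelengths)))

    def window_indices(self, wl_lo: float, wl_hi: float) -> np.ndarray:
        """Band indices with wavelength in [wl_lo, wl_hi]."""
        wl = self.wavelengths
        return np.nonzero((wl >= wl_lo) & (wl <= wl_hi))[0]

    def indices_for(self, wavelengths_nm) -> np.ndarray:
        """Nearest band index for each requested wavelength.

        Raises :class:`ContractError` listing any wavelength further than
        half the band spacing from its nearest grid point.
        """
        wl = self.wavelengths
        req = np.atleast_1d(np.asarray(wavelengths_nm, dtype=float))
        idx = np.abs(wl[None, :] - req[:, None]).argmin(axis=1)
        off = np.abs(wl[idx] - req)
        bad = req[off > 0.5 * self.spacing]
        if bad.size:
            raise ContractError(
                f"wavelengths not resolvable on the grid: {bad.tolist()}"
            )
        return idx


@dataclass
class SpectralCube:
    """``(rows, cols, bands)`` cube bound to a wavelength grid."""

    values: np.ndarray
    grid: WavelengthGrid
    kind: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ContractError("cube values must be rows x cols x bands")
        if self.values.shape[2] != len(self.grid):
            raise ContractError(
                f"cube has {self.values.shape[2]} bands but grid has {len(self.grid)}"
            )
        if self.kind not in CUBE_KINDS:
            raise ContractError(f"unknown cube kind {self.kind!r}")
        if self.kind == "reflectance" and np.any(self.values < 0):
            raise DomainError("reflectance cube must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class FruitMask:
    """Boolean fruit/background mask over a cube's spatial extent."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 2:
            raise ContractError("mask must be 2-D")
        if self.pixel_count == 0:
            raise DomainError("mask must contain at least one fruit pixel")

    @property
    def pixel_count(self) -> int:
        return int(self.values.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_png(self, path) -> None:
        Image.fromarray(self.values.astype(np.uint8) * 255, mode="L").save(path)

    @classmethod
    def from_png(cls, path) -> "FruitMask":
        return cls(np.asarray(Image.open(path)) > 127)


def correct_reflectance(
    raw: SpectralCube, white: SpectralCube, dark: SpectralCube
) -> SpectralCube:
    """Black/white reference correction ``I = (I0 - B) / (W - B)``.

    ``I0`` is the raw cube, ``B`` the dark (shutter-closed) reference and
    ``W`` the white (high-reflectance) reference.  Negative corrected values
    (raw below dark, i.e. sensor noise) are clipped to 0 and counted in the
    log.
    """
    for name, cube in (("raw", raw), ("white", white), ("dark", dark)):
        if cube.shape != raw.shape:
            raise ContractError(f"{name} cube shape {cube.shape} != raw {raw.shape}")
        if cube.grid != raw.grid:
            raise ContractError(f"{name} cube wavelength grid differs from raw")
    denom = white.values.astype(float) - dark.values.astype(float)
    degenerate = denom == 0
    if np.any(degenerate):
        loc = tuple(int(v) for v in np.argwhere(degenerate)[0])
        raise DomainError(
            f"degenerate reference: white == dark at (row, col, band) {loc}"
        )
    refl = (raw.values.astype(float) - dark.values.astype(float)) / denom
    n_neg = int((refl < 0).sum())
    if n_neg:
        logger.info("clipped %d negative corrected reflectance values to 0", n_neg)
        refl = np.clip(refl, 0.0, None)
    return SpectralCube(refl, raw.grid, kind="reflectance")


def segment_fruit(
    cube: SpectralCube,
    window: tuple[float, float] = (750.0, 850.0),
    min_area: int = 16,
) -> FruitMask:
    """Threshold-based fruit/background segmentation.

    The mean reflectance over a high-contrast NIR window (default
    750-850 nm) is thresholded by Otsu's criterion; holes are filled and
    connected components below ``min_area`` pixels are dropped.
    Deterministic; raises :class:`SegmentationError` if nothing survives.
    """
    if cube.kind != "reflectance":
        raise ContractError("segment_fruit requires a reflectance cube")
    idx = cube.grid.window_indices(*window)
    if idx.size == 0:
        raise DomainError(f"no bands inside window {window}")
    img = cube.values[:, :, idx].mean(axis=2)
    if np.ptp(img) == 0:
        raise SegmentationError("uniform image: no fruit/background contrast")
    fg = img > threshold_otsu(img)
    if not fg.any():
        raise SegmentationError("empty foreground after Otsu thresholding")
    fg = ndimage.binary_fill_holes(fg)
    labels, n = ndimage.label(fg)
    keep = np.zeros_like(fg)
    for lab in range(1, n + 1):
        comp = labels == lab
        if comp.sum() >= min_area:
            keep |= comp
    if not keep.any():
        raise SegmentationError(
            f"no connected component of at least {min_area} pixels"
        )
    return FruitMask(keep)


def mean_spectrum(cube: SpectralCube, mask: FruitMask) -> np.ndarray:
    """Arithmetic mean spectrum over the masked pixels."""
    if mask.shape != cube.shape[:2]:
        raise ContractError("mask shape does not match cube")
    if mask.pixel_count == 0:
        raise DomainError("mask is empty")
    return cube.values[mask.values].mean(axis=0)
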