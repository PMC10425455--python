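"""Synthetic loquat quality tables, reflectance spectra, and imaging scenes.

The generator emulates the statistical structure the downstream chemometrics
assumes: 256-band visible/NIR reflectance (390-1030 nm) with a chlorophyll
absorption dip near 675 nm whose depth shrinks as the fruit reddens (a*
rises), a water absorption dip near 980 nm, per-sample multiplicative and
additive scatter (the artefact SNV exists to remove), and three quality
parameters (colour e, firmness, SSC) each expressed at a known sparse set of
bands so that band-selection algorithms have a recoverable ground truth.

Stage-conditional quality distributions are Gaussians whose means follow the
observed ripening trends: colour e and SSC increase, firmness decreases from
stage I to III, with a* drawn inside each stage's defining interval
(thresholds 8.33 / 15.41).
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cube import FruitMask, SpectralCube, WavelengthGrid
from .errors import DomainError
from .quality import (
    STAGE_THRESHOLD_HIGH,
    STAGE_THRESHOLD_LOW,
    MaturityStage,
    QualityRecord,
    QualityTable,
    assign_maturity_stage,
    colour_e_value,
)

TARGETS = ("colour_e", "firmness", "ssc")

# Stage-conditional distribution parameters (mean, sd) for the quality
# generator.  a* is truncated to its stage's defining interval; the L*/b*
# trends (darker, yellower flesh with ripening) keep colour e inside the
# 1.2-9 range typical of loquat.
_STAGE_PARAMS = {
    MaturityStage.I: dict(a=(3.0, 3.0), L=(62.0, 3.0), b=(38.0, 3.0),
                          firmness=(3.2, 0.40), ssc=(6.5, 0.80)),
    MaturityStage.II: dict(a=(12.0, 2.0), L=(58.0, 3.0), b=(42.0, 3.0),
                           firmness=(2.4, 0.40), ssc=(7.8, 0.80)),
    MaturityStage.III: dict(a=(19.0, 2.5), L=(54.0, 3.0), b=(44.0, 3.0),
                            firmness=(1.5, 0.30), ssc=(9.3, 0.80)),
}

# a* truncation intervals per stage (so labels match assign_maturity_stage).
_STAGE_A_BOUNDS = {
    MaturityStage.I: (-10.0, STAGE_THRESHOLD_LOW - 1e-6),
    MaturityStage.II: (STAGE_THRESHOLD_LOW, STAGE_THRESHOLD_HIGH),
    MaturityStage.III: (STAGE_THRESHOLD_HIGH + 1e-6, 30.0),
}

# Fixed population location/scale used to standardise quality values before
# they are written into the spectra; table-independent so that spectra are a
# pure function of (quality vector, params).
_POP_NORM = {"colour_e": (4.8, 2.3), "firmness": (2.4, 0.8), "ssc": (7.8, 1.3)}

#: Default stage mix, matching a typical harvest skewed toward mid-ripe fruit.
DEFAULT_STAGE_PROPORTIONS = (0.27, 0.51, 0.22)


@dataclass(frozen=True)
class SynthSpectraParams:
    """Parameters of the synthetic reflectance generator.

    ``signal_wavelengths`` maps each quality target to the nm positions of
    the bands that carry its signal; ``component_sd`` is the spread of the
    per-band signal components around the target's standardised value (it
    makes the informative bands correlated but not collinear, so all of them
    are genuinely needed to recover the target).
    """

    n_bands: int = 256
    wl_min: float = 390.0
    wl_max: float = 1030.0
    chlorophyll_center: float = 675.0
    chlorophyll_width: float = 22.0
    water_center: float = 980.0
    water_width: float = 30.0
    water_depth: float = 0.12
    signal_amplitude: float = 0.02
    component_sd: float = 0.35
    scatter_gain_sd: float = 0.08
    scatter_offset_sd: float = 0.04
    noise_sd: float = 0.005
    loading_seed: int = 20230814
    stage_proportions: tuple[float, float, float] = DEFAULT_STAGE_PROPORTIONS
    signal_wavelengths: dict = field(default_factory=lambda: {
        "colour_e": (430.0, 520.0, 560.0, 640.0, 760.0),
        "firmness": (470.0, 600.0, 720.0, 840.0, 1010.0),
        "ssc": (490.0, 580.0, 690.0, 860.0, 940.0),
    })

    def __post_init__(self) -> None:
        if self.n_bands < 2:
            raise DomainError("n_bands must be >= 2")
        if not self.wl_min < self.wl_max:
            raise DomainError("wl_min must be < wl_max")
        for name in ("scatter_gain_sd", "scatter_offset_sd", "noise_sd",
                     "component_sd"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")

    @property
    def wavelengths(self) -> np.ndarray:
        return np.linspace(self.wl_min, self.wl_max, self.n_bands)

    @property
    def grid(self) -> WavelengthGrid:
        return WavelengthGrid(self.wavelengths)

    def true_bands(self, target: str) -> np.ndarray:
        """0-based band indices carrying ``target``'s signal (the ground truth
        a selection algorithm should recover)."""
        wl = self.wavelengths
        return np.array(
            sorted(int(np.argmin(np.abs(wl - w)))
                   for w in self.signal_wavelengths[target]),
            dtype=int,
        )


def _allocate_counts(n: int, proportions) -> list[int]:
    """Largest-remainder allocation of n samples across stages."""
    props = np.asarray(proportions, dtype=float)
    if props.size != 3 or np.any(props < 0) or not np.isclose(props.sum(), 1.0):
        raise DomainError("stage_proportions must be 3 non-negative values summing to 1")
    raw = props * n
    counts = np.floor(raw).astype(int)
    for i in np.argsort(-(raw - counts))[: n - counts.sum()]:
        counts[i] += 1
    for p, c in zip(props, counts):
        if p > 0 and c == 0:
            raise DomainError(
                f"degenerate stage_proportions: proportion {p} allocates 0 of {n} samples"
            )
    return counts.tolist()


def _truncated_normal(rng: np.random.Generator, mean, sd, lo, hi, size) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_quality_table(
    n: int,
    stage_proportions=DEFAULT_STAGE_PROPORTIONS,
    seed: int = 0,
) -> QualityTable:
    """Draw a synthetic :class:`QualityTable` of ``n`` fruit.

    Per stage, a* is drawn truncated to the stage's defining interval, L*/b*
    follow their ripening trends, colour e is computed from (L*, a*, b*),
    and firmness / SSC come from stage-conditional Gaussians whose means
    decrease / increase with maturity.  Deterministic under ``seed``.
    """
    if n < 3:
        raise DomainError("need n >= 3 samples")
    counts = _allocate_counts(n, stage_proportions)
    rng = np.random.default_rng(seed)
    records: list[QualityRecord] = []
    idx = 0
    for stage, count in zip(
        (MaturityStage.I, MaturityStage.II, MaturityStage.III), counts
    ):
        if count == 0:
            continue
        par = _STAGE_PARAMS[stage]
        lo, hi = _STAGE_A_BOUNDS[stage]
        a = _truncated_normal(rng, *par["a"], lo, hi, count)
        L = np.clip(rng.normal(*par["L"], size=count), 30.0, 90.0)
        b = np.clip(rng.normal(*par["b"], size=count), 20.0, 60.0)
        firm = np.clip(rng.normal(*par["firmness"], size=count), 0.3, None)
        ssc = np.clip(rng.normal(*par["ssc"], size=count), 3.0, None)
        for j in range(count):
            records.append(
                QualityRecord(
                    sample_id=f"S{idx:04d}",
                    L_star=float(L[j]),
                    a_star=float(a[j]),
                    b_star=float(b[j]),
                    colour_e=colour_e_value(float(L[j]), float(a[j]), float(b[j])),
                    firmness=float(firm[j]),
                    ssc=float(ssc[j]),
                    stage=assign_maturity_stage(float(a[j])),
                )
            )
            idx += 1
    return QualityTable(records=records, provenance="synthetic")


def _continuum(wl: np.ndarray) -> np.ndarray:
    """Smooth fruit-like baseline: low in the visible, high in the NIR."""
    return 0.22 + 0.48 / (1.0 + np.exp(-(wl - 700.0) / 60.0))


def _record_components(record: QualityRecord, params: SynthSpectraParams) -> dict:
    """Per-band signal components for one fruit.

    Each target contributes five components ``z + component_sd * eps`` where
    ``z`` is the fruit's standardised target value and ``eps`` is a fixed
    pseudo-random function of the fruit's quality vector (hash-seeded), so
    spectra are exactly deterministic given (quality vector, params).
    """
    zs = {
        t: (getattr(record, t) - _POP_NORM[t][0]) / _POP_NORM[t][1] for t in TARGETS
    }
    key = ",".join(f"{zs[t]:.12e}" for t in TARGETS).encode()
    eps_rng = np.random.default_rng(
        [params.loading_seed, zlib.crc32(key)]
    )
    return {
        t: zs[t] + params.component_sd * eps_rng.standard_normal(
            len(params.signal_wavelengths[t])
        )
        for t in TARGETS
    }


def clean_spectrum(record: QualityRecord, params: SynthSpectraParams) -> np.ndarray:
    """Noise- and scatter-free reflectance spectrum of one fruit."""
    wl = params.wavelengths
    spec = _continuum(wl).copy()
    chl_depth = float(np.clip(0.30 - 0.011 * record.a_star, 0.03, 0.45))
    spec -= chl_depth * np.exp(
        -0.5 * ((wl - params.chlorophyll_center) / params.chlorophyll_width) ** 2
    )
    spec -= params.water_depth * np.exp(
        -0.5 * ((wl - params.water_center) / params.water_width) ** 2
    )
    comps = _record_components(record, params)
    for t in TARGETS:
        idx = params.true_bands(t)
        spec[idx] += params.signal_amplitude * comps[t]
    return np.clip(spec, 0.0, 1.2)


def simulate_spectra(
    table: QualityTable,
    params: SynthSpectraParams | None = None,
    seed: int = 0,
):
    """One reflectance spectrum per table record, with scatter and noise.

    Returns a :class:`~hsifruit.preprocess.SpectrumMatrix` tagged ``raw``.
    Per sample: clean spectrum, then multiplicative gain ``N(1, gain_sd)``
    and additive offset ``N(0, offset_sd)`` (the scatter SNV removes), then
    i.i.d. noise, clipped to [0, 1.2].
    """
    from .preprocess import SpectrumMatrix  # local import to avoid a cycle

    params = params or SynthSpectraParams()
    rng = np.random.default_rng(seed)
    n = len(table)
    X = np.empty((n, params.n_bands))
    for i, record in enumerate(table):
        spec = clean_spectrum(record, params)
        gain = 1.0 + params.scatter_gain_sd * rng.standard_normal()
        offset = params.scatter_offset_sd * rng.standard_normal()
        noise = params.noise_sd * rng.standard_normal(params.n_bands)
        X[i] = np.clip(gain * spec + offset + noise, 0.0, 1.2)
    return SpectrumMatrix(
        values=X,
        grid=params.grid,
        sample_ids=list(table.sample_ids),
        preprocessing_tag="raw",
    )


def simulate_scene(
    record: QualityRecord,
    height: int,
    width: int,
    seed: int = 0,
    params: SynthSpectraParams | None = None,
):
    """Small labelled hyperspectral scene for one fruit.

    Returns ``(raw, white, dark, truth_mask)``.  An ellipsoidal fruit region
    carries the record's clean spectrum with radial shading normalised to
    mean 1 over the mask (so the mask-mean corrected spectrum matches the
    generating spectrum up to noise); the background is a dark, nearly flat
    surface.  White/dark reference cubes are constructed so that the
    black/white correction ``(raw - dark) / (white - dark)`` recovers
    reflectance.
    """
    if height < 8 or width < 8:
        raise DomainError("scene must be at least 8 x 8 pixels")
    params = params or SynthSpectraParams()
    rng = np.random.default_rng(seed)
    wl = params.wavelengths
    nb = params.n_bands

    yy, xx = np.mgrid[0:height, 0:width]
    cy, cx = (height - 1) / 2.0, (width - 1) / 2.0
    ry, rx = 0.40 * height, 0.36 * width
    r2 = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2
    mask = r2 <= 1.0

    shading = np.sqrt(np.clip(1.0 - 0.5 * r2, 0.0, None))
    shading /= shading[mask].mean()

    spec = clean_spectrum(record, params)
    refl = np.full((height, width, nb), 0.02)
    refl[mask] = shading[mask, None] * spec[None, :]
    refl += params.noise_sd * rng.standard_normal(refl.shape)
    refl = np.clip(refl, 0.0, 1.2)

    dark_level = 100.0 + 2.0 * rng.standard_normal(nb)
    white_level = 3500.0 * (0.85 + 0.15 * (wl - wl[0]) / (wl[-1] - wl[0]))
    dark = np.broadcast_to(dark_level, (height, width, nb)).copy()
    white = np.broadcast_to(white_level, (height, width, nb)).copy()
    raw = dark + refl * (white - dark)

    grid = params.grid
    return (
        SpectralCube(raw, grid, kind="raw"),
        SpectralCube(white, grid, kind="white_ref"),
        SpectralCube(dark, grid, kind="dark_ref"),
        FruitMask(mask),
    )
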