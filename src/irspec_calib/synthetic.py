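"""Synthetic ATR-IR-like spectra and reference-method absorbance values.

The generator emulates the statistical structure the calibration analysis
assumes: a Beer-Lambert analyte term (absorbance proportional to
concentration) built from overlapping Gaussian bands, interfering bands with
random per-sample levels, per-sample additive baseline offsets and
multiplicative scatter (which SNV must remove), and additive white noise.

The spectrum of sample ``i`` at wavenumber ``v`` is

    scatter_i * [ c_i * sum_a A_a g_a(v) + sum_k z_ik A_k g_k(v) + B(v) ]
        + baseline_i + eps_iv

with ``g`` unit-height Gaussians, ``B`` a fixed matrix/solvent background
(the internal intensity reference that keeps concentration identifiable
after SNV normalization), ``z_ik ~ N(1, interferent_conc_sd)``,
``scatter_i ~ N(1, scatter_sd)`` truncated to > 0.1,
``baseline_i ~ N(0, baseline_offset_sd)`` and ``eps ~ N(0, noise_sd)``.

All randomness flows from one config seed through per-operation derived
streams, so individual pieces are reproducible in isolation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dataset import ResponseVector, SpectraMatrix
from .exceptions import ConfigError, ShapeError

__all__ = [
    "BandSpec",
    "SyntheticConfig",
    "GroundTruth",
    "sample_concentrations",
    "generate_spectra",
    "regenerate_spectra",
    "generate_aas_absorbance",
    "default_config",
]


def derived_rng(seed: int, tag: str) -> np.random.Generator:
    """A reproducible stream derived from (seed, operation tag)."""
    return np.random.default_rng([int(seed) & 0xFFFFFFFF, zlib.crc32(tag.encode())])


@dataclass
class BandSpec:
    """A Gaussian absorption band.

    ``amplitude`` is absorbance per (mg L^-1) for analyte bands and absolute
    absorbance (at nominal unit level) for interferent bands.
    """

    center: float  # cm^-1
    width: float   # Gaussian sigma, cm^-1
    amplitude: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ConfigError("band width must be > 0")
        if self.amplitude < 0:
            raise ConfigError("band amplitude must be >= 0")

    def profile(self, wavenumbers: np.ndarray) -> np.ndarray:
        d = (np.asarray(wavenumbers, dtype=float) - self.center) / self.width
        return np.exp(-0.5 * d * d)


def _default_analyte_bands() -> list[BandSpec]:
    # three overlapping analyte bands in the 1500-900 cm^-1 fingerprint region
    return [
        BandSpec(center=1400.0, width=70.0, amplitude=0.012),
        BandSpec(center=1150.0, width=60.0, amplitude=0.009),
        BandSpec(center=980.0, width=80.0, amplitude=0.011),
    ]


def _default_interferent_bands() -> list[BandSpec]:
    # two interferents overlapping the analyte bands -> >= 2 extra latent
    # directions of spectral variation besides concentration
    return [
        BandSpec(center=1300.0, width=90.0, amplitude=0.40),
        BandSpec(center=1050.0, width=65.0, amplitude=0.30),
    ]


def _default_background_bands() -> list[BandSpec]:
    # constant aqueous-matrix bands (broad OH stretch + HOH bend). A fixed
    # spectral component is what keeps concentration identifiable after SNV:
    # without it the normalized shape is invariant to scaling all per-sample
    # levels jointly, and no calibration can recover absolute concentration.
    # Making it dominate total intensity keeps the SNV response near-linear,
    # so the number of useful latent variables equals the number of latent
    # concentration-like factors (analyte + the two interferents).
    return [
        BandSpec(center=3350.0, width=250.0, amplitude=2.25),
        BandSpec(center=1640.0, width=60.0, amplitude=1.50),
    ]


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic experiment.

    Defaults mirror the study design being emulated: 198 samples, iron
    concentrations uniform over 0.5-25 mg L^-1, spectra on a 4000-400 cm^-1
    grid at 4 cm^-1 steps.
    """

    n_samples: int = 198
    conc_range: tuple[float, float] = (0.5, 25.0)
    analyte_bands: list[BandSpec] = field(default_factory=_default_analyte_bands)
    interferent_bands: list[BandSpec] = field(
        default_factory=_default_interferent_bands
    )
    background_bands: list[BandSpec] = field(
        default_factory=_default_background_bands
    )
    interferent_conc_sd: float = 0.60
    baseline_offset_sd: float = 0.05
    scatter_sd: float = 0.10
    noise_sd: float = 0.002
    wavenumber_grid: tuple[float, float, float] = (4000.0, 400.0, 4.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ConfigError("n_samples must be >= 1")
        low, high = self.conc_range
        if not low < high:
            raise ConfigError("conc_range low must be < high")
        for name in ("interferent_conc_sd", "baseline_offset_sd", "scatter_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        start, stop, step = self.wavenumber_grid
        if step <= 0:
            raise ConfigError("wavenumber step must be > 0")
        span = abs(start - stop)
        k = span / step
        if abs(k - round(k)) > 1e-9:
            raise ConfigError("wavenumber step must divide (start - stop)")

    def wavenumbers(self) -> np.ndarray:
        start, stop, step = self.wavenumber_grid
        npts = int(round(abs(start - stop) / step)) + 1
        return np.linspace(start, stop, npts)


@dataclass
class GroundTruth:
    """Every latent draw of a generated data set.

    Together with the config, these reproduce the spectra matrix bit-exactly
    (see :func:`regenerate_spectra`).
    """

    concentrations: ResponseVector
    baselines: np.ndarray          # (n,)
    scatters: np.ndarray           # (n,)
    interferent_levels: np.ndarray  # (n, k)
    noise: np.ndarray              # (n, p)

    def __post_init__(self) -> None:
        n = self.concentrations.n_samples
        if self.baselines.shape != (n,) or self.scatters.shape != (n,):
            raise ShapeError("latent vectors inconsistent with sample count")
        if self.interferent_levels.shape[0] != n or self.noise.shape[0] != n:
            raise ShapeError("latent matrices inconsistent with sample count")


def sample_concentrations(
    n: int, conc_range: Sequence[float] = (0.5, 25.0), seed: int = 0
) -> ResponseVector:
    """Stratified uniform concentrations covering [low, high].

    The range is cut into ``n`` equal-width bins, one uniform draw is taken
    per bin, and the draws are shuffled — guaranteeing coverage of the whole
    calibration range at any n.
    """
    if n < 1:
        raise ConfigError("n must be >= 1")
    low, high = float(conc_range[0]), float(conc_range[1])
    if not low < high:
        raise ConfigError("conc_range low must be < high")
    rng = derived_rng(seed, "concentrations")
    edges = np.linspace(low, high, n + 1)
    values = edges[:-1] + rng.random(n) * (edges[1:] - edges[:-1])
    rng.shuffle(values)
    return ResponseVector(values=values)


def _band_matrix(bands: Sequence[BandSpec], wn: np.ndarray) -> np.ndarray:
    """(len(bands), p) matrix of amplitude-scaled band profiles."""
    if not bands:
        return np.zeros((0, wn.size))
    lo, hi = min(wn.min(), wn.max()), max(wn.min(), wn.max())
    for b in bands:
        if not (lo <= b.center <= hi):
            raise ConfigError(
                f"band center {b.center} cm^-1 outside wavenumber grid "
                f"[{lo}, {hi}]"
            )
    return np.stack([b.amplitude * b.profile(wn) for b in bands])


def _assemble(
    cfg: SyntheticConfig,
    conc: np.ndarray,
    z: np.ndarray,
    scatters: np.ndarray,
    baselines: np.ndarray,
    noise: np.ndarray,
) -> np.ndarray:
    wn = cfg.wavenumbers()
    analyte = _band_matrix(cfg.analyte_bands, wn).sum(axis=0)      # (p,)
    background = _band_matrix(cfg.background_bands, wn).sum(axis=0)  # (p,)
    interf = _band_matrix(cfg.interferent_bands, wn)               # (k, p)
    clean = np.outer(conc, analyte) + background
    if interf.shape[0]:
        clean = clean + z @ interf
    return scatters[:, None] * clean + baselines[:, None] + noise


def generate_spectra(cfg: SyntheticConfig) -> tuple[SpectraMatrix, GroundTruth]:
    """Generate an n x p spectra matrix plus the latent ground truth."""
    wn = cfg.wavenumbers()
    n, p = cfg.n_samples, wn.size
    k = len(cfg.interferent_bands)
    _band_matrix(cfg.analyte_bands, wn)  # validates centers early
    _band_matrix(cfg.interferent_bands, wn)
    _band_matrix(cfg.background_bands, wn)

    conc = sample_concentrations(n, cfg.conc_range, cfg.seed)

    rng_z = derived_rng(cfg.seed, "interferents")
    z = rng_z.normal(1.0, cfg.interferent_conc_sd, size=(n, k)) if k else np.zeros((n, 0))

    rng_s = derived_rng(cfg.seed, "scatter")
    scatters = rng_s.normal(1.0, cfg.scatter_sd, size=n)
    # truncate multiplicative scatter away from zero/negative
    for _ in range(1000):
        bad = scatters <= 0.1
        if not bad.any():
            break
        scatters[bad] = rng_s.normal(1.0, cfg.scatter_sd, size=int(bad.sum()))
    else:
        scatters = np.maximum(scatters, 0.1 + 1e-6)

    rng_b = derived_rng(cfg.seed, "baseline")
    baselines = rng_b.normal(0.0, cfg.baseline_offset_sd, size=n)

    rng_e = derived_rng(cfg.seed, "noise")
    noise = rng_e.normal(0.0, cfg.noise_sd, size=(n, p))

    intensities = _assemble(cfg, conc.values, z, scatters, baselines, noise)
    m = SpectraMatrix(
        intensities=intensities, wavenumbers=wn, sample_ids=list(conc.sample_ids)
    )
    truth = GroundTruth(
        concentrations=conc,
        baselines=baselines,
        scatters=scatters,
        interferent_levels=z,
        noise=noise,
    )
    return m, truth


def regenerate_spectra(cfg: SyntheticConfig, truth: GroundTruth) -> SpectraMatrix:
    """Rebuild the spectra matrix deterministically from recorded latents.

    Bit-exact with respect to the matrix returned by :func:`generate_spectra`
    for the same config.
    """
    intensities = _assemble(
        cfg,
        truth.concentrations.values,
        truth.interferent_levels,
        truth.scatters,
        truth.baselines,
        truth.noise,
    )
    return SpectraMatrix(
        intensities=intensities,
        wavenumbers=cfg.wavenumbers(),
        sample_ids=list(truth.concentrations.sample_ids),
    )


def generate_aas_absorbance(
    conc: ResponseVector | np.ndarray,
    slope: float = 0.032,
    intercept: float = 0.001,
    noise_sd: float = 0.002,
    seed: int = 0,
) -> np.ndarray:
    """Reference-method absorbance: a = slope * c + intercept + N(0, noise_sd)."""
    if slope <= 0:
        raise ConfigError("AAS calibration slope must be > 0")
    if noise_sd < 0:
        raise ConfigError("noise_sd must be >= 0")
    c = conc.values if isinstance(conc, ResponseVector) else np.asarray(conc, float)
    rng = derived_rng(seed, "aas")
    return slope * c + intercept + rng.normal(0.0, noise_sd, size=c.shape)


def default_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """The 198-sample default experiment with a given seed."""
    return SyntheticConfig(seed=seed, **overrides)
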