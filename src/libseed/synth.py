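"""Synthetic LIBS spectra for three grape-seed cultivars.

Emulates the acquisition design the downstream analysis assumes: an
Echelle-like wavelength axis (constant resolving power, so channel spacing
grows in proportion to wavelength), emission lines whose intensities carry
the cultivar signal, a smooth continuum baseline, shot noise, and per-shot /
per-sample intensity fluctuations.  Each sample spectrum is the average of
``n_craters * n_accumulations`` single-shot spectra, mirroring a 4x4 crater
raster with 5 accumulations per crater (80 shots).

The cultivar signal lives in the Sr II 407.78 nm ionic line, the CN
molecular band heads at 416.70/418.07/419.65/421.51 nm, and the Ca I
422.66 nm atomic line; a set of class-independent background lines (Ca II,
Na I, H-alpha, K I, ...) fills the rest of the range so that region
selection has something to reject.  No plasma physics is modelled: line
amplitudes are configured directly, not derived from Saha/Boltzmann
equilibria.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .dataset import SpectralDataset

__all__ = [
    "WavelengthAxis",
    "EmissionLine",
    "CultivarProfile",
    "SimConfig",
    "build_axis",
    "solve_resolving_power",
    "default_line_table",
    "simulate_shot",
    "simulate_sample",
    "generate_dataset",
]

# Closed wavelength interval retained by preprocessing, and the number of
# spectrometer channels it must contain.  The default resolving power is
# solved so the geometric axis reproduces this count exactly.
TRIM_LO_NM = 380.01
TRIM_HI_NM = 860.04
N_TRIMMED_VARIABLES = 13435

AXIS_LO_NM = 230.0
AXIS_HI_NM = 880.0


@dataclass(frozen=True)
class WavelengthAxis:
    """Strictly increasing wavelength grid with lambda-proportional spacing."""

    values: np.ndarray
    resolving_power: float

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.size < 2:
            raise ValueError("axis needs at least two points")
        d = np.diff(values)
        if np.any(d <= 0):
            raise ValueError("axis must be strictly increasing")

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class EmissionLine:
    """One emission line with per-cultivar intensity multipliers."""

    center_nm: float
    fwhm_nm: float
    species: str
    base_intensity: float
    class_multipliers: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        if self.fwhm_nm <= 0:
            raise ValueError("fwhm_nm must be positive")
        if self.base_intensity < 0:
            raise ValueError("base_intensity must be non-negative")
        if len(self.class_multipliers) != 3 or min(self.class_multipliers) <= 0:
            raise ValueError("need 3 positive class multipliers")


@dataclass(frozen=True)
class CultivarProfile:
    """Line table viewed from one cultivar (multipliers resolved)."""

    cultivar: int  # 1-based label
    lines: tuple[EmissionLine, ...]

    def amplitudes(self) -> np.ndarray:
        return np.array(
            [ln.base_intensity * ln.class_multipliers[self.cultivar - 1]
             for ln in self.lines]
        )


def default_line_table() -> tuple[EmissionLine, ...]:
    """Default emission lines (centers in nm, intensities in arbitrary counts).

    Cultivar contrast is confined to the Sr II / CN / Ca I lines between
    402.74 and 426.87 nm; all other lines are class-independent background.
    """
    L = EmissionLine
    return (
        # class-informative lines; the CN band trend is roughly monotone in
        # the cultivar code while Ca/Sr follow different patterns, so the
        # class centroids are affinely independent (a linear PLS1 on the
        # 1/2/3 coding can then resolve them)
        L(407.771, 0.08, "Sr II", 2500.0, (1.00, 1.30, 0.75)),
        L(416.70, 0.15, "CN", 3200.0, (0.70, 1.00, 1.25)),
        L(418.07, 0.15, "CN", 2800.0, (0.72, 1.00, 1.22)),
        L(419.65, 0.15, "CN", 2400.0, (0.68, 1.00, 1.28)),
        L(421.51, 0.15, "CN", 2000.0, (0.74, 1.00, 1.24)),
        L(422.673, 0.08, "Ca I", 5000.0, (1.25, 1.00, 0.80)),
        # class-independent background lines
        L(393.366, 0.09, "Ca II", 6000.0),
        L(396.847, 0.09, "Ca II", 5500.0),
        L(438.354, 0.08, "Fe I", 800.0),
        L(517.268, 0.08, "Mg I", 2000.0),
        L(518.360, 0.08, "Mg I", 2200.0),
        L(588.995, 0.10, "Na I", 3500.0),
        L(589.592, 0.10, "Na I", 2500.0),
        L(656.279, 0.12, "H I", 4000.0),
        L(746.831, 0.10, "N I", 1200.0),
        L(766.490, 0.12, "K I", 4500.0),
        L(769.896, 0.12, "K I", 3800.0),
        L(777.194, 0.10, "O I", 1500.0),
    )


@dataclass(frozen=True)
class SimConfig:
    """Study design and noise model for the simulator.

    Counts mirror the emulated acquisition: 3 cultivars x 59 pellets, each
    measured as the average of 16 craters x 5 accumulations = 80 shots.
    `noise_sd` is the additive per-shot detector noise (counts);
    `shot_jitter_sigma` / `sample_jitter_sigma` are log-normal sigmas for
    per-shot and per-sample line-amplitude fluctuation;
    `sample_scale_sigma` is a global per-sample intensity factor (pellet
    coupling).  `baseline_coeffs` are polynomial coefficients in the
    normalised coordinate u = (lambda - lo)/(hi - lo).
    """

    n_cultivars: int = 3
    n_samples_per_cultivar: int = 59
    n_craters: int = 16
    n_accumulations: int = 5
    noise_sd: float = 30.0
    heteroscedastic: bool = False
    shot_jitter_sigma: float = 0.15
    sample_jitter_sigma: float = 0.10
    sample_scale_sigma: float = 0.05
    baseline_coeffs: tuple[float, ...] = (25.0, -70.0, 50.0)
    peak_shape: str = "lorentzian"
    lambda_min: float = AXIS_LO_NM
    lambda_max: float = AXIS_HI_NM
    resolving_power: float | None = None  # None -> solved for 13,435 channels
    lines: tuple[EmissionLine, ...] = field(default_factory=default_line_table)
    seed: int = 20200215

    def __post_init__(self):
        for name in ("n_cultivars", "n_samples_per_cultivar", "n_craters",
                     "n_accumulations"):
            if int(getattr(self, name)) <= 0:
                raise ValueError(f"{name} must be a positive integer")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.peak_shape not in ("lorentzian", "gaussian"):
            raise ValueError("peak_shape must be 'lorentzian' or 'gaussian'")

    @property
    def n_shots(self) -> int:
        return self.n_craters * self.n_accumulations

    @property
    def n_samples(self) -> int:
        return self.n_cultivars * self.n_samples_per_cultivar

    def noiseless(self) -> "SimConfig":
        """Copy with every stochastic term switched off (separable limit)."""
        return dataclasses.replace(
            self, noise_sd=0.0, shot_jitter_sigma=0.0,
            sample_jitter_sigma=0.0, sample_scale_sigma=0.0)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["lines"] = [dataclasses.asdict(ln) for ln in self.lines]
        return d


def build_axis(lambda_min: float, lambda_max: float,
               resolving_power: float) -> WavelengthAxis:
    """Geometric wavelength grid: lambda_{i+1} = lambda_i * (1 + 1/R).

    Runs from `lambda_min` up to the first point >= `lambda_max`, so the
    channel spacing is everywhere lambda/R (Echelle-like constant resolving
    power).
    """
    if lambda_min <= 0 or lambda_max <= lambda_min or resolving_power <= 0:
        raise ValueError("require 0 < lambda_min < lambda_max and R > 0")
    q = math.log1p(1.0 / resolving_power)
    n_steps = math.ceil(math.log(lambda_max / lambda_min) / q)
    values = lambda_min * np.exp(q * np.arange(n_steps + 1))
    return WavelengthAxis(values=values, resolving_power=resolving_power)


def _count_in_band(resolving_power: float, lambda_min: float,
                   lo: float, hi: float) -> int:
    """Points of the geometric grid falling in the closed band [lo, hi]."""
    q = math.log1p(1.0 / resolving_power)
    i_lo = math.ceil(math.log(lo / lambda_min) / q - 1e-12)
    i_hi = math.floor(math.log(hi / lambda_min) / q + 1e-12)
    return max(0, i_hi - i_lo + 1)


@lru_cache(maxsize=8)
def solve_resolving_power(lambda_min: float = AXIS_LO_NM,
                          lo: float = TRIM_LO_NM, hi: float = TRIM_HI_NM,
                          n_points: int = N_TRIMMED_VARIABLES) -> float:
    """Solve for the resolving power R that puts exactly `n_points` grid
    points inside the closed band [lo, hi].

    The point count is a step function of R, nondecreasing apart from
    endpoint phase effects, so we start from the continuum estimate
    R0 ~ (n_points - 1)/ln(hi/lo) and scan outward on a fine grid for the
    first R that is exact.  Deterministic; cached.
    """
    r0 = (n_points - 1) / math.log(hi / lo)
    step = 0.02
    for k in range(200001):
        for r in ((r0 + k * step,) if k == 0 else
                  (r0 + k * step, r0 - k * step)):
            if r > 0 and _count_in_band(r, lambda_min, lo, hi) == n_points:
                return r
    raise RuntimeError("no resolving power found; inputs inconsistent")


def default_axis(config: SimConfig | None = None) -> WavelengthAxis:
    config = config or SimConfig()
    r = config.resolving_power
    if r is None:
        r = solve_resolving_power(config.lambda_min, TRIM_LO_NM, TRIM_HI_NM,
                                  N_TRIMMED_VARIABLES)
    return build_axis(config.lambda_min, config.lambda_max, r)


def _line_profiles(lines: tuple[EmissionLine, ...], axis: WavelengthAxis,
                   shape: str) -> np.ndarray:
    """Unit-height line profile matrix, (n_lines, n_channels)."""
    lam = axis.values[None, :]
    c = np.array([ln.center_nm for ln in lines])[:, None]
    w = np.array([ln.fwhm_nm for ln in lines])[:, None]
    if shape == "lorentzian":
        return 1.0 / (1.0 + ((lam - c) / (w / 2.0)) ** 2)
    return np.exp(-4.0 * math.log(2.0) * ((lam - c) / w) ** 2)


def _baseline(config: SimConfig, axis: WavelengthAxis) -> np.ndarray:
    u = (axis.values - config.lambda_min) / (config.lambda_max - config.lambda_min)
    return np.polynomial.polynomial.polyval(u, np.asarray(config.baseline_coeffs))


def _lognormal_factors(rng: np.random.Generator, sigma: float,
                       size) -> np.ndarray:
    """Mean-one multiplicative log-normal fluctuation."""
    if sigma == 0:
        return np.ones(size)
    return np.exp(rng.normal(-0.5 * sigma**2, sigma, size=size))


def simulate_shot(profile: CultivarProfile, axis: WavelengthAxis,
                  config: SimConfig, rng: np.random.Generator,
                  sample_line_scale: np.ndarray | None = None,
                  profiles: np.ndarray | None = None,
                  baseline: np.ndarray | None = None) -> np.ndarray:
    """One single-shot spectrum: lines + baseline + additive noise.

    Negative values are possible (and intended) where the baseline is small,
    so the downstream negative-clipping step has something to do.
    """
    if len(axis) == 0:
        raise ValueError("empty wavelength axis")
    if profiles is None:
        profiles = _line_profiles(profile.lines, axis, config.peak_shape)
    if baseline is None:
        baseline = _baseline(config, axis)
    amps = profile.amplitudes()
    if sample_line_scale is not None:
        amps = amps * sample_line_scale
    amps = amps * _lognormal_factors(rng, config.shot_jitter_sigma, amps.shape)
    spectrum = amps @ profiles + baseline
    if config.noise_sd > 0:
        sd = config.noise_sd
        if config.heteroscedastic:
            sd = sd * np.sqrt(1.0 + np.clip(spectrum, 0, None) / sd)
        spectrum = spectrum + rng.normal(0.0, 1.0, size=len(axis)) * sd
    return spectrum


def simulate_sample(profile: CultivarProfile, axis: WavelengthAxis,
                    config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Average of ``n_craters * n_accumulations`` shots for one pellet."""
    n_shots = config.n_shots
    if n_shots <= 0:
        raise ValueError("need at least one shot per sample")
    n_lines = len(profile.lines)
    line_scale = (
        _lognormal_factors(rng, config.sample_jitter_sigma, n_lines)
        * _lognormal_factors(rng, config.sample_scale_sigma, ())
    )
    profiles = _line_profiles(profile.lines, axis, config.peak_shape)
    baseline = _baseline(config, axis)
    acc = np.zeros(len(axis))
    for _ in range(n_shots):
        acc += simulate_shot(profile, axis, config, rng,
                             sample_line_scale=line_scale, profiles=profiles,
                             baseline=baseline)
    return acc / n_shots


def generate_dataset(config: SimConfig | None = None,
                     seed: int | None = None) -> SpectralDataset:
    """Full study dataset: n_cultivars x n_samples_per_cultivar spectra in
    per-cultivar acquisition order, labels coded 1..n_cultivars.

    A single master seed drives everything; per-sample substreams are spawned
    from it, so the output is reproducible bit for bit.
    """
    config = config or SimConfig()
    if seed is not None:
        config = dataclasses.replace(config, seed=int(seed))
    axis = default_axis(config)
    streams = np.random.SeedSequence(config.seed).spawn(config.n_samples)
    spectra = np.empty((config.n_samples, len(axis)))
    labels = np.empty(config.n_samples, dtype=int)
    sample_ids = []
    i = 0
    for cultivar in range(1, config.n_cultivars + 1):
        profile = CultivarProfile(cultivar=cultivar, lines=config.lines)
        for j in range(config.n_samples_per_cultivar):
            rng = np.random.default_rng(streams[i])
            spectra[i] = simulate_sample(profile, axis, config, rng)
            labels[i] = cultivar
            sample_ids.append(f"C{cultivar}-{j + 1:02d}")
            i += 1
    meta = {
        "generator": "libseed.synth.generate_dataset",
        "config": config.to_dict(),
        "resolving_power": axis.resolving_power,
        "seed": config.seed,
    }
    return SpectralDataset(wavelengths=axis.values, intensities=spectra,
                           labels=labels, sample_ids=sample_ids, meta=meta)
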