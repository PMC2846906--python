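"""Synthetic SELDI-like spectrum generator.

Emulates the statistical structure the pipeline assumes, so every stage is
testable without external downloads:

* a shared fine m/z grid, with per-sample independent dropout of points
  (exercising union alignment and refinement);
* a slowly decaying exponential baseline;
* Gaussian peaks at locations shared across samples, with per-sample
  amplitude variation; a subset of "informative" peaks have their mean
  amplitude shifted in the cancer class by ``effect_size`` within-class
  amplitude SDs;
* additive i.i.d. Gaussian noise, then truncation at zero (ion abundances
  are nonnegative).

The generator produces intensity differences at peak regions — the signal
the t-filter and the moment means/variances are designed to detect.  It
does not emulate isotope envelopes, chemical noise or calibration drift.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import UsageError
from .io import RawSpectrum, RefinedMatrix

__all__ = ["SynthConfig", "generate", "generate_matrix", "generate_null_matrix"]


@dataclass
class SynthConfig:
    """Generation parameters for a two-class synthetic spectrum cohort.

    Defaults describe a modest desk-scale cohort: 30 + 30 samples on a
    4,000-point grid over 700-12,000 Da with 40 peaks of width 20 Da, 10
    of them class-informative at 5 within-class SDs, 2% dropout.
    """

    n_control: int = 30
    n_cancer: int = 30
    grid: tuple[float, float, int] = (700.0, 12000.0, 4000)
    n_peaks: int = 40
    peak_width: float = 20.0
    n_informative_peaks: int = 10
    effect_size: float = 5.0
    noise_sd: float = 0.5
    dropout_rate: float = 0.02
    baseline_amplitude: float = 20.0
    baseline_decay: float = 3000.0  # Da; exp(-(mz - mz_min)/decay)
    peak_amplitude_mean: float = 30.0
    peak_amplitude_sd: float = 3.0  # within-class amplitude SD
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate < 1.0:
            raise UsageError("dropout_rate must be in [0, 1)")
        if self.n_informative_peaks > self.n_peaks:
            raise UsageError("n_informative_peaks cannot exceed n_peaks")
        if self.effect_size < 0:
            raise UsageError("effect_size must be >= 0")
        if self.n_control < 1 or self.n_cancer < 1:
            raise UsageError("need at least one sample per class")
        lo, hi, npts = self.grid
        if not (hi > lo and npts >= 2):
            raise UsageError(f"invalid grid {self.grid}")


def _spectrum_profile(
    mz: np.ndarray,
    config: SynthConfig,
    peak_locs: np.ndarray,
    amplitudes: np.ndarray,
) -> np.ndarray:
    lo = config.grid[0]
    baseline = config.baseline_amplitude * np.exp(-(mz - lo) / config.baseline_decay)
    # sum of Gaussian peaks; sigma chosen so peak_width spans ~4 sigma
    sigma = config.peak_width / 4.0
    peaks = np.zeros_like(mz)
    for loc, amp in zip(peak_locs, amplitudes):
        peaks += amp * np.exp(-0.5 * ((mz - loc) / sigma) ** 2)
    return baseline + peaks


def generate(config: SynthConfig) -> tuple[list[RawSpectrum], np.ndarray]:
    """Generate a cohort of raw spectra with labels (+1 cancer, -1 control).

    Fully reproducible from ``config.seed``.  Each grid point is dropped
    independently per sample with probability ``dropout_rate``; intensities
    are truncated at 0 after noise.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi, npts = config.grid
    mz = np.linspace(lo, hi, npts)

    # shared peak locations; the first n_informative are class-informative
    peak_locs = np.sort(rng.uniform(lo, hi, config.n_peaks))
    informative = rng.choice(config.n_peaks, config.n_informative_peaks, replace=False)

    n_total = config.n_control + config.n_cancer
    labels = np.concatenate(
        [np.full(config.n_control, -1), np.full(config.n_cancer, 1)]
    ).astype(int)

    shift = config.effect_size * config.peak_amplitude_sd
    spectra: list[RawSpectrum] = []
    for j in range(n_total):
        amp_means = np.full(config.n_peaks, config.peak_amplitude_mean)
        if labels[j] == 1:
            amp_means[informative] += shift
        amplitudes = rng.normal(amp_means, config.peak_amplitude_sd)
        profile = _spectrum_profile(mz, config, peak_locs, amplitudes)
        intensity = profile + rng.normal(0.0, config.noise_sd, npts)
        intensity = np.clip(intensity, 0.0, None)
        if config.dropout_rate > 0:
            keep = rng.random(npts) >= config.dropout_rate
        else:
            keep = np.ones(npts, dtype=bool)
        if not keep.any():
            keep[rng.integers(npts)] = True  # never emit an empty spectrum
        prefix = "cancer" if labels[j] == 1 else "control"
        spectra.append(
            RawSpectrum(f"{prefix}_{j:03d}", mz[keep], intensity[keep])
        )
    return spectra, labels


def generate_matrix(config: SynthConfig) -> RefinedMatrix:
    """Generate a dropout-free cohort directly as a complete matrix."""
    cfg = replace(config, dropout_rate=0.0)
    spectra, labels = generate(cfg)
    mz = spectra[0].mz
    mat = np.column_stack([s.intensity for s in spectra])
    return RefinedMatrix(
        mz_axis=mz,
        intensities=mat,
        sample_ids=[s.sample_id for s in spectra],
        labels=labels,
    )


def generate_null_matrix(
    m: int,
    n_per_class: int,
    loc: float = 0.0,
    scale: float = 1.0,
    seed: int = 0,
) -> RefinedMatrix:
    """Complete matrix with every row i.i.d. normal in both classes.

    Supports type-I error calibration of the t-filter: no row carries any
    class signal, so the retained fraction should be close to alpha.
    """
    if m < 1 or n_per_class < 2:
        raise UsageError("need m >= 1 rows and >= 2 samples per class")
    if scale <= 0:
        raise UsageError("scale must be positive")
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    mat = rng.normal(loc, scale, (m, n))
    labels = np.concatenate(
        [np.full(n_per_class, -1), np.full(n_per_class, 1)]
    ).astype(int)
    ids = [f"null_{j:03d}" for j in range(n)]
    return RefinedMatrix(
        mz_axis=np.arange(1.0, m + 1.0), intensities=mat,
        sample_ids=ids, labels=labels,
    )
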