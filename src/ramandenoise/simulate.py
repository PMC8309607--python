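"""Synthetic Raman spectrum generator.

Clean spectra are sums of a random number of Lorentzian lineshapes with
random centres, heights and linewidths, spanning profiles from isolated sharp
peaks (chemical-like) to dense overlapping broad peaks (biological-like).
Noise is photon shot noise: each channel of the noisy spectrum is an
independent Poisson draw whose mean is the clean intensity in that channel.

Calibration.  Under shot noise the expected global SNR of a clean spectrum
scaled to maximum M is sqrt(M / f) where f = mean/max is the spectrum's fill
factor, because the RMSE of Poisson noise is sqrt(mean intensity).  The fill
factor varies over roughly a decade across random peak layouts, so the
generator targets the SNR directly: it draws a target SNR uniformly from
``snr_range`` (default 15–145), converts it to an intensity maximum
M = snr²·f clipped into ``intensity_max_range`` (default (0, 4000]), and
redraws the noise with a corrected M (a few bounded retries) whenever the
realized SNR lands outside the band.  The result is a dataset whose peak
intensities span ~0–4000 and whose empirical global SNRs lie inside the
configured band.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .metrics import global_snr
from .spectra import (
    LorentzianPeak,
    PeakRegion,
    Spectrum,
    SpectrumPair,
    WavenumberAxis,
    default_axis,
)

__all__ = [
    "SimConfig",
    "lorentzian_lineshape",
    "scale_to_max",
    "add_shot_noise",
    "locate_peak_region",
    "generate_pair",
    "generate_dataset",
]


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the spectrum generator.

    Ranges are inclusive.  ``linewidth_range`` is in samples (converted to
    axis units with the axis step); ``amplitude_range`` bounds the relative
    peak heights A/Γ, drawn log-uniformly so no single peak dwarfs the rest
    by construction.  ``snr_range`` is the global-SNR band the noisy spectra
    are calibrated into and ``intensity_max_range`` caps the clean spectrum
    maximum (counts).
    """

    n_samples: int = 600
    n_peaks_range: Tuple[int, int] = (5, 30)
    amplitude_range: Tuple[float, float] = (1.0, 10.0)
    linewidth_range: Tuple[float, float] = (2.0, 40.0)
    intensity_max_range: Tuple[float, float] = (0.0, 4000.0)
    snr_range: Tuple[float, float] = (15.0, 145.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_peaks_range", "amplitude_range", "linewidth_range",
                     "intensity_max_range", "snr_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} is empty: ({lo}, {hi})")
        if self.n_peaks_range[0] < 1:
            raise ValueError("need at least one peak per spectrum")
        if self.amplitude_range[0] <= 0 or self.linewidth_range[0] <= 0:
            raise ValueError("amplitudes and linewidths must be positive")
        if self.snr_range[0] <= 0:
            raise ValueError("snr_range must be positive")
        if self.n_samples < 8:
            raise ValueError("n_samples too small")

    def axis(self) -> WavenumberAxis:
        return default_axis(self.n_samples)


def lorentzian_lineshape(peaks: Sequence[LorentzianPeak],
                         axis: WavenumberAxis) -> Spectrum:
    """Sum of Lorentzian lines: Σ Im{A/(Ω-ω-iΓ)} = Σ AΓ/((Ω-ω)²+Γ²).

    Strictly positive everywhere because every Lorentzian has infinite
    support.
    """
    if len(peaks) == 0:
        raise ValueError("peak list is empty")
    w = axis.values
    total = np.zeros_like(w)
    for p in peaks:
        # dataclass validates A > 0, Γ > 0
        d = p.center - w
        total += p.amplitude * p.linewidth / (d * d + p.linewidth * p.linewidth)
    return Spectrum(axis, total)


def scale_to_max(spectrum: Spectrum, target_max: float) -> Spectrum:
    """Rescale so the spectrum maximum equals ``target_max`` (shape preserved)."""
    if target_max <= 0:
        raise ValueError("target_max must be positive")
    peak = float(np.max(spectrum.intensity))
    if peak <= 0:
        raise ValueError("spectrum has no positive maximum to scale")
    return spectrum.with_intensity(spectrum.intensity * (target_max / peak))


def add_shot_noise(spectrum: Spectrum,
                   seed: Union[int, np.random.Generator]) -> Spectrum:
    """Poisson shot noise: each channel drawn with mean = clean intensity."""
    x = spectrum.intensity
    if np.any(x < 0):
        raise ValueError("clean intensities must be non-negative for Poisson noise")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return spectrum.with_intensity(rng.poisson(x).astype(float))


def _half_max_crossing(y: np.ndarray, pk: int, half: float, direction: int) -> float:
    """Distance (in samples, fractional) from pk to the half-maximum crossing.

    Walks from the peak in ``direction`` (+1 or -1) to the first sample below
    half maximum and interpolates linearly; falls back to the distance to the
    spectrum edge when the peak sits on a pedestal that never drops below
    half maximum.
    """
    n = y.size
    i = pk
    while 0 <= i + direction < n:
        j = i + direction
        if y[j] < half:
            # linear interpolation between samples i and j
            frac = (y[i] - half) / (y[i] - y[j])
            return abs(i - pk) + frac
        i = j
    return abs(i - pk)  # edge reached without crossing


def locate_peak_region(reference: Spectrum) -> PeakRegion:
    """Find the most prominent peak and size its window from the FWHM.

    pk is the argmax (first index on ties); the half-width n is half the
    FWHM in samples, rounded, floored at 1 and shrunk if needed so the
    2n+1 window stays inside the spectrum.
    """
    y = reference.intensity
    ymax = float(np.max(y))
    if ymax <= 0:
        raise ValueError("no peak: spectrum has no positive maximum")
    if np.all(y == y[0]):
        raise ValueError("no peak: spectrum is constant")
    pk = int(np.argmax(y))
    half = ymax / 2.0
    left = _half_max_crossing(y, pk, half, -1)
    right = _half_max_crossing(y, pk, half, +1)
    fwhm = left + right
    n = max(1, int(round(fwhm / 2.0)))
    # shrink so the window fits; peaks at the very edge have no valid window
    n = min(n, pk, reference.intensity.size - 1 - pk)
    if n < 1:
        raise ValueError("peak lies at the spectrum edge; no symmetric window fits")
    return PeakRegion(center_index=pk, half_width=n)


def _draw_clean_unit(cfg: SimConfig, rng: np.random.Generator) -> Spectrum:
    """One random clean spectrum, normalized to maximum 1."""
    axis = cfg.axis()
    step = axis.step
    n_peaks = int(rng.integers(cfg.n_peaks_range[0], cfg.n_peaks_range[1] + 1))
    # keep centres one max-linewidth away from the edges so the dominant
    # peak's window fits inside the spectrum
    margin = cfg.linewidth_range[1] * step
    lo, hi = axis.values[0] + margin, axis.values[-1] - margin
    centers = rng.uniform(lo, hi, n_peaks)
    widths = rng.uniform(*cfg.linewidth_range, n_peaks) * step
    log_a = rng.uniform(np.log(cfg.amplitude_range[0]),
                        np.log(cfg.amplitude_range[1]), n_peaks)
    heights = np.exp(log_a)
    peaks = [LorentzianPeak(amplitude=h * g, center=c, linewidth=g)
             for h, c, g in zip(heights, centers, widths)]
    return scale_to_max(lorentzian_lineshape(peaks, axis), 1.0)


_MAX_NOISE_RETRIES = 50


def generate_pair(cfg: SimConfig, rng: np.random.Generator) -> SpectrumPair:
    """One (clean, noisy) pair calibrated into the configured SNR band."""
    unit = _draw_clean_unit(cfg, rng)
    fill = float(np.mean(unit.intensity))  # mean/max with max == 1
    lo, hi = cfg.snr_range
    m_lo, m_hi = cfg.intensity_max_range
    # cap the target so the implied intensity max stays within range
    cap = float(np.sqrt(m_hi / fill))
    pair = None
    target = rng.uniform(lo, min(hi, cap)) if cap > lo else lo
    m = float(np.clip(target * target * fill, max(m_lo, 1.0), m_hi))
    for _ in range(_MAX_NOISE_RETRIES):
        clean = scale_to_max(unit, m)
        noisy = add_shot_noise(clean, rng)
        snr = global_snr(noisy, clean)
        if lo <= snr <= hi:
            pair = (clean, noisy, snr)
            break
        # realized SNR scales ~ sqrt(M): rescale toward a fresh in-band
        # target and redraw the noise (the realized value jitters around
        # the target, strongly so for dim spectra)
        target = rng.uniform(lo, min(hi, cap)) if cap > lo else lo
        m = float(np.clip(m * (target / snr) ** 2, max(m_lo, 1.0), m_hi))
    if pair is None:  # pragma: no cover - bounded retries exhausted
        raise RuntimeError("could not calibrate a pair into the SNR band; "
                           "check snr_range against intensity_max_range")
    clean, noisy, snr = pair
    region = locate_peak_region(clean)
    return SpectrumPair(reference=clean, noisy=noisy, peak_region=region,
                        snr=float(snr))


def generate_dataset(cfg: SimConfig, n_spectra: int,
                     seed: Optional[int] = None) -> List[SpectrumPair]:
    """Generate ``n_spectra`` independent pairs, reproducible from the seed.

    ``seed`` overrides ``cfg.seed`` when given.
    """
    if n_spectra < 1:
        raise ValueError("n_spectra must be >= 1")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    return [generate_pair(cfg, rng) for _ in range(n_spectra)]
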