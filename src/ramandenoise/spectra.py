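"""Core containers for Raman spectra and peak annotations.

A spectrum is a wavenumber axis plus an intensity vector of the same length.
The containers here are deliberately thin wrappers over NumPy arrays: they
validate the physical invariants (uniform, strictly increasing axis;
non-negative clean intensities; peak windows that fit inside the spectrum)
and otherwise stay out of the way.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WavenumberAxis",
    "LorentzianPeak",
    "Spectrum",
    "PeakRegion",
    "SpectrumPair",
    "default_axis",
]

#: default spectrum length (samples)
DEFAULT_LENGTH = 600
#: nominal axis range, cm^-1 (the fingerprint region); cosmetic — the
#: simulator and network operate on sample indices
DEFAULT_RANGE = (400.0, 2000.0)


@dataclass(frozen=True)
class WavenumberAxis:
    """Uniformly spaced, strictly increasing spectral axis (cm^-1-like units)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("axis must be a 1-D array with at least 2 points")
        steps = np.diff(values)
        if np.any(steps <= 0):
            raise ValueError("axis must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=0.0):
            raise ValueError("axis must be uniformly spaced")
        object.__setattr__(self, "values", values)

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def step(self) -> float:
        return float(self.values[1] - self.values[0])


def default_axis(n: int = DEFAULT_LENGTH,
                 lo: float = DEFAULT_RANGE[0],
                 hi: float = DEFAULT_RANGE[1]) -> WavenumberAxis:
    """The package-wide default axis: ``n`` uniform samples over [lo, hi]."""
    return WavenumberAxis(np.linspace(lo, hi, n))


@dataclass(frozen=True)
class LorentzianPeak:
    """One Raman transition: amplitude A, resonance Ω, linewidth Γ.

    The lineshape is the imaginary part of the complex susceptibility
    A / (Ω - ω - iΓ), i.e. A·Γ / ((Ω-ω)² + Γ²); its height at resonance is
    A/Γ and its FWHM is 2Γ.
    """

    amplitude: float
    center: float
    linewidth: float

    def __post_init__(self) -> None:
        if not self.amplitude > 0:
            raise ValueError(f"amplitude must be positive, got {self.amplitude}")
        if not self.linewidth > 0:
            raise ValueError(f"linewidth must be positive, got {self.linewidth}")

    @property
    def height(self) -> float:
        """Peak maximum A/Γ (value of the lineshape at ω = Ω)."""
        return self.amplitude / self.linewidth

    @property
    def fwhm(self) -> float:
        """Full width at half maximum, 2Γ, in axis units."""
        return 2.0 * self.linewidth


@dataclass(frozen=True)
class Spectrum:
    """An intensity vector on a wavenumber axis."""

    axis: WavenumberAxis
    intensity: np.ndarray

    def __post_init__(self) -> None:
        intensity = np.asarray(self.intensity, dtype=float)
        if intensity.ndim != 1:
            raise ValueError("intensity must be 1-D")
        if intensity.size != self.axis.n:
            raise ValueError(
                f"intensity length {intensity.size} != axis length {self.axis.n}")
        object.__setattr__(self, "intensity", intensity)

    def __len__(self) -> int:
        return int(self.intensity.size)

    def with_intensity(self, intensity: np.ndarray) -> "Spectrum":
        """Same axis, new intensity values."""
        return Spectrum(self.axis, intensity)


@dataclass(frozen=True)
class PeakRegion:
    """A 2n+1-sample window centred on the most prominent peak.

    ``center_index`` (pk) is the 0-based argmax of the clean spectrum and
    ``half_width`` (n) is half the peak's FWHM in samples, so the window
    [pk-n, pk+n] covers the peak at half maximum.
    """

    center_index: int
    half_width: int

    def __post_init__(self) -> None:
        if self.half_width < 1:
            raise ValueError("half_width must be >= 1")
        if self.center_index - self.half_width < 0:
            raise ValueError("window extends below index 0")

    @property
    def window(self) -> slice:
        """Inclusive 2n+1-sample slice [pk-n, pk+n]."""
        return slice(self.center_index - self.half_width,
                     self.center_index + self.half_width + 1)

    @property
    def size(self) -> int:
        return 2 * self.half_width + 1

    def validate_for(self, n_samples: int) -> None:
        if self.center_index + self.half_width > n_samples - 1:
            raise ValueError(
                f"window [{self.center_index - self.half_width}, "
                f"{self.center_index + self.half_width}] exceeds spectrum "
                f"length {n_samples}")

    def mask(self, n_samples: int) -> np.ndarray:
        """Boolean mask of the window over a length-``n_samples`` spectrum."""
        self.validate_for(n_samples)
        m = np.zeros(n_samples, dtype=bool)
        m[self.window] = True
        return m


@dataclass(frozen=True)
class SpectrumPair:
    """A supervised training example: clean reference + noisy realization.

    ``peak_region`` is located on the clean reference; ``snr`` is the global
    SNR of the noisy realization against the reference.
    """

    reference: Spectrum
    noisy: Spectrum
    peak_region: PeakRegion
    snr: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if len(self.reference) != len(self.noisy):
            raise ValueError("reference and noisy spectra differ in length")
        if self.reference.axis is not self.noisy.axis and not np.array_equal(
                self.reference.axis.values, self.noisy.axis.values):
            raise ValueError("reference and noisy spectra must share an axis")
        self.peak_region.validate_for(len(self.reference))
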