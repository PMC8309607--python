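"""Savitzky-Golay smoothing baselines.

Two presets bracket the smoothing/peak-fidelity trade-off: SG39 (polynomial
order 3, window 9) smooths aggressively at the cost of sharp peaks; SG57
(order 5, window 7) preserves sharp features but removes less noise.
Filtering delegates to :func:`scipy.signal.savgol_filter`; edges are handled
by evaluating the polynomial fitted to the terminal window at the edge
positions (scipy's ``mode="interp"``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy.signal import savgol_filter

from .spectra import Spectrum

__all__ = ["SGConfig", "savitzky_golay", "preset", "PRESETS"]


@dataclass(frozen=True)
class SGConfig:
    window: int
    polyorder: int

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError(f"window must be an odd integer >= 3, got {self.window}")
        if not 0 <= self.polyorder < self.window:
            raise ValueError(
                f"polyorder must satisfy 0 <= polyorder < window, got "
                f"polyorder={self.polyorder}, window={self.window}")


PRESETS = {
    "SG39": SGConfig(window=9, polyorder=3),
    "SG57": SGConfig(window=7, polyorder=5),
}


def preset(name: str) -> SGConfig:
    """Look up a named preset ('SG39' or 'SG57')."""
    try:
        return PRESETS[name.upper()]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; valid presets: {sorted(PRESETS)}") from None


def savitzky_golay(spectrum: Union[Spectrum, np.ndarray],
                   config: SGConfig) -> Union[Spectrum, np.ndarray]:
    """Apply the SG smoother; accepts a Spectrum or a 1-D/2-D array.

    2-D arrays are filtered row-wise (one spectrum per row).
    """
    if isinstance(spectrum, Spectrum):
        y = spectrum.intensity
        if y.size < config.window:
            raise ValueError(
                f"spectrum length {y.size} shorter than window {config.window}")
        return spectrum.with_intensity(
            savgol_filter(y, config.window, config.polyorder, mode="interp"))
    arr = np.asarray(spectrum, dtype=float)
    if arr.shape[-1] < config.window:
        raise ValueError(
            f"spectrum length {arr.shape[-1]} shorter than window {config.window}")
    return savgol_filter(arr, config.window, config.polyorder, axis=-1,
                         mode="interp")
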