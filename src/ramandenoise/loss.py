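"""Peak-weighted training loss.

The loss is the plain MSE over the whole spectrum plus alpha times the MSE
restricted to the window around the most prominent peak of the clean target:

    Loss(xe, xref) = MSE(xe, xref) + alpha * MSE(xe[win], xref[win])

Each MSE normalizes by its own length (N for the global term, 2n+1 for the
window term), so alpha expresses the relative priority of peak fidelity over
overall smoothing independently of the window size.  alpha = 0 recovers the
standard L2 training objective; alpha = 50 is the default operating point.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

from .spectra import PeakRegion, Spectrum

__all__ = ["LossConfig", "mse", "custom_loss", "loss_weights", "batch_loss"]

ArrayLike = Union[Spectrum, np.ndarray, Sequence[float]]


def _values(x: ArrayLike) -> np.ndarray:
    if isinstance(x, Spectrum):
        return x.intensity
    return np.asarray(x, dtype=float)


@dataclass(frozen=True)
class LossConfig:
    """alpha weights the peak-window MSE term; 0 disables it.

    ``normalize_peak_by_window``: divide the peak term by the window length
    2n+1 (default) rather than by the full spectrum length N.
    """

    alpha: float = 50.0
    normalize_peak_by_window: bool = True

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")


def mse(predicted: ArrayLike, target: ArrayLike) -> float:
    """Mean squared difference, 1/N Σ (p_i - t_i)² (no square root)."""
    p, t = _values(predicted), _values(target)
    if p.shape != t.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {t.shape}")
    d = p - t
    return float(np.mean(d * d))


def custom_loss(predicted: ArrayLike, target: ArrayLike, region: PeakRegion,
                config: LossConfig = LossConfig()) -> float:
    """Global MSE plus alpha-weighted MSE over the peak window."""
    p, t = _values(predicted), _values(target)
    if p.shape != t.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {t.shape}")
    region.validate_for(t.size)
    w = region.window
    peak_term = mse(p[w], t[w])
    if not config.normalize_peak_by_window:
        peak_term *= region.size / t.size
    return mse(p, t) + config.alpha * peak_term


def loss_weights(region: PeakRegion, n_samples: int,
                 config: LossConfig = LossConfig()) -> np.ndarray:
    """Per-sample quadratic weights w such that Σ w_i e_i² == custom_loss.

    The trainer uses these to evaluate the loss and its gradient in one
    vectorized pass: w_i = 1/N everywhere plus alpha/(2n+1) inside the
    window.
    """
    w = np.full(n_samples, 1.0 / n_samples)
    denom = region.size if config.normalize_peak_by_window else n_samples
    w[region.window] += config.alpha / denom
    return w


def batch_loss(predicted: np.ndarray, target: np.ndarray,
               weights: np.ndarray) -> float:
    """Mean over the batch of per-spectrum weighted losses.

    ``predicted``/``target``/``weights`` are (B, N) arrays; ``weights`` rows
    come from :func:`loss_weights`.  Permutation-invariant over the batch.
    """
    if predicted.shape != target.shape or predicted.shape != weights.shape:
        raise ValueError("batch arrays must share shape (B, N)")
    e = predicted - target
    return float(np.mean(np.sum(weights * e * e, axis=1)))
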