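"""Signal-to-noise metrics for denoiser evaluation.

Global SNR is the ratio of the reference spectrum's maximum intensity to the
RMSE between a spectrum and that reference.  Peak SNR restricts the RMSE to a
2n+1-sample window around the most prominent peak while keeping the *global*
maximum in the numerator, so the two numbers are directly comparable.  The
SNR product multiplies the global and peak SNR improvement ratios of a
denoised spectrum over its raw version: values above 1 mean the denoiser
helped on balance, values below 1 mean it hurt.

A zero RMSE (perfect reconstruction) yields ``math.inf`` rather than an
exception, except where noted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

from .spectra import PeakRegion, Spectrum

__all__ = [
    "rmse",
    "global_snr",
    "peak_snr",
    "snr_product",
    "SNRReport",
    "snr_report",
    "write_report_table",
]

ArrayLike = Union[Spectrum, np.ndarray, Sequence[float]]


def _values(x: ArrayLike) -> np.ndarray:
    if isinstance(x, Spectrum):
        return x.intensity
    return np.asarray(x, dtype=float)


def rmse(a: ArrayLike, b: ArrayLike) -> float:
    """Root mean square difference, sqrt(1/N Σ (a_i - b_i)²)."""
    av, bv = _values(a), _values(b)
    if av.shape != bv.shape:
        raise ValueError(f"length mismatch: {av.shape} vs {bv.shape}")
    d = av - bv
    return float(np.sqrt(np.mean(d * d)))


def global_snr(denoised: ArrayLike, reference: ArrayLike) -> float:
    """max(reference) / rmse(denoised, reference); inf when rmse is 0."""
    ref = _values(reference)
    peak = float(np.max(ref))
    if peak <= 0:
        raise ValueError("reference spectrum has no positive maximum")
    err = rmse(denoised, reference)
    return math.inf if err == 0.0 else peak / err


def peak_snr(denoised: ArrayLike, reference: ArrayLike,
             region: PeakRegion) -> float:
    """SNR with the RMSE restricted to the peak window.

    The numerator stays the global maximum of the full reference so peak and
    global SNR share a scale.
    """
    dv, ref = _values(denoised), _values(reference)
    if dv.shape != ref.shape:
        raise ValueError(f"length mismatch: {dv.shape} vs {ref.shape}")
    region.validate_for(ref.size)
    peak = float(np.max(ref))
    if peak <= 0:
        raise ValueError("reference spectrum has no positive maximum")
    w = region.window
    err = rmse(dv[w], ref[w])
    return math.inf if err == 0.0 else peak / err


def snr_product(denoised: ArrayLike, raw: ArrayLike, reference: ArrayLike,
                region: PeakRegion) -> float:
    """Product of the global and peak SNR improvement ratios.

    ``snr_product == 1`` for the identity denoiser, > 1 for a net
    improvement, < 1 for net degradation.
    """
    g_raw = global_snr(raw, reference)
    p_raw = peak_snr(raw, reference, region)
    if math.isinf(g_raw) or math.isinf(p_raw):
        raise ValueError(
            "raw spectrum equals the reference (infinite raw SNR); the "
            "improvement ratio is undefined — pass an actually noisy raw "
            "spectrum")
    g_den = global_snr(denoised, reference)
    p_den = peak_snr(denoised, reference, region)
    if math.isinf(g_den) or math.isinf(p_den):
        return math.inf
    return (g_den / g_raw) * (p_den / p_raw)


@dataclass(frozen=True)
class SNRReport:
    """All SNR figures for one denoised spectrum."""

    global_snr_raw: float
    global_snr_denoised: float
    peak_snr_raw: float
    peak_snr_denoised: float
    snr_product: float
    peak_region: PeakRegion

    @property
    def global_improvement(self) -> float:
        return self.global_snr_denoised / self.global_snr_raw

    @property
    def peak_improvement(self) -> float:
        return self.peak_snr_denoised / self.peak_snr_raw


def snr_report(denoised: ArrayLike, raw: ArrayLike, reference: ArrayLike,
               region: PeakRegion) -> SNRReport:
    """Compute the full SNRReport for one (denoised, raw, reference) triple."""
    return SNRReport(
        global_snr_raw=global_snr(raw, reference),
        global_snr_denoised=global_snr(denoised, reference),
        peak_snr_raw=peak_snr(raw, reference, region),
        peak_snr_denoised=peak_snr(denoised, reference, region),
        snr_product=snr_product(denoised, raw, reference, region),
        peak_region=region,
    )


def write_report_table(reports: Iterable[SNRReport], path) -> pd.DataFrame:
    """Write per-spectrum SNR reports plus a mean summary row as TSV."""
    rows = []
    for i, r in enumerate(reports):
        rows.append({
            "spectrum": i,
            "pk": r.peak_region.center_index,
            "n": r.peak_region.half_width,
            "global_snr_raw": r.global_snr_raw,
            "global_snr_denoised": r.global_snr_denoised,
            "peak_snr_raw": r.peak_snr_raw,
            "peak_snr_denoised": r.peak_snr_denoised,
            "global_improvement": r.global_improvement,
            "peak_improvement": r.peak_improvement,
            "snr_product": r.snr_product,
        })
    df = pd.DataFrame(rows)
    summary = df.drop(columns=["spectrum", "pk", "n"]).mean(numeric_only=True)
    summary["spectrum"] = "mean"
    table = pd.concat([df, summary.to_frame().T], ignore_index=True)
    table.to_csv(path, sep="\t", index=False)
    return table
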