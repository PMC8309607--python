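"""Readers and writers for spectra and simulated datasets.

Interchange formats are plain delimited text:

* single spectrum — two columns (wavenumber, intensity), optional header;
* dataset — one matrix per split (row = spectrum) for the clean and noisy
  sets, plus a sidecar annotation table (spectrum id, peak index pk, window
  half-width n, global SNR).
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Sequence, Union

import numpy as np
import pandas as pd

from .spectra import (
    PeakRegion,
    Spectrum,
    SpectrumPair,
    WavenumberAxis,
    default_axis,
)

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "write_dataset",
    "read_dataset",
]

PathLike = Union[str, Path]


def read_spectrum(path: PathLike, allow_descending: bool = False) -> Spectrum:
    """Parse a two-column (wavenumber, intensity) delimited text file.

    An optional single header line is skipped.  A descending axis is an
    error unless ``allow_descending`` is set, in which case both columns are
    reversed.
    """
    wavenumbers: List[float] = []
    intensities: List[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, "
                                 f"got {len(parts)}")
            try:
                w, y = float(parts[0]), float(parts[1])
            except ValueError:
                if not wavenumbers and lineno <= _first_data_line(path):
                    continue  # header line
                raise ValueError(
                    f"{path}:{lineno}: non-numeric row {line!r}") from None
            wavenumbers.append(w)
            intensities.append(y)
    if len(wavenumbers) < 2:
        raise ValueError(f"{path}: fewer than 2 data rows")
    w_arr = np.asarray(wavenumbers)
    y_arr = np.asarray(intensities)
    if w_arr[0] > w_arr[-1]:
        if not allow_descending:
            raise ValueError(
                f"{path}: wavenumber axis is descending; pass "
                f"allow_descending=True to reverse it")
        w_arr, y_arr = w_arr[::-1], y_arr[::-1]
    return Spectrum(WavenumberAxis(w_arr), y_arr)


def _first_data_line(path: PathLike) -> int:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if raw.strip() and not raw.strip().startswith("#"):
                return lineno
    return 0


def write_spectrum(spectrum: Spectrum, path: PathLike) -> None:
    """Write a spectrum as two tab-separated columns with a header."""
    pd.DataFrame({
        "wavenumber": spectrum.axis.values,
        "intensity": spectrum.intensity,
    }).to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_dataset(pairs: Sequence[SpectrumPair], out_dir: PathLike,
                  prefix: str = "dataset") -> dict:
    """Write clean/noisy matrices plus the annotation sidecar; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    clean = np.stack([p.reference.intensity for p in pairs])
    noisy = np.stack([p.noisy.intensity for p in pairs])
    ann = pd.DataFrame({
        "id": np.arange(len(pairs)),
        "pk": [p.peak_region.center_index for p in pairs],
        "n": [p.peak_region.half_width for p in pairs],
        "snr": [p.snr for p in pairs],
    })
    paths = {
        "clean": out / f"{prefix}_clean.tsv",
        "noisy": out / f"{prefix}_noisy.tsv",
        "annotations": out / f"{prefix}_annotations.tsv",
    }
    np.savetxt(paths["clean"], clean, delimiter="\t", fmt="%.10g")
    np.savetxt(paths["noisy"], noisy, delimiter="\t", fmt="%.10g")
    ann.to_csv(paths["annotations"], sep="\t", index=False)
    return paths


def read_dataset(path_clean: PathLike, path_noisy: PathLike,
                 path_annotations: PathLike) -> List[SpectrumPair]:
    """Load a dataset written by :func:`write_dataset`, with validation."""
    clean = np.atleast_2d(np.loadtxt(path_clean, delimiter="\t"))
    noisy = np.atleast_2d(np.loadtxt(path_noisy, delimiter="\t"))
    if clean.shape != noisy.shape:
        raise ValueError(
            f"clean matrix {clean.shape} and noisy matrix {noisy.shape} differ")
    ann = pd.read_csv(path_annotations, sep="\t")
    missing = {"id", "pk", "n", "snr"} - set(ann.columns)
    if missing:
        raise ValueError(f"annotation table lacks columns: {sorted(missing)}")
    if len(ann) != clean.shape[0]:
        raise ValueError(
            f"annotation table has {len(ann)} rows for {clean.shape[0]} spectra")
    n_samples = clean.shape[1]
    axis = default_axis(n_samples)
    pairs = []
    for i, row in ann.iterrows():
        pk, n = int(row["pk"]), int(row["n"])
        if not (0 <= pk - n and pk + n <= n_samples - 1):
            raise ValueError(
                f"annotation row {i}: window pk={pk}, n={n} outside spectrum "
                f"of length {n_samples}")
        pairs.append(SpectrumPair(
            reference=Spectrum(axis, clean[i]),
            noisy=Spectrum(axis, noisy[i]),
            peak_region=PeakRegion(center_index=pk, half_width=n),
            snr=float(row["snr"]),
        ))
    return pairs
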