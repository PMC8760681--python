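"""Welch spectra, band-power AUC, and spectrograms.

Spectral analysis runs on raw-rate data.  Welch periodograms are 10x the
sampling rate long (0.1-Hz resolution), Hann-windowed with 50% overlap, and
mean-detrended per segment (the acquisition chain is AC-coupled, so DC
carries no signal).  Band power is the area under the one-sided PSD within
the canonical hippocampal bands: delta [1, 4), theta [4, 12), beta
[12, 30), gamma [30, 120) Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .io_core import SessionLayout, ValidationError
from .preprocess import MaskedSignal, segment_session

__all__ = [
    "BANDS",
    "PSDResult",
    "BandPowerTable",
    "SpectrogramResult",
    "welch_psd",
    "band_auc",
    "band_power_table",
    "spectrogram",
    "hourly_band_power",
]

BANDS = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 120.0),
}


@dataclass
class PSDResult:
    """One-sided Welch PSD: integral of ``density`` over Hz ~= variance."""

    frequencies: np.ndarray
    density: np.ndarray          # mV^2/Hz
    fs: float
    nperseg: int
    n_segments: int = 1

    def __post_init__(self) -> None:
        if np.any(self.density < 0):
            raise ValidationError("PSD density must be non-negative")

    @property
    def df(self) -> float:
        return self.fs / self.nperseg


def welch_psd(x: np.ndarray, fs: float, periodogram_length: int | None = None,
              overlap: float = 0.5) -> PSDResult:
    """Welch PSD with periodogram length 10x the sampling rate by default."""
    x = np.asarray(x, dtype=float)
    nperseg = int(periodogram_length if periodogram_length is not None
                  else round(10 * fs))
    if x.size < nperseg:
        raise ValidationError(
            f"signal of {x.size} samples shorter than one periodogram ({nperseg})"
        )
    noverlap = int(round(nperseg * overlap))
    f, p = sps.welch(x, fs=fs, window="hann", nperseg=nperseg,
                     noverlap=noverlap, detrend="constant")
    n_seg = 1 + (x.size - nperseg) // (nperseg - noverlap)
    return PSDResult(frequencies=f, density=p, fs=fs, nperseg=nperseg,
                     n_segments=n_seg)


def band_auc(psd: PSDResult, band: tuple) -> float:
    """Trapezoidal area under the PSD over ``band`` = (f_lo, f_hi).

    Both edges are included as integration endpoints, so AUCs over adjacent
    bands sharing an edge add up exactly to the AUC of their union.
    """
    lo, hi = band
    if hi <= lo:
        raise ValidationError(f"inverted band ({lo}, {hi})")
    f = psd.frequencies
    if lo < f[0] - 1e-9 or hi > f[-1] + 1e-9:
        raise ValidationError(f"band ({lo}, {hi}) outside PSD grid")
    sel = (f >= lo - 1e-9) & (f <= hi + 1e-9)
    return float(np.trapezoid(psd.density[sel], f[sel]))


def band_power_table(psd: PSDResult, bands: dict | None = None) -> dict:
    """AUC power (mV^2) per named band."""
    return {name: band_auc(psd, b) for name, b in (bands or BANDS).items()}


@dataclass
class SpectrogramResult:
    times: np.ndarray
    frequencies: np.ndarray
    power: np.ndarray            # shape (n_freq, n_time)

    def __post_init__(self) -> None:
        if np.any(self.power < 0):
            raise ValidationError("spectrogram power must be non-negative")


def spectrogram(x: np.ndarray, fs: float) -> SpectrogramResult:
    """Hann-windowed, heavily zero-padded spectrogram.

    Segment length 0.5x fs samples, overlap 0.25x fs samples (so the time
    step is 0.25 s), FFT length 10x fs (zero-padded for a dense frequency
    grid).
    """
    x = np.asarray(x, dtype=float)
    nperseg = int(round(0.5 * fs))
    noverlap = int(round(0.25 * fs))
    nfft = int(round(10 * fs))
    if x.size < nperseg:
        raise ValidationError("signal shorter than one spectrogram segment")
    f, t, p = sps.spectrogram(x, fs=fs, window="hann", nperseg=nperseg,
                              noverlap=noverlap, nfft=nfft,
                              detrend="constant", mode="psd")
    return SpectrogramResult(times=t, frequencies=f, power=p)


@dataclass
class BandPowerTable:
    """Per-hour band AUC power with hour-1-referenced deltas."""

    hours: dict                  # {hour: {band: AUC}}
    deltas: dict                 # {hour: {band: AUC - AUC(hour 1)}}
    stim: bool = False


def _masked_welch(sig: MaskedSignal, nperseg: int) -> PSDResult:
    """Welch PSD of a masked trace via duration-weighted averaging over the
    contiguous unmasked runs long enough to hold one periodogram."""
    runs = _unmasked_runs(sig.mask)
    acc, wsum, f = None, 0.0, None
    n_segs = 0
    for i0, i1 in runs:
        if i1 - i0 < nperseg:
            continue
        psd = welch_psd(sig.samples[i0:i1], sig.fs, periodogram_length=nperseg)
        w = i1 - i0
        acc = psd.density * w if acc is None else acc + psd.density * w
        wsum += w
        f = psd.frequencies
        n_segs += psd.n_segments
    if acc is None:
        raise ValidationError(
            "no contiguous unmasked run holds a whole periodogram"
        )
    return PSDResult(frequencies=f, density=acc / wsum, fs=sig.fs,
                     nperseg=nperseg, n_segments=n_segs)


def _unmasked_runs(mask: np.ndarray) -> list:
    """Half-open index runs of consecutive included samples."""
    inc = np.r_[0, (~mask).astype(np.int8), 0]
    idx = np.flatnonzero(np.diff(inc))
    return [(idx[i], idx[i + 1]) for i in range(0, len(idx), 2)]


def hourly_band_power(sig: MaskedSignal, layout: SessionLayout,
                      stim: bool = False, bands: dict | None = None,
                      periodogram_length: int | None = None) -> BandPowerTable:
    """Band AUC per analysis hour (stim: 50-min light window for hour 2),
    with changes referenced to hour 1."""
    bands = bands or BANDS
    nperseg = int(periodogram_length if periodogram_length is not None
                  else round(10 * sig.fs))
    seg = segment_session(sig, layout, stim=stim)
    hours = {}
    for i, s in seg["analysis_hours"].items():
        psd = _masked_welch(s, nperseg)
        hours[i] = band_power_table(psd, bands)
    deltas = {
        i: {b: (0.0 if i == 1 else hours[i][b] - hours[1][b]) for b in bands}
        for i in hours
    }
    return BandPowerTable(hours=hours, deltas=deltas, stim=stim)
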