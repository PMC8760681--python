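"""Downsampling, exclusion masking, and session segmentation.

Feature extraction runs on 500-Hz data; generalized-seizure periods are
excluded by a per-sample boolean mask (excluded samples are dropped from
sums and the effective duration shrinks accordingly — they are never
zero-filled, which would deflate magnitude features at the boundaries).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .io_core import Recording, SessionLayout, ValidationError

__all__ = ["MaskedSignal", "downsample", "build_mask", "segment_session"]


@dataclass
class MaskedSignal:
    """A single-channel trace with a per-sample exclusion mask.

    ``mask`` is True where a sample is EXCLUDED from analysis.
    """

    samples: np.ndarray
    fs: float
    mask: np.ndarray = None
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.mask is None:
            self.mask = np.zeros(self.samples.size, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.samples.shape:
            raise ValidationError("mask length != sample length")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def masked_fraction(self) -> float:
        return float(self.mask.mean()) if self.mask.size else 0.0

    def slice_seconds(self, t0: float, t1: float) -> "MaskedSignal":
        """Sub-signal over the half-open time interval ``[t0, t1)``."""
        i0 = int(np.ceil(t0 * self.fs - 1e-9))
        i1 = int(np.ceil(t1 * self.fs - 1e-9))
        i0, i1 = max(i0, 0), min(i1, self.samples.size)
        return MaskedSignal(self.samples[i0:i1], self.fs, self.mask[i0:i1],
                            self.provenance + [f"slice[{t0},{t1})"])


def _decimation_fir(q: int) -> np.ndarray:
    """Linear-phase anti-alias FIR for decimation by ``q``.

    Cutoff 0.4x the output rate; 20*q+1 taps keep the transition width a
    fixed fraction of the output bandwidth regardless of q, with stopband
    attenuation well past 20 dB at the output Nyquist.
    """
    numtaps = 20 * q + 1
    return sps.firwin(numtaps, 0.8 / q)  # 0.8 of output Nyquist = 0.4*fs_out


def downsample(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Anti-alias low-pass then decimate; requires an integer factor."""
    ratio = fs_in / fs_out
    q = int(round(ratio))
    if abs(ratio - q) > 1e-9 or q < 1:
        raise ValidationError(
            f"downsampling {fs_in} -> {fs_out} Hz is not an integer factor"
        )
    x = np.asarray(x, dtype=float)
    if q == 1:
        return x.copy()
    h = _decimation_fir(q)
    # polyphase implementation computes only the kept samples; the filter is
    # linear-phase and resample_poly compensates its delay (zero-phase net)
    # 'line' edge padding keeps constant/slowly-varying edges unbiased
    return sps.resample_poly(x, up=1, down=q, window=h, padtype="line")


def interval_mask(intervals: np.ndarray, fs: float, n_samples: int) -> np.ndarray:
    """Boolean exclusion mask for a union of [onset, end) intervals.

    Overlapping intervals are OR-ed, so no sample is counted twice.
    """
    mask = np.zeros(n_samples, dtype=bool)
    for onset, end in np.atleast_2d(np.asarray(intervals, dtype=float).reshape(-1, 2)):
        i0 = int(np.ceil(onset * fs - 1e-9))
        i1 = int(np.ceil(end * fs - 1e-9))
        mask[max(i0, 0):min(i1, n_samples)] = True
    return mask


def build_mask(recording: Recording, labels=("GS",), channel: str | None = None,
               fs_out: float | None = None, warn=None) -> MaskedSignal:
    """Per-sample exclusion mask from annotated intervals with ``labels``.

    Operates on one channel (default: the first); if ``fs_out`` is given the
    channel is first decimated and the mask built on the output grid.
    Unknown labels contribute nothing (optionally reported via ``warn``).
    """
    if isinstance(labels, str):
        labels = (labels,)
    data = recording.channel(channel) if channel else recording.data[0]
    fs = recording.fs
    prov = []
    if fs_out is not None and fs_out != fs:
        data = downsample(data, fs, fs_out)
        prov.append(f"downsample({fs}->{fs_out})")
        fs = fs_out
    known = recording.annotations.labels()
    intervals = []
    for lbl in labels:
        if lbl not in known:
            if warn is not None:
                warn(f"no annotations labelled {lbl!r}")
            continue
        intervals.extend(recording.annotations.intervals(lbl).tolist())
    mask = interval_mask(np.asarray(intervals).reshape(-1, 2), fs, data.size)
    prov.append(f"mask{sorted(labels)}")
    return MaskedSignal(np.asarray(data, dtype=float), fs, mask, prov)


def segment_session(sig: MaskedSignal, layout: SessionLayout,
                    stim: bool = False) -> dict:
    """Named half-open segments of a session.

    Returns ``{"hour1": ..., "hour2": ..., "hour3": ..., "pre": ...,
    "light_analysis": ..., "post": ...}``.  For stimulation sessions the
    analysed part of the light-ON hour is its first 50 min (fade-off tail
    dropped); ``hour2`` always refers to the full clock hour.
    """
    if sig.duration + 0.5 / sig.fs < layout.total_s:
        missing = [f"hour{i}" for i in range(1, layout.n_hours + 1)
                   if layout.hour(i)[1] > sig.duration + 0.5 / sig.fs]
        raise ValidationError(
            f"recording of {sig.duration:.1f} s shorter than layout "
            f"({layout.total_s:.1f} s); missing segments: {missing}"
        )
    seg = {}
    for i in range(1, layout.n_hours + 1):
        seg[f"hour{i}"] = sig.slice_seconds(*layout.hour(i))
    seg["pre"] = sig.slice_seconds(*layout.pre)
    seg["light_analysis"] = sig.slice_seconds(*layout.light_analysis)
    seg["post"] = sig.slice_seconds(*layout.post)
    seg["analysis_hours"] = {
        1: seg["hour1"],
        2: seg["light_analysis"] if stim else seg["hour2"],
        3: seg["hour3"],
    }
    return seg
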