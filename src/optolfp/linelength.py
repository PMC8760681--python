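"""Line-length quantification of LFP magnitude.

The line length of a trace x over a window is

    L = sum_k |x(k-1) - x(k)| / t        [mV/s]

with t the included duration in seconds.  It grows with both amplitude and
frequency, which makes it a robust single-number summary of LFP magnitude.
Computed on 500-Hz downsampled data.  Excluded (masked) samples contribute
neither differences nor duration; differences bridging a masked gap are not
counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_core import SessionLayout, ValidationError
from .preprocess import MaskedSignal, segment_session

__all__ = [
    "FullyMaskedError",
    "line_length",
    "hourly_line_length",
    "pulse_triggered",
    "LineLengthSummary",
    "PulseResponse",
]


class FullyMaskedError(ValueError):
    """The requested window has fewer than two included samples."""


def line_length(sig: MaskedSignal, window: tuple | None = None) -> float:
    """Line length (mV/s) of ``sig`` over ``window`` = [t0, t1) seconds.

    Raises :class:`FullyMaskedError` when fewer than two samples remain —
    an undefined result is signalled distinctly, never reported as zero.
    """
    if window is not None:
        sig = sig.slice_seconds(*window)
    included = ~sig.mask
    n_inc = int(included.sum())
    if n_inc < 2:
        raise FullyMaskedError("window has fewer than 2 included samples")
    pair_ok = included[:-1] & included[1:]
    diffs = np.abs(np.diff(sig.samples))
    total = float(diffs[pair_ok].sum())
    t = n_inc / sig.fs
    return total / t


@dataclass
class LineLengthSummary:
    """Per-hour line length with hour-1-referenced deltas.

    ``hours[i]`` is L (mV/s) of analysis hour i (for stimulation sessions
    hour 2 is the 50-min light-analysis window); ``deltas[i]`` subtracts
    hour 1, so ``deltas[1] == 0`` identically.
    """

    hours: dict
    deltas: dict
    masked_fraction: dict
    stim: bool = False


def hourly_line_length(sig: MaskedSignal, layout: SessionLayout,
                       stim: bool = False) -> LineLengthSummary:
    """Hour-wise line length; baseline (hour 1) subtracted."""
    seg = segment_session(sig, layout, stim=stim)
    hours, frac = {}, {}
    for i, s in seg["analysis_hours"].items():
        hours[i] = line_length(s)
        frac[i] = s.masked_fraction
    deltas = {i: (0.0 if i == 1 else hours[i] - hours[1]) for i in hours}
    return LineLengthSummary(hours=hours, deltas=deltas, masked_fraction=frac,
                             stim=stim)


@dataclass
class PulseResponse:
    """Pulse-triggered 2-s line lengths and their session means.

    For each usable pulse p: ``before`` is L over [p-w, p), ``after`` is L
    over [p+pulse_width, p+pulse_width+w), and ``pre`` is L over the same
    clock offset shifted one hour back into the pre-recording.  Pulses whose
    windows touch excluded samples or fall outside the recording are dropped
    from all three series, keeping them aligned.
    """

    pulse_times: np.ndarray
    before: np.ndarray
    after: np.ndarray
    pre: np.ndarray
    window: float = 2.0
    n_dropped: int = 0

    def __post_init__(self) -> None:
        n = len(self.pulse_times)
        if not (len(self.before) == len(self.after) == len(self.pre) == n):
            raise ValidationError("pulse-response series lengths differ")

    @property
    def mean_before(self) -> float:
        return float(np.mean(self.before))

    @property
    def mean_after(self) -> float:
        return float(np.mean(self.after))

    @property
    def mean_pre(self) -> float:
        return float(np.mean(self.pre))

    def means(self) -> dict:
        return {"pre": self.mean_pre, "before": self.mean_before,
                "after": self.mean_after}


def pulse_triggered(sig: MaskedSignal, pulses: np.ndarray,
                    layout: SessionLayout, window: float = 2.0,
                    pulse_width: float = 0.010) -> PulseResponse:
    """Before/after/matched-pre line lengths around each light pulse.

    Only pulses inside the light-analysis window (fade-off tail excluded)
    are used.  The after-window starts at the pulse OFFSET (p + pulse
    width), so the illumination artifact itself is never included.
    """
    t0, t1 = layout.light_analysis
    pulses = np.asarray(pulses, dtype=float)
    pulses = pulses[(pulses >= t0) & (pulses < t1)]
    if pulses.size == 0:
        raise ValidationError("no pulses inside the light-analysis window")

    kept, before, after, pre = [], [], [], []
    dropped = 0
    for p in pulses:
        q = p - layout.hour_s  # matched clock offset in the pre-recording
        wins = [(p - window, p), (p + pulse_width, p + pulse_width + window),
                (q - window, q)]
        vals = []
        ok = True
        for a, b in wins:
            if a < 0 or b > sig.duration:
                ok = False
                break
            sub = sig.slice_seconds(a, b)
            if sub.mask.any() or sub.samples.size < 2:
                ok = False
                break
            vals.append(line_length(sub))
        if not ok:
            dropped += 1
            continue
        kept.append(p)
        before.append(vals[0])
        after.append(vals[1])
        pre.append(vals[2])
    if not kept:
        raise ValidationError("zero usable pulses after exclusions")
    return PulseResponse(np.asarray(kept), np.asarray(before),
                         np.asarray(after), np.asarray(pre),
                         window=window, n_dropped=dropped)
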