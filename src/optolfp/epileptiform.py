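"""Deterministic spike/burst detection and the burst-ratio metric.

Interictal epileptiform activity in the kainate model appears as single
sharp-wave spikes and as bursts (clusters of many spikes).  This module is
a transparent threshold pipeline: band-pass 5-80 Hz, detect suprathreshold
extrema against a robust (MAD-based) noise estimate, group spikes into
bursts by inter-spike gap, classify bursts by spike load, and report the
burst ratio — the fraction of recording time spent in high-load bursts.
The spike-load thresholds are configurable stand-ins documented here, not
the values of any published classifier.  Sessions containing a generalized
seizure are dropped from burst statistics entirely (the long postictal
suppression distorts them).

Everything here is deterministic: identical input gives identical events.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .io_core import EventList, ValidationError
from .preprocess import MaskedSignal

__all__ = [
    "SpikeEvent",
    "Burst",
    "BurstSummary",
    "detect_spikes",
    "group_bursts",
    "classify_load",
    "classify_spike_load",
    "burst_ratio",
    "detect_generalized_seizures",
    "LOAD_THRESHOLDS",
]

#: spike-load classification thresholds (intra-burst rate in Hz; duration s)
LOAD_THRESHOLDS = {
    "high_rate": 1.0,
    "high_duration": 10.0,
    "medium_rate": 0.5,
}

SPIKE_BAND = (5.0, 80.0)


@dataclass(frozen=True)
class SpikeEvent:
    time: float          # s
    amplitude: float = 0.0   # mV, band-passed peak value (signed)
    channel: str = ""


@dataclass
class Burst:
    onset: float
    offset: float
    spike_times: np.ndarray
    load_class: str = ""

    def __post_init__(self):
        if self.offset <= self.onset:
            raise ValidationError("burst offset must exceed onset")

    @property
    def duration(self) -> float:
        return self.offset - self.onset

    @property
    def n_spikes(self) -> int:
        return len(self.spike_times)

    @property
    def spike_rate(self) -> float:
        return self.n_spikes / self.duration


@dataclass
class BurstSummary:
    """Per-channel, per-session burst statistics.

    ``ratio`` is the high-load burst time over the session duration, in
    [0, 1]; it is None when the session was dropped because a generalized
    seizure occurred in it.
    """

    ratio: float | None
    counts: dict = field(default_factory=dict)
    dropped_gs: bool = False
    channel: str = ""


def detect_spikes(sig: MaskedSignal, threshold_sd: float = 5.0,
                  refractory: float = 0.080, channel: str = "") -> list:
    """Sharp-wave spikes as suprathreshold extrema of the 5-80 Hz band.

    The threshold is ``threshold_sd`` times the robust SD (1.4826 x median
    absolute deviation) of the band-passed trace; at most one event per
    refractory window.  Masked samples never produce events.
    """
    x = np.asarray(sig.samples, dtype=float)
    if not (~sig.mask).any():
        return []
    sos = sps.butter(4, SPIKE_BAND, btype="bandpass", fs=sig.fs, output="sos")
    xf = sps.sosfiltfilt(sos, x)
    mad = np.median(np.abs(xf[~sig.mask] - np.median(xf[~sig.mask])))
    sd = 1.4826 * float(mad)
    if sd == 0:
        raise ValidationError("flat signal: robust SD is zero")
    thr = threshold_sd * sd
    dist = max(int(round(refractory * sig.fs)), 1)
    peaks, _ = sps.find_peaks(np.abs(xf), height=thr, distance=dist)
    peaks = peaks[~sig.mask[peaks]]
    return [SpikeEvent(time=p / sig.fs, amplitude=float(xf[p]), channel=channel)
            for p in peaks]


def group_bursts(spikes: list, max_gap: float = 2.0, min_spikes: int = 5,
                 pad: float = 0.020) -> list:
    """Maximal runs of spikes with consecutive gaps <= ``max_gap`` and at
    least ``min_spikes`` members; onset/offset are the first/last spike time
    padded by half the sharp-wave kernel width."""
    times = np.asarray([s.time for s in spikes], dtype=float)
    if np.any(np.diff(times) < 0):
        raise ValidationError("spikes must be sorted by time")
    bursts = []
    i = 0
    while i < len(times):
        j = i
        while j + 1 < len(times) and times[j + 1] - times[j] <= max_gap:
            j += 1
        if j - i + 1 >= min_spikes:
            b = Burst(onset=float(times[i] - pad), offset=float(times[j] + pad),
                      spike_times=times[i:j + 1])
            b.load_class = classify_load(b)
            bursts.append(b)
        i = j + 1
    return bursts


def classify_spike_load(n_spikes: int, duration: float,
                        thresholds: dict | None = None) -> str:
    """Load class from spike count and duration (rate r = n/duration):
    high if r >= 1 Hz and duration >= 10 s; medium if r >= 0.5 Hz; else low.
    """
    th = {**LOAD_THRESHOLDS, **(thresholds or {})}
    if duration <= 0:
        raise ValidationError("zero-duration burst cannot be classified")
    r = n_spikes / duration
    if r >= th["high_rate"] and duration >= th["high_duration"]:
        return "high"
    if r >= th["medium_rate"]:
        return "medium"
    return "low"


def classify_load(burst: Burst, thresholds: dict | None = None) -> str:
    return classify_spike_load(burst.n_spikes, burst.duration, thresholds)


def burst_ratio(bursts: list, session_duration: float,
                gs_annotations: EventList | None = None,
                channel: str = "") -> BurstSummary:
    """High-load burst time over total recording time.

    Any generalized seizure in the session flags it as dropped; the ratio
    is then reported as missing, never as zero.
    """
    if session_duration <= 0:
        raise ValidationError("session duration must be > 0")
    counts = {"low": 0, "medium": 0, "high": 0}
    high_time = 0.0
    for b in bursts:
        cls = b.load_class or classify_load(b)
        counts[cls] += 1
        if cls == "high":
            high_time += b.duration
    dropped = bool(gs_annotations is not None
                   and len(gs_annotations.intervals("GS")))
    ratio = None if dropped else min(high_time / session_duration, 1.0)
    return BurstSummary(ratio=ratio, counts=counts, dropped_gs=dropped,
                        channel=channel)


def detect_generalized_seizures(data: np.ndarray, fs: float,
                                threshold_sd: float = 4.0,
                                min_duration: float = 10.0,
                                depression_duration: float = 30.0,
                                depression_ratio: float = 0.5) -> EventList:
    """Conservative cross-channel generalized-seizure auto-detector.

    A candidate is a period where BOTH channels simultaneously carry
    rhythmic 3-8 Hz activity above ``threshold_sd`` robust SDs for at
    least ``min_duration`` seconds, followed by at least
    ``depression_duration`` seconds in which broadband RMS falls below
    ``depression_ratio`` times the session baseline on both channels
    (postictal depression).  Intended as a QC aid: manual annotations
    remain authoritative for exclusion masking.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape[0] < 2:
        raise ValidationError("cross-channel detection needs two channels")
    n = data.shape[1]
    sos = sps.butter(4, (3.0, 8.0), btype="bandpass", fs=fs, output="sos")
    win = max(int(round(fs)), 1)          # 1-s envelope smoothing
    kernel = np.ones(win) / win
    above = np.ones(n, dtype=bool)
    baseline_rms = []
    for c in range(data.shape[0]):
        band = sps.sosfiltfilt(sos, data[c])
        env = np.sqrt(np.convolve(band ** 2, kernel, mode="same"))
        sd = 1.4826 * np.median(np.abs(band - np.median(band)))
        above &= env > threshold_sd * sd
        baseline_rms.append(np.sqrt(np.median(data[c] ** 2)))

    events = EventList()
    idx = np.flatnonzero(np.diff(np.r_[0, above.view(np.int8), 0]))
    runs = [(idx[k], idx[k + 1]) for k in range(0, len(idx), 2)]
    # rhythmic discharges dip below threshold briefly; close gaps < 2 s
    merged = []
    max_gap = int(round(2.0 * fs))
    for i0, i1 in runs:
        if merged and i0 - merged[-1][1] < max_gap:
            merged[-1] = (merged[-1][0], i1)
        else:
            merged.append((i0, i1))
    n_dep = int(round(depression_duration * fs))
    guard = int(round(2.0 * fs))  # envelope smoothing blurs the offset
    for i0, i1 in merged:
        if (i1 - i0) / fs < min_duration:
            continue
        j0, j1 = i1 + guard, i1 + guard + n_dep
        if j1 > n:
            continue
        depressed = all(
            np.sqrt(np.mean(data[c, j0:j1] ** 2))
            < depression_ratio * baseline_rms[c]
            for c in range(data.shape[0]))
        if depressed:
            events = events.with_event("GS", i0 / fs, (i1 - i0) / fs)
    return events
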