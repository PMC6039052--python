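"""Automated sleep-spindle detection on single- or multi-channel series.

The detector mirrors the standard analytic-signal procedure used on human
EEG/MEG: band-pass the signal to the spindle band, take the modulus of the
Hilbert transform, smooth the envelope with a Gaussian kernel (300 ms
support, 40 ms sigma), mark regions exceeding mean + 2 SD of the smoothed
envelope, expand them down to mean + 1 SD, and keep events within duration
gates.  Thresholds are expressed in SD units, so detection is invariant to
amplitude rescaling of the input.

Two parameter presets are provided: ``empirical`` (10-16 Hz band, 0.5-2 s
gate, as applied to human recordings) and ``model`` (6-15 Hz band, 0.5-3 s
gate, for simulated LFP whose spindles can run longer).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .lfp import bandpass

__all__ = ["DetectorParams", "SpindleEvent", "detect_spindles", "interspindle_intervals"]


@dataclass(frozen=True)
class DetectorParams:
    """Detection parameters; thresholds are in SD units of the smoothed envelope."""

    band: tuple[float, float] = (6.0, 15.0)
    smooth_width: float = 0.3    # Gaussian kernel half-support (s)
    smooth_sigma: float = 0.04   # Gaussian kernel sigma (s)
    onset_threshold: float = 2.0  # SD above mean required inside an event
    expand_threshold: float = 1.0  # SD above mean defining event extent
    min_dur: float = 0.5         # s
    max_dur: float = 3.0         # s
    merge_gap: float = 0.1       # events closer than this are merged (s); 0 disables
    isi_exclusion: float = 20.0  # s

    def __post_init__(self):
        if self.min_dur >= self.max_dur:
            raise ValueError("min_dur must be below max_dur")
        if self.expand_threshold >= self.onset_threshold:
            raise ValueError("expand_threshold must be below onset_threshold")

    @classmethod
    def model(cls) -> "DetectorParams":
        """Preset for simulated LFP (6-15 Hz, up to 3 s)."""
        return cls()

    @classmethod
    def empirical(cls) -> "DetectorParams":
        """Preset matching the human EEG/MEG pipeline (10-16 Hz, up to 2 s,
        no event merging)."""
        return cls(band=(10.0, 16.0), max_dur=2.0, merge_gap=0.0)

    def with_(self, **kw) -> "DetectorParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class SpindleEvent:
    """One detected spindle.  Times in seconds from the start of the series."""

    channel: int
    onset: float
    offset: float
    peak_freq: float = float("nan")

    @property
    def center(self) -> float:
        return 0.5 * (self.onset + self.offset)

    @property
    def duration(self) -> float:
        return self.offset - self.onset


def _gaussian_kernel(rate: float, width: float, sigma: float) -> np.ndarray:
    """Unit-sum Gaussian kernel truncated at +/- ``width`` seconds."""
    n = int(round(width * rate))
    x = np.arange(-n, n + 1) / rate
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()

def smoothed_envelope(series: np.ndarray, rate: float, params: DetectorParams) -> np.ndarray:
    """Gaussian-smoothed magnitude of the spindle-band analytic signal."""
    x = bandpass(series, rate, *params.band)
    env = np.abs(signal.hilbert(x, axis=0))
    kernel = _gaussian_kernel(rate, params.smooth_width, params.smooth_sigma)
    if env.ndim == 1:
        return np.convolve(env, kernel, mode="same")
    return np.apply_along_axis(lambda e: np.convolve(e, kernel, mode="same"), 0, env)


def _event_peak_freq(segment: np.ndarray, rate: float, band: tuple[float, float]) -> float:
    if len(segment) < 8:
        return float("nan")
    freqs, pxx = signal.periodogram(segment, fs=rate)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if not sel.any() or not np.any(pxx[sel] > 0):
        return float("nan")
    return float(freqs[sel][np.argmax(pxx[sel])])


def detect_spindles(
    series: np.ndarray,
    rate: float,
    params: DetectorParams | None = None,
    channel: int = 0,
) -> list[SpindleEvent]:
    """Detect spindles on one channel.

    Parameters
    ----------
    series:
        1-D signal (arbitrary units).  Must cover at least 10 s so the
        envelope mean/SD are stable.
    rate:
        Sampling rate in Hz; must exceed twice the upper band edge.
    params:
        Detection parameters (defaults to the model preset).
    channel:
        Channel id stamped on the returned events.

    Returns
    -------
    list of :class:`SpindleEvent`, ordered and disjoint.
    """
    if params is None:
        params = DetectorParams.model()
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise ValueError("detect_spindles expects a single channel; loop for matrices")
    if rate <= 2.0 * params.band[1]:
        raise ValueError(f"sampling rate {rate} Hz too low for band {params.band}")
    if len(series) < 10.0 * rate:
        raise ValueError("series must cover at least 10 s")

    env = smoothed_envelope(series, rate, params)
    mu, sd = env.mean(), env.std()
    hi = env > mu + params.onset_threshold * sd
    lo = env > mu + params.expand_threshold * sd

    # contiguous runs above the expansion threshold
    edges = np.flatnonzero(np.diff(np.r_[0, lo.astype(np.int8), 0]))
    starts, ends = edges[::2], edges[1::2]

    # keep runs containing at least one sample above the onset threshold
    cum_hi = np.r_[0, np.cumsum(hi)]
    keep = cum_hi[ends] - cum_hi[starts] > 0
    starts, ends = starts[keep], ends[keep]

    # merge runs separated by less than merge_gap (guards against envelope
    # ripple splitting one spindle in two)
    if params.merge_gap > 0 and len(starts) > 1:
        gap = (starts[1:] - ends[:-1]) / rate
        new_run = np.r_[True, gap >= params.merge_gap]
        run_id = np.cumsum(new_run) - 1
        starts = np.array([starts[run_id == i][0] for i in range(run_id[-1] + 1)])
        ends = np.array([ends[run_id == i][-1] for i in range(run_id[-1] + 1)])

    x_band = bandpass(series, rate, *params.band)
    events = []
    for s, e in zip(starts, ends):
        dur = (e - s) / rate
        if dur < params.min_dur or dur > params.max_dur:
            continue
        pf = _event_peak_freq(x_band[s:e], rate, params.band)
        events.append(SpindleEvent(channel, s / rate, e / rate, pf))
    return events


def interspindle_intervals(
    events: list[SpindleEvent], exclusion: float = 20.0
) -> np.ndarray:
    """Center-to-center intervals (s) between consecutive spindles.

    Intervals longer than ``exclusion`` seconds are dropped: such gaps are
    far more likely to reflect missed detections than true quiescence.
    Fewer than two events yield an empty array.
    """
    if len(events) < 2:
        return np.empty(0)
    centers = np.sort([ev.center for ev in events])
    isi = np.diff(centers)
    return isi[isi <= exclusion]
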