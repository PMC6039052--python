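"""Spindle ensemble statistics.

Everything downstream of detection lives here: per-channel spindle density,
inter-spindle-interval distribution fits (maximum-likelihood lognormal and
exponential, Lilliefors normality, two-sample Kolmogorov-Smirnov), spatial
correlation of band-passed LFP during spindle epochs, core/matrix
co-occurrence probabilities, onset-delay distributions, and spike-phase
histograms.

Phase convention: phases are the angle of the analytic signal of the
band-passed LFP, so the *peak* of the oscillation maps to phase 0 and the
trough to +-pi.  (Reports that describe spiking "at the peak" with phases
near +-pi use the trough-zero convention; add pi to convert.)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats as sps
from statsmodels.stats.diagnostic import lilliefors

from .detect import SpindleEvent, interspindle_intervals
from .lfp import bandpass

__all__ = [
    "CooccurrenceParams",
    "StatsReport",
    "spindle_density",
    "fit_isi_distributions",
    "ks_compare",
    "spatial_correlation",
    "cooccurrence_probability",
    "active_channel_counts",
    "onset_delays",
    "spike_phase_distribution",
    "merge_events",
    "isi_pooled",
]


@dataclass(frozen=True)
class CooccurrenceParams:
    """Rules for relating core and matrix event trains.

    ``window`` (s) only constrains onset-delay pairing; co-occurrence itself
    is plain temporal intersection of event spans.
    """

    window: float = 2.5
    merge_gap: float = 0.3   # s, gap below which same-layer channel events merge

    def __post_init__(self):
        if self.window <= 0:
            raise ValueError("window must be positive")


@dataclass
class StatsReport:
    """Bundle of spindle statistics for one simulation/condition."""

    density_per_channel: dict[str, np.ndarray]
    isi: dict[str, np.ndarray]
    isi_fits: dict[str, dict]
    durations: dict[str, np.ndarray]
    spatial_corr: dict[str, pd.DataFrame]
    cooccurrence: dict[str, float]
    delays: np.ndarray
    extra: dict = field(default_factory=dict)


def spindle_density(events: list[SpindleEvent], duration: float,
                    n_channels: int | None = None) -> np.ndarray:
    """Spindles per minute for each channel.

    ``duration`` is the analyzed time in seconds.  With ``n_channels`` unset,
    channels are inferred from the events (empty input gives an empty array).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    chans = sorted({e.channel for e in events})
    if n_channels is not None:
        chans = list(range(n_channels))
    counts = np.array([sum(e.channel == c for e in events) for c in chans], float)
    return counts / duration * 60.0


def fit_isi_distributions(intervals, min_n: int = 20) -> dict:
    """Maximum-likelihood fits and shape tests for inter-spindle intervals.

    Returns a dict with ``lognormal`` (mu, sigma of log-intervals),
    ``exponential`` (mean), and ``lilliefors`` (normality statistic and
    p-value of the raw intervals).  With fewer than ``min_n`` intervals the
    fits are skipped and ``ok`` is False.
    """
    x = np.asarray(intervals, dtype=float)
    x = x[np.isfinite(x) & (x > 0)]
    if len(x) < min_n:
        return {"ok": False, "n": int(len(x))}
    logx = np.log(x)
    mu, sigma = logx.mean(), logx.std(ddof=0)
    stat, pval = lilliefors(x, dist="norm", pvalmethod="table")
    return {
        "ok": True,
        "n": int(len(x)),
        "lognormal": {"mu": float(mu), "sigma": float(sigma)},
        "exponential": {"mean": float(x.mean())},
        "lilliefors": {"statistic": float(stat), "pvalue": float(pval)},
    }


def ks_compare(a, b) -> dict:
    """Two-sample Kolmogorov-Smirnov test between two samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        return {"statistic": float("nan"), "pvalue": float("nan")}
    res = sps.ks_2samp(a, b)
    return {"statistic": float(res.statistic), "pvalue": float(res.pvalue)}


def merge_events(events: list[SpindleEvent], gap: float = 0.3) -> list[tuple[float, float]]:
    """Collapse channel events into layer-level (onset, offset) spans.

    Events from any channel whose spans are separated by less than ``gap``
    seconds are merged; the result describes when the layer as a whole is
    spindling.
    """
    spans = sorted((e.onset, e.offset) for e in events)
    merged: list[list[float]] = []
    for a, b in spans:
        if merged and a - merged[-1][1] < gap:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def _epoch_mask(n: int, rate: float, spans) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for a, b in spans:
        mask[int(a * rate): int(b * rate) + 1] = True
    return mask


def spatial_correlation(
    lfp: np.ndarray,
    rate: float,
    events: list[SpindleEvent],
    band: tuple[float, float] = (6.0, 15.0),
) -> pd.DataFrame:
    """Pearson correlation of spindle-band LFP between channel pairs.

    ``lfp`` is (n_samples, n_channels).  The correlation is computed on the
    samples inside spindle epochs (the union of detected event spans over
    all channels) and averaged within each inter-channel distance.  Raises
    if there are no spindle epochs.
    """
    lfp = np.asarray(lfp, dtype=float)
    if lfp.ndim != 2 or lfp.shape[1] < 2:
        raise ValueError("need an (n_samples, n_channels>=2) LFP matrix")
    spans = merge_events(events, gap=0.0) if events else []
    mask = _epoch_mask(lfp.shape[0], rate, spans)
    if not mask.any():
        raise ValueError("no spindle epochs: spatial correlation undefined")
    xb = bandpass(lfp, rate, *band)[mask]
    n_ch = lfp.shape[1]
    rows = []
    for i in range(n_ch):
        for j in range(i + 1, n_ch):
            r = np.corrcoef(xb[:, i], xb[:, j])[0, 1]
            rows.append({"distance": j - i, "corr": r})
    df = pd.DataFrame(rows)
    return df.groupby("distance", as_index=False).agg(
        corr=("corr", "mean"), n_pairs=("corr", "size"))


def cooccurrence_probability(
    events_a: list[SpindleEvent],
    events_b: list[SpindleEvent],
    params: CooccurrenceParams | None = None,
) -> float:
    """P(system B is spindling | system A event).

    Fraction of A *channel* events whose span intersects at least one
    layer-level B event (B channel events merged across gaps).  Using the
    channel as the counting unit mirrors how per-channel co-occurrence is
    scored on multichannel recordings.  Returns NaN with no A events.
    """
    if params is None:
        params = CooccurrenceParams()
    b_spans = merge_events(events_b, params.merge_gap)
    if not events_a:
        return float("nan")
    hits = sum(
        1 for a in events_a
        if any(b[0] < a.offset and b[1] > a.onset for b in b_spans)
    )
    return hits / len(events_a)


def active_channel_counts(
    events_a: list[SpindleEvent],
    events_b: list[SpindleEvent],
    params: CooccurrenceParams | None = None,
) -> dict[str, float]:
    """Mean number of A channels active per A event, split by whether the
    event co-occurred with a B event."""
    if params is None:
        params = CooccurrenceParams()
    a_spans = merge_events(events_a, params.merge_gap)
    b_spans = merge_events(events_b, params.merge_gap)
    with_b, without_b = [], []
    for a in a_spans:
        chans = {
            e.channel for e in events_a if e.onset < a[1] and e.offset > a[0]
        }
        co = any(b[0] < a[1] and b[1] > a[0] for b in b_spans)
        (with_b if co else without_b).append(len(chans))
    return {
        "with_cooccurrence": float(np.mean(with_b)) if with_b else float("nan"),
        "without_cooccurrence": float(np.mean(without_b)) if without_b else float("nan"),
    }


def onset_delays(
    core_events: list[SpindleEvent],
    matrix_events: list[SpindleEvent],
    params: CooccurrenceParams | None = None,
) -> np.ndarray:
    """Onset delays (s) between co-occurring core and matrix spindles.

    Each core (layer-level) event is paired with the nearest-onset matrix
    event within the window; every matrix event is used at most once.
    Delay = core onset - matrix onset, so negative values mean the core
    led.
    """
    if params is None:
        params = CooccurrenceParams()
    core = [a for a, _ in merge_events(core_events, params.merge_gap)]
    matrix = [a for a, _ in merge_events(matrix_events, params.merge_gap)]
    used = np.zeros(len(matrix), dtype=bool)
    delays = []
    for c_on in core:
        best, best_j = None, -1
        for j, m_on in enumerate(matrix):
            if used[j]:
                continue
            d = c_on - m_on
            if abs(d) <= params.window and (best is None or abs(d) < abs(best)):
                best, best_j = d, j
        if best is not None:
            used[best_j] = True
            delays.append(best)
    return np.asarray(delays)


def spike_phase_distribution(
    spike_times: np.ndarray,
    lfp_channel: np.ndarray,
    rate: float,
    events: list[SpindleEvent],
    band: tuple[float, float] = (6.0, 15.0),
    n_bins: int = 100,
    min_spikes: int = 10,
) -> dict:
    """Normalized histogram of spindle phases at spike times.

    ``spike_times`` in seconds on the same clock as ``lfp_channel``.  Only
    spikes inside detected events count; with fewer than ``min_spikes``
    usable spikes the unit is flagged as excluded.  The histogram integrates
    to 1 over (-pi, pi]; phase 0 is the band-passed LFP peak.
    """
    x = bandpass(np.asarray(lfp_channel, dtype=float), rate, *band)
    phase = np.angle(signal.hilbert(x))
    t = np.asarray(spike_times, dtype=float)
    in_event = np.zeros(len(t), dtype=bool)
    for e in events:
        in_event |= (t >= e.onset) & (t <= e.offset)
    idx = np.clip((t[in_event] * rate).astype(int), 0, len(phase) - 1)
    phases = phase[idx]
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    if len(phases) < min_spikes:
        return {"ok": False, "n_spikes": int(len(phases)), "edges": edges}
    hist, _ = np.histogram(phases, bins=edges, density=True)
    return {
        "ok": True,
        "n_spikes": int(len(phases)),
        "edges": edges,
        "density": hist,
        "phases": phases,
        "mean_vector": complex(np.mean(np.exp(1j * phases))),
    }


def isi_pooled(per_channel_events: list[list[SpindleEvent]],
               exclusion: float = 20.0) -> np.ndarray:
    """Pool per-channel inter-spindle intervals into one sample."""
    out = [interspindle_intervals(ch, exclusion) for ch in per_channel_events]
    return np.concatenate(out) if out else np.empty(0)
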