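"""Configuration files, result serialization, and labeled burst fixtures.

The config format is YAML with three optional blocks (``network``,
``simulation``, ``detector``) whose keys mirror the corresponding
dataclasses; unknown keys are rejected with their location so typos fail
loudly.  Reports are JSON, versioned and stamped with a hash of the
generating configuration.

``generate_burst_series`` synthesizes multichannel test signals for the
detector and the statistics pipeline: 1/f-like background noise with
Tukey-tapered sinusoidal bursts (11-15 Hz, 0.5-3 s) whose ground truth
(onset, offset, frequency, amplitude) is returned alongside, so detector
sensitivity/precision and ISI-distribution recovery can be scored against
labels without running the network.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .detect import DetectorParams, SpindleEvent
from .network import NetworkSpec
from .simulator import SimConfig

__all__ = [
    "BurstGroundTruth",
    "generate_burst_series",
    "read_config",
    "write_config",
    "config_hash",
    "write_report",
    "read_report",
    "write_events_csv",
    "read_events_csv",
]

REPORT_VERSION = 1


@dataclass(frozen=True, order=True)
class BurstGroundTruth:
    """Label for one synthetic spindle-band burst."""

    channel: int
    onset: float       # s
    offset: float      # s
    freq: float        # Hz
    amplitude: float   # peak amplitude in SD units of the background

    @property
    def duration(self) -> float:
        return self.offset - self.onset


def _tukey(n: int, alpha: float) -> np.ndarray:
    from scipy.signal import windows

    return windows.tukey(n, alpha)


def _pink_noise(n: int, rate: float, rng: np.random.Generator,
                exponent: float = 1.0) -> np.ndarray:
    """1/f^exponent-amplitude-shaped Gaussian noise, unit standard deviation."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / rate)
    scale = np.ones_like(f)
    nz = f > 0
    scale[nz] = f[nz] ** (-exponent / 2.0)
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n=n)
    return x / x.std()


def generate_burst_series(
    n_channels: int,
    duration: float,
    rate: float = 200.0,
    gap_dist: str = "exp",
    gap_mean: float = 8.0,
    gap_sigma: float = 0.6,
    amplitude: float = 5.0,
    freq_range: tuple[float, float] = (11.0, 15.0),
    dur_range: tuple[float, float] = (0.5, 3.0),
    seed: int = 0,
) -> tuple[np.ndarray, list[BurstGroundTruth]]:
    """Labeled multichannel series of spindle-like bursts in 1/f noise.

    Burst onsets recur after gaps drawn from an exponential (``gap_dist=
    "exp"``, mean ``gap_mean`` s) or lognormal (``"lognorm"``, median
    ``gap_mean``, log-sd ``gap_sigma``) process; bursts are Tukey-tapered
    sinusoids with frequency ~ U(freq_range) and duration ~ U(dur_range),
    peak amplitude ``amplitude`` times the background SD.  Bursts never
    overlap within a channel.  Returns (series, labels) with series of
    shape (n_samples, n_channels).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if gap_dist not in ("exp", "lognorm"):
        raise ValueError(f"unknown gap distribution {gap_dist!r}")
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    series = np.empty((n, n_channels))
    labels: list[BurstGroundTruth] = []
    for ch in range(n_channels):
        x = _pink_noise(n, rate, rng)
        t = 2.0  # settle margin before the first burst
        while True:
            if gap_dist == "exp":
                gap = rng.exponential(gap_mean)
            else:
                gap = rng.lognormal(np.log(gap_mean), gap_sigma)
            dur = rng.uniform(*dur_range)
            onset = t + gap
            offset = onset + dur
            if offset >= duration - 1.0:
                break
            f = rng.uniform(*freq_range)
            i0, i1 = int(onset * rate), int(offset * rate)
            tt = np.arange(i1 - i0) / rate
            # Tukey taper: waxing-and-waning edges, but the suprathreshold
            # extent matches the labeled duration (a full Hann would push
            # short bursts under the detector's 500 ms gate by design)
            burst = amplitude * _tukey(i1 - i0, 0.3) * np.sin(
                2.0 * np.pi * f * tt + rng.uniform(0, 2 * np.pi))
            x[i0:i1] += burst
            labels.append(BurstGroundTruth(ch, onset, offset, f, amplitude))
            t = offset
        series[:, ch] = x
    return series, labels


# ---------------------------------------------------------------------------
# configuration round-trip
# ---------------------------------------------------------------------------

_BLOCKS = {
    "network": NetworkSpec,
    "simulation": SimConfig,
    "detector": DetectorParams,
}
# nested dataclass fields of SimConfig are configured elsewhere
_SKIP_FIELDS = {"tc_params", "re_params", "py_params", "in_params", "gabab"}


def _to_dict(obj) -> dict:
    out = {}
    for f in dataclasses.fields(obj):
        if f.name in _SKIP_FIELDS:
            continue
        v = getattr(obj, f.name)
        if isinstance(v, tuple):
            v = list(v)
        out[f.name] = v
    return out


def write_config(path, network: NetworkSpec | None = None,
                 simulation: SimConfig | None = None,
                 detector: DetectorParams | None = None) -> None:
    """Serialize configuration blocks to a YAML file."""
    doc = {}
    for key, obj in (("network", network), ("simulation", simulation),
                     ("detector", detector)):
        if obj is not None:
            doc[key] = _to_dict(obj)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def read_config(path) -> dict:
    """Parse a config file into dataclass instances.

    Returns a dict with any of the keys ``network``, ``simulation``,
    ``detector``.  Unknown blocks or keys raise ValueError naming the
    offending entry.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    out = {}
    for block, payload in doc.items():
        if block not in _BLOCKS:
            raise ValueError(f"{path}: unknown config block {block!r}")
        cls = _BLOCKS[block]
        valid = {f.name for f in dataclasses.fields(cls)} - _SKIP_FIELDS
        unknown = set(payload) - valid
        if unknown:
            raise ValueError(
                f"{path}: unknown key(s) {sorted(unknown)} in block {block!r}"
            )
        kw = {
            k: tuple(v) if isinstance(v, list) and k != "conductances" else v
            for k, v in payload.items()
        }
        # tuple-typed fields arrive as lists from YAML
        for tup_field in ("band", "record_layers", "record_v", "v_init_offset"):
            if tup_field in kw and isinstance(kw[tup_field], tuple):
                kw[tup_field] = tuple(
                    tuple(x) if isinstance(x, list) else x for x in kw[tup_field]
                )
        out[block] = cls(**kw)
    return out


def config_hash(*objs) -> str:
    """Stable short hash of one or more config dataclasses."""
    payload = json.dumps([_to_dict(o) for o in objs], sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# reports and event tables
# ---------------------------------------------------------------------------

def write_report(path, payload: dict, config_objs: tuple = ()) -> None:
    """Write a versioned JSON report stamped with the config hash."""
    doc = {
        "version": REPORT_VERSION,
        "config_hash": config_hash(*config_objs) if config_objs else None,
        **payload,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, default=_json_default)


def _json_default(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, pd.DataFrame):
        return x.to_dict(orient="records")
    raise TypeError(f"not JSON-serializable: {type(x)}")


def read_report(path) -> dict:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("version") != REPORT_VERSION:
        raise ValueError(f"{path}: unsupported report version {doc.get('version')}")
    return doc


def write_events_csv(path, events: list[SpindleEvent]) -> None:
    """Event table with columns channel, onset_s, offset_s, center_s,
    duration_s, peak_freq_hz."""
    pd.DataFrame(
        {
            "channel": [e.channel for e in events],
            "onset_s": [e.onset for e in events],
            "offset_s": [e.offset for e in events],
            "center_s": [e.center for e in events],
            "duration_s": [e.duration for e in events],
            "peak_freq_hz": [e.peak_freq for e in events],
        }
    ).to_csv(path, index=False)


def read_events_csv(path) -> list[SpindleEvent]:
    df = pd.read_csv(path)
    return [
        SpindleEvent(int(r.channel), float(r.onset_s), float(r.offset_s),
                     float(r.peak_freq_hz))
        for r in df.itertuples()
    ]
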