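"""Estimated local field potentials from dendritic synaptic currents.

The model's LFP proxy is the arithmetic mean of the chemical synaptic
currents entering the dendritic compartments of each contiguous group of
pyramidal cells (100 cells per group at full network size).  The layer 3/4
signal stands in for the core system ("MEG-like"), the layer 5 signal for
the matrix system ("EEG-like").  A zero-phase 6-15 Hz band-pass isolates
the spindle band without biasing event-onset statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = ["LfpSeries", "estimate_lfp", "bandpass"]


@dataclass
class LfpSeries:
    """Per-group estimated LFP for one cortical layer.

    ``data`` has shape (n_samples, n_groups); ``group_bounds[i]`` is the
    (first, last+1) cell-index range averaged into group ``i``.
    """

    layer: str
    data: np.ndarray
    rate: float
    group_bounds: list[tuple[int, int]]

    @property
    def n_groups(self) -> int:
        return self.data.shape[1]


def estimate_lfp(
    currents: np.ndarray,
    rate: float,
    layer: str = "L34",
    group_size: int = 100,
) -> LfpSeries:
    """Average dendritic synaptic currents over contiguous cell groups.

    Parameters
    ----------
    currents:
        Array of shape (n_cells, n_samples): synaptic current recorded at
        each cell's dendritic compartment (sign convention: inward current
        negative).
    rate:
        Sampling rate of the recordings (Hz).
    layer:
        Label stored on the result (``"L34"`` or ``"L5"``).
    group_size:
        Cells per group.  A trailing partial group is dropped with a warning.
    """
    currents = np.asarray(currents)
    if currents.ndim != 2:
        raise ValueError("currents must be (n_cells, n_samples)")
    n_cells = currents.shape[0]
    n_groups, rem = divmod(n_cells, group_size)
    if n_groups == 0:
        raise ValueError(f"need at least {group_size} cells, got {n_cells}")
    if rem:
        warnings.warn(
            f"dropping trailing partial group of {rem} cells", stacklevel=2
        )
    bounds = [(i * group_size, (i + 1) * group_size) for i in range(n_groups)]
    data = np.stack(
        [currents[a:b].mean(axis=0) for a, b in bounds], axis=1
    ).astype(float)
    return LfpSeries(layer=layer, data=data, rate=rate, group_bounds=bounds)


def bandpass(
    series: np.ndarray, rate: float, low: float = 6.0, high: float = 15.0
) -> np.ndarray:
    """Zero-phase Butterworth band-pass (4th order, forward-backward).

    Applied along axis 0.  Requires ``rate > 2 * high``.
    """
    if rate <= 2.0 * high:
        raise ValueError(f"sampling rate {rate} Hz too low for band ({low}, {high})")
    sos = signal.butter(4, [low, high], btype="bandpass", fs=rate, output="sos")
    x = np.asarray(series, dtype=float)
    return signal.sosfiltfilt(sos, x, axis=0)
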