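"""Shared domain model: uniformly sampled signals, trials and recordings.

All continuous signals (respiration flow, membrane potential, PID odour
traces) are carried by :class:`TimeSeries`.  Every time window in the
package is half-open ``[start, stop)`` on the sample grid, which makes
window partitions exact and prevents double counting in PSTHs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as _signal

__all__ = [
    "TimeSeries",
    "Trial",
    "Unit",
    "CellRecording",
    "UnitRecording",
    "resample",
    "window",
    "spike_count",
]


@dataclass(frozen=True)
class TimeSeries:
    """Uniformly sampled continuous signal.

    Parameters
    ----------
    samples : array-like
        Signal values; one sample per time step.
    fs : float
        Sampling rate in Hz; must be positive.
    t0 : float
        Time of the first sample in seconds.
    units : str
        Free-form unit label (``"mV"``, ``"a.u."``, ...).

    The time of sample ``i`` is ``t0 + i / fs``.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    units: str = "a.u."

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        object.__setattr__(self, "samples", arr)

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n / self.fs

    @property
    def t_end(self) -> float:
        """Time just past the last sample (end of the half-open span)."""
        return self.t0 + self.duration

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs

    def index_of(self, t: float) -> int:
        """Index of the sample-grid point nearest to time ``t``."""
        return int(round((t - self.t0) * self.fs))


@dataclass(frozen=True)
class Trial:
    """One stimulus presentation."""

    odour: str
    freq: float
    onset: float
    duration: float = 2.0
    is_blank: bool = False
    condition: str = "control"

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError("trial duration must be positive")
        if not self.freq >= 0:
            raise ValueError("trial freq must be non-negative")


@dataclass
class Unit:
    """One sorted extracellular unit."""

    unit_id: int
    spike_times: np.ndarray
    label: str = "good"
    true_class: str | None = None
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)


@dataclass
class CellRecording:
    """Whole-cell recording: Vm, respiration, spike times and metadata."""

    vm: TimeSeries
    resp: TimeSeries
    spike_times: np.ndarray
    trials: list[Trial]
    depth: float = 0.0
    rmp: float = -50.0
    rin: float = 150.0
    series_resistance: float = 10.0
    cell_id: str = "cell"
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        st = np.asarray(self.spike_times, dtype=float)
        if st.size and np.any(np.diff(st) <= 0):
            raise ValueError("spike_times must be strictly increasing")
        if st.size and (st[0] < self.vm.t0 or st[-1] >= self.vm.t_end):
            raise ValueError("spike_times must lie within the Vm span")
        if self.depth < 0:
            raise ValueError("depth must be non-negative")
        self.spike_times = st


@dataclass
class UnitRecording:
    """Population recording: sorted units plus shared respiration/trials."""

    units: list[Unit]
    resp: TimeSeries
    trials: list[Trial]
    ground_truth: dict = field(default_factory=dict)

    def good_units(self) -> list[Unit]:
        """Units that enter analysis (curation label 'good')."""
        return [u for u in self.units if u.label == "good"]


def resample(ts: TimeSeries, target_fs: float) -> TimeSeries:
    """Resample a signal to ``target_fs`` with band-limited (Fourier) interpolation.

    Total duration is preserved to within one sample period; constants are
    preserved exactly; no aliasing is introduced when upsampling.
    """
    if not target_fs > 0:
        raise ValueError("target_fs must be positive")
    if not np.all(np.isfinite(ts.samples)):
        raise ValueError("cannot resample non-finite samples")
    if target_fs == ts.fs:
        return ts
    num = int(round(ts.n * target_fs / ts.fs))
    if num < 1:
        raise ValueError("target_fs too low for signal length")
    out = _signal.resample(ts.samples, num)
    return TimeSeries(out, fs=target_fs, t0=ts.t0, units=ts.units)


def window(ts: TimeSeries, start: float, stop: float) -> TimeSeries:
    """Extract the half-open window ``[start, stop)``, snapped to the sample grid."""
    if not start < stop:
        raise ValueError("window start must precede stop")
    i0 = ts.index_of(start)
    n = int(round((stop - start) * ts.fs))
    if n < 1:
        raise ValueError("window contains no samples")
    if i0 < 0 or i0 + n > ts.n:
        raise ValueError("window outside signal span")
    return TimeSeries(
        ts.samples[i0 : i0 + n],
        fs=ts.fs,
        t0=ts.t0 + i0 / ts.fs,
        units=ts.units,
    )


def spike_count(spike_times: Sequence[float], start: float, stop: float) -> int:
    """Number of spikes with ``start <= t < stop`` (half-open)."""
    if not start < stop:
        raise ValueError("start must precede stop")
    st = np.asarray(spike_times, dtype=float)
    if st.size == 0:
        return 0
    return int(np.searchsorted(st, stop, side="left") - np.searchsorted(st, start, side="left"))
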