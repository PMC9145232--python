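"""Sniff-cycle detection, respiration-phase mapping and breathing statistics.

The raw flow convention throughout the package is *inhalation = negative
deflection* (thermal/mass flow sensor at the naris).  Detection therefore
high-pass filters the trace, flips it so inhalation is positive, subtracts
the median and clips negatives to zero before peak finding.  A sample is in
the inhalation phase from the point the flipped signal reaches 5% of that
inhalation's peak value until it drops below the same threshold again.

Respiration phase is defined on exhalation-peak-to-exhalation-peak
intervals, mapped linearly to [0, 360) degrees with 0 at peak exhalation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

from .core import TimeSeries

__all__ = [
    "SniffCycle",
    "detect_inhalations",
    "phase_of",
    "sniff_rate",
    "inhalation_flow",
    "preprocess_flow",
]

#: High-pass corner (Hz) used to remove slow baseline drift before detection.
HIGHPASS_CORNER = 0.1


@dataclass(frozen=True)
class SniffCycle:
    """One breath: inhalation onset/peak/end and the following exhalation peak."""

    inh_onset: float
    inh_peak: float
    inh_end: float
    exh_peak: float
    cycle_start: float
    cycle_end: float

    def __post_init__(self) -> None:
        ok = (
            self.cycle_start <= self.inh_onset < self.inh_peak < self.inh_end <= self.cycle_end
        )
        if not ok:
            raise ValueError("sniff cycle landmarks out of order")


def preprocess_flow(resp: TimeSeries) -> np.ndarray:
    """High-pass filter, flip (inhalation positive) and median-subtract the flow.

    Returns the *unclipped* processed signal; clip at zero for the
    inhalation-only signal.
    """
    x = resp.samples
    if not np.all(np.isfinite(x)):
        raise ValueError("respiration trace contains non-finite samples")
    if resp.fs > 2 * HIGHPASS_CORNER and resp.duration * HIGHPASS_CORNER > 0.01:
        sos = _signal.butter(2, HIGHPASS_CORNER, btype="highpass", fs=resp.fs, output="sos")
        # the 0.1 Hz corner has a seconds-long impulse response: use the
        # longest reflection padding available to suppress edge transients
        x = _signal.sosfiltfilt(sos, x, padlen=min(x.size - 1, int(30 * resp.fs)))
    x = -x
    return x - np.median(x)


def detect_inhalations(resp: TimeSeries, peak_frac: float = 0.05) -> list[SniffCycle]:
    """Detect sniff cycles from a raw flow trace.

    Inhalation onset/end are the crossings of ``peak_frac`` (default 5%) of
    each inhalation's own peak value, before and after the peak.  The
    exhalation peak is the extremum of the processed signal between
    successive inhalations.  The final inhalation (with no successor to
    bound its exhalation) is dropped, so every returned cycle is complete.

    Detection is invariant to positive rescaling of the input.  A flat
    (zero-range) trace yields an empty list.
    """
    if not 0 < peak_frac < 1:
        raise ValueError("peak_frac must be in (0, 1)")
    proc = preprocess_flow(resp)
    rng = proc.max() - proc.min()
    if rng == 0:
        return []
    clipped = np.clip(proc, 0.0, None)
    top = clipped.max()
    if top <= 0:
        return []
    min_dist = max(1, int(round(0.1 * resp.fs)))
    peaks, _ = _signal.find_peaks(
        clipped, height=0.3 * top, prominence=0.25 * top, distance=min_dist
    )
    if peaks.size < 2:
        return []

    dt = 1.0 / resp.fs
    cycles: list[SniffCycle] = []
    onsets = np.empty(peaks.size)
    ends = np.empty(peaks.size)
    for j, p in enumerate(peaks):
        thr = peak_frac * clipped[p]
        # walk back to the last sample below threshold before the peak
        lo = p
        while lo > 0 and clipped[lo - 1] >= thr:
            lo -= 1
        hi = p
        while hi < clipped.size - 1 and clipped[hi + 1] >= thr:
            hi += 1
        onsets[j] = lo
        ends[j] = hi + 1  # half-open end of the inhalation span
    for j in range(peaks.size - 1):
        a, b = peaks[j], peaks[j + 1]
        exh_idx = a + 1 + int(np.argmin(proc[a + 1 : b]))
        inh_end = min(ends[j], exh_idx)  # inhalation cannot outlast exhalation peak
        if not onsets[j] < peaks[j] < inh_end:
            continue
        cycles.append(
            SniffCycle(
                inh_onset=resp.t0 + onsets[j] * dt,
                inh_peak=resp.t0 + peaks[j] * dt,
                inh_end=resp.t0 + inh_end * dt,
                exh_peak=resp.t0 + exh_idx * dt,
                cycle_start=resp.t0 + onsets[j] * dt,
                cycle_end=resp.t0 + onsets[j + 1] * dt,
            )
        )
    return cycles


def _exh_peaks(cycles: list[SniffCycle]) -> np.ndarray:
    ep = np.asarray([c.exh_peak for c in cycles], dtype=float)
    if np.any(np.diff(ep) <= 0):
        raise ValueError("exhalation peaks must be strictly increasing")
    return ep


def phase_of(t, cycles: list[SniffCycle]):
    """Respiration phase (degrees) of time(s) ``t``.

    Phase is the linear map of ``t`` across the enclosing
    exhalation-peak-to-exhalation-peak interval onto [0, 360), with
    ``phase(exh_peak) = 0``.  Times outside every interval map to NaN.
    Accepts a scalar or an array; returns the same shape.
    """
    if len(cycles) < 2:
        raise ValueError("need at least two cycles to define phase")
    ep = _exh_peaks(cycles)
    tt = np.atleast_1d(np.asarray(t, dtype=float))
    idx = np.searchsorted(ep, tt, side="right") - 1
    out = np.full(tt.shape, np.nan)
    ok = (idx >= 0) & (idx < ep.size - 1)
    i = idx[ok]
    out[ok] = 360.0 * (tt[ok] - ep[i]) / (ep[i + 1] - ep[i])
    return out if np.ndim(t) else float(out[0])


def sniff_rate(cycles: list[SniffCycle]) -> tuple[float, float]:
    """Mean and SD of the instantaneous breathing frequency (1/period)."""
    if len(cycles) < 2:
        raise ValueError("need at least two cycles")
    onsets = np.asarray([c.inh_onset for c in cycles])
    freqs = 1.0 / np.diff(onsets)
    return float(freqs.mean()), float(freqs.std(ddof=0))


def inhalation_flow(resp: TimeSeries, cycles: list[SniffCycle]) -> np.ndarray:
    """Flipped, zero-clipped flow, zeroed outside detected inhalation spans.

    This is the 'inhalation only signal' used to weight the PID trace in the
    odour-respiration convolution.
    """
    proc = np.clip(preprocess_flow(resp), 0.0, None)
    mask = np.zeros(proc.size, dtype=bool)
    for c in cycles:
        i0 = max(0, resp.index_of(c.inh_onset))
        i1 = min(proc.size, resp.index_of(c.inh_end))
        mask[i0:i1] = True
    out = np.where(mask, proc, 0.0)
    return out
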