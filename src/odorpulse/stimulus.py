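"""Stimulus quality metrics: pulse fidelity and the odour-respiration convolution.

Fidelity measures how completely the odour concentration returns to
baseline between pulses: per pulse, the peak-to-trough excursion normalised
by peak-to-baseline.  1 means full return (clean temporal structure), ~0
means an effectively continuous stimulus.

The odour-respiration convolution estimates the odour actually inhaled in
each sniff: the inhalation-only flow signal (flipped, zero-clipped) is
multiplied sample-wise with the PID trace and summed per sniff, so odour is
weighted by the instantaneous inhaled flow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .core import TimeSeries, Trial
from .respiration import SniffCycle, inhalation_flow

__all__ = [
    "FidelityResult",
    "fidelity",
    "odour_integral_per_sniff",
    "odour_integral_table",
    "compare_integrals",
]


@dataclass(frozen=True)
class FidelityResult:
    freq: float
    per_pulse: np.ndarray  # one value per evaluable pulse, clipped to [0, 1]
    mean: float


def fidelity(pid: TimeSeries, pulse_onsets: np.ndarray, baseline: float,
             freq: float | None = None) -> FidelityResult:
    """Per-pulse fidelity of a PID pulse train.

    Pulse ``i``'s peak is the maximum in ``[onset_i, onset_{i+1})`` (the
    last pulse window extends one inter-onset interval); its trough is the
    minimum between that peak and the next pulse's peak (for the last
    pulse, the minimum to the end of the trace).  Pulses whose peak does
    not exceed ``baseline`` are skipped with a warning.
    """
    onsets = np.asarray(pulse_onsets, dtype=float)
    if onsets.size < 2:
        raise ValueError("need at least two pulses")
    if freq is None:
        freq = 1.0 / float(np.median(np.diff(onsets)))
    x = pid.samples
    idx = np.clip(((onsets - pid.t0) * pid.fs).round().astype(int), 0, pid.n - 1)
    bounds = np.append(idx, pid.n)
    peaks_i = np.array(
        [bounds[i] + int(np.argmax(x[bounds[i]:bounds[i + 1]])) for i in range(onsets.size)]
    )
    vals = []
    for i in range(onsets.size):
        peak = x[peaks_i[i]]
        if peak <= baseline:
            warnings.warn(f"pulse {i}: peak does not exceed baseline; skipped")
            continue
        stop = peaks_i[i + 1] if i + 1 < onsets.size else pid.n
        if stop <= peaks_i[i] + 1:
            continue
        trough = x[peaks_i[i]:stop].min()
        vals.append(np.clip((peak - trough) / (peak - baseline), 0.0, 1.0))
    per_pulse = np.asarray(vals, dtype=float)
    mean = float(per_pulse.mean()) if per_pulse.size else float("nan")
    return FidelityResult(freq=float(freq), per_pulse=per_pulse, mean=mean)


def odour_integral_per_sniff(
    pid: TimeSeries,
    resp: TimeSeries,
    cycles: list[SniffCycle],
    trial: Trial,
) -> np.ndarray:
    """Flow-weighted odour integral for each sniff overlapping a trial.

    ``pid`` must be aligned to the recording clock and share the
    respiration sampling rate (resample first if not).  Returns one value
    per sniff whose inhalation onset falls inside the trial window,
    ordered; empty if none do.
    """
    if pid.fs != resp.fs:
        raise ValueError("pid and resp must share a sampling rate; resample first")
    flow = inhalation_flow(resp, cycles)
    # overlay PID onto the respiration clock
    pid_full = np.zeros(resp.n)
    i0 = resp.index_of(pid.t0)
    lo, hi = max(i0, 0), min(i0 + pid.n, resp.n)
    if hi > lo:
        pid_full[lo:hi] = pid.samples[lo - i0 : hi - i0]
    out = []
    for c in cycles:
        if trial.onset <= c.inh_onset < trial.onset + trial.duration:
            a = max(0, resp.index_of(c.inh_onset))
            b = min(resp.n, resp.index_of(c.inh_end))
            out.append(float(np.sum(flow[a:b] * pid_full[a:b])))
    return np.asarray(out, dtype=float)


def odour_integral_table(
    pid_bank: dict[float, TimeSeries],
    resp: TimeSeries,
    cycles: list[SniffCycle],
    trials: list[Trial],
    animal: str = "animal0",
) -> pd.DataFrame:
    """Odour integrals for every sniff of every non-blank trial.

    The per-frequency PID template from ``pid_bank`` is placed at each
    trial's onset (the averaged-PID convention).  Columns:
    animal, odour, freq, sniff_index (1-based), integral.
    """
    rows = []
    for tr in trials:
        if tr.is_blank:
            continue
        tmpl = pid_bank[tr.freq]
        pid = TimeSeries(tmpl.samples, fs=tmpl.fs, t0=tr.onset, units=tmpl.units)
        vals = odour_integral_per_sniff(pid, resp, cycles, tr)
        for k, v in enumerate(vals, start=1):
            rows.append((animal, tr.odour, tr.freq, k, v))
    return pd.DataFrame(rows, columns=["animal", "odour", "freq", "sniff_index", "integral"])


def compare_integrals(table: pd.DataFrame, sniff_index: int) -> pd.DataFrame:
    """All pairwise Mann-Whitney U tests between frequencies at one sniff index.

    P-values are Bonferroni-corrected over the number of frequency pairs
    (10 for 5 frequencies).  Returns a symmetric frequency x frequency
    DataFrame of corrected p-values (NaN diagonal).
    """
    sub = table[table["sniff_index"] == sniff_index]
    freqs = sorted(sub["freq"].unique())
    if len(freqs) < 2:
        raise ValueError("need at least two frequencies")
    groups = {f: sub.loc[sub["freq"] == f, "integral"].to_numpy() for f in freqs}
    for f, g in groups.items():
        if g.size < 2:
            raise ValueError(f"frequency {f} has fewer than 2 observations")
    pairs = list(combinations(freqs, 2))
    mat = pd.DataFrame(np.nan, index=freqs, columns=freqs)
    for a, b in pairs:
        p = _stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided").pvalue
        p = min(1.0, p * len(pairs))
        mat.loc[a, b] = p
        mat.loc[b, a] = p
    return mat
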