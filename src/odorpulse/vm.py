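"""Membrane-potential cleaning and response metrics.

Two corrections precede every subthreshold analysis:

* **spike clipping** — action-potential waveforms are replaced by linear
  interpolation over [-1, +3] ms around each spike time (overlapping
  windows are merged);
* **sniff-phase-matched baseline subtraction** — baseline sniff cycles are
  collated on a common respiration-phase axis and averaged into a generic
  baseline trace per cell, which is then subtracted from every analysed
  window at the phase of each sample.  This removes the sniff-locked
  background Vm oscillation so that stimulus-locked structure stands out.

The baseline template is stored as the set of per-cycle phase
interpolants; evaluating it at a phase returns the across-cycle mean at
that phase.  On strictly periodic, noiseless data this cancels the
sniff-locked component exactly (to floating-point precision).  A 360-bin
summary grid is exposed for inspection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats

from .core import CellRecording, TimeSeries, Trial, spike_count
from .respiration import SniffCycle, detect_inhalations, phase_of

__all__ = [
    "clip_spikes",
    "BaselineTemplate",
    "build_baseline_template",
    "CorrectedTrace",
    "subtract_baseline",
    "PreparedCell",
    "prepare_cell",
    "corrected_window",
    "ResponseMetrics",
    "response_metrics",
    "classify_mixture_response",
    "SERIES_RESISTANCE_CUTOFF",
]

CLIP_PRE_S = 0.001
CLIP_POST_S = 0.003
#: Recordings with series resistance above this (MOhm) are excluded from analysis.
SERIES_RESISTANCE_CUTOFF = 25.0


def clip_spikes(vm: TimeSeries, spike_times) -> TimeSeries:
    """Replace [-1, +3] ms around each spike by linear interpolation.

    Overlapping clip windows are merged into a single interpolation span.
    With no spikes the input is returned unchanged.
    """
    st = np.asarray(spike_times, dtype=float)
    if st.size == 0:
        return vm
    if st.min() < vm.t0 or st.max() >= vm.t_end:
        raise ValueError("spike_times outside Vm span")
    lo = np.maximum(((st - CLIP_PRE_S - vm.t0) * vm.fs).astype(int), 0)
    hi = np.minimum(np.ceil((st + CLIP_POST_S - vm.t0) * vm.fs).astype(int), vm.n - 1)
    # merge overlapping windows
    merged: list[list[int]] = []
    for a, b in zip(lo, hi):
        if merged and a <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    out = vm.samples.copy()
    for a, b in merged:
        a0 = max(a - 1, 0)
        b0 = min(b + 1, vm.n - 1)
        out[a : b + 1] = np.interp(np.arange(a, b + 1), [a0, b0], [out[a0], out[b0]])
    return TimeSeries(out, fs=vm.fs, t0=vm.t0, units=vm.units)


@dataclass
class BaselineTemplate:
    """Sniff-phase-indexed generic baseline Vm trace.

    ``cycle_phases[k]`` / ``cycle_vm[k]`` hold the k-th baseline cycle's
    sample phases (degrees, exhalation-peak referenced) and Vm values.
    ``evaluate`` returns the across-cycle mean at arbitrary phases (circular
    linear interpolation within each cycle).  ``grid``/``grid_n`` summarise
    the template on ``n_bins`` equal phase bins.
    """

    cycle_phases: list[np.ndarray]
    cycle_vm: list[np.ndarray]
    grid: np.ndarray
    grid_n: np.ndarray
    n_bins: int = 360

    @property
    def n_cycles(self) -> int:
        return len(self.cycle_vm)

    def evaluate(self, phases) -> np.ndarray:
        q = np.atleast_1d(np.asarray(phases, dtype=float)) % 360.0
        acc = np.zeros(q.shape)
        for ph, v in zip(self.cycle_phases, self.cycle_vm):
            acc += np.interp(q, ph, v, period=360.0)
        return acc / self.n_cycles


def build_baseline_template(
    vm_clipped: TimeSeries,
    cycles: list[SniffCycle],
    n_bins: int = 360,
    min_cycles: int = 5,
) -> BaselineTemplate:
    """Collate baseline sniff cycles on a common phase axis and average them.

    ``cycles`` must be baseline cycles (no stimulus present).  Each cycle
    spans exhalation peak to exhalation peak; its samples are assigned
    phases 0-360 linearly across that span.
    """
    if len(cycles) < min_cycles + 1:
        raise ValueError(f"need at least {min_cycles} complete baseline cycles")
    eps = [c.exh_peak for c in cycles]
    cycle_phases: list[np.ndarray] = []
    cycle_vm: list[np.ndarray] = []
    for a, b in zip(eps[:-1], eps[1:]):
        i0 = max(0, vm_clipped.index_of(a))
        i1 = min(vm_clipped.n, vm_clipped.index_of(b))
        if i1 - i0 < 4:
            continue
        t = vm_clipped.t0 + np.arange(i0, i1) / vm_clipped.fs
        ph = 360.0 * (t - a) / (b - a)
        cycle_phases.append(ph)
        cycle_vm.append(vm_clipped.samples[i0:i1])
    if len(cycle_vm) < min_cycles:
        raise ValueError(f"need at least {min_cycles} complete baseline cycles")
    centres = (np.arange(n_bins) + 0.5) * 360.0 / n_bins
    acc = np.zeros(n_bins)
    for ph, v in zip(cycle_phases, cycle_vm):
        acc += np.interp(centres, ph, v, period=360.0)
    grid = acc / len(cycle_vm)
    grid_n = np.full(n_bins, len(cycle_vm))
    return BaselineTemplate(cycle_phases, cycle_vm, grid, grid_n, n_bins)


@dataclass
class CorrectedTrace:
    """Baseline-subtracted (and spike-clipped) Vm window."""

    vm_corrected: TimeSeries
    template: BaselineTemplate
    trial: Trial | None = None
    n_flagged: int = 0  # samples outside detected cycles (nearest-phase fallback)


def subtract_baseline(
    vm_window: TimeSeries,
    template: BaselineTemplate,
    cycles: list[SniffCycle],
    trial: Trial | None = None,
) -> CorrectedTrace:
    """Subtract the phase-matched baseline template from a Vm window.

    Each sample's respiration phase is looked up in ``cycles``; samples
    outside every cycle use the phase of the nearest covered time and are
    counted in ``n_flagged``.
    """
    t = vm_window.times()
    eps = np.asarray([c.exh_peak for c in cycles])
    if eps.size < 2:
        raise ValueError("need at least two cycles to phase-map the window")
    t_clamped = np.clip(t, eps[0], np.nextafter(eps[-1], -np.inf))
    n_flagged = int(np.sum((t < eps[0]) | (t >= eps[-1])))
    ph = phase_of(t_clamped, cycles)
    corrected = vm_window.samples - template.evaluate(ph)
    return CorrectedTrace(
        vm_corrected=TimeSeries(corrected, fs=vm_window.fs, t0=vm_window.t0, units=vm_window.units),
        template=template,
        trial=trial,
        n_flagged=n_flagged,
    )


@dataclass
class PreparedCell:
    """A whole-cell recording readied for subthreshold analysis.

    Holds the spike-clipped Vm, the detected sniff cycles, the baseline
    template built from the pre-stimulus period, and the source recording.
    """

    cell: CellRecording
    vm_clipped: TimeSeries
    cycles: list[SniffCycle]
    template: BaselineTemplate
    baseline_stop: float


def prepare_cell(
    cell: CellRecording,
    cycles: list[SniffCycle] | None = None,
    baseline_stop: float | None = None,
    n_bins: int = 360,
    max_template_cycles: int | None = 60,
    enforce_qc: bool = True,
) -> PreparedCell:
    """Clip spikes, detect sniff cycles and build the baseline template.

    The baseline period defaults to everything up to 1 s before the first
    trial onset.  Recordings failing the series-resistance criterion
    (> 25 MOhm) are rejected unless ``enforce_qc`` is False.
    """
    if enforce_qc and cell.series_resistance > SERIES_RESISTANCE_CUTOFF:
        raise ValueError("series resistance exceeds 25 MOhm; recording excluded")
    vm_clipped = clip_spikes(cell.vm, cell.spike_times)
    if cycles is None:
        cycles = detect_inhalations(cell.resp)
    if baseline_stop is None:
        if not cell.trials:
            baseline_stop = cell.vm.t_end
        else:
            baseline_stop = min(tr.onset for tr in cell.trials) - 1.0
    base_cycles = [c for c in cycles if c.cycle_end <= baseline_stop]
    if max_template_cycles is not None:
        base_cycles = base_cycles[:max_template_cycles]
    template = build_baseline_template(vm_clipped, base_cycles, n_bins=n_bins)
    return PreparedCell(cell, vm_clipped, cycles, template, baseline_stop)


def corrected_window(prep: PreparedCell, start: float, stop: float) -> np.ndarray:
    """Spike-clipped, baseline-subtracted Vm samples for [start, stop)."""
    from .core import window as _window

    win = _window(prep.vm_clipped, start, stop)
    return subtract_baseline(win, prep.template, prep.cycles).vm_corrected.samples


@dataclass
class ResponseMetrics:
    """Odour-response metrics for one trial."""

    dvm: float  # mV: mean corrected Vm, first 500 ms minus 2 s pre-onset
    dfr: float  # Hz: rate in first 500 ms minus 2 s pre-onset
    psth: np.ndarray  # Hz per 50 ms bin over [-2 s, +2 s) around onset
    p_vm: float
    p_fr: float
    sig_vs_blank: bool
    trial: Trial | None = None


_PRE_S = 2.0
_POST_S = 0.5
_PSTH_BIN_S = 0.05


def _trial_dvm(prep: PreparedCell, tr: Trial) -> float:
    pre = corrected_window(prep, tr.onset - _PRE_S, tr.onset)
    post = corrected_window(prep, tr.onset, tr.onset + _POST_S)
    return float(post.mean() - pre.mean())


def _trial_dfr(prep: PreparedCell, tr: Trial) -> float:
    st = prep.cell.spike_times
    pre = spike_count(st, tr.onset - _PRE_S, tr.onset) / _PRE_S
    post = spike_count(st, tr.onset, tr.onset + _POST_S) / _POST_S
    return float(post - pre)


def response_metrics(
    prep: PreparedCell,
    trial: Trial,
    alpha: float = 0.05,
) -> ResponseMetrics:
    """dVm / dFR / PSTH for one trial, with significance against blanks.

    dVm is the mean baseline-subtracted Vm in the first 500 ms after onset
    minus the mean in the 2 s before onset; dFR is the analogous rate
    difference on spike counts.  Significance: two-tailed unpaired t-test
    of per-trial metrics for all same-odour, same-frequency trials against
    blank trials at the same frequency.
    """
    if trial.onset - _PRE_S < prep.vm_clipped.t0:
        raise ValueError("trial lacks a full 2 s pre-onset span")
    blanks = [t for t in prep.cell.trials
              if t.is_blank and t.freq == trial.freq and t.condition == trial.condition]
    if not blanks:
        raise ValueError("no matched-frequency blank trials for significance")
    mates = [t for t in prep.cell.trials
             if (not t.is_blank) and t.odour == trial.odour and t.freq == trial.freq
             and t.condition == trial.condition]

    dvm = _trial_dvm(prep, trial)
    dfr = _trial_dfr(prep, trial)

    edges = np.arange(-_PRE_S, _PRE_S + 1e-9, _PSTH_BIN_S) + trial.onset
    counts = np.array([spike_count(prep.cell.spike_times, a, b)
                       for a, b in zip(edges[:-1], edges[1:])])
    psth = counts / _PSTH_BIN_S

    od_vm = np.array([_trial_dvm(prep, t) for t in mates])
    bl_vm = np.array([_trial_dvm(prep, t) for t in blanks])
    od_fr = np.array([_trial_dfr(prep, t) for t in mates])
    bl_fr = np.array([_trial_dfr(prep, t) for t in blanks])
    p_vm = _two_sample_p(od_vm, bl_vm)
    p_fr = _two_sample_p(od_fr, bl_fr)
    return ResponseMetrics(dvm=dvm, dfr=dfr, psth=psth, p_vm=p_vm, p_fr=p_fr,
                           sig_vs_blank=bool(p_vm < alpha), trial=trial)


def _two_sample_p(a: np.ndarray, b: np.ndarray) -> float:
    if a.size < 2 or b.size < 2:
        return float("nan")
    if a.std() == 0 and b.std() == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(_stats.ttest_ind(a, b).pvalue)


def classify_mixture_response(
    dvm_a: float, dvm_b: float, sig_a: bool = True, sig_b: bool = True
) -> str:
    """Mixture-interaction label from the signs of the two component dVm values."""
    if not (sig_a and sig_b):
        return "unclassified"
    if dvm_a >= 0 and dvm_b >= 0:
        return "Ex-Ex"
    if dvm_a < 0 and dvm_b < 0:
        return "In-In"
    return "Ex-In"
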