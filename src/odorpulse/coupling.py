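"""Frequency-coupling coefficient (CpC): stimulus-Vm cross-correlation statistics.

The CpC quantifies how strongly a cell's subthreshold membrane potential
follows the temporal structure of an odour stimulus.  For a cell-odour-
frequency triple:

1. every baseline-subtracted odour-trial Vm window is cross-correlated with
   the trial-averaged PID template and the *peak* correlation is kept
   (``CC_odour``, one value per trial);
2. the same is done for the blank (mineral-oil) trials at that frequency
   (``CC_blank``);
3. ``CpC = mean(CC_odour) / mean(CC_blank)``.

CpC > 1 indicates coupling to the odour stimulus beyond what residual
mechanical/flow artefacts produce.  Significance is assessed against a
baseline-control null: odour-free baseline stretches of trial length run
through the identical computation.

"Cross-correlation" here is the Pearson correlation coefficient evaluated
at every integer-sample lag in a +/-500 ms search window — a normalised
measure, so the CpC ratio is invariant to affine rescaling of Vm.  The
peak is the maximum *signed* correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats

from .core import TimeSeries, Trial
from .vm import PreparedCell, corrected_window

__all__ = [
    "MAX_LAG_S",
    "BLANK_EPS",
    "CpCResult",
    "crosscorr_curve",
    "peak_crosscorr",
    "compute_cpc",
    "baseline_cpc",
    "cpc_significance",
    "analyze_cell_odour",
    "cpc_vs_constant",
    "correlate_cpc_covariate",
    "mixture_prediction",
    "compare_cpc_paired",
]

#: Default lag search half-window (s); covers one full 2 Hz stimulus period.
MAX_LAG_S = 0.5
#: Guard on the blank aggregate: below this the CpC ratio is undefined.
BLANK_EPS = 1e-3
_VAR_FLOOR = 1e-300


@dataclass
class CpCResult:
    """CpC and its ingredients for one cell-odour-frequency triple."""

    cell_id: str
    odour: str
    freq: float
    cc_odour: np.ndarray  # per-trial peak correlations, odour trials
    cc_blank: np.ndarray  # per-trial peak correlations, blank trials
    cpc: float  # mean(cc_odour) / mean(cc_blank); NaN if flagged
    cpc_trials: np.ndarray  # per-trial cc_odour / mean(cc_blank)
    lag: float  # s, at the peak of the across-trial mean correlation curve
    cpc_baseline: np.ndarray | None = None  # control CpC distribution
    p_vs_baseline: float = float("nan")
    significant: bool = False
    flagged: bool = False  # blank aggregate below BLANK_EPS


def _lag_grid(fs: float, max_lag: float) -> np.ndarray:
    L = int(round(max_lag * fs))
    return np.arange(-L, L + 1)


def crosscorr_curve(
    template: np.ndarray,
    trace: np.ndarray,
    fs: float,
    max_lag: float = MAX_LAG_S,
    min_overlap: int = 8,
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation of ``template[i]`` vs ``trace[i + lag]`` per lag.

    Returns ``(lags_s, cc)`` for every integer-sample lag in
    ``[-max_lag, +max_lag]``; the correlation at each lag is computed over
    the overlapping part only.  Lags with fewer than ``min_overlap``
    overlapping samples, or zero variance in either overlapping segment,
    yield NaN.  A positive peak lag means the trace lags the template.
    """
    x = np.asarray(template, dtype=float)
    y = np.asarray(trace, dtype=float)
    m, n = x.size, y.size
    lags = _lag_grid(fs, max_lag)
    # cross term at every displacement via direct correlation
    full = np.correlate(y, x, mode="full")  # full[l + m - 1] = sum_i x[i] y[i+l]
    i0 = np.maximum(0, -lags)
    i1 = np.minimum(m, n - lags)
    cnt = (i1 - i0).astype(float)
    ok = i1 - i0 >= max(2, min_overlap)
    cx = np.concatenate([[0.0], np.cumsum(x)])
    cx2 = np.concatenate([[0.0], np.cumsum(x * x)])
    cy = np.concatenate([[0.0], np.cumsum(y)])
    cy2 = np.concatenate([[0.0], np.cumsum(y * y)])
    cc = np.full(lags.shape, np.nan)
    li = lags[ok]
    a0, a1 = i0[ok], i1[ok]
    b0, b1 = a0 + li, a1 + li
    c = cnt[ok]
    sx = cx[a1] - cx[a0]
    sxx = cx2[a1] - cx2[a0]
    sy = cy[b1] - cy[b0]
    syy = cy2[b1] - cy2[b0]
    k = li + m - 1
    sxy = full[np.clip(k, 0, full.size - 1)]
    num = sxy - sx * sy / c
    vx = sxx - sx * sx / c
    vy = syy - sy * sy / c
    denom = np.sqrt(np.clip(vx, 0, None) * np.clip(vy, 0, None))
    good = denom > _VAR_FLOOR
    vals = np.full(li.shape, np.nan)
    vals[good] = num[good] / denom[good]
    cc[ok] = vals
    return lags / fs, cc


def peak_crosscorr(
    template: np.ndarray | TimeSeries,
    trace: np.ndarray | TimeSeries,
    fs: float | None = None,
    max_lag: float = MAX_LAG_S,
) -> tuple[float, float]:
    """Peak signed Pearson correlation over lags, and the lag at the peak (s)."""
    if isinstance(template, TimeSeries):
        fs = template.fs
        template = template.samples
    if isinstance(trace, TimeSeries):
        fs = trace.fs if fs is None else fs
        trace = trace.samples
    if fs is None:
        raise ValueError("fs required when passing bare arrays")
    if np.std(np.asarray(trace, dtype=float)) == 0 or np.std(np.asarray(template, dtype=float)) == 0:
        warnings.warn("zero-variance input: peak correlation undefined")
        return float("nan"), 0.0
    lags, cc = crosscorr_curve(template, trace, fs, max_lag)
    if not np.any(np.isfinite(cc)):
        return float("nan"), 0.0
    k = int(np.nanargmax(cc))
    return float(cc[k]), float(lags[k])


def _trial_windows(prep: PreparedCell, trials: list[Trial]) -> list[np.ndarray]:
    return [corrected_window(prep, tr.onset, tr.onset + tr.duration) for tr in trials]


def _peak_ccs(
    prep: PreparedCell,
    windows: list[np.ndarray],
    pid_avg: np.ndarray,
    max_lag: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Peak correlations per window, plus the summed correlation-vs-lag curve."""
    fs = prep.vm_clipped.fs
    peaks = np.empty(len(windows))
    curve_sum = None
    for j, w in enumerate(windows):
        lags, cc = crosscorr_curve(pid_avg, w, fs, max_lag)
        peaks[j] = np.nanmax(cc) if np.any(np.isfinite(cc)) else np.nan
        curve_sum = cc if curve_sum is None else curve_sum + cc
    return peaks, curve_sum


def compute_cpc(
    prep: PreparedCell,
    odour: str,
    freq: float,
    pid_avg: TimeSeries | np.ndarray,
    max_lag: float = MAX_LAG_S,
    condition: str = "control",
) -> CpCResult:
    """CpC for one cell-odour-frequency triple.

    Odour trials are those matching ``odour``/``freq``/``condition``; blanks
    are the blank trials at the same frequency and condition.  Each odour
    trial's peak correlation is normalised by the across-trial mean of the
    blank peaks.  The reported lag is at the maximum of the across-trial
    mean correlation curve.  If the blank aggregate is below ``BLANK_EPS``
    the CpC is NaN and the result is flagged.
    """
    pid = pid_avg.samples if isinstance(pid_avg, TimeSeries) else np.asarray(pid_avg, float)
    od = [t for t in prep.cell.trials
          if (not t.is_blank) and t.odour == odour and t.freq == freq and t.condition == condition]
    bl = [t for t in prep.cell.trials
          if t.is_blank and t.freq == freq and t.condition == condition]
    if not od or not bl:
        raise ValueError("need at least one odour trial and one blank trial at this frequency")
    fs = prep.vm_clipped.fs
    cc_od, curve = _peak_ccs(prep, _trial_windows(prep, od), pid, max_lag)
    cc_bl, _ = _peak_ccs(prep, _trial_windows(prep, bl), pid, max_lag)
    agg = float(np.nanmean(cc_bl))
    lags = _lag_grid(fs, max_lag) / fs
    lag = float(lags[int(np.nanargmax(curve))]) if np.any(np.isfinite(curve)) else float("nan")
    flagged = not np.isfinite(agg) or abs(agg) < BLANK_EPS
    if flagged:
        warnings.warn("blank aggregate below guard: CpC undefined for this triple")
        cpc = float("nan")
        trials_norm = np.full(cc_od.shape, np.nan)
    else:
        trials_norm = cc_od / agg
        cpc = float(np.nanmean(trials_norm))
    return CpCResult(
        cell_id=prep.cell.cell_id, odour=odour, freq=freq,
        cc_odour=cc_od, cc_blank=cc_bl, cpc=cpc, cpc_trials=trials_norm,
        lag=lag, flagged=flagged,
    )


def baseline_cpc(
    prep: PreparedCell,
    freq: float,
    pid_avg: TimeSeries | np.ndarray,
    max_lag: float = MAX_LAG_S,
    condition: str = "control",
    min_segments: int = 5,
) -> np.ndarray:
    """Control CpC distribution from odour-free baseline stretches.

    The pre-onset window of every trial (one trial-length each) is
    baseline-subtracted and run through the identical peak-correlation
    computation; each peak is normalised by the same blank aggregate used
    for the odour CpC at this frequency.
    """
    pid = pid_avg.samples if isinstance(pid_avg, TimeSeries) else np.asarray(pid_avg, float)
    trs = [t for t in prep.cell.trials if t.condition == condition]
    segs = []
    for tr in trs:
        a = tr.onset - tr.duration
        if a >= prep.vm_clipped.t0:
            segs.append((a, tr.onset))
    if len(segs) < min_segments:
        raise ValueError(f"need at least {min_segments} baseline segments of trial length")
    bl = [t for t in trs if t.is_blank and t.freq == freq]
    if not bl:
        raise ValueError("no blank trials at this frequency")
    cc_bl, _ = _peak_ccs(prep, _trial_windows(prep, bl), pid, max_lag)
    agg = float(np.nanmean(cc_bl))
    if not np.isfinite(agg) or abs(agg) < BLANK_EPS:
        raise ValueError("blank aggregate below guard: control CpC undefined")
    windows = [corrected_window(prep, a, b) for a, b in segs]
    cc_base, _ = _peak_ccs(prep, windows, pid, max_lag)
    return cc_base / agg


def cpc_significance(
    result: CpCResult,
    baseline_controls: np.ndarray | None = None,
    alpha: float = 0.05,
) -> tuple[float, bool]:
    """Two-tailed unpaired t-test: per-trial odour CpC vs baseline-control CpC."""
    base = result.cpc_baseline if baseline_controls is None else np.asarray(baseline_controls)
    if base is None:
        raise ValueError("baseline controls required")
    a = result.cpc_trials[np.isfinite(result.cpc_trials)]
    b = np.asarray(base, dtype=float)
    b = b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    if a.std() == 0 and b.std() == 0:
        p = 1.0 if a.mean() == b.mean() else 0.0
    else:
        p = float(_stats.ttest_ind(a, b).pvalue)
    return p, bool(p < alpha)


def analyze_cell_odour(
    prep: PreparedCell,
    odour: str,
    freq: float,
    pid_avg: TimeSeries | np.ndarray,
    max_lag: float = MAX_LAG_S,
    condition: str = "control",
    alpha: float = 0.05,
) -> CpCResult:
    """CpC plus baseline-control null and significance, in one call."""
    res = compute_cpc(prep, odour, freq, pid_avg, max_lag, condition)
    if not res.flagged:
        base = baseline_cpc(prep, freq, pid_avg, max_lag, condition)
        res.cpc_baseline = base
        res.p_vs_baseline, res.significant = cpc_significance(res, base, alpha)
    return res


def cpc_vs_constant(
    cpc_pulsed: np.ndarray, cpc_constant: np.ndarray
) -> tuple[float, int]:
    """Paired t-test of pulsed-stimulus vs constant-stimulus per-trial CpC.

    Returns ``(p, direction)`` with direction the sign of
    ``mean(pulsed) - mean(constant)``.  Unequal trial counts cannot be
    paired and are rejected.
    """
    a = np.asarray(cpc_pulsed, dtype=float)
    b = np.asarray(cpc_constant, dtype=float)
    if a.size != b.size:
        raise ValueError("paired comparison requires equal trial counts")
    if a.size < 2:
        raise ValueError("need at least 2 paired trials")
    if np.allclose(a, b):
        return 1.0, 0
    p = float(_stats.ttest_rel(a, b).pvalue)
    return p, int(np.sign(a.mean() - b.mean()))


def correlate_cpc_covariate(
    cpcs: np.ndarray, covariate: np.ndarray
) -> tuple[float, float]:
    """Pearson correlation of CpC against a cell covariate (depth, Rin, RMP)."""
    x = np.asarray(covariate, dtype=float)
    y = np.asarray(cpcs, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 matched cells")
    if np.ptp(x) == 0:
        raise ValueError("constant covariate: correlation undefined")
    if np.ptp(y) == 0:
        return 0.0, 1.0
    r, p = _stats.pearsonr(x, y)
    return float(r), float(p)


def mixture_prediction(
    cpc_a: np.ndarray, cpc_b: np.ndarray, cpc_mix: np.ndarray
) -> dict:
    """Regress the mixture CpC on the mean of the component CpCs.

    Under odour-invariant coupling the mixture CpC should equal
    ``(CpC_A + CpC_B) / 2``; returns slope, intercept, r and the two-tailed
    p-value of the slope.
    """
    a = np.asarray(cpc_a, float)
    b = np.asarray(cpc_b, float)
    m = np.asarray(cpc_mix, float)
    if not (a.size == b.size == m.size) or a.size < 3:
        raise ValueError("need at least 3 cells with all three measurements")
    x = (a + b) / 2.0
    fit = _stats.linregress(x, m)
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r": float(fit.rvalue),
        "p": float(fit.pvalue),
    }


def compare_cpc_paired(
    pre: np.ndarray, post: np.ndarray
) -> tuple[float, int, bool]:
    """Paired t-test of per-trial CpC across conditions (e.g. pre/post drug).

    Returns ``(p, direction, paired)``; with unequal trial counts an
    unpaired test is used and ``paired`` is False.
    """
    a = np.asarray(pre, dtype=float)
    b = np.asarray(post, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 trials per condition")
    if a.size == b.size:
        if np.allclose(a, b):
            return 1.0, 0, True
        p = float(_stats.ttest_rel(a, b).pvalue)
        return p, int(np.sign(b.mean() - a.mean())), True
    warnings.warn("unequal trial counts: falling back to unpaired t-test")
    p = float(_stats.ttest_ind(a, b).pvalue)
    return p, int(np.sign(b.mean() - a.mean())), False
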