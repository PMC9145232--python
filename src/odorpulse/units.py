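"""Unit-level frequency-response characterisation.

Per unit and odour: blank responses are subtracted from odour responses at
the same pulse frequency, averaged across repeats, and z-scored across the
five frequencies into a five-value response vector.  Vectors are
hierarchically clustered (Euclidean, average linkage) with optimal leaf
ordering.  Mann-Whitney U screens flag units whose 500 ms post-onset spike
counts discriminate two frequencies (alpha 0.01) or odour from blank
(alpha 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats
from scipy.cluster import hierarchy as _hier

from .core import Trial, Unit, spike_count

__all__ = [
    "RESPONSE_WINDOW_S",
    "ResponseVector",
    "trial_counts",
    "response_vector",
    "cluster_units",
    "freq_discrimination_screen",
    "blank_screen",
]

#: Spike-count response window after odour onset (s).
RESPONSE_WINDOW_S = 0.5


@dataclass
class ResponseVector:
    unit_id: int
    odour: str
    freqs: np.ndarray
    raw: np.ndarray  # per-frequency blank-subtracted mean response
    zscored: np.ndarray | None  # None when variance across frequencies is zero
    flagged: bool = False


def trial_counts(unit: Unit, trials: list[Trial],
                 window: tuple[float, float] = (0.0, RESPONSE_WINDOW_S)) -> np.ndarray:
    """Spike counts per trial in ``[onset + window[0], onset + window[1])``."""
    return np.array(
        [spike_count(unit.spike_times, t.onset + window[0], t.onset + window[1])
         for t in trials],
        dtype=float,
    )


def _select(trials: list[Trial], odour: str | None, freq: float, blank: bool) -> list[Trial]:
    return [t for t in trials
            if t.is_blank == blank and t.freq == freq
            and (blank or odour is None or t.odour == odour)]


def response_vector(unit: Unit, trials: list[Trial], odour: str) -> ResponseVector:
    """Blank-subtracted, z-scored five-value frequency-response vector.

    Per frequency: mean over repeats of (odour-trial count minus the mean
    blank count at the same frequency) in the first 500 ms, then z-scored
    across the five values (mean 0, SD 1).  Zero variance across
    frequencies leaves ``zscored`` as None with the vector flagged.
    """
    freqs = sorted({t.freq for t in trials if not t.is_blank})
    raw = np.empty(len(freqs))
    for i, f in enumerate(freqs):
        od = _select(trials, odour, f, blank=False)
        bl = _select(trials, None, f, blank=True)
        if not od or not bl:
            raise ValueError(f"frequency {f} lacks odour or blank trials")
        od_counts = trial_counts(unit, od)
        bl_mean = trial_counts(unit, bl).mean()
        raw[i] = od_counts.mean() - bl_mean
    sd = raw.std(ddof=0)
    if sd == 0:
        return ResponseVector(unit.unit_id, odour, np.asarray(freqs), raw, None, flagged=True)
    z = (raw - raw.mean()) / sd
    return ResponseVector(unit.unit_id, odour, np.asarray(freqs), raw, z)


def cluster_units(vectors: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hierarchical clustering of response vectors with optimal leaf ordering.

    Euclidean distances, average linkage; the leaf order minimises the sum
    of adjacent-leaf distances.  Returns ``(linkage_matrix, leaf_order)``.
    """
    X = np.asarray(vectors, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 vectors")
    Z = _hier.linkage(X, method="average", metric="euclidean")
    Z = _hier.optimal_leaf_ordering(Z, X)
    return Z, _hier.leaves_list(Z)


def _mwu(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(np.concatenate([a, b])) == 0:
        return 1.0  # all counts tied
    return float(_stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def freq_discrimination_screen(
    unit: Unit, trials: list[Trial], odour: str, f_a: float, f_b: float,
    alpha: float = 0.01,
) -> tuple[float, bool]:
    """Mann-Whitney U on 500 ms counts between two pulse frequencies."""
    a = trial_counts(unit, _select(trials, odour, f_a, blank=False))
    b = trial_counts(unit, _select(trials, odour, f_b, blank=False))
    if a.size < 5 or b.size < 5:
        raise ValueError("need at least 5 repeats per condition")
    p = _mwu(a, b)
    return p, bool(p < alpha)


def blank_screen(
    unit: Unit, trials: list[Trial], odour: str, alpha: float = 0.05,
) -> tuple[float, bool]:
    """Mann-Whitney U of odour vs blank 500 ms counts, pooled over frequencies."""
    od = [t for t in trials if not t.is_blank and t.odour == odour]
    bl = [t for t in trials if t.is_blank]
    a = trial_counts(unit, od)
    b = trial_counts(unit, bl)
    if a.size < 5 or b.size < 5:
        raise ValueError("need at least 5 repeats per condition")
    p = _mwu(a, b)
    return p, bool(p < alpha)
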