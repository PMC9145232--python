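"""Linear decoding of stimulus frequency/identity from population spike counts.

Features are per-trial, per-unit spike counts in a window relative to
odour onset; no spikes beyond 4 s post-onset are used.  The decoder is a
weakly regularised linear support-vector classifier; features are
standardised with statistics fitted on the training split only (no test
leakage).  Accuracy is the distribution over repeated random 80/20
stratified splits; shuffle controls repeat the procedure with permuted
labels and converge to 1/n_classes for balanced designs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .core import Trial, UnitRecording

__all__ = [
    "DecodingConfig",
    "DecodingResult",
    "feature_matrix",
    "train_eval",
    "rolling_accuracy",
    "subset_curve",
    "pairwise_matrix",
    "confusion_matrix",
    "single_unit_accuracy",
]

#: Weak margin penalty: the hinge loss dominates, leaving unit weightings
#: essentially unrestricted.
SVC_C = 100.0
_MAX_POST_S = 4.0


@dataclass(frozen=True)
class DecodingConfig:
    window_start: float = 0.0
    window_size: float = 0.5
    train_frac: float = 0.8
    n_reps: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_start + self.window_size > _MAX_POST_S + 1e-9:
            raise ValueError("window must end within 4 s of odour onset")
        if not 0.01 <= self.window_size <= _MAX_POST_S:
            raise ValueError("window_size must be within [10 ms, 4 s]")
        if not 0 < self.train_frac < 1:
            raise ValueError("train_frac must be in (0, 1)")


@dataclass
class DecodingResult:
    accuracies: np.ndarray
    mean: float
    sd: float
    shuffled: np.ndarray | None = None
    shuffled_mean: float = float("nan")
    shuffled_sd: float = float("nan")
    confusion: np.ndarray | None = None
    classes: np.ndarray | None = None

    @property
    def sem(self) -> float:
        return float(self.sd / np.sqrt(self.accuracies.size))


def _make_clf():
    return make_pipeline(
        StandardScaler(),
        LinearSVC(C=SVC_C, max_iter=10000, tol=1e-3),
    )


def feature_matrix(
    population: UnitRecording,
    cfg: DecodingConfig,
    trials: list[Trial] | None = None,
    label_by: str = "freq",
) -> tuple[np.ndarray, np.ndarray]:
    """Trials x units raw spike-count matrix and trial labels.

    Counts are taken in ``[onset + window_start, onset + window_start +
    window_size)``.  ``label_by`` is ``"freq"``, ``"odour"`` or ``"type"``
    (odour-frequency pair).  Counts are returned raw; standardisation
    happens inside the decoders on the training split only.
    """
    if trials is None:
        trials = [t for t in population.trials if not t.is_blank]
    units = population.good_units()
    a = cfg.window_start
    b = cfg.window_start + cfg.window_size
    X = np.empty((len(trials), len(units)))
    for j, u in enumerate(units):
        st = u.spike_times
        lo = np.searchsorted(st, [t.onset + a for t in trials], side="left")
        hi = np.searchsorted(st, [t.onset + b for t in trials], side="left")
        X[:, j] = hi - lo
    if label_by == "freq":
        y = np.array([t.freq for t in trials])
    elif label_by == "odour":
        y = np.array([t.odour for t in trials])
    elif label_by == "type":
        y = np.array([f"{t.odour}@{t.freq:g}" for t in trials])
    else:
        raise ValueError("label_by must be 'freq', 'odour' or 'type'")
    return X, y


def train_eval(
    X: np.ndarray,
    y: np.ndarray,
    cfg: DecodingConfig,
    shuffle: bool = True,
    collect_confusion: bool = False,
) -> DecodingResult:
    """Accuracy distribution over repeated random stratified 80/20 splits.

    When ``shuffle`` is True the whole procedure is repeated with labels
    permuted independently per repetition (the chance control).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    rng = np.random.default_rng(cfg.seed)
    splitter = StratifiedShuffleSplit(
        n_splits=cfg.n_reps, test_size=1 - cfg.train_frac,
        random_state=int(rng.integers(2**31)),
    )
    accs = np.empty(cfg.n_reps)
    conf = np.zeros((classes.size, classes.size)) if collect_confusion else None
    cls_index = {c: i for i, c in enumerate(classes)}
    for r, (tr_idx, te_idx) in enumerate(splitter.split(X, y)):
        clf = _make_clf()
        clf.fit(X[tr_idx], y[tr_idx])
        pred = clf.predict(X[te_idx])
        accs[r] = float(np.mean(pred == y[te_idx]))
        if conf is not None:
            for yt, yp in zip(y[te_idx], pred):
                conf[cls_index[yt], cls_index[yp]] += 1
    shuffled = None
    if shuffle:
        shuffled = np.empty(cfg.n_reps)
        for r in range(cfg.n_reps):
            ys = y[rng.permutation(y.size)]
            # stratify on the permuted labels: keeps the chance control
            # balanced (otherwise majority-class imbalance between the
            # splits biases shuffled accuracy below 1/n_classes)
            sh_split = StratifiedShuffleSplit(
                n_splits=1, test_size=1 - cfg.train_frac,
                random_state=int(rng.integers(2**31)),
            )
            tr_idx, te_idx = next(sh_split.split(X, ys))
            clf = _make_clf()
            clf.fit(X[tr_idx], ys[tr_idx])
            shuffled[r] = float(np.mean(clf.predict(X[te_idx]) == ys[te_idx]))
    if conf is not None:
        rows = conf.sum(axis=1, keepdims=True)
        conf = np.divide(conf, rows, out=np.zeros_like(conf), where=rows > 0)
    return DecodingResult(
        accuracies=accs, mean=float(accs.mean()), sd=float(accs.std(ddof=1)),
        shuffled=shuffled,
        shuffled_mean=float(shuffled.mean()) if shuffled is not None else float("nan"),
        shuffled_sd=float(shuffled.std(ddof=1)) if shuffled is not None else float("nan"),
        confusion=conf, classes=classes,
    )


def rolling_accuracy(
    population: UnitRecording,
    window_starts: np.ndarray,
    cfg: DecodingConfig,
    label_by: str = "freq",
) -> np.ndarray:
    """Mean accuracy of a fixed-size window slid across start times."""
    out = np.empty(len(window_starts))
    for i, s in enumerate(window_starts):
        c = DecodingConfig(window_start=float(s), window_size=cfg.window_size,
                           train_frac=cfg.train_frac, n_reps=cfg.n_reps,
                           seed=cfg.seed + i)
        X, y = feature_matrix(population, c, label_by=label_by)
        out[i] = train_eval(X, y, c, shuffle=False).mean
    return out


def subset_curve(
    population: UnitRecording,
    n_grid: list[int],
    cfg: DecodingConfig,
    n_draws: int = 5,
    label_by: str = "freq",
) -> np.ndarray:
    """Mean accuracy over random unit subsets, per subset size."""
    X, y = feature_matrix(population, cfg, label_by=label_by)
    total = X.shape[1]
    rng = np.random.default_rng(cfg.seed)
    out = np.empty(len(n_grid))
    for i, n in enumerate(n_grid):
        if n > total:
            raise ValueError("subset size exceeds available units")
        accs = []
        draws = 1 if n == total else n_draws
        for d in range(draws):
            cols = rng.choice(total, size=n, replace=False)
            c = DecodingConfig(window_start=cfg.window_start, window_size=cfg.window_size,
                               train_frac=cfg.train_frac, n_reps=cfg.n_reps,
                               seed=cfg.seed + 1000 * i + d)
            accs.append(train_eval(X[:, cols], y, c, shuffle=False).mean)
        out[i] = float(np.mean(accs))
    return out


def _leave_one_per_type(X, y, rng, n_reps):
    """Repeated leave-one-per-type-out evaluation; yields (true, pred) pairs."""
    classes = np.unique(y)
    idx_by = {c: np.flatnonzero(y == c) for c in classes}
    results = []
    for _ in range(n_reps):
        held = np.array([rng.choice(idx_by[c]) for c in classes])
        mask = np.ones(y.size, dtype=bool)
        mask[held] = False
        clf = _make_clf()
        clf.fit(X[mask], y[mask])
        pred = clf.predict(X[held])
        results.append((y[held], pred))
    return classes, results


def pairwise_matrix(
    population: UnitRecording,
    cfg: DecodingConfig,
    label_by: str = "type",
    n_reps: int = 20,
) -> tuple[np.ndarray, np.ndarray]:
    """One-vs-one accuracy for every pair of trial types (chance 0.5).

    For each pair, classifiers train on all but one randomly held-out trial
    per type, repeatedly.  Diagonal entries split one type's trials into
    two arbitrary pseudo-classes, so they measure pure chance.
    Returns ``(types, matrix)``; the matrix is symmetric.
    """
    X, y = feature_matrix(population, cfg, label_by=label_by)
    types = np.unique(y)
    rng = np.random.default_rng(cfg.seed)
    M = np.full((types.size, types.size), np.nan)
    for i, a in enumerate(types):
        for j, b in enumerate(types):
            if j < i:
                continue
            if i == j:
                idx = np.flatnonzero(y == a)
                half = idx.size // 2
                if half < 2:
                    continue
                perm = rng.permutation(idx)
                Xi = X[perm]
                yi = np.array(["h0"] * half + ["h1"] * (idx.size - half))
            else:
                sel = (y == a) | (y == b)
                Xi, yi = X[sel], y[sel]
            _, res = _leave_one_per_type(Xi, yi, rng, n_reps)
            acc = float(np.mean([np.mean(t == p) for t, p in res]))
            M[i, j] = M[j, i] = acc
    return types, M


def confusion_matrix(
    population: UnitRecording,
    cfg: DecodingConfig,
    label_by: str = "type",
    n_reps: int = 20,
) -> tuple[np.ndarray, np.ndarray]:
    """Row-normalised confusion over all trial types (leave-one-per-type-out)."""
    X, y = feature_matrix(population, cfg, label_by=label_by)
    rng = np.random.default_rng(cfg.seed)
    classes, res = _leave_one_per_type(X, y, rng, n_reps)
    cls_index = {c: i for i, c in enumerate(classes)}
    conf = np.zeros((classes.size, classes.size))
    for t, p in res:
        for yt, yp in zip(t, p):
            conf[cls_index[yt], cls_index[yp]] += 1
    conf /= conf.sum(axis=1, keepdims=True)
    return classes, conf


def single_unit_accuracy(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    n_reps: int = 50,
    k: int = 5,
    seed: int = 0,
) -> float:
    """Stratified k-fold accuracy of a linear classifier on one unit's counts.

    ``counts_a``/``counts_b`` are per-trial 500 ms spike counts for the two
    stimulus classes (e.g. 2 Hz vs 20 Hz).  The k-fold shuffle is repeated
    ``n_reps`` times with different splits; the mean accuracy is returned.
    """
    a = np.asarray(counts_a, float)
    b = np.asarray(counts_b, float)
    if a.size < k or b.size < k:
        raise ValueError("need at least k trials per class")
    X = np.concatenate([a, b])[:, None]
    y = np.concatenate([np.zeros(a.size), np.ones(b.size)])
    rng = np.random.default_rng(seed)
    accs = []
    for _ in range(n_reps):
        skf = StratifiedKFold(n_splits=k, shuffle=True,
                              random_state=int(rng.integers(2**31)))
        for tr_idx, te_idx in skf.split(X, y):
            clf = _make_clf()
            clf.fit(X[tr_idx], y[tr_idx])
            accs.append(float(np.mean(clf.predict(X[te_idx]) == y[te_idx])))
    return float(np.mean(accs))
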