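"""Synthetic electrophysiology data with ground truth.

Generates the four raw ingredients the analysis pipeline consumes —
respiration flow, PID odour stimuli, whole-cell membrane potential and
extracellular spike trains — with the statistical structure the analyses
assume, plus ground-truth annotations (sniff onsets, preferred phases,
coupling gains, frequency tuning) for parameter-recovery tests.

Default study conditions
------------------------
* breathing 2.8 +/- 0.5 Hz (unit-recording animals) or 2.9 +/- 1.3 Hz
  (whole-cell animals), cycle-by-cycle lognormal jitter;
* square odour pulse trains at 2/5/10/15/20 Hz, 2 s trials, 50% duty,
  smoothed by a 10 ms first-order sensor/valve time constant;
* unit baseline rates lognormal with mean 11 Hz, SD 9 Hz;
* whole-cell RMP in [-60, -38] mV, input resistance in [45, 280] MOhm,
  depth in [180, 450] um;
* trials triggered at inhalation onset, >= 8 s inter-trial interval.

Signals are generated at 1 kHz by default: the analyses involve <= 20 Hz
content, so this is >= 25x Nyquist while keeping simulations desk-scale.
All operations downstream are rate-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import CellRecording, TimeSeries, Trial, Unit, UnitRecording
from .classify import classify_phase

__all__ = [
    "DEFAULT_FS",
    "UNIT_BREATHING",
    "WHOLECELL_BREATHING",
    "DEFAULT_FREQS",
    "StimulusSpec",
    "SynthCellSpec",
    "RespirationRecording",
    "PIDTrace",
    "CellSession",
    "UnitSession",
    "gen_respiration",
    "gen_pid",
    "gen_cell",
    "gen_unit_population",
    "design_trials",
    "make_cell_session",
    "make_unit_session",
]

DEFAULT_FS = 1000.0
#: Breathing rate (mean, SD) of the unit-recording animals, Hz.
UNIT_BREATHING = (2.8, 0.5)
#: Breathing rate (mean, SD) of the whole-cell animals, Hz.
WHOLECELL_BREATHING = (2.9, 1.3)
DEFAULT_FREQS = (2.0, 5.0, 10.0, 15.0, 20.0)

_INHALE_FRAC = 0.35  # fraction of the cycle occupied by inhalation
_EXHALE_FRAC = 0.40  # fraction occupied by exhalation; the rest is a pause
_EXHALE_AMP = 0.6  # exhalation lobe amplitude relative to inhalation
_SPIKE_AMP_MV = 40.0
_SPIKE_WIDTH_S = 0.002
_REFRACTORY_S = 0.003
_RATE_SLOPE_MV = 5.0  # e-fold of firing rate per mV of depolarisation
_ENV_RISE_S = 0.05  # odour-response envelope rise time constant
_ENV_DECAY_S = 0.5  # odour-response envelope decay time constant


@dataclass(frozen=True)
class StimulusSpec:
    """Square odour pulse train smoothed by first-order sensor/valve dynamics."""

    freq: float
    duration: float = 2.0
    duty: float = 0.5
    sensor_tau: float = 0.01
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.duty < 1:
            raise ValueError("duty must be in (0, 1)")
        if self.sensor_tau < 0:
            raise ValueError("sensor_tau must be non-negative")


@dataclass(frozen=True)
class SynthCellSpec:
    """Ground-truth parameters of one synthetic whole-cell neuron."""

    preferred_phase: float = 90.0  # degrees, peak of sniff-locked Vm oscillation
    osc_amp: float = 2.0  # mV
    coupling_gain_2hz: float = 0.5  # mV per unit PID
    coupling_gain_20hz: float = 0.3  # mV per unit PID
    response_sign: int = 1
    response_amp: float = 3.0  # mV
    noise_sd: float = 2.0  # mV
    baseline_rate: float = 11.0  # Hz
    rmp: float = -50.0  # mV
    rin: float = 150.0  # MOhm
    depth: float = 300.0  # um
    series_resistance: float = 10.0  # MOhm
    blank_gain: float = 0.05  # mV per unit PID, residual mechanical coupling
    seed: int = 0

    def __post_init__(self) -> None:
        if self.osc_amp < 0 or self.noise_sd < 0 or self.baseline_rate < 0:
            raise ValueError("osc_amp, noise_sd and baseline_rate must be >= 0")
        if not 0 <= self.preferred_phase < 360:
            raise ValueError("preferred_phase must be in [0, 360)")

    def coupling_gain(self, freq: float) -> float:
        """Stimulus-locked Vm gain at a pulse frequency (mV per unit PID).

        Exact at the two probed frequencies (2 and 20 Hz); log-linearly
        interpolated in between; the 2 Hz gain is used for unpatterned
        (constant) stimuli.
        """
        if freq <= 2.0:
            return self.coupling_gain_2hz
        if freq >= 20.0:
            return self.coupling_gain_20hz
        w = (np.log(freq) - np.log(2.0)) / (np.log(20.0) - np.log(2.0))
        return float((1 - w) * self.coupling_gain_2hz + w * self.coupling_gain_20hz)


@dataclass
class RespirationRecording:
    """Synthetic flow trace with ground-truth sniff landmarks."""

    ts: TimeSeries
    inh_onsets: np.ndarray
    inh_peaks: np.ndarray
    exh_peaks: np.ndarray
    periods: np.ndarray


@dataclass
class PIDTrace:
    """Synthetic PID odour trace with ground-truth pulse onsets."""

    ts: TimeSeries
    pulse_onsets: np.ndarray
    spec: StimulusSpec


def gen_respiration(
    rate_mean: float = UNIT_BREATHING[0],
    rate_sd: float = UNIT_BREATHING[1],
    duration: float = 60.0,
    fs: float = DEFAULT_FS,
    seed: int | np.random.Generator = 0,
) -> RespirationRecording:
    """Generate a flow-like respiration trace with cycle-by-cycle jitter.

    Cycle frequencies are drawn from a lognormal distribution with the given
    mean and SD, so the mean of 1/period across cycles is the requested
    ``rate_mean`` (what :func:`~odorpulse.respiration.sniff_rate` estimates).
    Each cycle is an asymmetric template: a fast negative inhalation lobe
    (40% of the cycle) followed by a slower, shallower positive exhalation
    lobe.  Inhalation deflects negative, matching the detection convention.
    """
    if not rate_mean > 0:
        raise ValueError("rate_mean must be positive")
    if rate_sd < 0:
        raise ValueError("rate_sd must be non-negative")
    if rate_sd > rate_mean:
        raise ValueError("rate_sd too large: cycle periods would degenerate")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    n_guess = int(np.ceil(duration * (rate_mean + 4 * rate_sd))) + 4
    if rate_sd == 0:
        freqs = np.full(n_guess, rate_mean)
    else:
        cv2 = (rate_sd / rate_mean) ** 2
        sigma = np.sqrt(np.log1p(cv2))
        mu = np.log(rate_mean) - sigma**2 / 2
        freqs = rng.lognormal(mu, sigma, n_guess)
    periods = 1.0 / freqs
    onsets = np.concatenate([[0.0], np.cumsum(periods)])
    keep = onsets[:-1] < duration
    onsets_k = onsets[:-1][keep]
    periods_k = periods[keep]

    n = int(round(duration * fs))
    t = np.arange(n) / fs
    idx = np.searchsorted(onsets_k, t, side="right") - 1
    s = t - onsets_k[idx]
    T = periods_k[idx]
    ti = _INHALE_FRAC * T
    te = _EXHALE_FRAC * T
    # fast negative inhalation lobe, slower positive exhalation lobe,
    # end-expiratory pause at zero flow
    flow = np.where(
        s < ti,
        -np.sin(np.pi * np.clip(s, 0, None) / ti),
        np.where(
            s < ti + te,
            _EXHALE_AMP * np.sin(np.pi * (s - ti) / te),
            0.0,
        ),
    )
    ts = TimeSeries(flow, fs=fs, t0=0.0, units="a.u.")
    ti_k = _INHALE_FRAC * periods_k
    te_k = _EXHALE_FRAC * periods_k
    return RespirationRecording(
        ts=ts,
        inh_onsets=onsets_k,
        inh_peaks=onsets_k + ti_k / 2,
        exh_peaks=onsets_k + ti_k + te_k / 2,
        periods=periods_k,
    )


def gen_pid(spec: StimulusSpec, fs: float = DEFAULT_FS) -> PIDTrace:
    """Generate a PID odour trace: square pulse train through a first-order sensor.

    The first-order response is computed with an exact exponential
    integrator, so sampled values equal the continuous RC response at the
    sample times for piecewise-constant input.
    """
    if spec.freq > 0 and fs < 10 * spec.freq:
        raise ValueError("fs must be at least 10x the pulse frequency")
    n = int(round(spec.duration * fs))
    t = np.arange(n) / fs
    if spec.freq == 0:
        x = np.full(n, spec.amplitude)
        onsets = np.array([0.0])
    else:
        period = 1.0 / spec.freq
        x = np.where((t % period) < spec.duty * period, spec.amplitude, 0.0)
        onsets = np.arange(0.0, spec.duration - 1e-12, period)
    if spec.sensor_tau > 0:
        from scipy.signal import lfilter

        a = np.exp(-1.0 / (fs * spec.sensor_tau))
        y = lfilter([1 - a], [1.0, -a], x)
    else:
        y = x
    return PIDTrace(TimeSeries(y, fs=fs, t0=0.0, units="a.u."), onsets, spec)


def design_trials(
    resp: RespirationRecording,
    odours: tuple[str, ...] = ("A", "B"),
    freqs: tuple[float, ...] = (2.0, 20.0),
    n_reps: int = 6,
    n_blank_reps: int | None = None,
    duration: float = 2.0,
    iti: float = 8.0,
    t_start: float = 30.0,
    condition: str = "control",
    seed: int | np.random.Generator = 0,
) -> list[Trial]:
    """Build an inhalation-triggered trial table.

    Conditions (odour x frequency, plus 'blank' at every frequency) are
    interleaved in random order.  Each onset snaps to the first ground-truth
    inhalation onset at or after the scheduled time; consecutive trials are
    separated by at least ``iti`` seconds (>= 8 s in the emulated design).
    """
    if iti < 0:
        raise ValueError("iti must be non-negative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if n_blank_reps is None:
        n_blank_reps = n_reps
    conds: list[tuple[str, float, bool]] = []
    for o in odours:
        for f in freqs:
            conds += [(o, f, False)] * n_reps
    for f in freqs:
        conds += [("blank", f, True)] * n_blank_reps
    order = rng.permutation(len(conds))
    cursor = t_start
    trials: list[Trial] = []
    for k in order:
        o, f, blank = conds[k]
        j = np.searchsorted(resp.inh_onsets, cursor, side="left")
        if j >= resp.inh_onsets.size or resp.inh_onsets[j] + duration > resp.ts.t_end:
            raise ValueError("respiration trace too short for the trial design")
        onset = float(resp.inh_onsets[j])
        trials.append(Trial(odour=o, freq=f, onset=onset, duration=duration, is_blank=blank,
                            condition=condition))
        cursor = onset + duration + iti
    return trials


def session_duration(n_trials: int, duration: float = 2.0, iti: float = 8.0,
                     t_start: float = 30.0) -> float:
    """Conservative respiration length needed for ``design_trials``."""
    return t_start + n_trials * (duration + iti + 1.0) + 5.0


def _phase_deg(resp: RespirationRecording, t: np.ndarray) -> np.ndarray:
    """Ground-truth respiration phase (0 deg at exhalation peak), unwrapped map."""
    ep = resp.exh_peaks
    ramp = 360.0 * np.arange(ep.size)
    return np.interp(t, ep, ramp)


def _response_envelope(t: np.ndarray, onset: float, duration: float) -> np.ndarray:
    """Difference-of-exponentials odour-response envelope, peak-normalised.

    The drive holds for the trial duration and decays after valve closure.
    """
    s = t - onset
    tp = (_ENV_RISE_S * _ENV_DECAY_S / (_ENV_DECAY_S - _ENV_RISE_S)
          * np.log(_ENV_DECAY_S / _ENV_RISE_S))
    norm = np.exp(-tp / _ENV_DECAY_S) - np.exp(-tp / _ENV_RISE_S)
    env = np.where(s >= 0, (np.exp(-np.clip(s, 0, None) / _ENV_DECAY_S)
                            - np.exp(-np.clip(s, 0, None) / _ENV_RISE_S)) / norm, 0.0)
    # after the valve closes, let the envelope continue its natural decay;
    # difference-of-exponentials already does so smoothly
    return env


def gen_cell(
    spec: SynthCellSpec,
    resp: RespirationRecording,
    trials: list[Trial],
    pid_bank: dict[float, TimeSeries],
    cell_id: str = "cell",
    store_clean: bool = True,
) -> CellRecording:
    """Generate a whole-cell membrane-potential recording.

    Vm = RMP + sniff-locked oscillation peaking at the preferred phase
    + per-trial odour-response envelope + stimulus-coupled PID component
    + Gaussian noise + stereotyped 2 ms spike waveforms drawn from an
    inhomogeneous rate process.  Ground truth (spike times, the spike-free
    trace, the spec) is stored in ``CellRecording.ground_truth``.
    """
    for tr in trials:
        if not tr.is_blank and tr.freq not in pid_bank:
            raise ValueError(f"trial frequency {tr.freq} missing from pid_bank")
    rng = np.random.default_rng(spec.seed)
    fs = resp.ts.fs
    n = resp.ts.n
    t = resp.ts.times()

    phase = _phase_deg(resp, t)
    osc = spec.osc_amp * np.cos(np.deg2rad(phase - spec.preferred_phase))

    drive = np.zeros(n)
    for tr in trials:
        gain = spec.blank_gain if tr.is_blank else spec.coupling_gain(tr.freq)
        pid = pid_bank.get(tr.freq)
        if pid is not None and gain != 0.0:
            i0 = resp.ts.index_of(tr.onset)
            m = min(pid.n, n - i0)
            drive[i0 : i0 + m] += gain * pid.samples[:m]
        if not tr.is_blank and spec.response_amp != 0.0:
            drive += spec.response_sign * spec.response_amp * _response_envelope(
                t, tr.onset, tr.duration
            )

    noise = rng.normal(0.0, spec.noise_sd, n) if spec.noise_sd > 0 else np.zeros(n)
    vm_nospike = spec.rmp + osc + drive + noise

    # inhomogeneous-rate spiking driven by the subthreshold deviation
    dev = osc + drive
    rate = spec.baseline_rate * np.exp(dev / _RATE_SLOPE_MV)
    np.clip(rate, 0.0, 200.0, out=rate)
    fire = rng.random(n) < rate / fs
    idx = np.flatnonzero(fire)
    if idx.size:
        min_gap = int(round(_REFRACTORY_S * fs))
        kept = [idx[0]]
        for i in idx[1:]:
            if i - kept[-1] >= min_gap:
                kept.append(i)
        idx = np.asarray(kept)
    # keep spikes clear of the trace edges so waveforms fit
    w = int(round(_SPIKE_WIDTH_S * fs))
    idx = idx[(idx > w) & (idx < n - w - 1)]
    spike_times = t[idx]

    vm = vm_nospike.copy()
    half = max(1, w // 2)
    wf = _SPIKE_AMP_MV * np.concatenate(
        [np.linspace(0, 1, half, endpoint=False), np.linspace(1, 0, w - half + 1)]
    )
    for i in idx:
        vm[i : i + wf.size] += wf[: n - i]

    gt = {
        "spec": spec,
        "spike_times": spike_times,
        "preferred_phase": spec.preferred_phase,
    }
    if store_clean:
        gt["vm_nospike"] = vm_nospike
        gt["vm_clean"] = spec.rmp + osc + drive
    return CellRecording(
        vm=TimeSeries(vm, fs=fs, t0=resp.ts.t0, units="mV"),
        resp=resp.ts,
        spike_times=spike_times,
        trials=list(trials),
        depth=spec.depth,
        rmp=spec.rmp,
        rin=spec.rin,
        series_resistance=spec.series_resistance,
        cell_id=cell_id,
        ground_truth=gt,
    )


def gen_unit_population(
    n_units: int,
    freq_tuning: list[dict[float, float]],
    trials: list[Trial],
    resp: RespirationRecording,
    seed: int = 0,
    baseline_rates: np.ndarray | None = None,
    pref_phases: np.ndarray | None = None,
    mod_depth: float = 0.6,
) -> UnitRecording:
    """Generate a population of extracellular units by thinned Poisson sampling.

    Each unit fires at ``baseline * (1 + mod_depth * cos(phase - pref))``
    plus a frequency-dependent odour-evoked rate change from
    ``freq_tuning[u]`` (full effect in the first 500 ms of a trial, half
    thereafter).  Blank trials evoke no odour component.  Baseline rates
    default to a lognormal with mean 11 Hz and SD 9 Hz.
    """
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    if len(freq_tuning) != n_units:
        raise ValueError("freq_tuning must have one entry per unit")
    if not 0 <= mod_depth < 1:
        raise ValueError("mod_depth must be in [0, 1)")
    rng = np.random.default_rng(seed)
    if baseline_rates is None:
        mean, sd = 11.0, 9.0
        sigma = np.sqrt(np.log1p((sd / mean) ** 2))
        mu = np.log(mean) - sigma**2 / 2
        baseline_rates = np.clip(rng.lognormal(mu, sigma, n_units), 0.2, 80.0)
    baseline_rates = np.asarray(baseline_rates, dtype=float)
    if pref_phases is None:
        # pTC-heavy mixture, matching the recorded population's skew
        draw = rng.random(n_units)
        pref_phases = np.where(
            draw < 0.66,
            rng.uniform(0.0, 160.0, n_units),
            np.where(draw < 0.92, rng.uniform(190.0, 350.0, n_units),
                     rng.uniform(0.0, 360.0, n_units)),
        )
    pref_phases = np.asarray(pref_phases, dtype=float)

    T = resp.ts.duration
    onsets = np.asarray([tr.onset for tr in trials])
    order = np.argsort(onsets)
    onsets = onsets[order]
    durations = np.asarray([tr.duration for tr in trials])[order]
    blanks = np.asarray([tr.is_blank for tr in trials])[order]
    trial_freqs = np.asarray([tr.freq for tr in trials])[order]

    units: list[Unit] = []
    for u in range(n_units):
        b = float(baseline_rates[u])
        tuning = {float(k): float(v) for k, v in freq_tuning[u].items()}
        dmax = max([0.0] + [abs(v) for v in tuning.values()])
        lam_max = b * (1 + mod_depth) + dmax
        n_cand = rng.poisson(lam_max * T)
        tc = np.sort(rng.uniform(0.0, T, n_cand))
        ph = np.deg2rad(_phase_deg(resp, tc) - pref_phases[u])
        lam = b * (1 + mod_depth * np.cos(ph))
        k = np.searchsorted(onsets, tc, side="right") - 1
        valid = k >= 0
        in_trial = valid & (tc < onsets[np.clip(k, 0, None)] + durations[np.clip(k, 0, None)])
        if np.any(in_trial):
            kk = k[in_trial]
            dt_on = tc[in_trial] - onsets[kk]
            delta = np.array([tuning.get(float(f), 0.0) for f in trial_freqs[kk]])
            delta = np.where(blanks[kk], 0.0, delta)
            lam_add = np.where(dt_on < 0.5, delta, 0.5 * delta)
            lam_in = lam[in_trial] + lam_add
            lam[in_trial] = lam_in
        np.clip(lam, 0.0, None, out=lam)
        accept = rng.random(n_cand) < lam / lam_max
        st = tc[accept]
        st = st[np.concatenate([[True], np.diff(st) > 0])] if st.size else st
        units.append(
            Unit(
                unit_id=u,
                spike_times=st,
                label="good",
                true_class=classify_phase(float(pref_phases[u])),
                ground_truth={
                    "baseline_rate": b,
                    "preferred_phase": float(pref_phases[u]),
                    "tuning": tuning,
                },
            )
        )
    return UnitRecording(
        units=units,
        resp=resp.ts,
        trials=[trials[i] for i in order],
        ground_truth={"pref_phases": pref_phases, "baseline_rates": baseline_rates},
    )


def random_cell_spec(rng: np.random.Generator, **overrides) -> SynthCellSpec:
    """Draw one realistic whole-cell spec.

    Preferred phases come from a pTC-heavy mixture; RMP, input resistance
    and depth are uniform over the recorded population's ranges; coupling
    gains are lognormal around the defaults.  Keyword overrides pin any
    field.
    """
    draw = rng.random()
    if draw < 0.45:
        pref = rng.uniform(0.0, 160.0)
    elif draw < 0.95:
        pref = rng.uniform(190.0, 350.0)
    else:
        pref = rng.uniform(0.0, 360.0)
    fields = dict(
        preferred_phase=float(pref),
        osc_amp=float(rng.uniform(1.0, 4.0)),
        coupling_gain_2hz=float(rng.lognormal(np.log(0.5), 0.5)),
        coupling_gain_20hz=float(rng.lognormal(np.log(0.3), 0.5)),
        response_sign=int(rng.choice([-1, 1])),
        response_amp=float(rng.uniform(1.0, 5.0)),
        noise_sd=2.0,
        baseline_rate=float(np.clip(rng.lognormal(np.log(8.0), 0.7), 0.5, 40.0)),
        rmp=float(rng.uniform(-60.0, -38.0)),
        rin=float(rng.uniform(45.0, 280.0)),
        depth=float(rng.uniform(180.0, 450.0)),
        seed=int(rng.integers(2**31)),
    )
    fields.update(overrides)
    return SynthCellSpec(**fields)


@dataclass
class CellSession:
    """One synthetic whole-cell session: cell, respiration truth, PID bank."""

    cell: CellRecording
    resp: RespirationRecording
    pid_bank: dict[float, TimeSeries]
    pid_traces: dict[float, PIDTrace] = field(default_factory=dict)


@dataclass
class UnitSession:
    """One synthetic unit-recording session."""

    population: UnitRecording
    resp: RespirationRecording
    pid_bank: dict[float, TimeSeries]


def make_cell_session(
    spec: SynthCellSpec,
    odours: tuple[str, ...] = ("A", "B"),
    freqs: tuple[float, ...] = (2.0, 20.0),
    n_reps: int = 6,
    iti: float = 8.0,
    t_start: float = 30.0,
    fs: float = DEFAULT_FS,
    breathing: tuple[float, float] = WHOLECELL_BREATHING,
    sensor_tau: float = 0.01,
    trial_duration: float = 2.0,
    cell_id: str = "cell",
) -> CellSession:
    """Generate a complete whole-cell session for one synthetic neuron.

    Respiration, the trial table (inhalation-triggered, randomised order,
    blanks at every frequency) and the PID bank all derive from
    ``spec.seed``, so a session is bit-for-bit reproducible.
    """
    ss = np.random.SeedSequence(spec.seed)
    s_resp, s_design = ss.spawn(2)
    n_trials = (len(odours) + 1) * len(freqs) * n_reps
    dur = session_duration(n_trials, trial_duration, iti, t_start)
    resp = gen_respiration(breathing[0], breathing[1], dur, fs,
                           np.random.default_rng(s_resp))
    trials = design_trials(resp, odours, freqs, n_reps, duration=trial_duration,
                           iti=iti, t_start=t_start,
                           seed=np.random.default_rng(s_design))
    pid_traces = {
        f: gen_pid(StimulusSpec(freq=f, duration=trial_duration, sensor_tau=sensor_tau), fs)
        for f in freqs
    }
    pid_bank = {f: p.ts for f, p in pid_traces.items()}
    cell = gen_cell(spec, resp, trials, pid_bank, cell_id=cell_id)
    return CellSession(cell=cell, resp=resp, pid_bank=pid_bank, pid_traces=pid_traces)


def make_unit_session(
    n_units: int = 50,
    odours: tuple[str, ...] = ("EB", "2H", "AA", "EU"),
    freqs: tuple[float, ...] = DEFAULT_FREQS,
    n_reps: int = 32,
    include_blank: bool = True,
    freq_tuning: list[dict[float, float]] | None = None,
    iti: float = 8.0,
    t_start: float = 30.0,
    fs: float = DEFAULT_FS,
    breathing: tuple[float, float] = UNIT_BREATHING,
    sensor_tau: float = 0.01,
    trial_duration: float = 2.0,
    seed: int = 0,
) -> UnitSession:
    """Generate a complete unit-recording session.

    With the emulated full design (4 odours, 5 frequencies, 32 repeats plus
    a blank at every frequency) the trial table holds 800 trials.  Zero
    tuning (the default) gives an untuned population suitable for chance
    calibration.
    """
    ss = np.random.SeedSequence(seed)
    s_resp, s_design, s_pop = ss.spawn(3)
    if freq_tuning is None:
        freq_tuning = [{} for _ in range(n_units)]
    n_blank_reps = n_reps if include_blank else 0
    n_trials = len(odours) * len(freqs) * n_reps + len(freqs) * n_blank_reps
    dur = session_duration(n_trials, trial_duration, iti, t_start)
    resp = gen_respiration(breathing[0], breathing[1], dur, fs,
                           np.random.default_rng(s_resp))
    trials = design_trials(resp, odours, freqs, n_reps, n_blank_reps=n_blank_reps,
                           duration=trial_duration, iti=iti, t_start=t_start,
                           seed=np.random.default_rng(s_design))
    pop = gen_unit_population(
        n_units, freq_tuning, trials, resp,
        seed=s_pop.generate_state(1)[0] % (2**31),
    )
    pid_bank = {
        f: gen_pid(StimulusSpec(freq=f, duration=trial_duration, sensor_tau=sensor_tau), fs).ts
        for f in freqs
    }
    return UnitSession(population=pop, resp=resp, pid_bank=pid_bank)
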