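"""Spike clipping, baseline templates, phase-matched subtraction, response metrics."""

import numpy as np
import pytest

from odorpulse import synthetic as synth
from odorpulse.core import TimeSeries, window
from odorpulse.respiration import SniffCycle
from odorpulse.vm import (
    build_baseline_template,
    classify_mixture_response,
    clip_spikes,
    corrected_window,
    prepare_cell,
    response_metrics,
    subtract_baseline,
)


def _truth_cycles(resp, stop=None):
    zs = zip(resp.inh_onsets[:-1], resp.inh_peaks[:-1], resp.exh_peaks[:-1],
             resp.inh_onsets[1:])
    out = [
        SniffCycle(o, p, (o + e) / 2, e, o, o2)
        for o, p, e, o2 in zs
        if stop is None or o2 <= stop
    ]
    return out


class TestClipSpikes:
    def test_no_spikes_is_identity(self):
        ts = TimeSeries(np.random.default_rng(0).normal(size=1000), fs=1000.0)
        assert clip_spikes(ts, []) is ts

    def test_recovers_spike_free_truth(self):
        spec = synth.SynthCellSpec(baseline_rate=20.0, noise_sd=1.0, seed=40)
        sess = synth.make_cell_session(spec, odours=("A",), freqs=(2.0,), n_reps=2)
        cell = sess.cell
        clipped = clip_spikes(cell.vm, cell.spike_times)
        err = clipped.samples - cell.ground_truth["vm_nospike"]
        # interpolation across clip windows leaves residuals bounded by noise
        assert np.sqrt(np.mean(err**2)) < 2 * spec.noise_sd

    def test_adjacent_spikes_merge(self):
        x = np.zeros(1000)
        ts = TimeSeries(x, fs=1000.0)
        out = clip_spikes(ts, [0.100, 0.101])  # windows overlap -> one span
        assert out.n == ts.n
        np.testing.assert_allclose(out.samples, 0.0, atol=1e-12)

    def test_spike_outside_span_rejected(self):
        ts = TimeSeries(np.zeros(100), fs=1000.0)
        with pytest.raises(ValueError):
            clip_spikes(ts, [5.0])


class TestBaselineTemplate:
    def test_sinusoid_self_consistency(self):
        resp = synth.gen_respiration(2.0, 0.0, 40.0, 1000.0, seed=41)
        spec = synth.SynthCellSpec(preferred_phase=45.0, osc_amp=3.0, noise_sd=0.0,
                                   response_amp=0.0, coupling_gain_2hz=0.0,
                                   coupling_gain_20hz=0.0, baseline_rate=0.0, seed=42)
        cell = synth.gen_cell(spec, resp, [], {})
        cycles = _truth_cycles(resp)
        tmpl = build_baseline_template(cell.vm, cycles[:40])
        win = window(cell.vm, 25.0, 30.0)
        resid = subtract_baseline(win, tmpl, cycles).vm_corrected.samples
        assert np.sqrt(np.mean(resid**2)) < 1e-9

    def test_template_error_scales_with_clt(self):
        # sinusoid + white noise, ~100 cycles: per-bin template error ~ sd/10
        resp = synth.gen_respiration(2.0, 0.0, 55.0, 1000.0, seed=43)
        noise_sd = 2.0
        spec = synth.SynthCellSpec(preferred_phase=0.0, osc_amp=3.0, noise_sd=noise_sd,
                                   response_amp=0.0, coupling_gain_2hz=0.0,
                                   coupling_gain_20hz=0.0, baseline_rate=0.0,
                                   rmp=0.0, seed=44)
        cell = synth.gen_cell(spec, resp, [], {})
        cycles = _truth_cycles(resp)
        tmpl = build_baseline_template(cell.vm, cycles[:100], min_cycles=5)
        centres = (np.arange(360) + 0.5)
        true = 3.0 * np.cos(np.deg2rad(centres))
        err = tmpl.grid - true
        rms = np.sqrt(np.mean(err**2))
        assert 0.02 * noise_sd < rms < 0.25 * noise_sd

    def test_template_peak_matches_preferred_phase(self, coupled_prep, coupled_session):
        grid = coupled_prep.template.grid
        peak = (np.argmax(grid) + 0.5)
        true = coupled_session.cell.ground_truth["preferred_phase"]
        d = abs(peak - true)
        assert min(d, 360 - d) < 15.0

    def test_too_few_cycles_rejected(self):
        resp = synth.gen_respiration(2.0, 0.0, 2.0, 1000.0, seed=45)
        cell = synth.gen_cell(synth.SynthCellSpec(seed=46), resp, [], {})
        with pytest.raises(ValueError):
            build_baseline_template(cell.vm, _truth_cycles(resp))


class TestSubtraction:
    def test_residual_bounded_by_noise(self, coupled_prep):
        # stimulus-free stretch: residual RMS < 1.2 x generator noise SD
        prep = coupled_prep
        t0 = prep.cell.trials[0].onset
        resid = corrected_window(prep, t0 - 10.0, t0 - 2.0)
        noise_sd = prep.cell.ground_truth["spec"].noise_sd
        assert np.sqrt(np.mean(resid**2)) < 1.2 * noise_sd

    def test_recovers_injected_pid_component(self):
        # high coupling gain, low noise: the corrected trace is dominated by
        # the stimulus-locked component
        spec = synth.SynthCellSpec(coupling_gain_2hz=5.0, noise_sd=0.5,
                                   response_amp=0.0, baseline_rate=0.0, seed=47)
        sess = synth.make_cell_session(spec, odours=("A",), freqs=(2.0,), n_reps=3)
        prep = prepare_cell(sess.cell)
        tr = next(t for t in sess.cell.trials if not t.is_blank)
        resid = corrected_window(prep, tr.onset, tr.onset + tr.duration)
        pid = sess.pid_bank[2.0].samples
        r = np.corrcoef(resid, pid)[0, 1]
        assert r > 0.9

    def test_dvm_invariant_to_sniff_locked_component(self):
        # two cells identical except for the oscillation phase/amplitude:
        # baseline subtraction removes it, so dVm agrees
        dvms = []
        for pref, amp in ((30.0, 1.0), (260.0, 4.0)):
            spec = synth.SynthCellSpec(preferred_phase=pref, osc_amp=amp,
                                       response_amp=4.0, noise_sd=0.0,
                                       coupling_gain_2hz=0.0, coupling_gain_20hz=0.0,
                                       baseline_rate=0.0, seed=48)
            sess = synth.make_cell_session(spec, odours=("A",), freqs=(2.0,), n_reps=3)
            prep = prepare_cell(sess.cell)
            tr = next(t for t in sess.cell.trials if not t.is_blank)
            m = response_metrics(prep, tr)
            dvms.append(m.dvm)
        assert dvms[0] == pytest.approx(dvms[1], abs=0.3)


class TestResponseMetrics:
    def test_dvm_monotone_in_response_amp(self):
        got = []
        for amp in (0.0, 2.0, 4.0):
            spec = synth.SynthCellSpec(response_amp=amp, noise_sd=1.0,
                                       coupling_gain_2hz=0.0, coupling_gain_20hz=0.0,
                                       baseline_rate=0.0, seed=49)
            sess = synth.make_cell_session(spec, odours=("A",), freqs=(2.0,), n_reps=4)
            prep = prepare_cell(sess.cell)
            trs = [t for t in sess.cell.trials if not t.is_blank]
            got.append(np.mean([response_metrics(prep, t).dvm for t in trs]))
        assert got[0] < got[1] < got[2]

    def test_psth_sums_to_spike_count(self, coupled_prep):
        prep = coupled_prep
        tr = next(t for t in prep.cell.trials if not t.is_blank)
        m = response_metrics(prep, tr)
        total = np.sum(
            (prep.cell.spike_times >= tr.onset - 2.0)
            & (prep.cell.spike_times < tr.onset + 2.0)
        )
        assert m.psth.sum() * 0.05 == pytest.approx(total)

    def test_requires_blanks_and_pre_span(self, coupled_prep):
        prep = coupled_prep
        tr = next(t for t in prep.cell.trials if not t.is_blank)
        from odorpulse.core import Trial

        orphan = Trial(odour=tr.odour, freq=99.0, onset=tr.onset)
        with pytest.raises(ValueError):
            response_metrics(prep, orphan)

    def test_series_resistance_qc(self):
        spec = synth.SynthCellSpec(series_resistance=30.0, seed=50)
        sess = synth.make_cell_session(spec, odours=("A",), freqs=(2.0,), n_reps=2)
        with pytest.raises(ValueError):
            prepare_cell(sess.cell)


@pytest.mark.parametrize(
    "a,b,expect",
    [
        (2.0, 3.0, "Ex-Ex"),
        (2.0, -3.0, "Ex-In"),
        (-1.0, -1.0, "In-In"),
        (-1.0, 2.0, "Ex-In"),
    ],
)
def test_mixture_labels(a, b, expect):
    assert classify_mixture_response(a, b) == expect


def test_mixture_unclassified_without_significance():
    assert classify_mixture_response(2.0, 3.0, sig_a=False) == "unclassified"
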