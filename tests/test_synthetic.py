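"""Generators: reproducibility, stimulus structure, ground-truth consistency."""

import numpy as np
import pytest

from odorpulse import synthetic as synth
from odorpulse.stimulus import fidelity


class TestRespirationGenerator:
    def test_bit_for_bit_reproducible(self):
        a = synth.gen_respiration(2.8, 0.5, 30.0, 1000.0, seed=9)
        b = synth.gen_respiration(2.8, 0.5, 30.0, 1000.0, seed=9)
        np.testing.assert_array_equal(a.ts.samples, b.ts.samples)
        np.testing.assert_array_equal(a.inh_onsets, b.inh_onsets)

    def test_zero_jitter_is_periodic(self):
        resp = synth.gen_respiration(2.0, 0.0, 10.0, 1000.0, seed=0)
        periods = np.diff(resp.inh_onsets)
        np.testing.assert_allclose(periods, 0.5, atol=1e-12)
        assert len(resp.inh_onsets) == 20

    def test_truth_landmark_ordering(self):
        resp = synth.gen_respiration(2.9, 1.3, 60.0, 1000.0, seed=1)
        assert np.all(resp.inh_peaks > resp.inh_onsets)
        assert np.all(resp.exh_peaks > resp.inh_peaks)

    def test_rejects_degenerate_jitter(self):
        with pytest.raises(ValueError):
            synth.gen_respiration(2.0, 3.0, 10.0, 1000.0, seed=0)


class TestPIDGenerator:
    def test_ideal_square_has_unit_fidelity(self):
        p = synth.gen_pid(synth.StimulusSpec(freq=5.0, sensor_tau=0.0), 1000.0)
        assert fidelity(p.ts, p.pulse_onsets, 0.0).mean == pytest.approx(1.0)

    def test_lowpass_degrades_fast_frequencies_more(self):
        f2 = synth.gen_pid(synth.StimulusSpec(freq=2.0, sensor_tau=0.02), 1000.0)
        f20 = synth.gen_pid(synth.StimulusSpec(freq=20.0, sensor_tau=0.02), 1000.0)
        m2 = fidelity(f2.ts, f2.pulse_onsets, 0.0).mean
        m20 = fidelity(f20.ts, f20.pulse_onsets, 0.0).mean
        assert m20 < m2

    def test_total_integral_frequency_independent(self):
        # equal duty and duration: inhaled odour volume does not depend on
        # the pulse frequency when the sensor is fast
        ints = [
            synth.gen_pid(synth.StimulusSpec(freq=f, sensor_tau=0.001), 1000.0).ts.samples.sum()
            for f in (2.0, 5.0, 10.0, 15.0, 20.0)
        ]
        assert (max(ints) - min(ints)) / np.mean(ints) < 0.02

    def test_integral_proportional_to_duty(self):
        lo = synth.gen_pid(synth.StimulusSpec(freq=5.0, duty=0.25, sensor_tau=0.0), 1000.0)
        hi = synth.gen_pid(synth.StimulusSpec(freq=5.0, duty=0.5, sensor_tau=0.0), 1000.0)
        assert hi.ts.samples.sum() == pytest.approx(2 * lo.ts.samples.sum(), rel=0.01)

    def test_rejects_undersampled(self):
        with pytest.raises(ValueError):
            synth.gen_pid(synth.StimulusSpec(freq=20.0), fs=100.0)


class TestTrialDesign:
    def test_emulated_full_design_has_800_trials(self):
        # 32 repeats x 5 frequencies x (4 odours + blank)
        resp = synth.gen_respiration(2.8, 0.0, 8600.0, 100.0, seed=2)
        trials = synth.design_trials(
            resp, odours=("EB", "2H", "AA", "EU"),
            freqs=(2.0, 5.0, 10.0, 15.0, 20.0), n_reps=32, seed=3,
        )
        assert len(trials) == 800
        assert sum(t.is_blank for t in trials) == 160

    def test_iti_and_inhalation_trigger(self):
        resp = synth.gen_respiration(2.8, 0.5, 400.0, 1000.0, seed=4)
        trials = synth.design_trials(resp, odours=("A",), freqs=(2.0,), n_reps=3,
                                     iti=8.0, seed=5)
        by_onset = sorted(trials, key=lambda t: t.onset)
        for a, b in zip(by_onset, by_onset[1:]):
            assert b.onset - (a.onset + a.duration) >= 8.0 - 1e-9
        for t in trials:
            assert np.min(np.abs(resp.inh_onsets - t.onset)) < 1e-9

    def test_too_short_recording_rejected(self):
        resp = synth.gen_respiration(2.8, 0.0, 40.0, 500.0, seed=6)
        with pytest.raises(ValueError):
            synth.design_trials(resp, odours=("A",), freqs=(2.0,), n_reps=10, seed=7)


class TestCellGenerator:
    def test_flat_cell_is_flat(self):
        resp = synth.gen_respiration(2.0, 0.0, 20.0, 1000.0, seed=8)
        spec = synth.SynthCellSpec(osc_amp=0.0, noise_sd=0.0, response_amp=0.0,
                                   coupling_gain_2hz=0.0, coupling_gain_20hz=0.0,
                                   baseline_rate=0.0, rmp=-52.0, seed=9)
        cell = synth.gen_cell(spec, resp, [], {})
        np.testing.assert_allclose(cell.vm.samples, -52.0, atol=1e-12)
        assert cell.spike_times.size == 0

    def test_session_reproducible(self):
        spec = synth.SynthCellSpec(seed=33)
        a = synth.make_cell_session(spec, odours=("A",), freqs=(2.0,), n_reps=3)
        b = synth.make_cell_session(spec, odours=("A",), freqs=(2.0,), n_reps=3)
        np.testing.assert_array_equal(a.cell.vm.samples, b.cell.vm.samples)
        assert [t.onset for t in a.cell.trials] == [t.onset for t in b.cell.trials]

    def test_spike_waveforms_recorded_in_truth(self):
        spec = synth.SynthCellSpec(baseline_rate=15.0, seed=10)
        sess = synth.make_cell_session(spec, odours=("A",), freqs=(2.0,), n_reps=2)
        gt = sess.cell.ground_truth
        assert gt["spike_times"].size == sess.cell.spike_times.size
        # the recorded trace differs from the spike-free truth only at spikes
        diff = sess.cell.vm.samples - gt["vm_nospike"]
        assert np.count_nonzero(diff) > 0
        assert diff.min() >= 0.0  # spike waveforms only add


class TestUnitGenerator:
    def test_baseline_rate_distribution(self):
        sess = synth.make_unit_session(n_units=200, odours=("EB",), freqs=(2.0,),
                                       n_reps=2, seed=12)
        rates = sess.population.ground_truth["baseline_rates"]
        # lognormal with mean 11 Hz, SD 9 Hz (clipped)
        assert abs(np.mean(rates) - 11.0) < 2.0
        assert 5.0 < np.std(rates) < 13.0

    def test_blank_trials_evoke_nothing(self):
        tuning = [{2.0: 40.0}]
        sess = synth.make_unit_session(n_units=1, odours=("EB",), freqs=(2.0,),
                                       n_reps=24, freq_tuning=tuning, seed=13)
        pop = sess.population
        u = pop.good_units()[0]
        od = [t for t in pop.trials if not t.is_blank]
        bl = [t for t in pop.trials if t.is_blank]
        n_od = np.mean([np.sum((u.spike_times >= t.onset) & (u.spike_times < t.onset + 2)) for t in od])
        n_bl = np.mean([np.sum((u.spike_times >= t.onset) & (u.spike_times < t.onset + 2)) for t in bl])
        assert n_od > n_bl + 5
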