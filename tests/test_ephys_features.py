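"""Current-clamp feature extraction against constructed and simulated truth."""

import numpy as np
import pytest

from conftest import add_triangular_spike, flat_sweep, make_sweep, rc_step_sweep
from nphys import ephys_features as ef
from nphys.ephys_synth import LifParams, simulate_protocol


class TestRmp:
    def test_constant_trace(self):
        assert ef.measure_rmp(flat_sweep(-65.0)) == pytest.approx(-65.0)

    def test_step_excluded_from_baseline(self):
        sw = rc_step_sweep(rmp=-70.0, amplitude_pa=50.0)
        assert ef.measure_rmp(sw) == pytest.approx(-70.0)

    def test_noisy_baseline_mean(self, rng):
        # 200 ms baseline at 10 kHz: SE of the mean = 0.2/sqrt(2000)
        sw = rc_step_sweep(rmp=-62.0, onset=200.0, noise_sigma=0.2, rng=rng)
        assert ef.measure_rmp(sw) == pytest.approx(-62.0, abs=0.05)

    def test_short_baseline_rejected(self):
        sw = rc_step_sweep(onset=30.0)
        with pytest.raises(ValueError, match="baseline"):
            ef.measure_rmp(sw)


def _subthreshold_set(r_mohm, tau_ms, noise=0.0, rng=None):
    return [rc_step_sweep(r_mohm=r_mohm, tau_ms=tau_ms, amplitude_pa=a,
                          noise_sigma=noise, rng=rng)
            for a in (-30, -20, -10, 0, 10, 20)]


class TestInputResistance:
    def test_noiseless_exact_recovery(self):
        sweeps = _subthreshold_set(150.0, 12.0)
        assert ef.fit_input_resistance(sweeps) == pytest.approx(150.0, abs=0.1)

    def test_zero_deflection_gives_zero(self):
        sweeps = [rc_step_sweep(r_mohm=1e-9, amplitude_pa=a)
                  for a in (-30, -20, -10)]
        assert ef.fit_input_resistance(sweeps) == pytest.approx(0.0, abs=1e-6)

    def test_too_few_sweeps_rejected(self):
        with pytest.raises(ValueError):
            ef.fit_input_resistance(_subthreshold_set(150.0, 12.0)[:2])

    def test_zero_current_spread_rejected(self):
        sweeps = [rc_step_sweep(amplitude_pa=-10.0) for _ in range(3)]
        with pytest.raises(ValueError, match="spread"):
            ef.fit_input_resistance(sweeps)

    def test_noisy_recovery_within_sampling_error(self):
        # R=200, tau=15, sigma=0.3 mV: mean estimate within 2% over seeds
        rng = np.random.default_rng(7)
        est = [ef.fit_input_resistance(
            _subthreshold_set(200.0, 15.0, noise=0.3, rng=rng))
            for _ in range(30)]
        assert np.mean(est) == pytest.approx(200.0, rel=0.02)
        assert np.std(est) < 4.0


class TestMembraneTau:
    def test_noiseless_exponential(self):
        sweeps = _subthreshold_set(150.0, 12.0)
        assert ef.fit_membrane_tau(sweeps) == pytest.approx(12.0, rel=0.01)

    def test_mean_of_identical_sweeps(self):
        sweeps = [rc_step_sweep(tau_ms=8.0, amplitude_pa=-30.0),
                  rc_step_sweep(tau_ms=8.0, amplitude_pa=-20.0)]
        assert ef.fit_membrane_tau(sweeps) == pytest.approx(8.0, rel=0.01)

    def test_requires_hyperpolarizing_sweep(self):
        with pytest.raises(ValueError, match="hyperpolarizing"):
            ef.fit_membrane_tau([rc_step_sweep(amplitude_pa=10.0)])

    def test_noisy_recovery(self):
        rng = np.random.default_rng(11)
        est = [ef.fit_membrane_tau(
            _subthreshold_set(200.0, 15.0, noise=0.3, rng=rng))
            for _ in range(30)]
        assert np.mean(est) == pytest.approx(15.0, abs=1.0)


class TestCapacitance:
    @pytest.mark.parametrize("r,tau,cm", [(200.0, 10.0, 50.0),
                                          (150.0, 15.0, 100.0),
                                          (1.0, 1.0, 1000.0)])
    def test_closed_form(self, r, tau, cm):
        assert ef.compute_capacitance(r, tau) == pytest.approx(cm)

    def test_unit_round_trip(self):
        # Cm * R = tau (pF * MOhm = ms * 1000) to machine precision
        r, tau = 173.4, 21.7
        assert ef.compute_capacitance(r, tau) * r == pytest.approx(
            tau * 1000.0, rel=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            ef.compute_capacitance(-1.0, 10.0)


class TestDetectAps:
    def test_flat_trace_empty(self):
        assert ef.detect_aps(flat_sweep(-65.0)) == []

    def test_single_bump_to_zero(self):
        sw = add_triangular_spike(flat_sweep(-65.0), 300.0, peak_v=0.0)
        events = ef.detect_aps(sw)
        assert len(events) == 1
        assert events[0].peak_time == pytest.approx(300.0)
        assert events[0].peak_voltage == pytest.approx(0.0)

    def test_subthreshold_bump_ignored(self):
        # peaks at -30 mV, only 35 mV above baseline: fails both criteria
        sw = add_triangular_spike(flat_sweep(-65.0), 300.0, peak_v=-30.0)
        assert ef.detect_aps(sw) == []

    def test_amplitude_criterion_without_voltage_criterion(self):
        # peak -15 mV from -90 baseline: 75 mV amplitude qualifies
        sw = add_triangular_spike(flat_sweep(-90.0), 300.0, peak_v=-15.0)
        assert len(ef.detect_aps(sw)) == 1

    @pytest.mark.parametrize("amplitude", [0, 40, 100, 200, 400])
    def test_count_matches_lif_spike_log(self, amplitude):
        params = LifParams(noise_sigma=0.3, seed=99)
        sweeps, log = simulate_protocol(
            params, ef.StepProtocolSpec.excitability_20pa())
        by_amp = {s.stimulus_amplitude: s for s in sweeps}
        assert len(ef.detect_aps(by_amp[amplitude])) == \
            len(log[float(amplitude)])


class TestApFeatures:
    def test_triangular_spike_slope_symmetry(self):
        sw = add_triangular_spike(flat_sweep(-65.0), 300.0, peak_v=0.0)
        ev = ef.ap_features(sw, 300.0)
        assert ev.max_rise_slope == pytest.approx(-ev.max_decay_slope)
        assert ev.max_rise_slope > 0 and ev.max_decay_slope < 0

    def test_threshold_at_constructed_crossing(self):
        # two-segment upstroke: slope 0.8 mV/ms (below 5% of 64), then
        # 64 mV/ms; the 5% crossing sits at the segment boundary
        khz = 10.0
        n = int(700 * khz) + 1
        v = np.full(n, -70.0)
        i0 = int(300 * khz)          # slow ramp start
        i1 = i0 + int(5 * khz)       # fast upstroke start: -66 mV
        i2 = i1 + int(1 * khz)       # peak: -2 mV
        v[i0:i1 + 1] = np.linspace(-70.0, -66.0, i1 - i0 + 1)
        v[i1:i2 + 1] = np.linspace(-66.0, -2.0, i2 - i1 + 1)
        v[i2:i2 + int(1 * khz) + 1] = np.linspace(-2.0, -70.0,
                                                  int(1 * khz) + 1)
        sw = make_sweep(v, sampling_khz=khz)
        ev = ef.ap_features(sw, sw.time[i2])
        assert abs(ev.threshold_time - sw.time[i1]) <= 1.0 / khz + 1e-9
        assert ev.threshold_voltage == pytest.approx(-66.0, abs=0.8)

    def test_amplitude_is_peak_minus_nadir(self):
        khz = 10.0
        n = int(700 * khz) + 1
        v = np.full(n, -65.0)
        ip = int(300 * khz)
        nr = int(1 * khz)
        v[ip - nr:ip + 1] = np.linspace(-65.0, 20.0, nr + 1)
        v[ip:ip + nr + 1] = np.linspace(20.0, -75.0, nr + 1)   # to the nadir
        v[ip + nr:ip + 3 * nr + 1] = np.linspace(-75.0, -65.0, 2 * nr + 1)
        sw = make_sweep(v, sampling_khz=khz)
        ev = ef.ap_features(sw, sw.time[ip])
        assert ev.amplitude == pytest.approx(95.0, abs=0.5)
        assert ev.fahp_voltage == pytest.approx(-75.0, abs=0.5)

    def test_half_width_of_symmetric_spike(self):
        # linear rise/fall 1 ms each: width at any level between
        # threshold and peak is twice the fractional distance
        sw = add_triangular_spike(flat_sweep(-65.0), 300.0, peak_v=0.0)
        ev = ef.ap_features(sw, 300.0)
        assert ev.half_width is not None
        assert 0.0 < ev.half_width < 2.0


class TestExcitabilityProfile:
    def test_latency_and_isi_arithmetic(self):
        onset = 100.0
        rheo = flat_sweep(-65.0, onset=onset, amplitude=100.0)
        add_triangular_spike(rheo, onset + 50.0)
        target = flat_sweep(-65.0, onset=onset, amplitude=200.0)
        add_triangular_spike(target, onset + 8.8)
        add_triangular_spike(target, onset + 19.3)
        prof = ef.excitability_profile([rheo, target])
        assert prof.rheobase == 100.0
        assert prof.latency_first_ap == pytest.approx(8.8, abs=0.11)
        assert prof.first_isi == pytest.approx(10.5, abs=0.11)

    def test_all_silent_profile_flagged(self):
        sweeps = [flat_sweep(-65.0, amplitude=a) for a in (0.0, 100.0)]
        prof = ef.excitability_profile(sweeps)
        assert prof.rheobase is None
        assert "no_aps" in prof.flags

    def test_lif_closed_form_rheobase(self):
        # (V_th - E_L)/R = 100 pA lands exactly on the 20 pA grid
        params = LifParams(e_l=-70.0, r_in=200.0, v_th=-50.0, tau=15.0)
        sweeps, _ = simulate_protocol(
            params, ef.StepProtocolSpec.excitability_20pa())
        prof = ef.excitability_profile(sweeps)
        assert prof.rheobase == 100.0

    def test_rheobase_monotone_in_lif_threshold(self):
        grid = ef.StepProtocolSpec.excitability_20pa()
        rheos = []
        for v_th in (-55.0, -50.0, -45.0, -40.0):
            params = LifParams(v_th=v_th, tau=10.0)
            sweeps, _ = simulate_protocol(params, grid)
            rheos.append(ef.excitability_profile(sweeps).rheobase)
        assert rheos == sorted(rheos)


class TestClassifyFs:
    @pytest.mark.parametrize("tau,count,expected", [
        (10.0, 50, "FS"),
        (15.0, 50, "non_FS"),      # strict: tau must be below 15
        (10.0, 35, "non_FS"),      # strict: count must exceed 35
        (14.9, 36, "FS"),
        (20.0, 10, "non_FS"),
    ])
    def test_criterion(self, tau, count, expected):
        assert ef.classify_fs(tau, count) == expected

    def test_missing_input_unclassified(self):
        assert ef.classify_fs(None, 50) == "unclassified"
        assert ef.classify_fs(10.0, None) == "unclassified"

    def test_pure_function(self):
        assert ef.classify_fs(10.0, 50) == ef.classify_fs(10.0, 50)


def _summary(rmp=-70.0, rin=150.0, tau=10.0, ra=10.0, max_count=40):
    passive = ef.PassiveProperties(rmp, rin, tau,
                                   ef.compute_capacitance(rin, tau))
    profile = ef.ExcitabilityProfile(io_curve={400.0: max_count},
                                     rheobase=100.0)
    return ef.NeuronSummary("c1", "WT", passive, profile,
                            access_resistance=ra)


class TestQcNeuron:
    def test_all_criteria_pass(self):
        s = ef.qc_neuron(_summary())
        assert s.qc_included and s.qc_reasons == []

    @pytest.mark.parametrize("kw,reason", [
        ({"rmp": -54.0}, "RMP"),
        ({"rin": 1200.0}, "input resistance"),
        ({"ra": 30.0}, "access resistance"),
        ({"max_count": 1}, "evoked APs"),
    ])
    def test_each_exclusion(self, kw, reason):
        s = ef.qc_neuron(_summary(**kw))
        assert not s.qc_included
        assert reason in s.qc_reasons

    def test_high_ra_kept_if_stable(self):
        # Ra 30 MOhm but only 10% drift across the recording
        s = ef.qc_neuron(_summary(ra=30.0), access_resistance_end=33.0)
        assert s.qc_included

    def test_excluded_iff_reasons(self):
        for s in (ef.qc_neuron(_summary()),
                  ef.qc_neuron(_summary(rmp=-50.0, rin=1500.0))):
            assert s.qc_included == (len(s.qc_reasons) == 0)
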