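"""Generator contracts: determinism, planted parameters, input validation."""

import numpy as np
import pytest

from asicephys import features, kinetics, plasticity, synth
from asicephys.behavior import conditioning_day1, freezing_percent, session_summary


class TestStepFamily:
    def test_unknown_phenotype_lists_valid_names(self):
        with pytest.raises(ValueError, match="accommodating.*fast_spiking"):
            synth.PhenotypeSpec("bursty")

    def test_same_seed_same_config_identical_samples(self):
        spec = synth.PhenotypeSpec("stuttering", gap_jitter_ms=40.0)
        fam1 = synth.gen_step_family(spec, synth.SimConfig(seed=11, noise_mv=0.5))
        fam2 = synth.gen_step_family(spec, synth.SimConfig(seed=11, noise_mv=0.5))
        for a, b in zip(fam1, fam2):
            np.testing.assert_array_equal(a.samples, b.samples)

    def test_different_seeds_differ(self):
        spec = synth.PhenotypeSpec("accommodating")
        fam1 = synth.gen_step_family(spec, synth.SimConfig(seed=1, noise_mv=0.5))
        fam2 = synth.gen_step_family(spec, synth.SimConfig(seed=2, noise_mv=0.5))
        assert not np.array_equal(fam1[0].samples, fam2[0].samples)

    def test_planted_accommodating_ratio_round_trip(self, cfg):
        spec = synth.PhenotypeSpec("accommodating", accommodation_factor=2.0)
        fam = synth.gen_step_family(spec, cfg)
        feats = features.extract_features(fam)
        assert feats.accommodating_ratio == pytest.approx(2.0, rel=2e-2)

    def test_late_spiking_planted_delay_on_2s_step(self, cfg_2s):
        spec = synth.PhenotypeSpec("late_spiking", first_spike_delay_ms=1769.0)
        fam = synth.gen_step_family(spec, cfg_2s)
        rheo = next(s for s in fam if s.injected_pa == spec.rheobase_pa)
        train = features.detect_spikes(rheo)
        assert train.times_ms[0] == pytest.approx(1769.0, abs=0.2)

    def test_delay_exceeding_step_rejected(self, cfg):
        spec = synth.PhenotypeSpec("late_spiking", first_spike_delay_ms=1769.0)
        with pytest.raises(ValueError, match="delay"):
            synth.gen_step_family(spec, cfg)

    def test_hyperpolarizing_deflection_encodes_input_resistance(self, cfg):
        spec = synth.PhenotypeSpec("fast_spiking", input_resistance_mohm=150.0)
        fam = synth.gen_step_family(spec, cfg)
        hyper = next(s for s in fam if s.injected_pa == -50.0)
        assert features.input_resistance(hyper) == pytest.approx(150.0, rel=1e-6)

    def test_nonmonotone_steps_rejected(self):
        cfg = synth.SimConfig(step_amps_pa=(50.0, 25.0))
        with pytest.raises(ValueError, match="increasing"):
            synth.gen_step_family(synth.PhenotypeSpec("accommodating"), cfg)


class TestASICCurrent:
    def test_trace_minimum_is_planted_peak_at_onset(self, cfg):
        sw = synth.gen_asic_current(-500.0, 300.0, -20.0, (0.1, 1.0), cfg)
        assert sw.samples.min() == pytest.approx(-500.0)
        assert sw.time_s[np.argmin(sw.samples)] == pytest.approx(0.1, abs=sw.dt)
        assert np.all(sw.samples[sw.time_s < 0.1] == 0.0)

    def test_negative_duration_rejected(self, cfg):
        with pytest.raises(ValueError, match="duration"):
            synth.gen_asic_current(-500.0, 300.0, -20.0, (0.1, -1.0), cfg)

    def test_noisy_trace_reproducible(self):
        a = synth.gen_asic_current(-500.0, 300.0, -20.0, (0.1, 1.0),
                                   synth.SimConfig(seed=5, noise_pa=5.0))
        b = synth.gen_asic_current(-500.0, 300.0, -20.0, (0.1, 1.0),
                                   synth.SimConfig(seed=5, noise_pa=5.0))
        np.testing.assert_array_equal(a.samples, b.samples)


class TestPhResponse:
    def test_half_maximal_at_planted_ph50(self, cfg, hill_wt):
        tab = synth.gen_ph_response(hill_wt, [6.3], 0.0, cfg)
        assert tab["response"].iloc[0] == pytest.approx(0.5)

    @pytest.mark.parametrize("ph,expected", [(5.0, 0.9954), (7.4, 0.0103)])
    def test_direct_evaluation_points(self, cfg, hill_wt, ph, expected):
        tab = synth.gen_ph_response(hill_wt, [ph], 0.0, cfg)
        assert tab["response"].iloc[0] == pytest.approx(expected, abs=1e-4)

    def test_empty_ph_values_rejected(self, cfg, hill_wt):
        with pytest.raises(ValueError, match="non-empty"):
            synth.gen_ph_response(hill_wt, [], 0.0, cfg)


class TestIVPoints:
    def test_zero_current_at_reversal_even_without_curvature(self, cfg):
        tab = synth.gen_iv_points(67.8, np.arange(-60.0, 91.0, 30.0), 0.0, cfg)
        interp = np.interp(67.8, tab["v_mv"], tab["i_pa"])
        assert interp == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_grid_odd_currents_at_zero_reversal(self, cfg):
        v = np.array([-60.0, -30.0, 0.0, 30.0, 60.0])
        tab = synth.gen_iv_points(0.0, v, 0.0, cfg)
        np.testing.assert_allclose(tab["i_pa"].to_numpy(),
                                   -tab["i_pa"].to_numpy()[::-1], atol=1e-12)

    def test_reversal_outside_span_rejected(self, cfg):
        with pytest.raises(ValueError, match="span"):
            synth.gen_iv_points(120.0, np.arange(-60.0, 91.0, 30.0), 0.0, cfg)

    def test_round_trip_through_fit_reversal(self, cfg):
        tab = synth.gen_iv_points(61.0, np.arange(-60.0, 91.0, 30.0), 0.02, cfg)
        assert kinetics.fit_reversal(tab).vrev_mv == pytest.approx(61.0, abs=1e-6)


class TestTachyphylaxis:
    def test_second_pulse_amplitude_closed_form(self, cfg):
        tab = synth.gen_tachyphylaxis_series(8.9, 0.2, 20.0, 5, cfg)
        expected = 0.2 + 0.8 * np.exp(-20.0 / 8.9)
        assert tab["amplitude"].iloc[1] == pytest.approx(expected)
        assert tab["amplitude"].iloc[0] == 1.0

    def test_unit_plateau_means_no_decay(self, cfg):
        tab = synth.gen_tachyphylaxis_series(10.0, 1.0, 20.0, 5, cfg)
        np.testing.assert_allclose(tab["amplitude"], 1.0)

    def test_too_few_pulses_rejected(self, cfg):
        with pytest.raises(ValueError, match="3 pulses"):
            synth.gen_tachyphylaxis_series(10.0, 0.2, 20.0, 2, cfg)


class TestLTPSeries:
    def test_noiseless_plateau_maps_to_magnitude(self, cfg):
        series = synth.gen_ltp_series(1.0, 2.11, 5.0, 35.0, cfg)
        assert plasticity.ltp_magnitude(series).magnitude_percent == pytest.approx(211.0)

    def test_unit_plateau_means_100_percent(self, cfg):
        series = synth.gen_ltp_series(1.0, 1.0, 5.0, 35.0, cfg)
        assert plasticity.ltp_magnitude(series).magnitude_percent == pytest.approx(100.0)

    def test_rs_drift_beyond_20_percent_flagged(self, cfg):
        series = synth.gen_ltp_series(1.0, 2.0, 5.0, 35.0, cfg, rs_drift=0.25)
        assert plasticity.qc_series(series).passed is False

    def test_nonpositive_plateau_rejected(self, cfg):
        with pytest.raises(ValueError, match="plateau"):
            synth.gen_ltp_series(1.0, 0.0, 5.0, 35.0, cfg)


class TestFreezingSession:
    def test_zero_fraction_gives_zero_percent_everywhere(self, cfg):
        proto = conditioning_day1()
        ses = synth.gen_freezing_session(proto, [0.0] * len(proto.epochs), 5.0, cfg)
        assert (session_summary(ses)["freezing_percent"] == 0.0).all()

    def test_unit_fraction_gives_single_spanning_bout(self, cfg):
        proto = conditioning_day1()
        fractions = [1.0] + [0.0] * (len(proto.epochs) - 1)
        ses = synth.gen_freezing_session(proto, fractions, 5.0, cfg)
        assert freezing_percent(ses, "H") == pytest.approx(100.0)

    def test_fixed_seed_identical_bouts(self):
        proto = conditioning_day1()
        fr = [0.3] * len(proto.epochs)
        a = synth.gen_freezing_session(proto, fr, 5.0, synth.SimConfig(seed=3))
        b = synth.gen_freezing_session(proto, fr, 5.0, synth.SimConfig(seed=3))
        assert a.bouts == b.bouts

    def test_fraction_count_mismatch_rejected(self, cfg):
        with pytest.raises(ValueError, match="epochs"):
            synth.gen_freezing_session(conditioning_day1(), [0.5], 5.0, cfg)


class TestCohort:
    def test_zero_like_dispersion_gives_separated_types(self, cfg):
        specs = [
            (synth.PhenotypeSpec("fast_spiking", max_rate_hz=120.0), 5,
             {"spike_delay_ms": 1e-6, "max_rate_hz": 1e-6,
              "accommodating_ratio": 1e-6, "max_cv_isi_ratio": 1e-6}),
            (synth.PhenotypeSpec("accommodating", max_rate_hz=30.0), 5,
             {"spike_delay_ms": 1e-6, "max_rate_hz": 1e-6,
              "accommodating_ratio": 1e-6, "max_cv_isi_ratio": 1e-6}),
        ]
        tab = synth.gen_cohort(specs, cfg)
        rates = tab.groupby("phenotype")["max_rate_hz"].mean()
        assert rates["fast_spiking"] == pytest.approx(120.0, abs=1e-3)
        assert rates["accommodating"] == pytest.approx(30.0, abs=1e-3)

    def test_nonpositive_dispersion_rejected(self, cfg):
        specs = [(synth.PhenotypeSpec("accommodating"), 3, {"spike_delay_ms": 0.0})]
        with pytest.raises(ValueError, match="positive"):
            synth.gen_cohort(specs, cfg)

    def test_ground_truth_labels_retained(self, cfg):
        tab = synth.gen_cohort(synth.bla_cohort_specs(), cfg)
        assert len(tab) == 72
        assert set(tab["phenotype"]) == {
            "accommodating", "stuttering", "delay_firing", "fast_spiking"
        }
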