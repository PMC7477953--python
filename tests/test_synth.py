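"""Ground-truth structure and determinism of the synthetic cohorts."""

import numpy as np
import pytest

import laminarpac as lp
from laminarpac.synth import sr_phase_deg


def _quick_spec(**kw):
    defaults = dict(n_animals=1, duration_s=30.0, fs=1000.0, seed=3)
    defaults.update(kw)
    return lp.CohortSpec(**defaults)


class TestDeterminism:
    def test_same_seed_byte_identical(self):
        a = lp.make_cohort(_quick_spec(), lp.sham_effects())
        b = lp.make_cohort(_quick_spec(), lp.sham_effects())
        assert np.array_equal(a.recordings[0].lfp, b.recordings[0].lfp)
        for ua, ub in zip(a.ca1_units + a.ms_units, b.ca1_units + b.ms_units):
            assert np.array_equal(ua.spike_times_s, ub.spike_times_s)
            assert np.array_equal(ua.mean_waveform, ub.mean_waveform)

    def test_different_seed_differs(self):
        a = lp.make_cohort(_quick_spec(seed=1), lp.sham_effects(), with_units=False)
        b = lp.make_cohort(_quick_spec(seed=2), lp.sham_effects(), with_units=False)
        assert not np.array_equal(a.recordings[0].lfp, b.recordings[0].lfp)


class TestLaminarStructure:
    def test_pure_tone_mode_peaks_at_tone_frequency(self, rng):
        fx = lp.sham_effects(sr_pure_tone_hz=12.0, theta_amp_uv=0.0,
                             hfo_amp_uv=0.0, noise_uv=1e-6, mua_amp_uv=0.0)
        rec, truth = lp.gen_laminar_lfp(_quick_spec(duration_s=10.0), fx, rng)
        ps = lp.welch_psd(rec)
        for ch in range(rec.n_channels):
            if ps.mean_power()[ch].max() < 1e-6:
                continue  # nodes of the depth profile carry no signal
            assert ps.freqs[np.argmax(ps.mean_power()[ch])] == pytest.approx(12.0)

    def test_phase_reversal_across_sp(self, rng):
        rec, truth = lp.gen_laminar_lfp(
            _quick_spec(), lp.sham_effects(noise_uv=1e-6, theta_amp_uv=0.0,
                                           hfo_amp_uv=0.0, mua_amp_uv=0.0), rng)
        sp = truth["sp_channel"]
        deep = rec.lfp[sp + 9]
        shallow = rec.lfp[max(sp - 4, 0)]
        r = np.corrcoef(deep, shallow)[0, 1]
        assert r < -0.95  # sign-inverted above SP

    def test_sr_amplitude_profile_peaks_in_sr(self, rng):
        rec, truth = lp.gen_laminar_lfp(
            _quick_spec(), lp.sham_effects(noise_uv=1e-6, theta_amp_uv=0.0,
                                           hfo_amp_uv=0.0, mua_amp_uv=0.0), rng)
        rms = rec.lfp.std(axis=1)
        assert np.argmax(rms) == truth["sr_peak_channel"]

    def test_truth_phase_matches_trough_times(self, rng):
        rec, truth = lp.gen_laminar_lfp(_quick_spec(), lp.sham_effects(), rng)
        ph = sr_phase_deg(truth, truth["trough_times"])
        # troughs sit at +/-180 deg of the carrier phase
        assert np.mean(np.abs(np.abs(ph) - 180.0) < 25.0) > 0.9

    def test_pac_off_decouples_burst_amplitude_from_phase(self, rng):
        import pingouin as pg

        fx = lp.sham_effects(pac_depth=0.0)
        _, truth = lp.gen_laminar_lfp(_quick_spec(duration_s=120.0), fx, rng)
        phases = np.radians(sr_phase_deg(truth, truth["burst_times"]))
        r = pg.circ_corrcl(phases, truth["burst_amps"])[0]
        assert abs(r) < 0.1

    def test_pac_on_couples_burst_amplitude_to_trough(self, rng):
        fx = lp.sham_effects(pac_depth=0.9)
        _, truth = lp.gen_laminar_lfp(_quick_spec(duration_s=60.0), fx, rng)
        ph = np.radians(sr_phase_deg(truth, truth["burst_times"]))
        amps = truth["burst_amps"]
        near = amps[np.abs(np.abs(ph) - np.pi) < 0.5]
        far = amps[np.abs(ph) < 0.5]
        assert near.mean() > 2.0 * far.mean()


class TestSpikeGenerators:
    def test_refractory_period_respected(self, sham_cohort):
        for u in sham_cohort.ca1_units + sham_cohort.ms_units:
            if u.n_spikes > 1:
                assert np.diff(u.spike_times_s).min() >= 0.001

    def test_pyramidal_rate_matches_target(self, rng):
        spec = _quick_spec(duration_s=300.0, n_pyr=10, n_int=0)
        fx = lp.sham_effects()
        rec, truth = lp.gen_laminar_lfp(spec, fx, rng)
        units = lp.gen_ca1_units(spec, fx, truth, rng)
        for u in units:
            target = u.truth["rate_hz"]
            measured = u.n_spikes / 300.0
            # Poisson counting error plus burst/refractory bookkeeping
            assert abs(measured - target) < 4.0 * np.sqrt(target / 300.0) + 0.1

    def test_high_kappa_concentrates_phases(self, rng):
        spec = _quick_spec(duration_s=60.0)
        fx = lp.sham_effects()
        _, truth = lp.gen_laminar_lfp(spec, fx, rng)
        from laminarpac.synth import _vm_modulated_train

        times = _vm_modulated_train(rng, 5.0, 60.0, truth, mu_deg=193.8, kappa=50.0)
        ph = sr_phase_deg(truth, times)
        _, r = lp.resultant(ph)
        assert r > 0.9

    def test_zero_kappa_phases_uniform(self, rng):
        spec = _quick_spec(duration_s=120.0)
        fx = lp.sham_effects()
        _, truth = lp.gen_laminar_lfp(spec, fx, rng)
        from laminarpac.synth import _vm_modulated_train

        rejections = 0
        for _ in range(40):
            times = _vm_modulated_train(rng, 8.0, 120.0, truth, mu_deg=0.0, kappa=0.0)
            p, _ = lp.rayleigh_test(sr_phase_deg(truth, times))
            rejections += p < 0.05
        assert rejections <= 6  # ~ alpha * 40 with slack

    def test_ms_inflected_ratio_exceeds_noninflected(self):
        from laminarpac.synth import _template
        from laminarpac.classify import ms_spectral_ratio

        wf_fs = 32000.0
        plain = _template(wf_fs, 0.15)
        inflected = _template(wf_fs, 0.15, bump_amp=0.45)
        assert (ms_spectral_ratio(inflected * 100, wf_fs)
                > 3.0 * ms_spectral_ratio(plain * 100, wf_fs))

    def test_ms_rate_increase_detectable_at_study_n(self):
        """Welch t on generated MS GABA/Glu rate draws at the study's n."""
        from scipy.stats import ttest_ind
        from laminarpac.synth import _lognormal

        sham_fx, inj_fx = lp.sham_effects(), lp.injured_effects()
        hits = 0
        reps = 25
        master = np.random.default_rng(42)
        for _ in range(reps):
            r = np.random.default_rng(master.integers(2**31))
            a = [_lognormal(r, sham_fx.ms_gaba_rate_hz, sham_fx.ms_gaba_rate_sd,
                            sham_fx.ms_gaba_rate_bounds) for _ in range(82)]
            b = [_lognormal(r, inj_fx.ms_gaba_rate_hz, inj_fx.ms_gaba_rate_sd,
                            inj_fx.ms_gaba_rate_bounds) for _ in range(143)]
            _, p = ttest_ind(a, b, equal_var=False)
            hits += p < 0.05
        assert hits >= int(0.6 * reps)

    def test_ms_flat_psth_without_inhibition(self, rng):
        spec = _quick_spec(duration_s=120.0, n_ms_gaba=6, n_ms_chol=0)
        fx = lp.sham_effects(ms_inhibition_depth=0.0)
        _, truth = lp.gen_laminar_lfp(spec, fx, rng)
        units = lp.gen_ms_units(spec, fx, truth, rng)
        probs = [lp.psth(u, truth["trough_times"]).prob for u in units]
        p = np.mean(probs, axis=0)
        centers = (np.arange(50) - 24.5) * 2.0
        dip = p[(centers >= 12) & (centers <= 20)].mean()
        base = p[centers < 0].mean()
        assert dip > 0.8 * base
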