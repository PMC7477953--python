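"""Spike-phase entrainment: phase sampling, resultant entrainment, fast MI."""

import numpy as np
import pytest

import laminarpac as lp
from laminarpac.core import SpikeUnit


FS = 1000.0


def _tone(f, dur=20.0, amp=50.0):
    t = np.arange(0, dur, 1 / FS)
    return t, amp * np.cos(2 * np.pi * f * t)


class TestSpikePhases:
    def test_spikes_at_troughs_read_180(self):
        t, x = _tone(10.0)
        troughs = np.arange(0.05, 19.5, 0.1)  # cos troughs at 0.05 + k/10
        ph = lp.spike_phases(SpikeUnit("u", troughs), x, FS, (5, 15))
        assert np.all(np.abs(np.abs(ph) - 180.0) < 6.0)

    def test_spikes_at_peaks_read_zero(self):
        t, x = _tone(10.0)
        peaks = np.arange(0.5, 19.5, 0.1)
        ph = lp.spike_phases(SpikeUnit("u", peaks), x, FS, (5, 15))
        assert np.all(np.abs(ph) < 6.0)

    def test_uniform_spikes_uniform_phases(self, rng):
        from scipy.stats import chisquare

        t, x = _tone(10.0, dur=60.0)
        hits = 0
        for _ in range(100):
            times = np.sort(rng.uniform(1.0, 59.0, 400))
            ph = lp.spike_phases(SpikeUnit("u", times), x, FS, (5, 15))
            counts, _ = np.histogram(ph, bins=12, range=(-180, 180))
            hits += chisquare(counts)[1] < 0.05
        assert hits <= 12  # ~5% type-I with slack

    def test_edge_spikes_dropped(self):
        t, x = _tone(10.0, dur=2.0)
        ph = lp.spike_phases(SpikeUnit("u", np.array([0.01, 1.0, 1.99])), x, FS,
                             (5, 15))
        assert ph.size == 1


class TestEntrainUnit:
    def test_locked_unit_entrained_with_correct_angle(self, rng):
        t, x = _tone(10.0, dur=60.0)
        troughs = np.arange(0.05, 59.0, 0.1)
        jitter = rng.normal(0, 0.004, troughs.size)
        unit = SpikeUnit("u", np.sort(troughs + jitter))
        er = lp.entrain_unit(unit, x, FS, band=(5, 15))
        assert er.entrained
        assert min(abs(er.mean_angle_deg - 180.0), abs(er.mean_angle_deg + 180.0),
                   abs(er.mean_angle_deg - 540.0)) < 15.0
        assert er.resultant_length > 0.8

    def test_uniform_unit_not_entrained_most_runs(self, rng):
        t, x = _tone(10.0, dur=30.0)
        flags = 0
        for _ in range(50):
            unit = SpikeUnit("u", np.sort(rng.uniform(1, 29, 300)))
            flags += lp.entrain_unit(unit, x, FS, band=(5, 15)).entrained
        assert flags <= 7

    def test_entrainment_channel_mapping(self):
        # 425 um at 50 um spacing: half-spacing tie resolves toward SP (8 below)
        assert lp.entrainment_channel(6, 50.0) == 14
        assert lp.entrainment_channel(6, 25.0) == 23
        assert lp.entrainment_channel(6, 100.0) == 10


class TestFastEntrainment:
    def test_locked_spikes_peak_at_lock_frequency(self, rng):
        dur = 60.0
        t = np.arange(0, dur, 1 / FS)
        x = 30 * np.cos(2 * np.pi * 225 * t) + rng.standard_normal(t.size)
        peaks = np.arange(1, dur - 1, 1 / 225.0)
        times = peaks[rng.uniform(size=peaks.size) < 0.02]
        # slight timing jitter breaks the lattice alias between the periodic
        # spike grid and off-lock analysis frequencies
        times = np.sort(times + rng.normal(0, 3e-4, times.size))
        freqs = np.arange(150.0, 301.0, 5.0)
        prof = lp.fast_entrainment_mi(SpikeUnit("u", times), x, FS, freqs=freqs)
        # a 10-cycle wavelet tracks a strong tone across neighbouring
        # frequencies, so the profile is a plateau centred on the lock: the
        # lock frequency is strongly modulated and the band edges fall off
        at = {f: m for f, m in zip(freqs, prof.mi)}
        assert at[225.0] > 0.3
        assert at[150.0] < 0.2 * at[225.0]

    def test_poisson_spikes_flat_profile(self, rng):
        dur = 60.0
        t = np.arange(0, dur, 1 / FS)
        x = 30 * np.cos(2 * np.pi * 225 * t) + rng.standard_normal(t.size)
        times = np.sort(rng.uniform(1, dur - 1, 600))
        prof = lp.fast_entrainment_mi(SpikeUnit("u", times), x, FS,
                                      freqs=np.arange(150.0, 301.0, 10.0))
        assert prof.mi.max() < 0.02

    def test_counts_sum_to_spike_count(self, rng):
        t = np.arange(0, 30, 1 / FS)
        x = rng.standard_normal(t.size)
        times = np.sort(rng.uniform(1, 29, 500))
        prof = lp.fast_entrainment_mi(SpikeUnit("u", times), x, FS,
                                      freqs=[100.0, 200.0])
        assert np.all(prof.phase_counts.sum(axis=1) == times.size)

    def test_requires_100_spikes(self, rng):
        with pytest.raises(ValueError):
            lp.fast_entrainment_mi(SpikeUnit("u", np.linspace(1, 2, 50)),
                                   rng.standard_normal(5000), FS, freqs=[50.0])

    def test_mi_rotation_invariance(self, rng):
        """Rotating all phases by a whole bin leaves the profile unchanged."""
        from laminarpac.entrain import FastEntrainmentProfile  # noqa: F401
        t = np.arange(0, 30, 1 / FS)
        x = 20 * np.cos(2 * np.pi * 50 * t)
        times = np.sort(rng.uniform(1, 29, 400))
        prof1 = lp.fast_entrainment_mi(SpikeUnit("u", times), x, FS, freqs=[50.0])
        shift = (1.0 / 50.0) * (20.0 / 360.0)  # one 20-deg bin at 50 Hz
        prof2 = lp.fast_entrainment_mi(SpikeUnit("u", times + shift), x, FS,
                                       freqs=[50.0])
        assert prof1.mi[0] == pytest.approx(prof2.mi[0], abs=5e-3)


class TestGeneratorEntrainmentRecovery:
    def test_sham_pyramidal_resultant_near_target(self, sham_cohort, sham_aligned):
        Rs, angles = [], []
        for rec in sham_cohort.recordings:
            sr_idx = lp.entrainment_channel(sham_aligned.sp_aligned_index,
                                            rec.spacing_um)
            chan = rec.lfp[sham_aligned.window_map[rec.animal_id][sr_idx]]
            for u in sham_cohort.units_for(rec.animal_id):
                if u.truth["subtype"] != "pyramidal" or u.n_spikes < 30:
                    continue
                er = lp.entrain_unit(u, chan, rec.fs)
                Rs.append(er.resultant_length)
                angles.append(er.mean_angle_deg)
        assert np.mean(Rs) == pytest.approx(0.24, abs=0.06)
        mean_dir = np.degrees(np.angle(np.mean(
            np.exp(1j * np.radians(angles))))) % 360
        assert abs(mean_dir - 193.8) < 25.0

    def test_most_sham_pyramidal_units_entrained(self, sham_cohort, sham_aligned):
        n, hit = 0, 0
        for rec in sham_cohort.recordings:
            sr_idx = lp.entrainment_channel(sham_aligned.sp_aligned_index,
                                            rec.spacing_um)
            chan = rec.lfp[sham_aligned.window_map[rec.animal_id][sr_idx]]
            for u in sham_cohort.units_for(rec.animal_id):
                if u.n_spikes < 150:
                    continue
                n += 1
                hit += lp.entrain_unit(u, chan, rec.fs).entrained
        assert n >= 8 and hit / n > 0.7
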