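"""Waveform/burstiness features and subtype classifiers."""

import numpy as np
import pytest

import laminarpac as lp
from laminarpac.classify import (
    CA1Label,
    acorr_first_moment,
    assign_layer,
    classify_ca1,
    ms_spectral_ratio,
    spike_width_25,
    two_means_split,
)
from laminarpac.core import SpikeUnit


class TestLayerAssignment:
    def test_band_geometry(self):
        assert assign_layer(10, 10, 32) == ("SP", False)
        assert assign_layer(12, 10, 32) == ("SP", False)
        assert assign_layer(7, 10, 32) == ("SO", True)    # adjacent to band
        assert assign_layer(13, 10, 32) == ("SR", True)
        assert assign_layer(20, 10, 32) == ("SR", False)
        assert assign_layer(4, 10, 32) == ("SO", False)

    def test_out_of_probe_rejected(self):
        with pytest.raises(ValueError):
            assign_layer(40, 10, 32)


class TestSpikeWidth:
    wf_fs = 32000.0

    def _grid_ms(self, n=160):
        return np.arange(n) * 1000.0 / self.wf_fs  # 5 ms window

    def test_triangular_pulse_closed_form(self):
        # triangle of base 1.0 ms: width at 25% height is 0.75 ms
        t = self._grid_ms()
        peak_ms, half_base = 2.5, 0.5
        wf = np.clip(1.0 - np.abs(t - peak_ms) / half_base, 0.0, None)
        assert spike_width_25(wf, self.wf_fs) == pytest.approx(0.75, abs=0.01)

    def test_gaussian_pulse_closed_form(self):
        t = self._grid_ms()
        sigma = 0.2
        wf = np.exp(-0.5 * ((t - 2.5) / sigma) ** 2)
        expected = 2 * sigma * np.sqrt(2 * np.log(4))  # ~0.666 ms
        assert spike_width_25(wf, self.wf_fs) == pytest.approx(expected, abs=0.01)

    def test_negative_going_spike_same_width(self):
        t = self._grid_ms()
        wf = -np.exp(-0.5 * ((t - 2.5) / 0.2) ** 2)
        assert spike_width_25(wf, self.wf_fs) == pytest.approx(
            2 * 0.2 * np.sqrt(2 * np.log(4)), abs=0.01)

    def test_flat_trace_undefined(self):
        assert np.isnan(spike_width_25(np.zeros(160), self.wf_fs))


class TestAcorrMoment:
    def test_point_mass_at_burst_lag(self):
        # doublets: every lag mass in the 4-6 ms bin (center 5 ms)
        base = np.arange(0, 50, 0.5)
        times = np.sort(np.concatenate([base, base + 0.005]))
        m = acorr_first_moment(times, max_lag_ms=50, bin_ms=2)
        # dominated by the 5 ms bin; cross-pair lags contribute the rest
        assert m < 15.0

    def test_uniform_lag_mass_centered(self, rng):
        # lags uniform on (0, 50]: moment ~ 25 ms
        times = np.sort(rng.uniform(0, 1000.0, 4000))
        m = acorr_first_moment(times)
        assert m == pytest.approx(25.0, abs=1.5)

    def test_poisson_trains_near_25ms(self, rng):
        moments = []
        for _ in range(100):
            times = np.sort(rng.uniform(0, 200.0, 1000))  # 5 Hz Poisson
            moments.append(acorr_first_moment(times))
        assert np.mean(moments) == pytest.approx(25.0, abs=1.0)

    def test_empty_histogram_undefined(self):
        assert np.isnan(acorr_first_moment(np.array([0.0, 10.0])))


class TestTwoMeansSplit:
    def test_separates_two_clusters(self, rng):
        v = np.r_[rng.normal(1.0, 0.1, 50), rng.normal(5.0, 0.3, 40)]
        thr = two_means_split(v)
        assert 1.5 < thr < 4.5

    def test_deterministic_under_permutation(self, rng):
        v = rng.normal(0, 1, 100)
        assert two_means_split(v) == two_means_split(rng.permutation(v))


def _unit(uid, times, wf, max_channel, wf_fs=32000.0):
    return SpikeUnit(uid, np.asarray(times), mean_waveform=wf, wf_fs=wf_fs,
                     max_channel=max_channel)


class TestClassifyCA1:
    def test_full_recovery_on_well_separated_cohort(self):
        spec = lp.CohortSpec(n_animals=2, duration_s=120.0, fs=1000.0, seed=11,
                             n_pyr=10, n_int=9)
        cohort = lp.make_cohort(spec, lp.well_separated_effects())
        al = lp.align_to_pyramidale(cohort.recordings)
        for rec in cohort.recordings:
            units = cohort.units_for(rec.animal_id)
            labels = classify_ca1(units, al.sp_indices[rec.animal_id],
                                  duration_s=120.0)
            for u, lab in zip(units, labels):
                assert lab.subtype == u.truth["subtype"]

    def test_outside_sp_is_interneuron_regardless_of_features(self, rng):
        """A wide, bursty, slow unit deep in SR is still an interneuron."""
        from laminarpac.synth import _multichannel_waveform

        pyr_wf = _multichannel_waveform(rng, 32000.0, "pyramidal", 50.0)
        int_wf = _multichannel_waveform(rng, 32000.0, "interneuron", 50.0)
        base = np.arange(0, 100, 2.0)
        times = np.sort(np.concatenate([base, base + 0.004]))
        unit = _unit("deep", times, pyr_wf, max_channel=20)
        # pair with contrasting SP units so the feature thresholds are learnable
        sp_pyr = _unit("sp_p", times + 0.0003, pyr_wf, max_channel=10)
        sp_int = _unit("sp_i", np.sort(rng.uniform(0, 100, 800)), int_wf,
                       max_channel=10)
        labels = classify_ca1([unit, sp_pyr, sp_int], sp_index=10,
                              duration_s=100.0)
        assert labels[0].subtype == "interneuron" and labels[0].layer == "SR"

    def test_border_interneuron_reassigned_next_to_pyramidal(self, rng):
        from laminarpac.synth import _multichannel_waveform

        pyr_wf = _multichannel_waveform(rng, 32000.0, "pyramidal", 50.0)
        int_wf = _multichannel_waveform(rng, 32000.0, "interneuron", 50.0)
        base = np.arange(0, 120, 1.0)
        bursty = np.sort(np.concatenate([base, base + 0.004]))
        tonic = np.sort(np.random.default_rng(1).uniform(0, 120, 960))  # ~8 Hz
        pyr = _unit("pyr", bursty, pyr_wf, max_channel=13)   # border channel
        pyr2 = _unit("pyr2", bursty + 0.0002, pyr_wf, max_channel=13)
        border_int = _unit("int", tonic, int_wf, max_channel=13)
        labels = {l.unit_id: l for l in classify_ca1(
            [pyr, pyr2, border_int], sp_index=10, duration_s=120.0)}
        # both border pyramidal cells move into SP...
        assert labels["pyr"].layer == "SP" and labels["pyr"].subtype == "pyramidal"
        # ...and the border interneuron sharing their channel follows
        assert labels["int"].subtype == "interneuron" and labels["int"].layer == "SP"

    def test_label_order_invariance(self):
        spec = lp.CohortSpec(n_animals=1, duration_s=120.0, fs=1000.0, seed=13,
                             n_pyr=6, n_int=6)
        cohort = lp.make_cohort(spec, lp.well_separated_effects())
        al = lp.align_to_pyramidale(cohort.recordings)
        units = cohort.units_for(cohort.recordings[0].animal_id)
        sp = al.sp_indices[cohort.recordings[0].animal_id]
        fwd = {l.unit_id: l.subtype for l in classify_ca1(units, sp, 120.0)}
        rev = {l.unit_id: l.subtype for l in classify_ca1(units[::-1], sp, 120.0)}
        assert fwd == rev


class TestClassifyMS:
    def test_ratio_scale_invariance(self, rng):
        from laminarpac.synth import _template

        wf = _template(32000.0, 0.15, bump_amp=0.45) * 80
        assert ms_spectral_ratio(wf, 32000.0) == pytest.approx(
            ms_spectral_ratio(3.0 * wf, 32000.0), rel=1e-12)

    def test_tone_power_lands_in_expected_bin(self):
        wf_fs = 32000.0
        t = np.arange(256) / wf_fs
        tone = np.sin(2 * np.pi * 1900.0 * t)  # inside the 2nd bin (1.6-2.2 kHz)
        from scipy.signal import periodogram

        freqs, pxx = periodogram(tone - tone.mean(), fs=wf_fs, nfft=4096)
        edges = np.linspace(1000, 16000, 26)
        powers = [pxx[(freqs >= lo) & (freqs < hi)].sum()
                  for lo, hi in zip(edges[:-1], edges[1:])]
        assert np.argmax(powers) == 1

    def test_rate_gate_for_inflected_units(self):
        spec = lp.CohortSpec(n_animals=1, duration_s=120.0, fs=1000.0, seed=19,
                             n_ms_gaba=10, n_ms_chol=10)
        cohort = lp.make_cohort(spec, lp.well_separated_effects())
        labels = lp.classify_ms(cohort.ms_units, duration_s=120.0)
        for u, lab in zip(cohort.ms_units, labels):
            assert lab.subtype == u.truth["subtype"]
            if lab.subtype == "cholinergic":
                assert lab.rate_hz < 4.0

    def test_fast_inflected_unit_unclassified(self, rng):
        from laminarpac.synth import _template

        inflected = _template(32000.0, 0.15, bump_amp=0.45) * 80
        plain = _template(32000.0, 0.15) * 80
        fast = SpikeUnit("fast", np.arange(0, 100, 0.11), mean_waveform=inflected,
                         wf_fs=32000.0)  # ~9 Hz
        slow = SpikeUnit("slow", np.arange(0, 100, 0.4), mean_waveform=inflected,
                         wf_fs=32000.0)
        g = SpikeUnit("g", np.arange(0, 100, 0.2), mean_waveform=plain,
                      wf_fs=32000.0)
        labels = {l.unit_id: l.subtype
                  for l in lp.classify_ms([fast, slow, g], duration_s=100.0)}
        assert labels == {"fast": "unclassified", "slow": "cholinergic",
                          "g": "GABA/Glu"}
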