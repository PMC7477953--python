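"""Synthetic sham/injured laminar cohorts with ground truth.

The generator emulates the statistical structure the downstream analyses
assume for CA1 recordings under isoflurane anesthesia:

* a dominant 10-15 Hz oscillation with a Gaussian depth envelope peaking in
  stratum radiatum (SR) and a sign inversion (180 deg phase reversal) above
  the pyramidal layer (SP), the sharp-wave-like CA3 input;
* a 2-5 Hz "anesthesia theta" component growing toward the deep end of the
  probe with a gradual laminar phase shift;
* brief (~50-100 ms) high-frequency oscillatory bursts (centre ~225 Hz)
  confined to SP whose per-burst amplitude is modulated by the phase of the
  SR oscillation (phase-amplitude coupling of adjustable depth);
* 1/f pink-noise background on every channel, and an SP-localised
  multiunit-band power bump used for channel alignment;
* low-rate bursty pyramidal cells and tonic faster interneurons whose spike
  phases follow von Mises distributions around the SR oscillation, and
  medial-septal units (inflected "cholinergic" vs non-inflected "GABA/Glu"
  waveforms) whose firing is suppressed in a window starting ~14 ms after
  each SR trough.

Injury ("fluid percussion") is parameterised continuously by
:class:`InjuryEffects`; the named presets encode the printed effect sizes of
the study conditions (a 46.7% SR low-frequency power loss, a 74.4% SP
high-frequency power loss, attenuated coupling, broadened entrainment, and
medial-septal GABA/Glu disinhibition).  Every generated artifact carries its
ground-truth parameters so recovery tests never peek at the analysis path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
from scipy.special import i0

from .core import LaminarRecording, SpikeUnit
from .circstats import kappa_from_R
from .filters import bandpass

__all__ = [
    "CohortSpec",
    "InjuryEffects",
    "Cohort",
    "sham_effects",
    "injured_effects",
    "well_separated_effects",
    "gen_laminar_lfp",
    "gen_ca1_units",
    "gen_ms_units",
    "make_cohort",
    "sr_phase_deg",
]

SR_POWER_LOSS = 0.467   # peak low-frequency power reduction in SR
SP_POWER_LOSS = 0.744   # peak high-frequency power reduction in SP


@dataclass
class CohortSpec:
    """Geometry and size of a generated cohort (one group)."""

    n_animals: int = 5
    duration_s: float = 900.0
    fs: float = 2000.0
    n_channels: int = 32
    spacing_um: float = 50.0
    wf_fs: float = 32000.0
    sp_range: tuple[int, int] = (6, 13)  # randomised SP channel per animal
    n_pyr: int = 8          # per animal (study median)
    n_int: int = 6
    n_ms_gaba: int = 14
    n_ms_chol: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_animals, self.n_channels) <= 0 or self.duration_s <= 0:
            raise ValueError("all cohort counts must be positive")
        if not self.fs > 0:
            raise ValueError("fs must be positive")


@dataclass
class InjuryEffects:
    """Continuous injury parameterisation (see module docstring)."""

    group: str = "sham"
    # laminar LFP components
    sr_low_gain: float = 1.0          # amplitude factor on the 10-15 Hz SR component
    hfo_gain: float = 1.0             # amplitude factor on SP high-frequency bursts
    pac_depth: float = 0.9            # coupling depth in [0, 1]
    sr_band: tuple[float, float] = (10.5, 13.5)  # narrowband carrier, peaked ~12 Hz
    sr_amp_uv: float = 200.0          # RMS at the SR peak channel
    sr_pure_tone_hz: float | None = None  # replace the carrier by a pure cosine
    theta_carrier_band: tuple[float, float] = (2.0, 5.0)
    theta_amp_uv: float = 100.0       # RMS at the deep end
    hfo_center_hz: float = 225.0
    hfo_center_sd_hz: float = 10.0    # per-burst carrier spread; broadened after injury
    hfo_amp_uv: float = 60.0
    hfo_rate_hz: float = 8.0
    hfo_sigma_s: float = 0.012        # Gaussian burst envelope (~60 ms events)
    mua_amp_uv: float = 30.0
    noise_uv: float = 20.0            # pink-noise RMS per channel
    # CA1 units
    pyr_rate_hz: float = 1.25
    pyr_rate_sd: float = 0.91
    int_rate_hz: float = 5.12
    int_rate_sd: float = 7.50
    pyr_rate_bounds: tuple = (0.2, 60.0)
    int_rate_bounds: tuple = (0.2, 60.0)
    pyr_mu_deg: float = 193.8
    pyr_mu_sd_deg: float = 24.9
    pyr_R: float = 0.24
    pyr_R_sd: float = 0.09
    int_mu_deg: float = 181.8
    int_mu_sd_deg: float = 35.6
    int_R: float = 0.27
    int_R_sd: float = 0.13
    burst_prob: float = 0.35          # geometric continuation of pyramidal bursts
    burst_isi_s: float = 0.004
    fast_lock_frac: float = 0.8       # pull of in-burst spikes toward the burst carrier peak
    # medial septum units
    ms_gaba_rate_hz: float = 5.30
    ms_gaba_rate_sd: float = 6.42
    ms_chol_rate_hz: float = 2.84
    ms_chol_rate_sd: float = 1.64
    ms_gaba_rate_bounds: tuple = (0.3, 60.0)
    ms_chol_rate_bounds: tuple = (0.3, 60.0)
    ms_inhibition_depth: float = 0.7  # fractional suppression after the SR trough
    ms_inhib_onset_s: float = 0.014
    ms_inhib_dur_s: float = 0.020

    def __post_init__(self) -> None:
        if min(self.sr_low_gain, self.hfo_gain) < 0:
            raise ValueError("gains must be non-negative")
        if not 0.0 <= self.pac_depth <= 1.0:
            raise ValueError("pac_depth must lie in [0, 1]")
        if min(self.ms_gaba_rate_hz, self.ms_chol_rate_hz,
               self.pyr_rate_hz, self.int_rate_hz) < 0:
            raise ValueError("rates must be non-negative")


def sham_effects(**overrides) -> InjuryEffects:
    return replace(InjuryEffects(group="sham"), **overrides)


def injured_effects(**overrides) -> InjuryEffects:
    fx = InjuryEffects(
        group="injured",
        sr_low_gain=math.sqrt(1.0 - SR_POWER_LOSS),
        hfo_gain=math.sqrt(1.0 - SP_POWER_LOSS),
        pac_depth=0.25,
        hfo_center_sd_hz=25.0,
        pyr_rate_hz=1.26, pyr_rate_sd=0.91,
        int_rate_hz=4.26, int_rate_sd=7.51,
        pyr_mu_deg=208.7, pyr_mu_sd_deg=32.7,
        pyr_R=0.19, pyr_R_sd=0.07,
        int_mu_deg=189.0, int_mu_sd_deg=50.0,
        int_R=0.22, int_R_sd=0.10,
        ms_gaba_rate_hz=8.46, ms_gaba_rate_sd=9.76,
        ms_chol_rate_hz=2.89, ms_chol_rate_sd=1.55,
        ms_inhibition_depth=0.15,
    )
    return replace(fx, **overrides)


def well_separated_effects(group: str = "sham", **overrides) -> InjuryEffects:
    """Preset with unit feature clusters pulled away from the decision cuts.

    Used for classifier-recovery checks: the paper-matched lognormal rate
    spreads straddle the hard-coded 3.5 Hz (CA1) and 4 Hz (MS) divisions, so
    exact label recovery is only a meaningful target when the generated
    clusters are separable.
    """
    base = sham_effects() if group == "sham" else injured_effects()
    fx = replace(
        base,
        pyr_rate_bounds=(0.3, 3.0),
        int_rate_bounds=(4.2, 25.0),
        int_rate_hz=7.0,
        ms_chol_rate_bounds=(0.3, 3.6),
        ms_gaba_rate_bounds=(0.5, 40.0),
    )
    return replace(fx, **overrides)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _lognormal(rng, mean: float, sd: float, bounds=(0.0, np.inf), max_tries=1000) -> float:
    """Draw from a lognormal matched to the given mean/SD, truncated to bounds."""
    cv2 = (sd / mean) ** 2
    sigma2 = math.log1p(cv2)
    mu = math.log(mean) - sigma2 / 2.0
    lo, hi = bounds[0] or 0.0, bounds[1] if bounds[1] is not None else np.inf
    for _ in range(max_tries):
        x = float(rng.lognormal(mu, math.sqrt(sigma2)))
        if lo <= x <= hi:
            return x
    return float(np.clip(math.exp(mu), lo, hi))


def _pink_noise(rng, n: int, rms: float) -> np.ndarray:
    """1/f-amplitude noise with the requested RMS.

    Synthesised in the frequency domain with a deterministic magnitude
    spectrum and random phases, so every realisation has the same long-run
    PSD (identical noise floors across animals and groups).
    """
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    mag = 1.0 / np.sqrt(f)
    mag[0] = 0.0
    spec = mag * np.exp(2j * np.pi * rng.uniform(size=f.size))
    x = np.fft.irfft(spec, n)
    x *= rms / np.std(x)
    return x


def sr_phase_deg(truth: dict, times) -> np.ndarray:
    """Ground-truth SR phase (degrees, (-180, 180]) at the given times.

    Linear interpolation on the stored unwrapped phase trace of the SR
    carrier (0 deg = carrier peak, +/-180 deg = trough).
    """
    t_grid = np.arange(truth["sr_phase_unwrapped_deg"].size) / truth["fs"]
    ph = np.interp(np.asarray(times, dtype=float), t_grid,
                   truth["sr_phase_unwrapped_deg"])
    return _wrap_deg(ph)


def _wrap_deg(x):
    return (np.asarray(x) + 180.0) % 360.0 - 180.0


def _narrowband_carrier(rng, n: int, fs: float, band) -> np.ndarray:
    """Unit-RMS narrowband quasi-oscillation with a Gaussian spectral bump.

    Frequency-domain synthesis: deterministic magnitude spectrum centred on
    the band midpoint (sigma = quarter bandwidth) with random phases.  The
    long-run spectrum is identical across realisations; the instantaneous
    Hilbert phase and envelope behave like a natural narrowband rhythm.
    """
    f = np.fft.rfftfreq(n, 1.0 / fs)
    f0 = (band[0] + band[1]) / 2.0
    sigma = (band[1] - band[0]) / 4.0
    mag = np.exp(-0.5 * ((f - f0) / sigma) ** 2)
    spec = mag * np.exp(2j * np.pi * rng.uniform(size=f.size))
    spec[0] = 0.0
    x = np.fft.irfft(spec, n)
    return x / np.std(x)


# ---------------------------------------------------------------------------
# LFP generator
# ---------------------------------------------------------------------------

def gen_laminar_lfp(
    spec: CohortSpec,
    fx: InjuryEffects,
    rng: np.random.Generator,
    sp_channel: int | None = None,
    animal_id: str = "a0",
) -> tuple[LaminarRecording, dict]:
    """Generate one laminar recording and its ground-truth record."""
    from scipy.signal import find_peaks, hilbert

    fs, n_ch = spec.fs, spec.n_channels
    n = int(round(spec.duration_s * fs))
    t = np.arange(n) / fs
    c = np.arange(n_ch)
    if sp_channel is None:
        sp_channel = int(rng.integers(spec.sp_range[0], spec.sp_range[1] + 1))
    sp = sp_channel

    # (a) SR-peaked quasi-oscillation (~10-15 Hz) with phase reversal above SP
    if fx.sr_pure_tone_hz is not None:
        phi0 = rng.uniform(0.0, 360.0)
        sr_wave = np.cos(np.radians(360.0 * fx.sr_pure_tone_hz * t + phi0)) * np.sqrt(2)
        sr_phase_unwrapped = 360.0 * fx.sr_pure_tone_hz * t + phi0
    else:
        sr_wave = _narrowband_carrier(rng, n, fs, fx.sr_band)
        sr_phase_unwrapped = np.degrees(np.unwrap(np.angle(hilbert(sr_wave))))
    c_sr = sp + 9  # ~450 um below SP at 50 um spacing
    prof_sr = np.exp(-0.5 * ((c - c_sr) / 4.0) ** 2)
    sign = np.where(c <= sp - 3, -1.0, 1.0)
    lfp = (fx.sr_amp_uv * fx.sr_low_gain * prof_sr * sign)[:, None] * sr_wave[None, :]

    # trough times of the SR carrier (local minima where the carrier is active)
    min_dist = max(1, int(round(0.5 * fs / fx.sr_band[1])))
    troughs, _ = find_peaks(-sr_wave, distance=min_dist, height=0.3)
    troughs = troughs / fs

    # (b) anesthesia theta: deep-peaked envelope, gradual laminar phase shift
    if fx.theta_amp_uv > 0:
        th_analytic = hilbert(_narrowband_carrier(rng, n, fs, fx.theta_carrier_band))
        prof_th = 0.25 + 0.75 * (c / (n_ch - 1)) ** 2
        shift = np.pi * c / (n_ch - 1)  # progressive SO -> SL-M shift
        lfp += (fx.theta_amp_uv * prof_th)[:, None] * np.real(
            th_analytic[None, :] * np.exp(-1j * shift[:, None])
        )

    # (c) SP-localised high-frequency bursts, amplitude-modulated by SR phase
    prof_h = np.exp(-0.5 * ((c - sp) / 1.2) ** 2)
    n_bursts = rng.poisson(fx.hfo_rate_hz * spec.duration_s)
    bt = np.sort(rng.uniform(0.0, spec.duration_s, n_bursts))
    bphase = np.interp(bt, t, sr_phase_unwrapped)
    mod = (1.0 + np.cos(np.radians(bphase) - np.pi)) / 2.0  # max at the SR trough
    bamp = fx.hfo_amp_uv * fx.hfo_gain * (1.0 - fx.pac_depth + fx.pac_depth * mod)
    bamp = bamp * rng.lognormal(0.0, 0.25, n_bursts)  # intrinsic event variability
    bfreq = rng.normal(fx.hfo_center_hz, fx.hfo_center_sd_hz, n_bursts)
    bfreq = np.clip(bfreq, 60.0, 0.45 * fs)
    btheta = rng.uniform(0.0, 2 * np.pi, n_bursts)
    burst_sig = np.zeros(n)
    half = int(round(3 * fx.hfo_sigma_s * fs))
    for tk, ak, fk, thk in zip(bt, bamp, bfreq, btheta):
        k = int(round(tk * fs))
        lo, hi = max(0, k - half), min(n, k + half + 1)
        tt = t[lo:hi] - tk
        burst_sig[lo:hi] += ak * np.exp(-0.5 * (tt / fx.hfo_sigma_s) ** 2) * np.cos(
            2 * np.pi * fk * tt + thk
        )
    lfp += prof_h[:, None] * burst_sig[None, :]

    # (d) multiunit-band bump at SP (for alignment) when the rate allows it
    prof_mua = fx.mua_amp_uv * np.exp(-0.5 * ((c - sp) / 1.0) ** 2)
    if fs >= 1900.0:
        mua = _narrowband_carrier(rng, n, fs, (600.0, min(900.0, 0.45 * fs)))
        lfp += prof_mua[:, None] * mua[None, :]

    # (e) pink-noise background
    for ch in range(n_ch):
        lfp[ch] += _pink_noise(rng, n, fx.noise_uv)

    rec = LaminarRecording(
        lfp=lfp, fs=fs, spacing_um=spec.spacing_um,
        animal_id=animal_id, group=fx.group,
        mua_power=prof_mua ** 2 + 1e-9,
    )
    truth = {
        "animal_id": animal_id,
        "group": fx.group,
        "sp_channel": sp,
        "sr_band": tuple(fx.sr_band),
        "sr_phase_unwrapped_deg": sr_phase_unwrapped,
        "sr_profile": prof_sr * sign,
        "sr_peak_channel": int(c_sr),
        "trough_times": troughs,
        "burst_times": bt,
        "burst_amps": bamp,
        "burst_freqs": bfreq,
        "burst_phases0": btheta,
        "duration_s": float(spec.duration_s),
        "fs": float(fs),
        "effects": asdict(fx),
    }
    return rec, truth


# ---------------------------------------------------------------------------
# spike generators
# ---------------------------------------------------------------------------

def _vm_modulated_train(
    rng, rate_hz: float, duration_s: float, truth: dict,
    mu_deg: float, kappa: float,
) -> np.ndarray:
    """Inhomogeneous Poisson train with von Mises phase modulation (thinning)."""
    if kappa <= 0:
        n = rng.poisson(rate_hz * duration_s)
        return np.sort(rng.uniform(0.0, duration_s, n))
    lam_max = rate_hz * math.exp(kappa) / i0(kappa)
    n_cand = rng.poisson(lam_max * duration_s)
    cand = np.sort(rng.uniform(0.0, duration_s, n_cand))
    ph = np.radians(sr_phase_deg(truth, cand) - mu_deg)
    accept = rng.uniform(0, 1, n_cand) < np.exp(kappa * (np.cos(ph) - 1.0))
    return cand[accept]


def _enforce_refractory(times: np.ndarray, refractory_s: float = 0.001) -> np.ndarray:
    times = np.sort(times)
    keep = []
    last = -np.inf
    for tt in times:
        if tt - last >= refractory_s:
            keep.append(tt)
            last = tt
    return np.asarray(keep)


def _template(wf_fs: float, main_sigma_ms: float, ahp_frac: float = 0.45,
              ahp_delay_ms: float = 0.55, ahp_sigma_ms: float = 0.45,
              bump_amp: float = 0.0, bump_delay_ms: float = 0.45,
              bump_sigma_ms: float = 0.06, length_ms: float = 4.0,
              peak_ms: float = 1.5) -> np.ndarray:
    """Difference-of-Gaussians action-potential template (unit peak, negative)."""
    t = np.arange(int(round(length_ms * wf_fs / 1000.0))) * 1000.0 / wf_fs
    w = -np.exp(-0.5 * ((t - peak_ms) / main_sigma_ms) ** 2)
    w += ahp_frac * np.exp(-0.5 * ((t - peak_ms - ahp_delay_ms) / ahp_sigma_ms) ** 2)
    if bump_amp:
        w += bump_amp * np.exp(-0.5 * ((t - peak_ms - bump_delay_ms) / bump_sigma_ms) ** 2)
    return w


PYR_WF_SIGMA_MS = 0.22
INT_WF_SIGMA_MS = 0.08
MS_WF_SIGMA_MS = 0.15
MS_INFLECTION_AMP = 0.45


def _multichannel_waveform(rng, wf_fs: float, kind: str, spacing_um: float,
                           n_side: int = 3) -> np.ndarray:
    if kind == "pyramidal":
        base = _template(wf_fs, PYR_WF_SIGMA_MS)
    elif kind == "interneuron":
        base = _template(wf_fs, INT_WF_SIGMA_MS, ahp_delay_ms=0.35, ahp_sigma_ms=0.25)
    elif kind == "ms_noninflected":
        base = _template(wf_fs, MS_WF_SIGMA_MS)
    elif kind == "ms_inflected":
        base = _template(wf_fs, MS_WF_SIGMA_MS, bump_amp=MS_INFLECTION_AMP)
    else:
        raise ValueError(kind)
    amp = rng.uniform(60.0, 150.0)
    decay = np.exp(-np.abs(np.arange(-n_side, n_side + 1)) * spacing_um / 50.0)
    wf = amp * decay[:, None] * base[None, :]
    wf += rng.normal(0.0, 1.0, wf.shape)  # residual averaging noise, ~1 uV
    return wf


def gen_ca1_units(
    spec: CohortSpec,
    fx: InjuryEffects,
    truth: dict,
    rng: np.random.Generator,
) -> list[SpikeUnit]:
    """CA1 pyramidal cells and interneurons phase-locked to the SR oscillation."""
    sp = truth["sp_channel"]
    duration = truth["duration_s"]
    animal = truth["animal_id"]
    units: list[SpikeUnit] = []

    def lock_to_bursts(times: np.ndarray) -> np.ndarray:
        """Pull spikes inside a high-frequency burst toward the carrier peak."""
        if times.size == 0 or fx.fast_lock_frac <= 0:
            return times
        bt, bf, bth = truth["burst_times"], truth["burst_freqs"], truth["burst_phases0"]
        if len(bt) == 0:
            return times
        idx = np.clip(np.searchsorted(bt, times), 0, len(bt) - 1)
        # nearest burst (compare with the previous one as well)
        prev = np.clip(idx - 1, 0, len(bt) - 1)
        idx = np.where(np.abs(times - bt[prev]) < np.abs(times - bt[idx]), prev, idx)
        dt = times - bt[idx]
        in_burst = np.abs(dt) < 2.5 * fx.hfo_sigma_s
        psi = 2 * np.pi * bf[idx] * dt + bth[idx]
        wrapped = (psi + np.pi) % (2 * np.pi) - np.pi
        shift = np.where(in_burst, fx.fast_lock_frac * wrapped / (2 * np.pi * bf[idx]), 0.0)
        return times - shift

    for i in range(spec.n_pyr):
        rate = _lognormal(rng, fx.pyr_rate_hz, fx.pyr_rate_sd, fx.pyr_rate_bounds)
        r_target = float(np.clip(rng.normal(fx.pyr_R, fx.pyr_R_sd), 0.02, 0.9))
        kappa = kappa_from_R(r_target)
        mu = fx.pyr_mu_deg + rng.normal(0.0, fx.pyr_mu_sd_deg)
        # the drawn rate is the target total rate; burst continuation adds an
        # expected p/(1-p) spikes per event, so scale the event rate down
        event_rate = rate * (1.0 - fx.burst_prob)
        events = _vm_modulated_train(rng, event_rate, duration, truth, mu, kappa)
        # geometric burst continuation: doublets/triplets at ~4 ms
        extras = []
        for ev in events:
            tt = ev
            while rng.uniform() < fx.burst_prob:
                tt = tt + fx.burst_isi_s + rng.normal(0.0, 0.0003)
                extras.append(tt)
        times = np.concatenate([events, np.asarray(extras)]) if extras else events
        times = lock_to_bursts(times)
        times = _enforce_refractory(times[(times >= 0) & (times < duration)])
        max_ch = int(np.clip(sp + rng.integers(-1, 2), 0, spec.n_channels - 1))
        units.append(SpikeUnit(
            unit_id=f"{animal}_pyr{i}", spike_times_s=times, animal_id=animal,
            group=fx.group, region="CA1",
            mean_waveform=_multichannel_waveform(rng, spec.wf_fs, "pyramidal", spec.spacing_um),
            wf_fs=spec.wf_fs, max_channel=max_ch,
            truth={"subtype": "pyramidal", "layer": "SP", "rate_hz": rate,
                   "mu_deg": mu % 360.0, "kappa": kappa, "R_target": r_target},
        ))

    layer_cycle = ["SP", "SR", "SO"]
    for i in range(spec.n_int):
        rate = _lognormal(rng, fx.int_rate_hz, fx.int_rate_sd, fx.int_rate_bounds)
        r_target = float(np.clip(rng.normal(fx.int_R, fx.int_R_sd), 0.02, 0.9))
        kappa = kappa_from_R(r_target)
        mu = fx.int_mu_deg + rng.normal(0.0, fx.int_mu_sd_deg)
        times = _vm_modulated_train(rng, rate, duration, truth, mu, kappa)
        times = _enforce_refractory(times)
        layer = layer_cycle[i % 3]
        if layer == "SP":
            max_ch = sp + int(rng.integers(-1, 2))
        elif layer == "SO":
            max_ch = sp - int(rng.integers(4, 7))
        else:
            max_ch = sp + int(rng.integers(4, 16))
        max_ch = int(np.clip(max_ch, 0, spec.n_channels - 1))
        units.append(SpikeUnit(
            unit_id=f"{animal}_int{i}", spike_times_s=times, animal_id=animal,
            group=fx.group, region="CA1",
            mean_waveform=_multichannel_waveform(rng, spec.wf_fs, "interneuron", spec.spacing_um),
            wf_fs=spec.wf_fs, max_channel=max_ch,
            truth={"subtype": "interneuron", "layer": layer, "rate_hz": rate,
                   "mu_deg": mu % 360.0, "kappa": kappa, "R_target": r_target},
        ))
    return units


def _trough_suppressed_train(
    rng, rate_hz: float, duration_s: float, troughs: np.ndarray,
    depth: float, onset_s: float, dur_s: float,
) -> np.ndarray:
    """Poisson train multiplicatively suppressed in a post-trough window."""
    frac = min(len(troughs) * dur_s / duration_s, 1.0)
    g_mean = max(1.0 - depth * frac, 1e-6)
    lam_max = rate_hz / g_mean
    n_cand = rng.poisson(lam_max * duration_s)
    cand = np.sort(rng.uniform(0.0, duration_s, n_cand))
    if len(troughs):
        prev = np.searchsorted(troughs, cand, side="right") - 1
        since = np.where(prev >= 0, cand - troughs[np.maximum(prev, 0)], np.inf)
        g = np.where((since >= onset_s) & (since < onset_s + dur_s),
                     1.0 - depth, 1.0)
    else:
        g = np.ones(n_cand)
    accept = rng.uniform(0, 1, n_cand) < g
    return cand[accept]


def gen_ms_units(
    spec: CohortSpec,
    fx: InjuryEffects,
    truth: dict,
    rng: np.random.Generator,
) -> list[SpikeUnit]:
    """Medial-septal units rhythmically inhibited after the SR trough."""
    duration = truth["duration_s"]
    animal = truth["animal_id"]
    units: list[SpikeUnit] = []
    groups = [("gaba", spec.n_ms_gaba, fx.ms_gaba_rate_hz, fx.ms_gaba_rate_sd,
               fx.ms_gaba_rate_bounds, "ms_noninflected"),
              ("chol", spec.n_ms_chol, fx.ms_chol_rate_hz, fx.ms_chol_rate_sd,
               fx.ms_chol_rate_bounds, "ms_inflected")]
    for name, count, rmean, rsd, rbounds, wf_kind in groups:
        for i in range(count):
            rate = _lognormal(rng, rmean, rsd, rbounds)
            depth = float(np.clip(
                fx.ms_inhibition_depth * rng.lognormal(0.0, 0.2), 0.0, 0.95))
            times = _trough_suppressed_train(
                rng, rate, duration, truth["trough_times"], depth,
                fx.ms_inhib_onset_s, fx.ms_inhib_dur_s)
            times = _enforce_refractory(times)
            subtype = "GABA/Glu" if name == "gaba" else "cholinergic"
            units.append(SpikeUnit(
                unit_id=f"{animal}_ms_{name}{i}", spike_times_s=times,
                animal_id=animal, group=fx.group, region="MS",
                mean_waveform=_multichannel_waveform(
                    rng, spec.wf_fs, wf_kind, spec.spacing_um, n_side=0),
                wf_fs=spec.wf_fs, max_channel=int(rng.integers(0, 4)),
                truth={"subtype": subtype, "rate_hz": rate,
                       "inhibition_depth": depth},
            ))
    return units


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    spec: CohortSpec
    effects: InjuryEffects
    recordings: list[LaminarRecording] = field(default_factory=list)
    ca1_units: list[SpikeUnit] = field(default_factory=list)
    ms_units: list[SpikeUnit] = field(default_factory=list)
    truths: dict[str, dict] = field(default_factory=dict)

    def units_for(self, animal_id: str, region: str = "CA1") -> list[SpikeUnit]:
        pool = self.ca1_units if region == "CA1" else self.ms_units
        return [u for u in pool if u.animal_id == animal_id]


def make_cohort(spec: CohortSpec, fx: InjuryEffects,
                with_units: bool = True) -> Cohort:
    """Generate a full single-group cohort, fully determined by ``spec.seed``."""
    ss = np.random.SeedSequence(spec.seed)
    cohort = Cohort(spec=spec, effects=fx)
    for a, child in enumerate(ss.spawn(spec.n_animals)):
        rng = np.random.default_rng(child)
        animal = f"{fx.group}{a:02d}"
        rec, truth = gen_laminar_lfp(spec, fx, rng, animal_id=animal)
        cohort.recordings.append(rec)
        cohort.truths[animal] = truth
        if with_units:
            cohort.ca1_units.extend(gen_ca1_units(spec, fx, truth, rng))
            cohort.ms_units.extend(gen_ms_units(spec, fx, truth, rng))
    return cohort
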