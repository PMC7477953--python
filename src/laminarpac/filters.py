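"""Band-pass filtering, analytic-signal phase/amplitude, and Morlet transforms.

Phase convention used throughout the package: the instantaneous phase of a
band-passed signal is the angle of its analytic (Hilbert) signal, so a local
peak of the field is 0 deg and the trough is +/-180 deg.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt

__all__ = [
    "bandpass",
    "analytic_phase_deg",
    "analytic_amplitude",
    "morlet_tfr",
    "morlet_amplitude",
    "morlet_phase_deg",
]


def _check_band(band, fs: float) -> tuple[float, float]:
    lo, hi = float(band[0]), float(band[1])
    if not (0.0 < lo < hi < fs / 2.0):
        raise ValueError(f"invalid band {band!r} for fs={fs} Hz")
    return lo, hi


def bandpass(x: np.ndarray, fs: float, band, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis."""
    lo, hi = _check_band(band, fs)
    sos = butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, np.asarray(x, dtype=float), axis=-1)


def analytic_phase_deg(x: np.ndarray) -> np.ndarray:
    """Instantaneous phase (degrees, (-180, 180]) of an already-filtered signal."""
    return np.degrees(np.angle(hilbert(np.asarray(x, dtype=float), axis=-1)))


def analytic_amplitude(x: np.ndarray) -> np.ndarray:
    """Instantaneous amplitude envelope of an already-filtered signal."""
    return np.abs(hilbert(np.asarray(x, dtype=float), axis=-1))


def morlet_tfr(
    x: np.ndarray,
    fs: float,
    freqs,
    n_cycles: float = 10.0,
    chunk: int = 64,
) -> np.ndarray:
    """Complex Morlet transform of a single-channel signal.

    Returns an (n_freqs, n_samples) complex array whose magnitude is calibrated
    to passband gain 1: a pure tone ``A*sin(2*pi*f*t)`` yields an envelope of
    ``A`` at frequency ``f`` (away from the edges).  The wavelet family is
    MNE's zero-mean Morlet with a fixed number of cycles.
    """
    from mne.time_frequency import tfr_array_morlet
    from mne.time_frequency.tfr import morlet as _mne_morlet

    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("morlet_tfr expects a single-channel 1-D signal")
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    if np.any(freqs >= fs / 2.0) or np.any(freqs <= 0):
        raise ValueError("wavelet frequencies must lie in (0, fs/2)")

    # Passband gain of each wavelet: response of the convolution to a unit
    # complex exponential at the wavelet's own centre frequency, halved for a
    # real-valued tone.
    wavelets = _mne_morlet(fs, freqs, n_cycles=n_cycles, zero_mean=True)
    gains = np.empty(len(freqs))
    for i, (w, f) in enumerate(zip(wavelets, freqs)):
        tw = (np.arange(w.size) - (w.size - 1) / 2.0) / fs
        gains[i] = np.abs(np.sum(w * np.exp(-2j * np.pi * f * tw))) / 2.0

    out = np.empty((len(freqs), x.size), dtype=complex)
    data = x[np.newaxis, np.newaxis, :]
    for start in range(0, len(freqs), chunk):
        sl = slice(start, min(start + chunk, len(freqs)))
        tfr = tfr_array_morlet(
            data, sfreq=fs, freqs=freqs[sl], n_cycles=n_cycles,
            output="complex", verbose=False,
        )
        out[sl] = tfr[0, 0, :, :] / gains[sl, np.newaxis]
    return out


def morlet_amplitude(x, fs, freqs, n_cycles: float = 10.0) -> np.ndarray:
    """Amplitude envelopes of Morlet components (n_freqs, n_samples)."""
    return np.abs(morlet_tfr(x, fs, freqs, n_cycles=n_cycles))


def morlet_phase_deg(x, fs, freqs, n_cycles: float = 10.0) -> np.ndarray:
    """Instantaneous phases (degrees) of Morlet components."""
    return np.degrees(np.angle(morlet_tfr(x, fs, freqs, n_cycles=n_cycles)))
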