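"""Hippocampo-septal coupling: spike-triggered averages and trough PSTHs.

The spike-triggered average (STA) of the unfiltered CA1 LFP around each
medial-septal spike reveals the CA1 oscillation preceding MS firing; its
peak-to-peak deflection on a deep stratum-radiatum channel quantifies the
strength of CA1 feedback.  The trough-triggered peristimulus time histogram
(PSTH) expresses each unit's firing probability per 2 ms bin in a +/-50 ms
window around detected troughs of the band-passed SR oscillation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .core import LaminarRecording, SpikeUnit
from .filters import analytic_amplitude, bandpass

__all__ = ["STAResult", "PSTHResult", "spike_triggered_average",
           "detect_troughs", "psth"]


@dataclass
class STAResult:
    sta: np.ndarray          # (n_channels, window_samples) averaged LFP, uV
    fs: float
    half_window_s: float
    n_spikes: int
    p2p_uv: float            # max-positive minus max-negative on the designated channel
    p2p_channel: int

    @property
    def times_s(self) -> np.ndarray:
        n = self.sta.shape[1]
        return (np.arange(n) - (n - 1) // 2) / self.fs


@dataclass
class PSTHResult:
    bin_edges_ms: np.ndarray
    prob: np.ndarray         # spike count per bin / total unit spikes
    n_triggers: int
    total_spikes: int

    @property
    def bin_centers_ms(self) -> np.ndarray:
        return (self.bin_edges_ms[:-1] + self.bin_edges_ms[1:]) / 2.0


def spike_triggered_average(
    unit: SpikeUnit,
    rec: LaminarRecording,
    half_window_s: float = 0.5,
    p2p_channel: int | None = None,
    min_spikes: int = 1,
) -> STAResult:
    """Mean multichannel LFP snippet centred on each usable spike.

    Only spikes whose full +/- ``half_window_s`` window lies inside the
    recording are used.  ``p2p_channel`` defaults to the deepest channel.
    """
    w = int(round(half_window_s * rec.fs))
    idx = np.round(unit.spike_times_s * rec.fs).astype(int)
    idx = idx[(idx - w >= 0) & (idx + w < rec.n_samples)]
    if idx.size < max(min_spikes, 1):
        raise ValueError(f"unit {unit.unit_id}: no usable spikes for the STA window")
    length = 2 * w + 1
    sta = np.zeros((rec.n_channels, length))
    offsets = np.arange(-w, w + 1)
    for ch in range(rec.n_channels):
        sta[ch] = rec.lfp[ch][idx[:, None] + offsets[None, :]].mean(axis=0)
    if p2p_channel is None:
        p2p_channel = rec.n_channels - 1
    trace = sta[p2p_channel]
    return STAResult(
        sta=sta, fs=rec.fs, half_window_s=half_window_s, n_spikes=int(idx.size),
        p2p_uv=float(trace.max() - trace.min()), p2p_channel=int(p2p_channel),
    )


def detect_troughs(
    lfp_channel: np.ndarray,
    fs: float,
    band,
    min_env_factor: float = 2.0,
) -> np.ndarray:
    """Trough times (s) of the band-passed oscillation.

    Troughs are local minima of the filtered trace, accepted only where the
    analytic envelope clears an amplitude floor: either the envelope exceeds
    ``min_env_factor`` times its median while also being a non-negligible
    fraction of the peak envelope (suppressing spurious triggers in near-
    silent stretches), or it lies close to the peak envelope (so a steady
    oscillation, whose envelope never exceeds twice its own median, still
    triggers).  A zero signal yields no triggers.
    """
    xf = bandpass(np.asarray(lfp_channel, dtype=float), fs, band)
    env = analytic_amplitude(xf)
    med, mx = np.median(env), env.max()
    min_dist = max(1, int(round(0.5 * fs / band[1])))
    peaks, _ = find_peaks(-xf, distance=min_dist)
    e = env[peaks]
    accept = ((e > min_env_factor * med) & (e > 0.2 * mx)) | (e > 0.6 * mx)
    return peaks[accept] / fs


def psth(
    unit: SpikeUnit,
    triggers_s: np.ndarray,
    window_ms: float = 100.0,
    bin_ms: float = 2.0,
) -> PSTHResult:
    """Trigger-centred firing-probability histogram.

    Counts spikes in ``bin_ms`` bins spanning +/- ``window_ms``/2 around
    each trigger and divides by the unit's total spike count, so the
    histogram sums to the in-window fraction of the unit's spikes.
    """
    triggers = np.asarray(triggers_s, dtype=float)
    if triggers.size == 0:
        raise ValueError("need at least one trigger")
    half = window_ms / 2.0 * 1e-3
    times = unit.spike_times_s
    deltas = []
    for trig in triggers:
        lo = np.searchsorted(times, trig - half, side="left")
        hi = np.searchsorted(times, trig + half, side="right")
        deltas.append(times[lo:hi] - trig)
    deltas = np.concatenate(deltas) * 1e3 if deltas else np.empty(0)
    n_bins = int(round(window_ms / bin_ms))
    edges = np.linspace(-window_ms / 2.0, window_ms / 2.0, n_bins + 1)
    counts, _ = np.histogram(deltas, bins=edges)
    total = max(unit.n_spikes, 1)
    return PSTHResult(
        bin_edges_ms=edges, prob=counts / total,
        n_triggers=int(triggers.size), total_spikes=unit.n_spikes,
    )
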