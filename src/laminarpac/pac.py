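"""Kullback-Leibler phase-amplitude coupling (modulation index).

The coupling of a slow phase (stratum radiatum) with a fast amplitude
(stratum pyramidale) is quantified by binning the phase into N equal bins,
averaging the amplitude envelope in each bin, normalising the binned means
to a distribution P(j), and measuring its KL divergence from uniform:

    H   = -sum_j P(j) log P(j)
    H0  = log N
    MI  = (H0 - H) / H0            in [0, 1]

MI is 0 when the amplitude is independent of the phase (uniform P) and 1
when all amplitude mass concentrates in a single bin; it is invariant to
global amplitude scaling and to circular rotation of the phase series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import ttest_ind

from .filters import analytic_phase_deg, bandpass, morlet_tfr

__all__ = [
    "PhaseAmplitudeDistribution",
    "ComodulogramResult",
    "extract_amplitude",
    "extract_phase",
    "modulation_index",
    "comodulogram",
    "compare_comodulograms",
]

DEFAULT_N_BINS = 18  # 20 deg bins


@dataclass
class PhaseAmplitudeDistribution:
    bin_centers_deg: np.ndarray
    mean_amp: np.ndarray   # mean amplitude per phase bin
    p: np.ndarray          # normalised distribution, sums to 1
    n_bins: int


@dataclass
class ComodulogramResult:
    phase_freqs: np.ndarray  # Hz
    amp_freqs: np.ndarray    # Hz
    mi: np.ndarray           # (n_phase_freqs, n_amp_freqs)

    def peak(self) -> tuple[float, float, float]:
        """(phase_freq, amp_freq, mi) of the comodulogram maximum."""
        i, j = np.unravel_index(np.argmax(self.mi), self.mi.shape)
        return float(self.phase_freqs[i]), float(self.amp_freqs[j]), float(self.mi[i, j])


def extract_amplitude(signal: np.ndarray, fs: float, f: float,
                      n_cycles: float = 10.0) -> np.ndarray:
    """Amplitude envelope of the Morlet (10-cycle) component at frequency f."""
    if f >= fs / 2.0:
        raise ValueError(f"f={f} Hz is at or above Nyquist for fs={fs}")
    return np.abs(morlet_tfr(signal, fs, [f], n_cycles=n_cycles)[0])


def extract_phase(signal: np.ndarray, fs: float, band) -> np.ndarray:
    """Instantaneous phase (degrees) of the band-passed signal.

    Convention: 0 deg at the local-field peak, +/-180 deg at the trough.
    """
    return analytic_phase_deg(bandpass(signal, fs, band))


def _bin_indices(phase_deg: np.ndarray, n_bins: int) -> np.ndarray:
    wrapped = (np.asarray(phase_deg, dtype=float) + 180.0) % 360.0 - 180.0
    edges = np.linspace(-180.0, 180.0, n_bins + 1)
    # bins (edges[j], edges[j+1]]; -180 itself lands in the first bin
    idx = np.digitize(wrapped, edges[1:-1], right=True)
    return idx


def modulation_index(
    phase_deg: np.ndarray,
    amp: np.ndarray,
    n_bins: int = DEFAULT_N_BINS,
) -> tuple[float, PhaseAmplitudeDistribution]:
    """KL-based modulation index of one phase/amplitude series pair."""
    phase_deg = np.asarray(phase_deg, dtype=float)
    amp = np.asarray(amp, dtype=float)
    if phase_deg.shape != amp.shape or phase_deg.ndim != 1:
        raise ValueError("phase and amplitude must be equal-length 1-D series")
    if n_bins < 2:
        raise ValueError("need at least 2 phase bins")
    idx = _bin_indices(phase_deg, n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=amp, minlength=n_bins)
    if np.any(counts == 0):
        warnings.warn(
            f"{int((counts == 0).sum())} empty phase bin(s); their mean "
            "amplitude is treated as 0", stacklevel=2)
    means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    centers = np.linspace(-180.0, 180.0, n_bins + 1)[:-1] + 180.0 / n_bins
    total = means.sum()
    if total <= 0:
        warnings.warn("all-zero amplitude; MI undefined, returning 0", stacklevel=2)
        p = np.full(n_bins, 1.0 / n_bins)
        return 0.0, PhaseAmplitudeDistribution(centers, means, p, n_bins)
    p = means / total
    nz = p[p > 0]
    h = float(-(nz * np.log(nz)).sum())
    h0 = np.log(n_bins)
    mi = float((h0 - h) / h0)
    return mi, PhaseAmplitudeDistribution(centers, means, p, n_bins)


def _mi_matrix(amp: np.ndarray, idx: np.ndarray, n_bins: int) -> np.ndarray:
    """Vectorised MI of each amplitude row against one binned phase series."""
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    onehot = np.zeros((n_bins, idx.size))
    onehot[idx, np.arange(idx.size)] = 1.0
    sums = amp @ onehot.T                       # (n_rows, n_bins)
    means = sums / np.maximum(counts, 1.0)[None, :]
    totals = means.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(totals > 0, means / totals, 1.0 / n_bins)
    logp = np.log(p, out=np.zeros_like(p), where=p > 0)
    h = -(p * logp).sum(axis=1)
    return (np.log(n_bins) - h) / np.log(n_bins)


def comodulogram(
    sr_signal: np.ndarray,
    sp_signal: np.ndarray,
    fs: float,
    phase_freqs=None,
    amp_freqs=None,
    n_bins: int = DEFAULT_N_BINS,
    trim_s: float = 0.5,
    phase_halfwidth_hz: float = 1.0,
    n_cycles: float = 10.0,
) -> ComodulogramResult:
    """Comodulogram: SR phase (1-20 Hz) vs SP amplitude (1-300 Hz) MI grid.

    Amplitudes come from 10-cycle Morlet components of the SP signal; the
    phase at each slow frequency comes from a narrow band-pass
    (+/- ``phase_halfwidth_hz``) of the SR signal followed by the Hilbert
    transform.  The first and last ``trim_s`` seconds are discarded to
    suppress filter transients.
    """
    if phase_freqs is None:
        phase_freqs = np.arange(1.0, 21.0)
    if amp_freqs is None:
        amp_freqs = np.arange(1.0, 301.0)
    phase_freqs = np.asarray(phase_freqs, dtype=float)
    amp_freqs = np.asarray(amp_freqs, dtype=float)
    sr_signal = np.asarray(sr_signal, dtype=float)
    sp_signal = np.asarray(sp_signal, dtype=float)
    if sr_signal.shape != sp_signal.shape:
        raise ValueError("SR and SP signals must be equal length")

    ntrim = int(round(trim_s * fs))
    sl = slice(ntrim, sr_signal.size - ntrim if ntrim else None)
    amp = np.abs(morlet_tfr(sp_signal, fs, amp_freqs, n_cycles=n_cycles))[:, sl]

    mi = np.empty((phase_freqs.size, amp_freqs.size))
    for i, f in enumerate(phase_freqs):
        lo = max(0.2, f - phase_halfwidth_hz)
        ph = extract_phase(sr_signal, fs, (lo, f + phase_halfwidth_hz))[sl]
        idx = _bin_indices(ph, n_bins)
        mi[i] = _mi_matrix(amp, idx, n_bins)
    return ComodulogramResult(phase_freqs=phase_freqs, amp_freqs=amp_freqs, mi=mi)


def compare_comodulograms(
    group_a: list[ComodulogramResult],
    group_b: list[ComodulogramResult],
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell two-sample t comparison of MI matrices.

    Returns ``(diff, pvals)`` with ``diff = mean(group_a) - mean(group_b)``
    so swapping the groups negates the difference matrix.  Significance is
    intended to be read at p < 0.05 uncorrected; apply a multiplicity
    correction downstream if desired.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least 2 comodulograms per group")
    a = np.stack([c.mi for c in group_a])
    b = np.stack([c.mi for c in group_b])
    diff = a.mean(axis=0) - b.mean(axis=0)
    _, pvals = ttest_ind(a, b, axis=0, equal_var=True)
    return diff, np.asarray(pvals)
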