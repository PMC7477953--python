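"""Putative unit subtype classification.

CA1 (three steps): units are first assigned to an anatomic layer from the
channel of maximum amplitude relative to a five-channel stratum-pyramidale
band; non-border units outside SP are interneurons by definition.  SP and
border units are then split on three features — firing rate (division at
3.5 Hz), waveform width at 25% of spike height on the x5-upsampled mean
waveform, and burstiness (first moment of the autocorrelogram, smaller =
burstier) — into putative pyramidal cells (wide, bursty, slow) and putative
interneurons (narrow, tonic, fast).  Finally, border interneurons sharing a
max-amplitude channel with an isolated pyramidal cell are reassigned to SP.

Medial septum (two steps): the ratio of the 4th to 2nd frequency bin of the
waveform power spectrum (1-16 kHz, 25 equal bins) separates "inflected"
(putative cholinergic) from non-inflected (putative GABAergic/glutamatergic)
waveforms; inflected units are accepted as cholinergic only below a 4 Hz
firing-rate cut.

Width/burstiness/ratio thresholds are data driven (valley of the bimodal
feature distribution via a 1-D two-means split) since only the 3.5 Hz rate
division is a fixed constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import periodogram, resample_poly

from .core import SpikeUnit

__all__ = [
    "CA1Features",
    "CA1Label",
    "MSLabel",
    "assign_layer",
    "spike_width_25",
    "acorr_first_moment",
    "two_means_split",
    "classify_ca1",
    "ms_spectral_ratio",
    "classify_ms",
]

RATE_DIVISION_HZ = 3.5
MS_RATE_CUT_HZ = 4.0
SP_BAND_HALFWIDTH = 2  # five-channel SP band (100 um at 50 um spacing)


@dataclass
class CA1Features:
    rate_hz: float
    width25_ms: float
    acorr_moment_ms: float


@dataclass
class CA1Label:
    unit_id: str
    layer: str              # {"SO", "SP", "SR"}
    subtype: str            # {"pyramidal", "interneuron", "unclassified"}
    border: bool
    features: CA1Features | None = None


@dataclass
class MSLabel:
    unit_id: str
    subtype: str            # {"GABA/Glu", "cholinergic", "unclassified"}
    spectral_ratio: float
    rate_hz: float


def assign_layer(max_channel: int, sp_index: int, n_channels: int,
                 band_halfwidth: int = SP_BAND_HALFWIDTH) -> tuple[str, bool]:
    """Layer from max-amplitude channel geometry; returns (layer, border)."""
    if not 0 <= max_channel < n_channels:
        raise ValueError(f"max_channel {max_channel} outside probe (0..{n_channels - 1})")
    delta = max_channel - sp_index
    if abs(delta) <= band_halfwidth:
        return "SP", False
    if abs(delta) == band_halfwidth + 1:
        return ("SO" if delta < 0 else "SR"), True
    return ("SO" if delta < 0 else "SR"), False


def spike_width_25(mean_waveform: np.ndarray, wf_fs: float,
                   upsample: int = 5) -> float:
    """Waveform width (ms) at 25% of spike height on the upsampled trace.

    Height is the extremum relative to a baseline taken 1 ms before the
    peak; the width is the interval between the two 25%-height crossings
    bracketing the peak.  Returns NaN when undefined (flat trace, no
    crossings, or insufficient pre-peak context).
    """
    wf = np.asarray(mean_waveform, dtype=float)
    if wf.ndim != 1:
        raise ValueError("expects a single-channel mean waveform")
    up = resample_poly(wf, upsample, 1)
    fs_up = wf_fs * upsample
    pre = int(round(1e-3 * fs_up))
    peak = int(np.argmax(np.abs(up - np.median(up))))
    if peak - pre < 0:
        return float("nan")
    baseline = up[peak - pre]
    d = up - baseline
    if d[peak] < 0:
        d = -d
    height = d[peak]
    if height <= 0:
        return float("nan")
    level = 0.25 * height
    below_left = np.nonzero(d[:peak] < level)[0]
    below_right = np.nonzero(d[peak:] < level)[0]
    if below_left.size == 0 or below_right.size == 0:
        return float("nan")
    il = below_left[-1]
    left = il + (level - d[il]) / (d[il + 1] - d[il])
    ir = peak + below_right[0]
    right = ir - 1 + (level - d[ir - 1]) / (d[ir] - d[ir - 1])
    return float((right - left) / fs_up * 1e3)


def acorr_first_moment(spike_times_s: np.ndarray, max_lag_ms: float = 50.0,
                       bin_ms: float = 2.0) -> float:
    """First moment (ms) of the spike-train autocorrelogram.

    Positive inter-spike lags up to ``max_lag_ms`` are histogrammed in
    ``bin_ms`` bins; the moment is the count-weighted mean of bin centres.
    Smaller values indicate burstier trains.  Returns NaN on an empty
    histogram.
    """
    times = np.asarray(spike_times_s, dtype=float)
    max_lag = max_lag_ms * 1e-3
    lags = []
    for i, t0 in enumerate(times[:-1]):
        j = np.searchsorted(times, t0 + max_lag, side="right")
        lags.append(times[i + 1:j] - t0)
    if not lags:
        return float("nan")
    lags = np.concatenate(lags) * 1e3
    lags = lags[lags > 0]
    if lags.size == 0:
        return float("nan")
    n_bins = int(round(max_lag_ms / bin_ms))
    counts, edges = np.histogram(lags, bins=n_bins, range=(0.0, max_lag_ms))
    if counts.sum() == 0:
        return float("nan")
    centers = (edges[:-1] + edges[1:]) / 2.0
    return float((centers * counts).sum() / counts.sum())


def two_means_split(values: np.ndarray) -> float:
    """Deterministic 1-D two-means threshold (valley between two clusters).

    Scans all split points of the sorted sample and returns the midpoint
    between the two cluster means that minimises within-cluster sum of
    squares.
    """
    v = np.sort(np.asarray(values, dtype=float))
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("need at least two finite values to split")
    csum = np.cumsum(v)
    csum2 = np.cumsum(v ** 2)
    total, total2 = csum[-1], csum2[-1]
    best, best_k = np.inf, 1
    for k in range(1, v.size):
        s1, s2 = csum[k - 1], total - csum[k - 1]
        q1, q2 = csum2[k - 1], total2 - csum2[k - 1]
        ss = (q1 - s1 ** 2 / k) + (q2 - s2 ** 2 / (v.size - k))
        if ss < best - 1e-15:
            best, best_k = ss, k
    m1 = csum[best_k - 1] / best_k
    m2 = (total - csum[best_k - 1]) / (v.size - best_k)
    return float((m1 + m2) / 2.0)


def _ca1_features(unit: SpikeUnit, duration_s: float) -> CA1Features:
    return CA1Features(
        rate_hz=unit.firing_rate(duration_s),
        width25_ms=spike_width_25(unit.max_channel_waveform(), unit.wf_fs),
        acorr_moment_ms=acorr_first_moment(unit.spike_times_s),
    )


def classify_ca1(
    units: list[SpikeUnit],
    sp_index: int,
    duration_s: float,
    n_channels: int = 32,
    width_threshold_ms: float | None = None,
    moment_threshold_ms: float | None = None,
    rate_division_hz: float = RATE_DIVISION_HZ,
) -> list[CA1Label]:
    """Three-step CA1 classification (layer -> features -> border resolution).

    Width and burstiness thresholds default to the valley between the two
    clusters of the SP/border feature distributions.
    """
    layers = [assign_layer(u.max_channel, sp_index, n_channels) for u in units]
    in_band = [i for i, (layer, border) in enumerate(layers)
               if layer == "SP" or border]
    feats: dict[int, CA1Features] = {i: _ca1_features(units[i], duration_s)
                                     for i in in_band}
    def _threshold(values: np.ndarray) -> float:
        finite = values[np.isfinite(values)]
        if finite.size < 2:
            return float("nan")  # not learnable; affected units stay unclassified
        return two_means_split(finite)

    if in_band:
        if width_threshold_ms is None:
            width_threshold_ms = _threshold(
                np.array([feats[i].width25_ms for i in in_band]))
        if moment_threshold_ms is None:
            moment_threshold_ms = _threshold(
                np.array([feats[i].acorr_moment_ms for i in in_band]))

    labels: list[CA1Label] = []
    for i, u in enumerate(units):
        layer, border = layers[i]
        if i not in feats:
            # non-border unit outside SP: interneuron regardless of rate
            labels.append(CA1Label(u.unit_id, layer, "interneuron", border))
            continue
        f = feats[i]
        wide = f.width25_ms > width_threshold_ms
        bursty = f.acorr_moment_ms < moment_threshold_ms
        slow = f.rate_hz < rate_division_hz
        if not np.all(np.isfinite([f.width25_ms, f.acorr_moment_ms,
                                   width_threshold_ms, moment_threshold_ms])):
            subtype = "unclassified"
        elif wide and bursty and slow:
            subtype = "pyramidal"
        elif (not wide) and (not bursty) and (not slow):
            subtype = "interneuron"
        else:
            subtype = "unclassified"
        labels.append(CA1Label(u.unit_id, layer, subtype, border, f))

    # step 3: resolve border units.  Border pyramidal cells move into SP
    # first; a border interneuron follows when an isolated pyramidal cell has
    # its maximum amplitude on the same channel.
    for lab in labels:
        if lab.border and lab.subtype == "pyramidal":
            lab.layer, lab.border = "SP", False
    pyr_channels = {units[i].max_channel for i, lab in enumerate(labels)
                    if lab.subtype == "pyramidal" and lab.layer == "SP"}
    for i, lab in enumerate(labels):
        if lab.border and lab.subtype == "interneuron" \
                and units[i].max_channel in pyr_channels:
            lab.layer, lab.border = "SP", False
        # otherwise the border unit keeps its SO/SR side assignment
    return labels


def ms_spectral_ratio(mean_waveform: np.ndarray, wf_fs: float,
                      fmin: float = 1000.0, fmax: float = 16000.0,
                      n_freq_bins: int = 25, nfft: int = 4096) -> float:
    """Waveform power ratio of the 4th to 2nd frequency bin (1-16 kHz grid).

    The mean waveform's power spectrum is integrated over 25 equal-width
    bins spanning 1-16 kHz; the inflection on the repolarisation phase of
    cholinergic waveforms adds high-frequency power and raises the ratio.
    """
    wf = np.asarray(mean_waveform, dtype=float)
    if wf.ndim != 1:
        raise ValueError("expects a single-channel mean waveform")
    if wf_fs < 2.0 * fmax:
        raise ValueError(f"waveform sampling rate {wf_fs} cannot cover {fmax} Hz")
    freqs, pxx = periodogram(wf - wf.mean(), fs=wf_fs, nfft=max(nfft, wf.size))
    edges = np.linspace(fmin, fmax, n_freq_bins + 1)
    binpow = np.array([
        pxx[(freqs >= lo) & (freqs < hi)].sum() for lo, hi in zip(edges[:-1], edges[1:])
    ])
    if binpow[1] <= 0:
        return float("nan")
    return float(binpow[3] / binpow[1])  # 4th over 2nd (1-indexed)


def classify_ms(
    units: list[SpikeUnit],
    duration_s: float,
    ratio_threshold: float | None = None,
    rate_cut_hz: float = MS_RATE_CUT_HZ,
) -> list[MSLabel]:
    """Two-step medial-septum classification (waveform ratio, then rate)."""
    ratios = np.array([ms_spectral_ratio(u.max_channel_waveform(), u.wf_fs)
                       for u in units])
    if ratio_threshold is None:
        ratio_threshold = two_means_split(ratios)
    labels = []
    for u, ratio in zip(units, ratios):
        rate = u.firing_rate(duration_s)
        if not np.isfinite(ratio):
            subtype = "unclassified"
        elif ratio < ratio_threshold:
            subtype = "GABA/Glu"
        elif rate < rate_cut_hz:
            subtype = "cholinergic"
        else:
            subtype = "unclassified"
        labels.append(MSLabel(u.unit_id, subtype, float(ratio), rate))
    return labels
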