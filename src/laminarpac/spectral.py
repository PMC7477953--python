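"""Channel alignment, Welch power, and power-difference-distribution maps.

The laminar probes of different animals are aligned on the pyramidal-layer
channel (maximum multiunit-band power), producing a 25-channel common window
with 6 channels on the stratum-oriens side and 18 on the stratum-radiatum
side of SP.  Power is computed per channel in 1 s epochs (60% overlap, Hann
taper, zero-padded to a 0.5 Hz bin grid) and the injured-vs-sham contrast is
expressed as the percent power difference distribution (PDD) with a
significance mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import spectrogram
from scipy.stats import f_oneway, ttest_ind

from .core import AlignedCohort, AlignmentError, LaminarRecording
from .filters import bandpass

__all__ = ["PSDStack", "PDDMap", "align_to_pyramidale", "welch_psd", "pdd_map"]


@dataclass
class PSDStack:
    """Per-epoch power spectral densities, (channel, freq, epoch), in uV^2/Hz."""

    freqs: np.ndarray
    power: np.ndarray
    epoch_len_s: float
    animal_id: str = ""
    group: str = "sham"

    @property
    def n_epochs(self) -> int:
        return self.power.shape[2]

    def mean_power(self) -> np.ndarray:
        """Epoch-averaged power, (channel, freq)."""
        return self.power.mean(axis=2)


@dataclass
class PDDMap:
    """Percent power change of injured relative to sham, with significance mask."""

    freqs: np.ndarray
    pdd: np.ndarray          # (channel, freq), 100*(injured/sham - 1); NaN where undefined
    pvals: np.ndarray
    mask: np.ndarray         # boolean, p < alpha and pdd defined
    masked_pdd: np.ndarray   # pdd * mask, exactly 0 off-mask
    alpha: float


def align_to_pyramidale(
    recordings: list[LaminarRecording],
    channels_above: int = 6,
    channels_below: int = 18,
    mua_band: tuple[float, float] = (600.0, 900.0),
) -> AlignedCohort:
    """Align probes on the channel of maximum multiunit-band power.

    The SP channel is the argmax of band-limited average power per animal
    (ties resolved to the most superficial channel).  When a recording
    carries a generator-supplied ``mua_power`` proxy it is used directly;
    otherwise the power is estimated from the LFP, which requires the
    sampling rate to cover the multiunit band.
    """
    sp_indices: dict[str, int] = {}
    window_map: dict[str, np.ndarray] = {}
    n_window = channels_above + channels_below + 1
    for rec in recordings:
        if rec.mua_power is not None:
            p = rec.mua_power
        else:
            if rec.fs < 2.0 * mua_band[1]:
                raise AlignmentError(
                    f"animal {rec.animal_id!r}: no multiunit-band proxy and "
                    f"fs={rec.fs} Hz cannot cover {mua_band} Hz"
                )
            p = np.mean(bandpass(rec.lfp, rec.fs, mua_band) ** 2, axis=1)
        sp = int(np.argmax(p))  # argmax takes the first (most superficial) on ties
        lo, hi = sp - channels_above, sp + channels_below
        if lo < 0 or hi >= rec.n_channels:
            raise AlignmentError(
                f"animal {rec.animal_id!r}: {n_window}-channel window around "
                f"SP channel {sp} exceeds the {rec.n_channels}-channel probe"
            )
        sp_indices[rec.animal_id] = sp
        window_map[rec.animal_id] = np.arange(lo, hi + 1)
    return AlignedCohort(
        recordings=list(recordings), sp_indices=sp_indices,
        window_map=window_map, channels_above=channels_above,
        channels_below=channels_below,
    )


def welch_psd(
    rec: LaminarRecording,
    fmin: float = 1.0,
    fmax: float = 300.0,
    epoch_len_s: float = 1.0,
    overlap: float = 0.6,
) -> PSDStack:
    """Per-epoch Welch power on a 0.5 Hz grid.

    Each 1 s epoch is Hann-tapered and zero-padded to twice its length so the
    frequency grid has exactly 0.5 Hz spacing while the epoch length stays at
    the stated 1 s.
    """
    if rec.fs < 2.0 * fmax:
        raise ValueError(f"fs={rec.fs} Hz cannot resolve {fmax} Hz")
    nper = int(round(epoch_len_s * rec.fs))
    if rec.n_samples < nper:
        raise ValueError("recording shorter than one epoch")
    freqs, _, power = spectrogram(
        rec.lfp, fs=rec.fs, window="hann", nperseg=nper,
        noverlap=int(round(overlap * nper)), nfft=2 * nper,
        detrend=False, scaling="density", mode="psd",
    )
    sel = (freqs >= fmin) & (freqs <= fmax)
    return PSDStack(
        freqs=freqs[sel], power=power[:, sel, :], epoch_len_s=epoch_len_s,
        animal_id=rec.animal_id, group=rec.group,
    )


def pdd_map(
    sham: list[PSDStack],
    injured: list[PSDStack],
    alpha: float = 0.05,
    mode: str = "epochs",
) -> PDDMap:
    """Percent power-difference map with a per-bin significance mask.

    ``mode="epochs"`` compares the two groups bin-wise with a one-way ANOVA
    over pooled epochs (the study's procedure; epochs are treated as
    replicates).  ``mode="animals"`` is a conservative alternative comparing
    per-animal epoch means with Welch's t test.
    """
    if not sham or not injured:
        raise ValueError("both groups need at least one PSD stack")
    freqs = sham[0].freqs
    for s in [*sham, *injured]:
        if not np.array_equal(s.freqs, freqs) or s.power.shape[0] != sham[0].power.shape[0]:
            raise ValueError("PSD stacks are not on a common channel/frequency grid")

    mean_sham = np.mean([s.mean_power() for s in sham], axis=0)
    mean_inj = np.mean([s.mean_power() for s in injured], axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        pdd = 100.0 * (mean_inj / mean_sham - 1.0)
    pdd[mean_sham == 0] = np.nan

    if mode == "epochs":
        a = np.concatenate([s.power for s in sham], axis=2)
        b = np.concatenate([s.power for s in injured], axis=2)
        _, pvals = f_oneway(a, b, axis=2)
    elif mode == "animals":
        a = np.stack([s.mean_power() for s in sham], axis=2)
        b = np.stack([s.mean_power() for s in injured], axis=2)
        _, pvals = ttest_ind(a, b, axis=2, equal_var=False)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    pvals = np.asarray(pvals)
    mask = (pvals < alpha) & np.isfinite(pdd)
    masked = np.where(mask, pdd, 0.0)
    return PDDMap(freqs=freqs, pdd=pdd, pvals=pvals, mask=mask,
                  masked_pdd=masked, alpha=alpha)
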