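"""Domain containers and on-disk formats.

A laminar recording is a channels x samples matrix of extracellular voltage
(microvolts) from a single-shank silicon probe, ordered superficial (stratum
oriens side) to deep (stratum lacunosum-moleculare side).  Spike-sorted units
carry spike times, a mean waveform and the channel of maximum amplitude.

Storage formats (all generatable byte-exactly):

* LFP: ``<stem>.dat`` flat binary (channel-major ``int16`` or ``float32``)
  plus ``<stem>.meta.json`` sidecar with keys ``fs_hz``, ``n_channels``,
  ``dtype``, ``gain_uv_per_bit``, ``spacing_um``, ``channel_order``,
  ``group``, ``animal_id``.
* Spike tables: long-format CSV (``unit_id, animal_id, group, region,
  spike_time_s``), waveforms in ``<stem>.wf.bin`` (float32) indexed by
  ``<stem>.wf.json`` per-unit offsets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LaminarRecording",
    "SpikeUnit",
    "CurationReport",
    "AlignedCohort",
    "FormatError",
    "AlignmentError",
    "read_recording",
    "write_recording",
    "read_units",
    "write_units",
    "curate_unit",
]

ISI_REFRACTORY_S = 0.003
MIN_SPIKES = 100
MAX_ISI_VIOLATION_RATE = 0.02


class FormatError(ValueError):
    """Raised when a file does not match its sidecar metadata."""


class AlignmentError(ValueError):
    """Raised when the common laminar window does not fit on a probe."""


@dataclass
class LaminarRecording:
    """Multichannel LFP in microvolts, channel 0 = most superficial."""

    lfp: np.ndarray
    fs: float
    spacing_um: float = 50.0
    animal_id: str = ""
    group: str = "sham"
    mua_power: np.ndarray | None = None  # per-channel multiunit-band power proxy

    def __post_init__(self) -> None:
        self.lfp = np.asarray(self.lfp, dtype=float)
        if self.lfp.ndim != 2 or self.lfp.shape[0] < 3:
            raise ValueError("lfp must be (n_channels >= 3, n_samples)")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.lfp)):
            raise ValueError("lfp contains non-finite samples")
        if self.mua_power is not None:
            self.mua_power = np.asarray(self.mua_power, dtype=float)
            if self.mua_power.shape != (self.n_channels,):
                raise ValueError("mua_power must have one value per channel")

    @property
    def n_channels(self) -> int:
        return self.lfp.shape[0]

    @property
    def n_samples(self) -> int:
        return self.lfp.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


@dataclass
class SpikeUnit:
    """A curated putative single unit."""

    unit_id: str
    spike_times_s: np.ndarray
    animal_id: str = ""
    group: str = "sham"
    region: str = "CA1"  # {"CA1", "MS"}
    mean_waveform: np.ndarray | None = None  # (n_channels, n_samples) or (n_samples,)
    wf_fs: float = 32000.0
    max_channel: int = 0
    truth: dict = field(default_factory=dict)  # generator ground truth, if synthetic

    def __post_init__(self) -> None:
        self.spike_times_s = np.asarray(self.spike_times_s, dtype=float)
        if self.spike_times_s.ndim != 1:
            raise ValueError("spike_times_s must be 1-D")
        if self.spike_times_s.size > 1 and np.any(np.diff(self.spike_times_s) <= 0):
            raise ValueError("spike times must be strictly ascending")
        if self.mean_waveform is not None:
            self.mean_waveform = np.atleast_1d(np.asarray(self.mean_waveform, dtype=float))

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times_s.size)

    def firing_rate(self, duration_s: float) -> float:
        if duration_s <= 0:
            raise ValueError("duration must be positive")
        return self.n_spikes / duration_s

    def max_channel_waveform(self) -> np.ndarray:
        if self.mean_waveform is None:
            raise ValueError(f"unit {self.unit_id} has no stored waveform")
        if self.mean_waveform.ndim == 1:
            return self.mean_waveform
        return self.mean_waveform[np.argmax(np.ptp(self.mean_waveform, axis=1))]


@dataclass
class CurationReport:
    n_spikes: int
    isi_violation_rate: float  # NaN when < 2 spikes (undefined)
    passed: bool


def curate_unit(unit: SpikeUnit) -> CurationReport:
    """Spike-count and refractory-violation curation.

    A unit passes with >= 100 spikes and < 2% of inter-spike intervals
    shorter than 3 ms.  The denominator is the number of intervals.
    """
    n = unit.n_spikes
    if n < 2:
        return CurationReport(n_spikes=n, isi_violation_rate=float("nan"), passed=False)
    isis = np.diff(unit.spike_times_s)
    rate = float(np.count_nonzero(isis < ISI_REFRACTORY_S) / isis.size)
    passed = (n >= MIN_SPIKES) and (rate < MAX_ISI_VIOLATION_RATE)
    return CurationReport(n_spikes=n, isi_violation_rate=rate, passed=passed)


@dataclass
class AlignedCohort:
    """A cohort re-indexed to a common laminar window centred on SP.

    ``window_map[animal_id]`` lists, for each of the ``n_window`` aligned
    channels (superficial to deep), the original channel index on that
    animal's probe.  Aligned index ``channels_above`` is the SP channel.
    """

    recordings: list[LaminarRecording]
    sp_indices: dict[str, int]
    window_map: dict[str, np.ndarray]
    channels_above: int = 6
    channels_below: int = 18

    @property
    def n_window(self) -> int:
        return self.channels_above + self.channels_below + 1

    @property
    def sp_aligned_index(self) -> int:
        return self.channels_above

    def aligned_lfp(self, animal_id: str) -> np.ndarray:
        rec = self.recording(animal_id)
        return rec.lfp[self.window_map[animal_id]]

    def recording(self, animal_id: str) -> LaminarRecording:
        for rec in self.recordings:
            if rec.animal_id == animal_id:
                return rec
        raise KeyError(animal_id)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_DTYPES = {"int16": np.int16, "float32": np.float32}


def write_recording(stem: str | Path, rec: LaminarRecording,
                    dtype: str = "float32", gain_uv_per_bit: float = 1.0) -> None:
    stem = Path(stem)
    if dtype not in _DTYPES:
        raise FormatError(f"unsupported dtype {dtype!r}")
    data = rec.lfp
    if dtype == "int16":
        data = np.round(data / gain_uv_per_bit)
        if np.any(np.abs(data) > np.iinfo(np.int16).max):
            raise FormatError("int16 overflow at the requested gain")
    data.astype(_DTYPES[dtype]).tofile(stem.with_suffix(".dat"))
    meta = {
        "fs_hz": rec.fs,
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
        "dtype": dtype,
        "gain_uv_per_bit": gain_uv_per_bit,
        "spacing_um": rec.spacing_um,
        "channel_order": "superficial_to_deep",
        "group": rec.group,
        "animal_id": rec.animal_id,
    }
    if rec.mua_power is not None:
        meta["mua_power"] = list(map(float, rec.mua_power))
    stem.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1))


def read_recording(stem: str | Path) -> LaminarRecording:
    stem = Path(stem)
    meta = json.loads(stem.with_suffix(".meta.json").read_text())
    dtype = meta["dtype"]
    if dtype not in _DTYPES:
        raise FormatError(f"unsupported dtype {dtype!r}")
    raw = np.fromfile(stem.with_suffix(".dat"), dtype=_DTYPES[dtype])
    n_ch = int(meta["n_channels"])
    if raw.size % n_ch != 0 or (
        "n_samples" in meta and raw.size != n_ch * int(meta["n_samples"])
    ):
        raise FormatError(
            f"{stem}.dat holds {raw.size} values, inconsistent with "
            f"{n_ch} channels in the sidecar"
        )
    lfp = raw.reshape(n_ch, -1).astype(float)
    if dtype == "int16":
        lfp *= float(meta["gain_uv_per_bit"])
    return LaminarRecording(
        lfp=lfp,
        fs=float(meta["fs_hz"]),
        spacing_um=float(meta.get("spacing_um", 50.0)),
        animal_id=str(meta.get("animal_id", "")),
        group=str(meta.get("group", "sham")),
        mua_power=np.asarray(meta["mua_power"], dtype=float) if "mua_power" in meta else None,
    )


def write_units(stem: str | Path, units: list[SpikeUnit]) -> None:
    stem = Path(stem)
    rows = []
    for u in units:
        for t in u.spike_times_s:
            rows.append((u.unit_id, u.animal_id, u.group, u.region, t))
    pd.DataFrame(
        rows, columns=["unit_id", "animal_id", "group", "region", "spike_time_s"]
    ).to_csv(stem.with_suffix(".csv"), index=False)

    index: dict[str, dict] = {}
    offset = 0
    with open(stem.with_suffix(".wf.bin"), "wb") as fh:
        for u in units:
            if u.mean_waveform is None:
                continue
            wf = np.atleast_2d(u.mean_waveform).astype(np.float32)
            fh.write(wf.tobytes())
            index[u.unit_id] = {
                "offset": offset,
                "n_channels": wf.shape[0],
                "n_samples": wf.shape[1],
                "wf_fs": u.wf_fs,
                "max_channel": u.max_channel,
            }
            offset += wf.size
    stem.with_suffix(".wf.json").write_text(json.dumps(index, indent=1))


def read_units(stem: str | Path) -> list[SpikeUnit]:
    stem = Path(stem)
    table = pd.read_csv(stem.with_suffix(".csv"))
    index = json.loads(stem.with_suffix(".wf.json").read_text())
    wf_flat = np.fromfile(stem.with_suffix(".wf.bin"), dtype=np.float32)
    units = []
    for uid, grp in table.groupby("unit_id", sort=False):
        meta = index.get(str(uid))
        wf = None
        wf_fs, max_channel = 32000.0, 0
        if meta is not None:
            n = meta["n_channels"] * meta["n_samples"]
            wf = wf_flat[meta["offset"]: meta["offset"] + n].astype(float)
            wf = wf.reshape(meta["n_channels"], meta["n_samples"])
            if wf.shape[0] == 1:
                wf = wf[0]
            wf_fs = float(meta["wf_fs"])
            max_channel = int(meta["max_channel"])
        units.append(SpikeUnit(
            unit_id=str(uid),
            spike_times_s=np.sort(grp["spike_time_s"].to_numpy()),
            animal_id=str(grp["animal_id"].iloc[0]),
            group=str(grp["group"].iloc[0]),
            region=str(grp["region"].iloc[0]),
            mean_waveform=wf,
            wf_fs=wf_fs,
            max_channel=max_channel,
        ))
    return units
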