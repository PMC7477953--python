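"""Current-source-density estimation across the laminar probe.

The standard estimator: the negative second spatial difference of the
band-passed potential along depth, in relative units (extracellular
conductivity treated as a unit scalar).  Current sinks (inward current) are
negative by convention.  Edge channels are dropped unless boundary
replication (Vaknin padding) is requested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import LaminarRecording
from .filters import bandpass

__all__ = ["CSDMap", "csd_standard"]


@dataclass
class CSDMap:
    csd: np.ndarray             # (n_interior_channels, n_samples); sinks negative
    band: tuple[float, float]
    spacing_um: float
    channel_offset: int         # original index of the first CSD row


def csd_standard(
    rec: LaminarRecording,
    band: tuple[float, float],
    t0: float | None = None,
    t1: float | None = None,
    vaknin: bool = False,
) -> CSDMap:
    """Second-spatial-derivative CSD of a band-passed LFP segment.

    csd_i(t) = -(V_{i-1} - 2 V_i + V_{i+1}) / h^2 with h the inter-site
    spacing; a depth-affine potential therefore maps to exactly zero.
    """
    if rec.n_channels < 3:
        raise ValueError("CSD needs at least 3 channels")
    lo = 0 if t0 is None else int(round(t0 * rec.fs))
    hi = rec.n_samples if t1 is None else int(round(t1 * rec.fs))
    if not (0 <= lo < hi <= rec.n_samples):
        raise ValueError("invalid time window")
    v = bandpass(rec.lfp[:, lo:hi], rec.fs, band)
    if vaknin:
        v = np.vstack([v[:1], v, v[-1:]])
        offset = 0
    else:
        offset = 1
    h2 = rec.spacing_um ** 2
    csd = -(v[:-2] - 2.0 * v[1:-1] + v[2:]) / h2
    return CSDMap(csd=csd, band=(float(band[0]), float(band[1])),
                  spacing_um=rec.spacing_um, channel_offset=offset)
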