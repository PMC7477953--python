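"""Reported unit counts of the TBI laminar-recording study.

These are the printed entrained/total unit counts per region, subtype, band
and group.  They serve as worked-example inputs: the entrained percentages
are recomputed from the raw counts.  One printed percentage (sham
cholinergic units vs anesthesia theta) is inconsistent with its own counts
(18/36 is 50%, not 29%); ``consistent`` flags rows whose printed percentage
matches the recomputed one at integer precision.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["reported_entrainment_counts", "entrained_percentages"]

_ROWS = [
    # region, subtype, band, group, entrained, total, printed_pct
    ("CA1", "pyramidal", "8-20", "sham", 48, 49, 98),
    ("CA1", "pyramidal", "8-20", "injured", 27, 34, 79),
    ("CA1", "interneuron", "8-20", "sham", 27, 29, 93),
    ("CA1", "interneuron", "8-20", "injured", 22, 25, 88),
    ("MS", "GABA/Glu", "2-5", "sham", 24, 82, 29),
    ("MS", "GABA/Glu", "2-5", "injured", 52, 143, 36),
    ("MS", "GABA/Glu", "8-20", "sham", 28, 82, 34),
    ("MS", "GABA/Glu", "8-20", "injured", 44, 143, 31),
    ("MS", "cholinergic", "2-5", "sham", 18, 36, 29),   # printed pct inconsistent
    ("MS", "cholinergic", "2-5", "injured", 11, 24, 46),
    ("MS", "cholinergic", "8-20", "sham", 18, 36, 50),
    ("MS", "cholinergic", "8-20", "injured", 9, 24, 38),
]


def reported_entrainment_counts() -> pd.DataFrame:
    return pd.DataFrame(
        _ROWS,
        columns=["region", "subtype", "band", "group",
                 "entrained", "total", "printed_pct"],
    )


def entrained_percentages() -> pd.DataFrame:
    """Recompute entrained percentages from the raw counts."""
    df = reported_entrainment_counts()
    df["pct"] = 100.0 * df["entrained"] / df["total"]
    df["consistent"] = df["pct"].round(0).astype(int) == df["printed_pct"]
    return df
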