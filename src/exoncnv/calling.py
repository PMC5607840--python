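"""Threshold-run CNV caller for exon-targeted aCGH log2-ratio profiles.

The caller declares a deletion wherever at least ``min_probes``
consecutive probes all have a log2 ratio strictly below ``del_log2``
(default -0.6), and a duplication wherever at least ``min_probes``
consecutive probes are strictly above ``gain_log2`` (default 0.4).
"Consecutive" means adjacent rows of the position-sorted probe table
with no interruption; runs never cross a chromosome boundary.  Call
boundaries are the positions of the first and last supporting probes.

Input profiles are assumed pre-normalized log2 ratios; no
centralization or wave correction is applied here.  The same thresholds
apply on male chrX — hemizygous losses (log2 well below -1) are still
"loss"; dosage interpretation happens downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "CallerThresholds",
    "CnvCall",
    "call_cnvs",
    "estimate_mosaic_fraction",
]


@dataclass(frozen=True)
class CallerThresholds:
    """Fixed log2 thresholds of the run caller.

    ``del_log2`` must be negative and ``gain_log2`` positive, so a probe
    can never support both a loss and a gain.
    """

    del_log2: float = -0.6
    gain_log2: float = 0.4
    min_probes: int = 3

    def __post_init__(self):
        if not (self.del_log2 < 0.0 < self.gain_log2):
            raise ValueError("need del_log2 < 0 < gain_log2")
        if self.min_probes < 1:
            raise ValueError("min_probes must be >= 1")


@dataclass
class CnvCall:
    """One called copy-number event.

    ``start``/``end`` are the 1-based positions of the first and last
    supporting probes.  ``mosaic_fraction_est`` is filled by
    :func:`estimate_mosaic_fraction` when requested; ``mosaic_flag``
    records "sub_threshold" when the mean signal implies a non-positive
    cell fraction.
    """

    sample_id: Optional[str]
    chrom: str
    start: int
    end: int
    type: str  # "loss" | "gain"
    n_probes: int
    mean_log2: float
    mosaic_fraction_est: Optional[float] = None
    mosaic_flag: Optional[str] = None

    @property
    def size_bp(self) -> int:
        return self.end - self.start + 1

    @property
    def id(self) -> str:
        return f"{self.sample_id}:{self.chrom}:{self.start}-{self.end}:{self.type}"


def _runs(mask: np.ndarray, min_len: int):
    """Yield (i, j) half-open index bounds of maximal True runs of length >= min_len."""
    if mask.size == 0:
        return
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    for i, j in zip(starts, ends):
        if j - i >= min_len:
            yield int(i), int(j)


def call_cnvs(
    probes: pd.DataFrame,
    thresholds: CallerThresholds = CallerThresholds(),
    sample_id: Optional[str] = None,
    estimate_mosaics: bool = False,
) -> list:
    """Call CNVs from one sample's probe table.

    Parameters
    ----------
    probes : DataFrame
        Columns ``chrom``, ``pos``, ``log2`` (extra columns ignored),
        sorted by chromosome block then strictly increasing position.
        Unsorted input raises; it is never silently re-sorted.
    thresholds : CallerThresholds
    sample_id : str, optional
        Stamped onto the emitted calls.
    estimate_mosaics : bool
        Also invert the mean log2 into a mosaic-fraction estimate.

    Returns
    -------
    list of CnvCall, non-overlapping, in input (genomic) order.
    """
    if len(probes) == 0:
        return []
    chroms = probes["chrom"].to_numpy()
    pos = probes["pos"].to_numpy()
    log2 = probes["log2"].to_numpy(dtype=float)
    if not np.all(np.isfinite(log2)):
        raise ValueError("non-finite log2 ratios in probe table")

    # locate contiguous chromosome blocks; a chromosome may not reappear
    block_start = np.flatnonzero(np.concatenate(([True], chroms[1:] != chroms[:-1])))
    block_end = np.concatenate((block_start[1:], [len(chroms)]))
    seen = set()
    calls: list = []
    for bs, be in zip(block_start, block_end):
        chrom = chroms[bs]
        if chrom in seen:
            raise ValueError(f"probe table not sorted: chromosome {chrom} reappears")
        seen.add(chrom)
        p = pos[bs:be]
        if np.any(np.diff(p) <= 0):
            raise ValueError(f"probe table not sorted: positions on {chrom} not strictly increasing")
        v = log2[bs:be]
        events = []
        for i, j in _runs(v < thresholds.del_log2, thresholds.min_probes):
            events.append((i, j, "loss"))
        for i, j in _runs(v > thresholds.gain_log2, thresholds.min_probes):
            events.append((i, j, "gain"))
        events.sort()
        for i, j, kind in events:
            call = CnvCall(
                sample_id=sample_id,
                chrom=str(chrom),
                start=int(p[i]),
                end=int(p[j - 1]),
                type=kind,
                n_probes=j - i,
                mean_log2=float(v[i:j].mean()),
            )
            if estimate_mosaics:
                call.mosaic_fraction_est = estimate_mosaic_fraction(call)
                if call.mosaic_fraction_est is None:
                    call.mosaic_flag = "sub_threshold"
            calls.append(call)
    return calls


def estimate_mosaic_fraction(call: CnvCall) -> Optional[float]:
    """Invert the mean log2 ratio into a mosaic cell fraction.

    Assumes a one-copy event against a diploid background: a fraction f
    of cells carrying a heterozygous loss gives an expected ratio
    (2 - f)/2, hence f = 2 - 2^(mean_log2 + 1); a one-copy gain gives
    (2 + f)/2, hence f = 2^(mean_log2 + 1) - 2.  The estimate is clamped
    to (0, 1]; constitutional events (including hemizygous male-X losses,
    whose ratio goes far below -1) therefore report 1.0.  A mean signal
    implying f <= 0 returns None ("sub-threshold").
    """
    if call.type == "loss":
        f = 2.0 - 2.0 ** (call.mean_log2 + 1.0)
    elif call.type == "gain":
        f = 2.0 ** (call.mean_log2 + 1.0) - 2.0
    else:
        raise ValueError(f"unknown call type {call.type!r}")
    if not math.isfinite(f) or f <= 0.0:
        return None
    return min(f, 1.0)
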