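"""Interval lookup helpers (0-based half-open throughout)."""

from __future__ import annotations

import numpy as np
import pandas as pd


def assign_nonoverlapping(intervals: pd.DataFrame, chroms: np.ndarray,
                          pos0: np.ndarray) -> np.ndarray:
    """Map 0-based positions to row indices of a sorted, non-overlapping
    interval table; -1 where no interval contains the position."""
    out = np.full(len(pos0), -1, dtype=np.int64)
    for chrom, grp in intervals.groupby("chrom", sort=False):
        mask = chroms == chrom
        if not mask.any():
            continue
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        p = pos0[mask]
        idx = np.searchsorted(starts, p, side="right") - 1
        valid = (idx >= 0) & (p < ends[np.clip(idx, 0, len(ends) - 1)])
        rows = grp.index.to_numpy()[np.clip(idx, 0, len(ends) - 1)]
        out[np.flatnonzero(mask)] = np.where(valid, rows, -1)
    return out


def overlapping_hits(intervals: pd.DataFrame, chrom: str, pos0: int) -> list[int]:
    """Row indices of all intervals containing pos0 (intervals may overlap)."""
    grp = intervals[intervals["chrom"] == chrom]
    contained = (grp["start"] <= pos0) & (pos0 < grp["end"])
    return list(grp.index[contained])


def covered_mask(intervals: pd.DataFrame, chroms: np.ndarray,
                 pos0: np.ndarray) -> np.ndarray:
    """Boolean mask: position lies inside at least one interval."""
    hit = np.zeros(len(pos0), dtype=bool)
    for chrom, grp in intervals.groupby("chrom", sort=False):
        mask = chroms == chrom
        if not mask.any():
            continue
        p = pos0[mask]
        sub = np.zeros(p.shape, dtype=bool)
        for start, end in zip(grp["start"].to_numpy(), grp["end"].to_numpy()):
            sub |= (p >= start) & (p < end)
        hit[np.flatnonzero(mask)] = sub
    return hit
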