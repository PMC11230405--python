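"""Genomic-interval primitives and BED-family input/output.

Intervals are 0-based half-open, carried as pandas DataFrames with at least
``chrom``, ``start`` and ``end`` columns.  The overlap/merge/coverage
operations below are simple sorted-array sweeps — sufficient for the interval
algebra this pipeline needs (any-overlap membership, merging, and
replicate-coverage thresholding).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

BED_COLS = ["chrom", "start", "end"]


def read_bed(path: str, extra_cols: list[str] | None = None) -> pd.DataFrame:
    """Read a BED(+) file; ``extra_cols`` names columns 4, 5, ..."""
    cols = BED_COLS + (extra_cols or [])
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=cols).astype({"start": int, "end": int})
    df = df.iloc[:, : len(cols)]
    df.columns = cols[: df.shape[1]]
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def write_bed(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping or touching intervals per chromosome."""
    out = []
    for chrom, grp in df.sort_values(["chrom", "start"]).groupby(
            "chrom", sort=True):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=BED_COLS)


def any_overlap(query: pd.DataFrame, targets: pd.DataFrame) -> np.ndarray:
    """Boolean per query row: does it overlap any target interval?"""
    flags = np.zeros(len(query), dtype=bool)
    if len(targets) == 0 or len(query) == 0:
        return flags
    merged = merge_intervals(targets)
    for chrom, tgrp in merged.groupby("chrom"):
        qmask = (query["chrom"] == chrom).to_numpy()
        if not qmask.any():
            continue
        t_starts = tgrp["start"].to_numpy()
        t_ends = tgrp["end"].to_numpy()
        q_starts = query.loc[qmask, "start"].to_numpy()
        q_ends = query.loc[qmask, "end"].to_numpy()
        j = np.searchsorted(t_starts, q_ends, side="left")
        hit = (j > 0) & (t_ends[np.maximum(j - 1, 0)] > q_starts)
        flags[np.where(qmask)[0]] = hit
    return flags


def coverage_intervals(replicates: list[pd.DataFrame], min_reps: int,
                       min_width: int = 1) -> pd.DataFrame:
    """Positions covered by >= ``min_reps`` replicates, as merged intervals.

    Each replicate's intervals are merged first, so overlapping peaks within
    one replicate count once.
    """
    events: dict[str, list[tuple[int, int]]] = {}
    for rep in replicates:
        if len(rep) == 0:
            continue
        for chrom, grp in merge_intervals(rep).groupby("chrom"):
            ev = events.setdefault(chrom, [])
            ev.extend((s, 1) for s in grp["start"])
            ev.extend((e, -1) for e in grp["end"])
    out = []
    for chrom in sorted(events):
        ev = sorted(events[chrom])
        pos = np.array([p for p, _ in ev])
        delta = np.array([d for _, d in ev])
        # collapse simultaneous events, then running coverage
        upos, inv = np.unique(pos, return_inverse=True)
        dsum = np.zeros(len(upos), dtype=int)
        np.add.at(dsum, inv, delta)
        cov = np.cumsum(dsum)
        above = cov >= min_reps
        for i in range(len(upos) - 1):
            if above[i]:
                out.append((chrom, int(upos[i]), int(upos[i + 1])))
    if not out:
        return pd.DataFrame(columns=BED_COLS)
    df = merge_intervals(pd.DataFrame(out, columns=BED_COLS))
    return df[df["end"] - df["start"] >= min_width].reset_index(drop=True)
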