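"""Interval arithmetic on 0-based half-open genomic intervals.

All functions operate on pandas DataFrames with at least the columns
``chrom``, ``start``, ``end`` (``start < end``, half-open).  These helpers
back the annotation catalog, the enrichment module's overlap sweep and the
profile extractors; they are deliberately small and fully deterministic.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

INTERVAL_COLS = ["chrom", "start", "end"]


def as_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and return a copy restricted to the interval columns."""
    missing = [c for c in INTERVAL_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"interval frame lacks columns {missing}")
    out = df.copy()
    if (out["start"] >= out["end"]).any():
        raise ValueError("intervals must satisfy start < end (half-open)")
    if (out["start"] < 0).any():
        raise ValueError("negative interval start")
    return out


def sort_intervals(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Union of intervals: merge overlapping/adjacent intervals per chromosome."""
    if len(df) == 0:
        return df.copy()
    df = sort_intervals(as_intervals(df)[INTERVAL_COLS])
    rows = []
    for chrom, sub in df.groupby("chrom", sort=True):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e:  # overlapping or abutting -> merge
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        rows.append((chrom, cur_s, cur_e))
    return pd.DataFrame(rows, columns=INTERVAL_COLS)


def complement_intervals(df: pd.DataFrame, chrom_sizes: dict[str, int]) -> pd.DataFrame:
    """Gaps not covered by ``df`` over the given chromosomes."""
    merged = merge_intervals(df) if len(df) else pd.DataFrame(columns=INTERVAL_COLS)
    rows = []
    for chrom, size in chrom_sizes.items():
        sub = merged[merged["chrom"] == chrom] if len(merged) else merged
        prev = 0
        if len(sub):
            for s, e in zip(sub["start"], sub["end"]):
                if s > prev:
                    rows.append((chrom, prev, s))
                prev = max(prev, e)
        if prev < size:
            rows.append((chrom, prev, size))
    return pd.DataFrame(rows, columns=INTERVAL_COLS)


def _is_sorted_disjoint(starts: np.ndarray, ends: np.ndarray) -> bool:
    if len(starts) <= 1:
        return True
    return bool(np.all(starts[1:] >= ends[:-1]))


def overlap_any(regions: pd.DataFrame, features: pd.DataFrame) -> np.ndarray:
    """Per-region flag: does the region intersect >= 1 bp of any feature?

    Linear sweep on sorted, merged features per chromosome.  Unsorted or
    self-overlapping feature input is merged internally with a warning.
    Half-open semantics: [100,200) and [200,300) do NOT overlap.
    """
    regions = as_intervals(regions)
    out = np.zeros(len(regions), dtype=bool)
    if len(features) == 0 or len(regions) == 0:
        return out
    features = as_intervals(features)
    feats_by_chrom = {}
    for chrom, sub in features.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        order = np.argsort(starts, kind="mergesort")
        starts, ends = starts[order], ends[order]
        if not _is_sorted_disjoint(starts, ends):
            warnings.warn("features self-overlap or were unsorted; merging internally")
            m = merge_intervals(sub)
            starts, ends = m["start"].to_numpy(), m["end"].to_numpy()
        feats_by_chrom[chrom] = (starts, ends)
    for chrom, sub in regions.groupby("chrom", sort=False):
        if chrom not in feats_by_chrom:
            continue
        fs, fe = feats_by_chrom[chrom]
        rs = sub["start"].to_numpy()
        re_ = sub["end"].to_numpy()
        # first feature whose end is > region start; overlap iff its start < region end
        idx = np.searchsorted(fe, rs, side="right")
        hit = (idx < len(fs)) & (fs[np.minimum(idx, len(fs) - 1)] < re_)
        out[regions.index.get_indexer(sub.index)] = hit
    return out


def total_length(df: pd.DataFrame) -> int:
    m = merge_intervals(df)
    if len(m) == 0:
        return 0
    return int((m["end"] - m["start"]).sum())
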