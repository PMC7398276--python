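"""Genome model and interval arithmetic.

All intervals follow the BED convention: 0-based, half-open ``[start, end)``.
allc cytosine positions are 1-based (see :mod:`methkit.allc`); conversion
between the two conventions is centralised here via :func:`pos_to_interval`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

INTERVAL_COLS = ["chrom", "start", "end"]


def interval_frame(records) -> pd.DataFrame:
    """Build a canonical interval DataFrame from (chrom, start, end[, ...]) rows."""
    df = pd.DataFrame(records, columns=INTERVAL_COLS if records and len(records[0]) == 3 else None)
    if df.empty:
        return empty_intervals()
    df = df.rename(columns=dict(zip(df.columns[:3], INTERVAL_COLS)))
    return sort_intervals(df)


def empty_intervals() -> pd.DataFrame:
    return pd.DataFrame({"chrom": pd.Series(dtype=object),
                         "start": pd.Series(dtype=np.int64),
                         "end": pd.Series(dtype=np.int64)})


def sort_intervals(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)


def validate_intervals(df: pd.DataFrame) -> None:
    if len(df) and not (df["start"] < df["end"]).all():
        bad = df[~(df["start"] < df["end"])].iloc[0]
        raise ValueError(f"invalid interval {bad['chrom']}:{bad['start']}-{bad['end']}")
    if len(df) and (df["start"] < 0).any():
        raise ValueError("negative interval start")


def pos_to_interval(pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """1-based site position -> 0-based half-open single-base interval."""
    pos = np.asarray(pos)
    return pos - 1, pos


def merge_intervals(df: pd.DataFrame, gap: int = 0) -> pd.DataFrame:
    """Merge intervals whose gap is <= ``gap`` (0 merges overlapping/abutting)."""
    if df.empty:
        return empty_intervals()
    df = sort_intervals(df[INTERVAL_COLS])
    out = []
    for chrom, sub in df.groupby("chrom", sort=True):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s - cur_e <= gap:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=INTERVAL_COLS)


def intersect_intervals(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Base-level intersection of two interval sets (each merged internally)."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    out = []
    for chrom, sub_a in a.groupby("chrom"):
        sub_b = b[b["chrom"] == chrom]
        if sub_b.empty:
            continue
        bs, be = sub_b["start"].to_numpy(), sub_b["end"].to_numpy()
        for s, e in zip(sub_a["start"].to_numpy(), sub_a["end"].to_numpy()):
            lo = np.searchsorted(be, s, side="right")
            hi = np.searchsorted(bs, e, side="left")
            for j in range(lo, hi):
                os_, oe = max(s, bs[j]), min(e, be[j])
                if os_ < oe:
                    out.append((chrom, os_, oe))
    if not out:
        return empty_intervals()
    return sort_intervals(pd.DataFrame(out, columns=INTERVAL_COLS))


def subtract_intervals(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Bases of ``a`` not covered by ``b``."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    out = []
    for chrom, sub_a in a.groupby("chrom"):
        sub_b = b[b["chrom"] == chrom]
        bs, be = sub_b["start"].to_numpy(), sub_b["end"].to_numpy()
        for s, e in zip(sub_a["start"].to_numpy(), sub_a["end"].to_numpy()):
            cur = s
            lo = np.searchsorted(be, s, side="right")
            hi = np.searchsorted(bs, e, side="left")
            for j in range(lo, hi):
                if bs[j] > cur:
                    out.append((chrom, cur, min(bs[j], e)))
                cur = max(cur, be[j])
            if cur < e:
                out.append((chrom, cur, e))
    if not out:
        return empty_intervals()
    return sort_intervals(pd.DataFrame(out, columns=INTERVAL_COLS))


def total_bases(df: pd.DataFrame) -> int:
    m = merge_intervals(df)
    return int((m["end"] - m["start"]).sum()) if len(m) else 0


def overlap_bases(query: pd.DataFrame, targets: pd.DataFrame) -> np.ndarray:
    """Per query interval, number of bases covered by the (merged) targets."""
    targets = merge_intervals(targets)
    result = np.zeros(len(query), dtype=np.int64)
    for chrom, sub_t in targets.groupby("chrom"):
        mask = (query["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        qs = query.loc[mask, "start"].to_numpy()
        qe = query.loc[mask, "end"].to_numpy()
        ts, te = sub_t["start"].to_numpy(), sub_t["end"].to_numpy()
        cov_cum = np.concatenate([[0], np.cumsum(te - ts)])

        def cov_upto(p):
            # total target bases in [0, p); targets are merged & sorted
            i = np.searchsorted(ts, p, side="right") - 1
            safe = np.maximum(i, 0)
            base = np.where(i >= 0, cov_cum[safe], 0)
            inside = np.where(i >= 0, np.clip(p - ts[safe], 0, te[safe] - ts[safe]), 0)
            return base + inside

        result[mask] = cov_upto(qe) - cov_upto(qs)
    return result


def overlaps_any(query: pd.DataFrame, targets: pd.DataFrame) -> np.ndarray:
    return overlap_bases(query, targets) > 0


def positions_in_intervals(pos: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Boolean mask: is 1-based site position inside any (merged, sorted) interval."""
    if len(starts) == 0:
        return np.zeros(len(pos), dtype=bool)
    p0 = np.asarray(pos) - 1  # 0-based base index
    idx = np.searchsorted(starts, p0, side="right") - 1
    ok = idx >= 0
    inside = np.zeros(len(p0), dtype=bool)
    inside[ok] = p0[ok] < ends[idx[ok]]
    return inside


def mask_sites(pos: np.ndarray, chrom: str, intervals: pd.DataFrame) -> np.ndarray:
    sub = merge_intervals(intervals[intervals["chrom"] == chrom]) if len(intervals) else empty_intervals()
    return positions_in_intervals(pos, sub["start"].to_numpy(), sub["end"].to_numpy())


def jaccard(a: pd.DataFrame, b: pd.DataFrame) -> float:
    """Base-level Jaccard index between two interval sets."""
    inter = total_bases(intersect_intervals(a, b))
    union = total_bases(a) + total_bases(b) - inter
    return inter / union if union else 0.0


@dataclass
class GenomeSpec:
    """A synthetic or real genome skeleton: chromosome sizes, cytosine
    positions by context, and named annotation tracks.

    ``cg_positions[chrom]`` holds the 1-based position of the + strand C of
    each CpG dyad (the - strand C sits at position + 1).  ``ch_positions``
    holds CH cytosines with their trinucleotide context and strand.
    """

    chrom_names: list[str]
    chrom_lengths: dict[str, int]
    cg_positions: dict[str, np.ndarray]
    ch_positions: dict[str, np.ndarray]
    ch_contexts: dict[str, np.ndarray]
    ch_strands: dict[str, np.ndarray]
    annotation_tracks: dict[str, pd.DataFrame] = field(default_factory=dict)

    def validate(self) -> None:
        for chrom in self.chrom_names:
            L = self.chrom_lengths[chrom]
            if L <= 0:
                raise ValueError(f"zero-length chromosome {chrom}")
            cg = self.cg_positions.get(chrom, np.empty(0, dtype=np.int64))
            ch = self.ch_positions.get(chrom, np.empty(0, dtype=np.int64))
            for arr, label in ((cg, "CG"), (ch, "CH")):
                if len(arr) and (np.diff(arr) <= 0).any():
                    raise ValueError(f"{label} positions not strictly increasing on {chrom}")
                if len(arr) and (arr[-1] > L or arr[0] < 1):
                    raise ValueError(f"{label} position outside {chrom}")
            # CG dyads occupy pos and pos+1; neither may collide with CH sites
            occupied = set(cg.tolist()) | set((cg + 1).tolist())
            if occupied & set(ch.tolist()):
                raise ValueError(f"CG and CH positions overlap on {chrom}")
        for name, track in self.annotation_tracks.items():
            validate_intervals(track)
            for _, row in track.iterrows():
                if row["end"] > self.chrom_lengths.get(row["chrom"], -1):
                    raise ValueError(f"annotation {name} outside chromosome bounds")

    def track(self, name: str) -> pd.DataFrame:
        return self.annotation_tracks.get(name, empty_intervals())

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())
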