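"""Enrichment statistics: hypergeometric item enrichment with BH control,
Monte-Carlo interval-shuffle overlap tests, and Monte-Carlo gene-set
resampling tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genome import merge_intervals, overlap_bases, overlaps_any, subtract_intervals


def extend_to_mean_width(regions: pd.DataFrame, target_mean: int = 400) -> pd.DataFrame:
    """Symmetrically extend regions so their mean width reaches
    ``target_mean`` bp (size-normalisation before motif enrichment).
    Regions already at or above the target mean are returned unchanged."""
    widths = regions["end"] - regions["start"]
    mean_w = widths.mean()
    if len(regions) == 0 or mean_w >= target_mean:
        return regions.copy()
    pad = int(round((target_mean - mean_w) / 2))
    out = regions.copy()
    out["start"] = np.maximum(out["start"] - pad, 0)
    out["end"] = out["end"] + pad
    return out


def hypergeom_pvalue(n_f: int, N_f: int, n_b: int, N_b: int) -> float:
    """Upper-tail probability of seeing >= n_f foreground overlaps.

    P = sum_{x=n_f}^{n_t} C(N_f, x) C(N_b, n_t - x) / C(N_t, n_t)
    with n_t = n_f + n_b and N_t = N_f + N_b.
    """
    n_t = n_f + n_b
    N_t = N_f + N_b
    if n_f == 0 or N_f == 0 or n_t == 0:
        return 1.0
    return float(stats.hypergeom.sf(n_f - 1, N_t, N_f, n_t))


def hypergeom_enrichment(overlaps: pd.DataFrame, N_f: int, N_b: int,
                         fdr: float = 0.01,
                         tf_tpm: pd.Series | None = None,
                         min_tpm: float = 10.0) -> pd.DataFrame:
    """Per-item (e.g. TF motif) enrichment of foreground vs background
    region overlap counts.

    ``overlaps`` needs columns item, n_f, n_b (number of foreground /
    background regions overlapped by at least one occurrence of the item).
    BH adjustment runs across all items of one call (one tissue).  When a
    ``tf_tpm`` Series is supplied, items whose expression falls below
    ``min_tpm`` are dropped before testing.
    """
    df = overlaps.copy()
    if tf_tpm is not None:
        expr = df["item"].map(tf_tpm).fillna(0.0)
        df = df[expr >= min_tpm].reset_index(drop=True)
    if (df["n_f"] > N_f).any() or (df["n_b"] > N_b).any():
        raise ValueError("overlap count exceeds region count")
    df["p"] = [hypergeom_pvalue(nf, N_f, nb, N_b)
               for nf, nb in zip(df["n_f"], df["n_b"])]
    if len(df):
        order = np.argsort(df["p"].to_numpy(), kind="stable")
        n = len(df)
        adj = df["p"].to_numpy()[order] * n / np.arange(1, n + 1)
        adj = np.minimum.accumulate(adj[::-1])[::-1]
        p_adj = np.empty(n)
        p_adj[order] = np.minimum(adj, 1.0)
        df["p_adj"] = p_adj
        df["significant"] = df["p_adj"] <= fdr
    else:
        df["p_adj"] = []
        df["significant"] = []
    df["N_f"] = N_f
    df["N_b"] = N_b
    return df


@dataclass
class MCResult:
    """A Monte-Carlo permutation test outcome.

    p = (sum_i I(x_obs <= x_i) + 1) / (k + 1); the indicator is inclusive,
    so p is floored at 1/(k+1) and ties count against enrichment.
    """

    observed: float
    permuted: np.ndarray = field(repr=False)
    statistic: str = "count"

    @property
    def k(self) -> int:
        return len(self.permuted)

    @property
    def p(self) -> float:
        return (int(np.sum(self.observed <= self.permuted)) + 1) / (self.k + 1)

    @property
    def fold_enrichment(self) -> float:
        mean_perm = float(np.mean(self.permuted))
        return self.observed / mean_perm if mean_perm > 0 else float("inf")


def _usable_space(chrom_lengths: dict[str, int], gaps: pd.DataFrame):
    """Per-chromosome placeable coordinate blocks (chromosome minus gaps)."""
    space = {}
    for chrom, L in chrom_lengths.items():
        whole = pd.DataFrame({"chrom": [chrom], "start": [0], "end": [L]})
        sub = gaps[gaps["chrom"] == chrom] if len(gaps) else gaps
        usable = subtract_intervals(whole, sub) if len(sub) else whole
        space[chrom] = usable[["start", "end"]].to_numpy()
    return space


def _flat_blocks(chrom_lengths: dict[str, int], gaps: pd.DataFrame):
    """Usable blocks flattened across chromosomes: (chrom labels, starts,
    lengths) arrays."""
    space = _usable_space(chrom_lengths, gaps)
    chroms, starts, lens = [], [], []
    for c, blk in space.items():
        for s, e in blk:
            chroms.append(c)
            starts.append(int(s))
            lens.append(int(e - s))
    return np.asarray(chroms), np.asarray(starts, dtype=np.int64), \
        np.asarray(lens, dtype=np.int64)


def shuffle_intervals(features: pd.DataFrame, chrom_lengths: dict[str, int],
                      gaps: pd.DataFrame, rng: np.random.Generator,
                      _blocks=None) -> pd.DataFrame:
    """Length-preserving uniform re-placement of features.

    Each feature lands uniformly in the usable space (chromosomes minus
    assembly gaps), with placement probability proportional to the number
    of start coordinates that can host its length; shuffled features may
    overlap each other (the shuffleBed-default dialect).
    """
    b_chrom, b_start, b_len = _blocks if _blocks is not None \
        else _flat_blocks(chrom_lengths, gaps)
    feat_len = (features["end"] - features["start"]).to_numpy()
    n = len(feat_len)
    out_chrom = np.empty(n, dtype=object)
    out_start = np.empty(n, dtype=np.int64)
    for flen in np.unique(feat_len):
        sel = feat_len == flen
        fit = np.maximum(b_len - flen + 1, 0)
        tot = fit.sum()
        if tot == 0:
            raise ValueError(f"feature of length {flen} fits nowhere in the genome")
        blk = rng.choice(len(fit), size=int(sel.sum()), p=fit / tot)
        offset = np.floor(rng.random(int(sel.sum())) * fit[blk]).astype(np.int64)
        out_chrom[sel] = b_chrom[blk]
        out_start[sel] = b_start[blk] + offset
    return pd.DataFrame({"chrom": out_chrom, "start": out_start,
                         "end": out_start + feat_len})


def mc_overlap_test(features: pd.DataFrame, targets: pd.DataFrame,
                    chrom_lengths: dict[str, int], gaps: pd.DataFrame | None = None,
                    k: int = 1000, seed: int = 0,
                    statistic: str = "count") -> MCResult:
    """Monte-Carlo interval-shuffle test of feature/target overlap.

    ``statistic="count"`` counts features overlapping any target (the
    transposon-overlap dialect); ``"bases"`` sums overlapping bases (used
    for intragenic-fraction style questions).  Shuffles are uniform,
    length-preserving and exclude assembly gaps.
    """
    from .genome import empty_intervals
    gaps = gaps if gaps is not None else empty_intervals()
    targets = merge_intervals(targets)
    t_by_chrom = {c: (sub["start"].to_numpy(), sub["end"].to_numpy())
                  for c, sub in targets.groupby("chrom")}

    def count_overlapping(chrom_arr, start_arr, end_arr) -> int:
        # merged+sorted targets: a feature overlaps iff the first target
        # ending after its start begins before its end
        total = 0
        for c, (ts, te) in t_by_chrom.items():
            m = chrom_arr == c
            if not m.any():
                continue
            j = np.searchsorted(te, start_arr[m], side="right")
            ok = j < len(ts)
            hit = np.zeros(int(m.sum()), dtype=bool)
            hit[ok] = ts[j[ok]] < end_arr[m][ok]
            total += int(hit.sum())
        return total

    def stat_of(regions):
        if statistic == "count":
            return count_overlapping(regions["chrom"].to_numpy(),
                                     regions["start"].to_numpy(),
                                     regions["end"].to_numpy())
        if statistic == "bases":
            return int(overlap_bases(regions, targets).sum())
        raise ValueError(f"unknown statistic {statistic!r}")

    rng = np.random.default_rng(seed)
    observed = stat_of(features)
    blocks = _flat_blocks(chrom_lengths, gaps)
    permuted = np.empty(k, dtype=float)
    for i in range(k):
        shuf = shuffle_intervals(features, chrom_lengths, gaps, rng, _blocks=blocks)
        permuted[i] = stat_of(shuf)
    return MCResult(observed=float(observed), permuted=permuted, statistic=statistic)


def mc_geneset_test(query: set, universe: list, property_set: set,
                    k: int = 1000, seed: int = 0) -> MCResult:
    """Monte-Carlo resampling test: is |query ∩ property| larger than for
    random same-size draws from the universe (without replacement)?"""
    universe = list(universe)
    query = set(query)
    if not query <= set(universe):
        raise ValueError("query genes must be a subset of the universe")
    if len(query) > len(universe):
        raise ValueError("query larger than universe")
    rng = np.random.default_rng(seed)
    prop = np.asarray([g in property_set for g in universe])
    observed = len(query & property_set)
    n = len(query)
    permuted = np.empty(k, dtype=float)
    for i in range(k):
        idx = rng.choice(len(universe), size=n, replace=False)
        permuted[i] = prop[idx].sum()
    return MCResult(observed=float(observed), permuted=permuted, statistic="count")
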