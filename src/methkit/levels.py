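"""Methylation levels, binned level tracks, the significant-mCH binomial
test and sequence-context tallies.

The methylation level of a site or region is the pooled ratio of methylated
basecalls over total basecalls, minus the bisulfite non-conversion rate
(estimated from the unmethylated lambda spike-in), clamped at zero.  Region
levels always pool counts before dividing — they are never a mean of
per-site levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .allc import is_cg_context

#: sentinel for a level that cannot be computed (zero coverage)
UNDEFINED = float("nan")


def methylation_level(mc_sum, cov_sum, nonconversion: float = 0.0):
    """Pooled methylation level with non-conversion correction.

    level = max(0, mc_sum / cov_sum - nonconversion).  Zero coverage yields
    NaN (an undefined level is never reported as 0).  Accepts scalars or
    arrays.
    """
    mc_sum = np.asarray(mc_sum, dtype=float)
    cov_sum = np.asarray(cov_sum, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(cov_sum > 0, mc_sum / np.where(cov_sum > 0, cov_sum, 1), np.nan)
    level = np.clip(raw - nonconversion, 0.0, 1.0)
    level = np.where(cov_sum > 0, level, np.nan)
    if level.ndim == 0:
        return float(level)
    return level


@dataclass
class LevelTrack:
    """Non-overlapping fixed-width bins tiling one or more chromosomes.

    ``table`` columns: chrom, start, end, level, n_sites, frac_covered,
    mc, cov.  Bins failing the site-count / coverage criteria (or with no
    reads at all) carry ``level = NaN`` and ``has_data = False``.
    """

    bin_size: int
    context: str  # "CG" or "CH"
    table: pd.DataFrame

    def with_data(self) -> pd.DataFrame:
        return self.table[self.table["has_data"]]


def binned_levels(sites: pd.DataFrame, chrom_lengths: dict[str, int], bin_size: int,
                  context: str = "CG", nonconversion: float = 0.0,
                  min_sites: int = 1, min_covered_fraction: float = 0.0,
                  cov_threshold: int = 10) -> LevelTrack:
    """Pool site counts into fixed-width bins and compute corrected levels.

    A bin is flagged no-data when it has fewer than ``min_sites`` sites of
    the requested context, when fewer than ``min_covered_fraction`` of its
    sites reach ``cov_threshold`` reads, or when its pooled coverage is zero.
    CG input should be strand-merged.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    cg_mask = is_cg_context(sites["context"]) if len(sites) else np.empty(0, dtype=bool)
    sel = cg_mask if context == "CG" else ~cg_mask
    sites = sites[sel]
    rows = []
    for chrom in chrom_lengths:
        L = chrom_lengths[chrom]
        n_bins = (L + bin_size - 1) // bin_size
        sub = sites[sites["chrom"] == chrom]
        pos0 = sub["pos"].to_numpy() - 1
        which = pos0 // bin_size
        mc = np.bincount(which, weights=sub["mc"].to_numpy(), minlength=n_bins)
        cov = np.bincount(which, weights=sub["cov"].to_numpy(), minlength=n_bins)
        n_sites = np.bincount(which, minlength=n_bins)
        n_covered = np.bincount(which, weights=(sub["cov"].to_numpy() >= cov_threshold),
                                minlength=n_bins)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(n_sites > 0, n_covered / np.maximum(n_sites, 1), 0.0)
        level = methylation_level(mc, cov, nonconversion)
        has_data = (n_sites >= min_sites) & (frac >= min_covered_fraction) & (cov > 0)
        starts = np.arange(n_bins, dtype=np.int64) * bin_size
        rows.append(pd.DataFrame({
            "chrom": chrom, "start": starts,
            "end": np.minimum(starts + bin_size, L),
            "level": np.where(has_data, level, np.nan),
            "n_sites": n_sites.astype(np.int64), "frac_covered": frac,
            "mc": mc.astype(np.int64), "cov": cov.astype(np.int64),
            "has_data": has_data,
        }))
    table = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
    return LevelTrack(bin_size=bin_size, context=context, table=table)


@dataclass
class SignificantSiteSet:
    """Sites whose methylation exceeds non-conversion noise, per context."""

    sites: pd.DataFrame           # allc columns + p; significant rows only
    cutoffs: dict[str, float]     # per-context BH p-value cutoff
    pvalues: pd.DataFrame         # all tested sites with p


def bh_cutoff(pvals: np.ndarray, fdr: float) -> float:
    """Largest Benjamini-Hochberg-passing p (0.0 when nothing passes)."""
    p = np.sort(np.asarray(pvals, dtype=float))
    n = len(p)
    if n == 0:
        return 0.0
    thresh = fdr * np.arange(1, n + 1) / n
    ok = p <= thresh
    return float(p[np.nonzero(ok)[0][-1]]) if ok.any() else 0.0


def mch_site_test(ch_sites: pd.DataFrame, nonconversion: float,
                  fdr: float = 0.01, min_cov: int = 1) -> SignificantSiteSet:
    """Binomial test of each CH site against the non-conversion rate.

    Per site, p = P(X >= mc | n = cov, p = nonconversion).  BH control at
    ``fdr`` is applied independently within each trinucleotide context, so
    each context gets its own p-value cutoff.
    """
    if not 0.0 < nonconversion < 1.0:
        raise ValueError("nonconversion must lie in (0, 1); supply a floor "
                         "when the lambda estimate is zero")
    df = ch_sites[ch_sites["cov"] >= min_cov].copy()
    mc = df["mc"].to_numpy()
    cov = df["cov"].to_numpy()
    df["p"] = stats.binom.sf(mc - 1, cov, nonconversion)
    cutoffs: dict[str, float] = {}
    keep = np.zeros(len(df), dtype=bool)
    for ctx, idx in df.groupby("context").indices.items():
        cut = bh_cutoff(df["p"].to_numpy()[idx], fdr)
        cutoffs[ctx] = cut
        keep[idx] = df["p"].to_numpy()[idx] <= cut if cut > 0 else False
    return SignificantSiteSet(sites=df[keep].reset_index(drop=True),
                              cutoffs=cutoffs, pvalues=df)


def context_preference(seqs: list[str], center: int = 5) -> pd.DataFrame:
    """Position-specific base counts around significant sites.

    ``seqs`` are equal-length strings centred on the cytosine at index
    ``center`` (e.g. an 11-mer for +/-5 bp).  Returns a positions x bases
    count matrix indexed by offset from the cytosine; each column of the
    transposed matrix (each position) sums to the number of counted sites.
    Bases outside ACGT are not counted.
    """
    bases = ["A", "C", "G", "T"]
    if not seqs:
        return pd.DataFrame(0, index=pd.Index([], name="offset"), columns=bases)
    width = len(seqs[0])
    if any(len(s) != width for s in seqs):
        raise ValueError("sequences must share one length")
    counts = np.zeros((width, 4), dtype=np.int64)
    arr = np.frombuffer("".join(seqs).upper().encode(), dtype="S1").reshape(len(seqs), width)
    for j, b in enumerate(bases):
        counts[:, j] = (arr == b.encode()).sum(axis=0)
    idx = pd.Index(np.arange(width) - center, name="offset")
    return pd.DataFrame(counts, index=idx, columns=bases)


def write_significant_sites(sig: SignificantSiteSet, bed_path, tsv_path) -> None:
    """Serialise significant mCH sites: BED6 with a scaled p in the score
    field (-10 log10 p, capped at 1000) and the exact p in a side TSV."""
    from .allc import _open_text
    with _open_text(bed_path, "wt") as bed, _open_text(tsv_path, "wt") as tsv:
        tsv.write("chrom\tpos\tstrand\tcontext\tmc\tcov\tp\n")
        for _, r in sig.sites.iterrows():
            score = int(min(-10 * np.log10(max(r["p"], 1e-300)), 1000))
            bed.write(f"{r['chrom']}\t{r['pos'] - 1}\t{r['pos']}\t{r['context']}"
                      f"\t{score}\t{r['strand']}\n")
            tsv.write(f"{r['chrom']}\t{r['pos']}\t{r['strand']}\t{r['context']}"
                      f"\t{r['mc']}\t{r['cov']}\t{r['p']:.6g}\n")


def global_level(sites: pd.DataFrame, context: str, nonconversion: float = 0.0) -> float:
    """Genome-wide pooled level for one context (counts pooled, then divided)."""
    cg = is_cg_context(sites["context"])
    sel = cg if context == "CG" else ~cg
    sub = sites[sel]
    return methylation_level(sub["mc"].sum(), sub["cov"].sum(), nonconversion)
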