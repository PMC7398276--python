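"""CG-DMR calling and downstream annotation.

The pipeline is: per-site differential test across samples (DMSs), merging
of compatible nearby DMSs into CG-DMRs, a bulk-baseline outlier scan that
labels each DMR's hypomethylated samples (tissue specificity), effect
sizes, loss/gain event accounting across developmental stages, category
assignment, the mCG/H3K27ac association table and trajectory clustering.

The per-site test is a permutation goodness-of-fit test: the statistic is
the root-mean-square deviation of per-sample methylated fractions from the
pooled fraction, and the null redistributes the pooled methylated reads
across samples at fixed per-sample coverage (sequential hypergeometric
draws, equivalent to a multivariate hypergeometric).  Liver-like globally
hypomethylated samples are excluded by the caller, and biological
replicates are combined before testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .genome import overlaps_any
from .levels import bh_cutoff, methylation_level

PROXIMAL_PRIORITY = ["cgi_promoter", "non_cgi_promoter", "cgi", "cgi_shore"]
DISTAL_CATEGORIES = ["distal_fedmr", "flanking_distal_fedmr", "primed_distal_fedmr",
                     "te_unxdmr", "nte_unxdmr"]
ALL_CATEGORIES = PROXIMAL_PRIORITY + DISTAL_CATEGORIES


def stack_counts(samples: dict[str, pd.DataFrame]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align per-sample allc tables on (chrom, pos): returns (mc, cov)
    DataFrames with one column per sample, outer-joined with 0 fill."""
    mcs, covs = [], []
    for name, df in samples.items():
        idx = df.set_index(["chrom", "pos"])
        mcs.append(idx["mc"].rename(name))
        covs.append(idx["cov"].rename(name))
    mc = pd.concat(mcs, axis=1).fillna(0).astype(np.int64).sort_index()
    cov = pd.concat(covs, axis=1).fillna(0).astype(np.int64).sort_index()
    return mc, cov


def _rms_stat(mc: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """RMS deviation of per-sample fractions from the pooled fraction."""
    pooled = mc.sum(axis=-1, keepdims=True) / cov.sum(axis=-1, keepdims=True)
    frac = mc / cov
    return np.sqrt(np.mean((frac - pooled) ** 2, axis=-1))


def _permute_exceed(rng, Mt, Ct, idx, obs, n_perm, chunk=200):
    """For each site in ``idx``: count permutations whose RMS statistic
    reaches the observed one.  Null draws redistribute the pooled
    methylated reads over samples at fixed coverage (sequential
    hypergeometric, i.e. multivariate hypergeometric)."""
    n_samples = Mt.shape[1]
    total_mc = Mt[idx].sum(axis=1)
    total_cov = Ct[idx].sum(axis=1)
    pooled = total_mc / total_cov
    exceed = np.zeros(len(idx), dtype=np.int64)
    for lo in range(0, n_perm, chunk):
        B = min(chunk, n_perm - lo)
        rem_good = np.broadcast_to(total_mc, (B, len(idx))).copy()
        rem_tot = np.broadcast_to(total_cov, (B, len(idx))).copy()
        sq = np.zeros((B, len(idx)))
        for s in range(n_samples):
            cs = Ct[idx, s]
            draw = rng.hypergeometric(rem_good, rem_tot - rem_good,
                                      np.broadcast_to(cs, (B, len(idx))))
            sq += (draw / cs - pooled[None, :]) ** 2
            rem_good -= draw
            rem_tot -= cs
        perm_stat = np.sqrt(sq / n_samples)
        exceed += (perm_stat >= obs[idx][None, :]).sum(axis=0)
    return exceed


def call_dms(mc: pd.DataFrame, cov: pd.DataFrame, n_permutations: int = 1000,
             fdr: float = 0.01, hypo_margin: float = 0.1,
             seed: int | None = 0, escalate_p: float = 0.02,
             max_permutations: int = 30_000) -> pd.DataFrame:
    """Permutation test for differentially methylated sites.

    ``mc`` / ``cov`` are (sites x samples) count matrices indexed by
    (chrom, pos) with replicates already combined.  Sites with zero
    coverage in any sample are not tested (NaN p).

    Permutations are adaptive: every testable site gets
    ``n_permutations`` draws, and sites whose first-stage p falls at or
    below ``escalate_p`` continue to ``max_permutations`` so their
    p-values gain the resolution BH needs at low FDR (a p floored at
    1/(k+1) could otherwise never clear the threshold when true signal is
    sparse).  Each reported p uses all permutations run for that site and
    the inclusive (count + 1)/(k + 1) convention.

    Returns a DataFrame indexed like the input with columns stat, p,
    is_dms and hypo_samples (samples whose fraction sits more than
    ``hypo_margin`` below the across-sample mean — the pattern label used
    for merging).
    """
    if mc.shape[1] < 2:
        raise ValueError("need at least 2 samples for differential testing")
    rng = np.random.default_rng(seed)
    M = mc.to_numpy(dtype=np.int64)
    C = cov.to_numpy(dtype=np.int64)
    n_sites, n_samples = M.shape
    testable = (C > 0).all(axis=1)
    p = np.full(n_sites, np.nan)
    stat = np.full(n_sites, np.nan)

    Mt, Ct = M[testable], C[testable]
    obs = _rms_stat(Mt, Ct)
    stat[testable] = obs
    total_mc = Mt.sum(axis=1)
    total_cov = Ct.sum(axis=1)
    # sites where every read agrees have statistic 0; every permutation ties,
    # so p = 1 by the inclusive (+1)/(k+1) convention without sampling
    degenerate = (total_mc == 0) | (total_mc == total_cov)
    active = np.nonzero(~degenerate)[0]
    exceed = np.full(len(obs), n_permutations, dtype=np.int64)
    n_perm_used = np.full(len(obs), n_permutations, dtype=np.int64)
    exceed[active] = _permute_exceed(rng, Mt, Ct, active, obs, n_permutations)
    p_stage1 = (exceed[active] + 1) / (n_permutations + 1)
    esc = active[p_stage1 <= escalate_p]
    if len(esc) and max_permutations > n_permutations:
        extra = max_permutations - n_permutations
        exceed[esc] += _permute_exceed(rng, Mt, Ct, esc, obs, extra)
        n_perm_used[esc] = max_permutations
    p[testable] = (exceed + 1) / (n_perm_used + 1)

    out = pd.DataFrame(index=mc.index)
    out["stat"] = stat
    out["p"] = p
    tested = out["p"].dropna()
    cut = bh_cutoff(tested.to_numpy(), fdr)
    out["is_dms"] = out["p"] <= cut if cut > 0 else False
    frac = np.where(C > 0, M / np.maximum(C, 1), np.nan)
    mean_frac = np.nanmean(frac, axis=1, keepdims=True)
    hypo = frac < mean_frac - hypo_margin
    names = np.asarray(mc.columns)
    out["hypo_samples"] = [tuple(names[row]) for row in hypo]
    return out


def merge_dms_to_dmrs(dms: pd.DataFrame, max_gap: int = 250,
                      min_dms: int = 3) -> pd.DataFrame:
    """Merge DMSs into CG-DMRs.

    Adjacent DMSs join one block when they are within ``max_gap`` bp AND
    their hypo-sample sets intersect (the pattern-compatibility rule).
    Blocks with fewer than ``min_dms`` DMSs are discarded.  ``dms`` needs
    index (chrom, pos) and a hypo_samples column; only rows flagged
    ``is_dms`` (when present) are used.  The output interval covers the
    member dyads: [first_pos - 1, last_pos + 1).
    """
    if "is_dms" in dms.columns:
        dms = dms[dms["is_dms"]]
    records = []
    for chrom in dms.index.get_level_values(0).unique():
        sub = dms.xs(chrom, level=0).sort_index()
        if sub.empty:
            continue
        positions = sub.index.to_numpy()
        hypos = [set(h) for h in sub["hypo_samples"]]
        block = [0]
        for i in range(1, len(sub)):
            if (positions[i] - positions[block[-1]] <= max_gap
                    and hypos[i] & hypos[block[-1]]):
                block.append(i)
            else:
                records.append((chrom, positions[block[0]], positions[block[-1]], len(block),
                                tuple(positions[j] for j in block)))
                block = [i]
        if block:
            records.append((chrom, positions[block[0]], positions[block[-1]], len(block),
                            tuple(positions[j] for j in block)))
    df = pd.DataFrame(records, columns=["chrom", "first", "last", "n_dms", "dms_pos"])
    df = df[df["n_dms"] >= min_dms].reset_index(drop=True)
    df["start"] = df["first"] - 1
    df["end"] = df["last"] + 1
    return df[["chrom", "start", "end", "n_dms", "dms_pos"]]


def dmr_levels(dmrs: pd.DataFrame, mc: pd.DataFrame, cov: pd.DataFrame,
               nonconversion: float = 0.0) -> pd.DataFrame:
    """Per-sample pooled methylation level of each CG-DMR (counts pooled
    over member DMSs, then corrected)."""
    levels = np.full((len(dmrs), mc.shape[1]), np.nan)
    for i, row in dmrs.reset_index(drop=True).iterrows():
        idx = [(row["chrom"], p) for p in row["dms_pos"]]
        sub_mc = mc.loc[idx].sum(axis=0).to_numpy()
        sub_cov = cov.loc[idx].sum(axis=0).to_numpy()
        levels[i] = methylation_level(sub_mc, sub_cov, nonconversion)
    return pd.DataFrame(levels, columns=mc.columns)


@dataclass
class BaselineResult:
    """Bulk baseline of one region's level vector across N samples.

    The bulk is the narrowest window of ceil(N/2) consecutive order
    statistics; ``a`` is its 0-based start in the sorted vector, ``b`` its
    mean.  ``hypo`` holds the original sample indices whose level sits at
    least ``margin`` below ``b``.
    """

    n: int
    order: np.ndarray
    a: int
    b: float
    hypo: tuple[int, ...]
    margin: float


def baseline_bulk(levels, margin: float = 0.3) -> BaselineResult:
    """Bulk-baseline outlier detection for one region.

    Sorts the N levels, finds the window of w = ceil(N/2) consecutive
    values with the smallest range (ties break to the smallest start
    index; equal values keep their stable sample order), takes the window
    mean as baseline b, and flags samples with x - b <= -margin as
    hypomethylated.
    """
    x = np.asarray(levels, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    if np.isnan(x).any():
        raise ValueError("missing level; drop regions with uncovered samples upstream")
    n = len(x)
    w = -(-n // 2)  # ceil(N/2)
    order = np.argsort(x, kind="stable")
    xs = x[order]
    ranges = xs[w - 1:] - xs[:n - w + 1]
    a = int(np.argmin(ranges))  # argmin returns the first (smallest a) on ties
    b = float(xs[a:a + w].mean())
    hypo = tuple(int(i) for i in np.nonzero(x - b <= -margin)[0])
    return BaselineResult(n=n, order=order, a=a, b=b, hypo=hypo, margin=margin)


def baseline_bulk_matrix(levels: np.ndarray, margin: float = 0.3):
    """Vectorised :func:`baseline_bulk` over M regions (rows).

    Returns (b, hypo) with b shape (M,) and hypo a boolean (M, N) mask.
    Rows containing NaN yield NaN baseline and an all-False mask.
    """
    x = np.asarray(levels, dtype=float)
    m, n = x.shape
    w = -(-n // 2)
    xs = np.sort(x, axis=1)
    ranges = xs[:, w - 1:] - xs[:, :n - w + 1]
    a = np.argmin(ranges, axis=1)
    idx = a[:, None] + np.arange(w)[None, :]
    b = np.take_along_axis(xs, idx, axis=1).mean(axis=1)
    ok = ~np.isnan(x).any(axis=1)
    b = np.where(ok, b, np.nan)
    hypo = (x - b[:, None] <= -margin) & ok[:, None]
    return b, hypo


def effect_size(levels, baseline: BaselineResult | None = None,
                margin: float = 0.3) -> float:
    """Gap between the most hypomethylated sample and the bulk baseline."""
    if baseline is None:
        baseline = baseline_bulk(levels, margin=margin)
    return float(abs(np.min(np.asarray(levels, dtype=float)) - baseline.b))


def tissue_specific_dmrs(levels: pd.DataFrame, margin: float = 0.3) -> pd.DataFrame:
    """Baseline scan over a DMR x sample level matrix.

    Regions with any missing (NaN) level are dropped, mirroring the
    upstream zero-coverage exclusion.  Returns per region: baseline,
    effect, hypo_samples (tuple of column names) and tissue_specific flag.
    """
    x = levels.to_numpy(dtype=float)
    b, hypo = baseline_bulk_matrix(x, margin=margin)
    names = np.asarray(levels.columns)
    out = pd.DataFrame(index=levels.index)
    out["baseline"] = b
    with np.errstate(invalid="ignore"):
        out["effect"] = np.abs(np.nanmin(x, axis=1) - b)
    out["hypo_samples"] = [tuple(names[row]) for row in hypo]
    out["tissue_specific"] = hypo.any(axis=1)
    ok = ~np.isnan(x).any(axis=1)
    return out[ok]


def count_mcg_events(trajectory, delta: float = 0.1) -> pd.DataFrame:
    """Loss/gain accounting along one stage-ordered level trajectory.

    A stage interval is the transition between two adjacent sampled
    stages; a drop of at least ``delta`` is one loss-of-mCG event and a
    rise of at least ``delta`` one gain-of-mCG event.  At most one of each
    per interval per region by construction.
    """
    x = np.asarray(trajectory, dtype=float)
    if len(x) < 2:
        return pd.DataFrame(columns=["interval", "loss", "gain"])
    d = np.diff(x)
    return pd.DataFrame({"interval": np.arange(len(d)),
                         "loss": d <= -delta, "gain": d >= delta})


def count_events_table(trajectories: pd.DataFrame, delta: float = 0.1) -> pd.DataFrame:
    """Aggregate loss/gain events over many regions (rows = regions,
    columns = chronologically ordered stages).  Returns per stage interval
    the total loss and gain counts."""
    x = trajectories.to_numpy(dtype=float)
    d = np.diff(x, axis=1)
    losses = (d <= -delta).sum(axis=0)
    gains = (d >= delta).sum(axis=0)
    labels = [f"{a}-{b}" for a, b in zip(trajectories.columns[:-1], trajectories.columns[1:])]
    return pd.DataFrame({"interval": labels, "loss": losses, "gain": gains})


def categorize_dmrs(dmrs: pd.DataFrame, promoters: pd.DataFrame, cgis: pd.DataFrame,
                    shores: pd.DataFrame, transposons: pd.DataFrame,
                    enhancer_scores: np.ndarray | None = None,
                    tissue_specific: np.ndarray | None = None,
                    score_cutoff: float = 0.3, flank_dist: int = 1000) -> pd.Series:
    """Assign each CG-DMR exactly one category.

    Proximal DMRs (overlapping a promoter, CGI or CGI shore) take the
    highest-priority overlapping feature: CGI promoter > non-CGI promoter >
    CGI > CGI shore.  Remaining distal DMRs become: distal feDMR when
    enhancer score > ``score_cutoff``; flanking when within ``flank_dist``
    bp of a distal feDMR; primed when tissue-specifically hypomethylated;
    otherwise unexplained (te/nte by transposon overlap).  Categories
    partition the input.
    """
    n = len(dmrs)
    cat = pd.Series(pd.NA, index=dmrs.index, dtype=object)
    prom_is_cgi = overlaps_any(promoters, cgis) if len(promoters) else np.empty(0, bool)
    cgi_prom = promoters[prom_is_cgi]
    non_cgi_prom = promoters[~prom_is_cgi]
    for name, track in (("cgi_promoter", cgi_prom), ("non_cgi_promoter", non_cgi_prom),
                        ("cgi", cgis), ("cgi_shore", shores)):
        hit = overlaps_any(dmrs, track)
        cat[cat.isna() & hit] = name
    distal = cat.isna()
    if enhancer_scores is not None:
        scores = np.asarray(enhancer_scores, dtype=float)
        fedmr = distal.to_numpy() & (scores > score_cutoff)
        cat[fedmr] = "distal_fedmr"
        fe_regions = dmrs[fedmr]
        if len(fe_regions):
            widened = fe_regions.copy()
            widened["start"] = np.maximum(widened["start"] - flank_dist, 0)
            widened["end"] = widened["end"] + flank_dist
            near = overlaps_any(dmrs, widened)
            cat[cat.isna() & near] = "flanking_distal_fedmr"
    elif distal.any():
        import warnings
        warnings.warn("no enhancer scores supplied: feDMR tiers skipped for distal DMRs")
    if tissue_specific is not None:
        cat[cat.isna() & np.asarray(tissue_specific, dtype=bool)] = "primed_distal_fedmr"
    rest = cat.isna()
    if rest.any():
        te = overlaps_any(dmrs, transposons)
        cat[rest & te] = "te_unxdmr"
        cat[rest & ~te] = "nte_unxdmr"
    assert cat.notna().all() and len(cat) == n
    return cat


H3K27AC_BINS = [0.0, 2.0, 4.0, 6.0, np.inf]
H3K27AC_LABELS = ["[0,2]", "(2,4]", "(4,6]", "(6,inf)"]
MCG_LABELS = ["L", "M", "H"]


def mcg_h3k27ac_association(mcg: np.ndarray, h3k27ac: np.ndarray) -> pd.DataFrame:
    """3x4 contingency table of mCG class vs H3K27ac enrichment class.

    Rows: L (mCG <= 0.2), M (0.2 < mCG <= 0.6), H (mCG > 0.6).  Columns:
    [0,2], (2,4], (4,6], (6,inf); negative enrichment falls in the first
    column.  Cell counts sum to the number of paired observations.
    """
    mcg = np.asarray(mcg, dtype=float)
    ac = np.clip(np.asarray(h3k27ac, dtype=float), 0.0, None)
    row = np.where(mcg <= 0.2, 0, np.where(mcg <= 0.6, 1, 2))
    col = np.clip(np.searchsorted(H3K27AC_BINS[1:-1], ac, side="left"), 0, 3)
    table = np.zeros((3, 4), dtype=np.int64)
    np.add.at(table, (row, col), 1)
    return pd.DataFrame(table, index=MCG_LABELS, columns=H3K27AC_LABELS)


def normalize_h3k27ac(matrix: np.ndarray) -> np.ndarray:
    """Per-row rescaling of H3K27ac enrichment to [0, 1]: negatives clamp
    to zero, each row divides by its maximum; all-zero rows stay zero."""
    x = np.clip(np.asarray(matrix, dtype=float), 0.0, None)
    mx = x.max(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(mx > 0, x / np.where(mx > 0, mx, 1.0), 0.0)
    return out


def cluster_dmr_trajectories(mcg: np.ndarray, h3k27ac: np.ndarray, k: int,
                             seed: int = 0) -> np.ndarray:
    """k-means over concatenated [mCG trajectory, rescaled H3K27ac
    trajectory] vectors; returns cluster labels."""
    mcg = np.asarray(mcg, dtype=float)
    if k > mcg.shape[0]:
        raise ValueError("k exceeds number of regions")
    feats = np.concatenate([mcg, normalize_h3k27ac(h3k27ac)], axis=1)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    return km.fit_predict(feats)
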