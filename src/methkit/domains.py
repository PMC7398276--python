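"""Large-scale methylome features: large hypo CG-DMR blocks, DNA
methylation valleys (DMVs), partially methylated domains (PMDs) and
non-CG methylation (mCH) domains, plus mCH-domain clustering and the
expression-repression contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestClassifier

from .genome import (INTERVAL_COLS, empty_intervals, intersect_intervals,
                     mask_sites, merge_intervals, overlaps_any, sort_intervals,
                     total_bases)
from .levels import LevelTrack
from .segment import SCALE_FACTOR, pelt_segment

# ---------------------------------------------------------------------------
# Large hypo CG-DMRs


def call_large_hypo(tissue_dmrs: pd.DataFrame, gap: int = 1000,
                    min_length: int = 2000) -> pd.DataFrame:
    """Merge one tissue's tissue-specific CG-DMRs within ``gap`` bp and
    keep merged blocks of at least ``min_length`` bp."""
    merged = merge_intervals(tissue_dmrs, gap=gap)
    keep = (merged["end"] - merged["start"]) >= min_length
    return merged[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# DMVs


def dmv_blocks(track: LevelTrack, threshold: float = 0.15,
               min_bins: int = 5) -> pd.DataFrame:
    """Runs of 1-kb bins below ``threshold`` in one replicate.

    No-data bins are skipped: they neither break a run nor count toward
    the ``min_bins`` with-data minimum.  A with-data bin at or above the
    threshold terminates the run.  Block intervals span from the first to
    the last with-data bin of the run.
    """
    out = []
    for chrom, sub in track.table.groupby("chrom", sort=True):
        run: list[tuple[int, int]] = []
        for start, end, level, has_data in zip(sub["start"], sub["end"],
                                               sub["level"], sub["has_data"]):
            if not has_data:
                continue
            if level < threshold:
                run.append((start, end))
            else:
                if len(run) >= min_bins:
                    out.append((chrom, run[0][0], run[-1][1], len(run)))
                run = []
        if len(run) >= min_bins:
            out.append((chrom, run[0][0], run[-1][1], len(run)))
    if not out:
        df = empty_intervals()
        df["n_bins"] = pd.Series(dtype=np.int64)
        return df
    return pd.DataFrame(out, columns=INTERVAL_COLS + ["n_bins"])


def reconcile_replicates(rep1: pd.DataFrame, rep2: pd.DataFrame) -> pd.DataFrame:
    """Keep calls from either replicate that overlap a call in the other,
    then merge overlapping survivors."""
    if rep1.empty or rep2.empty:
        return empty_intervals()
    k1 = rep1[overlaps_any(rep1, rep2)]
    k2 = rep2[overlaps_any(rep2, rep1)]
    return merge_intervals(pd.concat([k1[INTERVAL_COLS], k2[INTERVAL_COLS]]))


def call_dmvs(replicate_tracks: dict[str, list[LevelTrack]], threshold: float = 0.15,
              min_bins: int = 5) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """DMVs per sample (replicate-reproducible) and the cross-sample union.

    ``replicate_tracks`` maps sample name -> list of per-replicate 1-kb CG
    LevelTracks.  With a single replicate, its blocks are used directly
    (with a warning path handled by the caller).
    """
    per_sample: dict[str, pd.DataFrame] = {}
    for name, tracks in replicate_tracks.items():
        blocks = [dmv_blocks(t, threshold=threshold, min_bins=min_bins) for t in tracks]
        if len(blocks) >= 2:
            per_sample[name] = reconcile_replicates(blocks[0], blocks[1])
        else:
            per_sample[name] = merge_intervals(blocks[0])
    frames = [df for df in per_sample.values() if len(df)]
    final = merge_intervals(pd.concat(frames)) if frames else empty_intervals()
    return per_sample, final


# ---------------------------------------------------------------------------
# PMDs

PMD_PERCENTILES = np.arange(5, 100, 5)  # 5th..95th, 19 features


def pmd_bin_features(cg_sites: pd.DataFrame, chrom_lengths: dict[str, int],
                     exclude: pd.DataFrame, bin_size: int = 10_000,
                     min_sites: int = 10, min_cov: int = 5,
                     nonconversion: float = 0.0) -> pd.DataFrame:
    """Percentile features of per-site mCG levels in 10-kb bins.

    Sites inside ``exclude`` (CGIs, DMVs, Hox-like loci) or with fewer
    than ``min_cov`` reads are discarded; bins retaining fewer than
    ``min_sites`` sites are flagged no-data.  Features are the 5th-95th
    percentiles (steps of 5) of the per-site corrected methylation levels;
    they are invariant to site order.
    """
    feat_cols = [f"p{q}" for q in PMD_PERCENTILES]
    rows = []
    for chrom, L in chrom_lengths.items():
        sub = cg_sites[cg_sites["chrom"] == chrom]
        pos = sub["pos"].to_numpy()
        cov = sub["cov"].to_numpy()
        mc = sub["mc"].to_numpy()
        drop = mask_sites(pos, chrom, exclude) | (cov < min_cov)
        pos, cov, mc = pos[~drop], cov[~drop], mc[~drop]
        with np.errstate(divide="ignore", invalid="ignore"):
            lev = np.clip(mc / np.maximum(cov, 1) - nonconversion, 0.0, 1.0)
        n_bins = (L + bin_size - 1) // bin_size
        which = (pos - 1) // bin_size
        order = np.argsort(which, kind="stable")
        which, lev = which[order], lev[order]
        bounds = np.searchsorted(which, np.arange(n_bins + 1))
        for b in range(n_bins):
            vals = lev[bounds[b]:bounds[b + 1]]
            start = b * bin_size
            row = {"chrom": chrom, "start": start, "end": min(start + bin_size, L),
                   "n_sites": len(vals), "has_data": len(vals) >= min_sites}
            if row["has_data"]:
                row.update(dict(zip(feat_cols, np.percentile(vals, PMD_PERCENTILES))))
            else:
                row.update(dict.fromkeys(feat_cols, np.nan))
            rows.append(row)
    return pd.DataFrame(rows)


def train_pmd_classifier(features: pd.DataFrame, labels: np.ndarray,
                         n_estimators: int = 1000, seed: int = 0) -> RandomForestClassifier:
    """Random forest over percentile features (PMD vs non-PMD bins).

    1000 trees by default; a 10,000-tree setting is available via
    ``n_estimators``.  All features are considered at every split
    (``max_features=None``) and out-of-bag scoring is enabled.
    """
    feat_cols = [f"p{q}" for q in PMD_PERCENTILES]
    X = features.loc[features["has_data"], feat_cols].to_numpy()
    y = np.asarray(labels)[features["has_data"].to_numpy()]
    clf = RandomForestClassifier(n_estimators=n_estimators, max_features=None,
                                 oob_score=True, random_state=seed, n_jobs=1)
    clf.fit(X, y)
    return clf


def save_pmd_classifier(clf: RandomForestClassifier, path) -> None:
    """Persist a trained PMD forest with a versioned sidecar header."""
    import json
    import joblib
    from . import __version__
    path = str(path)
    joblib.dump(clf, path)
    header = {"methkit_version": __version__, "model": "RandomForestClassifier",
              "n_estimators": clf.n_estimators,
              "features": [f"p{q}" for q in PMD_PERCENTILES]}
    with open(path + ".json", "w") as fh:
        json.dump(header, fh, indent=1)


def load_pmd_classifier(path) -> RandomForestClassifier:
    import joblib
    return joblib.load(path)


def _pmd_blocks_one_rep(features: pd.DataFrame, clf: RandomForestClassifier,
                        min_length: int, gaps: pd.DataFrame) -> pd.DataFrame:
    feat_cols = [f"p{q}" for q in PMD_PERCENTILES]
    pred = np.zeros(len(features), dtype=bool)
    hd = features["has_data"].to_numpy()
    if hd.any():
        pred[hd] = clf.predict(features.loc[hd, feat_cols].to_numpy()).astype(bool)
    bins = features[pred][INTERVAL_COLS]
    blocks = merge_intervals(bins, gap=0)
    blocks = blocks[(blocks["end"] - blocks["start"]) >= min_length]
    if len(blocks) and len(gaps):
        blocks = blocks[~overlaps_any(blocks, gaps)]
    return blocks.reset_index(drop=True)


def call_pmds(clf: RandomForestClassifier, replicate_features: list[pd.DataFrame],
              gaps: pd.DataFrame, exclusion_loci: pd.DataFrame,
              min_length: int = 100_000) -> pd.DataFrame:
    """Classify 10-kb bins per replicate and reconcile into final PMDs.

    Per replicate: consecutive PMD-predicted bins merge into blocks,
    blocks under ``min_length`` or overlapping assembly gaps are dropped.
    With two replicates the final calls are the >= ``min_length`` pieces
    of their base-level intersection; a single replicate is used alone.
    PMDs overlapping the Hox-like exclusion loci are removed last.
    """
    per_rep = [_pmd_blocks_one_rep(f, clf, min_length, gaps) for f in replicate_features]
    if len(per_rep) >= 2:
        inter = intersect_intervals(per_rep[0], per_rep[1])
        final = inter[(inter["end"] - inter["start"]) >= min_length] if len(inter) else inter
    else:
        final = per_rep[0]
    if len(final) and len(exclusion_loci):
        final = final[~overlaps_any(final, exclusion_loci)]
    return sort_intervals(final.reset_index(drop=True)) if len(final) else empty_intervals()


# ---------------------------------------------------------------------------
# mCH domains


@dataclass
class MCHDomainResult:
    excluded: pd.DataFrame
    n_iterations: int
    per_sample: dict[str, pd.DataFrame] = field(default_factory=dict)
    per_tissue: dict[str, pd.DataFrame] = field(default_factory=dict)
    final: pd.DataFrame = field(default_factory=empty_intervals)


def _sample_mch_domains(track: LevelTrack, excluded: pd.DataFrame,
                        penalty: float | None, elevation: float,
                        pseudo: float) -> pd.DataFrame:
    """One segmentation + elevation pass over a 5-kb mCH track.

    Bins overlapping the exclusion list or flagged no-data are ignored.
    Chunks (segments of the remaining bin sequence) become domains when
    their mean level is at least ``elevation`` times that of every
    existing neighbouring chunk (pseudo-level added to both sides of the
    ratio to avoid dividing by zero).
    """
    out = []
    for chrom, sub in track.table.groupby("chrom", sort=True):
        sub = sub[sub["has_data"]]
        if len(excluded):
            keep = ~overlaps_any(sub[INTERVAL_COLS], excluded)
            sub = sub[keep]
        if len(sub) < 2:
            continue
        values = sub["level"].to_numpy() * SCALE_FACTOR
        seg = pelt_segment(values, penalty=penalty, minseglen=2)
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        levels = sub["level"].to_numpy()
        chunk_levels = [levels[i:j].mean() for i, j in seg.segments]
        for c, (i, j) in enumerate(seg.segments):
            neighbours = [chunk_levels[c - 1]] if c > 0 else []
            if c + 1 < len(chunk_levels):
                neighbours.append(chunk_levels[c + 1])
            if not neighbours:
                continue
            lev = chunk_levels[c]
            if all((lev + pseudo) >= elevation * (nb + pseudo) for nb in neighbours):
                out.append((chrom, int(starts[i]), int(ends[j - 1])))
    return pd.DataFrame(out, columns=INTERVAL_COLS) if out else empty_intervals()


def call_mch_domains(tracks: dict[str, LevelTrack], meta: pd.DataFrame,
                     penalty: float | None = None, elevation: float = 1.5,
                     pseudo: float = 0.001, min_length: int = 15_000,
                     min_bins: int = 3, bin_size: int = 5000,
                     max_iterations: int = 50) -> MCHDomainResult:
    """Iterative mCH-domain calling with control-sample artefact exclusion.

    ``meta`` is indexed by sample name with columns tissue, stage,
    replicate, is_control.  Control samples (no biological mCH) are
    segmented repeatedly; any domain they yield is an artefact and joins a
    growing exclusion list until that list stops expanding.  The final
    pass segments every sample with the converged exclusions; per tissue,
    only regions called in both replicates survive, pieces shorter than
    ``min_length`` or spanning fewer than ``min_bins`` bins are dropped,
    and per-tissue calls merge into one combined list.
    """
    controls = meta.index[meta["is_control"]]
    excluded = empty_intervals()
    n_iter = 0
    while True:
        n_iter += 1
        if n_iter > max_iterations:
            raise RuntimeError(
                f"mCH exclusion loop did not converge in {max_iterations} iterations "
                f"({total_bases(excluded)} bases excluded so far)")
        found = [_sample_mch_domains(tracks[s], excluded, penalty, elevation, pseudo)
                 for s in controls]
        combined = merge_intervals(pd.concat([excluded] + found)) if found else excluded
        if total_bases(combined) == total_bases(excluded):
            break
        excluded = combined

    result = MCHDomainResult(excluded=excluded, n_iterations=n_iter)
    for s in meta.index:
        result.per_sample[s] = _sample_mch_domains(tracks[s], excluded, penalty,
                                                   elevation, pseudo)
    for tissue, group in meta.groupby("tissue"):
        pieces = []
        for stage, stage_group in group.groupby("stage"):
            reps = [result.per_sample[s] for s in stage_group.index]
            if len(reps) >= 2:
                agreed = intersect_intervals(reps[0], reps[1])
            else:
                agreed = reps[0]
            pieces.append(agreed)
        tissue_calls = merge_intervals(pd.concat(pieces)) if pieces else empty_intervals()
        if len(tissue_calls):
            length = tissue_calls["end"] - tissue_calls["start"]
            tissue_calls = tissue_calls[(length >= min_length)
                                        & (length >= min_bins * bin_size)]
        result.per_tissue[tissue] = tissue_calls.reset_index(drop=True)
    frames = [df for df in result.per_tissue.values() if len(df)]
    result.final = merge_intervals(pd.concat(frames)) if frames else empty_intervals()
    return result


# ---------------------------------------------------------------------------
# mCH domain profiles & clustering

PROFILE_FLANK_BINS = 20
PROFILE_BODY_BINS = 10
PROFILE_LEN = 2 * PROFILE_FLANK_BINS + PROFILE_BODY_BINS


def mch_domain_profile(domain: pd.Series, track: LevelTrack, bin_size: int = 5000,
                       pseudo: float = 0.001) -> np.ndarray:
    """Length-50 normalised mCH profile of one domain in one sample:
    20 upstream 5-kb bins, 10 equal body divisions, 20 downstream bins,
    each divided by the mean level of the 40 flanking bins (pseudo-level
    in the denominator).  Domains shorter than 10 body bins still divide
    into 10 fractional parts."""
    tab = track.table[track.table["chrom"] == domain["chrom"]]
    starts = tab["start"].to_numpy()
    levels = np.where(tab["has_data"].to_numpy(), tab["level"].to_numpy(), np.nan)

    def bin_level_at(coord):
        i = np.searchsorted(starts, coord, side="right") - 1
        if i < 0 or i >= len(starts):
            return np.nan
        return levels[i]

    up = [bin_level_at(domain["start"] - (k + 1) * bin_size)
          for k in reversed(range(PROFILE_FLANK_BINS))]
    down = [bin_level_at(domain["end"] + k * bin_size)
            for k in range(PROFILE_FLANK_BINS)]
    body = []
    width = (domain["end"] - domain["start"]) / PROFILE_BODY_BINS
    for k in range(PROFILE_BODY_BINS):
        lo = domain["start"] + k * width
        hi = domain["start"] + (k + 1) * width
        i0 = max(np.searchsorted(starts, lo, side="right") - 1, 0)
        i1 = np.searchsorted(starts, hi, side="left")
        seg = levels[i0:max(i1, i0 + 1)]
        body.append(np.nanmean(seg) if np.isfinite(seg).any() else np.nan)
    profile = np.array(up + body + down, dtype=float)
    flanks = np.concatenate([profile[:PROFILE_FLANK_BINS], profile[-PROFILE_FLANK_BINS:]])
    denom = (np.nanmean(flanks) if np.isfinite(flanks).any() else 0.0) + pseudo
    profile = np.nan_to_num(profile, nan=0.0)
    return profile / denom


def cluster_mch_domains(domains: pd.DataFrame, tracks: dict[str, LevelTrack],
                        sample_names: list[str], k: int = 5, bin_size: int = 5000,
                        pseudo: float = 0.001, seed: int = 0):
    """k-means over concatenated per-sample length-50 domain profiles."""
    feats = []
    profiles = {}
    for _, dom in domains.iterrows():
        vecs = [mch_domain_profile(dom, tracks[s], bin_size=bin_size, pseudo=pseudo)
                for s in sample_names]
        profiles[(dom["chrom"], dom["start"], dom["end"])] = np.stack(vecs)
        feats.append(np.concatenate(vecs))
    X = np.stack(feats)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(X)
    return labels, profiles


# ---------------------------------------------------------------------------
# Expression contrast


def mch_repression_zscores(tpm: pd.DataFrame, sample_meta: pd.DataFrame,
                           domain_genes: set, tissue: str) -> pd.Series:
    """Relative expression trajectory of genes inside mCH domains.

    For one tissue, each gene's TPM across that tissue's stages is
    z-scored (non-expressed and zero-variance genes are skipped); the
    result per stage is mean z of domain-overlapping genes minus mean z of
    genes outside all domains, so sustained repression of domain genes
    drives the late-stage values negative.
    """
    cols = sample_meta.index[sample_meta["tissue"] == tissue]
    meta = sample_meta.loc[cols].sort_values("stage_order") \
        if "stage_order" in sample_meta.columns else sample_meta.loc[cols]
    ordered = meta.index
    sub = tpm[ordered]
    expressed = (sub.sum(axis=1) > 0) & (sub.std(axis=1, ddof=0) > 0)
    sub = sub[expressed]
    z = sub.sub(sub.mean(axis=1), axis=0).div(sub.std(axis=1, ddof=0), axis=0)
    in_dom = z.index.isin(domain_genes)
    rel = z[in_dom].mean(axis=0) - z[~in_dom].mean(axis=0)
    rel.index = meta.loc[ordered, "stage"].to_numpy()
    return rel
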