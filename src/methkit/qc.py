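"""Sample-level quality control and mappability-style annotation filters."""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .allc import is_cg_context, merge_strand_cg


@dataclass
class QCReport:
    """Per-sample QC: strand-combined CG coverage, lambda non-conversion,
    and (when a partner replicate is supplied) the Pearson correlation of
    per-site mCG levels at sites with >= ``min_cov`` reads in both."""

    mean_coverage: float
    nonconversion_rate: float
    replicate_r: float | None = None
    n_replicate_sites: int | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def nonconversion_from_lambda(lambda_allc: pd.DataFrame) -> float:
    """Pooled methylated fraction of the unmethylated lambda spike-in."""
    if lambda_allc.empty or lambda_allc["cov"].sum() == 0:
        raise ValueError("empty lambda table: cannot estimate non-conversion")
    return float(lambda_allc["mc"].sum() / lambda_allc["cov"].sum())


def replicate_correlation(rep1: pd.DataFrame, rep2: pd.DataFrame,
                          min_cov: int = 10) -> tuple[float, int]:
    """Pearson r of strand-merged per-site mCG fractions at sites covered by
    at least ``min_cov`` reads in both replicates."""
    frames = []
    for rep in (rep1, rep2):
        m = merge_strand_cg(rep)
        m = m[is_cg_context(m["context"])]
        frames.append(m.set_index(["chrom", "pos"])[["mc", "cov"]])
    joined = frames[0].join(frames[1], lsuffix="_1", rsuffix="_2", how="inner")
    joined = joined[(joined["cov_1"] >= min_cov) & (joined["cov_2"] >= min_cov)]
    n = len(joined)
    if n < 2:
        return float("nan"), n
    x = joined["mc_1"] / joined["cov_1"]
    y = joined["mc_2"] / joined["cov_2"]
    return float(np.corrcoef(x, y)[0, 1]), n


def compute_qc(sample_allc: pd.DataFrame, lambda_allc: pd.DataFrame,
               partner_allc: pd.DataFrame | None = None, min_cov: int = 10) -> QCReport:
    """QC metrics for one sample (replicate fields absent without a partner)."""
    r = nonconversion_from_lambda(lambda_allc)
    merged = merge_strand_cg(sample_allc)
    cg = merged[is_cg_context(merged["context"])]
    mean_cov = float(cg["cov"].mean()) if len(cg) else float("nan")
    if partner_allc is None:
        return QCReport(mean_coverage=mean_cov, nonconversion_rate=r)
    rr, n = replicate_correlation(sample_allc, partner_allc, min_cov=min_cov)
    return QCReport(mean_coverage=mean_cov, nonconversion_rate=r,
                    replicate_r=rr, n_replicate_sites=n)


def filter_mappable_transposons(transposons: pd.DataFrame,
                                sample_cg_sites: list[pd.DataFrame],
                                min_cg: int = 2, min_covered_fraction: float = 0.6,
                                cov_threshold: int = 10) -> pd.DataFrame:
    """Keep transposons measurable by WGBS across every sample.

    An element survives when it contains at least ``min_cg`` strand-merged CG
    sites and at least ``min_covered_fraction`` of those sites carry
    ``cov_threshold`` or more reads in *all* samples (replicates combined by
    the caller).  Both boundaries are inclusive: exactly 60% covered is kept.
    """
    if transposons.empty:
        return transposons.copy()
    ref = sample_cg_sites[0]
    keep = np.zeros(len(transposons), dtype=bool)
    per_chrom = {c: s for c, s in ref.groupby("chrom")}
    cov_by_sample = []
    for s in sample_cg_sites:
        cov_by_sample.append({c: sub.set_index("pos")["cov"] for c, sub in s.groupby("chrom")})
    for i, row in transposons.reset_index(drop=True).iterrows():
        sub = per_chrom.get(row["chrom"])
        if sub is None:
            continue
        pos = sub["pos"].to_numpy()
        inside = (pos - 1 >= row["start"]) & (pos - 1 < row["end"])
        n_cg = int(inside.sum())
        if n_cg < min_cg:
            continue
        site_pos = pos[inside]
        ok = np.ones(n_cg, dtype=bool)
        for cov_map in cov_by_sample:
            covs = cov_map.get(row["chrom"])
            vals = covs.reindex(site_pos).fillna(0).to_numpy() if covs is not None else np.zeros(n_cg)
            ok &= vals >= cov_threshold
        keep[i] = ok.mean() >= min_covered_fraction
    return transposons.reset_index(drop=True)[keep].reset_index(drop=True)
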