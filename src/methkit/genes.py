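"""Expressed-gene filtering and region-to-gene assignment by nearest TSS."""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

_ILL_DEFINED = re.compile(r"^(Rik|Gm[0-9])")


def filter_expressed_genes(tpm: pd.DataFrame, min_fraction: float = 0.1,
                           ontology_clean: bool = False) -> list[str]:
    """Genes with non-zero TPM in at least ``min_fraction`` of samples.

    The fraction boundary is inclusive (1 of 10 samples passes at 10%).
    With ``ontology_clean`` set, genes whose names start with 'Rik' or
    'Gm' followed by a digit are dropped (their ontology is ill-defined).
    """
    if tpm.shape[1] == 0:
        raise ValueError("TPM table has no samples")
    frac = (tpm > 0).sum(axis=1) / tpm.shape[1]
    genes = tpm.index[frac >= min_fraction]
    if ontology_clean:
        genes = [g for g in genes if not _ILL_DEFINED.match(str(g))]
    return list(genes)


def drop_ill_defined(genes) -> list[str]:
    """Remove names starting with 'Rik' or 'Gm<digit>'."""
    return [g for g in genes if not _ILL_DEFINED.match(str(g))]


def link_regions_to_genes(regions: pd.DataFrame, tss: pd.DataFrame) -> pd.Series:
    """Assign each region the gene with the nearest TSS.

    ``tss`` needs columns chrom, pos (0-based genomic coordinate of the
    transcription start) and gene.  Distance is measured to the region
    boundary; a TSS inside the region has distance 0.  Equidistant ties
    break to the lower TSS coordinate.  Returns a Series of gene names
    aligned to ``regions``' index; regions on chromosomes without any TSS
    get NA.
    """
    if tss.empty:
        raise ValueError("empty gene set")
    out = pd.Series(pd.NA, index=regions.index, dtype=object)
    for chrom, sub in tss.sort_values(["pos"]).groupby("chrom"):
        mask = regions["chrom"] == chrom
        if not mask.any():
            continue
        tpos = sub["pos"].to_numpy()
        tgene = sub["gene"].to_numpy()
        starts = regions.loc[mask, "start"].to_numpy()
        ends = regions.loc[mask, "end"].to_numpy()
        # candidate left and right neighbours of each boundary
        choices = []
        for q in (starts, ends - 1):
            i = np.searchsorted(tpos, q)
            for j in (np.clip(i - 1, 0, len(tpos) - 1), np.clip(i, 0, len(tpos) - 1)):
                choices.append(j)
        cand = np.stack(choices, axis=1)  # (n_regions, 4)
        cpos = tpos[cand]
        # distance 0 when TSS lies inside [start, end)
        dist = np.where(cpos < starts[:, None], starts[:, None] - cpos,
                        np.where(cpos >= ends[:, None], cpos - (ends[:, None] - 1), 0))
        # tie-break: among minimal distances pick lowest coordinate
        best = np.full(len(starts), -1, dtype=np.int64)
        best_d = np.full(len(starts), np.iinfo(np.int64).max)
        for k in range(cand.shape[1]):
            d, idx = dist[:, k], cand[:, k]
            better = (d < best_d) | ((d == best_d) & (tpos[idx] < np.where(best >= 0, tpos[np.maximum(best, 0)], np.iinfo(np.int64).max)))
            best[better] = idx[better]
            best_d[better] = d[better]
        out.loc[mask] = tgene[best]
    return out
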