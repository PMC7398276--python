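"""Reading and writing per-cytosine count tables (the methylpy "allc" dialect)
and plain-text BED / TPM tables.

An allc file is a TSV with one row per cytosine::

    chrom  pos  strand  context  mc  cov  [methylated-flag]

``pos`` is 1-based, ``context`` is the trinucleotide starting at the cytosine
on its own strand, ``mc``/``cov`` are methylated and total read counts.  A
seventh 0/1 column, when present, is accepted and ignored.  Gzip is handled
transparently by extension.
"""

from __future__ import annotations

import gzip
import io
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import INTERVAL_COLS, empty_intervals, sort_intervals

ALLC_COLS = ["chrom", "pos", "strand", "context", "mc", "cov"]


class AllcParseError(ValueError):
    """Raised on a malformed allc row; message names the offending line."""


def _open_text(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        if "w" in mode:
            # fixed mtime and no embedded filename keep reruns byte-identical
            raw = gzip.GzipFile(filename="", mode="wb", mtime=0,
                                fileobj=open(path, "wb"))
            return io.TextIOWrapper(raw)
        return gzip.open(path, mode)
    return open(path, mode)


def read_allc(path) -> pd.DataFrame:
    """Read an allc table into a DataFrame with columns ``ALLC_COLS``.

    Row order is preserved.  Invariant violations (mc > cov, pos <= 0,
    unknown strand) raise :class:`AllcParseError` naming the 1-based line.
    """
    rows = {k: [] for k in ALLC_COLS}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise AllcParseError(f"line {lineno}: expected >=6 columns, got {len(parts)}")
            chrom, pos_s, strand, context, mc_s, cov_s = parts[:6]
            try:
                pos, mc, cov = int(pos_s), int(mc_s), int(cov_s)
            except ValueError as exc:
                raise AllcParseError(f"line {lineno}: non-integer field ({exc})") from None
            if pos <= 0:
                raise AllcParseError(f"line {lineno}: position {pos} must be positive")
            if strand not in ("+", "-"):
                raise AllcParseError(f"line {lineno}: unknown strand {strand!r}")
            if mc > cov:
                raise AllcParseError(f"line {lineno}: mc={mc} exceeds cov={cov}")
            if mc < 0:
                raise AllcParseError(f"line {lineno}: negative mc={mc}")
            rows["chrom"].append(chrom)
            rows["pos"].append(pos)
            rows["strand"].append(strand)
            rows["context"].append(context)
            rows["mc"].append(mc)
            rows["cov"].append(cov)
    df = pd.DataFrame(rows)
    df["pos"] = df["pos"].astype(np.int64)
    df["mc"] = df["mc"].astype(np.int64)
    df["cov"] = df["cov"].astype(np.int64)
    return df


def write_allc(df: pd.DataFrame, path) -> None:
    """Write an allc table; inverse of :func:`read_allc` on canonical files."""
    with _open_text(path, "wt") as fh:
        for chrom, pos, strand, context, mc, cov in zip(
                df["chrom"], df["pos"], df["strand"], df["context"], df["mc"], df["cov"]):
            fh.write(f"{chrom}\t{pos}\t{strand}\t{context}\t{mc}\t{cov}\n")


def is_cg_context(context: pd.Series | np.ndarray) -> np.ndarray:
    """CpG rows are recognised by the second base of the trinucleotide."""
    return np.char.startswith(np.asarray(context, dtype=str), "CG")


def merge_strand_cg(df: pd.DataFrame) -> pd.DataFrame:
    """Combine the two strands of each CpG dyad into one + strand record.

    A dyad at (+: p) and (-: p+1) becomes a single row at position p with
    ``mc`` and ``cov`` summed.  Lone-strand CG rows and non-CG rows pass
    through untouched.  Input must be sorted by (chrom, pos); total mc and
    cov are conserved.
    """
    if df.empty:
        return df.copy()
    cg = is_cg_context(df["context"])
    out_parts = [df[~cg]]
    cg_df = df[cg]
    merged_rows = []
    for chrom, sub in cg_df.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        strand = sub["strand"].to_numpy()
        mc = sub["mc"].to_numpy()
        cov = sub["cov"].to_numpy()
        ctx = sub["context"].to_numpy()
        used = np.zeros(len(sub), dtype=bool)
        i = 0
        while i < len(sub):
            if (i + 1 < len(sub) and strand[i] == "+" and strand[i + 1] == "-"
                    and pos[i + 1] == pos[i] + 1):
                merged_rows.append((chrom, pos[i], "+", ctx[i], mc[i] + mc[i + 1],
                                    cov[i] + cov[i + 1]))
                i += 2
            else:
                p = pos[i] if strand[i] == "+" else pos[i] - 1
                merged_rows.append((chrom, p, "+", ctx[i], mc[i], cov[i]))
                i += 1
        del used
    if merged_rows:
        out_parts.append(pd.DataFrame(merged_rows, columns=ALLC_COLS))
    out = pd.concat(out_parts, ignore_index=True)
    return out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def combine_counts(frames: list[pd.DataFrame]) -> pd.DataFrame:
    """Sum mc/cov across samples (e.g. biological replicates) site by site.

    Sites are keyed by (chrom, pos, strand, context); missing sites count 0.
    """
    cat = pd.concat(frames, ignore_index=True)
    g = cat.groupby(["chrom", "pos", "strand"], sort=True, as_index=False)
    out = g.agg(context=("context", "first"), mc=("mc", "sum"), cov=("cov", "sum"))
    return out[ALLC_COLS].sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# BED and TPM tables


def read_bed(path) -> pd.DataFrame:
    """Read BED3/BED6 into an interval DataFrame (extra columns kept)."""
    names = ["chrom", "start", "end", "name", "score", "strand"]
    with _open_text(path) as fh:
        text = fh.read()
    if not text.strip():
        return empty_intervals()
    ncol = len(text.splitlines()[0].split("\t"))
    df = pd.read_csv(io.StringIO(text), sep="\t", header=None,
                     names=names[:ncol] + [f"extra{i}" for i in range(max(0, ncol - 6))])
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return sort_intervals(df)


def write_bed(df: pd.DataFrame, path, extra_cols: list[str] | None = None) -> None:
    cols = INTERVAL_COLS + [c for c in (extra_cols or []) if c in df.columns]
    with _open_text(path, "wt") as fh:
        for _, row in df.iterrows():
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")


def read_tpm(path) -> pd.DataFrame:
    """Read a genes x samples TPM matrix (TSV, first column = gene name)."""
    return pd.read_csv(path, sep="\t", index_col=0)
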