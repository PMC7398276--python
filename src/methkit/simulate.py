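"""Synthetic multi-tissue, multi-stage bisulfite methylomes with ground truth.

The generator emulates the statistical structure of developmental WGBS
data: a genome skeleton with CpG dyads, CH cytosines and annotation
tracks; planted tissue-specific CG-DMRs with prenatal-demethylation or
postnatal-remethylation trajectories; constitutive DMVs; liver-like PMDs;
stage-accumulating mCH domains; alignment-artefact regions that show
apparent mCH in every sample (including zero-mCH controls); and a lambda
spike-in per sample for non-conversion estimation.

Read counts follow Poisson coverage and binomial methylated basecalls with
observed probability m + (1 - m) * r, where m is the true level and r the
non-conversion rate (conversion failure only affects unmethylated
cytosines).  Everything is deterministic given the seed, and a
TruthManifest records the planted features plus the generative parameters
needed to recompute every site's exact true level.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .allc import ALLC_COLS, write_allc
from .genome import GenomeSpec, empty_intervals, mask_sites


@dataclass
class SampleDesign:
    """One sequencing library: tissue, developmental stage, replicate.

    ``is_control`` marks samples designed with zero true mCH (the early
    stages used to learn artefact regions).  ``coverage_mean`` is the
    Poisson mean read depth per allc row (per strand for CG dyads).
    """

    tissue: str
    stage: str
    replicate: int
    is_control: bool = False
    coverage_mean: float = 30.0
    nonconversion_rate: float = 0.005

    def __post_init__(self):
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be positive")
        if not 0 <= self.nonconversion_rate < 0.05:
            raise ValueError("nonconversion_rate must lie in [0, 0.05)")

    @property
    def sample_id(self) -> str:
        return f"{self.tissue}_{self.stage}_r{self.replicate}"


@dataclass
class GenomeConfig:
    chrom_lengths: dict[str, int]
    cg_density: float = 0.01   # CpG dyads per bp
    ch_density: float = 0.12   # CH cytosines per bp
    genes_per_mb: int = 25
    cgi_fraction_of_promoters: float = 0.6
    n_distal_cgis_per_mb: int = 3
    transposons_per_mb: int = 60
    seed: int = 0

    def __post_init__(self):
        for chrom, L in self.chrom_lengths.items():
            if L <= 0:
                raise ValueError(f"zero-length chromosome {chrom}")


def _rng_for(seed: int, tag: str) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(tag.encode())])


def generate_genome(config: GenomeConfig) -> GenomeSpec:
    """Build a deterministic genome skeleton from a configuration.

    CpG dyads start at even coordinates and CH sites occupy odd
    coordinates, which keeps the two site classes disjoint by
    construction.  Annotation tracks (genes/TSSs, promoters, CGIs, CGI
    shores, transposons, assembly gaps, Hox-like exclusion loci) are
    placed with simple non-overlap rules where category disjointness is
    required downstream.
    """
    cg_positions, ch_positions, ch_contexts, ch_strands = {}, {}, {}, {}
    tracks: dict[str, list] = {k: [] for k in
                               ["promoters", "cgi", "cgi_shores", "transposons",
                                "hox_like", "gaps", "tss", "gene_bodies"]}
    for ci, (chrom, L) in enumerate(config.chrom_lengths.items()):
        rng = _rng_for(config.seed, f"genome/{chrom}")
        n_cg = int(round(config.cg_density * L))
        even = np.arange(2, max(L - 2, 3), 2)
        n_cg = min(n_cg, len(even))
        cg = np.sort(rng.choice(even, size=n_cg, replace=False)) if n_cg else np.empty(0, np.int64)
        cg_positions[chrom] = cg.astype(np.int64)

        odd = np.arange(1, L, 2)
        forbidden = cg + 1  # minus-strand C of each dyad sits at an odd coordinate
        odd = np.setdiff1d(odd, forbidden, assume_unique=True)
        n_ch = min(int(round(config.ch_density * L)), len(odd))
        ch = np.sort(rng.choice(odd, size=n_ch, replace=False)) if n_ch else np.empty(0, np.int64)
        ch_positions[chrom] = ch.astype(np.int64)
        h1 = rng.choice(np.array(["A", "C", "T"]), size=n_ch, p=[0.5, 0.25, 0.25])
        h2 = rng.choice(np.array(["A", "C", "G", "T"]), size=n_ch)
        ch_contexts[chrom] = np.char.add(np.char.add("C", h1), h2)
        ch_strands[chrom] = rng.choice(np.array(["+", "-"]), size=n_ch)

        # genes with promoters; a fraction of promoters carry a CGI
        n_genes = max(int(config.genes_per_mb * L / 1e6), 1)
        spacing = L // (n_genes + 1)
        for g in range(n_genes):
            tss = (g + 1) * spacing + int(rng.integers(-spacing // 4, spacing // 4 + 1))
            tss = int(np.clip(tss, 3000, L - 25_000))
            body_len = int(rng.integers(5_000, 20_000))
            name = f"gene_{chrom}_{g}"
            tracks["tss"].append((chrom, tss, tss + 1, name))
            tracks["gene_bodies"].append((chrom, tss, min(tss + body_len, L), name))
            tracks["promoters"].append((chrom, max(tss - 2500, 0), min(tss + 2500, L), name))
            if rng.random() < config.cgi_fraction_of_promoters:
                tracks["cgi"].append((chrom, max(tss - 500, 0), min(tss + 500, L), name))
        n_distal_cgi = int(config.n_distal_cgis_per_mb * L / 1e6)
        for d in range(n_distal_cgi):
            s = int(rng.integers(5_000, L - 5_000))
            tracks["cgi"].append((chrom, s, s + int(rng.integers(500, 1500)), f"dcgi_{chrom}_{d}"))
        n_te = int(config.transposons_per_mb * L / 1e6)
        for t in range(n_te):
            s = int(rng.integers(0, L - 700))
            tracks["transposons"].append((chrom, s, s + int(rng.integers(150, 700)),
                                          f"te_{chrom}_{t}"))
        # one assembly gap and (first chromosome only) one Hox-like locus
        gs = int(L * 0.45)
        tracks["gaps"].append((chrom, gs, gs + 20_000, f"gap_{chrom}"))
        if ci == 0:
            hs = int(L * 0.62)
            tracks["hox_like"].append((chrom, hs, hs + 10_000, "hox_like_0"))

    ann = {}
    for name, rows in tracks.items():
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"]) if rows \
            else empty_intervals()
        ann[name] = df.sort_values(["chrom", "start"]).reset_index(drop=True)
    # CGI shores: 2 kb flanks on each side of each CGI
    shores = []
    for _, row in ann["cgi"].iterrows():
        shores.append((row["chrom"], max(row["start"] - 2000, 0), row["start"], row["name"]))
        shores.append((row["chrom"], row["end"], row["end"] + 2000, row["name"]))
    ann["cgi_shores"] = pd.DataFrame(shores, columns=["chrom", "start", "end", "name"]) \
        if shores else empty_intervals()

    spec = GenomeSpec(
        chrom_names=list(config.chrom_lengths),
        chrom_lengths=dict(config.chrom_lengths),
        cg_positions=cg_positions, ch_positions=ch_positions,
        ch_contexts=ch_contexts, ch_strands=ch_strands,
        annotation_tracks=ann)
    spec.validate()
    return spec


@dataclass
class PlantConfig:
    """What to plant and at what strength; defaults reflect the study
    conditions the generator emulates (see docs/methods.md)."""

    n_dmrs_per_tissue: int = 12
    dmr_length: int = 800
    n_dmr_clusters_per_tissue: int = 3
    cluster_size: int = 3
    cluster_gap: int = 800
    dmr_baseline: float = 0.8
    # stage-level trajectories for the hypomethylated tissue (4 stages);
    # every level keeps >= margin_headroom distance from the hypomethylation
    # threshold (baseline - 0.3) so truth hypo-sets are stable under noise
    trajectory_shapes: dict = field(default_factory=lambda: {
        "loss": (0.8, 0.7, 0.4, 0.2),
        "regain": (0.8, 0.4, 0.2, 0.6),
    })
    min_effect: float = 0.4
    hypo_margin: float = 0.3
    margin_headroom: float = 0.1
    n_dmvs: int = 6
    dmv_length_range: tuple = (6_000, 10_000)
    dmv_level: float = 0.05
    pmd_lengths: tuple = (500_000, 400_000)
    pmd_tissue: str = "liver"
    pmd_level: float = 0.5
    n_mch_domains: int = 5
    mch_length_range: tuple = (25_000, 40_000)
    mch_tissues: tuple = ("forebrain",)
    mch_elevation: tuple = (1.0, 2.0, 2.0, 2.0)
    n_artefacts: int = 2
    artefact_length: int = 25_000
    artefact_level: float = 0.02
    background_mch: tuple = (0.0, 0.004, 0.009, 0.015)
    background_beta: tuple = (15.0, 2.5)   # site-to-site mCG heterogeneity
    cgi_level: float = 0.05
    feature_buffer: int = 2_000
    seed: int = 0


@dataclass
class TruthManifest:
    """The planted features and generative parameters of one dataset.

    True per-site levels are recomputed deterministically from the stored
    seed rather than materialised, so the manifest stays small and
    serialisable while still defining the exact truth for every
    (site, sample) pair.
    """

    tissues: list[str]
    stages: list[str]
    planted_dmrs: pd.DataFrame
    planted_dmvs: pd.DataFrame
    planted_pmds: pd.DataFrame
    planted_mch_domains: pd.DataFrame
    planted_artefacts: pd.DataFrame
    background_mch: tuple
    background_beta: tuple
    cgi_level: float
    dmr_baseline: float
    seed: int

    def stage_index(self, stage: str) -> int:
        return self.stages.index(stage)

    # -- true level computation -------------------------------------------
    def background_cg_levels(self, genome: GenomeSpec) -> dict[str, np.ndarray]:
        """Sample-independent heterogeneous background mCG per CG dyad."""
        a, b = self.background_beta
        out = {}
        for chrom in genome.chrom_names:
            rng = _rng_for(self.seed, f"background/{chrom}")
            pos = genome.cg_positions[chrom]
            lev = rng.beta(a, b, size=len(pos))
            cgi = mask_sites(pos, chrom, genome.track("cgi"))
            lev[cgi] = self.cgi_level
            out[chrom] = lev
        return out

    def true_cg_levels(self, genome: GenomeSpec, tissue: str, stage: str,
                       _background=None) -> dict[str, np.ndarray]:
        """Exact true mCG level of every CpG dyad for one tissue-stage."""
        si = self.stage_index(stage)
        base = _background if _background is not None else self.background_cg_levels(genome)
        out = {}
        for chrom in genome.chrom_names:
            pos = genome.cg_positions[chrom]
            lev = base[chrom].copy()
            for _, row in self.planted_dmrs[self.planted_dmrs["chrom"] == chrom].iterrows():
                inside = (pos - 1 >= row["start"]) & (pos - 1 < row["end"])
                lev[inside] = row["levels"][si] if row["tissue"] == tissue else row["baseline"]
            for _, row in self.planted_dmvs[self.planted_dmvs["chrom"] == chrom].iterrows():
                inside = (pos - 1 >= row["start"]) & (pos - 1 < row["end"])
                lev[inside] = row["level"]
            for _, row in self.planted_pmds[self.planted_pmds["chrom"] == chrom].iterrows():
                if row["tissue"] == tissue:
                    inside = (pos - 1 >= row["start"]) & (pos - 1 < row["end"])
                    lev[inside] = row["level"]
            out[chrom] = lev
        return out

    def true_ch_levels(self, genome: GenomeSpec, design: SampleDesign) -> dict[str, np.ndarray]:
        """True mCH per CH site: zero for control samples, otherwise the
        per-stage background, multiplied by the planted elevation factor
        inside mCH domains of the sample's tissue."""
        si = self.stage_index(design.stage)
        out = {}
        for chrom in genome.chrom_names:
            pos = genome.ch_positions[chrom]
            if design.is_control:
                out[chrom] = np.zeros(len(pos))
                continue
            lev = np.full(len(pos), self.background_mch[si])
            for _, row in self.planted_mch_domains[
                    self.planted_mch_domains["chrom"] == chrom].iterrows():
                if design.tissue in row["tissues"]:
                    inside = (pos - 1 >= row["start"]) & (pos - 1 < row["end"])
                    lev[inside] = lev[inside] * row["elevation"][si]
            out[chrom] = lev
        return out

    def apparent_ch_levels(self, genome: GenomeSpec, design: SampleDesign) -> dict[str, np.ndarray]:
        """True mCH plus artefact regions, which present apparent
        methylation in every sample (misalignment-like noise)."""
        levels = self.true_ch_levels(genome, design)
        for chrom, lev in levels.items():
            pos = genome.ch_positions[chrom]
            for _, row in self.planted_artefacts[
                    self.planted_artefacts["chrom"] == chrom].iterrows():
                inside = (pos - 1 >= row["start"]) & (pos - 1 < row["end"])
                lev[inside] = np.maximum(lev[inside], row["level"])
        return levels

    def true_hypo_samples(self, dmr_row: pd.Series, sample_keys: list[tuple[str, str]],
                          margin: float = 0.3) -> tuple:
        """Ground-truth hypo-sample set of a planted DMR over the given
        (tissue, stage) samples, via the same bulk-baseline rule applied
        to the exact true levels."""
        from .dmr import baseline_bulk
        levels = [dmr_row["levels"][self.stage_index(st)] if ti == dmr_row["tissue"]
                  else dmr_row["baseline"] for ti, st in sample_keys]
        res = baseline_bulk(levels, margin=margin)
        return tuple(sample_keys[i] for i in res.hypo)

    def true_effect(self, dmr_row: pd.Series) -> float:
        return dmr_row["baseline"] - min(dmr_row["levels"])

    # -- serialisation -----------------------------------------------------
    def to_json(self, path) -> None:
        def frame(df):
            return df.assign(**{c: df[c].map(list) for c in df.columns
                                if len(df) and isinstance(df[c].iloc[0], tuple)}) \
                     .to_dict(orient="records")
        payload = {
            "tissues": self.tissues, "stages": self.stages,
            "planted_dmrs": frame(self.planted_dmrs),
            "planted_dmvs": frame(self.planted_dmvs),
            "planted_pmds": frame(self.planted_pmds),
            "planted_mch_domains": frame(self.planted_mch_domains),
            "planted_artefacts": frame(self.planted_artefacts),
            "background_mch": list(self.background_mch),
            "background_beta": list(self.background_beta),
            "cgi_level": self.cgi_level, "dmr_baseline": self.dmr_baseline,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "TruthManifest":
        d = json.loads(Path(path).read_text())

        def df(key, tuple_cols=()):
            rows = d[key]
            out = pd.DataFrame(rows)
            for c in tuple_cols:
                if c in out.columns:
                    out[c] = out[c].map(tuple)
            return out

        return cls(tissues=d["tissues"], stages=d["stages"],
                   planted_dmrs=df("planted_dmrs", ("levels",)),
                   planted_dmvs=df("planted_dmvs"),
                   planted_pmds=df("planted_pmds"),
                   planted_mch_domains=df("planted_mch_domains", ("tissues", "elevation")),
                   planted_artefacts=df("planted_artefacts"),
                   background_mch=tuple(d["background_mch"]),
                   background_beta=tuple(d["background_beta"]),
                   cgi_level=d["cgi_level"], dmr_baseline=d["dmr_baseline"],
                   seed=d["seed"])


class _Placer:
    """Sequential non-overlapping placement of planted features."""

    def __init__(self, genome: GenomeSpec, buffer: int, rng: np.random.Generator):
        self.genome = genome
        self.buffer = buffer
        self.rng = rng
        self.occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.chrom_names}
        # avoid assembly gaps from the start
        for _, row in genome.track("gaps").iterrows():
            self.occupied[row["chrom"]].append((int(row["start"]), int(row["end"])))

    def _free(self, chrom, start, end):
        for s, e in self.occupied[chrom]:
            if start < e + self.buffer and end + self.buffer > s:
                return False
        return True

    @staticmethod
    def _has_chain(dpos: np.ndarray, k: int, max_gap: int) -> bool:
        """Does a run of >= k consecutive dyads with adjacent gaps
        <= max_gap exist?  (Needed so a planted DMR's significant sites
        can legally merge into a block downstream.)"""
        if len(dpos) < k:
            return False
        ok = np.diff(dpos) <= max_gap
        run = 0
        for good in ok:
            run = run + 1 if good else 0
            if run >= k - 1:
                return True
        return False

    def place(self, length: int, align: int = 1, chrom: str | None = None,
              min_cg: int = 0, windows: list[tuple[int, int]] | None = None,
              chain: tuple[int, int] | None = None,
              max_tries: int = 2000) -> tuple[str, int, int]:
        """Find a free spot.  With ``min_cg``, the placed interval (or, when
        ``windows`` gives sub-interval offsets, every sub-interval) must
        contain at least that many CpG dyads; ``chain=(k, max_gap)``
        additionally requires k consecutive dyads within max_gap of each
        other in every such span."""
        chroms = [chrom] if chrom else list(self.genome.chrom_names)
        lengths = np.array([self.genome.chrom_lengths[c] for c in chroms], dtype=float)
        if length >= lengths.max():
            raise ValueError(f"planted feature of {length} bp exceeds every chromosome")
        for _ in range(max_tries):
            c = chroms[self.rng.choice(len(chroms), p=lengths / lengths.sum())]
            hi = (self.genome.chrom_lengths[c] - length) // align
            if hi <= 1:
                continue
            s = int(self.rng.integers(1, hi)) * align
            e = s + length
            if not self._free(c, s, e):
                continue
            if min_cg or chain:
                pos = self.genome.cg_positions[c]
                spans = [(s + w0, s + w1) for w0, w1 in windows] if windows else [(s, e)]
                ok = True
                for a, b in spans:
                    inside = pos[(pos - 1 >= a) & (pos - 1 < b)]
                    if len(inside) < min_cg:
                        ok = False
                        break
                    if chain and not self._has_chain(inside, *chain):
                        ok = False
                        break
                if not ok:
                    continue
            self.occupied[c].append((s, e))
            return c, s, e
        raise ValueError("could not place feature; requested features exceed genome space")


def plant_truth(genome: GenomeSpec, designs: list[SampleDesign],
                config: PlantConfig) -> TruthManifest:
    """Plant tissue-specific DMRs, DMVs, PMDs, mCH domains and artefact
    regions into a genome, recording exact truth for every sample."""
    tissues = sorted({d.tissue for d in designs})
    # stage order is chronological as provided by the design list
    stages = list(dict.fromkeys(d.stage for d in designs))
    if len(tissues) < 2 or len(stages) < 2:
        raise ValueError("need >=2 tissues and >=2 stages to plant DMR trajectories")
    shapes = {}
    for name, shape in config.trajectory_shapes.items():
        xp = np.linspace(0, 1, len(shape))
        xq = np.linspace(0, 1, len(stages))
        shapes[name] = tuple(np.round(np.interp(xq, xp, shape), 4))
    threshold = config.dmr_baseline - config.hypo_margin
    for name, levels in shapes.items():
        eff = config.dmr_baseline - min(levels)
        if eff < config.min_effect:
            raise ValueError(f"trajectory {name!r} effect {eff:.2f} below configured minimum")
        # configured control points must keep clear of the hypomethylation
        # threshold, else truth hypo-sets flip under read noise; interpolated
        # stage grids may cross the band and only warn
        shape = config.trajectory_shapes[name]
        close = [lv for lv in shape if abs(lv - threshold) < config.margin_headroom - 1e-9]
        if close:
            raise ValueError(
                f"trajectory {name!r} has levels {close} within {config.margin_headroom} "
                f"of the hypomethylation threshold {threshold}; truth hypo-sets would "
                "be unstable under read noise")
        interp_close = [lv for lv in levels
                        if abs(lv - threshold) < config.margin_headroom - 1e-9]
        if interp_close:
            import warnings
            warnings.warn(f"trajectory {name!r}: interpolated levels {interp_close} sit "
                          "near the hypomethylation threshold; recovery of the affected "
                          "stages may be noisy")

    rng = _rng_for(config.seed, "plant")
    placer = _Placer(genome, config.feature_buffer, rng)
    dmr_tissues = [t for t in tissues if t != config.pmd_tissue] or tissues

    # large features first so they still fit once small ones fragment space
    pmd_rows = []
    for length in config.pmd_lengths:
        c, s, e = placer.place(int(length), align=10_000)
        pmd_rows.append((c, s, e, config.pmd_tissue, config.pmd_level))
    planted_pmds = pd.DataFrame(pmd_rows, columns=["chrom", "start", "end", "tissue", "level"])

    if len(config.mch_elevation) != len(stages):
        raise ValueError("mch_elevation must give one factor per stage")
    mch_rows = []
    for _ in range(config.n_mch_domains):
        length = int(rng.integers(config.mch_length_range[0] // 5000,
                                  config.mch_length_range[1] // 5000 + 1)) * 5000
        c, s, e = placer.place(length, align=5000)
        mch_rows.append((c, s, e, tuple(config.mch_tissues), tuple(config.mch_elevation)))
    planted_mch = pd.DataFrame(mch_rows, columns=["chrom", "start", "end",
                                                  "tissues", "elevation"])

    art_rows = []
    for _ in range(config.n_artefacts):
        c, s, e = placer.place(config.artefact_length, align=5000)
        art_rows.append((c, s, e, config.artefact_level))
    planted_artefacts = pd.DataFrame(art_rows, columns=["chrom", "start", "end", "level"])

    dmv_rows = []
    for _ in range(config.n_dmvs):
        length = int(rng.integers(config.dmv_length_range[0] // 1000,
                                  config.dmv_length_range[1] // 1000 + 1)) * 1000
        c, s, e = placer.place(length, align=1000)
        dmv_rows.append((c, s, e, config.dmv_level))
    planted_dmvs = pd.DataFrame(dmv_rows, columns=["chrom", "start", "end", "level"])

    dmr_rows = []
    shape_names = list(shapes)
    chain = (3, 250)  # every planted DMR must be callable as >= 3 mergeable DMSs
    for tissue in dmr_tissues:
        for i in range(config.n_dmrs_per_tissue):
            shape = shape_names[i % len(shape_names)]
            c, s, e = placer.place(config.dmr_length, min_cg=5, chain=chain)
            dmr_rows.append((c, s, e, tissue, shape, shapes[shape], config.dmr_baseline, False))
        for j in range(config.n_dmr_clusters_per_tissue):
            shape = shape_names[j % len(shape_names)]
            span = (config.cluster_size * config.dmr_length
                    + (config.cluster_size - 1) * config.cluster_gap)
            member_windows = [(m * (config.dmr_length + config.cluster_gap),
                               m * (config.dmr_length + config.cluster_gap)
                               + config.dmr_length)
                              for m in range(config.cluster_size)]
            c, s, e = placer.place(span, min_cg=5, windows=member_windows, chain=chain)
            for m in range(config.cluster_size):
                ds = s + m * (config.dmr_length + config.cluster_gap)
                dmr_rows.append((c, ds, ds + config.dmr_length, tissue, shape,
                                 shapes[shape], config.dmr_baseline, True))
    planted_dmrs = pd.DataFrame(dmr_rows, columns=["chrom", "start", "end", "tissue",
                                                   "shape", "levels", "baseline",
                                                   "in_cluster"])

    bg_mch = config.background_mch
    if len(bg_mch) != len(stages):
        xp = np.linspace(0, 1, len(bg_mch))
        bg_mch = tuple(np.round(np.interp(np.linspace(0, 1, len(stages)), xp, bg_mch), 6))

    return TruthManifest(
        tissues=tissues, stages=stages,
        planted_dmrs=planted_dmrs, planted_dmvs=planted_dmvs,
        planted_pmds=planted_pmds, planted_mch_domains=planted_mch,
        planted_artefacts=planted_artefacts,
        background_mch=bg_mch, background_beta=config.background_beta,
        cgi_level=config.cgi_level, dmr_baseline=config.dmr_baseline,
        seed=config.seed)


def simulate_counts(genome: GenomeSpec, truth: TruthManifest, design: SampleDesign,
                    seed: int, n_lambda_sites: int = 2000,
                    _background=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one sample's allc table and its lambda spike-in.

    Per site: cov ~ Poisson(coverage_mean) and mc ~ Binomial(cov,
    m + (1 - m) * r).  CpG dyads are emitted as two strand rows sharing
    one true level, so strand merging is exercised downstream.  Lambda
    sites have m = 0, so their pooled methylated fraction estimates r.
    """
    rng = _rng_for(seed, f"counts/{design.sample_id}")
    r = design.nonconversion_rate
    cg_levels = truth.true_cg_levels(genome, design.tissue, design.stage,
                                     _background=_background)
    ch_levels = truth.apparent_ch_levels(genome, design)
    frames = []
    for chrom in genome.chrom_names:
        parts = []
        cg = genome.cg_positions[chrom]
        m = cg_levels[chrom]
        for strand, pos in (("+", cg), ("-", cg + 1)):
            cov = rng.poisson(design.coverage_mean, size=len(pos))
            mc = rng.binomial(cov, m + (1 - m) * r)
            # third context base is a deterministic genome property
            h = np.array(list("ACT"))[cg % 3]
            parts.append(pd.DataFrame({
                "chrom": chrom, "pos": pos, "strand": strand,
                "context": np.char.add("CG", h), "mc": mc, "cov": cov}))
        ch = genome.ch_positions[chrom]
        mch = ch_levels[chrom]
        cov = rng.poisson(design.coverage_mean, size=len(ch))
        mc = rng.binomial(cov, mch + (1 - mch) * r)
        parts.append(pd.DataFrame({
            "chrom": chrom, "pos": ch, "strand": genome.ch_strands[chrom],
            "context": genome.ch_contexts[chrom], "mc": mc, "cov": cov}))
        sub = pd.concat(parts, ignore_index=True)
        frames.append(sub.sort_values("pos", kind="mergesort"))
    allc = pd.concat(frames, ignore_index=True)[ALLC_COLS]

    lam_pos = np.arange(1, n_lambda_sites + 1) * 3
    lam_cov = rng.poisson(design.coverage_mean, size=n_lambda_sites)
    lam_mc = rng.binomial(lam_cov, r)
    lam = pd.DataFrame({"chrom": "lambda", "pos": lam_pos, "strand": "+",
                        "context": "CAA", "mc": lam_mc, "cov": lam_cov})[ALLC_COLS]
    return allc, lam


def simulate_expression(genome: GenomeSpec, truth: TruthManifest,
                        designs: list[SampleDesign], seed: int,
                        repression: tuple = (1.0, 0.75, 0.45, 0.25)) -> pd.DataFrame:
    """Synthetic TPM table (genes x samples).

    Genes whose bodies overlap a planted mCH domain are progressively
    repressed across stages in the domain's tissues; all other genes
    fluctuate around a flat baseline.  Non-expressed genes (a small
    random subset) stay at zero everywhere.
    """
    rng = _rng_for(seed, "expression")
    bodies = genome.track("gene_bodies")
    genes = bodies["name"].tolist()
    from .genome import overlaps_any
    in_domain = overlaps_any(bodies, truth.planted_mch_domains) if len(bodies) else []
    domain_tissues = set().union(*truth.planted_mch_domains["tissues"]) \
        if len(truth.planted_mch_domains) else set()
    base = rng.lognormal(mean=2.0, sigma=1.0, size=len(genes))
    silent = rng.random(len(genes)) < 0.05
    if len(repression) != len(truth.stages):
        repression = tuple(np.interp(np.linspace(0, 1, len(truth.stages)),
                                     np.linspace(0, 1, len(repression)), repression))
    cols = {}
    for d in designs:
        si = truth.stage_index(d.stage)
        factor = np.ones(len(genes))
        if d.tissue in domain_tissues:
            factor = np.where(in_domain, repression[si], 1.0)
        noise = rng.lognormal(mean=0.0, sigma=0.15, size=len(genes))
        tpm = np.where(silent, 0.0, base * factor * noise)
        cols[d.sample_id] = np.round(tpm, 3)
    return pd.DataFrame(cols, index=pd.Index(genes, name="gene"))


# ---------------------------------------------------------------------------
# dataset writing / reading


def write_dataset(outdir, genome: GenomeSpec, truth: TruthManifest,
                  designs: list[SampleDesign], seed: int) -> None:
    """Materialise a dataset: per-sample allc + lambda tables (gzip TSV),
    truth.json, genome.json and BED annotation tracks."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    background = truth.background_cg_levels(genome)
    for d in designs:
        sdir = outdir / d.sample_id
        sdir.mkdir(exist_ok=True)
        allc, lam = simulate_counts(genome, truth, d, seed, _background=background)
        write_allc(allc, sdir / "allc.tsv.gz")
        write_allc(lam, sdir / "lambda.tsv.gz")
    truth.to_json(outdir / "truth.json")
    save_genome(genome, outdir / "genome.json")
    ann_dir = outdir / "annotations"
    ann_dir.mkdir(exist_ok=True)
    from .allc import write_bed
    for name, track in genome.annotation_tracks.items():
        write_bed(track, ann_dir / f"{name}.bed", extra_cols=["name"])
    sheet = pd.DataFrame([asdict(d) | {"sample_id": d.sample_id} for d in designs])
    sheet.to_csv(outdir / "samples.tsv", sep="\t", index=False)


def save_genome(genome: GenomeSpec, path) -> None:
    payload = {
        "chrom_names": genome.chrom_names,
        "chrom_lengths": genome.chrom_lengths,
        "cg_positions": {c: genome.cg_positions[c].tolist() for c in genome.chrom_names},
        "ch_positions": {c: genome.ch_positions[c].tolist() for c in genome.chrom_names},
        "ch_contexts": {c: genome.ch_contexts[c].tolist() for c in genome.chrom_names},
        "ch_strands": {c: genome.ch_strands[c].tolist() for c in genome.chrom_names},
        "annotation_tracks": {k: v.to_dict(orient="records")
                              for k, v in genome.annotation_tracks.items()},
    }
    Path(path).write_text(json.dumps(payload))


def load_genome(path) -> GenomeSpec:
    d = json.loads(Path(path).read_text())
    tracks = {}
    for k, rows in d["annotation_tracks"].items():
        tracks[k] = pd.DataFrame(rows) if rows else empty_intervals()
    return GenomeSpec(
        chrom_names=d["chrom_names"], chrom_lengths=d["chrom_lengths"],
        cg_positions={c: np.asarray(v, dtype=np.int64) for c, v in d["cg_positions"].items()},
        ch_positions={c: np.asarray(v, dtype=np.int64) for c, v in d["ch_positions"].items()},
        ch_contexts={c: np.asarray(v) for c, v in d["ch_contexts"].items()},
        ch_strands={c: np.asarray(v) for c, v in d["ch_strands"].items()},
        annotation_tracks=tracks)


def load_designs(path) -> list[SampleDesign]:
    sheet = pd.read_csv(path, sep="\t")
    return [SampleDesign(tissue=r["tissue"], stage=str(r["stage"]),
                         replicate=int(r["replicate"]), is_control=bool(r["is_control"]),
                         coverage_mean=float(r["coverage_mean"]),
                         nonconversion_rate=float(r["nonconversion_rate"]))
            for _, r in sheet.iterrows()]


# ---------------------------------------------------------------------------
# presets


def make_designs(tissues: list[str], stages: list[str], n_replicates: int = 2,
                 coverage_mean: float = 30.0, nonconversion_rate: float = 0.005,
                 control_stages: tuple = None) -> list[SampleDesign]:
    """Full factorial tissue x stage x replicate design; samples from
    ``control_stages`` (default: the first stage) carry no true mCH."""
    control_stages = control_stages if control_stages is not None else (stages[0],)
    return [SampleDesign(tissue=t, stage=s, replicate=r,
                         is_control=s in control_stages,
                         coverage_mean=coverage_mean,
                         nonconversion_rate=nonconversion_rate)
            for s in stages for t in tissues for r in range(1, n_replicates + 1)]


def preset(name: str, seed: int = 0):
    """Bundled simulation presets.

    ``"5mb"`` — the packaged benchmark: 5-Mb two-chromosome genome, three
    tissues (forebrain, heart, liver) across four stages with two
    replicates at 30x, the full feature complement.  ``"tiny"`` — a
    sub-megabase smoke-test configuration for fast end-to-end runs.
    """
    if name == "5mb":
        gcfg = GenomeConfig(chrom_lengths={"chr1": 3_000_000, "chr2": 2_000_000},
                            seed=seed)
        pcfg = PlantConfig(seed=seed)
        designs = make_designs(["forebrain", "heart", "liver"],
                               ["E10.5", "E13.5", "E16.5", "P0"])
    elif name == "tiny":
        gcfg = GenomeConfig(chrom_lengths={"chr1": 400_000}, ch_density=0.13, seed=seed)
        pcfg = PlantConfig(n_dmrs_per_tissue=4, n_dmr_clusters_per_tissue=1,
                           n_dmvs=2, dmv_length_range=(6_000, 8_000),
                           pmd_lengths=(120_000,), n_mch_domains=1,
                           mch_length_range=(25_000, 30_000), n_artefacts=1,
                           artefact_length=15_000, feature_buffer=1_000, seed=seed)
        designs = make_designs(["forebrain", "liver"], ["E10.5", "P0"],
                               coverage_mean=15.0)
        pcfg.trajectory_shapes = {"loss": (0.8, 0.2)}
        pcfg.mch_elevation = (1.0, 2.5)
        pcfg.background_mch = (0.0, 0.012)
    else:
        raise ValueError(f"unknown preset {name!r}")
    return gcfg, pcfg, designs
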