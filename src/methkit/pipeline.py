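"""End-to-end orchestration: simulate -> QC -> site stats -> CG-DMRs ->
domains -> enrichment, plus recovery scoring against the planted truth.

These functions are the programmatic API the CLI wraps; they also back
the acceptance benchmark, which runs the full pipeline on the packaged
5-Mb preset and scores recovery of every planted feature class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import allc as allc_io
from . import dmr as dmr_mod
from . import domains as dom
from . import qc as qc_mod
from .enrich import mc_overlap_test, mc_geneset_test
from .genome import GenomeSpec, empty_intervals, jaccard, merge_intervals, overlap_bases
from .levels import binned_levels
from .simulate import (PlantConfig, SampleDesign, TruthManifest, generate_genome,
                       load_designs, load_genome, plant_truth, preset,
                       simulate_counts, simulate_expression)


@dataclass
class Dataset:
    """An in-memory dataset: genome + truth + per-sample allc tables."""

    genome: GenomeSpec
    truth: TruthManifest
    designs: list[SampleDesign]
    allc: dict[str, pd.DataFrame]
    lamb: dict[str, pd.DataFrame]
    expression: pd.DataFrame | None = None

    _merged_cg: dict[str, pd.DataFrame] = field(default_factory=dict, repr=False)

    @property
    def meta(self) -> pd.DataFrame:
        rows = {d.sample_id: {"tissue": d.tissue, "stage": d.stage,
                              "replicate": d.replicate, "is_control": d.is_control}
                for d in self.designs}
        df = pd.DataFrame(rows).T
        df.index.name = "sample_id"
        return df

    def merged_cg(self, sample_id: str) -> pd.DataFrame:
        """Strand-merged CG rows of one sample (cached)."""
        if sample_id not in self._merged_cg:
            df = self.allc[sample_id]
            merged = allc_io.merge_strand_cg(df)
            self._merged_cg[sample_id] = merged[allc_io.is_cg_context(merged["context"])]
        return self._merged_cg[sample_id]

    def ch_sites(self, sample_id: str) -> pd.DataFrame:
        df = self.allc[sample_id]
        return df[~allc_io.is_cg_context(df["context"])]

    def nonconversion(self, sample_id: str) -> float:
        return qc_mod.nonconversion_from_lambda(self.lamb[sample_id])


def simulate_dataset(preset_name: str = "5mb", seed: int = 0,
                     with_expression: bool = True) -> Dataset:
    """Generate a full in-memory dataset from a bundled preset."""
    gcfg, pcfg, designs = preset(preset_name, seed=seed)
    gcfg.seed = seed
    pcfg.seed = seed
    genome = generate_genome(gcfg)
    truth = plant_truth(genome, designs, pcfg)
    background = truth.background_cg_levels(genome)
    allc, lamb = {}, {}
    for d in designs:
        a, l = simulate_counts(genome, truth, d, seed, _background=background)
        allc[d.sample_id] = a
        lamb[d.sample_id] = l
    expr = simulate_expression(genome, truth, designs, seed) if with_expression else None
    return Dataset(genome=genome, truth=truth, designs=designs,
                   allc=allc, lamb=lamb, expression=expr)


def dataset_from_dir(path) -> Dataset:
    """Load a dataset previously written by :func:`methkit.simulate.write_dataset`."""
    path = Path(path)
    genome = load_genome(path / "genome.json")
    truth = TruthManifest.from_json(path / "truth.json")
    designs = load_designs(path / "samples.tsv")
    allc, lamb = {}, {}
    for d in designs:
        allc[d.sample_id] = allc_io.read_allc(path / d.sample_id / "allc.tsv.gz")
        lamb[d.sample_id] = allc_io.read_allc(path / d.sample_id / "lambda.tsv.gz")
    expr_path = path / "expression.tsv"
    expr = allc_io.read_tpm(expr_path) if expr_path.exists() else None
    return Dataset(genome=genome, truth=truth, designs=designs,
                   allc=allc, lamb=lamb, expression=expr)


# ---------------------------------------------------------------------------
# QC stage


def run_qc(ds: Dataset) -> dict[str, qc_mod.QCReport]:
    """QC per sample, pairing each replicate with its partner."""
    out = {}
    meta = ds.meta
    for sid, row in meta.iterrows():
        partner = meta[(meta["tissue"] == row["tissue"]) & (meta["stage"] == row["stage"])
                       & (meta.index != sid)]
        partner_allc = ds.allc[partner.index[0]] if len(partner) else None
        out[sid] = qc_mod.compute_qc(ds.allc[sid], ds.lamb[sid], partner_allc)
    return out


# ---------------------------------------------------------------------------
# CG-DMR stage


def tissue_stage_counts(ds: Dataset, exclude_tissues: tuple = ("liver",)
                        ) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, float]]:
    """Strand-merged CG counts combined across replicates, one column per
    tissue-stage sample (globally hypomethylated tissues excluded).
    Returns (mc, cov, nonconversion-per-column)."""
    meta = ds.meta
    combined: dict[str, pd.DataFrame] = {}
    ncr: dict[str, float] = {}
    for (tissue, stage), group in meta.groupby(["tissue", "stage"], sort=False):
        if tissue in exclude_tissues:
            continue
        key = f"{tissue}|{stage}"
        frames = [ds.merged_cg(sid) for sid in group.index]
        combined[key] = allc_io.combine_counts(frames)
        ncr[key] = float(np.mean([ds.nonconversion(sid) for sid in group.index]))
    mc, cov = dmr_mod.stack_counts(combined)
    return mc, cov, ncr


@dataclass
class DMRResults:
    dms: pd.DataFrame
    dmrs: pd.DataFrame
    levels: pd.DataFrame
    specificity: pd.DataFrame
    events_by_tissue: dict[str, pd.DataFrame]
    large_hypo: dict[str, pd.DataFrame]
    sample_keys: list[tuple[str, str]]


def run_dmr_stage(ds: Dataset, exclude_tissues: tuple = ("liver",),
                  n_permutations: int = 1000, fdr: float = 0.01,
                  hypo_margin: float = 0.3, event_delta: float = 0.1,
                  seed: int = 0) -> DMRResults:
    """DMS calling, DMR merging, tissue-specificity, event accounting and
    large hypo blocks on a dataset."""
    mc, cov, ncr = tissue_stage_counts(ds, exclude_tissues)
    dms = dmr_mod.call_dms(mc, cov, n_permutations=n_permutations, fdr=fdr, seed=seed)
    dmrs = dmr_mod.merge_dms_to_dmrs(dms)
    nonconv = float(np.mean(list(ncr.values()))) if ncr else 0.0
    levels = dmr_mod.dmr_levels(dmrs, mc, cov, nonconversion=nonconv)
    spec = dmr_mod.tissue_specific_dmrs(levels, margin=hypo_margin)
    sample_keys = [tuple(c.split("|")) for c in levels.columns]

    stages = [s for s in ds.truth.stages]
    events_by_tissue: dict[str, pd.DataFrame] = {}
    large_hypo: dict[str, pd.DataFrame] = {}
    tissues = sorted({t for t, _ in sample_keys})
    for tissue in tissues:
        cols = [f"{tissue}|{s}" for s in stages if f"{tissue}|{s}" in levels.columns]
        traj = levels.loc[spec.index, cols]
        traj.columns = [c.split("|")[1] for c in cols]
        events_by_tissue[tissue] = dmr_mod.count_events_table(traj, delta=event_delta)
        mine = spec["hypo_samples"].map(
            lambda h, t=tissue: any(k.startswith(f"{t}|") for k in h))
        tdmrs = dmrs.loc[spec.index[mine & spec["tissue_specific"]]]
        large_hypo[tissue] = dom.call_large_hypo(tdmrs) if len(tdmrs) else empty_intervals()
    return DMRResults(dms=dms, dmrs=dmrs, levels=levels, specificity=spec,
                      events_by_tissue=events_by_tissue, large_hypo=large_hypo,
                      sample_keys=sample_keys)


# ---------------------------------------------------------------------------
# domain stage


@dataclass
class DomainResults:
    dmvs_by_sample: dict[str, pd.DataFrame]
    dmvs: pd.DataFrame
    pmds_by_sample: dict[str, pd.DataFrame]
    pmds: pd.DataFrame
    mch: dom.MCHDomainResult
    pmd_classifier: object = None


def run_domain_stage(ds: Dataset, dmv_threshold: float = 0.15, dmv_min_bins: int = 5,
                     pmd_min_length: int = 100_000, pmd_trees: int = 1000,
                     mch_elevation: float = 1.5, mch_pseudo: float = 0.001,
                     seed: int = 0, pmd_tissues: tuple | None = None) -> DomainResults:
    """DMVs, random-forest PMDs and iterative-exclusion mCH domains."""
    meta = ds.meta
    genome = ds.genome
    chrom_lengths = genome.chrom_lengths

    # ---- DMVs: 1-kb CG tracks per replicate, reconciled per tissue-stage
    rep_tracks: dict[str, list] = {}
    for (tissue, stage), group in meta.groupby(["tissue", "stage"], sort=False):
        key = f"{tissue}|{stage}"
        rep_tracks[key] = [
            binned_levels(ds.merged_cg(sid), chrom_lengths, 1000, context="CG",
                          nonconversion=ds.nonconversion(sid))
            for sid in group.index]
    dmvs_by_sample, dmvs = dom.call_dmvs(rep_tracks, threshold=dmv_threshold,
                                         min_bins=dmv_min_bins)

    # ---- PMDs: percentile features per replicate, forest trained on the
    # planted-truth labels of the designated PMD tissue (synthetic analogue
    # of the manually annotated training regions)
    exclude = pd.concat([genome.track("cgi")[["chrom", "start", "end"]],
                         dmvs[["chrom", "start", "end"]] if len(dmvs) else empty_intervals(),
                         genome.track("hox_like")[["chrom", "start", "end"]]],
                        ignore_index=True)
    pmd_tissue = ds.truth.planted_pmds["tissue"].iloc[0] if len(ds.truth.planted_pmds) \
        else meta["tissue"].iloc[0]
    train_stage = ds.truth.stages[min(1, len(ds.truth.stages) - 1)]
    train_ids = meta[(meta["tissue"] == pmd_tissue) & (meta["stage"] == train_stage)].index
    train_counts = allc_io.combine_counts([ds.merged_cg(s) for s in train_ids])
    train_feats = dom.pmd_bin_features(train_counts, chrom_lengths, exclude)
    bins_iv = train_feats[["chrom", "start", "end"]]
    frac_in = overlap_bases(bins_iv, ds.truth.planted_pmds) / (bins_iv["end"] - bins_iv["start"])
    labels = (frac_in >= 0.99).to_numpy()  # fully-contained bins are positives
    usable = labels | (frac_in.to_numpy() == 0)
    clf = dom.train_pmd_classifier(train_feats[usable], labels[usable],
                                   n_estimators=pmd_trees, seed=seed)

    pmds_by_sample: dict[str, pd.DataFrame] = {}
    tissues_for_pmd = pmd_tissues if pmd_tissues is not None \
        else tuple(meta["tissue"].unique())
    for (tissue, stage), group in meta.groupby(["tissue", "stage"], sort=False):
        if tissue not in tissues_for_pmd:
            continue
        rep_feats = [dom.pmd_bin_features(ds.merged_cg(sid), chrom_lengths, exclude)
                     for sid in group.index]
        pmds_by_sample[f"{tissue}|{stage}"] = dom.call_pmds(
            clf, rep_feats, genome.track("gaps"), genome.track("hox_like"),
            min_length=pmd_min_length)
    pmd_frames = [v for k, v in pmds_by_sample.items()
                  if k.startswith(f"{pmd_tissue}|") and len(v)]
    pmds = merge_intervals(pd.concat(pmd_frames)) if pmd_frames else empty_intervals()

    # ---- mCH domains: 5-kb CH tracks, iterative control exclusion
    ch_tracks = {
        sid: binned_levels(ds.ch_sites(sid), chrom_lengths, 5000, context="CH",
                           nonconversion=ds.nonconversion(sid),
                           min_sites=500, min_covered_fraction=0.5)
        for sid in meta.index}
    mch = dom.call_mch_domains(ch_tracks, meta, elevation=mch_elevation,
                               pseudo=mch_pseudo)
    return DomainResults(dmvs_by_sample=dmvs_by_sample, dmvs=dmvs,
                         pmds_by_sample=pmds_by_sample, pmds=pmds, mch=mch,
                         pmd_classifier=clf)


# ---------------------------------------------------------------------------
# recovery scoring against planted truth


def _match_fraction(a: pd.DataFrame, b: pd.DataFrame) -> np.ndarray:
    """Per interval of ``a``: fraction of its bases covered by ``b``."""
    if len(a) == 0:
        return np.empty(0)
    return overlap_bases(a, b) / (a["end"] - a["start"]).to_numpy()


def recovery_report(ds: Dataset, dmr_res: DMRResults, dom_res: DomainResults,
                    min_true_effect: float = 0.4, overlap_frac: float = 0.5) -> dict:
    """Score the pipeline's calls against the planted truth."""
    truth = ds.truth
    report: dict[str, float] = {}

    # DMR hypo-sample-set recovery
    planted = truth.planted_dmrs
    called = dmr_res.dmrs.loc[dmr_res.specificity.index]
    called_hypo = dmr_res.specificity["hypo_samples"]
    n_eval = n_recovered = 0
    for _, row in planted.iterrows():
        if truth.true_effect(row) < min_true_effect:
            continue
        true_set = {f"{t}|{s}" for t, s in
                    truth.true_hypo_samples(row, dmr_res.sample_keys)}
        hits = called[(called["chrom"] == row["chrom"])
                      & (called["start"] < row["end"]) & (called["end"] > row["start"])]
        n_eval += 1
        if any(set(called_hypo.loc[i]) == true_set for i in hits.index):
            n_recovered += 1
    report["dmr_n_planted"] = n_eval
    report["dmr_hypo_set_recovery"] = n_recovered / n_eval if n_eval else float("nan")

    # false-positive tissue-specific calls outside planted regions
    spec_calls = called[dmr_res.specificity["tissue_specific"]]
    if len(spec_calls):
        outside = _match_fraction(spec_calls[["chrom", "start", "end"]],
                                  planted[["chrom", "start", "end"]]) == 0
        report["dmr_calls_outside_truth"] = int(outside.sum())
    else:
        report["dmr_calls_outside_truth"] = 0

    report["dmv_jaccard"] = jaccard(dom_res.dmvs, truth.planted_dmvs)
    report["pmd_jaccard"] = jaccard(dom_res.pmds, truth.planted_pmds)

    mch_final = dom_res.mch.final
    planted_mch = truth.planted_mch_domains
    if len(planted_mch):
        rec = _match_fraction(planted_mch[["chrom", "start", "end"]], mch_final)
        report["mch_recall"] = float((rec >= overlap_frac).mean())
    else:
        report["mch_recall"] = float("nan")
    if len(mch_final):
        prec = _match_fraction(mch_final, planted_mch[["chrom", "start", "end"]])
        report["mch_precision"] = float((prec >= overlap_frac).mean())
        art = _match_fraction(mch_final, truth.planted_artefacts[["chrom", "start", "end"]])
        report["mch_artefact_calls"] = int((art > 0).sum())
    else:
        report["mch_precision"] = float("nan")
        report["mch_artefact_calls"] = 0
    report["mch_iterations"] = dom_res.mch.n_iterations
    return report


# ---------------------------------------------------------------------------
# enrichment stage (generic overlap machinery on the synthetic annotations)


def run_enrichment_stage(ds: Dataset, dmr_res: DMRResults, dom_res: DomainResults,
                         k: int = 1000, seed: int = 0) -> dict:
    """Monte-Carlo overlap and gene-set tests on the dataset's own tracks."""
    genome = ds.genome
    out = {}
    spec = dmr_res.specificity
    dmrs = dmr_res.dmrs
    cats = dmr_mod.categorize_dmrs(
        dmrs, genome.track("promoters"), genome.track("cgi"),
        genome.track("cgi_shores"), genome.track("transposons"),
        enhancer_scores=None,
        tissue_specific=spec.reindex(dmrs.index)["tissue_specific"].fillna(False).to_numpy())
    unx = dmrs[cats.isin(["te_unxdmr", "nte_unxdmr"])]
    if len(unx):
        res = mc_overlap_test(unx[["chrom", "start", "end"]], genome.track("transposons"),
                              genome.chrom_lengths, genome.track("gaps"), k=k, seed=seed)
        out["unxdmr_te_overlap"] = {"observed": res.observed, "p": res.p,
                                    "fold": res.fold_enrichment}
    if ds.expression is not None and len(dom_res.mch.final):
        from .genes import drop_ill_defined
        bodies = genome.track("gene_bodies")
        in_dom = overlap_bases(bodies, dom_res.mch.final) > 0
        domain_genes = set(drop_ill_defined(bodies.loc[in_dom, "name"]))
        universe = drop_ill_defined(bodies["name"])
        # synthetic "TF" property: first 20% of gene names, a fixed set
        prop = set(universe[: max(len(universe) // 5, 1)])
        res = mc_geneset_test(domain_genes & set(universe), universe, prop, k=k, seed=seed)
        out["mch_domain_gene_set"] = {"observed": res.observed, "p": res.p,
                                      "fold": res.fold_enrichment}
    out["category_counts"] = cats.value_counts().to_dict()
    return out


# ---------------------------------------------------------------------------
# null calibration (signal-free conditions)


def baseline_null_fp_rate(n_regions: int = 10_000, n_samples: int = 8,
                          reads_per_region: int = 600, level: float = 0.8,
                          margin: float = 0.3, seed: int = 0) -> float:
    """Fraction of signal-free regions that produce any hypomethylated
    call at the given margin: all samples share one true level and differ
    only by binomial read sampling."""
    rng = np.random.default_rng(seed)
    counts = rng.binomial(reads_per_region, level, size=(n_regions, n_samples))
    levels = counts / reads_per_region
    _, hypo = dmr_mod.baseline_bulk_matrix(levels, margin=margin)
    return float(hypo.any(axis=1).mean())


def mc_overlap_null_pvalues(n_runs: int = 500, k: int = 200, n_features: int = 20,
                            feature_len: int = 500, seed: int = 0) -> np.ndarray:
    """p-values of the interval-shuffle test when features are themselves
    placed uniformly (the null); should be super-uniform."""
    chrom_lengths = {"chrN": 1_000_000}
    rng = np.random.default_rng(seed)
    t_starts = np.sort(rng.integers(0, 990_000, size=50))
    targets = pd.DataFrame({"chrom": "chrN", "start": t_starts, "end": t_starts + 2000})
    pvals = np.empty(n_runs)
    for i in range(n_runs):
        f_starts = rng.integers(0, 999_000, size=n_features)
        feats = pd.DataFrame({"chrom": "chrN", "start": f_starts,
                              "end": f_starts + feature_len})
        res = mc_overlap_test(feats, targets, chrom_lengths, k=k,
                              seed=int(rng.integers(0, 2**31 - 1)))
        pvals[i] = res.p
    return pvals


def ks_uniformity(pvals: np.ndarray) -> float:
    """One-sided KS p-value of observed p-values against Uniform(0, 1).

    Tests the anti-conservative direction only (empirical CDF above the
    uniform CDF, i.e. an excess of small p-values).  Permutation p-values
    with the (count + 1)/(k + 1) correction are discrete and conservative
    by construction, so the two-sided statistic would flag exactly the
    deviation super-uniformity permits."""
    return float(sps.kstest(pvals, "uniform", alternative="greater").pvalue)
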