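# Methods

This note documents the models, procedures and numerical choices behind
methkit: what each caller computes, which parameters matter, what the
synthetic-data generator does and does not emulate, and where the design
was genuinely open.

## Methylation levels

The methylation level of a cytosine, bin or region is the pooled ratio of
methylated basecalls over total basecalls, minus the bisulfite
non-conversion rate, clamped at zero:

    level = max(0, sum(mc) / sum(cov) - r)

`r` is estimated per sample as the pooled methylated fraction of the
unmethylated lambda spike-in. Two conventions are fixed package-wide:

- **Pooling, not averaging.** A region's level pools counts before
  dividing; it is never the mean of per-site levels, so deeply covered
  sites weigh more. Genome-wide levels pool all counts rather than
  weighting chromosomes equally.
- **Clamping.** Corrected levels below zero are reported as 0; a site
  with zero coverage has an *undefined* level (NaN), never 0.

CpG dyads are strand-merged before any CG-level computation: the + strand
row at position p and the − strand row at p+1 combine into one record at
p with counts summed. Coordinates are 1-based in allc tables and 0-based
half-open in all interval (BED) structures; conversion is centralised in
`methkit.genome`.

## DMS calling and CG-DMR assembly

Differential methylation across N samples (biological replicates
combined, globally hypomethylated liver-like samples excluded) is tested
per strand-merged CG site with a permutation goodness-of-fit test:

- statistic: root-mean-square deviation of per-sample methylated
  fractions from the pooled fraction;
- null: the pooled methylated reads are redistributed over samples at
  fixed per-sample coverage — sequential hypergeometric draws, equivalent
  to a multivariate hypergeometric;
- p-value: inclusive `(count + 1) / (k + 1)`.

Permutations are adaptive. Every testable site receives 1,000 draws
(`dms_permutations`); sites whose first-stage p falls at or below 0.02
continue to 30,000 draws (`max_permutations`). This matters because a
p-value floored at 1/1001 can never clear Benjamini–Hochberg control at
FDR 0.01 when true signal is sparse (with ~1% differential sites among
50,000, BH demands p below ~1e-4 at the relevant rank); the escalation
keeps every reported p a valid permutation p-value while giving the tail
the required resolution. Sites with zero coverage in any sample are not
tested; sites where every read agrees have statistic 0 and p = 1 without
sampling.

BH control at FDR 0.01 yields DMSs. Each DMS carries a hypo-sample label
set: samples whose fraction sits more than 0.1 below the across-sample
mean. Adjacent DMSs merge into a CG-DMR when within 250 bp *and* their
hypo-sample sets intersect (the merge-compatibility rule is not fully
specified by the upstream callers this emulates; set intersection is the
documented, configurable choice). Blocks with fewer than three DMSs are
dropped. A DMR's per-sample level pools counts over its member sites.

## Tissue specificity: the bulk baseline

For each CG-DMR with levels x_1..x_N (regions with any uncovered sample
are dropped first), sort the levels and find the window of w = ceil(N/2)
consecutive order statistics with the smallest range; ties break to the
smallest start index, equal values keep stable sample order. The window
mean b is the baseline; samples with x_s − b ≤ −0.3 are hypomethylated,
and a DMR with any such sample is tissue-specific. The effect size is
|min(x) − b|. The implementation is vectorised over regions and is
checked exactly against an exhaustive window-enumeration oracle.

## mCG dynamics

A loss-of-mCG (gain-of-mCG) event is a decrease (increase) of at least
0.1 in one DMR's level across one adjacent-stage interval, counted per
tissue. At most one loss and one gain per interval per DMR can occur, so
reversing a trajectory swaps loss and gain totals exactly.

## CG-DMR categories

Each DMR receives exactly one category. Proximal DMRs take the highest-
priority overlapping feature: CGI promoter > non-CGI promoter > CGI > CGI
shore (promoters are TSS ± 2.5 kb; shores are 2-kb CGI flanks; a promoter
is a CGI promoter when it overlaps a CGI). Remaining distal DMRs become:
distal feDMR when the externally supplied enhancer score exceeds 0.3
(strictly); flanking when within 1 kb of a distal feDMR; primed when
tissue-specifically hypomethylated; otherwise unexplained, split te/nte
by transposon overlap. Without a score column the feDMR tiers are skipped
with a warning. Categories always partition the input.

## Large hypo blocks, DMVs, PMDs

- **Large hypo CG-DMRs**: per tissue, tissue-specific DMRs within 1 kb
  merge; merged blocks under 2 kb are dropped.
- **DMVs**: 1-kb bins; runs of with-data bins below mCG 0.15 (no-data
  bins are skipped — they neither break the run nor count toward the
  minimum) with ≥ 5 with-data bins are called per replicate; calls
  overlapping a call in the partner replicate are kept and merged, then
  unioned across samples. The maximum no-data gap a run may span is
  unlimited by default and configurable.
- **PMDs**: per 10-kb bin, the 5th–95th percentiles (steps of 5, 19
  features) of per-site corrected levels, excluding sites in CGIs, DMVs
  or Hox-like loci and sites under 5 reads; bins with < 10 remaining
  sites are dropped. A random forest (1,000 trees by default, 10,000
  available; `max_features=None`, out-of-bag scoring) classifies bins;
  consecutive PMD bins merge, blocks under 100 kb or overlapping assembly
  gaps are dropped, final calls are the ≥ 100-kb pieces of the
  two-replicate intersection (a lone replicate is used alone), and calls
  overlapping the Hox-like exclusion loci are removed. On synthetic data
  the forest trains on manifest truth labels of the designated PMD
  tissue — the stand-in for manually annotated training regions.

## mCH sites and domains

Significantly methylated CH sites are found by a one-sided binomial test
against the non-conversion rate, with BH at 1% FDR applied independently
per trinucleotide context (each context gets its own p cutoff). The test
requires no minimum coverage; `min_cov` is exposed. A zero non-conversion
rate is rejected — callers must supply a floor.

mCH domains are called on 5-kb bins (≥ 500 CH sites, ≥ 50% of sites at
≥ 10 reads) by penalised least-squares change-point segmentation (PELT;
levels scaled ×1000), iteratively:

1. Segment each zero-mCH control sample, ignoring bins on the exclusion
   list; chunks whose mean level is at least 1.5× both neighbouring
   chunks (pseudo-level 0.001 added to both sides of the ratio; boundary
   chunks compare against their single neighbour) join the exclusion
   list.
2. Repeat until the list stops growing (it can only grow, so the loop
   terminates; a configurable iteration cap raises with diagnostics).
3. Segment every sample with the converged exclusions; per tissue keep
   regions called in both replicates of a stage, drop pieces under 15 kb
   or three bins, union across stages and merge across tissues.

The PELT implementation is an exact minimiser of squared-error cost plus
a per-changepoint penalty under a minimum-segment-length constraint,
pruned but provably optimal; tests require exact agreement with an
unpruned O(n²) optimal-partitioning oracle. The default penalty is
`4·σ̂²·log n` with σ̂ the MAD of first differences over √2 (falling back
to the standard deviation of differences when the MAD degenerates to
zero, as happens on the mostly-zero clamped tracks of mCH-free control
samples): the robust genome-wide σ̂ reflects background bins, and since
binomial variance
grows with the level, the classic BIC multiplier 2 tends to split
elevated domains into sub-chunks that then fail the both-neighbours
elevation rule; 4 suppresses these false splits while leaving true
boundaries (many σ in this regime) untouched. The multiplier and the
absolute penalty are both exposed. No equivalence is claimed with the R
`changepoint` package's "Asymptotic" penalty at pen.value 0.05, which
assumes unit known variance.

Domain profiles for clustering are length-50 vectors — 20 upstream 5-kb
bins, 10 equal body divisions (fractional for short domains), 20
downstream bins — normalised by the flank mean plus the pseudo-level;
k-means (fixed seed) clusters the concatenated per-sample profiles. The
expression contrast z-scores each gene's TPM across one tissue's stages
(non-expressed and zero-variance genes skipped) and reports mean z of
domain-overlapping genes minus mean z of genes outside all domains, per
stage — negative late values indicate repression of domain genes.

## Enrichment statistics

- **Hypergeometric item enrichment**: for foreground/background region
  sets (symmetrically extended so the mean width reaches 400 bp when
  below it), the upper-tail probability of the observed foreground
  overlap count, BH-adjusted across items within one call (one tissue),
  1% FDR; items whose TF expression is below 10 TPM can be dropped.
  Exactness is tested against integer enumeration for all margins ≤ 20.
- **Interval-shuffle test**: features are re-placed uniformly in the
  gap-excluded genome, length-preserving, overlaps among shuffled
  features allowed (the shuffleBed-default dialect); the statistic is the
  count of target-overlapping features or the base-pair overlap, both
  offered because reported fold enrichments in this field rarely state
  which convention was used.
  p = (Σ I(x_obs ≤ x_i) + 1)/(k + 1), floored at 1/(k+1); permuted
  statistics are retained on the result object for audit.
- **Gene-set resampling**: same p-value formula over draws of |query|
  genes without replacement from the universe.

These permutation p-values are discrete and conservative by construction;
calibration is therefore checked one-sidedly (no excess of small
p-values), which is the direction super-uniformity constrains.

## The synthetic-data generator

The generator emulates the statistical structure of a multi-tissue,
multi-stage WGBS developmental atlas, not its sequence content:

- **Genome**: configurable chromosomes; CpG dyads (default 1 per 100 bp)
  on even coordinates, CH cytosines (default 0.12/bp) on odd coordinates
  with weighted CA/CC/CT contexts; annotation tracks (genes/TSSs,
  promoters, CGIs, shores, transposons, one assembly gap per chromosome,
  a Hox-like exclusion locus).
- **Background mCG** is heterogeneous across sites — Beta(15, 2.5)
  (mean ≈ 0.86) outside CGIs, 0.05 inside — and shared across samples.
  The heterogeneity is what makes replicate Pearson correlation a
  meaningful QC statistic (a flat background would leave nothing but
  binomial noise to correlate).
- **Planted features**: tissue-specific DMRs with piecewise-linear
  trajectories (prenatal loss 0.8→0.2 and a postnatal re-gain shape;
  minimum effect 0.4), some in clusters spaced < 1 kb to exercise
  large-hypo merging; DMVs at 0.05 in all samples; liver-like PMDs at
  0.5; mCH domains with per-stage elevation factors in designated
  tissues; artefact regions with apparent mCH of 0.02 in *every* sample,
  including zero-mCH controls, to exercise the iterative exclusion loop.
  Trajectory levels are chosen ≥ 0.1 away from the 0.3 hypomethylation
  margin so that truth hypo-sets are stable under read noise.
- **Counts**: per allc row, coverage ~ Poisson(30) (per strand, so
  strand-combined CG depth ≈ 60×) and methylated count ~ Binomial(cov,
  m + (1−m)·r) with r = 0.005 — non-conversion affects only unmethylated
  cytosines, per the chemistry. Lambda spike-in rows have m = 0.
  Everything is deterministic given the seed; gzip output is written
  with fixed mtime so reruns are byte-identical.
- **Truth manifest**: planted intervals plus the generative parameters
  and seed; exact per-site true levels are recomputed on demand rather
  than materialised. Ground-truth hypo-sample sets are derived by
  applying the same bulk-baseline rule to the exact true levels.

What the generator does **not** emulate: read-level errors and mapping
biases (artefact regions are a coarse proxy), sequence composition,
within-tissue cell-type mixtures (samples are homogeneous), CNVs, and
chromosome-scale covariates such as replication timing. Passing recovery
tests therefore demonstrates the correctness of the callers' logic and
their behaviour under binomial/Poisson sampling noise at realistic depth
— not robustness to every artefact of real libraries.

## Packaged presets and problem sizes

Two bundled presets define the test conditions. `5mb`: two chromosomes
totalling 5 Mb, tissues forebrain/heart/liver, stages E10.5→P0 (E10.5
samples are the zero-mCH controls), two replicates, ~50,000 CpG dyads and
~600,000 CH sites per sample; 42 planted DMRs, 6 DMVs, 2 PMDs (500 kb +
400 kb, liver), 5 mCH domains, 2 artefact regions. `tiny`: one 400-kb
chromosome, two tissues, two stages, a reduced feature complement, for
smoke tests and the CLI. The full benchmark (simulation + all callers)
runs in a few minutes on one CPU; these sizes are the package's chosen
test conditions and all tests and the acceptance script use them as-is.

## Known limitations

- The DMS test follows the permutation approach of established WGBS DMR
  callers in spirit; those tools' exact statistic and merge rule are not
  documented authoritatively, so this module's defaults are documented
  stand-ins (configurable).
- The hypomethylation margin (0.3) is applied to replicate-combined
  levels; per-replicate application is not offered.
- PMD training on real data would require manually curated region
  labels; the synthetic path trains on manifest truth.
- k-means cluster labels are stable only for a fixed seed; no
  model-selection criterion for k is provided beyond inspection.
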