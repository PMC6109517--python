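# Methods

`cytometh` reimplements, as a tested library, a cross-disease DNA
methylation workflow for cytokine genes on Illumina 450K-style arrays:
three autoimmune diseases (one measured on several chips), case/control
beta-value matrices, and the question of which cytokine CpG sites are
concordantly or discordantly methylated across the diseases. This note
records the models, the defaults and why they were chosen, and what the
synthetic data does and does not establish.

## Data model

A methylation **beta value** is the methylated signal fraction at a CpG
probe, in [0, 1]. The **M-value** is its logit2 transform,
M = log2(beta / (1 − beta)); effects are additive on this scale. The
pipeline's carrier is a probes × samples beta matrix plus a sample sheet
(group, dataset, age, sex) and companion detection-p and bead-count
matrices. One probe annotation (position, gene symbols, gene-region
feature, CGI relation, Infinium design type, QC flags) serves all
datasets, as a real array manifest would.

## Synthetic data generator

The generator's role is to produce inputs whose statistical structure
matches what the analysis assumes, with known ground truth.

* **Baselines.** Each probe draws an unmethylated / hemimethylated /
  methylated state with probabilities (0.4, 0.2, 0.4) and a baseline M
  around the state mode with SD 0.3. Type-I modes sit at beta
  (0.05, 0.50, 0.95); type-II modes are compressed to (0.10, 0.50, 0.85),
  mimicking the Infinium type-I/type-II discrepancy so that the
  normalization stage has real signal to correct.
* **Effects.** Case samples receive a signed shift of `effect_delta`
  M-units (default 1.0) at planted probes; beta values are generated by
  adding Gaussian M-noise (`noise_sd`, default 0.5) and back-transforming
  beta = 2^M / (2^M + 1). The logit-normal construction (rather than
  beta-distributed draws) keeps effects additive and the expected
  delta-beta available in closed form: a 1 M-unit shift at M = 0 gives
  delta-beta = 2/3 − 1/2 = 1/6.
* **Layout.** Gene probe clusters are separated by > 1 kb; within a
  cluster, gaps are 50–900 bp. Every cluster starts with TSS200, TSS1500
  and 1stExon probes, so every gene has a promoter-level statistic.
  Planted regions occupy one gene's whole cluster (5+ consecutive probes,
  gaps < 1 kb) and are kept free of SNP-overlap/multi-hit flags so QC
  cannot make them unrecoverable by construction. Coordinates are
  1-based.
* **Companions.** Detection p-values are ~U(0, 0.005) with failures
  (p in 0.02–0.6) at `detection_fail_rate`; bead counts are 3 + Poisson(11)
  with low counts (1–2) at `beadcount_low_rate`. Both rates default to
  0.002, low enough that QC removes few informative probes yet the
  filters are exercised.
* **Cross-disease wrapper.** Three diseases share the annotation and
  baselines; the first spans three constituent datasets (meta-analyzed
  downstream). Similarity sites share one direction in all diseases;
  difference sites flip exactly one disease, rotated round-robin;
  disease-specific sites are planted in one disease only. Default
  planting: 40 / 30 / 15 sites, 2 shared hypomethylated regions.
* **PPI.** An Erdős–Rényi background (150 nodes, edge probability 0.05)
  over gene symbols plus a planted module of 12 planted-effect genes
  wired as a random spanning path with extra edges at probability 0.8,
  guaranteeing connectivity.

What the generator does **not** emulate: cell-type composition,
batch/chip-position effects, probe cross-hybridization structure, or
IDAT-level intensities. Passing tests therefore demonstrate the
statistical machinery under the stated model, not robustness to those
real-data artifacts.

## QC

Samples first, then probes (the sample filter changes the denominator of
the probe bead-count fraction, so order matters and is fixed). A sample
is dropped when the fraction of probes with detection p > 0.01 is
strictly greater than 10%. A probe is dropped when its bead count is
below 3 in ≥ 5% of samples, when it overlaps a SNP, multi-maps, or lies
on chromosome Y. The published bead-count criterion this follows is
ambiguously worded in the array-QC literature; the standard reading
implemented here is stated in the QC report JSON. QC is idempotent.

## BMIQ-style normalization

Per sample, a three-component beta mixture is fitted separately to
type-I and type-II probes by EM. The M-step maximizes the weighted beta
likelihood exactly (L-BFGS on log-shapes with digamma gradients), which
keeps the log-likelihood monotone — a property the tests assert.
Initialization is a quantile-seeded 1-d k-means with method-of-moments
shapes; beta values are clipped to [1e-6, 1 − 1e-6]; convergence at
|Δ log L| < 1e-5 or 500 iterations; components relabeled by ascending
mean so U < H < M.

Type-II probes assigned (max posterior) to U are mapped through
q = F⁻¹_{U,I}(F_{U,II}(beta)); M-class probes through the analogous
upper-tail map so the fully methylated end anchors at 1; H-class probes
by a linear dilation whose target interval is bounded by the transformed
U-class upper end and M-class lower end, offset by the class gaps
observed on the input scale — this keeps the map close to the identity
when the two design types already agree. Type-I probes are never
touched; a failed fit leaves the sample unnormalized with a warning.

## Differential testing

Per probe, a two-group linear-model t-test on the beta scale by default
(the M scale is an option; the beta default matches delta-beta-centric
reporting). With shrinkage off this is exactly the pooled two-sample
t-test, which the acceptance suite verifies to 1e-10. Optional
empirical-Bayes-style moderation pulls the pooled variance toward the
cross-probe mean with prior df 3 and adds the prior df to the reference
t distribution; it is documented as an approximation of the moderated
tests in the standard array toolchains, not a clone. Effect size is
always delta-beta = mean(beta_case) − mean(beta_control) with flags
HyperM (> 0) / HypoM (< 0) / none (= 0).

Selection modes: BH FDR < 0.05 (default), or the stringent mode
(Bonferroni-adjusted p < 0.05 and |delta-beta| ≥ 0.01) used for a
disease whose controls come from stochastic resampling. BH is
implemented directly (step-up with stable tie ordering) and
property-tested against a brute-force restatement of the definition.

## Meta-analysis

Datasets of one disease are combined per probe by inverse-variance
weighting with SE(delta-beta) = sqrt(s²_case/n_case + s²_ctrl/n_ctrl).
Heterogeneity uses Cochran's Q and DerSimonian–Laird tau². The fixed
effect is primary; the random-effects estimate is reported alongside and
used when tau² > 0 (`model="auto"`), since which model the original
analyses used is generally unstated. Probes absent from some datasets
after QC are combined over the datasets that retain them.

## DMR calling

A region is a maximal run of significant probes on one chromosome with
successive gaps ≤ 1000 bp, reported at ≥ 5 probes. This is the
operational clustering definition itself, not a kernel-smoothed
recomputation of probe statistics (a deliberate divergence from
smoothing-based callers, which need tuning that the definition does not
state). The region p combines member evidence by Stouffer's method on
z-scores signed by delta-beta — opposing directions cancel rather than
reinforce — with Fisher's method as an unsigned option, then BH across
regions. Direction requires unanimous member flags; mixed regions are
reported but excluded from cross-disease region comparison. Unsorted
input is an error, never silently re-sorted. Output spans are 1-based
inclusive; the BED export converts to 0-based half-open.

## Cross-disease comparison

Shared sites are the intersection of the three significant DMP sets,
stratified island / neighbor (shore + shelf) / opensea. Classification
of a flag triple: similarity when all three agree (none excluded),
difference when exactly one disease opposes the other two, other
otherwise — verified against an exhaustively enumerated 27-triple table.
Shared regions are matched by ≥ 1 bp interval overlap on the same
chromosome, since per-disease probe sets differ after QC.

The across-disease test is a one-way fixed-effects ANOVA on per-sample
case-group beta values, BH-corrected across sites. Using case values
(not case-minus-control residuals) is a design choice — the comparison
asks whether case methylation differs across diseases; a residual mode
is available via `control_betas` for designs where control cohorts are
not comparable.

## FEM-style hotspots

Gene statistics average probe t statistics over TSS200 probes, falling
back to 1stExon then TSS1500 (genes with only gene-body/UTR probes are
absent, not zero-filled). Edges of the PPI restricted to genes with
statistics are weighted w_ij = (|t_i| + |t_j|)/2, normalized by the
maximum. The module score is the total induced edge weight divided by
the member count — an average edge weight per member. A per-edge mean
score cannot support greedy growth under strict improvement (it peaks at
the single best edge), so the per-member form is used; it rewards
modules that are simultaneously heavy and dense, and the toy-graph test
verifies the greedy optimum against exhaustive enumeration of connected
subgraphs. Growth is deterministic (ties by gene symbol), stops at no
strict improvement or 100 members.

Significance permutes the gene statistics over nodes (graph fixed),
recomputes weights including the normalization, regrows from the same
seed, and reports the add-one estimator (1 + #{perm ≥ obs})/(n_mc + 1),
so p is never 0 and is bounded below by 1/(n_mc + 1). Defaults follow
the cited parameterization: 100 seeds, 1000 Monte Carlo runs, minimum
module size 10, p < 0.05; the orchestrated synthetic runs use 15–30
seeds and 200–500 runs, which the recovery experiments show is ample at
these network sizes. Seeds are the top-|stat| genes not yet absorbed
into an accepted module; accepted modules sharing ≥ 50% of the smaller
one's members are deduplicated keeping the better score. The null
validity of the permutation p (super-uniformity under exchangeable
stats) is checked empirically in the acceptance suite.

## Over-representation analysis

Hypergeometric upper tail p = P(X ≥ k) per gene set, BH across sets.
The universe defaults to the genes on the cytokine chip, not the whole
genome, so enrichment is relative to the chip's own composition. Hyper-
and hypomethylated gene lists are tested separately. Real GO/KEGG
databases are deliberately not bundled (version-dependent); any GMT
works.

## Reporting

Percentages are 100·count/total rounded half-up — 2 decimals for
probe-level shares, 1 decimal for region-level shares, matching common
mixed usage in published summaries. Zero denominators report
not-applicable (None), never 0. Inconsistent inputs (flags not summing
to totals) raise rather than being silently repaired. A counts-only mode
(`summary_from_counts`) recomputes derived percentages directly from
printed summary cells, so the arithmetic can be exercised when the
underlying matrices are unavailable.

## Problem sizes

The orchestrated synthetic study runs at 1 200 probes across 240 genes,
with 50/50 case/control samples for the single-dataset diseases and
3 × 30/30 for the meta-analyzed one; calibration experiments use 10 000
probes (null type-I error), 1 000 replicates (meta coverage, BH oracle),
100 / 60 replicates (region recovery) and 20 replicates at 500 Monte
Carlo runs (module recovery). These sizes are the package's desk-scale
defaults; every stage scales linearly in probes × samples except the
Monte Carlo permutation, which scales with n_mc × edges.

## Known limitations

* No covariate adjustment (age, sex, smoking, cell composition) in the
  per-probe model; matched designs are assumed.
* The region caller reports the stated clustering definition; it does
  not recompute smoothed statistics, so very sparse but real regions
  with gaps > 1 kb are split.
* The greedy module growth is a local optimizer; it is validated against
  exhaustive search only on small graphs, and a spin-glass/community
  optimizer is out of scope.
* The EM beta mixture assumes three components; samples with genuinely
  bimodal distributions fail the fit and are left unnormalized (logged).
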