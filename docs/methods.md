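# Methods

This note documents the models, estimators and design choices behind
`clonescape`, and what the synthetic cohort does and does not establish
about real data.

## CCF model and multiplicity

A somatic mutation present in a fraction `ccf` of tumor cells, on `m` of
the `n_t` tumor allele copies at its locus, in a sample of purity `rho`
(normal cells diploid), has expected variant allele fraction

    f = ccf · rho · m / (rho · n_t + (1 − rho) · 2).

`expected_vaf` and `compute_ccf` are exact inverses; raw CCFs above 1.25
are clipped and flagged rather than discarded (1.25 matches the clustering
prior's support and tolerates multiplicity mis-calls and noise above 1).
Sex chromosomes are excluded by default; the normal copy number is fixed at
2.

Multiplicity enters everything downstream, so it is estimated carefully.
The single-region rule (`estimate_multiplicity`) rounds the mutation copy
number `vaf · (rho·n_t + (1−rho)·2)/rho` half-away-from-zero and clamps to
[1, major]. For clustering, `build_observation_matrix` instead pools the
mutation copy number across the regions that carry the mutation
(depth-weighted): a mutation has one multiplicity wherever it is present,
and pooling shrinks the estimator's noise by about the square root of the
number of carrying regions. At 80X this removes essentially all
multiplicity mis-calls for clonal mutations; regions without supporting
reads are excluded because an absent clone would dilute the estimate.
Multiplicities are then held fixed during sampling — there is no joint
re-estimation inside the sampler.

## Dirichlet-process clustering

Mutations are clustered jointly over regions under a truncated
stick-breaking DP binomial mixture (default truncation 20 components,
concentration sampled under a Gamma(1,1) prior with the usual
auxiliary-variable scheme). Cluster locations live on a regular CCF grid
(step 0.01, support [0, 1.25]) and are drawn from their exact discrete
conditionals; assignments are drawn from categorical conditionals
(Gumbel-argmax). Defaults: 2000 iterations, 500 burn-in, thinning 10.
Mutations with zero depth in a region contribute no likelihood term there.
The sampler iterates mutations in a canonical content order (lexicographic
locus key), so permuting the input rows cannot change the result — the
exchangeability property is structural, not statistical.

Fewer than 50 mutations triggers a warned single-cluster maximum-likelihood
fallback.

### Consensus and polish

The post-burn-in trace is summarized by the pairwise co-clustering matrix;
average-linkage hierarchical clustering on (1 − co-clustering) is cut at
0.5. Three deterministic refinements follow, all operating on the same
binomial likelihood table:

1. **Small-cluster dissolution.** Clusters below `min_cluster_frac`
   (default 1%) of mutations are released to the best-likelihood retained
   cluster; coincident cluster locations merge.
2. **Soft-EM polish with an outlier component.** Cluster locations are
   re-estimated as responsibility-weighted grid maximum-likelihood points.
   Two reasons to prefer this over raw posterior medians or hard
   reassignment: the posterior median is biased upward where a clone is
   absent from a region (the likelihood is one-sided at CCF 0, so its
   median sits above the boundary), and hard assignment truncates
   overlapping clusters, dragging both centers. A fixed-weight (2%)
   uniform-VAF outlier component absorbs mutations that fit no cluster
   (multiplicity or copy-state mis-calls) so they cannot bias locations;
   every mutation still reports its best real cluster.
3. **Model-selection moves.** Each cluster is offered a two-component
   split (centers initialized at its members' 25th/75th CCF percentiles)
   and kept only if the mixture log-likelihood beats the single component
   by a BIC penalty for the extra location vector and weight; conversely,
   a cluster whose members fit their best alternative almost as well
   (summed advantage below the same penalty) is dissolved — such clusters
   are boundary artifacts of overlapping clones.

Credible intervals are computed from the trace conditional on the final
membership. This polish is deterministic given the trace, so the overall
pipeline is reproducible from the single Gibbs seed.

A note on limits: a binomial mixture whose components are separated by
about one standard deviation of the per-observation noise is statistically
unidentifiable no matter how many mutations are observed (mixture
estimation converges at the notoriously slow n^(1/4) rate near overlap).
No consensus or polish can recover clusters the likelihood cannot
distinguish; the synthetic generator therefore only plants clones whose
separations are resolvable (below).

## Clone trees

`build_forest` processes clusters in decreasing total-CCF order. The
candidate parent of a cluster is the smallest already-placed cluster that
nests it (CCF at least the child's minus `eps` in every region, `eps`
default 0.1 to absorb 80X binomial noise); ties prefer the smaller total
CCF, i.e. the most recent ancestor. Clusters nested by nobody become
roots. Attaching a child that would break the pigeonhole constraint
(children summing above the parent plus `eps` in some region) re-attaches
it to the nearest ancestor that restores the constraint; a cluster with no
consistent placement attaches to its component root with a flag, never
silently dropped. Crossing clusters (CCF order flipping between regions
beyond `eps`) can never nest, so they end up as siblings or in different
subtrees. Every emitted tree is auditable post hoc (`audit_sum_rule`).

Trajectory calls are structural: two or more roots = multiple MRCAs
(independently initiated lesions); any node with two or more children =
branching growth. Exclusive ("oval plot") fractions are CCF minus the
children's CCF sum, with small negatives clipped.

Structural variants are not clustered; per-region SV sets attach to the
most specific cluster present in that region (fewest supporting regions,
then highest CCF) — a documented heuristic.

## Timing

Trunk status comes from the tree (root clusters). For a trunk mutation in
a gained region (major ≥ 2), multiplicity ≥ 2 means it predates the gain
(clonal-early), multiplicity 1 postdates it (clonal-late); without a gain
the order is unresolvable (clonal-unspecified). Non-trunk mutations are
subclonal. These are hard rules, not a probabilistic timing model; they
are exact when the multiplicity is exact, which the pooled estimator makes
near-certain at the default depth.

## Signatures

SBS96 channels use the standard pyrimidine-strand trinucleotide encoding;
ID83 uses indel length, homopolymer/repeat context and microhomology
classes (layout documented in `signature_engine`); CN48 classifies
segments by zygosity (homozygous deletion / LOH / heterozygous), total
copy class and length class, 48 channels exactly.

Refitting is non-negative least squares against a channel × signature
catalog with iterative pruning of signatures below 5% of total activity
(restores sparsity; threshold configurable). Per-mutation signature
probabilities follow `P(s|c) ∝ e_s · S_cs`. Branch profiles default to
refitting each branch's own channel counts; summing per-mutation
probabilities under the case-wide fit is available as an alternative. The
de novo extractor is a minimal multiplicative-update NMF minimizing KL
divergence, best of several seeded restarts; its objective trace is
non-increasing by construction and the rank is user-supplied.

The packaged catalogs are synthetic: their column shapes imitate
well-known processes (CpG deamination, APOBEC TpC mutagenesis, flat
clock-like spectra, homopolymer-slippage and microhomology indels, LOH-rich
copy-number states) but they are generated constructs for simulation and
testing, not measured references. Real catalogs in the same layout drop
in via `load_catalog(path=...)`.

## Transcriptome scoring

All scores operate on log2(TPM+1). Gene-set scores are mean per-gene
z-scores across samples (simple and auditable). The gradient score is the
squamous-set score minus the classical-set score and is exactly
antisymmetric under swapping the sets. The enrichment score used for
stromal/immune summaries is a single-sample rank statistic: genes ranked
per sample (ties broken by gene id), a running sum weighted by rank^0.25
at set genes against a uniform decrement elsewhere, signed maximum
deviation; being rank-based it is invariant to monotone within-sample
transformations. Cell fractions minimize ‖R·w − g‖² over w ≥ 0, Σw ≤ 1 on
the shared reference genes (SLSQP; near-collinear references are warned
and ridge-stabilized), with 1 − Σw reported as the uncharacterized
fraction. Sample clustering is PCA on z-scored log expression followed by
seeded k-means, labels ordered by decreasing mean gradient score.

## Statistics

The Fisher–Pitman permutation test uses the difference in means, full
enumeration of label assignments when C(n, n₁) ≤ 200,000 and seeded Monte
Carlo otherwise, with the observed assignment counted in both numerator
and denominator (so p > 0). Mann–Whitney uses midranks, exact null for
min(n) ≤ 8 without ties, otherwise the tie- and continuity-corrected
normal approximation. Fisher's exact test sums hypergeometric
probabilities of tables at most as probable as the observed one. Spearman
p-values are exact permutation enumerations for n ≤ 7 and seeded Monte
Carlo beyond. A Benjamini–Hochberg utility is provided but no correction
is applied by default.

## Synthetic cohort: what it emulates, and what it does not

Defaults emulate a 12-patient surgical cohort: 2–6 regions per lesion,
80X tumor coverage (Poisson-distributed depths), per-region purity drawn
uniformly from 0.3–0.9, clone trees of three archetypes (4 single-MRCA
linear, 5 single-MRCA branching, 3 multiple-MRCA per 12 patients),
diploid genomes with a configurable 20% of segment length in gained/LOH
states, ~7% indels, per-clone SBS/ID signature exposures (clock-like
trunks, occasional APOBEC subclones, early-clone ID1/ID2), per-region
intrachromosomal SV counts Poisson(85) for branching cases versus
Poisson(30) for linear ones, and invasive-labeled regions carrying extra
private mutations (2x boost in their dominant subclone). Mutation loads
(trunk 450–650, subclones 200–400) are scaled down from the emulated
study's per-sample SNV counts for desk-scale runtime but keep cluster-level
CCF standard errors comfortably inside the 0.05 recovery tolerance.

**Identifiability by construction.** Planted CCF configurations satisfy:
the sum rule; a ≥ 0.08 CCF separation between siblings in at least one
region; every clone detectable (CCF ≥ 0.25 somewhere); uniqueness of the
noiseless reconstruction (every non-ancestor pair fails mutual nesting by
a margin); and — with the drawn purities — every informative clone gap
exceeding z = 2.2 binomial standard errors of expected VAF at the study
depth in at least one region. Purities are drawn before the tree; lesions
whose clones cannot be resolved at the drawn purities are redrawn, and
failing that present fewer clones. This mirrors practice: samples with
purity too low for subclonal deconvolution are excluded from clonal
analyses, and a lesion only exhibits as many clones as its data resolve.

**Consequences for interpretation.** Passing recovery tests shows the
pipeline extracts what is extractable under its own generative model:
clonal copy-number states shared across regions, binomial read noise,
correct purities, and resolvable clone separations. It does not establish
performance under subclonal copy number, purity mis-estimation, caller
artifacts, kataegis or regional coverage bias — none of which the
generator emulates. The expression simulator likewise produces idealized
mixtures (reference profiles + subtype shifts + lognormal noise) without
batch effects or compositional read-depth artifacts.

## Numerical choices

CCF grid step 0.01; CCF cap 1.25; tree tolerance `eps` 0.1 CCF units;
clonal tolerance 0.1; NNLS pruning 5%; deconvolution via SLSQP with
ftol 1e-14; ssGSEA exponent 0.25 with gene-id tie-breaks; k-means 10
restarts, seeded; all Monte Carlo seeded with one user seed, per-patient
streams spawned deterministically. Degenerate inputs fail loudly
(zero-variance correlations, empty gene sets, all-zero margins are
flagged) rather than returning silent defaults.

## Known limitations

Single clonal copy-number state per region (no subclonal CNA mixtures);
no mutation-multiplicity resampling inside the Gibbs sampler; hard timing
rules rather than a probabilistic timing model; SV/CNA branch annotation
by region-support heuristic; DBS fitting and de novo rank selection out of
scope; gradient-score gene sets are user-supplied (the packaged sets are
small illustrative stand-ins).
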