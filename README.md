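# clonescape

Multi-region tumor subclonal reconstruction for precursor-to-cancer
progression studies: cancer-cell-fraction (CCF) computation, Bayesian
Dirichlet-process mutation clustering across tumor regions, clone-tree
reconstruction with trajectory classification, branch-level mutational
signatures, mutation timing, and bulk-transcriptome scoring — together with
a synthetic multi-region cohort generator that provides ground truth for
every stage.

The intended setting is a surgical cohort of cystic pancreatic precursor
lesions (IPMN) with associated invasive cancer (PDAC): a dozen patients,
2–6 spatially distinct regions per lesion sequenced at ~80X whole genome,
variable tumor purity, plus bulk RNA-seq on matched regions. The package is
agnostic to the tissue; it consumes standard formats (VCF with AD depths,
Battenberg-style allele-specific segment tables, BEDPE structural variants,
gene × sample TPM matrices).

## The model

For a somatic mutation carried by a fraction `ccf` of tumor cells at a locus
with tumor copy number `n_t`, mutated-allele multiplicity `m`, in a sample
of purity `rho`, the expected variant allele fraction is

```
f = ccf · rho · m / (rho · n_t + (1 − rho) · 2)
```

Alt read counts are modeled as `y ~ Binomial(N, f)`. Mutations are
clustered jointly over regions with a truncated stick-breaking
Dirichlet-process mixture whose cluster locations `pi_kd` live on a grid
over [0, 1.25]; the Gibbs trace is summarized by posterior co-clustering
and polished with a model-based soft-EM step (see `docs/methods.md`).

Clone trees are built from cluster CCFs with the pigeonhole (sum) rule —
a parent's CCF must cover the sum of its children's in every region — and
the crossing rule — two clusters whose CCF ordering flips between regions
cannot share a lineage. Two or more tree roots mean independently initiated
lesions (multiple MRCAs); a node with two or more children marks branching
rather than linear growth.

Branches are annotated with driver mutations, region-specific structural
variants, and mutational-signature exposures obtained by non-negative
least-squares refitting of SBS96 channel counts against a catalog. Trunk
mutations in gained regions are timed (clonal-early when on all gained
copies, clonal-late otherwise); non-trunk mutations are subclonal.

On the expression side: mean-z gene-set scores, the squamous-minus-classical
gradient score, rank-based stromal/immune (ESTIMATE-like) enrichment,
constrained-least-squares cell-fraction deconvolution with an explicit
uncharacterized remainder, and PCA + k-means sample clustering.

## Worked example

```
clonescape simulate --out demo --patients 3 --seed 5
clonescape run --manifest demo/cohort.yaml --out demo_results --seed 5
```

The `simulate` step prints `wrote 3 patients under demo`. The `run` step
analyzes each patient and ends by printing the cohort report (seed 5,
abridged):

```
{
 "n_patients": 3,
 "n_snv": 14934,
 "n_indel": 1143,
 "n_sv": 569,
 "trajectories": [
  {"patient_id": "P01", "mrca_pattern": "single_mrca", "growth_pattern": "linear",    "n_roots": 1, "n_clusters": 4},
  {"patient_id": "P02", "mrca_pattern": "single_mrca", "growth_pattern": "branching", "n_roots": 1, "n_clusters": 3},
  {"patient_id": "P03", "mrca_pattern": "multiple_mrca", "growth_pattern": "linear",  "n_roots": 2, "n_clusters": 4}
 ],
 "sv_burden": {"branching_mean": 72.75, "linear_mean": 21.67,
               "p_value": 0.0014, "method": "fisher_pitman"},
 "tmb": {"pdac_mean": 0.554, "ipmn_mean": 0.37},
 "expression": {"n_samples": 13, "mean_gradient": -0.0,
                "cluster_sizes": {"2": 10, "1": 3}}
}
```

Reading the output: each patient's mutations were clustered by CCF across
its regions (`n_clusters`), the clone forest classified by number of
independent origins (`mrca_pattern`) and growth mode (`growth_pattern`).
`sv_burden` compares per-region intrachromosomal structural-variant counts
between branching and linear cases with a two-sided Fisher–Pitman
permutation test; `tmb` is mutations per megabase by histology. Per-case
outputs land under `demo_results/<patient>/`: `tree.nwk` (branch lengths =
SNV+indel counts per cluster), `tree.json` (per-region CCFs, annotations,
oval-plot fractions), `branch_signatures.tsv`, `timing.tsv` and per-region
feature tables. Exact numbers depend on the seed.

Library use mirrors the CLI: `clonescape.synthetic_data.simulate_cohort`,
`clonescape.pipeline.run_cohort`, and the per-stage modules (`dp_cluster`,
`tree_builder`, `signature_engine`, `transcriptome`, `stats`) are importable
directly.

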