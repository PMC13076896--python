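"""End-to-end cohort analysis: ingest -> cluster -> tree -> annotate -> report.

Orchestrates the library modules over a cohort manifest: reads per-region
variant calls, copy-number segments, purities and SVs; estimates per-mutation
CCFs and multiplicities; clusters mutations across regions; reconstructs and
annotates clone trees; classifies evolutionary trajectories; assigns mutation
timing; computes branch signature profiles; scores bulk expression when
present; and writes per-case and cohort-level result files.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import io_formats as iof
from . import tree_builder as tb
from .dp_cluster import (CCFObservationMatrix, ClusterSolution, GibbsConfig,
                         build_observation_matrix, cluster_mutations)
from .signature_engine import (branch_signature_profile,
                               encode_sbs96, load_catalog)
from .transcriptome import (deconvolve_matrix, estimate_scores,
                            gradient_score, pca_cluster)
from .variant_features import classify_timing, compute_ccf, compute_tmb

__all__ = ["CaseResult", "ingest_patient", "analyze_patient", "run_cohort",
           "timing_table"]


@dataclass
class CaseResult:
    patient_id: str
    solution: ClusterSolution
    tree: tb.CloneTree
    trajectory: tb.TrajectoryCall
    data: CCFObservationMatrix
    calls: list
    svs_by_region: dict
    timing: pd.DataFrame
    branch_profiles: pd.DataFrame
    feature_tables: dict[str, pd.DataFrame] = field(default_factory=dict)


def ingest_patient(manifest: iof.CohortManifest, base_dir: str):
    """Load and assemble one patient's multi-region inputs."""
    if len(manifest.regions) < 2:
        raise ValueError(
            f"{manifest.patient_id}: multi-region clustering needs >=2 regions")
    manifest.validate_paths(base_dir)
    calls_by_region, segments_by_region, svs_by_region = {}, {}, {}
    purity: dict[str, float] = {}
    for r in manifest.regions:
        rid = r.region_id
        calls_by_region[rid] = iof.read_vcf(
            os.path.join(base_dir, r.vcf), rid)
        segments_by_region[rid] = iof.read_segments(
            os.path.join(base_dir, r.segments), rid)
        svs_by_region[rid] = (iof.read_bedpe(
            os.path.join(base_dir, r.bedpe), rid) if r.bedpe else [])
        purity[rid] = iof.read_purity(
            os.path.join(base_dir, r.purity))[rid]
    calls = iof.merge_region_calls(calls_by_region)
    iof.attach_copy_states(calls, segments_by_region)
    return calls, segments_by_region, svs_by_region, purity


def _sbs_channel_counts(calls, assignment: dict[str, str],
                        nodes) -> dict[str, np.ndarray]:
    counts = {n: np.zeros(96) for n in nodes}
    for c in calls:
        if c.is_indel or not c.context or "|" in c.context:
            continue
        node = assignment.get(c.key)
        if node not in counts:
            continue
        try:
            counts[node][encode_sbs96(c.ref, c.alt, c.context)] += 1
        except ValueError:
            continue
    return counts


def timing_table(calls, data: CCFObservationMatrix,
                 solution: ClusterSolution, tree: tb.CloneTree) -> pd.DataFrame:
    """Per-mutation timing labels.

    A mutation is trunk when its cluster is a tree root.  The informative
    region is the first one with a copy-number gain and coverage (gains are
    what separate early from late); otherwise the deepest-covered region.
    """
    trunk = set(tree.roots)
    rows = []
    key_to_row = {k: i for i, k in enumerate(data.keys)}
    for c in calls:
        i = key_to_row[c.key]
        node = solution.assignment.get(c.key)
        j_star = None
        for j, rid in enumerate(data.regions):
            maj, _ = c.copy_state.get(rid, (1, 1))
            if data.depth[i, j] > 0 and maj >= 2:
                j_star = j
                break
        if j_star is None:
            j_star = int(np.argmax(data.depth[i]))
        rid = data.regions[j_star]
        maj, mino = c.copy_state.get(rid, (1, 1))
        m = int(min(data.multiplicity[i, j_star], max(maj, 1)))
        timing = classify_timing(node in trunk, m, max(maj, 1), mino)
        rows.append({"key": c.key, "cluster": node, "region": rid,
                     "multiplicity": m, "major": maj, "minor": mino,
                     "timing": timing.value})
    return pd.DataFrame(rows)


def _feature_tables(calls, data: CCFObservationMatrix,
                    solution: ClusterSolution,
                    timing: pd.DataFrame) -> dict[str, pd.DataFrame]:
    timing_by_key = dict(zip(timing["key"], timing["timing"]))
    key_to_row = {k: i for i, k in enumerate(data.keys)}
    tables = {}
    for j, rid in enumerate(data.regions):
        rows = []
        for c in calls:
            i = key_to_row[c.key]
            N = data.depth[i, j]
            if N == 0:
                continue
            vaf = data.alt[i, j] / N
            ccf, capped = compute_ccf(vaf, data.purity[j],
                                      data.multiplicity[i, j],
                                      data.total_cn[i, j])
            rows.append({
                "key": c.key, "vaf": round(float(vaf), 4),
                "multiplicity": int(data.multiplicity[i, j]),
                "ccf": round(float(ccf), 4), "capped": bool(capped),
                "cluster": solution.assignment.get(c.key),
                "timing": timing_by_key.get(c.key),
                "is_indel": c.is_indel,
            })
        tables[rid] = pd.DataFrame(rows)
    return tables


def analyze_patient(manifest: iof.CohortManifest, base_dir: str,
                    config: Optional[GibbsConfig] = None,
                    eps: float = tb.DEFAULT_EPS,
                    sbs_catalog=None) -> CaseResult:
    """Full per-case analysis from files to annotated clone tree."""
    calls, segments, svs, purity = ingest_patient(manifest, base_dir)
    data = build_observation_matrix(calls, purity, manifest.region_ids)
    solution = cluster_mutations(data, config)
    tree = tb.build_forest(solution.cluster_ccf, solution.cluster_size, eps)
    trajectory = tb.classify_trajectory(tree, manifest.patient_id)
    tb.annotate_drivers(tree, calls, solution.assignment)
    tb.annotate_svs_by_support(tree, svs)
    timing = timing_table(calls, data, solution, tree)
    catalog = sbs_catalog if sbs_catalog is not None else load_catalog("sbs")
    channel_counts = _sbs_channel_counts(calls, solution.assignment,
                                         tree.nodes)
    profiles = branch_signature_profile(tree, channel_counts, catalog)
    for n in tree.nodes:
        tree.annotations[n]["signatures"] = {
            s: round(float(v), 4)
            for s, v in profiles.loc[n].items() if v > 0}
    features = _feature_tables(calls, data, solution, timing)
    return CaseResult(
        patient_id=manifest.patient_id, solution=solution, tree=tree,
        trajectory=trajectory, data=data, calls=calls, svs_by_region=svs,
        timing=timing, branch_profiles=profiles, feature_tables=features)


def _intra_sv_counts(svs_by_region: dict) -> dict[str, int]:
    return {rid: sum(1 for s in svs if s.intrachromosomal)
            for rid, svs in svs_by_region.items()}


def run_cohort(manifest_path: str, out_dir: str,
               config: Optional[GibbsConfig] = None,
               seed: Optional[int] = None,
               callable_mb: float = 3000.0) -> dict:
    """Analyze every patient in a cohort manifest and write result files.

    Emits per case: Newick + annotated JSON trees, per-region feature TSVs
    and branch signature profiles; cohort-level: trajectory table, SV burden
    comparison, TMB table, expression score tables when expression is
    present, and a summary ``report.json``.  Returns the report dict.
    """
    base_dir = os.path.dirname(os.path.abspath(manifest_path))
    patients = iof.load_manifest(manifest_path)
    os.makedirs(out_dir, exist_ok=True)
    config = config or GibbsConfig()
    sbs_catalog = load_catalog("sbs")

    seeds = np.random.SeedSequence(seed).spawn(len(patients))
    results: list[CaseResult] = []
    traj_rows = []
    tmb_rows = []
    sv_counts: dict[str, dict[str, int]] = {}
    trajectories: dict[str, tb.TrajectoryCall] = {}
    totals = {"n_snv": 0, "n_indel": 0, "n_sv": 0}

    for man, ss in zip(patients, seeds):
        cfg = GibbsConfig(**{**config.__dict__,
                             "seed": int(ss.generate_state(1)[0] % (2**31))})
        res = analyze_patient(man, base_dir, cfg, sbs_catalog=sbs_catalog)
        results.append(res)
        pdir = os.path.join(out_dir, man.patient_id)
        os.makedirs(pdir, exist_ok=True)
        iof.write_tree(res.tree, os.path.join(pdir, "tree.nwk"), "newick")
        iof.write_tree(res.tree, os.path.join(pdir, "tree.json"), "json")
        res.branch_profiles.to_csv(
            os.path.join(pdir, "branch_signatures.tsv"), sep="\t",
            index_label="cluster")
        res.timing.to_csv(os.path.join(pdir, "timing.tsv"), sep="\t",
                          index=False)
        for rid, ft in res.feature_tables.items():
            ft.to_csv(os.path.join(pdir, f"features_{rid}.tsv"), sep="\t",
                      index=False)
        tc = res.trajectory
        trajectories[man.patient_id] = tc
        traj_rows.append({
            "patient_id": man.patient_id, "mrca_pattern": tc.mrca_pattern,
            "growth_pattern": tc.growth_pattern, "n_roots": tc.n_roots,
            "n_clusters": len(res.solution.clusters)})
        sv_counts[man.patient_id] = _intra_sv_counts(res.svs_by_region)
        hist = {r.region_id: r.histology for r in man.regions}
        for rid in man.region_ids:
            n_snv = sum(1 for c in res.calls
                        if not c.is_indel and c.alt_count.get(rid, 0) > 0)
            n_ind = sum(1 for c in res.calls
                        if c.is_indel and c.alt_count.get(rid, 0) > 0)
            tmb_rows.append({
                "patient_id": man.patient_id, "region_id": rid,
                "histology": hist[rid], "n_snv": n_snv, "n_indel": n_ind,
                "tmb": round(compute_tmb(n_snv, n_ind, callable_mb), 4)})
            totals["n_snv"] += n_snv
            totals["n_indel"] += n_ind
            totals["n_sv"] += len(res.svs_by_region.get(rid, []))

    traj_df = pd.DataFrame(traj_rows)
    traj_df.to_csv(os.path.join(out_dir, "trajectories.tsv"), sep="\t",
                   index=False)
    tmb_df = pd.DataFrame(tmb_rows)
    tmb_df.to_csv(os.path.join(out_dir, "tmb.tsv"), sep="\t", index=False)

    report = {"n_patients": len(patients), **totals,
              "trajectories": traj_rows}
    patterns = {t["growth_pattern"] for t in traj_rows}
    if patterns == {"branching", "linear"}:
        bmean, lmean, test = tb.compare_sv_burden_by_pattern(
            trajectories, sv_counts, seed=seed)
        report["sv_burden"] = {
            "branching_mean": round(bmean, 2), "linear_mean": round(lmean, 2),
            "p_value": test.p_value, "method": test.method}
    pdac = tmb_df[tmb_df.histology == "PDAC"]["tmb"]
    ipmn = tmb_df[tmb_df.histology != "PDAC"]["tmb"]
    if len(pdac) and len(ipmn):
        report["tmb"] = {"pdac_mean": round(float(pdac.mean()), 3),
                         "ipmn_mean": round(float(ipmn.mean()), 3)}

    expr_paths = {p.expression_path for p in patients if p.expression_path}
    if expr_paths:
        expr = iof.read_expression(os.path.join(base_dir,
                                                next(iter(expr_paths))))
        scores = score_expression(expr, base_dir, out_dir, seed)
        report["expression"] = scores
    with open(os.path.join(out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=1)
    return report


def score_expression(expr: pd.DataFrame, base_dir: str, out_dir: str,
                     seed: Optional[int] = None) -> dict:
    """Gradient, stromal/immune and clustering read-outs for a cohort
    expression matrix; uses the packaged illustrative gene sets when the
    cohort directory provides none."""
    from .synthetic_data import default_gene_sets, make_reference_profiles

    gmt = os.path.join(base_dir, "gene_sets.gmt")
    sets = iof.read_gene_sets(gmt) if os.path.exists(gmt) else default_gene_sets()
    table = pd.DataFrame({
        "gradient": gradient_score(expr, sets["squamous"], sets["classical"])})
    est = estimate_scores(expr, sets["stromal"], sets["immune"])
    table = table.join(est)
    ref = make_reference_profiles(list(expr.index), sets,
                                  np.random.default_rng(seed))
    fractions = deconvolve_matrix(expr, ref)
    labels = pca_cluster(expr, n_clusters=2, seed=seed,
                         squamous_set=sets["squamous"],
                         classical_set=sets["classical"])
    table["cluster"] = labels
    table.to_csv(os.path.join(out_dir, "expression_scores.tsv"), sep="\t",
                 index_label="sample")
    fractions.to_csv(os.path.join(out_dir, "cell_fractions.tsv"), sep="\t",
                     index_label="sample")
    return {"n_samples": int(expr.shape[1]),
            "mean_gradient": round(float(table["gradient"].mean()), 4),
            "cluster_sizes": {int(k): int(v)
                              for k, v in labels.value_counts().items()}}
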