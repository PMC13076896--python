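"""Ground-truth generator: archetypes, read counts, contexts, expression."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare

from clonescape import io_formats as iof
from clonescape.signature_engine import (ID83_LABELS, encode_id83,
                                         load_catalog)
from clonescape.synthetic_data import (CohortConfig, _id83_example,
                                       make_reference_profiles,
                                       default_gene_sets,
                                       simulate_clone_tree,
                                       simulate_expression, simulate_patient,
                                       simulate_reads,
                                       simulate_signature_contexts)
from clonescape.variant_features import expected_vaf


class TestCloneTreeSim:
    def test_linear_chain_nested(self):
        spec = simulate_clone_tree("single_mrca_linear", 3, 2, seed=1)
        assert spec.parent == {"T0": None, "T1": "T0", "T2": "T1"}
        # nested CCFs along the chain
        assert (spec.ccf.loc["T0"] >= spec.ccf.loc["T1"] - 1e-9).all()
        assert (spec.ccf.loc["T1"] >= spec.ccf.loc["T2"] - 1e-9).all()

    def test_multi_mrca_two_roots_disjoint(self):
        spec = simulate_clone_tree("multi_mrca", 2, 2, seed=7)
        assert len(spec.roots) == 2
        supp = [set(spec.ccf.columns[spec.ccf.loc[r] > 0])
                for r in spec.roots]
        assert supp[0].isdisjoint(supp[1])

    def test_branching_realized(self):
        spec = simulate_clone_tree("single_mrca_branching", 4, 3, seed=3)
        assert spec.growth_pattern() == "branching"
        assert len(spec.roots) == 1

    def test_infeasible_requests_rejected(self):
        with pytest.raises(ValueError):
            simulate_clone_tree("multi_mrca", 1, 2, seed=0)
        with pytest.raises(ValueError):
            simulate_clone_tree("single_mrca_linear", 3, 1, seed=0)

    @pytest.mark.parametrize("archetype", ["single_mrca_linear",
                                           "single_mrca_branching",
                                           "multi_mrca"])
    def test_validator_sweep(self, archetype):
        rng = np.random.default_rng(42)
        for _ in range(60):
            n_clones = int(rng.integers(3, 6))
            n_regions = int(rng.integers(2, 7))
            spec = simulate_clone_tree(archetype, n_clones, n_regions, rng)
            spec.validate()   # sum rule + archetype + exposures
            # sibling separation in at least one region
            for node in spec.nodes:
                ch = spec.children(node)
                for i, a in enumerate(ch):
                    for b in ch[i + 1:]:
                        diff = (spec.ccf.loc[a] - spec.ccf.loc[b]).abs()
                        assert diff.max() >= 0.08 - 1e-9


class TestReads:
    def test_vaf_within_three_se(self):
        spec = simulate_clone_tree("single_mrca_branching", 4, 3, seed=11)
        purity = {d: 0.6 for d in spec.regions}
        calls, segs, svs, truth = simulate_reads(
            spec, purity, 80.0, load_catalog("sbs"), load_catalog("id"),
            seed=5)
        by_clone = {}
        for c in calls:
            t = truth["mutations"][c.key]
            by_clone.setdefault(t["clone"], []).append((c, t))
        for clone, items in by_clone.items():
            for rid in spec.regions:
                fs, vafs, ws = [], [], []
                for c, t in items:
                    if c.depth[rid] == 0:
                        continue
                    maj, mino = t["copy_state"]
                    fs.append(expected_vaf(float(spec.ccf.loc[clone, rid]),
                                           purity[rid], t["multiplicity"],
                                           maj + mino))
                    vafs.append(c.alt_count[rid] / c.depth[rid])
                    ws.append(c.depth[rid])
                fs, vafs, ws = map(np.asarray, (fs, vafs, ws))
                mean_obs = np.average(vafs, weights=ws)
                mean_exp = np.average(fs, weights=ws)
                se = np.sqrt(np.sum(ws * fs * (1 - fs)) / ws.sum() ** 2)
                assert abs(mean_obs - mean_exp) <= 3 * se + 1e-6

    def test_truth_complete_and_unique(self):
        spec = simulate_clone_tree("single_mrca_linear", 3, 2, seed=2)
        purity = {d: 0.8 for d in spec.regions}
        calls, _, _, truth = simulate_reads(
            spec, purity, 60.0, load_catalog("sbs"), load_catalog("id"),
            seed=3)
        keys = [c.key for c in calls]
        assert len(set(keys)) == len(keys)
        assert set(keys) == set(truth["mutations"])

    def test_bad_purity_rejected(self):
        spec = simulate_clone_tree("single_mrca_linear", 3, 2, seed=2)
        with pytest.raises(ValueError):
            simulate_reads(spec, {d: 1.5 for d in spec.regions}, 60.0,
                           load_catalog("sbs"), load_catalog("id"))


class TestSignatureContexts:
    def test_pure_exposure_matches_catalog_column(self):
        catalog = load_catalog("sbs")
        spec = simulate_clone_tree("single_mrca_linear", 2, 2, seed=4)
        spec.exposures_sbs.loc[:, :] = 0.0
        spec.exposures_sbs["SBS2"] = 1.0
        channels = simulate_signature_contexts(
            spec, catalog, {"T0": 5000, "T1": 0}, seed=9)
        obs = np.bincount(channels["T0"], minlength=96)
        expected = catalog["SBS2"].values * 5000
        keep = expected > 1e-6
        stat = chisquare(obs[keep], expected[keep] * obs[keep].sum()
                         / expected[keep].sum())
        assert stat.pvalue > 1e-3
        assert channels["T1"].size == 0

    def test_id83_examples_realize_every_channel(self):
        rng = np.random.default_rng(0)
        for ch in range(83):
            ref, alt, left, right = _id83_example(ch, rng)
            assert encode_id83(ref, alt, left, right) == ch, ID83_LABELS[ch]


class TestExpression:
    def test_noiseless_single_profile(self):
        sets = default_gene_sets()
        genes = [g for s in sets.values() for g in s] + ["F1", "F2"]
        ref = make_reference_profiles(genes, sets, seed=1)
        W = np.zeros((1, ref.shape[1]))
        W[0, 0] = 1.0
        expr, _ = simulate_expression(
            1, sets["squamous"], sets["classical"], sets["stromal"],
            sets["immune"], ref, W, noise_sd=0.0, seed=0)
        assert np.allclose(expr.values[:, 0], ref.values[:, 0])

    def test_squamous_shift_scores_higher(self):
        from clonescape.transcriptome import gene_set_score

        sets = default_gene_sets()
        genes = [g for s in sets.values() for g in s]
        ref = make_reference_profiles(genes, sets, seed=2)
        W = np.tile([0.8, 0.05, 0.05, 0.05, 0.02, 0.03], (4, 1))
        expr, _ = simulate_expression(
            4, sets["squamous"], sets["classical"], sets["stromal"],
            sets["immune"], ref, W, noise_sd=0.0, seed=0,
            subtype=["squamous", "squamous", "classical", "classical"])
        sq = gene_set_score(expr, sets["squamous"])
        cl = gene_set_score(expr, sets["classical"])
        assert (sq.iloc[:2] > cl.iloc[:2]).all()
        assert (cl.iloc[2:] > sq.iloc[2:]).all()

    def test_invalid_fractions_rejected(self):
        sets = default_gene_sets()
        ref = make_reference_profiles(["A", "B"], sets, seed=3)
        with pytest.raises(ValueError):
            simulate_expression(1, [], [], [], [], ref,
                                np.array([[0.7, 0.7, 0, 0, 0, 0]]))


def test_emitted_files_pass_readers(tmp_path):
    man, spec, truth = simulate_patient(
        "P77", "single_mrca_branching", str(tmp_path), seed=6)
    calls_by_region = {}
    for r in man.regions:
        calls = iof.read_vcf(str(tmp_path / r.vcf), r.region_id)
        assert len(calls) == len(truth["mutations"])
        calls_by_region[r.region_id] = calls
        segs = iof.read_segments(str(tmp_path / r.segments), r.region_id)
        assert segs
        svs = iof.read_bedpe(str(tmp_path / r.bedpe), r.region_id)
        assert len(svs) == spec.sv_count[r.region_id]
        rho = iof.read_purity(str(tmp_path / r.purity))[r.region_id]
        assert 0 < rho <= 1
    merged = iof.merge_region_calls(calls_by_region)
    assert len(merged) == len(truth["mutations"])
    # write-then-read equality of counts
    for c in merged[:20]:
        for r in man.regions:
            assert c.depth[r.region_id] >= c.alt_count[r.region_id]
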