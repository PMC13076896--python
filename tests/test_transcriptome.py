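"""Expression scoring, enrichment, deconvolution and clustering."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from clonescape.synthetic_data import (default_gene_sets,
                                       make_reference_profiles,
                                       simulate_expression)
from clonescape.transcriptome import (deconvolve_fractions, estimate_scores,
                                      gene_set_score, gradient_score,
                                      pca_cluster, ssgsea_score)


def _expr(seed=0, n_genes=30, n_samples=6):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(rng.lognormal(2, 1, size=(n_genes, n_samples)),
                        index=[f"g{i:02d}" for i in range(n_genes)],
                        columns=[f"s{j}" for j in range(n_samples)])


class TestGeneSetScore:
    def test_constant_genes_score_zero(self):
        expr = _expr()
        expr.loc[["g00", "g01"]] = 7.0
        assert np.allclose(gene_set_score(expr, ["g00", "g01"]), 0.0)

    def test_shifted_sample_scores_high(self):
        expr = _expr(1)
        genes = ["g00", "g01", "g02"]
        lg = np.log2(expr.loc[genes] + 1)
        shifted = expr.copy()
        # push sample s0 two SDs up on every set gene (in log space)
        shifted.loc[genes, "s0"] = 2 ** (
            lg.mean(axis=1) + 2 * lg.std(axis=1, ddof=0)) - 1
        s = gene_set_score(shifted, genes)
        # s0 re-enters the mean/sd, shrinking its own z slightly below 2
        assert s["s0"] > 1.2
        assert s.idxmax() == "s0"

    def test_sample_permutation_equivariance(self):
        expr = _expr(2)
        s1 = gene_set_score(expr, ["g00", "g05"])
        perm = expr[["s3", "s0", "s5", "s1", "s2", "s4"]]
        s2 = gene_set_score(perm, ["g00", "g05"])
        assert np.allclose(s1.reindex(s2.index), s2)

    def test_missing_set_rejected(self):
        with pytest.raises(KeyError):
            gene_set_score(_expr(), ["nope"])


class TestGradient:
    def test_antisymmetry_exact(self):
        expr = _expr(3)
        a = gradient_score(expr, ["g00", "g01"], ["g02", "g03"])
        b = gradient_score(expr, ["g02", "g03"], ["g00", "g01"])
        assert np.allclose(a, -b)

    def test_all_equal_expression_zero(self):
        expr = pd.DataFrame(5.0, index=["g1", "g2"], columns=["a", "b"])
        g = gradient_score(expr, ["g1"], ["g2"])
        assert np.allclose(g, 0.0)

    def test_noiseless_separation_auc_one(self):
        sets = default_gene_sets()
        genes = [g for s in sets.values() for g in s]
        ref = make_reference_profiles(genes, sets, seed=4)
        W = np.tile([0.9, 0.02, 0.02, 0.02, 0.02, 0.02], (6, 1))
        expr, _ = simulate_expression(
            6, sets["squamous"], sets["classical"], sets["stromal"],
            sets["immune"], ref, W, noise_sd=0.0, seed=0,
            subtype=["squamous"] * 3 + ["classical"] * 3)
        g = gradient_score(expr, sets["squamous"], sets["classical"])
        assert g.iloc[:3].min() > g.iloc[3:].max()    # AUC = 1


class TestSsgsea:
    def test_top_set_beats_bottom_set(self):
        expr = _expr(5)
        col = expr["s0"].sort_values(ascending=False)
        top, bottom = list(col.index[:5]), list(col.index[-5:])
        assert ssgsea_score(expr, top)["s0"] > \
            ssgsea_score(expr, bottom)["s0"]

    def test_hand_computed_three_genes(self):
        expr = pd.DataFrame({"s": [3.0, 2.0, 1.0]},
                            index=["g1", "g2", "g3"])
        # set {g2}: walk = (-1/2, +1/2, 0); first extreme is -1/2
        val = ssgsea_score(expr, ["g2"])["s"]
        assert val == pytest.approx(-0.5)
        # set {g1}: top-ranked hit gives +1 immediately
        assert ssgsea_score(expr, ["g1"])["s"] == pytest.approx(1.0)

    def test_monotone_transform_invariance(self):
        expr = _expr(6)
        a = ssgsea_score(expr, ["g00", "g07", "g11"])
        b = ssgsea_score(expr ** 2, ["g00", "g07", "g11"])
        assert np.allclose(a, b)

    def test_random_set_anticorrelated_with_complement(self):
        expr = _expr(7, n_genes=40, n_samples=12)
        genes = list(expr.index)
        s = ssgsea_score(expr, genes[:20])
        c = ssgsea_score(expr, genes[20:])
        assert np.corrcoef(s, c)[0, 1] < 0

    def test_estimate_combines_stromal_and_immune(self):
        expr = _expr(8)
        out = estimate_scores(expr, ["g00", "g01"], ["g02", "g03"])
        assert np.allclose(out["estimate"],
                           out["stromal"] + out["immune"])


@pytest.fixture(scope="module")
def ref():
    sets = default_gene_sets()
    genes = [g for s in sets.values() for g in s] + \
        [f"X{i}" for i in range(20)]
    return make_reference_profiles(genes, sets, seed=9)


class TestDeconvolution:
    def test_noiseless_recovery_exact(self, ref):
        w = np.array([0.2, 0.3, 0.1, 0.0, 0.0, 0.0])
        g = pd.Series(ref.values @ w, index=ref.index, name="s")
        est = deconvolve_fractions(g, ref)
        got = np.array([est.fractions[c] for c in ref.columns])
        assert np.allclose(got, w, atol=1e-6)
        assert est.uncharacterized == pytest.approx(0.4, abs=1e-6)

    def test_pure_reference_column(self, ref):
        g = pd.Series(ref["CAF"].values, index=ref.index, name="s")
        est = deconvolve_fractions(g, ref)
        assert est.fractions["CAF"] == pytest.approx(1.0, abs=1e-5)

    def test_noisy_recovery(self, ref):
        rng = np.random.default_rng(10)
        errs = []
        for _ in range(20):
            w = rng.dirichlet([3, 2, 1, 1, 1, 1]) * rng.uniform(0.7, 1.0)
            g = ref.values @ w * rng.lognormal(0, 0.2, size=ref.shape[0])
            est = deconvolve_fractions(
                pd.Series(g, index=ref.index, name="s"), ref)
            got = np.array([est.fractions[c] for c in ref.columns])
            errs.append(np.abs(got - w))
        # per-cell-type recovery under lognormal noise
        assert np.mean(errs, axis=0).max() <= 0.05

    def test_collinear_reference_warns(self):
        genes = [f"g{i}" for i in range(60)]
        rng = np.random.default_rng(11)
        col = rng.lognormal(2, 1, 60)
        ref = pd.DataFrame({"A": col, "B": col * 2.0}, index=genes)
        g = pd.Series(col * 1.2, index=genes, name="s")
        with pytest.warns(UserWarning, match="ill-conditioned"):
            est = deconvolve_fractions(g, ref)
        total = sum(est.fractions.values()) + est.uncharacterized
        assert total == pytest.approx(1.0, abs=1e-6)


class TestPcaCluster:
    def _two_groups(self, seed=12, n_per=6):
        rng = np.random.default_rng(seed)
        base = rng.lognormal(2, 0.5, size=(50, 1))
        a = base * rng.lognormal(0, 0.05, size=(50, n_per))
        b = base * 8.0 * rng.lognormal(0, 0.05, size=(50, n_per))
        b[25:] = base[25:] * 0.1
        expr = pd.DataFrame(
            np.hstack([a, b]), index=[f"g{i}" for i in range(50)],
            columns=[f"s{j}" for j in range(2 * n_per)])
        truth = [0] * n_per + [1] * n_per
        return expr, truth

    def test_planted_groups_recovered(self):
        expr, truth = self._two_groups()
        labels = pca_cluster(expr, n_clusters=2, seed=0)
        assert adjusted_rand_score(truth, labels.values) == 1.0

    def test_duplicate_samples_cocluster(self):
        expr, _ = self._two_groups(13)
        expr["dup"] = expr["s0"]
        labels = pca_cluster(expr, n_clusters=2, seed=0)
        assert labels["dup"] == labels["s0"]

    def test_label_order_invariant_to_sample_permutation(self):
        expr, _ = self._two_groups(14)
        labels_a = pca_cluster(expr, n_clusters=2, seed=0)
        perm = expr[list(reversed(expr.columns))]
        labels_b = pca_cluster(perm, n_clusters=2, seed=0)
        assert (labels_a.sort_index() == labels_b.sort_index()).all()

    def test_too_few_samples_rejected(self):
        expr = _expr(15, n_samples=1)
        with pytest.raises(ValueError):
            pca_cluster(expr, n_clusters=2)
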