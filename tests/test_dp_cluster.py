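"""Dirichlet-process CCF clustering: recovery, consensus, likelihood."""

import numpy as np
import pytest
from scipy.stats import binom

from conftest import make_obs
from clonescape.dp_cluster import (GibbsConfig, build_observation_matrix,
                                   cluster_mutations, consense_clusters,
                                   loglik, run_dp_gibbs, CCFObservationMatrix,
                                   ClusterSolution)
import pandas as pd


FAST = GibbsConfig(n_iter=800, burn_in=300, seed=0)


class TestGibbs:
    def test_single_planted_cluster(self):
        data = make_obs([(1.0, 1.0)], 300, depth=100, rho=(1.0, 1.0), seed=1)
        sol = cluster_mutations(data, GibbsConfig(seed=2))
        assert len(sol.clusters) == 1
        assert np.all(np.abs(sol.cluster_ccf.values - 1.0) <= 0.03)

    def test_two_planted_clusters(self):
        data = make_obs([(1.0, 1.0), (0.4, 0.05)], 300, depth=100,
                        rho=(1.0, 1.0), seed=3)
        sol = cluster_mutations(data, GibbsConfig(seed=4))
        assert len(sol.clusters) == 2
        got = sol.cluster_ccf.sort_values("R1", ascending=False).values
        assert np.all(np.abs(got - np.array([[1.0, 1.0], [0.4, 0.05]]))
                      <= 0.05)

    def test_zero_mutations_rejected(self):
        with pytest.raises(ValueError):
            data = make_obs([(1.0, 1.0)], 1, seed=0)
            data.alt = data.alt[:0]
            data.depth = data.depth[:0]
            data.multiplicity = data.multiplicity[:0]
            data.total_cn = data.total_cn[:0]
            data.keys = []
            run_dp_gibbs(data, FAST)

    def test_ccf_stays_in_prior_support(self):
        data = make_obs([(1.0, 0.2), (0.5, 0.9)], 100, seed=5)
        trace = run_dp_gibbs(data, FAST)
        assert trace.locations.min() >= 0.0
        assert trace.locations.max() <= 1.25 + 1e-9

    def test_exchangeability_under_row_permutation(self):
        data = make_obs([(1.0, 1.0), (0.4, 0.1)], 100, seed=6)
        perm = np.random.default_rng(0).permutation(data.n_mutations)
        data_p = CCFObservationMatrix(
            keys=[data.keys[i] for i in perm], regions=data.regions,
            alt=data.alt[perm], depth=data.depth[perm], purity=data.purity,
            multiplicity=data.multiplicity[perm],
            total_cn=data.total_cn[perm])
        sol_a = cluster_mutations(data, GibbsConfig(n_iter=600, burn_in=200,
                                                    seed=7))
        sol_b = cluster_mutations(data_p, GibbsConfig(n_iter=600, burn_in=200,
                                                      seed=7))
        assert sol_a.assignment == sol_b.assignment
        assert np.allclose(sol_a.cluster_ccf.values, sol_b.cluster_ccf.values)

    def test_deeper_coverage_tightens_intervals(self):
        widths = []
        for depth in (60, 600):
            data = make_obs([(0.6, 0.6)], 200, depth=depth, seed=8)
            cfg = GibbsConfig(n_iter=800, burn_in=300, seed=9)
            sol = cluster_mutations(data, cfg)
            widths.append(float(
                (sol.ci_high.values - sol.ci_low.values).mean()))
        assert widths[1] < widths[0]

    def test_small_input_single_cluster_fallback(self):
        data = make_obs([(0.8, 0.8)], 20, depth=100, seed=10)
        with pytest.warns(UserWarning, match="single cluster"):
            sol = cluster_mutations(data, FAST)
        assert sol.cluster_size == {"cl00": 20}
        assert np.all(np.abs(sol.cluster_ccf.values - 0.8) <= 0.06)


class TestConsensus:
    def test_always_coclustered_pair_stays_together(self):
        data = make_obs([(1.0, 1.0)], 60, seed=11)
        trace = run_dp_gibbs(data, FAST)
        sol = consense_clusters(trace, data)
        labels = set(sol.assignment.values())
        assert len(labels) == 1

    def test_three_cluster_ari(self):
        from sklearn.metrics import adjusted_rand_score

        data = make_obs([(1.0, 1.0), (0.6, 0.1), (0.1, 0.6)], 150,
                        depth=100, seed=12)
        sol = cluster_mutations(data, GibbsConfig(seed=13))
        true = np.repeat([0, 1, 2], 150)
        est = [sol.assignment[k] for k in data.keys]
        assert adjusted_rand_score(true, est) >= 0.9


class TestLoglik:
    def _tiny(self):
        keys = ["a", "b", "c"]
        alt = np.array([[50], [30], [10]])
        depth = np.array([[100], [100], [100]])
        data = CCFObservationMatrix(
            keys=keys, regions=["R1"], alt=alt, depth=depth,
            purity=np.array([1.0]),
            multiplicity=np.ones((3, 1), int),
            total_cn=np.full((3, 1), 2))
        ccf = pd.DataFrame({"R1": [1.0, 0.6, 0.2]},
                           index=["cl00", "cl01", "cl02"])
        sol = ClusterSolution(
            assignment={"a": "cl00", "b": "cl01", "c": "cl02"},
            cluster_ccf=ccf,
            cluster_size={"cl00": 1, "cl01": 1, "cl02": 1},
            ci_low=ccf, ci_high=ccf)
        return data, sol

    def test_matches_hand_computation(self):
        data, sol = self._tiny()
        expected = (binom.logpmf(50, 100, 0.5) + binom.logpmf(30, 100, 0.3)
                    + binom.logpmf(10, 100, 0.1))
        assert loglik(sol, data) == pytest.approx(expected, rel=1e-9)

    def test_permutation_invariance(self):
        data, sol = self._tiny()
        perm = CCFObservationMatrix(
            keys=list(reversed(data.keys)), regions=data.regions,
            alt=data.alt[::-1].copy(), depth=data.depth[::-1].copy(),
            purity=data.purity,
            multiplicity=data.multiplicity[::-1].copy(),
            total_cn=data.total_cn[::-1].copy())
        assert loglik(sol, perm) == pytest.approx(loglik(sol, data))

    def test_moving_ccf_off_mle_decreases(self):
        data, sol = self._tiny()
        base = loglik(sol, data)
        worse = sol.cluster_ccf.copy()
        worse.loc["cl01", "R1"] = 0.45
        sol2 = ClusterSolution(sol.assignment, worse, sol.cluster_size,
                               worse, worse)
        assert loglik(sol2, data) < base


def test_build_observation_matrix_masks_missing_regions():
    from clonescape.variant_features import MutationCall

    calls = [MutationCall("chr1", 1, "A", "T", {"R1": 20, "R2": 0},
                          {"R1": 40, "R2": 0},
                          copy_state={"R1": (1, 1), "R2": (1, 1)}),
             MutationCall("chr1", 2, "A", "T", {"R1": 10}, {"R1": 40},
                          copy_state={"R1": (2, 1)})]
    data = build_observation_matrix(calls, {"R1": 0.5, "R2": 0.5})
    assert data.depth[1, 1] == 0          # absent region contributes nothing
    assert data.total_cn[1, 0] == 3
    assert data.alt.shape == (2, 2)
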