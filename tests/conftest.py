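import numpy as np
import pytest


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260925)


def make_obs(cluster_ccfs, n_per_cluster, depth=100, rho=(1.0, 1.0),
             seed=0):
    """Planted-cluster observation matrix for direct sampler tests.

    ``cluster_ccfs``: list of per-region CCF tuples; diploid het loci,
    multiplicity 1.
    """
    from clonescape.dp_cluster import CCFObservationMatrix
    from clonescape.variant_features import expected_vaf

    rng = np.random.default_rng(seed)
    rho = np.asarray(rho, dtype=float)
    D = rho.size
    rows_alt, rows_depth, keys = [], [], []
    i = 0
    for ci, ccfs in enumerate(cluster_ccfs):
        for _ in range(n_per_cluster):
            N = rng.poisson(depth, size=D)
            f = np.array([expected_vaf(c, r, 1, 2)
                          for c, r in zip(ccfs, rho)])
            y = rng.binomial(N, np.clip(f, 0, 1))
            rows_alt.append(y)
            rows_depth.append(N)
            keys.append(f"chr1:{i:06d}:A>T")
            i += 1
    n = len(keys)
    return CCFObservationMatrix(
        keys=keys, regions=[f"R{d + 1}" for d in range(D)],
        alt=np.array(rows_alt), depth=np.array(rows_depth), purity=rho,
        multiplicity=np.ones((n, D), dtype=int),
        total_cn=np.full((n, D), 2, dtype=int))
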