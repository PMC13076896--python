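"""Multi-region Dirichlet-process clustering of mutations by CCF.

Mutations are clustered jointly across tumor regions with a truncated
stick-breaking Dirichlet-process binomial mixture, sampled by Gibbs:

* observation: alt reads ``y_id ~ Binomial(N_id, f)`` with
  ``f = expected_vaf(pi_kd, rho_d, m_id, n_id)`` for the cluster ``k`` the
  mutation is assigned to;
* cluster locations ``pi_kd`` live on a regular grid over [0, 1.25] and are
  sampled from their discrete conditional per region;
* assignments are sampled from categorical conditionals under
  stick-breaking weights; the concentration ``alpha`` can be fixed or
  sampled with the usual auxiliary-variable scheme under a Gamma(1, 1)
  prior.

A consensus solution is extracted from the posterior co-clustering matrix
(average-linkage cut at 0.5), with small clusters dissolved into their
nearest retained neighbor.

Multiplicities are estimated once, upstream, and held fixed during
sampling.  Mutations with zero depth in a region contribute no likelihood
term there.  The sampler iterates mutations in a canonical content order
(lexicographic locus key), so permuting the input rows permutes nothing
internally: results are exchangeable by construction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .variant_features import CCF_CAP

logger = logging.getLogger(__name__)

__all__ = [
    "CCFObservationMatrix",
    "GibbsConfig",
    "GibbsTrace",
    "ClusterSolution",
    "build_observation_matrix",
    "run_dp_gibbs",
    "consense_clusters",
    "cluster_mutations",
    "loglik",
]

MIN_MUTATIONS = 50


@dataclass
class CCFObservationMatrix:
    """Aligned per-mutation, per-region read counts and locus states.

    Arrays are (n_mutations x n_regions); ``depth == 0`` marks a mutation
    unobserved in that region.
    """

    keys: list[str]
    regions: list[str]
    alt: np.ndarray
    depth: np.ndarray
    purity: np.ndarray           # (n_regions,)
    multiplicity: np.ndarray
    total_cn: np.ndarray

    def __post_init__(self) -> None:
        n, d = self.alt.shape
        if self.depth.shape != (n, d) or len(self.regions) != d:
            raise ValueError("misaligned observation matrix")
        if np.any(self.alt > self.depth):
            raise ValueError("alt count exceeds depth")

    @property
    def n_mutations(self) -> int:
        return self.alt.shape[0]

    @property
    def n_regions(self) -> int:
        return self.alt.shape[1]


def build_observation_matrix(calls, purity: dict[str, float],
                             regions: Optional[Sequence[str]] = None
                             ) -> CCFObservationMatrix:
    """Assemble the clustering input from multi-region MutationCalls.

    Multiplicity is fixed here, before sampling, by pooling the mutation
    copy number ``vaf * (rho n_t + (1 - rho) 2) / rho`` across regions
    (depth-weighted).  A mutation sits on the same number of allele copies
    in every region that carries it, so pooling shrinks the estimator noise
    by roughly sqrt(n_regions) relative to the single-region rule in
    :func:`clonescape.variant_features.estimate_multiplicity`; for
    subclonal mutations the pooled copy number is below 1 and clamps to 1.
    The pooled value is re-clamped to each region's major copy number.
    """
    regions = list(regions) if regions is not None else sorted(purity)
    n, d = len(calls), len(regions)
    alt = np.zeros((n, d), dtype=np.int64)
    depth = np.zeros((n, d), dtype=np.int64)
    mult = np.ones((n, d), dtype=np.int64)
    ncn = np.full((n, d), 2, dtype=np.int64)
    majors = np.ones((n, d), dtype=np.int64)
    rho = np.array([purity[r] for r in regions], dtype=float)
    for i, c in enumerate(calls):
        for j, rid in enumerate(regions):
            dp = c.depth.get(rid, 0)
            if dp <= 0:
                continue
            depth[i, j] = dp
            alt[i, j] = c.alt_count.get(rid, 0)
            major, minor = c.copy_state.get(rid, (1, 1))
            ncn[i, j] = major + minor
            majors[i, j] = max(major, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        vaf = np.where(depth > 0, alt / np.maximum(depth, 1), 0.0)
        mut_cn = vaf * (rho * ncn + (1.0 - rho) * 2.0) / rho
    # pool only over regions that carry the mutation; regions where the
    # clone is absent would otherwise dilute the copy-number estimate
    w = np.where(alt > 0, depth.astype(float), 0.0)
    pooled = (mut_cn * w).sum(axis=1) / np.maximum(w.sum(axis=1), 1e-12)
    m_shared = np.clip(np.floor(pooled + 0.5), 1, None).astype(int)
    mult = np.minimum(m_shared[:, None], majors)
    return CCFObservationMatrix(
        keys=[c.key for c in calls], regions=regions, alt=alt, depth=depth,
        purity=rho, multiplicity=mult, total_cn=ncn)


@dataclass
class GibbsConfig:
    n_iter: int = 2000
    burn_in: int = 500
    concentration_alpha: float | str = "sample"
    max_clusters: int = 20
    ccf_grid_step: float = 0.01
    min_cluster_frac: float = 0.01
    thin: int = 10
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be < n_iter")
        if not (0 < self.min_cluster_frac < 1):
            raise ValueError("min_cluster_frac must be in (0, 1)")


@dataclass
class GibbsTrace:
    assignments: np.ndarray   # (n_iter, n) int16, canonical mutation order
    locations: np.ndarray     # (n_iter, K, D) float32
    alpha: np.ndarray         # (n_iter,)
    grid: np.ndarray
    order: np.ndarray         # canonical -> input index map
    config: GibbsConfig


@dataclass
class ClusterSolution:
    assignment: dict[str, str]
    cluster_ccf: pd.DataFrame           # clusters x regions
    cluster_size: dict[str, int]
    ci_low: pd.DataFrame
    ci_high: pd.DataFrame
    flags: dict = field(default_factory=dict)

    @property
    def clusters(self) -> list[str]:
        return [str(c) for c in self.cluster_ccf.index]


def _likelihood_table(data: CCFObservationMatrix, grid: np.ndarray
                      ) -> np.ndarray:
    """Binomial log-likelihood of every mutation at every grid CCF, per
    region; constant terms dropped.  Shape (n, G, D), float32."""
    y = data.alt[:, None, :].astype(np.float64)
    N = data.depth[:, None, :].astype(np.float64)
    rho = data.purity[None, None, :]
    coef = rho * data.multiplicity[:, None, :] / (
        rho * data.total_cn[:, None, :] + (1.0 - rho) * 2.0)
    f = np.clip(grid[None, :, None] * coef, 1e-9, 1 - 1e-9)
    L = y * np.log(f) + (N - y) * np.log1p(-f)
    L[np.broadcast_to(data.depth[:, None, :] == 0, L.shape)] = 0.0
    if np.isnan(L).any():
        raise FloatingPointError("NaN in binomial likelihood table")
    return L.astype(np.float32)


def run_dp_gibbs(data: CCFObservationMatrix, config: GibbsConfig) -> GibbsTrace:
    """Run the truncated stick-breaking Gibbs sampler; returns the trace."""
    if data.n_regions < 1:
        raise ValueError("need at least one region")
    if data.n_mutations == 0:
        raise ValueError("no mutations to cluster")
    if data.n_mutations < MIN_MUTATIONS:
        warnings.warn(
            f"only {data.n_mutations} mutations (<{MIN_MUTATIONS}); "
            "posterior will be dominated by the prior", stacklevel=2)

    rng = np.random.default_rng(config.seed)
    order = np.argsort(np.asarray(data.keys))   # canonical content order
    grid = np.round(np.arange(0.0, CCF_CAP + config.ccf_grid_step / 2,
                              config.ccf_grid_step), 10)
    G = grid.size
    K = config.max_clusters
    n, D = data.n_mutations, data.n_regions

    sub = CCFObservationMatrix(
        keys=[data.keys[i] for i in order], regions=data.regions,
        alt=data.alt[order], depth=data.depth[order],
        purity=data.purity, multiplicity=data.multiplicity[order],
        total_cn=data.total_cn[order])
    L = _likelihood_table(sub, grid)          # (n, G, D)
    Lflat = L.reshape(n, G * D)

    z = rng.integers(0, K, size=n)
    gidx = rng.integers(0, G, size=(K, D))
    alpha = 1.0
    sample_alpha = config.concentration_alpha == "sample"
    if not sample_alpha:
        alpha = float(config.concentration_alpha)

    assign_tr = np.empty((config.n_iter, n), dtype=np.int16)
    loc_tr = np.empty((config.n_iter, K, D), dtype=np.float32)
    alpha_tr = np.empty(config.n_iter)

    for it in range(config.n_iter):
        # --- cluster locations ------------------------------------------
        counts = np.bincount(z, minlength=K)
        occupied = np.flatnonzero(counts)
        if occupied.size:
            S = np.empty((occupied.size, G, D), dtype=np.float32)
            for j, k in enumerate(occupied):
                S[j] = L[z == k].sum(axis=0)
            gum = rng.gumbel(size=S.shape).astype(np.float32)
            gidx[occupied] = np.argmax(S + gum, axis=1)
        empty = np.flatnonzero(counts == 0)
        if empty.size:
            gidx[empty] = rng.integers(0, G, size=(empty.size, D))

        # --- stick-breaking weights -------------------------------------
        tail = counts[::-1].cumsum()[::-1]
        tail = np.append(tail[1:], 0)
        v = rng.beta(1.0 + counts, alpha + tail)
        v[-1] = 1.0
        with np.errstate(divide="ignore"):
            log1mv = np.log1p(-np.clip(v, 0, 1 - 1e-12))
            logw = np.log(np.clip(v, 1e-300, 1)) + np.concatenate(
                ([0.0], np.cumsum(log1mv[:-1])))

        # --- assignments -------------------------------------------------
        A = Lflat[:, gidx[:, 0] * D + 0].copy()
        for d in range(1, D):
            A += Lflat[:, gidx[:, d] * D + d]
        A += logw.astype(np.float32)[None, :]
        z = np.argmax(A + rng.gumbel(size=A.shape).astype(np.float32), axis=1)

        # --- concentration ------------------------------------------------
        k_occ = np.unique(z).size
        if sample_alpha:
            eta = rng.beta(alpha + 1.0, n)
            a0, b0 = 1.0, 1.0
            odds = (a0 + k_occ - 1) / (n * (b0 - np.log(eta)))
            pi_eta = odds / (1.0 + odds)
            shape = a0 + k_occ if rng.random() < pi_eta else a0 + k_occ - 1
            alpha = rng.gamma(shape, 1.0 / (b0 - np.log(eta)))

        assign_tr[it] = z
        loc_tr[it] = grid[gidx]
        alpha_tr[it] = alpha

    return GibbsTrace(assignments=assign_tr, locations=loc_tr,
                      alpha=alpha_tr, grid=grid, order=order, config=config)


def consense_clusters(trace: GibbsTrace, data: CCFObservationMatrix,
                      config: Optional[GibbsConfig] = None) -> ClusterSolution:
    """Posterior-summary clustering from the Gibbs trace.

    Average pairwise co-clustering over post-burn-in (thinned) iterations,
    average-linkage hierarchical clustering on 1 - co-clustering cut at
    0.5, then a deterministic maximum-likelihood polish: cluster locations
    are re-estimated as the grid argmax of their members' summed binomial
    log-likelihood and mutations reassigned to their best cluster until
    stable.  (The grid MLE, unlike a posterior mean or median, is not
    biased upward for clones absent from a region, where the likelihood is
    one-sided at CCF 0.)  Clusters below ``min_cluster_frac`` of mutations
    are dissolved into the best-likelihood retained cluster.  Credible
    intervals come from the trace, conditional on the final membership.
    """
    config = config or trace.config
    kept = np.arange(config.burn_in, trace.assignments.shape[0], config.thin)
    if kept.size == 0:
        raise ValueError("empty post-burn-in trace")
    n = trace.assignments.shape[1]

    co = np.zeros((n, n), dtype=np.float64)
    for t in kept:
        zt = trace.assignments[t]
        co += zt[:, None] == zt[None, :]
    co /= kept.size

    if n == 1:
        labels = np.zeros(1, dtype=int)
    else:
        dist = squareform(1.0 - co, checks=False)
        labels = fcluster(linkage(dist, method="average"), t=0.5,
                          criterion="distance") - 1

    # canonical-order likelihood table for the ML polish
    sub = CCFObservationMatrix(
        keys=[data.keys[i] for i in trace.order], regions=data.regions,
        alt=data.alt[trace.order], depth=data.depth[trace.order],
        purity=data.purity, multiplicity=data.multiplicity[trace.order],
        total_cn=data.total_cn[trace.order])
    L = _likelihood_table(sub, trace.grid)          # (n, G, D)
    G, D = L.shape[1], L.shape[2]

    def centers_of(lbls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ids = np.unique(lbls)
        cen = np.empty((ids.size, D))
        gix = np.empty((ids.size, D), dtype=int)
        for j, c in enumerate(ids):
            S = L[lbls == c].sum(axis=0)            # (G, D)
            gix[j] = np.argmax(S, axis=0)
            cen[j] = trace.grid[gix[j]]
        return ids, gix

    min_size = max(1, int(np.ceil(config.min_cluster_frac * n)))

    def dissolve_small(labels: np.ndarray) -> np.ndarray:
        while True:
            ids, counts = np.unique(labels, return_counts=True)
            small = ids[counts < min_size]
            if small.size == 0 or small.size == ids.size:
                return labels
            keep = ids[counts >= min_size]
            _, gix = centers_of(labels)
            keep_cols = [int(np.flatnonzero(ids == k)[0]) for k in keep]
            score = np.zeros((n, len(keep_cols)), dtype=np.float32)
            for d in range(D):
                score += L[:, gix[keep_cols, d], d]
            mask = np.isin(labels, small)
            labels = labels.copy()
            labels[mask] = keep[np.argmax(score[mask], axis=1)]

    def merge_coincident(labels: np.ndarray) -> np.ndarray:
        ids, gix = centers_of(labels)
        seen: dict[tuple, int] = {}
        remap = {}
        for j, c in enumerate(ids):
            key = tuple(gix[j])
            if key in seen:
                remap[int(c)] = seen[key]
            else:
                seen[key] = int(c)
        if remap:
            labels = np.array([remap.get(int(l), int(l)) for l in labels])
        return labels

    Lflat = L.reshape(n, G * D)
    # uniform-VAF outlier term: mutations whose read counts fit no cluster
    # (multiplicity mis-calls, copy-state errors) are absorbed here instead
    # of dragging cluster locations.  L drops the binomial coefficient, so
    # the same constant is subtracted here to keep the scales comparable:
    # integrating Binom(y | N, f) over f uniform gives 1/(N+1), and the
    # dropped coefficient is log C(N, y).
    from scipy.special import gammaln

    y_, N_ = sub.alt.astype(float), sub.depth.astype(float)
    log_coef = (gammaln(N_ + 1) - gammaln(y_ + 1) - gammaln(N_ - y_ + 1))
    log_outlier = np.where(N_ > 0, -np.log(N_ + 1.0) - log_coef, 0.0
                           ).sum(axis=1)
    PI_OUT = 0.02

    def soft_em(labels: np.ndarray):
        """Soft-EM polish of the retained mixture: responsibilities under
        the binomial model plus a fixed-weight outlier component,
        responsibility-weighted grid-MLE locations, until the grid indices
        stabilize.  Soft assignment keeps overlapping clusters' location
        estimates consistent where hard assignment would truncate them."""
        ids, gix = centers_of(labels)
        K_fin = ids.size
        pi = np.array([(labels == c).mean() for c in ids]) * (1 - PI_OUT)
        r = None
        for _ in range(50):
            logr = np.empty((n, K_fin + 1), dtype=np.float64)
            logr[:, :K_fin] = 0.0
            for d in range(D):
                logr[:, :K_fin] += Lflat[:, gix[:, d] * D + d]
            logr[:, :K_fin] += np.log(np.maximum(pi, 1e-12))[None, :]
            logr[:, K_fin] = log_outlier + np.log(PI_OUT)
            logr -= logr.max(axis=1, keepdims=True)
            r = np.exp(logr)
            r /= r.sum(axis=1, keepdims=True)
            S = (r[:, :K_fin].T @ Lflat).reshape(K_fin, G, D)
            new_gix = np.argmax(S, axis=1)
            pi = r[:, :K_fin].mean(axis=0)
            pi *= (1 - PI_OUT) / max(pi.sum(), 1e-12)
            if np.array_equal(new_gix, gix):
                break
            gix = new_gix
        # every mutation reports a real cluster; outliers go to their best fit
        return ids, gix, ids[np.argmax(r[:, :K_fin], axis=1)]

    def try_split(labels: np.ndarray) -> tuple[np.ndarray, bool]:
        """Attempt a BIC-justified 2-way split of each cluster.

        The consensus cut can merge adjacent clones whose co-clustering
        hovers near 0.5; a split is kept when the 2-component mixture
        log-likelihood beats the single component by the BIC penalty for
        the extra location vector and weight."""
        ids, gix = centers_of(labels)
        next_id = int(labels.max()) + 1
        changed = False
        for j, c in enumerate(ids):
            mask = labels == c
            n_c = int(mask.sum())
            if n_c < 2 * min_size:
                continue
            Lc = L[mask].astype(np.float64)           # (n_c, G, D)
            single = sum(Lc[:, gix[j, d], d].sum() for d in range(D))
            locs = trace.grid[np.argmax(Lc, axis=1)]  # per-mutation MLEs
            # initialize the two candidate centers at the member CCF
            # quantiles; labeling members by a median cut would be close
            # to random under per-mutation noise and make EM collapse
            step = trace.grid[1] - trace.grid[0]
            g2 = np.stack([
                np.clip((np.percentile(locs, q, axis=0) / step), 0,
                        G - 1).round().astype(int)
                for q in (25, 75)])
            if np.array_equal(g2[0], g2[1]):
                continue
            pi2 = np.array([0.5, 0.5])
            Lcf = Lc.reshape(n_c, G * D)
            for _ in range(30):
                s = np.zeros((n_c, 2))
                for d in range(D):
                    s += Lcf[:, g2[:, d] * D + d]
                logr = s + np.log(np.maximum(pi2, 1e-12))
                mx = logr.max(axis=1, keepdims=True)
                r2 = np.exp(logr - mx)
                tot = r2.sum(axis=1, keepdims=True)
                r2 /= tot
                new_g2 = np.argmax((r2.T @ Lcf).reshape(2, G, D), axis=1)
                pi2 = r2.mean(axis=0)
                if np.array_equal(new_g2, g2):
                    break
                g2 = new_g2
            mix = float((mx[:, 0] + np.log(tot[:, 0])).sum())
            if (mix - single > 0.5 * (D + 1) * np.log(n_c)
                    and min(pi2) * n_c >= min_size
                    and not np.array_equal(g2[0], g2[1])):
                hard = np.argmax(r2, axis=1)
                idx = np.flatnonzero(mask)
                labels = labels.copy()
                labels[idx[hard == 1]] = next_id
                next_id += 1
                changed = True
        return labels, changed

    def drop_unjustified(labels: np.ndarray) -> np.ndarray:
        """Backward elimination of clusters the likelihood does not earn.

        A cluster whose members fit their best alternative cluster almost
        as well (summed advantage below the BIC penalty for one location
        vector and weight) is a boundary artifact of overlapping clones;
        its members are released to the remaining clusters."""
        while True:
            ids, gix = centers_of(labels)
            if ids.size <= 1:
                return labels
            s = np.zeros((n, ids.size), dtype=np.float64)
            for d in range(D):
                s += Lflat[:, gix[:, d] * D + d]
            best = None
            for j, c in enumerate(ids):
                mask = labels == c
                n_c = int(mask.sum())
                others = np.delete(np.arange(ids.size), j)
                adv = (s[mask, j]
                       - s[np.ix_(mask, others)].max(axis=1)).sum()
                thresh = 0.5 * (D + 1) * np.log(max(n_c, 2))
                if adv < thresh and (best is None or adv < best[1]):
                    best = (j, adv)
            if best is None:
                return labels
            j = best[0]
            mask = labels == ids[j]
            others = np.delete(np.arange(ids.size), j)
            labels = labels.copy()
            labels[mask] = ids[others[np.argmax(
                s[np.ix_(mask, others)], axis=1)]]

    labels = merge_coincident(dissolve_small(labels))
    _, _, labels = soft_em(labels)
    labels = merge_coincident(dissolve_small(labels))
    for _ in range(4):
        labels, changed = try_split(labels)
        if not changed:
            break
        _, _, labels = soft_em(labels)
        labels = merge_coincident(dissolve_small(labels))
    labels = drop_unjustified(labels)
    for _ in range(3):
        ids, gix, labels = soft_em(labels)
        ids2, counts2 = np.unique(labels, return_counts=True)
        if counts2.min() >= min_size or ids2.size == 1:
            break
        labels = merge_coincident(dissolve_small(labels))
    occupied = np.isin(ids, np.unique(labels))
    ids, gix = ids[occupied], gix[occupied]
    centers = trace.grid[gix]

    # credible intervals from the trace, conditional on final membership
    loc_samples = np.empty((kept.size, ids.size, D))
    for ti, t in enumerate(kept):
        per_mut = trace.locations[t][trace.assignments[t]]  # (n, D)
        for j, c in enumerate(ids):
            loc_samples[ti, j] = per_mut[labels == c].mean(axis=0)
    lo = np.percentile(loc_samples, 2.5, axis=0)
    hi = np.percentile(loc_samples, 97.5, axis=0)

    order_by_ccf = np.argsort(-centers.sum(axis=1))
    name_map = {int(ids[j]): f"cl{r:02d}"
                for r, j in enumerate(order_by_ccf)}
    names = [name_map[int(ids[j])] for j in order_by_ccf]

    ccf = pd.DataFrame(np.clip(centers[order_by_ccf], 0, CCF_CAP),
                       index=names, columns=data.regions)
    ci_lo = pd.DataFrame(lo[order_by_ccf], index=names, columns=data.regions)
    ci_hi = pd.DataFrame(hi[order_by_ccf], index=names, columns=data.regions)

    inv = np.empty_like(trace.order)
    inv[trace.order] = np.arange(n)
    assignment = {data.keys[i]: name_map[int(labels[inv[i]])]
                  for i in range(n)}
    size = {nm: sum(1 for v in assignment.values() if v == nm) for nm in names}
    return ClusterSolution(assignment=assignment, cluster_ccf=ccf,
                           cluster_size=size, ci_low=ci_lo, ci_high=ci_hi)


def cluster_mutations(data: CCFObservationMatrix,
                      config: Optional[GibbsConfig] = None) -> ClusterSolution:
    """Convenience wrapper: Gibbs sampling plus consensus extraction.

    Below :data:`MIN_MUTATIONS` mutations, falls back (with a warning) to a
    single-cluster maximum-likelihood fit on the CCF grid.
    """
    config = config or GibbsConfig()
    if data.n_mutations < MIN_MUTATIONS:
        warnings.warn("too few mutations for DP clustering; "
                      "fitting a single cluster", stacklevel=2)
        grid = np.round(np.arange(0.0, CCF_CAP + config.ccf_grid_step / 2,
                                  config.ccf_grid_step), 10)
        L = _likelihood_table(data, grid).sum(axis=0)   # (G, D)
        ccf = pd.DataFrame([grid[np.argmax(L, axis=0)]], index=["cl00"],
                           columns=data.regions)
        return ClusterSolution(
            assignment={k: "cl00" for k in data.keys},
            cluster_ccf=ccf,
            cluster_size={"cl00": data.n_mutations},
            ci_low=ccf.copy(), ci_high=ccf.copy(),
            flags={"single_cluster_fallback": True})
    trace = run_dp_gibbs(data, config)
    return consense_clusters(trace, data, config)


def loglik(solution: ClusterSolution, data: CCFObservationMatrix) -> float:
    """Total binomial log-likelihood of the data at the assigned cluster
    CCFs (full logpmf, including binomial coefficients)."""
    total = 0.0
    key_to_row = {k: i for i, k in enumerate(data.keys)}
    for key, cl in solution.assignment.items():
        i = key_to_row[key]
        for j in range(data.n_regions):
            N = data.depth[i, j]
            if N == 0:
                continue
            rho = data.purity[j]
            coef = rho * data.multiplicity[i, j] / (
                rho * data.total_cn[i, j] + (1 - rho) * 2.0)
            f = float(np.clip(
                solution.cluster_ccf.loc[cl, data.regions[j]] * coef,
                1e-9, 1 - 1e-9))
            total += float(sps.binom.logpmf(data.alt[i, j], N, f))
    return total
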