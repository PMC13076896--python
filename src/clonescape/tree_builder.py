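"""Clone-tree reconstruction from clustered cancer cell fractions.

Given per-cluster, per-region CCF estimates, build a rooted forest using the
pigeonhole (sum) rule and the crossing rule:

* a parent must contain each child in every region (nesting within a
  tolerance ``eps``),
* the CCFs of sibling clones may not sum to more than their parent's
  (enforced greedily, re-attaching violators higher up the lineage),
* two clusters whose CCF ordering flips between regions (beyond ``eps``)
  cannot lie on one lineage.

Cases with two or more roots are called multiple-MRCA (independently
initiated lesions); a node with two or more children marks branching
growth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .stats import TestResult, fisher_pitman

__all__ = [
    "CloneTree",
    "TrajectoryCall",
    "identify_clonal_clusters",
    "build_forest",
    "classify_trajectory",
    "subclone_fractions",
    "compare_sv_burden_by_pattern",
]

DEFAULT_EPS = 0.1
DEFAULT_CLONAL_TOL = 0.1


@dataclass
class CloneTree:
    """Rooted forest of mutation clusters.

    ``ccf`` is a cluster x region table; ``branch_length`` counts the SNVs
    and indels assigned to each cluster; ``annotations`` holds drivers, SV
    and CNA labels and signature exposures attached downstream.
    """

    nodes: list[str]
    parent: dict[str, Optional[str]]
    ccf: pd.DataFrame
    branch_length: dict[str, int]
    annotations: dict[str, dict] = field(default_factory=dict)
    flags: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._check_acyclic()
        for n in self.nodes:
            self.annotations.setdefault(
                n, {"drivers": [], "svs": [], "cnas": [], "signatures": {}})

    def _check_acyclic(self) -> None:
        for n in self.nodes:
            seen = {n}
            cur = self.parent.get(n)
            while cur is not None:
                if cur in seen:
                    raise ValueError(f"cyclic parent links at {n}")
                seen.add(cur)
                cur = self.parent.get(cur)

    @property
    def regions(self) -> list[str]:
        return list(self.ccf.columns)

    @property
    def roots(self) -> list[str]:
        return [n for n in self.nodes if self.parent.get(n) is None]

    def children(self, node: str) -> list[str]:
        return [n for n in self.nodes if self.parent.get(n) == node]

    def ancestors(self, node: str) -> list[str]:
        out = []
        cur = self.parent.get(node)
        while cur is not None:
            out.append(cur)
            cur = self.parent.get(cur)
        return out

    def audit_sum_rule(self, eps: float = DEFAULT_EPS) -> list[tuple]:
        """Return (node, region, parent_ccf, child_sum) sum-rule violations."""
        violations = []
        for n in self.nodes:
            ch = self.children(n)
            if not ch:
                continue
            for d in self.regions:
                s = float(sum(self.ccf.loc[c, d] for c in ch))
                p = float(self.ccf.loc[n, d])
                if s > p + eps:
                    violations.append((n, d, p, s))
        return violations

    def to_dict(self) -> dict:
        return {
            "nodes": list(self.nodes),
            "parent": {k: v for k, v in self.parent.items()},
            "regions": self.regions,
            "ccf": {n: [float(self.ccf.loc[n, d]) for d in self.regions]
                    for n in self.nodes},
            "branch_length": {n: int(self.branch_length[n]) for n in self.nodes},
            "annotations": self.annotations,
            "flags": self.flags,
            "oval_fractions": {
                d: subclone_fractions(self, d, strict=False)
                for d in self.regions},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CloneTree":
        ccf = pd.DataFrame(
            {n: d["ccf"][n] for n in d["nodes"]}, index=d["regions"]).T
        return cls(nodes=list(d["nodes"]),
                   parent={k: v for k, v in d["parent"].items()},
                   ccf=ccf,
                   branch_length={k: int(v) for k, v in d["branch_length"].items()},
                   annotations=d.get("annotations", {}),
                   flags=d.get("flags", {}))


@dataclass
class TrajectoryCall:
    patient_id: str
    mrca_pattern: str   # single_mrca | multiple_mrca
    growth_pattern: str  # linear | branching
    n_roots: int
    root_region_support: dict[str, list[str]]


def identify_clonal_clusters(cluster_ccf: pd.DataFrame,
                             clonal_tol: float = DEFAULT_CLONAL_TOL
                             ) -> dict[str, tuple[str, bool]]:
    """Per region, the clonal cluster: maximal CCF among clusters with
    CCF >= 1 - clonal_tol.  If none qualifies the maximal-CCF cluster is
    returned flagged pseudo-clonal (second tuple element True)."""
    out = {}
    for d in cluster_ccf.columns:
        col = cluster_ccf[d]
        qual = col[col >= 1.0 - clonal_tol]
        if len(qual):
            out[d] = (str(qual.idxmax()), False)
        else:
            out[d] = (str(col.idxmax()), True)
    return out


def _nests(ccf: pd.DataFrame, a: str, b: str, eps: float) -> bool:
    """True when cluster ``a`` can contain ``b``: a >= b - eps everywhere."""
    return bool((ccf.loc[a] >= ccf.loc[b] - eps).all())


def _crossing(ccf: pd.DataFrame, a: str, b: str, eps: float) -> bool:
    """CCF ordering flips between regions beyond eps."""
    da = ccf.loc[a] - ccf.loc[b]
    return bool((da > eps).any() and (da < -eps).any())


def build_forest(cluster_ccf: pd.DataFrame,
                 cluster_size: dict[str, int],
                 eps: float = DEFAULT_EPS) -> CloneTree:
    """Reconstruct the clone forest from a cluster x region CCF table.

    Clusters are processed in decreasing total-CCF order.  The candidate
    parent of B is the smallest-CCF already-placed cluster that nests B
    (ties broken toward the smaller total CCF, i.e. the most recent
    ancestor).  When attaching B under P would break the sum rule, B is
    re-attached to the nearest ancestor of P that restores it.  Clusters
    nested by nobody become roots; a cluster with no consistent placement is
    attached to its component root and flagged, never dropped.
    """
    nodes = [str(n) for n in cluster_ccf.index]
    ccf = cluster_ccf.copy()
    ccf.index = nodes
    totals = ccf.sum(axis=1)
    order = sorted(nodes, key=lambda n: (-totals[n], n))

    parent: dict[str, Optional[str]] = {}
    children: dict[str, list[str]] = {n: [] for n in nodes}
    flags: dict[str, list[str]] = {}

    def sum_ok(p: str, extra: str) -> bool:
        ch = children[p] + [extra]
        return bool((ccf.loc[ch].sum(axis=0) <= ccf.loc[p] + eps).all())

    for b in order:
        placed = [n for n in parent]  # all have total CCF >= b's
        cands = [a for a in placed
                 if _nests(ccf, a, b, eps) and not _crossing(ccf, a, b, eps)]
        if not cands:
            parent[b] = None
            continue
        cands.sort(key=lambda a: (totals[a], a))
        p = cands[0]
        if not sum_ok(p, b):
            # climb toward the root until the pigeonhole constraint holds
            alt = parent.get(p)
            while alt is not None and not sum_ok(alt, b):
                alt = parent.get(alt)
            if alt is None:
                root = p
                while parent.get(root) is not None:
                    root = parent[root]
                flags.setdefault(b, []).append("no_consistent_placement")
                p = root
            else:
                p = alt
        parent[b] = p
        children[p].append(b)

    return CloneTree(nodes=nodes, parent=parent, ccf=ccf,
                     branch_length={n: int(cluster_size.get(n, 0)) for n in nodes},
                     flags=flags)


def classify_trajectory(tree: CloneTree, patient_id: str = "",
                        support_min: float = DEFAULT_EPS) -> TrajectoryCall:
    roots = tree.roots
    branching = any(len(tree.children(n)) >= 2 for n in tree.nodes)
    support = {
        r: [d for d in tree.regions if tree.ccf.loc[r, d] > support_min]
        for r in roots}
    return TrajectoryCall(
        patient_id=patient_id,
        mrca_pattern="multiple_mrca" if len(roots) >= 2 else "single_mrca",
        growth_pattern="branching" if branching else "linear",
        n_roots=len(roots),
        root_region_support=support,
    )


def subclone_fractions(tree: CloneTree, region: str,
                       eps: float = DEFAULT_EPS,
                       strict: bool = True) -> dict[str, float]:
    """Exclusive cell fraction of each clone in one region (oval plot).

    fraction(node) = CCF(node) - sum of children CCFs; small negatives
    (within eps) are clipped to zero, larger ones are a sum-rule violation.
    """
    out = {}
    for n in tree.nodes:
        ch_sum = float(sum(tree.ccf.loc[c, region] for c in tree.children(n)))
        frac = float(tree.ccf.loc[n, region]) - ch_sum
        if frac < -eps:
            if strict:
                raise ValueError(
                    f"sum-rule violation at {n} in {region}: {frac:.3f}")
            frac = 0.0
        out[n] = max(frac, 0.0)
    return out


def compare_sv_burden_by_pattern(
    trajectories: dict[str, TrajectoryCall],
    sv_counts: dict[str, dict[str, int]],
    seed: Optional[int] = None,
) -> tuple[float, float, TestResult]:
    """Compare per-region SV counts between branching and linear cases.

    Returns (branching mean, linear mean, Fisher-Pitman two-sided result).
    Region counts are pooled by the growth pattern of their case.
    """
    groups: dict[str, list[float]] = {"branching": [], "linear": []}
    for pid, tc in trajectories.items():
        counts = sv_counts.get(pid, {})
        groups[tc.growth_pattern].extend(float(v) for v in counts.values())
    if not groups["branching"] or not groups["linear"]:
        raise ValueError("need at least one case of each growth pattern")
    res = fisher_pitman(groups["branching"], groups["linear"], seed=seed)
    return (float(np.mean(groups["branching"])),
            float(np.mean(groups["linear"])), res)


def annotate_drivers(tree: CloneTree, calls, assignment: dict[str, str]) -> None:
    """Attach driver SNV/indel gene names to their clusters."""
    for c in calls:
        if c.is_driver and c.key in assignment:
            node = assignment[c.key]
            if node in tree.annotations:
                label = c.gene or c.key
                tree.annotations[node]["drivers"].append(label)


def annotate_svs_by_support(tree: CloneTree, svs_by_region: dict[str, list],
                            support_min: float = DEFAULT_EPS) -> None:
    """Attach SVs to clusters by region-presence pattern.

    SVs are not clustered; each region's SV count is attached to the cluster
    whose region support (CCF above threshold) best matches a presence
    pattern concentrated in that region, preferring the most specific
    (smallest-support) cluster.
    """
    for rid, svs in svs_by_region.items():
        if not svs:
            continue
        present = [n for n in tree.nodes
                   if tree.ccf.loc[n, rid] > support_min]
        if not present:
            continue
        # most specific cluster present in this region
        best = min(present, key=lambda n: (
            sum(tree.ccf.loc[n, d] > support_min for d in tree.regions),
            -tree.ccf.loc[n, rid]))
        labels = [f"{rid}:{s.sv_class}" for s in svs]
        tree.annotations[best]["svs"].extend(labels)
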