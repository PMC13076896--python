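"""Synthetic multi-region tumor cohorts with full ground truth.

The generator emulates a surgical cohort of cystic pancreatic precursor
lesions with associated invasive cancer: ~12 patients, 2-6 sampled regions
per lesion, tumor whole-genome coverage around 80X, variable purity, clone
trees of three archetypes (single-MRCA linear, single-MRCA branching, and
multiple independent MRCAs), branch-specific mutational-signature
exposures, archetype-dependent structural-variant burdens and bulk
expression with squamous/classical and stromal/immune structure.

Every emitted file passes the :mod:`clonescape.io_formats` readers, and a
truth JSON records the clone tree, per-mutation clone assignment,
multiplicity, copy state and signature channel, so each downstream stage
can be tested by parameter recovery.

Clone CCFs are drawn so that the planted tree is identifiable from
noiseless CCFs: sibling clones cross (each beats the other by at least the
configured separation in some region), every parent exceeds its child
somewhere by the same margin, and no clone is nested (within margin) under
a cluster outside its own ancestry.  Subclonal mutations carry
multiplicity 1 (they postdate the clonal copy-number changes simulated
here); trunk mutations draw multiplicity uniformly from {1..major}.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import io_formats as iof
from .variant_features import MutationCall, expected_vaf
from .signature_engine import decode_sbs96, ID83_LABELS

__all__ = [
    "CohortConfig",
    "CloneTreeSpec",
    "simulate_clone_tree",
    "simulate_signature_contexts",
    "simulate_reads",
    "simulate_patient",
    "simulate_expression",
    "simulate_cohort",
    "make_reference_profiles",
    "default_gene_sets",
]

ARCHETYPES = ("single_mrca_linear", "single_mrca_branching", "multi_mrca")


@dataclass
class CohortConfig:
    """Study-condition defaults for the synthetic cohort."""

    n_patients: int = 12
    region_range: tuple[int, int] = (2, 6)
    mean_depth: float = 80.0
    purity_range: tuple[float, float] = (0.3, 0.9)
    min_separation: float = 0.08
    min_detectable_ccf: float = 0.25
    trunk_mutations: tuple[int, int] = (450, 650)
    subclone_mutations: tuple[int, int] = (200, 400)
    indel_fraction: float = 0.07
    copy_profile: dict = field(default_factory=lambda: {
        (1, 1): 0.80, (2, 1): 0.10, (2, 0): 0.05, (2, 2): 0.05})
    sv_rate_branching: float = 85.0
    sv_rate_linear: float = 30.0
    pdac_mutation_boost: float = 2.5
    archetype_counts: dict = field(default_factory=lambda: {
        "single_mrca_linear": 4, "single_mrca_branching": 5, "multi_mrca": 3})
    clones_range: tuple[int, int] = (3, 5)
    expression_noise_sd: float = 0.2


@dataclass
class CloneTreeSpec:
    """Ground-truth clone tree for one simulated patient."""

    patient_id: str
    archetype: str
    nodes: list[str]
    parent: dict[str, Optional[str]]
    regions: list[str]
    ccf: pd.DataFrame                     # nodes x regions
    mutations_per_clone: dict[str, int]
    exposures_sbs: pd.DataFrame           # nodes x signatures, rows sum to 1
    exposures_id: pd.DataFrame
    sv_count: dict[str, int]              # per region
    histology: dict[str, str]             # per region

    @property
    def roots(self) -> list[str]:
        return [n for n in self.nodes if self.parent[n] is None]

    def children(self, node: str) -> list[str]:
        return [n for n in self.nodes if self.parent[n] == node]

    def ancestors(self, node: str) -> list[str]:
        out, cur = [], self.parent[node]
        while cur is not None:
            out.append(cur)
            cur = self.parent[cur]
        return out

    def growth_pattern(self) -> str:
        return ("branching" if any(len(self.children(n)) >= 2
                                   for n in self.nodes) else "linear")

    def validate(self, min_sep: float = 0.0) -> None:
        for n in self.nodes:
            ch = self.children(n)
            if ch:
                s = self.ccf.loc[ch].sum(axis=0)
                if (s > self.ccf.loc[n] + 1e-9).any():
                    raise ValueError(f"sum rule violated at {n}")
        if self.archetype == "single_mrca_linear":
            if any(len(self.children(n)) > 1 for n in self.nodes):
                raise ValueError("linear archetype has a branching node")
            if len(self.roots) != 1:
                raise ValueError("linear archetype must have one root")
        elif self.archetype == "single_mrca_branching":
            if len(self.roots) != 1 or self.growth_pattern() != "branching":
                raise ValueError("branching archetype not realized")
        elif self.archetype == "multi_mrca":
            if len(self.roots) < 2:
                raise ValueError("multi_mrca archetype needs >=2 roots")
        for _, row in self.exposures_sbs.iterrows():
            if abs(row.sum() - 1.0) > 1e-6 or (row < -1e-12).any():
                raise ValueError("invalid exposure vector")


# ---------------------------------------------------------------------------
# Clone-tree simulation
# ---------------------------------------------------------------------------

def _resolvable(delta_ccf: np.ndarray, mean_ccf: np.ndarray,
                rho: np.ndarray, depth: float, z: float) -> bool:
    """Is a CCF difference detectable in at least one region?

    Projects the CCF gap onto the expected-VAF scale (diploid heterozygous
    approximation, f = ccf * rho / 2) and requires it to exceed ``z``
    binomial standard errors at the study depth somewhere."""
    f_gap = np.maximum(delta_ccf, 0.0) * rho / 2.0
    f_mid = np.clip(mean_ccf * rho / 2.0, 1e-4, 0.5)
    se = np.sqrt(f_mid * (1.0 - f_mid) / depth)
    return bool((f_gap >= z * se).any())


def _identifiable(ccf: pd.DataFrame, parent: dict, min_sep: float,
                  min_det: float, rho: Optional[np.ndarray] = None,
                  depth: float = 80.0, z: float = 2.2) -> bool:
    """CCF configurations under which the planted tree is recoverable.

    Geometric margins (CCF units) guarantee the noiseless reconstruction is
    unique; when per-region purities are supplied, every informative gap
    must additionally be resolvable at the sequencing depth (see
    :func:`_resolvable`), the practical identifiability limit the sibling
    separation floor stands for.
    """
    nodes = list(ccf.index)
    anc = {n: set() for n in nodes}
    for n in nodes:
        cur = parent[n]
        while cur is not None:
            anc[n].add(cur)
            cur = parent[cur]

    def separable(hi: pd.Series, lo: pd.Series) -> bool:
        gap = (hi - lo).values
        if gap.max() < min_sep:
            return False
        if rho is None:
            return True
        return _resolvable(gap, (hi.values + lo.values) / 2.0, rho, depth, z)

    for b in nodes:
        if ccf.loc[b].max() < min_det:
            return False
        p = parent[b]
        if p is not None and not separable(ccf.loc[p], ccf.loc[b]):
            return False
        for u in nodes:
            if u == b or u in anc[b]:
                continue
            # b must escape nesting under u: exceed it somewhere by margin
            if not separable(ccf.loc[b], ccf.loc[u]):
                return False
    # sibling crossing (both directions) is implied pairwise by the loop
    return True


def _topology(archetype: str, n_clones: int, rng) -> dict[str, Optional[str]]:
    nodes = [f"T{i}" for i in range(n_clones)]
    parent: dict[str, Optional[str]] = {nodes[0]: None}
    if archetype == "single_mrca_linear":
        for a, b in zip(nodes, nodes[1:]):
            parent[b] = a
    elif archetype == "single_mrca_branching":
        if n_clones < 3:
            raise ValueError("branching archetype needs >=3 clones")
        parent[nodes[1]] = nodes[0]
        parent[nodes[2]] = nodes[0]
        for n in nodes[3:]:
            parent[n] = nodes[rng.integers(0, nodes.index(n))]
    elif archetype == "multi_mrca":
        if n_clones < 2:
            raise ValueError("multi_mrca needs >=2 clones")
        parent[nodes[1]] = None
        tips = {nodes[0]: nodes[0], nodes[1]: nodes[1]}  # root -> chain tip
        roots = [nodes[0], nodes[1]]
        for i, n in enumerate(nodes[2:]):
            r = roots[i % 2]          # alternate chains under the two roots
            parent[n] = tips[r]
            tips[r] = n
    else:
        raise ValueError(f"unknown archetype {archetype!r}")
    return parent


def _assign_ccfs(parent: dict, regions: list[str], archetype: str,
                 rng) -> pd.DataFrame:
    nodes = list(parent)
    ccf = pd.DataFrame(0.0, index=nodes, columns=regions)
    roots = [n for n in nodes if parent[n] is None]
    if archetype == "multi_mrca":
        # disjoint region support per independent origin
        order = list(rng.permutation(regions))
        half = max(1, len(regions) // 2)
        support = {roots[0]: order[:half], roots[1]: order[half:]}
        for r in roots:
            for d in support[r]:
                ccf.loc[r, d] = rng.uniform(0.85, 1.0)
    else:
        ccf.loc[roots[0]] = 1.0

    children = {n: [c for c in nodes if parent[c] == n] for n in nodes}
    # breadth-first assignment
    queue = list(roots)
    while queue:
        p = queue.pop(0)
        ch = children[p]
        if not ch:
            continue
        support = [d for d in regions if ccf.loc[p, d] >= 0.4]
        if len(support) == 0:
            support = [ccf.loc[p].idxmax()]
        homes = list(rng.permutation(support))
        for i, c in enumerate(ch):
            home = homes[i % len(homes)]
            for d in regions:
                pv = ccf.loc[p, d]
                if pv <= 0:
                    continue
                if len(ch) == 1:
                    # chains keep most of the parent so deep clones stay
                    # detectable; rejection below enforces the CCF gap
                    frac = rng.uniform(0.50, 0.85)
                elif d == home:
                    frac = rng.uniform(0.50, 0.75)
                else:
                    # sibling subclones are often confined to the regions
                    # they were sampled from
                    frac = 0.0 if rng.random() < 0.6 else rng.uniform(0.0,
                                                                      0.12)
                ccf.loc[c, d] = pv * frac
        # rescale if children overshoot the parent anywhere
        for d in regions:
            s = sum(ccf.loc[c, d] for c in ch)
            pv = ccf.loc[p, d]
            if s > 0.95 * pv:
                for c in ch:
                    ccf.loc[c, d] *= 0.95 * pv / s if pv > 0 else 0.0
        queue.extend(ch)
    return ccf.round(4)


def simulate_clone_tree(archetype: str, n_clones: int, n_regions: int,
                        seed=None, min_sep: float = 0.08,
                        min_det: float = 0.25, max_tries: int = 3000,
                        patient_id: str = "P00",
                        config: Optional[CohortConfig] = None,
                        purity: Optional[dict[str, float]] = None,
                        depth: float = 80.0) -> CloneTreeSpec:
    """Sample an identifiable clone-tree spec of the requested archetype.

    When per-region purities are given, clone separations must also be
    resolvable on the VAF scale at the study depth; a lesion whose clones
    cannot be resolved at the given purities raises RuntimeError (callers
    typically redraw the purities, the analogue of excluding low-purity
    samples from clonal analyses).
    """
    if n_regions < 2:
        raise ValueError("need >=2 regions for multi-region analysis")
    if n_clones < 1:
        raise ValueError("need >=1 clone")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    config = config or CohortConfig()
    regions = [f"R{i + 1}" for i in range(n_regions)]
    rho = (np.array([purity[r] for r in regions], dtype=float)
           if purity is not None else None)
    for _ in range(max_tries):
        parent = _topology(archetype, n_clones, rng)
        ccf = _assign_ccfs(parent, regions, archetype, rng)
        if _identifiable(ccf, parent, min_sep, min_det, rho, depth):
            break
    else:
        raise RuntimeError(
            f"could not draw an identifiable {archetype} tree "
            f"({n_clones} clones, {n_regions} regions)")

    nodes = list(parent)
    roots = [n for n in nodes if parent[n] is None]
    muts = {}
    for n in nodes:
        lo, hi = (config.trunk_mutations if n in roots
                  else config.subclone_mutations)
        muts[n] = int(rng.integers(lo, hi + 1))

    # the invasive region is the one hosting the most exclusive expanded
    # subclone; that subclone carries extra private mutations, so
    # invasive-labeled regions show a higher burden than precursor regions
    non_roots = [n for n in nodes if n not in roots]
    pdac_region = regions[-1]
    if non_roots:
        best_pair, best_excess = None, 0.0
        for d in regions:
            for n1 in non_roots:
                excess = float(ccf.loc[n1, d] - ccf.loc[n1].drop(d).max())
                if excess > best_excess:
                    best_pair, best_excess = (n1, d), excess
        if best_pair is not None and best_excess > 0.1:
            muts[best_pair[0]] = int(muts[best_pair[0]]
                                     * config.pdac_mutation_boost)
            pdac_region = best_pair[1]
    histology = _assign_histology(regions, pdac_region)

    expo_sbs = _draw_exposures_sbs(nodes, roots, rng)
    expo_id = _draw_exposures_id(nodes, roots, rng)
    growth = ("branching" if any(
        sum(1 for c in nodes if parent[c] == n) >= 2 for n in nodes)
        else "linear")
    rate = (config.sv_rate_branching if growth == "branching"
            else config.sv_rate_linear)
    sv_count = {d: int(rng.poisson(rate)) for d in regions}

    spec = CloneTreeSpec(
        patient_id=patient_id, archetype=archetype, nodes=nodes,
        parent=parent, regions=regions, ccf=ccf,
        mutations_per_clone=muts, exposures_sbs=expo_sbs,
        exposures_id=expo_id, sv_count=sv_count, histology=histology)
    spec.validate()
    return spec


def _assign_histology(regions: list[str],
                      pdac_region: Optional[str] = None) -> dict[str, str]:
    pdac_region = pdac_region or regions[-1]
    labels = {}
    first_non_pdac = next(d for d in regions
                          if d != pdac_region or len(regions) == 1)
    for d in regions:
        if d == pdac_region:
            labels[d] = "PDAC"
        elif d == first_non_pdac:
            labels[d] = "LGD"
        else:
            labels[d] = "HGD"
    return labels


_SBS_SIGS = ["SBS1", "SBS2", "SBS5", "SBS13", "SBS28", "SBS40"]
_ID_SIGS = ["ID1", "ID2", "ID5", "ID6", "ID8", "ID9", "ID14"]


def _draw_exposures_sbs(nodes, roots, rng) -> pd.DataFrame:
    expo = pd.DataFrame(0.0, index=nodes, columns=_SBS_SIGS)
    for n in nodes:
        clock = rng.dirichlet([5.0, 4.0, 2.0])   # SBS1 / SBS5 / SBS40
        row = pd.Series(0.0, index=_SBS_SIGS)
        row[["SBS1", "SBS5", "SBS40"]] = clock
        if n not in roots and rng.random() < 0.25:
            apobec = rng.uniform(0.35, 0.6)
            row *= (1 - apobec)
            row["SBS2"] = apobec * 0.5
            row["SBS13"] = apobec * 0.5
        expo.loc[n] = row
    return expo


def _draw_exposures_id(nodes, roots, rng) -> pd.DataFrame:
    expo = pd.DataFrame(0.0, index=nodes, columns=_ID_SIGS)
    for n in nodes:
        row = pd.Series(0.0, index=_ID_SIGS)
        if n in roots:   # early clones: mismatch-repair-like indel activity
            row[["ID1", "ID2", "ID5"]] = rng.dirichlet([4.0, 3.0, 2.0])
        else:
            row[["ID9", "ID14", "ID8"]] = rng.dirichlet([3.0, 2.0, 2.0])
        expo.loc[n] = row
    return expo


# ---------------------------------------------------------------------------
# Signature contexts
# ---------------------------------------------------------------------------

def simulate_signature_contexts(spec: CloneTreeSpec, catalog: pd.DataFrame,
                                counts: dict[str, int], seed=None
                                ) -> dict[str, np.ndarray]:
    """Draw channel indices per clone from its exposure-mixed catalog."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    sigs = [s for s in catalog.columns if s in spec.exposures_sbs.columns]
    out = {}
    for n in spec.nodes:
        k = counts.get(n, 0)
        if k == 0:
            out[n] = np.array([], dtype=int)
            continue
        expo = spec.exposures_sbs.loc[n, sigs].values
        if expo.sum() <= 0:
            raise ValueError(f"clone {n}: exposure/catalog mismatch")
        p = catalog[sigs].values @ (expo / expo.sum())
        out[n] = rng.choice(catalog.shape[0], size=k, p=p / p.sum())
    return out


def _id83_example(channel: int, rng) -> tuple[str, str, str, str]:
    """(ref, alt, left_flank, right_flank) realizing an ID83 channel."""
    label = ID83_LABELS[channel]
    kind, unit_kind, ln_s, cls_s = label.split(":")
    anchor = "G"
    filler = "GGGGG"   # G never occurs in simulated indel units (A/C/T)
    if unit_kind in "CT":       # 1bp
        b = unit_kind
        if kind == "DEL":
            hp = 6 if cls_s == "6+" else int(cls_s)
            left, right = filler, b * (hp - 1) + filler
            return anchor + b, anchor, anchor, right
        run = 5 if cls_s == "5+" else int(cls_s)
        return anchor, anchor + b, anchor, b * run + filler
    ln = 5 if ln_s == "5+" else int(ln_s)
    unit = ("ACT" * ln)[:ln]
    if unit_kind == "R":
        if kind == "DEL":
            copies = 6 if cls_s == "6+" else int(cls_s)
            right = unit * (copies - 1) + filler
        else:
            copies = 5 if cls_s == "5+" else int(cls_s)
            right = unit * copies + filler
        if kind == "DEL":
            return anchor + unit, anchor, filler, right
        return anchor, anchor + unit, filler, right
    # microhomology deletion (microhomology must be shorter than the unit)
    mh = 5 if cls_s == "5+" else int(cls_s)
    if mh >= ln:
        ln = mh + 1
        unit = ("ACT" * ln)[:ln]
    right = unit[:mh] + filler
    return anchor + unit, anchor, filler, right


def _mutation_loci(n: int, segments: list[iof.SegmentRecord], rng
                   ) -> list[tuple[str, int, tuple[int, int]]]:
    lengths = np.array([s.length for s in segments], dtype=float)
    probs = lengths / lengths.sum()
    seen = set()
    out = []
    while len(out) < n:
        s = segments[rng.choice(len(segments), p=probs)]
        pos = int(rng.integers(s.start, s.end + 1))
        if (s.chrom, pos) in seen:
            continue
        seen.add((s.chrom, pos))
        out.append((s.chrom, pos, (s.major, s.minor)))
    return out


def _simulate_segments(copy_profile: dict, rng) -> list[iof.SegmentRecord]:
    """Clonal allele-specific segments over a simplified 22-chromosome genome."""
    states = list(copy_profile)
    probs = np.array([copy_profile[s] for s in states], dtype=float)
    probs /= probs.sum()
    segs = []
    for ci in range(1, 23):
        chrom = f"chr{ci}"
        n_seg = int(rng.integers(1, 4))
        bounds = np.sort(rng.choice(
            np.arange(10_000_000, 110_000_000, 1_000_000), size=n_seg - 1,
            replace=False)) if n_seg > 1 else np.array([], dtype=int)
        starts = [1] + [int(b) + 1 for b in bounds]
        ends = [int(b) for b in bounds] + [120_000_000]
        for s, e in zip(starts, ends):
            maj, mino = states[rng.choice(len(states), p=probs)]
            segs.append(iof.SegmentRecord(chrom, s, e, maj, mino))
    return segs


def simulate_reads(spec: CloneTreeSpec, purity_per_region: dict[str, float],
                   mean_depth: float, sbs_catalog: pd.DataFrame,
                   id_catalog: pd.DataFrame,
                   copy_profile: Optional[dict] = None, seed=None,
                   indel_fraction: float = 0.07):
    """Generate per-region read counts, segments, SVs and the truth set.

    Returns ``(calls, segments, svs_by_region, truth)``: multi-region
    MutationCall records (with copy states and contexts attached), clonal
    segment list, per-region SV records, and the truth dictionary.
    """
    for rid, rho in purity_per_region.items():
        if not (0 < rho <= 1):
            raise ValueError(f"purity {rho} for {rid} outside (0, 1]")
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    copy_profile = copy_profile or CohortConfig().copy_profile
    segments = _simulate_segments(copy_profile, rng)
    roots = spec.roots

    n_ind = {n: rng.binomial(spec.mutations_per_clone[n], indel_fraction)
             for n in spec.nodes}
    n_snv = {n: spec.mutations_per_clone[n] - n_ind[n] for n in spec.nodes}
    snv_channels = simulate_signature_contexts(spec, sbs_catalog, n_snv, rng)

    calls: list[MutationCall] = []
    truth_muts = {}
    id_sigs = [s for s in id_catalog.columns if s in spec.exposures_id.columns]
    for n in spec.nodes:
        total = spec.mutations_per_clone[n]
        loci = _mutation_loci(total, segments, rng)
        # indel channels from the clone's indel-signature mixture
        expo = spec.exposures_id.loc[n, id_sigs].values
        p_id = id_catalog[id_sigs].values @ (expo / expo.sum())
        id_channels = rng.choice(id_catalog.shape[0], size=n_ind[n],
                                 p=p_id / p_id.sum())
        for j, (chrom, pos, (major, minor)) in enumerate(loci):
            is_indel = j >= n_snv[n]
            if is_indel:
                ch = int(id_channels[j - n_snv[n]])
                ref, alt, left, right = _id83_example(ch, rng)
                context = f"{left}|{right}"
                kind = "id"
            else:
                ch = int(snv_channels[n][j])
                ref, alt, context = decode_sbs96(ch)
                kind = "sbs"
            m = int(rng.integers(1, major + 1)) if n in roots else 1
            call = MutationCall(chrom=chrom, pos=pos, ref=ref, alt=alt,
                                context=context)
            for rid in spec.regions:
                rho = purity_per_region[rid]
                depth = int(rng.poisson(mean_depth))
                f = expected_vaf(float(spec.ccf.loc[n, rid]), rho, m,
                                 major + minor)
                altc = int(rng.binomial(depth, min(max(f, 0.0), 1.0)))
                call.depth[rid] = depth
                call.alt_count[rid] = altc
                call.copy_state[rid] = (major, minor)
            calls.append(call)
            truth_muts[call.key] = {
                "clone": n, "multiplicity": m, "copy_state": [major, minor],
                "channel_kind": kind, "channel": ch,
            }

    svs_by_region = {
        rid: _simulate_svs(spec.sv_count[rid], rng, rid)
        for rid in spec.regions}
    truth = {
        "patient_id": spec.patient_id,
        "archetype": spec.archetype,
        "growth_pattern": spec.growth_pattern(),
        "nodes": spec.nodes,
        "parent": spec.parent,
        "regions": spec.regions,
        "ccf": {n: [float(spec.ccf.loc[n, d]) for d in spec.regions]
                for n in spec.nodes},
        "mutations_per_clone": spec.mutations_per_clone,
        "purity": purity_per_region,
        "mean_depth": mean_depth,
        "histology": spec.histology,
        "sv_count": spec.sv_count,
        "exposures_sbs": {n: spec.exposures_sbs.loc[n].to_dict()
                          for n in spec.nodes},
        "mutations": truth_muts,
    }
    return calls, segments, svs_by_region, truth


def _simulate_svs(count: int, rng, region_id: str) -> list[iof.SVRecord]:
    out = []
    intra_strands = {"deletion": ("+", "-"), "tandem_duplication": ("-", "+"),
                     "inversion": ("+", "+")}
    classes = list(intra_strands)
    for _ in range(count):
        if rng.random() < 0.85:
            cls = classes[rng.integers(0, 3)]
            s1, s2 = intra_strands[cls]
            chrom = f"chr{rng.integers(1, 23)}"
            p1 = int(rng.integers(1_000_000, 100_000_000))
            p2 = p1 + int(rng.integers(10_000, 5_000_000))
            out.append(iof.SVRecord(chrom, p1, s1, chrom, p2, s2, cls,
                                    region_id))
        else:
            c1 = f"chr{rng.integers(1, 23)}"
            c2 = f"chr{rng.integers(1, 23)}"
            while c2 == c1:
                c2 = f"chr{rng.integers(1, 23)}"
            out.append(iof.SVRecord(
                c1, int(rng.integers(1_000_000, 100_000_000)), "+",
                c2, int(rng.integers(1_000_000, 100_000_000)), "-",
                "translocation", region_id))
    return out


# ---------------------------------------------------------------------------
# Patient / cohort emission
# ---------------------------------------------------------------------------

def draw_resolvable_lesion(archetype: str, n_clones: int, n_regions: int,
                           rng, config: CohortConfig,
                           patient_id: str = "P00"
                           ) -> tuple[CloneTreeSpec, dict[str, float]]:
    """Draw per-region purities and a clone tree resolvable under them.

    Purities come first; if no identifiable tree exists at those purities
    (every clone gap buried in binomial noise at the study depth), the
    purities are redrawn — the cohort emulates lesions that pass the usual
    purity screen for clonal deconvolution.
    """
    floor = {"single_mrca_branching": 3}.get(archetype, 2)
    last_err = None
    for k in range(n_clones, floor - 1, -1):
        for _ in range(15):
            purity = {f"R{i + 1}": float(rng.uniform(*config.purity_range))
                      for i in range(n_regions)}
            try:
                spec = simulate_clone_tree(
                    archetype, k, n_regions, rng,
                    min_sep=config.min_separation,
                    min_det=config.min_detectable_ccf,
                    patient_id=patient_id, config=config, purity=purity,
                    depth=config.mean_depth)
                return spec, purity
            except RuntimeError as err:
                last_err = err
        # a lesion only presents as many clones as the data can resolve
    raise RuntimeError(f"no resolvable lesion found: {last_err}")


def simulate_patient(patient_id: str, archetype: str, out_dir: str,
                     seed=None, n_regions: Optional[int] = None,
                     config: Optional[CohortConfig] = None,
                     sbs_catalog: Optional[pd.DataFrame] = None,
                     id_catalog: Optional[pd.DataFrame] = None):
    """Simulate one patient and write the full per-region file layout.

    Returns (manifest, spec, truth).  Paths in the manifest are relative to
    ``out_dir``.
    """
    from .signature_engine import load_catalog

    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    config = config or CohortConfig()
    sbs_catalog = sbs_catalog if sbs_catalog is not None else load_catalog("sbs")
    id_catalog = id_catalog if id_catalog is not None else load_catalog("id")
    if n_regions is None:
        n_regions = int(rng.integers(config.region_range[0],
                                     config.region_range[1] + 1))
    n_clones = int(rng.integers(config.clones_range[0],
                                config.clones_range[1] + 1))
    if archetype == "single_mrca_branching":
        n_clones = max(n_clones, 3)
    spec, purity = draw_resolvable_lesion(
        archetype, n_clones, n_regions, rng, config, patient_id)
    calls, segments, svs, truth = simulate_reads(
        spec, purity, config.mean_depth, sbs_catalog, id_catalog,
        config.copy_profile, rng, config.indel_fraction)

    pdir = os.path.join(out_dir, patient_id)
    os.makedirs(pdir, exist_ok=True)
    regions = []
    for rid in spec.regions:
        rel = os.path.join(patient_id, f"{rid}")
        iof.write_vcf(os.path.join(pdir, f"{rid}.vcf"), calls, rid)
        iof.write_segments(os.path.join(pdir, f"{rid}.segments.tsv"), segments)
        iof.write_bedpe(os.path.join(pdir, f"{rid}.bedpe"), svs[rid])
        regions.append(iof.RegionFiles(
            region_id=rid, vcf=rel + ".vcf",
            segments=rel + ".segments.tsv",
            purity=os.path.join(patient_id, "purity.tsv"),
            bedpe=rel + ".bedpe", histology=spec.histology[rid]))
    iof.write_purity(os.path.join(pdir, "purity.tsv"), purity)
    with open(os.path.join(pdir, "truth.json"), "w") as fh:
        json.dump(truth, fh, indent=1)
    manifest = iof.CohortManifest(patient_id=patient_id, regions=regions)
    return manifest, spec, truth


def simulate_cohort(out_dir: str, seed: int = 0,
                    config: Optional[CohortConfig] = None,
                    with_expression: bool = True):
    """Simulate the default cohort and write a cohort manifest.

    Archetypes follow ``config.archetype_counts``; the per-patient random
    streams are spawned deterministically from the single cohort seed.
    """
    from .signature_engine import load_catalog

    config = config or CohortConfig()
    os.makedirs(out_dir, exist_ok=True)
    sbs_catalog = load_catalog("sbs")
    id_catalog = load_catalog("id")
    # round-robin over archetypes so cohorts of any size span the patterns
    pool = dict(config.archetype_counts)
    archetypes: list[str] = []
    while len(archetypes) < config.n_patients:
        progressed = False
        for a in pool:
            if pool[a] > 0 and len(archetypes) < config.n_patients:
                archetypes.append(a)
                pool[a] -= 1
                progressed = True
        if not progressed:
            pool = dict(config.archetype_counts)
    streams = np.random.SeedSequence(seed).spawn(config.n_patients + 1)
    manifests, specs, truths = [], [], []
    for i, arch in enumerate(archetypes):
        pid = f"P{i + 1:02d}"
        m, s, t = simulate_patient(
            pid, arch, out_dir, np.random.default_rng(streams[i]),
            config=config, sbs_catalog=sbs_catalog, id_catalog=id_catalog)
        manifests.append(m)
        specs.append(s)
        truths.append(t)
    if with_expression:
        expr, etruth = simulate_cohort_expression(
            specs, noise_sd=config.expression_noise_sd,
            seed=np.random.default_rng(streams[-1]))
        iof.write_expression(os.path.join(out_dir, "expression.tsv"), expr)
        with open(os.path.join(out_dir, "expression_truth.json"), "w") as fh:
            json.dump(etruth, fh, indent=1)
        sets = default_gene_sets()
        iof.write_gene_sets(os.path.join(out_dir, "gene_sets.gmt"), sets)
        for man in manifests:
            man.expression_path = "expression.tsv"
    iof.save_manifest(os.path.join(out_dir, "cohort.yaml"), manifests)
    return manifests, specs, truths


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

CELL_TYPES = ["epithelial", "CAF", "CD4T", "CD8T", "Bcell", "macrophage"]


def default_gene_sets(n_fill: int = 12) -> dict[str, list[str]]:
    """Small illustrative marker sets (user-supplied sets are expected for
    real analyses)."""
    sq = ["TP63", "KRT6A", "S100A2"] + [f"SQG{i:03d}" for i in range(n_fill)]
    cl = ["GATA6", "HNF4A"] + [f"CLG{i:03d}" for i in range(n_fill)]
    st = ["COL1A1", "FAP", "ACTA2"] + [f"STG{i:03d}" for i in range(n_fill)]
    im = ["PTPRC", "CD8A", "CD4"] + [f"IMG{i:03d}" for i in range(n_fill)]
    return {"squamous": sq, "classical": cl, "stromal": st, "immune": im}


def _gene_universe(sets: dict[str, list[str]], n_background: int = 400
                   ) -> list[str]:
    genes: list[str] = []
    for s in sets.values():
        genes.extend(s)
    genes.extend(f"BG{i:04d}" for i in range(n_background))
    return list(dict.fromkeys(genes))


def make_reference_profiles(genes: list[str],
                            sets: Optional[dict[str, list[str]]] = None,
                            seed=None) -> pd.DataFrame:
    """Synthetic cell-type reference expression (genes x cell types, TPM
    scale); stromal markers load on fibroblasts, immune markers on the
    leukocyte types."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    sets = sets or default_gene_sets()
    base = rng.lognormal(2.0, 1.0, size=(len(genes), len(CELL_TYPES)))
    ref = pd.DataFrame(base, index=genes, columns=CELL_TYPES)
    for g in sets["stromal"]:
        if g in ref.index:
            ref.loc[g, "CAF"] *= 40.0
    for g in sets["immune"]:
        if g in ref.index:
            ref.loc[g, ["CD4T", "CD8T", "Bcell", "macrophage"]] *= 25.0
    for g in sets["squamous"] + sets["classical"]:
        if g in ref.index:
            ref.loc[g, "epithelial"] *= 15.0
    return ref


def simulate_expression(n_samples: int, squamous_set, classical_set,
                        stromal_set, immune_set,
                        reference_profiles: pd.DataFrame,
                        true_fractions: np.ndarray,
                        noise_sd: float = 0.2, seed=None,
                        subtype: Optional[list[str]] = None,
                        subtype_shift: float = 3.0):
    """Mixture-of-profiles bulk expression with subtype shifts and noise.

    ``true_fractions`` is samples x cell-types, rows non-negative with sums
    <= 1 (the remainder is uncharacterized and contributes no signal).
    ``subtype`` labels ('squamous' / 'classical' / None) add a fold-change
    shift on the respective marker genes.  Returns (genes x samples
    DataFrame, truth dict).
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    W = np.asarray(true_fractions, dtype=float)
    if W.shape != (n_samples, reference_profiles.shape[1]):
        raise ValueError("true_fractions must be samples x cell-types")
    if (W < 0).any() or (W.sum(axis=1) > 1 + 1e-9).any():
        raise ValueError("fractions must be >= 0 with row sums <= 1")
    genes = list(reference_profiles.index)
    X = reference_profiles.values @ W.T        # genes x samples
    subtype = subtype or [None] * n_samples
    for j, st in enumerate(subtype):
        markers = (squamous_set if st == "squamous"
                   else classical_set if st == "classical" else [])
        for g in markers:
            if g in reference_profiles.index:
                X[genes.index(g), j] *= subtype_shift
    if noise_sd > 0:
        X = X * rng.lognormal(0.0, noise_sd, size=X.shape)
    cols = [f"S{j + 1:02d}" for j in range(n_samples)]
    expr = pd.DataFrame(X, index=genes, columns=cols)
    truth = {"fractions": {c: dict(zip(reference_profiles.columns, W[j]))
                           for j, c in enumerate(cols)},
             "subtype": dict(zip(cols, subtype))}
    return expr, truth


def simulate_cohort_expression(specs: list[CloneTreeSpec],
                               noise_sd: float = 0.2, seed=None):
    """Per-region bulk expression for a simulated cohort.

    Invasive (PDAC) regions receive fibroblast-rich, epithelial-poor
    compositions and a higher chance of the squamous subtype shift;
    precursor regions are epithelial-rich and classical.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    sets = default_gene_sets()
    genes = _gene_universe(sets)
    ref = make_reference_profiles(genes, sets, rng)
    samples, fractions, subtypes = [], [], []
    for spec in specs:
        for rid in spec.regions:
            hist = spec.histology[rid]
            if hist == "PDAC":
                caf, epi = rng.normal(0.24, 0.04), rng.normal(0.50, 0.05)
                p_sq = 0.7
            else:
                caf, epi = rng.normal(0.05, 0.02), rng.normal(0.64, 0.05)
                p_sq = 0.1
            caf, epi = max(caf, 0.01), max(epi, 0.1)
            immune = rng.dirichlet([2, 2, 1, 1]) * max(
                0.0, rng.uniform(0.05, 0.95 - caf - epi))
            row = np.array([epi, caf, *immune])
            fractions.append(row)
            subtypes.append("squamous" if rng.random() < p_sq else "classical")
            samples.append(f"{spec.patient_id}_{rid}")
    W = np.vstack(fractions)
    expr, truth = simulate_expression(
        len(samples), sets["squamous"], sets["classical"], sets["stromal"],
        sets["immune"], ref, W, noise_sd, rng, subtype=subtypes)
    expr.columns = samples
    truth["fractions"] = {s: f for s, f in
                          zip(samples, truth["fractions"].values())}
    truth["subtype"] = dict(zip(samples, subtypes))
    truth["histology"] = {f"{sp.patient_id}_{rid}": sp.histology[rid]
                          for sp in specs for rid in sp.regions}
    return expr, truth
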