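"""Readers and writers for every on-disk format the pipeline touches.

Formats: VCF 4.x (via cyvcf2) with per-sample AD depths, BEDPE breakpoint
pairs, Battenberg-style allele-specific segment tables, purity tables,
gene x sample expression TSVs, GMT gene sets, YAML cohort manifests, and
Newick/JSON clone trees.

Coordinate conventions: genomic coordinates are 1-based inclusive
internally.  BEDPE is read as 0-based half-open and converted on ingest.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import yaml
from intervaltree import IntervalTree

from .variant_features import MutationCall

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentRecord",
    "SVRecord",
    "RegionFiles",
    "CohortManifest",
    "read_vcf",
    "write_vcf",
    "read_segments",
    "write_segments",
    "read_bedpe",
    "write_bedpe",
    "read_purity",
    "write_purity",
    "read_expression",
    "write_expression",
    "read_gene_sets",
    "write_gene_sets",
    "load_manifest",
    "save_manifest",
    "merge_region_calls",
    "attach_copy_states",
    "write_tree",
    "read_tree_json",
]

HISTOLOGY_LABELS = ("LGD", "HGD", "HGD_microinvasive", "PDAC")


@dataclass(frozen=True)
class SegmentRecord:
    """Allele-specific copy-number segment (1-based inclusive coords)."""

    chrom: str
    start: int
    end: int
    major: int
    minor: int
    region_id: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment start {self.start} > end {self.end}")
        if self.minor < 0 or self.major < self.minor:
            raise ValueError(
                f"need major >= minor >= 0, got ({self.major}, {self.minor})"
            )

    @property
    def total(self) -> int:
        return self.major + self.minor

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SVRecord:
    """One structural-variant breakpoint pair, canonicalized."""

    chrom1: str
    pos1: int
    strand1: str
    chrom2: str
    pos2: int
    strand2: str
    sv_class: str = "unclassified"
    region_id: str = ""

    def __post_init__(self) -> None:
        for s in (self.strand1, self.strand2):
            if s not in ("+", "-"):
                raise ValueError(f"strand must be + or -, got {s!r}")

    def canonical(self) -> "SVRecord":
        """Order intrachromosomal breakends so pos1 <= pos2."""
        if self.chrom1 == self.chrom2 and self.pos1 > self.pos2:
            return SVRecord(self.chrom2, self.pos2, self.strand2,
                            self.chrom1, self.pos1, self.strand1,
                            self.sv_class, self.region_id)
        return self

    @property
    def intrachromosomal(self) -> bool:
        return self.chrom1 == self.chrom2


@dataclass
class RegionFiles:
    region_id: str
    vcf: str
    segments: str
    purity: str
    bedpe: Optional[str] = None
    histology: str = "LGD"

    def __post_init__(self) -> None:
        if self.histology not in HISTOLOGY_LABELS:
            raise ValueError(f"unknown histology {self.histology!r}")


@dataclass
class CohortManifest:
    """One patient's multi-region file layout."""

    patient_id: str
    regions: list[RegionFiles] = field(default_factory=list)
    expression_path: Optional[str] = None

    def __post_init__(self) -> None:
        ids = [r.region_id for r in self.regions]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate region ids for patient {self.patient_id}")

    @property
    def region_ids(self) -> list[str]:
        return [r.region_id for r in self.regions]

    def validate_paths(self, base: str = ".") -> None:
        for r in self.regions:
            for p in (r.vcf, r.segments, r.purity, r.bedpe):
                if p and not os.path.exists(os.path.join(base, p)):
                    raise FileNotFoundError(
                        f"{self.patient_id}/{r.region_id}: missing {p}")
        if self.expression_path and not os.path.exists(
                os.path.join(base, self.expression_path)):
            raise FileNotFoundError(self.expression_path)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str, region_id: str) -> list[MutationCall]:
    """Read PASS somatic calls with AD depths into MutationCall records.

    Multi-allelic records are split, one call per alt allele.  Records
    without a usable AD field are skipped with a logged count; a VCF whose
    header lacks AD entirely is a hard error.
    """
    from cyvcf2 import VCF

    if not os.path.exists(path):
        raise FileNotFoundError(path)
    vcf = VCF(path)
    if "AD" not in [f["ID"] for f in _format_headers(vcf)]:
        raise ValueError(f"{path}: no AD depth field in FORMAT header")
    calls: list[MutationCall] = []
    skipped = 0
    for v in vcf:
        if v.FILTER is not None:  # None == PASS
            continue
        ad = v.format("AD")
        if ad is None:
            skipped += 1
            continue
        ad = np.asarray(ad[0]).ravel()  # single-sample
        ref_depth = int(ad[0])
        context = v.INFO.get("TNC")
        gene = v.INFO.get("GENE")
        driver = bool(v.INFO.get("DRIVER", False))
        for ai, alt in enumerate(v.ALT):
            if ai + 1 >= len(ad) or ad[ai + 1] < 0:
                skipped += 1
                continue
            alt_depth = int(ad[ai + 1])
            depth = ref_depth + alt_depth
            calls.append(MutationCall(
                chrom=v.CHROM, pos=v.POS, ref=v.REF, alt=alt,
                alt_count={region_id: alt_depth},
                depth={region_id: depth},
                context=context, is_driver=driver, gene=gene,
            ))
    if skipped:
        logger.info("read_vcf(%s): skipped %d records without usable depths",
                    path, skipped)
    return calls


def _format_headers(vcf) -> list[dict]:
    out = []
    for h in vcf.header_iter():
        try:
            if h["HeaderType"] == "FORMAT":
                out.append(h)
        except KeyError:
            continue
    return out


_VCF_HEADER = ("""##fileformat=VCFv4.2
##FILTER=<ID=PASS,Description="All filters passed">
##INFO=<ID=TNC,Number=1,Type=String,Description="Trinucleotide context of the reference allele">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=DRIVER,Number=0,Type=Flag,Description="Driver mutation">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""
               + "".join(f"##contig=<ID=chr{i}>\n" for i in range(1, 23))
               + "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")


def write_vcf(path: str, calls: Iterable[MutationCall], region_id: str,
              sample_name: Optional[str] = None) -> None:
    """Write single-sample VCF with AD depths for one region."""
    sample = sample_name or region_id
    rows = []
    for c in sorted(calls, key=lambda c: (c.chrom, c.pos, c.ref, c.alt)):
        depth = c.depth.get(region_id)
        alt = c.alt_count.get(region_id)
        if depth is None:
            continue
        info = []
        if c.context:
            info.append(f"TNC={c.context}")
        if c.gene:
            info.append(f"GENE={c.gene}")
        if c.is_driver:
            info.append("DRIVER")
        rows.append("\t".join([
            c.chrom, str(c.pos), ".", c.ref, c.alt, ".", "PASS",
            ";".join(info) or ".", "AD:DP", f"{depth - alt},{alt}:{depth}",
        ]))
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(sample=sample))
        fh.write("\n".join(rows) + ("\n" if rows else ""))


# ---------------------------------------------------------------------------
# Segments / purity / BEDPE
# ---------------------------------------------------------------------------

SEGMENT_COLUMNS = ["chrom", "start", "end", "major", "minor"]


def read_segments(path: str, region_id: str = "") -> list[SegmentRecord]:
    """Read a Battenberg-style tab-separated segment table.

    Columns: chrom, start, end, major, minor (1-based inclusive).
    Overlapping segments within one region are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(SEGMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    segs = [SegmentRecord(r.chrom, int(r.start), int(r.end),
                          int(r.major), int(r.minor), region_id)
            for r in df.itertuples()]
    _check_non_overlapping(segs, path)
    return segs


def _check_non_overlapping(segs: list[SegmentRecord], origin: str) -> None:
    by_chrom: dict[str, list[SegmentRecord]] = {}
    for s in segs:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, ss in by_chrom.items():
        ss = sorted(ss, key=lambda s: s.start)
        for a, b in zip(ss, ss[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"{origin}: overlapping segments on {chrom}: "
                    f"{a.start}-{a.end} and {b.start}-{b.end}")


def write_segments(path: str, segments: Iterable[SegmentRecord]) -> None:
    df = pd.DataFrame(
        [(s.chrom, s.start, s.end, s.major, s.minor) for s in segments],
        columns=SEGMENT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_purity(path: str) -> dict[str, float]:
    """Read a purity table: columns region_id, purity (and optional ploidy)."""
    df = pd.read_csv(path, sep="\t", dtype={"region_id": str})
    out = {}
    for r in df.itertuples():
        rho = float(r.purity)
        if not (0 < rho <= 1):
            raise ValueError(f"{path}: purity {rho} outside (0, 1]")
        out[r.region_id] = rho
    return out


def write_purity(path: str, purity: dict[str, float],
                 ploidy: Optional[dict[str, float]] = None) -> None:
    rows = [{"region_id": rid, "purity": rho,
             "ploidy": (ploidy or {}).get(rid, 2.0)}
            for rid, rho in purity.items()]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


BEDPE_COLUMNS = ["chrom1", "start1", "end1", "chrom2", "start2", "end2",
                 "name", "score", "strand1", "strand2"]


def read_bedpe(path: str, region_id: str = "") -> list[SVRecord]:
    """Read BEDPE (0-based half-open) into 1-based canonicalized SVRecords.

    The breakend position is taken as the (1-based) start of each interval.
    """
    from .variant_features import classify_sv

    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=BEDPE_COLUMNS, dtype={0: str, 3: str})
    out = []
    for r in df.itertuples():
        rec = SVRecord(str(r.chrom1), int(r.start1) + 1, r.strand1,
                       str(r.chrom2), int(r.start2) + 1, r.strand2,
                       region_id=region_id).canonical()
        out.append(SVRecord(rec.chrom1, rec.pos1, rec.strand1,
                            rec.chrom2, rec.pos2, rec.strand2,
                            classify_sv(rec), region_id))
    return out


def write_bedpe(path: str, svs: Iterable[SVRecord]) -> None:
    rows = []
    for s in svs:
        s = s.canonical()
        rows.append([s.chrom1, s.pos1 - 1, s.pos1, s.chrom2, s.pos2 - 1,
                     s.pos2, s.sv_class, ".", s.strand1, s.strand2])
    pd.DataFrame(rows, columns=BEDPE_COLUMNS).to_csv(
        path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# Expression / gene sets
# ---------------------------------------------------------------------------

def read_expression(path: str) -> pd.DataFrame:
    """Gene x sample TPM table; first column gene ids, remaining samples."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicate gene ids")
    if (df.values < 0).any():
        raise ValueError(f"{path}: negative expression values")
    return df


def write_expression(path: str, expr: pd.DataFrame) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")


def read_gene_sets(path: str) -> dict[str, list[str]]:
    """GMT format: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name, genes = parts[0], [g for g in parts[2:] if g]
            if not genes:
                raise ValueError(f"{path}: empty gene set {name}")
            sets[name] = list(dict.fromkeys(genes))
    return sets


def write_gene_sets(path: str, sets: dict[str, list[str]]) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na"] + list(genes)) + "\n")


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

def load_manifest(path: str) -> list[CohortManifest]:
    """Load a cohort YAML listing patients, regions and file paths."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    patients = []
    for p in doc["patients"]:
        regions = [RegionFiles(**r) for r in p["regions"]]
        patients.append(CohortManifest(
            patient_id=p["patient_id"], regions=regions,
            expression_path=p.get("expression_path")))
    return patients


def save_manifest(path: str, patients: list[CohortManifest]) -> None:
    doc = {"patients": [
        {
            "patient_id": p.patient_id,
            "expression_path": p.expression_path,
            "regions": [
                {"region_id": r.region_id, "vcf": r.vcf,
                 "segments": r.segments, "purity": r.purity,
                 "bedpe": r.bedpe, "histology": r.histology}
                for r in p.regions
            ],
        } for p in patients
    ]}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Cross-region assembly
# ---------------------------------------------------------------------------

def merge_region_calls(calls_by_region: dict[str, list[MutationCall]]
                       ) -> list[MutationCall]:
    """Merge per-region call lists into multi-region MutationCalls by locus key."""
    merged: dict[str, MutationCall] = {}
    for rid, calls in calls_by_region.items():
        for c in calls:
            if c.key not in merged:
                merged[c.key] = MutationCall(
                    chrom=c.chrom, pos=c.pos, ref=c.ref, alt=c.alt,
                    context=c.context, is_driver=c.is_driver, gene=c.gene)
            m = merged[c.key]
            m.alt_count[rid] = c.alt_count.get(rid, 0)
            m.depth[rid] = c.depth.get(rid, 0)
            m.is_driver = m.is_driver or c.is_driver
            m.context = m.context or c.context
            m.gene = m.gene or c.gene
    return list(merged.values())


def attach_copy_states(calls: list[MutationCall],
                       segments_by_region: dict[str, list[SegmentRecord]],
                       default: tuple[int, int] = (1, 1)) -> None:
    """Annotate each call with its (major, minor) copy state per region.

    Loci outside any segment fall back to ``default`` (diploid het).
    """
    trees: dict[str, dict[str, IntervalTree]] = {}
    for rid, segs in segments_by_region.items():
        per_chrom: dict[str, IntervalTree] = {}
        for s in segs:
            per_chrom.setdefault(s.chrom, IntervalTree()).addi(
                s.start, s.end + 1, (s.major, s.minor))
        trees[rid] = per_chrom
    for c in calls:
        for rid in c.depth:
            hits = trees.get(rid, {}).get(c.chrom, IntervalTree())[c.pos]
            c.copy_state[rid] = next(iter(hits)).data if hits else default


# ---------------------------------------------------------------------------
# Clone-tree serialization
# ---------------------------------------------------------------------------

def write_tree(tree, path: str, fmt: str = "newick") -> None:
    """Serialize a clone tree (forest) to Newick or JSON.

    Newick branch lengths are SNV+indel counts per cluster; a forest yields
    one Newick statement per root.  JSON carries per-region CCFs, branch
    lengths, annotations and exclusive (oval-plot) fractions.
    """
    if fmt == "newick":
        with open(path, "w") as fh:
            for root in tree.roots:
                fh.write(_newick(tree, root) + ";\n")
    elif fmt == "json":
        with open(path, "w") as fh:
            json.dump(tree.to_dict(), fh, indent=1)
    else:
        raise ValueError(f"unknown tree format {fmt!r}")


def _newick(tree, node) -> str:
    children = tree.children(node)
    label = f"{node}:{tree.branch_length[node]}"
    if not children:
        return label
    inner = ",".join(_newick(tree, c) for c in children)
    return f"({inner}){label}"


def read_tree_json(path: str):
    from .tree_builder import CloneTree

    with open(path) as fh:
        return CloneTree.from_dict(json.load(fh))


def parse_newick_forest(path: str):
    """Parse Newick statements back to (parent-map, branch-length) pairs.

    Used for round-trip checks; dendropy handles the grammar.
    """
    import dendropy

    forests = []
    with open(path) as fh:
        text = fh.read()
    for stmt in [s.strip() + ";" for s in text.split(";") if s.strip()]:
        t = dendropy.Tree.get(data=stmt, schema="newick")
        parent: dict[str, Optional[str]] = {}
        lengths: dict[str, float] = {}
        for node in t.preorder_node_iter():
            name = node.taxon.label if node.taxon else node.label
            pname = None
            if node.parent_node is not None:
                pn = node.parent_node
                pname = pn.taxon.label if pn.taxon else pn.label
            parent[name] = pname
            lengths[name] = node.edge.length or 0.0
        forests.append((parent, lengths))
    return forests
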