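"""Per-mutation genomic computations.

Cancer cell fraction (CCF) arithmetic, mutation multiplicity estimation,
mutation timing relative to copy-number gains, tumor mutation burden,
structural-variant classification and CN48 copy-number channel encoding.

The central identity relating the variant allele fraction ``f`` of a somatic
mutation to the fraction of tumor cells carrying it is::

    f = ccf * rho * m / (rho * n_t + (1 - rho) * n_normal)

where ``rho`` is tumor purity, ``m`` the number of mutated allele copies in
carrying cells (multiplicity), ``n_t`` the total tumor copy number at the
locus and ``n_normal`` the copy number in contaminating normal cells
(2 on autosomes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np

__all__ = [
    "MutationCall",
    "PurityEstimate",
    "TimingClass",
    "CCF_CAP",
    "expected_vaf",
    "compute_ccf",
    "estimate_multiplicity",
    "classify_timing",
    "compute_tmb",
    "classify_sv",
    "encode_cn48",
    "CN48_LABELS",
]

#: CCF values above this are clipped and flagged (matches the clustering
#: prior's support, [0, 1.25]); measurement noise and multiplicity
#: mis-estimates can push raw CCFs above 1.
CCF_CAP = 1.25


class TimingClass(str, Enum):
    """Timing of a mutation relative to clonal expansion and copy gains."""

    clonal_early = "clonal_early"
    clonal_late = "clonal_late"
    clonal_unspecified = "clonal_unspecified"
    subclonal = "subclonal"


@dataclass
class PurityEstimate:
    region_id: str
    rho: float

    def __post_init__(self) -> None:
        if not (0.0 < self.rho <= 1.0):
            raise ValueError(f"purity must be in (0, 1], got {self.rho}")


@dataclass
class MutationCall:
    """One somatic SNV or indel with per-region read support.

    Per-region dictionaries are keyed by region id.  ``copy_state`` maps a
    region to its (major, minor) allele-specific copy number at the locus;
    it must be present for every region with non-zero depth.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    alt_count: dict[str, int] = field(default_factory=dict)
    depth: dict[str, int] = field(default_factory=dict)
    copy_state: dict[str, tuple[int, int]] = field(default_factory=dict)
    context: Optional[str] = None
    is_driver: bool = False
    gene: Optional[str] = None

    def __post_init__(self) -> None:
        for rid, d in self.depth.items():
            a = self.alt_count.get(rid, 0)
            if a > d:
                raise ValueError(
                    f"{self.key}: alt_count {a} exceeds depth {d} in region {rid}"
                )

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    def vaf(self, region_id: str) -> float:
        d = self.depth.get(region_id, 0)
        return self.alt_count.get(region_id, 0) / d if d else float("nan")


def expected_vaf(ccf, rho, m, n_t, n_normal: int = 2):
    """Expected variant allele fraction for a mutation at CCF ``ccf``.

    Accepts scalars or numpy arrays (broadcasting).  Exact inverse of
    :func:`compute_ccf`.
    """
    ccf = np.asarray(ccf, dtype=float)
    rho = np.asarray(rho, dtype=float)
    m = np.asarray(m, dtype=float)
    n_t = np.asarray(n_t, dtype=float)
    out = ccf * rho * m / (rho * n_t + (1.0 - rho) * n_normal)
    return float(out) if out.ndim == 0 else out


def compute_ccf(vaf, rho, m, n_t, n_normal: int = 2, cap: float = CCF_CAP):
    """Cancer cell fraction from an observed VAF.

    Returns ``(ccf, capped)``; raw values above ``cap`` are clipped with the
    flag set rather than discarded.  Array inputs broadcast.
    """
    rho = np.asarray(rho, dtype=float)
    if np.any(rho <= 0):
        raise ValueError("purity must be positive")
    vaf = np.asarray(vaf, dtype=float)
    m = np.asarray(m, dtype=float)
    n_t = np.asarray(n_t, dtype=float)
    raw = vaf * (rho * n_t + (1.0 - rho) * n_normal) / (rho * m)
    capped = raw > cap
    ccf = np.minimum(raw, cap)
    if ccf.ndim == 0:
        return float(ccf), bool(capped)
    return ccf, capped


def estimate_multiplicity(vaf, rho, n_t, major, n_normal: int = 2):
    """Most plausible integer multiplicity given an observed VAF.

    ``m = clamp(round(vaf * (rho * n_t + (1 - rho) * 2) / rho), 1, major)``
    with ties rounded half away from zero.  Array inputs broadcast.
    """
    rho = np.asarray(rho, dtype=float)
    vaf = np.asarray(vaf, dtype=float)
    n_t = np.asarray(n_t, dtype=float)
    major = np.asarray(major)
    if np.any(major < 1):
        raise ValueError("major copy number must be >= 1 at a mutated locus")
    raw = vaf * (rho * n_t + (1.0 - rho) * n_normal) / rho
    # round half away from zero (np.round rounds half to even)
    m = np.floor(raw + 0.5)
    m = np.clip(m, 1, major).astype(int)
    return int(m) if m.ndim == 0 else m


def classify_timing(cluster_is_trunk: bool, m: int, major: int, minor: int) -> TimingClass:
    """Timing label for one mutation.

    Subclonal mutations postdate the most recent common ancestor.  For trunk
    mutations in a gained region (major >= 2), multiplicity distinguishes
    mutations acquired before the gain (carried on every gained copy,
    m >= 2: clonal-early) from those acquired after it (m = 1: clonal-late).
    Without a gain the ordering is not resolvable (clonal-unspecified).
    """
    if m > major:
        raise ValueError(f"multiplicity {m} exceeds major copy number {major}")
    if not cluster_is_trunk:
        return TimingClass.subclonal
    if major >= 2:
        return TimingClass.clonal_early if m >= 2 else TimingClass.clonal_late
    return TimingClass.clonal_unspecified


def compute_tmb(n_snv: int, n_indel: int, callable_mb: float = 3000.0) -> float:
    """Tumor mutation burden in mutations per megabase."""
    if callable_mb <= 0:
        raise ValueError("callable_mb must be positive")
    return (n_snv + n_indel) / callable_mb


def classify_sv(sv) -> str:
    """Classify a breakpoint pair by the discordant read-pair convention.

    Different chromosomes give a translocation.  On one chromosome, ordered
    breakends with strands (+,-) indicate a deletion, (-,+) a tandem
    duplication and (+,+)/(-,-) an inversion.  Missing strands give
    ``unclassified``.
    """
    s1, s2 = getattr(sv, "strand1", None), getattr(sv, "strand2", None)
    if s1 not in ("+", "-") or s2 not in ("+", "-"):
        return "unclassified"
    if sv.chrom1 != sv.chrom2:
        return "translocation"
    if (s1, s2) == ("+", "-"):
        return "deletion"
    if (s1, s2) == ("-", "+"):
        return "tandem_duplication"
    return "inversion"


# ---------------------------------------------------------------------------
# CN48 copy-number channel encoding
# ---------------------------------------------------------------------------

_LEN_EDGES_KB = (100.0, 1_000.0, 10_000.0, 40_000.0)  # 0-100kb,100kb-1Mb,1-10Mb,10-40Mb,>40Mb
_LEN_LABELS = ("0-100kb", "100kb-1Mb", "1Mb-10Mb", "10Mb-40Mb", ">40Mb")
_HOMDEL_EDGES_KB = (100.0, 1_000.0)
_HOMDEL_LEN_LABELS = ("0-100kb", "100kb-1Mb", ">1Mb")
_TCN_CLASSES = ((1, 1, "1"), (2, 2, "2"), (3, 4, "3-4"), (5, 8, "5-8"), (9, 10**9, "9+"))


def _len_class(length_kb: float, edges) -> int:
    for i, e in enumerate(edges):
        if length_kb <= e:
            return i
    return len(edges)


def _build_cn48_labels() -> list[str]:
    labels = [f"0:homdel:{l}" for l in _HOMDEL_LEN_LABELS]
    for lo, hi, tcn in _TCN_CLASSES:
        for l in _LEN_LABELS:
            labels.append(f"{tcn}:LOH:{l}")
    for lo, hi, tcn in _TCN_CLASSES[1:]:  # het requires minor >= 1, total >= 2
        for l in _LEN_LABELS:
            labels.append(f"{tcn}:het:{l}")
    return labels


#: 48 channel labels: 3 homozygous-deletion length classes, 5 total-copy
#: classes x 5 length classes with LOH, and 4 x 5 heterozygous.
CN48_LABELS = _build_cn48_labels()
assert len(CN48_LABELS) == 48


def encode_cn48(segment) -> int:
    """Map an allele-specific copy-number segment to its CN48 channel.

    Segments are classified by zygosity (homozygous deletion / LOH /
    heterozygous), total copy number class and length class.
    """
    major, minor = segment.major, segment.minor
    if major < 0 or minor < 0:
        raise ValueError("negative copy numbers")
    if minor > major:
        major, minor = minor, major
    length_kb = (segment.end - segment.start + 1) / 1000.0
    total = major + minor
    if total == 0:
        return _len_class(length_kb, _HOMDEL_EDGES_KB)
    lc = _len_class(length_kb, _LEN_EDGES_KB)
    if minor == 0:
        for i, (lo, hi, _) in enumerate(_TCN_CLASSES):
            if lo <= total <= hi:
                return 3 + 5 * i + lc
    # heterozygous (minor >= 1 implies total >= 2)
    for i, (lo, hi, _) in enumerate(_TCN_CLASSES[1:]):
        if lo <= total <= hi:
            return 3 + 25 + 5 * i + lc
    raise AssertionError("unreachable")
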