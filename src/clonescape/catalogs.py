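"""Construction of the packaged synthetic signature catalogs.

Each catalog is a channel x signature probability matrix whose column
shapes imitate well-characterized mutational processes — clock-like CpG
deamination, APOBEC cytidine deamination in TpC context, broad flat
"featureless" SBS processes, homopolymer slippage indels, microhomology
deletions, and LOH-rich copy-number states.  The matrices are generated
deterministically (fixed seeds) and shipped as TSV files; they are
synthetic stand-ins for testing and simulation, not measured reference
signatures.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .signature_engine import ID83_LABELS, SBS96_LABELS, _BASES, _SUBS
from .variant_features import CN48_LABELS

__all__ = ["build_sbs_catalog", "build_id_catalog", "build_cn_catalog",
           "write_catalogs"]


def _chan(sub: str, five: str, three: str) -> int:
    return _SUBS.index(sub) * 16 + _BASES.index(five) * 4 + _BASES.index(three)


def _normalize(df: pd.DataFrame) -> pd.DataFrame:
    return df / df.sum(axis=0)


def build_sbs_catalog() -> pd.DataFrame:
    rng = np.random.default_rng(960001)
    cat = pd.DataFrame(0.0, index=SBS96_LABELS,
                       columns=["SBS1", "SBS2", "SBS5", "SBS13", "SBS28",
                                "SBS40"])
    # clock-like CpG deamination: C>T at NpCpG
    for five in _BASES:
        cat.iloc[_chan("C>T", five, "G"), 0] = 0.21
    cat["SBS1"] += rng.dirichlet(np.ones(96)) * 0.16
    # APOBEC: C>T at TpCpN
    for three in _BASES:
        cat.iloc[_chan("C>T", "T", three), 1] = 0.20
    cat["SBS2"] += rng.dirichlet(np.ones(96)) * 0.20
    # broad, flat-ish processes
    cat["SBS5"] = rng.dirichlet(np.full(96, 6.0))
    cat["SBS40"] = rng.dirichlet(np.full(96, 3.0))
    # APOBEC: C>G (and some C>A) at TpCpN
    for three in _BASES:
        cat.iloc[_chan("C>G", "T", three), 3] = 0.17
        cat.iloc[_chan("C>A", "T", three), 3] = 0.04
    cat["SBS13"] += rng.dirichlet(np.ones(96)) * 0.16
    # T>G in TpTpT-like context
    cat.iloc[_chan("T>G", "T", "T"), 4] = 0.45
    cat.iloc[_chan("T>G", "T", "C"), 4] = 0.15
    cat.iloc[_chan("T>C", "T", "T"), 4] = 0.10
    cat["SBS28"] += rng.dirichlet(np.ones(96)) * 0.30
    return _normalize(cat)


def build_id_catalog() -> pd.DataFrame:
    rng = np.random.default_rng(830001)
    idx = {lab: i for i, lab in enumerate(ID83_LABELS)}
    cat = pd.DataFrame(0.0, index=ID83_LABELS,
                       columns=["ID1", "ID2", "ID5", "ID6", "ID8", "ID9",
                                "ID14"])
    cat.loc["INS:T:1:5+", "ID1"] = 0.6
    cat.loc["INS:T:1:4", "ID1"] = 0.2
    cat.loc["DEL:T:1:6+", "ID2"] = 0.6
    cat.loc["DEL:T:1:5", "ID2"] = 0.2
    cat.loc["DEL:T:1:2", "ID5"] = 0.3
    cat.loc["DEL:T:1:3", "ID5"] = 0.3
    cat.loc["DEL:C:1:2", "ID5"] = 0.15
    for lab in ["DEL:M:5+:2", "DEL:M:5+:3", "DEL:M:5+:4", "DEL:M:5+:5+",
                "DEL:M:4:3"]:
        cat.loc[lab, "ID6"] = 0.15
    for lab in ["DEL:R:5+:1", "DEL:R:4:1", "DEL:M:5+:1", "DEL:M:4:1"]:
        cat.loc[lab, "ID8"] = 0.18
    for lab in ["DEL:C:1:1", "DEL:T:1:1", "DEL:R:2:1", "DEL:R:3:1"]:
        cat.loc[lab, "ID9"] = 0.18
    for lab in ["INS:C:1:0", "INS:C:1:1", "INS:T:1:0", "INS:R:2:0",
                "INS:R:3:0"]:
        cat.loc[lab, "ID14"] = 0.15
    for c in cat.columns:
        cat[c] += rng.dirichlet(np.ones(83)) * 0.2
    return _normalize(cat)


def build_cn_catalog() -> pd.DataFrame:
    rng = np.random.default_rng(480001)
    cat = pd.DataFrame(0.0, index=CN48_LABELS,
                       columns=["CN1", "CN9", "CN24", "CNV48B"])

    def block(prefix_tcn: str, zyg: str, weights) -> list[tuple[str, float]]:
        lens = ["0-100kb", "100kb-1Mb", "1Mb-10Mb", "10Mb-40Mb", ">40Mb"]
        return [(f"{prefix_tcn}:{zyg}:{l}", w) for l, w in zip(lens, weights)]

    # diploid heterozygous genome, long segments
    for lab, w in block("2", "het", [0.02, 0.05, 0.13, 0.25, 0.45]):
        cat.loc[lab, "CN1"] = w
    # chromosomal instability: mid-size gains and LOH
    for lab, w in block("3-4", "het", [0.04, 0.08, 0.14, 0.10, 0.06]):
        cat.loc[lab, "CN9"] = w
    for lab, w in block("2", "LOH", [0.04, 0.08, 0.12, 0.08, 0.04]):
        cat.loc[lab, "CN9"] = w
    # amplified states
    for lab, w in block("5-8", "het", [0.08, 0.14, 0.16, 0.08, 0.04]):
        cat.loc[lab, "CN24"] = w
    for lab, w in block("3-4", "LOH", [0.05, 0.10, 0.12, 0.06, 0.03]):
        cat.loc[lab, "CN24"] = w
    # extensive LOH
    for lab, w in block("1", "LOH", [0.04, 0.09, 0.16, 0.18, 0.13]):
        cat.loc[lab, "CNV48B"] = w
    for lab, w in block("2", "LOH", [0.02, 0.05, 0.10, 0.12, 0.08]):
        cat.loc[lab, "CNV48B"] = w
    for c in cat.columns:
        cat[c] += rng.dirichlet(np.ones(48)) * 0.1
    return _normalize(cat)


def write_catalogs(out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    build_sbs_catalog().to_csv(
        os.path.join(out_dir, "sbs_catalog_synthetic.tsv"), sep="\t",
        index_label="channel")
    build_id_catalog().to_csv(
        os.path.join(out_dir, "id_catalog_synthetic.tsv"), sep="\t",
        index_label="channel")
    build_cn_catalog().to_csv(
        os.path.join(out_dir, "cn_catalog_synthetic.tsv"), sep="\t",
        index_label="channel")
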