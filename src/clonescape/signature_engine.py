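"""Mutational-signature channel encoding, refitting and branch profiles.

Channels: SBS96 (pyrimidine-strand trinucleotide substitution classes),
ID83 (indel length / homopolymer / repeat / microhomology classes) and CN48
(copy-number segment classes, see
:func:`clonescape.variant_features.encode_cn48`).

Refitting decomposes a channel count vector onto a fixed catalog of
signatures by non-negative least squares with iterative pruning of weak
activities.  Per-mutation signature assignment follows the posterior
probability ``P(s | channel c) = e_s S_cs / sum_s' e_s' S_cs'``.  A minimal
multiplicative-update NMF (KL divergence) supports small-scale de novo
extraction.

The packaged catalogs (``data/*_catalog_synthetic.tsv``) are synthetic
stand-ins whose shapes imitate well-known COSMIC processes (clock-like,
APOBEC, mismatch-repair-associated indels, LOH-rich copy-number states);
they are intended for testing and simulation, not for interpreting real
tumors.  Real COSMIC catalogs in the same channel layout can be supplied
instead.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import nnls

__all__ = [
    "SBS96_LABELS",
    "ID83_LABELS",
    "encode_sbs96",
    "encode_id83",
    "decode_sbs96",
    "load_catalog",
    "fit_exposures_nnls",
    "mutation_signature_probability",
    "probability_matrix",
    "branch_signature_profile",
    "extract_denovo_nnmf",
    "cosine_similarity",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_SUBS = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]
_BASES = "ACGT"


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def _build_sbs96_labels() -> list[str]:
    return [f"{five}[{sub}]{three}"
            for sub in _SUBS for five in _BASES for three in _BASES]


SBS96_LABELS = _build_sbs96_labels()


def encode_sbs96(ref: str, alt: str, context: str) -> int:
    """Channel index of a single-base substitution in its trinucleotide
    context; purine-reference mutations are reverse-complemented onto the
    pyrimidine strand."""
    ref, alt, context = ref.upper(), alt.upper(), context.upper()
    if len(ref) != 1 or len(alt) != 1 or len(context) != 3:
        raise ValueError("need single bases and a 3-mer context")
    if any(b not in _BASES for b in ref + alt + context):
        raise ValueError(f"ambiguous base in {context} {ref}>{alt}")
    if context[1] != ref:
        raise ValueError(f"context middle {context[1]} != ref {ref}")
    if ref in "AG":
        ref, alt, context = _COMPLEMENT[ref], _COMPLEMENT[alt], _revcomp(context)
    sub = _SUBS.index(f"{ref}>{alt}")
    return sub * 16 + _BASES.index(context[0]) * 4 + _BASES.index(context[2])


def decode_sbs96(channel: int) -> tuple[str, str, str]:
    """(ref, alt, context) on the pyrimidine strand for a channel index."""
    label = SBS96_LABELS[channel]
    five, rest = label[0], label[2:]
    sub, three = rest[:3], label[-1]
    ref, alt = sub[0], sub[2]
    return ref, alt, f"{five}{ref}{three}"


# ---------------------------------------------------------------------------
# ID83
# ---------------------------------------------------------------------------

def _build_id83_labels() -> list[str]:
    labels = []
    for base in "CT":
        labels += [f"DEL:{base}:1:{h}" for h in ["1", "2", "3", "4", "5", "6+"]]
    for base in "CT":
        labels += [f"INS:{base}:1:{h}" for h in ["0", "1", "2", "3", "4", "5+"]]
    for ln in ["2", "3", "4", "5+"]:
        labels += [f"DEL:R:{ln}:{r}" for r in ["1", "2", "3", "4", "5", "6+"]]
    for ln in ["2", "3", "4", "5+"]:
        labels += [f"INS:R:{ln}:{r}" for r in ["0", "1", "2", "3", "4", "5+"]]
    mh = {"2": ["1"], "3": ["1", "2"], "4": ["1", "2", "3"],
          "5+": ["1", "2", "3", "4", "5+"]}
    for ln, ms in mh.items():
        labels += [f"DEL:M:{ln}:{m}" for m in ms]
    return labels


ID83_LABELS = _build_id83_labels()
assert len(ID83_LABELS) == 83

_MH_OFFSET = {("2", 1): 0, ("3", 1): 1, ("3", 2): 2, ("4", 1): 3, ("4", 2): 4,
              ("4", 3): 5, ("5+", 1): 6, ("5+", 2): 7, ("5+", 3): 8,
              ("5+", 4): 9, ("5+", 5): 10}


def _run_left(seq: str, flank: str) -> int:
    """Adjacent copies of ``seq`` at the end of the left flank."""
    n, u = 0, len(seq)
    while flank.endswith(seq * (n + 1)):
        n += 1
        if n * u > len(flank):
            break
    return n


def _run_right(seq: str, flank: str) -> int:
    n, u = 0, len(seq)
    while flank.startswith(seq * (n + 1)):
        n += 1
        if n * u > len(flank):
            break
    return n


def encode_id83(ref: str, alt: str, left_flank: str, right_flank: str) -> int:
    """ID83 channel of a simple insertion or deletion.

    ``ref``/``alt`` follow VCF convention (shared anchor base first);
    flanks are the reference sequence immediately 5' and 3' of the
    inserted/deleted bases.  Complex (substitution-like) indels raise.
    """
    ref, alt = ref.upper(), alt.upper()
    left, right = left_flank.upper(), right_flank.upper()
    if len(ref) > len(alt) and ref.startswith(alt):
        seq, is_del = ref[len(alt):], True
    elif len(alt) > len(ref) and alt.startswith(ref):
        seq, is_del = alt[len(ref):], False
    else:
        raise ValueError(f"not a simple indel: {ref}>{alt}")
    if any(b not in _BASES for b in seq):
        raise ValueError(f"ambiguous base in indel {seq}")
    ln = len(seq)
    if ln == 1:
        b = seq if seq in "CT" else _COMPLEMENT[seq]
        run = _run_left(seq, left) + _run_right(seq, right)
        base_off = 0 if b == "C" else 6
        if is_del:
            hp = min(run + 1, 6)          # homopolymer incl. deleted base
            return base_off + hp - 1
        return 12 + base_off + min(run, 5)
    ln_class = str(ln) if ln <= 4 else "5+"
    ln_idx = min(ln, 5) - 2
    copies = _run_left(seq, left) + _run_right(seq, right)
    if is_del:
        if copies == 0:
            mh = 0
            for k in range(ln - 1, 0, -1):
                if right.startswith(seq[:k]) or left.endswith(seq[-k:]):
                    mh = k
                    break
            if mh:
                mh = min(mh, 5 if ln_class == "5+" else
                         {"2": 1, "3": 2, "4": 3}[ln_class])
                return 72 + _MH_OFFSET[(ln_class, mh)]
        return 24 + ln_idx * 6 + min(copies + 1, 6) - 1
    return 48 + ln_idx * 6 + min(copies, 5)


# ---------------------------------------------------------------------------
# Catalogs
# ---------------------------------------------------------------------------

_CATALOG_FILES = {
    "sbs": "sbs_catalog_synthetic.tsv",
    "id": "id_catalog_synthetic.tsv",
    "cn": "cn_catalog_synthetic.tsv",
}


def load_catalog(kind: str = "sbs", path: Optional[str] = None) -> pd.DataFrame:
    """Load a channel x signature catalog (columns sum to 1).

    ``kind`` selects a packaged synthetic catalog; ``path`` overrides with a
    user-supplied TSV in the same layout (channel labels in first column).
    """
    if path is None:
        if kind not in _CATALOG_FILES:
            raise ValueError(f"unknown catalog kind {kind!r}")
        ref = importlib.resources.files("clonescape.data") / _CATALOG_FILES[kind]
        with importlib.resources.as_file(ref) as p:
            cat = pd.read_csv(p, sep="\t", index_col=0)
    else:
        cat = pd.read_csv(path, sep="\t", index_col=0)
    _validate_catalog(cat)
    return cat


def _validate_catalog(cat: pd.DataFrame) -> None:
    if (cat.values < 0).any():
        raise ValueError("catalog entries must be non-negative")
    sums = cat.sum(axis=0)
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise ValueError(f"catalog columns must sum to 1, got {sums.values}")


# ---------------------------------------------------------------------------
# Refitting
# ---------------------------------------------------------------------------

def fit_exposures_nnls(channel_counts, catalog: pd.DataFrame,
                       prune_frac: float = 0.05) -> pd.Series:
    """Non-negative least-squares exposures with iterative pruning.

    Signatures whose fitted activity falls below ``prune_frac`` of the total
    are dropped and the remainder refitted, until the active set is stable.
    Deterministic; all-zero counts give all-zero exposures.
    """
    counts = np.asarray(channel_counts, dtype=float)
    if counts.shape[0] != catalog.shape[0]:
        raise ValueError("counts length does not match catalog channels")
    sigs = list(catalog.columns)
    if counts.sum() == 0:
        return pd.Series(0.0, index=sigs)
    active = list(sigs)
    while True:
        sol, _ = nnls(catalog[active].values, counts)
        total = sol.sum()
        if total == 0:
            break
        weak = [s for s, v in zip(active, sol) if v < prune_frac * total]
        if not weak or len(weak) == len(active):
            break
        active = [s for s in active if s not in weak]
    out = pd.Series(0.0, index=sigs)
    for s, v in zip(active, sol):
        out[s] = float(v)
    return out


def mutation_signature_probability(channel: int, exposures: pd.Series,
                                   catalog: pd.DataFrame) -> pd.Series:
    """Posterior signature probabilities for one channel given exposures.

    A channel with zero density under every active signature returns the
    uniform distribution over active signatures (``.attrs['flat']`` set).
    """
    if exposures.sum() <= 0:
        raise ValueError("exposure total must be positive")
    dens = catalog.iloc[channel].reindex(exposures.index).values * exposures.values
    total = dens.sum()
    if total == 0:
        active = exposures.values > 0
        out = pd.Series(np.where(active, 1.0 / active.sum(), 0.0),
                        index=exposures.index)
        out.attrs["flat"] = True
        return out
    return pd.Series(dens / total, index=exposures.index)


def probability_matrix(exposures: pd.Series, catalog: pd.DataFrame
                       ) -> pd.DataFrame:
    """Channel x signature posterior probabilities (rows sum to 1 where the
    mixture has support)."""
    rows = [mutation_signature_probability(c, exposures, catalog).values
            for c in range(catalog.shape[0])]
    return pd.DataFrame(rows, index=catalog.index, columns=exposures.index)


def assign_signature(channel: int, exposures: pd.Series,
                     catalog: pd.DataFrame) -> str:
    """Argmax signature for a channel; ties break by catalog column order."""
    p = mutation_signature_probability(channel, exposures, catalog)
    return str(p.index[int(np.argmax(p.values))])


def branch_signature_profile(tree, channels_by_node: dict[str, np.ndarray],
                             catalog: pd.DataFrame,
                             method: str = "refit",
                             prune_frac: float = 0.05) -> pd.DataFrame:
    """Per-branch signature proportions for a clone tree.

    ``channels_by_node`` maps each cluster to its channel count vector.
    ``refit`` (default) runs NNLS on each branch's counts; ``probability``
    sums per-mutation posterior probabilities under the tree-wide fit.
    Branches with one mutation are flagged low-confidence; empty branches
    yield all-zero rows.
    """
    nodes = list(tree.nodes)
    out = pd.DataFrame(0.0, index=nodes, columns=catalog.columns)
    flagged = []
    if method == "probability":
        total = np.sum([channels_by_node.get(n, np.zeros(catalog.shape[0]))
                        for n in nodes], axis=0)
        global_expo = fit_exposures_nnls(total, catalog, prune_frac)
        pm = (probability_matrix(global_expo, catalog)
              if global_expo.sum() > 0 else None)
    for n in nodes:
        counts = np.asarray(channels_by_node.get(
            n, np.zeros(catalog.shape[0])), dtype=float)
        tot = counts.sum()
        if tot == 0:
            continue
        if tot == 1:
            flagged.append(n)
        if method == "refit":
            expo = fit_exposures_nnls(counts, catalog, prune_frac)
            if expo.sum() > 0:
                out.loc[n] = expo / expo.sum()
        elif method == "probability":
            if pm is not None:
                mass = pm.values * counts[:, None]
                out.loc[n] = mass.sum(axis=0) / tot
        else:
            raise ValueError(f"unknown method {method!r}")
    out.attrs["low_confidence"] = flagged
    return out


# ---------------------------------------------------------------------------
# De novo extraction (multiplicative-update NMF, KL divergence)
# ---------------------------------------------------------------------------

@dataclass
class NMFResult:
    signatures: pd.DataFrame   # channels x k, columns sum to 1
    exposures: pd.DataFrame    # samples x k
    objective: float
    objective_trace: np.ndarray


def _kl_div(X: np.ndarray, Y: np.ndarray) -> float:
    mask = X > 0
    return float((X[mask] * np.log(X[mask] / Y[mask])).sum() - X.sum() + Y.sum())


def extract_denovo_nnmf(count_matrix, k: int, n_restarts: int = 5,
                        seed: Optional[int] = None, n_iter: int = 500,
                        tol: float = 1e-6) -> NMFResult:
    """De novo signature extraction by KL-NMF with multiplicative updates.

    ``count_matrix`` is samples x channels (DataFrame or array).  The best
    of ``n_restarts`` random initializations by final KL objective is kept;
    the per-iteration objective trace of the winner is returned (it is
    non-increasing, a property of the multiplicative updates).
    """
    X_df = pd.DataFrame(count_matrix)
    X = X_df.values.astype(float)
    n_samples, n_channels = X.shape
    if k < 1 or k > min(n_samples, n_channels):
        raise ValueError(f"rank k={k} outside [1, {min(n_samples, n_channels)}]")
    best = None
    root = np.random.default_rng(seed)
    eps = 1e-12
    for _ in range(n_restarts):
        rng = np.random.default_rng(root.integers(0, 2**31 - 1))
        W = rng.uniform(0.5, 1.5, size=(n_samples, k)) * X.mean()
        H = rng.uniform(0.5, 1.5, size=(k, n_channels))
        trace = []
        prev = np.inf
        for _ in range(n_iter):
            WH = W @ H + eps
            H *= (W.T @ (X / WH)) / np.maximum(W.sum(axis=0)[:, None], eps)
            WH = W @ H + eps
            W *= ((X / WH) @ H.T) / np.maximum(H.sum(axis=1)[None, :], eps)
            obj = _kl_div(X, W @ H + eps)
            trace.append(obj)
            if prev - obj < tol * max(abs(prev), 1.0):
                break
            prev = obj
        if best is None or trace[-1] < best[2]:
            best = (W, H, trace[-1], np.array(trace))
    W, H, obj, trace = best
    scale = H.sum(axis=1)
    scale[scale == 0] = 1.0
    sig = (H / scale[:, None]).T     # channels x k
    expo = W * scale[None, :]
    sig_names = [f"DN{i + 1}" for i in range(k)]
    return NMFResult(
        signatures=pd.DataFrame(sig, index=X_df.columns, columns=sig_names),
        exposures=pd.DataFrame(expo, index=X_df.index, columns=sig_names),
        objective=obj, objective_trace=trace)


def cosine_similarity(a, b) -> float:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))
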