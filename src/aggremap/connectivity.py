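"""Connectivity scoring of an up/down query against a signature library.

Per signature: a weighted Kolmogorov-Smirnov-style enrichment score for
the up and down sets, combined into a two-sided score (wtcs), normalized
within a stratum (ncs) and expressed as a signed percentile (tau) in
[-100, 100]. Perturbagens are summarized by the median tau of their
replicate signatures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synth.signatures import SignatureLibrary

__all__ = ["QuerySignature", "enrichment_score", "wtcs", "score_library",
           "normalize_and_tau", "summarize_perturbagens", "write_gmt",
           "read_gmt"]


@dataclass(frozen=True)
class QuerySignature:
    """Disjoint up/down gene sets."""

    up: tuple
    down: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "up", tuple(self.up))
        object.__setattr__(self, "down", tuple(self.down))
        if not self.up or not self.down:
            raise ValueError("up and down sets must both be non-empty")
        if set(self.up) & set(self.down):
            raise ValueError("up and down sets must be disjoint")

    def restricted_to(self, universe: "set | list") -> "QuerySignature":
        """Drop genes outside the library universe (with a warning)."""
        uni = set(universe)
        up = tuple(g for g in self.up if g in uni)
        down = tuple(g for g in self.down if g in uni)
        missing = (len(self.up) - len(up)) + (len(self.down) - len(down))
        if missing:
            warnings.warn(f"{missing} query genes absent from the library "
                          "universe were dropped", stacklevel=2)
        return QuerySignature(up=up, down=down)


def enrichment_score(
    signature: pd.Series, gene_set, weight_exponent: float = 1.0
) -> float:
    """Weighted KS running-sum enrichment of ``gene_set`` in ``signature``.

    Genes are ranked by descending z-score (ties broken by stable gene-id
    order); hits contribute ``|z|**weight_exponent`` (normalized), misses
    a constant penalty. The score is the maximum running-sum deviation,
    signed by its direction; top-concentrated sets score positive.
    """
    genes = set(gene_set) & set(signature.index)
    if not genes:
        raise ValueError("gene set has empty intersection with the signature")
    ordered = signature.sort_values(ascending=False, kind="mergesort")
    z = ordered.to_numpy(dtype=float)
    hit = np.fromiter((g in genes for g in ordered.index), dtype=bool,
                      count=len(ordered))
    n = len(z)
    n_hit = int(hit.sum())
    if n_hit == n:
        return 1.0
    w = np.abs(z) ** weight_exponent
    w_hit = np.where(hit, w, 0.0)
    total = w_hit.sum()
    if total <= 0:  # all hit weights zero: fall back to unweighted steps
        w_hit = hit.astype(float)
        total = float(n_hit)
    steps = w_hit / total - (~hit) / (n - n_hit)
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    # clamp float accumulation error at the theoretical bounds
    return float(np.clip(running[i], -1.0, 1.0))


def wtcs(
    query: QuerySignature, signature: pd.Series, weight_exponent: float = 1.0
) -> tuple[float, float, float]:
    """Two-sided combined score: ``(es_up - es_down)/2`` when the two
    one-sided scores disagree in sign, else 0 (a coherent query should
    enrich up and down sets at opposite ends).

    Returns ``(wtcs, es_up, es_down)``.
    """
    es_up = enrichment_score(signature, query.up, weight_exponent)
    es_down = enrichment_score(signature, query.down, weight_exponent)
    if es_up * es_down < 0:
        score = (es_up - es_down) / 2.0
    else:
        score = 0.0
    assert -1.0 <= score <= 1.0
    return score, es_up, es_down


def score_library(
    query: QuerySignature,
    library: SignatureLibrary,
    weight_exponent: float = 1.0,
) -> pd.DataFrame:
    """wtcs of the query against every signature in the library."""
    q = query.restricted_to(library.gene_universe)
    rows = []
    for sid in library.signature_ids:
        sig = library.values[sid]
        score, es_up, es_down = wtcs(q, sig, weight_exponent)
        meta = library.meta.loc[sid]
        rows.append({
            "signature_id": sid,
            "perturbagen_id": meta["perturbagen_id"],
            "perturbagen_class": meta.get("perturbagen_class", ""),
            "es_up": es_up,
            "es_down": es_down,
            "wtcs": score,
        })
    return pd.DataFrame(rows)


def normalize_and_tau(
    scores: pd.DataFrame, stratum_col: "str | None" = None
) -> pd.DataFrame:
    """Add stratum-normalized scores (ncs) and signed percentiles (tau).

    ncs divides each wtcs by the mean of same-sign wtcs values within its
    stratum (whole library when ``stratum_col`` is None); a stratum with
    no same-sign scores yields NaN. tau is the signed percentage of other
    stratum members with strictly smaller |ncs|, so the stratum extreme
    reaches +-100 and wtcs = 0 maps to tau = 0.
    """
    out = scores.copy()
    if stratum_col is None:
        groups = [(None, out.index)]
    else:
        groups = list(out.groupby(stratum_col).groups.items())

    ncs = np.full(len(out), np.nan)
    tau = np.full(len(out), np.nan)
    for _, idx in groups:
        loc = out.index.get_indexer(idx)
        w = out.loc[idx, "wtcs"].to_numpy(dtype=float)
        if len(w) < 20:
            warnings.warn(f"stratum with {len(w)} signatures (< 20); "
                          "percentiles are unstable", stacklevel=2)
        mu_pos = w[w > 0].mean() if (w > 0).any() else np.nan
        mu_neg = w[w < 0].mean() if (w < 0).any() else np.nan
        nv = np.empty(len(w))
        for i, wi in enumerate(w):
            if wi > 0:
                nv[i] = wi / mu_pos if np.isfinite(mu_pos) else np.nan
            elif wi < 0:
                nv[i] = wi / abs(mu_neg) if np.isfinite(mu_neg) else np.nan
            else:
                nv[i] = 0.0
        absn = np.abs(nv)
        tv = np.zeros(len(w))
        m = len(w) - 1
        for i in range(len(w)):
            if not np.isfinite(nv[i]):
                tv[i] = np.nan
                continue
            if nv[i] == 0 or m == 0:
                tv[i] = 0.0
                continue
            smaller = np.sum(absn[np.arange(len(w)) != i] < absn[i])
            tv[i] = np.sign(nv[i]) * 100.0 * smaller / m
        ncs[loc] = nv
        tau[loc] = tv

    out["ncs"] = ncs
    out["tau"] = tau
    finite = out["tau"].dropna()
    assert ((finite >= -100) & (finite <= 100)).all()
    return out


def summarize_perturbagens(results: pd.DataFrame, top_k: int = 20) -> pd.DataFrame:
    """Median tau per perturbagen, ranked descending.

    Adds a ``top_{k}`` flag column; class representation among the top
    ranks can be read off ``perturbagen_class``.
    """
    if results.empty:
        raise ValueError("no connectivity results to summarize")
    agg = (
        results.groupby("perturbagen_id")
        .agg(median_tau=("tau", "median"),
             n_signatures=("tau", "size"),
             perturbagen_class=("perturbagen_class", "first"))
        .sort_values("median_tau", ascending=False)
        .reset_index()
    )
    agg[f"top_{top_k}"] = np.arange(len(agg)) < top_k
    return agg


def write_gmt(path, sets: dict) -> None:
    """Write gene sets as GMT lines: name, description, genes..."""
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, name] + [str(g) for g in genes]) + "\n")


def read_gmt(path) -> dict:
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = tuple(parts[2:])
    return sets
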