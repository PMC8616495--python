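"""Synthetic perturbagen signature libraries with planted structure.

Each signature is a z-scored gene vector over a shared universe.
Perturbagens fall into three classes relative to a designated query
template: ``concordant`` (positively correlated), ``discordant``
(negatively correlated), and ``null`` (independent). Replicate signatures
of one perturbagen share a latent component so they agree with each other.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SignatureLibrary", "generate_signature_library",
           "write_library_tsv", "read_library_tsv"]

CLASSES = ("concordant", "discordant", "null")


@dataclass
class SignatureLibrary:
    """Library of z-scored signatures plus metadata and the planted template.

    ``values``: DataFrame, index = gene ids, columns = signature ids.
    ``meta``: DataFrame indexed by signature id with columns
    (perturbagen_id, perturbagen_class).
    ``template``: Series over the gene universe that the concordant class
    was built to follow.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    template: pd.Series

    @property
    def gene_universe(self) -> list[str]:
        return list(self.values.index)

    @property
    def signature_ids(self) -> list[str]:
        return list(self.values.columns)


def _class_counts(n: int, fractions: dict) -> dict:
    """Largest-remainder apportionment of n perturbagens into classes."""
    raw = {c: n * fractions.get(c, 0.0) for c in CLASSES}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    short = n - sum(counts.values())
    order = sorted(CLASSES, key=lambda c: raw[c] - counts[c], reverse=True)
    for c in order[:short]:
        counts[c] += 1
    return counts


def generate_signature_library(
    gene_universe: "int | list[str]" = 1000,
    n_perturbagens: int = 100,
    class_fractions: "dict | None" = None,
    replicates: int = 3,
    seed: int = 0,
    *,
    concordance: float = 0.75,
    discordance: float = 0.10,
    replicate_share: float = 0.5,
) -> SignatureLibrary:
    """Build a library with planted concordant/discordant/null classes.

    ``concordance`` is the correlation of concordant-class signatures
    with the template; ``discordance`` is the magnitude of the (negative)
    correlation for the discordant class. ``replicate_share`` is the
    fraction of residual variance shared across a perturbagen's
    replicates.
    """
    if class_fractions is None:
        class_fractions = {"concordant": 0.17, "discordant": 0.13, "null": 0.70}
    total = sum(class_fractions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"class fractions must sum to 1, got {total}")
    if not (0.0 <= concordance < 1.0) or not (0.0 <= discordance < 1.0):
        raise ValueError("concordance and discordance must be in [0, 1)")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")

    if isinstance(gene_universe, int):
        genes = [f"G{i:05d}" for i in range(gene_universe)]
    else:
        genes = [str(g) for g in gene_universe]
    n_genes = len(genes)
    if n_genes < 10:
        raise ValueError(f"gene universe too small ({n_genes} genes)")

    rng = np.random.default_rng(seed)
    template = rng.normal(0.0, 1.0, n_genes)

    counts = _class_counts(n_perturbagens, class_fractions)
    labels = [c for c in CLASSES for _ in range(counts[c])]

    cols, meta_rows = [], []
    values = np.empty((n_genes, n_perturbagens * replicates))
    j = 0
    for pi, cls in enumerate(labels):
        pid = f"P{pi:04d}"
        rho = {"concordant": concordance, "discordant": -discordance,
               "null": 0.0}[cls]
        resid = np.sqrt(1.0 - rho**2)
        a = resid * np.sqrt(replicate_share)      # perturbagen-level latent
        b = resid * np.sqrt(1.0 - replicate_share)  # replicate-level noise
        latent = rng.normal(0.0, 1.0, n_genes)
        for r in range(replicates):
            eps = rng.normal(0.0, 1.0, n_genes)
            sig = rho * template + a * latent + b * eps
            sid = f"{pid}_r{r}"
            values[:, j] = sig
            cols.append(sid)
            meta_rows.append({"signature_id": sid, "perturbagen_id": pid,
                              "perturbagen_class": cls})
            j += 1

    vals = pd.DataFrame(values, index=genes, columns=cols)
    meta = pd.DataFrame(meta_rows).set_index("signature_id")
    return SignatureLibrary(values=vals, meta=meta,
                            template=pd.Series(template, index=genes))


def write_library_tsv(lib: SignatureLibrary, values_path: "str | Path",
                      meta_path: "str | Path") -> None:
    lib.values.to_csv(values_path, sep="\t", index_label="gene")
    lib.meta.to_csv(meta_path, sep="\t")


def read_library_tsv(values_path: "str | Path",
                     meta_path: "str | Path") -> SignatureLibrary:
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    template = pd.Series(np.nan, index=values.index)
    return SignatureLibrary(values=values, meta=meta, template=template)
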