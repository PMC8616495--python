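"""Synthetic gene-expression panels with genes planted on aggregation parameters.

Emulates a log-expression matrix (genes x cell lines) in which a small,
recorded set of genes is linearly coupled to per-line aggregation
parameters, and every other gene is independent of them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ExpressionPanel", "generate_expression_panel",
           "write_expression_tsv", "read_expression_tsv"]


@dataclass
class ExpressionPanel:
    """Genes x cell-lines log-expression matrix with planted-gene metadata.

    ``matrix``: DataFrame, index = gene ids, columns = line ids.
    ``planted``: DataFrame with columns (gene, parameter, sign, beta,
    noise_sd) describing each coupled gene.
    ``params``: lines x parameters DataFrame used to plant the signal.
    """

    matrix: pd.DataFrame
    planted: pd.DataFrame
    params: pd.DataFrame

    @property
    def gene_ids(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def line_ids(self) -> list[str]:
        return list(self.matrix.columns)


def generate_expression_panel(
    params_per_line: pd.DataFrame,
    n_genes: int = 1000,
    n_planted_per_parameter: int = 10,
    effect_size: float = 2.0,
    noise_sd: float = 0.5,
    seed: int = 0,
    *,
    baseline_mean: float = 7.0,
    baseline_sd: float = 1.5,
    null_sd: float = 1.0,
) -> ExpressionPanel:
    """Generate a panel whose planted genes track the given parameters.

    For each parameter column, ``n_planted_per_parameter`` genes get
    ``expr = baseline + beta * z(parameter) + N(0, noise_sd)`` with
    ``beta = +-effect_size`` (alternating signs); all remaining genes are
    ``baseline + N(0, null_sd)``, independent of the parameters.

    Raises
    ------
    ValueError
        On fewer than 3 lines, too many planted genes, or a zero-variance
        parameter column (named in the message).
    """
    params = pd.DataFrame(params_per_line).astype(float)
    n_lines = len(params)
    if n_lines < 3:
        raise ValueError(f"need >= 3 cell lines, got {n_lines}")
    n_params = params.shape[1]
    if n_planted_per_parameter * n_params > n_genes:
        raise ValueError(
            f"{n_planted_per_parameter} planted genes x {n_params} parameters "
            f"exceeds n_genes={n_genes}"
        )
    sds = params.std(ddof=0)
    for col, sd in sds.items():
        if sd == 0:
            raise ValueError(f"parameter column {col!r} has zero variance")
    z = (params - params.mean()) / sds  # lines x params, standardized

    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    line_ids = [str(c) for c in params.index]

    baseline = rng.normal(baseline_mean, baseline_sd, n_genes)
    expr = baseline[:, None] + rng.normal(0.0, null_sd, (n_genes, n_lines))

    planted_rows = []
    gi = 0
    for pi, pname in enumerate(params.columns):
        for j in range(n_planted_per_parameter):
            sign = 1.0 if j % 2 == 0 else -1.0
            beta = sign * effect_size
            expr[gi] = (
                baseline[gi]
                + beta * z.iloc[:, pi].to_numpy()
                + rng.normal(0.0, noise_sd, n_lines)
            )
            planted_rows.append(
                {"gene": gene_ids[gi], "parameter": str(pname), "sign": int(sign),
                 "beta": beta, "noise_sd": noise_sd}
            )
            gi += 1

    matrix = pd.DataFrame(expr, index=gene_ids, columns=line_ids)
    planted = pd.DataFrame(
        planted_rows, columns=["gene", "parameter", "sign", "beta", "noise_sd"]
    )
    out_params = params.copy()
    out_params.index = line_ids
    return ExpressionPanel(matrix=matrix, planted=planted, params=out_params)


def write_expression_tsv(panel: ExpressionPanel, path: "str | Path") -> None:
    """Write the matrix as genes-by-lines TSV with a header row of line ids."""
    pd.DataFrame(panel.matrix).to_csv(path, sep="\t", index_label="gene")


def read_expression_tsv(path: "str | Path") -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
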