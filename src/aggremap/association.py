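"""Sparse PLS linking aggregation parameters to gene expression.

Regression-mode sparse partial least squares: per component, the leading
direction of the X-Y cross-covariance is computed by alternating
iterations, with the X-weight vector soft-thresholded each pass so that
exactly ``keep_x`` genes survive (an L1-style selection). Components are
extracted from successively deflated matrices.

Gene selections are split by loading sign, with the component sign
anchored so its score correlates positively with the named parameter
group; selections map onto up/down query gene sets for connectivity
scoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SPLSConfig", "SPLSFit", "GeneSelection", "fit_spls",
           "select_genes", "build_query_signature", "DEFAULT_GROUPS"]

# default interpretation: component 1 against AUC + area-2h, component 2
# against circularity; overridable via select_genes(anchor_params=...)
DEFAULT_GROUPS = {
    0: ("AUC+area-2h", ("auc", "area_2h")),
    1: ("circularity", ("circularity_end",)),
}


@dataclass(frozen=True)
class SPLSConfig:
    n_components: int = 2
    keep_x: int = 300
    scale: bool = True
    max_iter: int = 500
    tol: float = 1e-9

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.keep_x < 1:
            raise ValueError("keep_x must be >= 1")


@dataclass
class SPLSFit:
    """Fitted sparse PLS model.

    ``x_weights``: (genes x components), exactly ``keep_x`` nonzeros per
    column. ``y_weights``: (parameters x components). Scores are
    (lines x components) for each block. ``explained_cov`` is the
    cross-covariance captured per component.
    """

    x_weights: np.ndarray
    y_weights: np.ndarray
    x_scores: np.ndarray
    y_scores: np.ndarray
    explained_cov: np.ndarray
    gene_ids: list
    param_names: list
    config: SPLSConfig
    dropped_genes: list = field(default_factory=list)


def _soft_threshold_keep(a: np.ndarray, keep: int, gene_ids: list) -> np.ndarray:
    """Soft-threshold ``a`` so exactly ``keep`` entries are nonzero.

    The threshold is the largest excluded |a|; ties at the boundary are
    broken deterministically (larger |a| first, then lexicographic gene
    id) and tied survivors get a minimal positive magnitude so the
    nonzero count is exact.
    """
    p = len(a)
    if keep >= p:
        return a.copy()
    absa = np.abs(a)
    order = sorted(range(p), key=lambda i: (-absa[i], str(gene_ids[i])))
    selected = order[:keep]
    lam = absa[order[keep]]
    w = np.zeros(p)
    tiny = max(1e-12, 1e-9 * absa[order[0]])
    for i in selected:
        mag = absa[i] - lam
        if mag <= 0:  # tie with the cut: keep it at a minimal magnitude
            mag = tiny
        w[i] = np.sign(a[i]) * mag
    return w


def fit_spls(
    X: "pd.DataFrame | np.ndarray",
    Y: "pd.DataFrame | np.ndarray",
    config: "SPLSConfig | None" = None,
) -> SPLSFit:
    """Fit regression-mode sparse PLS.

    ``X`` is genes x lines (the expression-export orientation) and is
    transposed internally to lines x genes; ``Y`` is lines x parameters.
    Columns of both blocks are standardized when ``config.scale`` (the
    default). Constant genes are dropped with a warning. A zero-variance
    ``Y`` block is rejected as degenerate.
    """
    if config is None:
        config = SPLSConfig()

    if isinstance(X, pd.DataFrame):
        gene_ids = list(X.index)
        line_ids = list(X.columns)
        Xmat = X.to_numpy(dtype=float).T  # -> lines x genes
    else:
        Xmat = np.asarray(X, dtype=float).T
        gene_ids = [f"G{i:05d}" for i in range(Xmat.shape[1])]
        line_ids = list(range(Xmat.shape[0]))

    if isinstance(Y, pd.DataFrame):
        param_names = [str(c) for c in Y.columns]
        Ymat = Y.loc[line_ids].to_numpy(dtype=float) if set(line_ids) <= set(Y.index) \
            else Y.to_numpy(dtype=float)
    else:
        Ymat = np.asarray(Y, dtype=float)
        if Ymat.ndim == 1:
            Ymat = Ymat[:, None]
        param_names = [f"y{i}" for i in range(Ymat.shape[1])]

    n = Xmat.shape[0]
    if n < 3:
        raise ValueError(f"need >= 3 lines, got {n}")
    if Ymat.shape[0] != n:
        raise ValueError("X and Y disagree on the number of lines")
    if np.isnan(Xmat).any() or np.isnan(Ymat).any():
        raise ValueError("missing values present; impute before fitting")
    if not np.any(Ymat.std(axis=0) > 0):
        raise ValueError("degenerate response: Y has no variance")

    # drop constant genes
    xsd = Xmat.std(axis=0, ddof=0)
    keep_cols = xsd > 0
    dropped = [g for g, k in zip(gene_ids, keep_cols) if not k]
    if dropped:
        warnings.warn(f"dropping {len(dropped)} constant gene columns", stacklevel=2)
        Xmat = Xmat[:, keep_cols]
        gene_ids = [g for g, k in zip(gene_ids, keep_cols) if k]
        xsd = xsd[keep_cols]

    p = Xmat.shape[1]
    q = Ymat.shape[1]
    keep_x = config.keep_x
    if keep_x > p:
        raise ValueError(f"keep_x={keep_x} exceeds the {p} usable genes")
    H = config.n_components
    if H > min(n, p, max(q, 1)) and H > q:
        # more components than Y directions is permitted (deflation keeps
        # going) but beyond min(n, p) the problem is empty
        if H > min(n, p):
            raise ValueError(f"n_components={H} exceeds min(n, p) = {min(n, p)}")

    Xd = Xmat - Xmat.mean(axis=0)
    Yd = Ymat - Ymat.mean(axis=0)
    if config.scale:
        Xd = Xd / xsd
        ysd = Yd.std(axis=0, ddof=0)
        ysd[ysd == 0] = 1.0
        Yd = Yd / ysd

    W = np.zeros((p, H))
    C = np.zeros((q, H))
    Tt = np.zeros((n, H))
    U = np.zeros((n, H))
    expl = np.zeros(H)

    for h in range(H):
        M = Xd.T @ Yd  # p x q cross-covariance (up to 1/n)
        # init v from the leading eigenvector of M'M (q x q, tiny)
        mm = M.T @ M
        evals, evecs = np.linalg.eigh(mm)
        v = evecs[:, -1]
        w = np.zeros(p)
        for it in range(config.max_iter):
            a = M @ v
            w_new = _soft_threshold_keep(a, keep_x, gene_ids)
            nrm = np.linalg.norm(w_new)
            if nrm == 0:
                raise RuntimeError(
                    f"component {h + 1}: all X-weights thresholded to zero"
                )
            w_new /= nrm
            b = M.T @ w_new
            bn = np.linalg.norm(b)
            if bn == 0:
                w = w_new
                break
            v = b / bn
            if np.linalg.norm(w_new - w) < config.tol:
                w = w_new
                break
            w = w_new
        else:
            raise RuntimeError(
                f"component {h + 1}: no convergence after {config.max_iter} "
                f"iterations (last weight change above tol={config.tol})"
            )

        t = Xd @ w
        tt = float(t @ t)
        if tt == 0:
            raise RuntimeError(f"component {h + 1}: zero X-score variance")
        c = (Yd.T @ t) / tt
        u = Yd @ (c / max(np.linalg.norm(c), 1e-30))
        W[:, h], C[:, h], Tt[:, h], U[:, h] = w, c, t, u
        expl[h] = abs(w @ (Xd.T @ Yd) @ v)

        # regression-mode deflation of both blocks by the X-scores
        pload = (Xd.T @ t) / tt
        Xd = Xd - np.outer(t, pload)
        Yd = Yd - np.outer(t, c)

    return SPLSFit(x_weights=W, y_weights=C, x_scores=Tt, y_scores=U,
                   explained_cov=expl, gene_ids=gene_ids,
                   param_names=param_names, config=config,
                   dropped_genes=dropped)


@dataclass
class GeneSelection:
    """Signed gene selection for one component / parameter group."""

    group_label: str
    positive: list
    negative: list
    loadings: pd.Series

    def __post_init__(self) -> None:
        if set(self.positive) & set(self.negative):
            raise ValueError("positive and negative gene lists overlap")


def select_genes(
    fit: SPLSFit,
    component: int = 0,
    group_label: "str | None" = None,
    anchor_params: "tuple | None" = None,
) -> GeneSelection:
    """Split a component's nonzero loadings by sign.

    The component sign is anchored so that the summed Y-weight of the
    anchor parameters is positive (a wholesale sign flip of the fit then
    yields the identical selection). Default anchors follow
    ``DEFAULT_GROUPS``.
    """
    if not (0 <= component < fit.x_weights.shape[1]):
        raise IndexError(f"component {component} not fitted")
    w = fit.x_weights[:, component].copy()
    if not np.any(w):
        raise ValueError(f"component {component} has all-zero loadings")

    if group_label is None or anchor_params is None:
        default_label, default_anchor = DEFAULT_GROUPS.get(
            component, (f"component-{component + 1}", tuple(fit.param_names))
        )
        group_label = group_label or default_label
        anchor_params = anchor_params or default_anchor

    idx = [i for i, name in enumerate(fit.param_names) if name in anchor_params]
    if not idx:
        raise KeyError(f"anchor parameters {anchor_params} not in fit "
                       f"({fit.param_names})")
    anchor = float(fit.y_weights[idx, component].sum())
    if anchor < 0:
        w = -w
    ser = pd.Series(w, index=fit.gene_ids)
    nz = ser[ser != 0].sort_values(key=lambda s: -s.abs())
    positive = list(nz[nz > 0].index)
    negative = list(nz[nz < 0].index)
    return GeneSelection(group_label=group_label, positive=positive,
                         negative=negative, loadings=nz)


def build_query_signature(selection: GeneSelection) -> tuple[tuple, tuple]:
    """Map a signed selection to (up, down) gene sets for connectivity.

    Positive loadings become the up set, negative the down set;
    duplicates are removed order-preservingly. Empty lists or up/down
    overlap raise.
    """
    up = tuple(dict.fromkeys(selection.positive))
    down = tuple(dict.fromkeys(selection.negative))
    if not up or not down:
        raise ValueError("both positive and negative gene lists must be non-empty")
    if set(up) & set(down):
        raise ValueError("up and down gene sets overlap")
    return up, down
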