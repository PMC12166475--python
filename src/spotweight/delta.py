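"""Weighted detection via diagonal rescaling of data and design.

For a diagonal weight matrix W, if y ~ N(X beta, Sigma) then
Wy ~ N(WX beta, W Sigma W), and W Sigma W = W C W + tau2 W^2 retains the
spatial-plus-nugget form, so the same GP detector can run on the rescaled
inputs.  The design column fed downstream is the weighted ones column — the
downstream fit must not add its own intercept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datamodel import CountsDataset, RankTable
from .gp import (
    DEFAULT_RIDGE_TOL,
    DEFAULT_EXACT_BELOW,
    DEFAULT_NEIGHBORS,
    GPFit,
    fit_genes,
    rank_genes,
)
from .preprocess import logcpm
from .weights import WeightsMatrix

logger = logging.getLogger("spotweight")

__all__ = ["WeightedDesign", "apply_weights", "detect_weighted"]


@dataclass
class WeightedDesign:
    """One gene's rescaled response and design: Wy and WX."""

    y_w: np.ndarray
    X_w: np.ndarray
    w_col: np.ndarray


def apply_weights(
    y: np.ndarray,
    X: np.ndarray,
    w_col: np.ndarray,
    weight_scale: str = "w",
) -> WeightedDesign:
    """Element-wise rescaling of response and design by one gene's weights.

    ``weight_scale='w'`` multiplies by the weights themselves (the literal
    diagonal-W convention); ``'sqrt'`` multiplies by their square root (the
    common precision-weight convention elsewhere).
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    w_col = np.asarray(w_col, dtype=float)
    if w_col.shape != y.shape or X.shape[0] != len(y):
        raise ValueError("dimension mismatch between y, X and w_col")
    if np.any(w_col <= 0) or not np.all(np.isfinite(w_col)):
        raise ValueError("weights must be strictly positive and finite")
    if weight_scale == "sqrt":
        w_col = np.sqrt(w_col)
    elif weight_scale != "w":
        raise ValueError("weight_scale must be 'w' or 'sqrt'")
    return WeightedDesign(y_w=w_col * y, X_w=w_col[:, None] * X, w_col=w_col)


def detect_weighted(
    data: CountsDataset,
    weights: WeightsMatrix | np.ndarray,
    m: int = DEFAULT_NEIGHBORS,
    exact_below: int = DEFAULT_EXACT_BELOW,
    weight_scale: str = "w",
    ridge_tol: float = DEFAULT_RIDGE_TOL,
) -> tuple[RankTable, list[GPFit]]:
    """Weighted spatially-variable-gene detection.

    Per gene: take logCPM y, the intercept-only design (ones column), rescale
    both by that gene's weight column, and fit the GP with no additional
    intercept.  Ranking is by decreasing likelihood-ratio statistic against
    the matching weighted iid linear model.
    """
    W = weights.values if isinstance(weights, WeightsMatrix) else np.asarray(weights)
    if W.shape != (data.n_spots, data.n_genes):
        raise ValueError(
            f"weights shape {W.shape} does not match dataset "
            f"({data.n_spots} spots x {data.n_genes} genes)"
        )
    if np.any(W <= 0) or not np.all(np.isfinite(W)):
        raise ValueError("weights must be strictly positive and finite")
    if weight_scale == "sqrt":
        W = np.sqrt(W)
    elif weight_scale != "w":
        raise ValueError("weight_scale must be 'w' or 'sqrt'")
    lc = logcpm(data)
    Yw = W * lc.values
    Xw = W.copy()  # weighted ones column, one per gene
    fits = fit_genes(Yw, data.coords, Xcols=Xw, m=m, exact_below=exact_below,
                     ridge_tol=ridge_tol)
    table = rank_genes(fits, data.gene_ids)
    table.method_label = "gp-lr-weighted"
    return table, fits
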