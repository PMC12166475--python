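"""Evaluation machinery: decile signal/background diagnostics, a scalar
mean-rank bias metric, and FDR/TNR/TPR curves averaged over seeds."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import RankTable
from .simulate import SimTruth

logger = logging.getLogger("spotweight")

__all__ = [
    "DecileDiagnostic",
    "ErrorCurves",
    "decile_diagnostic",
    "bias_metric",
    "error_curves",
    "average_over_seeds",
    "tpr_at_fdr",
    "default_alpha_grid",
]


def default_alpha_grid(n_points: int = 200) -> np.ndarray:
    return np.geomspace(1e-4, 0.5, n_points)


@dataclass
class DecileDiagnostic:
    """Genes binned into mean-expression deciles, split into 'signal' (top
    10% of ranks overall) and 'background'."""

    decile: np.ndarray        # per gene, 1..10 (1 = lowest mean)
    is_signal: np.ndarray     # per gene
    signal_counts: np.ndarray     # 10
    background_counts: np.ndarray  # 10
    mean_rank_by_decile: np.ndarray  # 10

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "decile": np.arange(1, 11),
                "n_signal": self.signal_counts,
                "n_background": self.background_counts,
                "mean_rank": self.mean_rank_by_decile,
            }
        )


def decile_diagnostic(
    ranks: RankTable, mean_logcounts: np.ndarray
) -> DecileDiagnostic:
    """Bin genes into deciles of mean logcounts (ties to the lower decile)
    and flag the overall top floor(G/10) ranks as signal."""
    mean_logcounts = np.asarray(mean_logcounts, dtype=float)
    G = ranks.n_genes
    if mean_logcounts.shape != (G,):
        raise ValueError("mean_logcounts length does not match rank table")
    if G < 10:
        raise ValueError("need at least 10 genes for a decile diagnostic")
    order = np.argsort(mean_logcounts, kind="stable")
    decile = np.empty(G, dtype=np.int64)
    for d, chunk in enumerate(np.array_split(order, 10), start=1):
        decile[chunk] = d
    is_signal = ranks.rank <= G // 10
    signal_counts = np.array([(is_signal & (decile == d)).sum() for d in range(1, 11)])
    background_counts = np.array(
        [(~is_signal & (decile == d)).sum() for d in range(1, 11)]
    )
    mean_rank = np.array(
        [ranks.rank[decile == d].mean() if (decile == d).any() else np.nan
         for d in range(1, 11)]
    )
    return DecileDiagnostic(decile, is_signal, signal_counts,
                            background_counts, mean_rank)


def bias_metric(
    ranks: RankTable,
    mean_logcounts: np.ndarray,
    truth: SimTruth | None = None,
) -> float:
    """Spearman correlation between mean logcounts and rank.

    Computed over true SVGs when ``truth`` is given, else over all genes.
    Near 0 means unbiased; negative means high-mean genes get better
    (smaller) ranks.
    """
    mean_logcounts = np.asarray(mean_logcounts, dtype=float)
    if mean_logcounts.shape != (ranks.n_genes,):
        raise ValueError("mean_logcounts length does not match rank table")
    mask = np.ones(ranks.n_genes, dtype=bool)
    if truth is not None:
        if len(truth.is_svg) != ranks.n_genes:
            raise ValueError("truth length does not match rank table")
        mask = truth.is_svg
    m = mean_logcounts[mask]
    r = ranks.rank[mask]
    if np.ptp(m) == 0:
        raise ValueError("bias metric undefined for constant mean logcounts")
    return float(stats.spearmanr(m, r).statistic)


@dataclass
class ErrorCurves:
    """Empirical FDR/TNR/TPR as functions of the p-value threshold alpha."""

    alphas: np.ndarray
    fdr: np.ndarray
    tnr: np.ndarray
    tpr: np.ndarray
    type1: np.ndarray
    n_seeds: int = 1
    per_seed: list["ErrorCurves"] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "alpha": self.alphas,
                "fdr": self.fdr,
                "tnr": self.tnr,
                "tpr": self.tpr,
                "type1": self.type1,
            }
        )


def error_curves(
    pvalues: np.ndarray,
    truth: SimTruth,
    alphas: np.ndarray | None = None,
) -> ErrorCurves:
    """Sweep p-value thresholds: FDR = FP / max(1, FP + TP), TPR = TP / P,
    TNR = TN / N, empirical type-I error = FP / N."""
    pvalues = np.asarray(pvalues, dtype=float)
    labels = np.asarray(truth.is_svg, dtype=bool)
    if pvalues.shape != labels.shape:
        raise ValueError("pvalues and truth must align")
    P = int(labels.sum())
    N = int((~labels).sum())
    if N == 0:
        raise ValueError(
            "no null genes; FDR/TNR undefined (simulate with null_fraction > 0)"
        )
    if alphas is None:
        alphas = default_alpha_grid()
    alphas = np.asarray(alphas, dtype=float)
    disc = pvalues[None, :] <= alphas[:, None]
    tp = (disc & labels[None, :]).sum(axis=1)
    fp = (disc & ~labels[None, :]).sum(axis=1)
    fdr = fp / np.maximum(1, fp + tp)
    tpr = tp / P if P > 0 else np.full(len(alphas), np.nan)
    tnr = (N - fp) / N
    type1 = fp / N
    return ErrorCurves(alphas=alphas, fdr=fdr, tnr=tnr, tpr=tpr, type1=type1)


def average_over_seeds(
    run: Callable[[int], ErrorCurves], seeds: Sequence[int]
) -> ErrorCurves:
    """Pointwise mean of per-seed curves (per-seed curves retained)."""
    if len(seeds) < 1:
        raise ValueError("need at least one seed")
    curves = [run(s) for s in seeds]
    ref = curves[0].alphas
    for c in curves[1:]:
        if not np.array_equal(c.alphas, ref):
            raise ValueError("per-seed curves use different alpha grids")
    return ErrorCurves(
        alphas=ref.copy(),
        fdr=np.mean([c.fdr for c in curves], axis=0),
        tnr=np.mean([c.tnr for c in curves], axis=0),
        tpr=np.mean([c.tpr for c in curves], axis=0),
        type1=np.mean([c.type1 for c in curves], axis=0),
        n_seeds=len(seeds),
        per_seed=curves,
    )


def tpr_at_fdr(curves: ErrorCurves, fdr_targets: np.ndarray) -> np.ndarray:
    """Best TPR achieved at or below each target FDR (0 when unattainable)."""
    fdr_targets = np.asarray(fdr_targets, dtype=float)
    out = np.zeros_like(fdr_targets)
    for i, f in enumerate(fdr_targets):
        ok = curves.fdr <= f
        out[i] = curves.tpr[ok].max() if ok.any() else 0.0
    return out
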