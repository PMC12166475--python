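"""Reproducible simulation benchmarks: weighted vs unweighted detection.

One benchmark = simulate a dataset, filter genes, run unweighted detection,
estimate precision weights (reusing the unweighted fits), run weighted
detection, and summarize mean-rank bias plus error curves against the ground
truth.  Used by the acceptance suite and the report script.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

import numpy as np

from .datamodel import RankTable
from .delta import detect_weighted
from .evaluate import ErrorCurves, bias_metric, error_curves, tpr_at_fdr
from .gp import detect
from .preprocess import filter_genes, logcpm
from .simulate import SimConfig, SimTruth, simulate_dataset
from .weights import estimate_weights

logger = logging.getLogger("spotweight")

__all__ = ["BenchmarkResult", "run_benchmark", "matched_tpr", "power_at_alpha"]


@dataclass
class BenchmarkResult:
    seed: int
    lengthscale: float
    n_spots: int
    n_genes: int
    truth: SimTruth
    ranks_unweighted: RankTable
    ranks_weighted: RankTable
    mean_logcounts: np.ndarray
    bias_unweighted: float
    bias_weighted: float
    curves_unweighted: ErrorCurves
    curves_weighted: ErrorCurves
    runtime_s: float


def _subset_truth(truth: SimTruth, keep: np.ndarray) -> SimTruth:
    return SimTruth(
        beta=truth.beta[keep],
        sigma2=truth.sigma2[keep],
        lengthscale=truth.lengthscale[keep],
        is_svg=truth.is_svg[keep],
        gene_ids=[g for g, k in zip(truth.gene_ids, keep) if k],
    )


def run_benchmark(
    seed: int,
    lengthscale: float = 100.0,
    n_genes: int = 1000,
    grid_rows: int = 31,
    grid_cols: int = 32,
    null_fraction: float = 0.5,
    m: int = 15,
    exact_below: int = 300,
) -> BenchmarkResult:
    """Simulate, detect with and without precision weights, evaluate."""
    t0 = time.time()
    cfg = SimConfig(
        n_genes=n_genes, grid_rows=grid_rows, grid_cols=grid_cols,
        lengthscale=lengthscale, null_fraction=null_fraction, seed=seed,
    )
    data, truth = simulate_dataset(cfg)
    kept = filter_genes(data)
    keep = np.isin(np.array(data.gene_ids), np.array(kept.gene_ids))
    truth_kept = _subset_truth(truth, keep)

    unw, fits = detect(kept, m=m, exact_below=exact_below)
    weights = estimate_weights(kept, m=m, exact_below=exact_below, fits=fits)
    wt, _ = detect_weighted(kept, weights, m=m, exact_below=exact_below)

    lc = logcpm(kept)
    result = BenchmarkResult(
        seed=seed,
        lengthscale=lengthscale,
        n_spots=kept.n_spots,
        n_genes=kept.n_genes,
        truth=truth_kept,
        ranks_unweighted=unw,
        ranks_weighted=wt,
        mean_logcounts=lc.mean_logcounts,
        bias_unweighted=bias_metric(unw, lc.mean_logcounts, truth_kept),
        bias_weighted=bias_metric(wt, lc.mean_logcounts, truth_kept),
        curves_unweighted=error_curves(unw.pvalue, truth_kept),
        curves_weighted=error_curves(wt.pvalue, truth_kept),
        runtime_s=time.time() - t0,
    )
    logger.info(
        "benchmark seed=%d l=%g: bias %.3f -> %.3f (%.0fs)",
        seed, lengthscale, result.bias_unweighted, result.bias_weighted,
        result.runtime_s,
    )
    return result


def power_at_alpha(
    results: list[BenchmarkResult], alpha: float = 0.05
) -> tuple[float, float]:
    """Seed-averaged true-positive rate of both methods at one p-value
    threshold.  Returns ``(tpr_unweighted, tpr_weighted)``."""
    tu, tw = [], []
    for r in results:
        sv = r.truth.is_svg
        tu.append(float((r.ranks_unweighted.pvalue[sv] <= alpha).mean()))
        tw.append(float((r.ranks_weighted.pvalue[sv] <= alpha).mean()))
    return float(np.mean(tu)), float(np.mean(tw))


def matched_tpr(
    results: list[BenchmarkResult],
    fdr_targets: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Seed-averaged TPR of both methods at matched achieved-FDR targets.

    Returns ``(targets, tpr_unweighted, tpr_weighted)`` restricted to FDR
    targets that BOTH seed-averaged curves actually achieve (comparing a
    method at an error level it never attains would be meaningless).
    """
    if fdr_targets is None:
        fdr_targets = np.linspace(0.01, 0.5, 50)
    fdr_targets = np.asarray(fdr_targets, dtype=float)
    # a target is "matched" when every run of both methods achieves it
    min_u = max(r.curves_unweighted.fdr.min() for r in results)
    min_w = max(r.curves_weighted.fdr.min() for r in results)
    ok = fdr_targets >= max(min_u, min_w)
    targets = fdr_targets[ok]
    tpr_u = np.mean([tpr_at_fdr(r.curves_unweighted, targets) for r in results],
                    axis=0)
    tpr_w = np.mean([tpr_at_fdr(r.curves_weighted, targets) for r in results],
                    axis=0)
    return targets, tpr_u, tpr_w
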