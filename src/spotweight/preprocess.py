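"""Gene filtering and logCPM normalization.

The pipeline always filters genes first and then recomputes library sizes on
the filtered matrix, so the normalization reflects the retained genes only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .datamodel import CountsDataset, ValidationError

logger = logging.getLogger("spotweight")

__all__ = ["LogCPMMatrix", "filter_genes", "filter_genes_umi", "logcpm"]

LOG2_1E6 = math.log2(1e6)


class EmptyResultError(ValueError):
    """Every gene was removed by a filter."""


@dataclass
class LogCPMMatrix:
    """log2 counts-per-million values with the library sizes that produced them."""

    values: np.ndarray          # n_spots x n_genes
    lib_sizes: np.ndarray       # n_spots, total UMIs per spot
    mean_logcounts: np.ndarray  # n_genes, per-gene mean over spots
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.lib_sizes = np.asarray(self.lib_sizes)
        self.mean_logcounts = np.asarray(self.mean_logcounts, dtype=float)
        n, G = self.values.shape
        if self.lib_sizes.shape != (n,):
            raise ValidationError("lib_sizes length mismatch")
        if self.mean_logcounts.shape != (G,):
            raise ValidationError("mean_logcounts length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("logCPM values must be finite")


def filter_genes(
    data: CountsDataset, min_count: int = 2, min_prop_spots: float = 0.002
) -> CountsDataset:
    """Keep genes with at least ``min_count`` counts in at least
    ``ceil(min_prop_spots * n_spots)`` spots (default: >=2 counts in >=0.2%
    of spots)."""
    if not (0 < min_prop_spots <= 1):
        raise ValueError("min_prop_spots must be in (0, 1]")
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    n = data.n_spots
    need = math.ceil(min_prop_spots * n)
    n_hit = (data.counts >= min_count).sum(axis=0)
    keep = n_hit >= need
    if not keep.any():
        raise EmptyResultError(
            "all genes removed by expression filter; lower min_count or "
            "min_prop_spots"
        )
    out = data.subset_genes(keep)
    logger.info("filter_genes: %d -> %d genes", data.n_genes, out.n_genes)
    return out


def filter_genes_umi(data: CountsDataset, min_total_umi: int = 80) -> CountsDataset:
    """Keep genes whose total UMI count over all spots is >= ``min_total_umi``."""
    if min_total_umi < 0:
        raise ValueError("min_total_umi must be >= 0")
    keep = data.counts.sum(axis=0) >= min_total_umi
    if not keep.any():
        raise EmptyResultError(
            "all genes removed by UMI filter; lower min_total_umi"
        )
    out = data.subset_genes(keep)
    logger.info("filter_genes_umi: %d -> %d genes", data.n_genes, out.n_genes)
    return out


def logcpm(data: CountsDataset) -> LogCPMMatrix:
    """log2 counts-per-million with pseudocounts.

    ``y[i, g] = log2((counts[i, g] + 0.5) / (R_i + 1) * 1e6)`` where ``R_i``
    is the spot's total UMI count.  The pseudocounts keep every entry finite,
    including spots with zero library size (which are retained with a
    warning).
    """
    R = data.counts.sum(axis=1)
    if np.any(R == 0):
        logger.warning("%d spot(s) have zero library size; retained", int((R == 0).sum()))
    y = np.log2((data.counts + 0.5) / (R[:, None] + 1.0) * 1e6)
    return LogCPMMatrix(
        values=y,
        lib_sizes=R,
        mean_logcounts=y.mean(axis=0),
        gene_ids=list(data.gene_ids),
    )
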