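"""Synthetic spatial count data: Poisson counts with a GP log-rate on a
hexagonal (Visium-like) spot lattice, with per-gene ground truth labels."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import cholesky
from scipy.spatial.distance import pdist, squareform

from .datamodel import CountsDataset

logger = logging.getLogger("spotweight")

__all__ = [
    "SimConfig",
    "SimTruth",
    "make_hexgrid",
    "simulate_dataset",
    "lengthscale_to_scaled",
    "write_truth",
    "read_truth",
]

LN_HALF = math.log(0.5)


@dataclass
class SimConfig:
    n_genes: int = 1000
    grid_rows: int = 31
    grid_cols: int = 32
    spacing: float = 100.0
    lengthscale: float = 100.0
    sigma2_range: tuple[float, float] = (0.2, 1.0)
    beta_range: tuple[float, float] = (LN_HALF, 0.0)
    null_fraction: float = 0.0
    kernel: str = "squared_exponential"
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("n_genes, grid_rows, grid_cols must be >= 1")
        if not (0 <= self.null_fraction <= 1):
            raise ValueError("null_fraction must be in [0, 1]")
        for lo, hi in (self.sigma2_range, self.beta_range):
            if lo > hi:
                raise ValueError("ranges must be ordered lo <= hi")
        if self.kernel not in ("squared_exponential", "exponential"):
            raise ValueError("kernel must be 'squared_exponential' or 'exponential'")
        if self.lengthscale <= 0 or self.spacing <= 0:
            raise ValueError("lengthscale and spacing must be positive")


@dataclass
class SimTruth:
    """Per-gene generative parameters; a gene is a true SVG iff sigma2 > 0."""

    beta: np.ndarray
    sigma2: np.ndarray
    lengthscale: np.ndarray
    is_svg: np.ndarray
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.sigma2 = np.asarray(self.sigma2, dtype=float)
        self.lengthscale = np.asarray(self.lengthscale, dtype=float)
        self.is_svg = np.asarray(self.is_svg, dtype=bool)
        if not np.array_equal(self.is_svg, self.sigma2 > 0):
            raise ValueError("is_svg must equal (sigma2 > 0)")


def make_hexgrid(rows: int, cols: int, spacing: float = 100.0) -> np.ndarray:
    """Hexagonally offset lattice: odd rows shifted by spacing/2, row pitch
    spacing * sqrt(3) / 2.  Returns rows*cols points, nearest pair exactly
    ``spacing`` apart."""
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    r, c = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    x = c.ravel() * spacing + (r.ravel() % 2) * spacing / 2.0
    y = r.ravel() * spacing * math.sqrt(3.0) / 2.0
    return np.column_stack([x, y]).astype(float)


def _corr_matrix(coords: np.ndarray, lengthscale: float, kernel: str) -> np.ndarray:
    d = squareform(pdist(coords))
    if kernel == "exponential":
        return np.exp(-d / lengthscale)
    return np.exp(-(d ** 2) / (2.0 * lengthscale ** 2))


def simulate_dataset(
    config: SimConfig, return_latent: bool = False
) -> tuple[CountsDataset, SimTruth] | tuple[CountsDataset, SimTruth, np.ndarray]:
    """Draw counts c_i ~ Poisson(exp(beta_g + eta_gi)) with eta_g a zero-mean
    GP draw of variance sigma2_g and the configured shared lengthscale.

    Per gene: beta ~ Uniform(beta_range); with probability ``null_fraction``
    sigma2 = 0, otherwise sigma2 ~ Uniform(sigma2_range), independently of
    beta.  Fully deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed)
    coords = make_hexgrid(config.grid_rows, config.grid_cols, config.spacing)
    n = coords.shape[0]
    G = config.n_genes

    beta = rng.uniform(*config.beta_range, size=G)
    is_null = rng.random(G) < config.null_fraction
    sigma2 = rng.uniform(*config.sigma2_range, size=G)
    sigma2[is_null] = 0.0

    if np.any(sigma2 > 0):
        R = _corr_matrix(coords, config.lengthscale, config.kernel)
        try:
            L = cholesky(R, lower=True)
        except np.linalg.LinAlgError:
            logger.info("correlation matrix not positive definite; adding 1e-8 jitter")
            R[np.diag_indices(n)] += 1e-8
            L = cholesky(R, lower=True)
        z = rng.standard_normal((n, G))
        eta = (L @ z) * np.sqrt(sigma2)[None, :]
    else:
        rng.standard_normal((n, G))  # keep the RNG stream position fixed
        eta = np.zeros((n, G))
    lam = np.exp(beta[None, :] + eta)
    counts = rng.poisson(lam).astype(np.int64)

    width = max(len(str(G)), 4)
    gene_ids = [f"gene{g + 1:0{width}d}" for g in range(G)]
    spot_ids = [f"spot{i + 1:05d}" for i in range(n)]
    data = CountsDataset(counts, coords, gene_ids, spot_ids)
    truth = SimTruth(
        beta=beta,
        sigma2=sigma2,
        lengthscale=np.full(G, config.lengthscale),
        is_svg=sigma2 > 0,
        gene_ids=gene_ids,
    )
    logger.info(
        "simulated %d spots x %d genes (seed=%d, l=%g, null_fraction=%g)",
        n, G, config.seed, config.lengthscale, config.null_fraction,
    )
    if return_latent:
        return data, truth, eta
    return data, truth


def lengthscale_to_scaled(l: float, coords: np.ndarray) -> float:
    """Lengthscale divided by the larger bounding-box dimension."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    extent = float(np.max(coords.max(axis=0) - coords.min(axis=0)))
    if extent <= 0:
        raise ValueError("coordinates have zero extent")
    return l / extent


def write_truth(truth: SimTruth, path: Path | str) -> None:
    pd.DataFrame(
        {
            "gene_id": truth.gene_ids,
            "beta": truth.beta,
            "sigma2": truth.sigma2,
            "lengthscale": truth.lengthscale,
            "is_svg": truth.is_svg.astype(int),
        }
    ).to_csv(path, sep="\t", index=False)


def read_truth(path: Path | str) -> SimTruth:
    df = pd.read_csv(path, sep="\t")
    return SimTruth(
        beta=df["beta"].to_numpy(),
        sigma2=df["sigma2"].to_numpy(),
        lengthscale=df["lengthscale"].to_numpy(),
        is_svg=df["is_svg"].to_numpy().astype(bool),
        gene_ids=[str(g) for g in df["gene_id"]],
    )
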