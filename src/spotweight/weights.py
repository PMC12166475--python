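"""Observation-level precision weights from the empirical mean-variance trend.

Pipeline: logCPM -> per-gene intercept-only GP fit -> residual SD per gene ->
average log-count abscissa (geometric-mean library size) -> smoothing-spline
trend of sqrt(residual SD) -> map each observation's predicted count-scale
value through the trend -> weight = (predicted sqrt SD)^-4.

Predicted values outside the training range of the trend are clamped to the
boundary (no extrapolation), and spline predictions are floored at a small
positive epsilon before the inverse-fourth power, since an unconstrained
spline may dip to or below zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import make_smoothing_spline

from .datamodel import CountsDataset, ValidationError
from .preprocess import LOG2_1E6, LogCPMMatrix, logcpm
from .gp import (
    DEFAULT_RIDGE_TOL,
    DEFAULT_EXACT_BELOW,
    DEFAULT_NEIGHBORS,
    GPFit,
    fit_genes,
    fitted_values,
)

logger = logging.getLogger("spotweight")

__all__ = [
    "MeanVarCurve",
    "WeightsMatrix",
    "residual_sd",
    "avg_logcount",
    "fit_meanvar_curve",
    "predicted_count_scale",
    "predict_weights",
    "estimate_weights",
    "WeightsResult",
]

DEFAULT_SD_FLOOR = 1e-4
DEFAULT_REL_FLOOR = 0.25  # fraction of the median training sqrt-SD


@dataclass
class MeanVarCurve:
    """Fitted mean-variance trend: sqrt(residual SD) as a function of the
    count-log2 abscissa, valid on [domain_lo, domain_hi]."""

    spline: object            # callable, BSpline from make_smoothing_spline
    domain_lo: float
    domain_hi: float
    train_x: np.ndarray       # per-gene average logcount
    train_y: np.ndarray       # per-gene sqrt(residual SD)
    sd_floor: float = DEFAULT_SD_FLOOR

    def predict_sqrt_sd(self, x: np.ndarray) -> np.ndarray:
        """Evaluate the trend with boundary clamping and a positivity floor."""
        x = np.clip(np.asarray(x, dtype=float), self.domain_lo, self.domain_hi)
        pred = np.asarray(self.spline(x), dtype=float)
        if np.any(pred <= self.sd_floor):
            logger.warning(
                "mean-variance spline predicted %d value(s) <= %g; floored",
                int(np.sum(pred <= self.sd_floor)), self.sd_floor,
            )
            pred = np.maximum(pred, self.sd_floor)
        return pred


@dataclass
class WeightsMatrix:
    """Strictly positive n_spots x n_genes precision weights."""

    values: np.ndarray
    source_curve: MeanVarCurve | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("weights must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("weights must be finite")
        if np.any(self.values <= 0):
            raise ValidationError("weights must be strictly positive")


def residual_sd(y_g: np.ndarray, mu_hat_g: np.ndarray) -> float:
    """sqrt( sum((y - mu)^2) / (n - 1) )."""
    y_g = np.asarray(y_g, dtype=float)
    mu_hat_g = np.asarray(mu_hat_g, dtype=float)
    n = len(y_g)
    if n < 2:
        raise ValueError("residual SD needs at least two observations")
    r = y_g - mu_hat_g
    return math.sqrt(float(r @ r) / (n - 1))


def avg_logcount(mean_logcpm: np.ndarray, lib_sizes: np.ndarray) -> np.ndarray:
    """Average log-count per gene: mean logCPM shifted by the log2 geometric
    mean of library sizes, minus log2(1e6).

    The geometric mean is computed in log space, exp(mean(log R_i)); if any
    library size is zero the mean is taken over R_i + 1 with a warning.
    """
    mean_logcpm = np.asarray(mean_logcpm, dtype=float)
    R = np.asarray(lib_sizes, dtype=float)
    if np.any(R < 0):
        raise ValueError("library sizes must be non-negative")
    if np.any(R == 0):
        logger.warning("zero library size(s); geometric mean uses R + 1")
        R = R + 1.0
    log_gm = float(np.mean(np.log(R)))  # natural log; convert below
    return mean_logcpm + log_gm / math.log(2.0) - LOG2_1E6


def fit_meanvar_curve(
    r_tilde: np.ndarray,
    resid_sd: np.ndarray,
    sd_floor: float = DEFAULT_SD_FLOOR,
    rel_floor: float = DEFAULT_REL_FLOOR,
) -> MeanVarCurve:
    """Cubic smoothing spline of sqrt(residual SD) on average logcount.

    Smoothness is selected by generalized cross-validation; duplicated
    abscissa values are averaged.  The valid domain is the training range
    (callers must clamp — see :meth:`MeanVarCurve.predict_sqrt_sd`).

    Genes whose spatial fit has a collapsed nugget contribute residual SDs
    near zero; a cliff of such values makes the spline overshoot below zero
    and the inverse-fourth-power weights explode.  Training values (and later
    predictions) are therefore floored at ``max(sd_floor, rel_floor *
    median(sqrt SD))``, which preserves the shape of the trend while bounding
    the weight range.
    """
    r_tilde = np.asarray(r_tilde, dtype=float)
    resid_sd = np.asarray(resid_sd, dtype=float)
    G = len(r_tilde)
    if G < 10:
        raise ValueError(
            f"need at least 10 genes to fit the mean-variance trend, got {G}"
        )
    if len(resid_sd) != G:
        raise ValueError("r_tilde and resid_sd must have equal length")
    if np.any(resid_sd < 0):
        raise ValueError("residual SDs must be non-negative")
    if np.ptp(r_tilde) == 0:
        raise ValueError("all average logcounts identical; trend undefined")
    sqrt_sd = np.sqrt(resid_sd)
    floor = max(sd_floor, rel_floor * float(np.median(sqrt_sd)))
    if np.any(sqrt_sd < floor):
        logger.info("floored %d training sqrt-SD value(s) at %g",
                    int(np.sum(sqrt_sd < floor)), floor)
        sqrt_sd = np.maximum(sqrt_sd, floor)

    order = np.argsort(r_tilde, kind="stable")
    xs, ys = r_tilde[order], sqrt_sd[order]
    ux, inv = np.unique(xs, return_inverse=True)
    if len(ux) < len(xs):
        uy = np.zeros(len(ux))
        cnt = np.zeros(len(ux))
        np.add.at(uy, inv, ys)
        np.add.at(cnt, inv, 1.0)
        uy /= cnt
    else:
        uy = ys
    if len(ux) < 4:
        raise ValueError("too few distinct average logcounts for a cubic spline")
    try:
        spline = make_smoothing_spline(ux, uy)  # lam=None -> GCV
    except ValueError:
        # GCV occasionally reports an ill-posed problem; fall back to a
        # deterministic K-fold cross-validated smoothing parameter
        logger.warning("GCV smoothing selection failed; using K-fold fallback")
        spline = _cv_smoothing_spline(ux, uy)
    return MeanVarCurve(
        spline=spline,
        domain_lo=float(r_tilde.min()),
        domain_hi=float(r_tilde.max()),
        train_x=r_tilde,
        train_y=sqrt_sd,
        sd_floor=floor,
    )


def _cv_smoothing_spline(ux: np.ndarray, uy: np.ndarray, n_folds: int = 5):
    """Pick the smoothing parameter by deterministic K-fold cross-validation."""
    base = max(np.ptp(ux), 1e-12) ** 3 / len(ux)
    candidates = base * np.geomspace(1e-6, 1e8, 29)
    folds = np.arange(len(ux)) % n_folds
    best_lam, best_err = candidates[-1], np.inf
    for lam in candidates:
        err = 0.0
        try:
            for f in range(n_folds):
                tr = folds != f
                if tr.sum() < 4:
                    raise ValueError
                sp = make_smoothing_spline(ux[tr], uy[tr], lam=lam)
                err += float(np.sum((sp(ux[~tr]) - uy[~tr]) ** 2))
        except (ValueError, np.linalg.LinAlgError):
            continue
        if err < best_err:
            best_err, best_lam = err, lam
    return make_smoothing_spline(ux, uy, lam=best_lam)


def predicted_count_scale(mu_hat: np.ndarray, lib_sizes: np.ndarray) -> np.ndarray:
    """Move fitted logCPM values onto the count-log2 scale:
    ``lambda_i = mu_i + log2(R_i + 1) - log2(1e6)``."""
    mu_hat = np.asarray(mu_hat, dtype=float)
    R = np.asarray(lib_sizes, dtype=float)
    return mu_hat + np.log2(R + 1.0) - LOG2_1E6


def predict_weights(curve: MeanVarCurve, lambda_hat: np.ndarray) -> WeightsMatrix:
    """Weights = (predicted sqrt residual SD)^-4 at clamped lambda values."""
    lam = np.asarray(lambda_hat, dtype=float)
    pred = curve.predict_sqrt_sd(lam)
    return WeightsMatrix(values=pred ** -4.0, source_curve=curve)


@dataclass
class WeightsResult:
    """Everything produced along the weight-estimation pipeline."""

    weights: WeightsMatrix
    curve: MeanVarCurve
    fits: list[GPFit]
    logcpm: LogCPMMatrix
    r_tilde: np.ndarray
    resid_sd: np.ndarray
    lambda_hat: np.ndarray


def estimate_weights(
    data: CountsDataset,
    m: int = DEFAULT_NEIGHBORS,
    exact_below: int = DEFAULT_EXACT_BELOW,
    clamp: str = "rtilde",
    sd_floor: float = DEFAULT_SD_FLOOR,
    mu_source: str = "kriging",
    ridge_tol: float = DEFAULT_RIDGE_TOL,
    return_details: bool = False,
    fits: list[GPFit] | None = None,
):
    """End-to-end weight estimation for a (filtered) dataset.

    Parameters
    ----------
    clamp
        ``"rtilde"`` (default) clamps predicted count-scale values to the
        range of the average logcounts; ``"ybar"`` uses the literal range of
        the mean logCPM values instead.
    mu_source
        ``"kriging"`` (default) takes per-observation fitted values from the
        GP (fixed effect plus predicted spatial signal), so the residuals
        isolate the non-spatial noise and the weights vary over space for
        spatially structured genes.  ``"fixed"`` uses the fixed-effect
        prediction x' beta only; with an intercept-only design that makes
        weights vary across spots solely through library size, which is too
        weak a signal to correct the ranking bias — kept for diagnostics.
    fits
        Pre-computed intercept-only GP fits (e.g. from an unweighted
        detection pass) to avoid refitting.
    """
    if clamp not in ("rtilde", "ybar"):
        raise ValueError("clamp must be 'rtilde' or 'ybar'")
    if mu_source not in ("kriging", "fixed"):
        raise ValueError("mu_source must be 'kriging' or 'fixed'")
    lc = logcpm(data)
    if fits is None:
        fits = fit_genes(lc.values, data.coords, m=m, exact_below=exact_below,
                         ridge_tol=ridge_tol)
    elif len(fits) != data.n_genes:
        raise ValueError("fits length does not match gene count")
    if mu_source == "kriging":
        mu = fitted_values(lc.values, data.coords, fits, m=m)
    else:
        mu = np.column_stack([f.mu_hat for f in fits])
    s_g = np.array([residual_sd(lc.values[:, g], mu[:, g])
                    for g in range(data.n_genes)])
    r_t = avg_logcount(lc.mean_logcounts, lc.lib_sizes)
    curve = fit_meanvar_curve(r_t, s_g, sd_floor=sd_floor)
    if clamp == "ybar":
        curve.domain_lo = float(lc.mean_logcounts.min())
        curve.domain_hi = float(lc.mean_logcounts.max())
    lam = mu + np.log2(lc.lib_sizes[:, None] + 1.0) - LOG2_1E6
    weights = predict_weights(curve, lam)
    logger.info("estimate_weights: %d spots x %d genes", *weights.values.shape)
    if return_details:
        return WeightsResult(weights, curve, fits, lc, r_t, s_g, lam)
    return weights
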