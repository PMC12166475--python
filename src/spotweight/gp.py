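"""Per-gene Gaussian-process regression with an exponential kernel + nugget.

Two likelihood backends share one model, y ~ N(X beta, sigma2 * K + tau2 * I)
with K_ij = exp(-||s_i - s_j|| / l):

* a dense (exact) evaluation for small n, and
* a Vecchia / nearest-neighbor factorization for larger n, where each spot is
  conditioned only on its ``m`` nearest previously-ordered neighbors.

Maximum-likelihood fitting comes in two flavours:

* :func:`fit_gene_gp` — the single-gene reference fitter (L-BFGS-B on
  log-transformed parameters, three lengthscale multi-starts);
* :func:`fit_genes` — a batched fitter used by the detection pipeline.  It
  exploits the fact that within one dataset every gene shares the same
  covariance *structure*: the total variance and the regression coefficient
  are profiled out analytically, so the likelihood of all genes can be
  evaluated together for each candidate (spatial-proportion, lengthscale)
  pair on a deterministic grid that is then locally refined.

The likelihood-ratio screen compares each GP fit against the iid linear
model (sigma2 = 0) and refers 2 * (ll_gp - ll_lin) to a chi-square with 2
degrees of freedom, a deliberately conservative reference for this boundary
test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse, stats
from scipy.linalg import cholesky, solve_triangular
from scipy.optimize import minimize
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist, pdist, squareform

from .datamodel import (
    CountsDataset,
    RankTable,
    rank_from_statistic,
)
from .preprocess import logcpm

logger = logging.getLogger("spotweight")

__all__ = [
    "KernelParams",
    "GPFit",
    "exp_kernel",
    "gp_loglik_exact",
    "gp_loglik_nn",
    "fit_gene_gp",
    "fit_genes",
    "rank_genes",
    "morans_i",
    "detect",
    "linear_loglik",
]

LOG2PI = math.log(2.0 * math.pi)
DEFAULT_NEIGHBORS = 15
DEFAULT_EXACT_BELOW = 300
# a spatial fit must beat the iid model by this many log-likelihood units to
# be kept; 2.0 sits at the chi2(2) 0.135 upper quantile, so p-values below
# ~0.13 are unaffected while near-null genes cannot drift to degenerate fits
DEFAULT_RIDGE_TOL = 2.0
_RHO_MAX = 0.9999
_VAR_FLOOR = 1e-300


@dataclass
class KernelParams:
    """Exponential-kernel parameters: spatial variance, nugget, lengthscale."""

    sigma2: float
    tau2: float
    lengthscale: float

    def __post_init__(self) -> None:
        if not np.isfinite([self.sigma2, self.tau2, self.lengthscale]).all():
            raise ValueError("kernel parameters must be finite")
        if self.sigma2 < 0 or self.tau2 < 0:
            raise ValueError("variances must be non-negative")
        if self.lengthscale <= 0:
            raise ValueError("lengthscale must be positive")


@dataclass
class GPFit:
    """Maximum-likelihood fit of the spatial model for one gene."""

    params: KernelParams
    beta_hat: np.ndarray
    loglik: float
    mu_hat: np.ndarray
    lr_stat: float
    pvalue: float
    prop_sv: float
    converged: bool
    n_neighbors_used: int
    lengthscale_scaled: float = float("nan")
    loglik_null: float = float("nan")


def exp_kernel(coords: np.ndarray, params: KernelParams) -> np.ndarray:
    """Dense covariance matrix sigma2 * exp(-d / l) over Euclidean distances."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    d = cdist(coords, coords)
    return params.sigma2 * np.exp(-d / params.lengthscale)


def linear_loglik(y: np.ndarray, X: np.ndarray) -> tuple[float, np.ndarray]:
    """ML log-likelihood of the iid Gaussian linear model (variance profiled)."""
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = len(y)
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    rss = float(np.sum((y - X @ beta) ** 2))
    s2 = max(rss / n, _VAR_FLOOR)
    return -0.5 * n * (LOG2PI + math.log(s2) + 1.0), beta


def gp_loglik_exact(
    y: np.ndarray,
    X: np.ndarray,
    coords: np.ndarray,
    params: KernelParams,
    dense_limit: int = 2000,
) -> tuple[float, np.ndarray]:
    """Exact Gaussian log-likelihood with the GLS-profiled coefficient.

    Computes ``max_beta log N(y; X beta, sigma2 K + tau2 I)`` via a dense
    Cholesky factorization.  Intended for moderate n (``dense_limit`` guard).
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        raise ValueError("X rows must match y length")
    n = len(y)
    if n > dense_limit:
        raise ValueError(f"n={n} exceeds dense limit {dense_limit}")
    if params.sigma2 + params.tau2 <= 0:
        raise np.linalg.LinAlgError(
            "singular covariance: sigma2 + tau2 must be positive"
        )
    Sigma = exp_kernel(coords, params)
    Sigma[np.diag_indices(n)] += params.tau2
    try:
        L = cholesky(Sigma, lower=True)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise np.linalg.LinAlgError(
            f"covariance factorization failed ({exc}); consider a larger nugget"
        )
    yw = solve_triangular(L, y, lower=True)
    Xw = solve_triangular(L, X, lower=True)
    beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    resid = yw - Xw @ beta
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    ll = -0.5 * (n * LOG2PI + logdet + float(resid @ resid))
    return ll, beta


# ---------------------------------------------------------------------------
# Vecchia / nearest-neighbor factorization
# ---------------------------------------------------------------------------

class NNStructure:
    """Ordering and nearest previously-ordered neighbor sets for one geometry.

    Spots are ordered by the sum of their coordinates; spot ``i`` (in
    ordering position i) conditions on its ``min(m, i)`` nearest neighbors
    among positions ``< i``.  Distance blocks are precomputed so that each
    parameter evaluation only exponentiates and solves small systems.
    """

    def __init__(self, coords: np.ndarray, m: int) -> None:
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        n = coords.shape[0]
        if m < 1:
            raise ValueError("neighbor count m must be >= 1")
        self.n = n
        self.m = int(min(m, n - 1))
        self.order = np.argsort(coords.sum(axis=1), kind="stable")
        oc = coords[self.order]
        self._oc = oc
        m_ = self.m

        nbrs = np.zeros((n, m_), dtype=np.intp)
        if n <= 4096:
            D = squareform(pdist(oc))
            for i in range(m_, n):
                idx = np.argpartition(D[i, :i], m_ - 1)[:m_]
                nbrs[i] = idx
        else:
            # prefix-tree blocks: query enough neighbors that at least m
            # precede i in the ordering
            block = 256
            for a in range(m_, n, block):
                b = min(a + block, n)
                tree = cKDTree(oc[:b])
                k = min(b, m_ + (b - a))
                _, idx = tree.query(oc[a:b], k=k)
                for row, i in enumerate(range(a, b)):
                    prev = idx[row][idx[row] < i][:m_]
                    if len(prev) < m_:  # pragma: no cover - fallback
                        d = np.linalg.norm(oc[:i] - oc[i], axis=1)
                        prev = np.argpartition(d, m_ - 1)[:m_]
                    nbrs[i] = prev
        self.nbrs = nbrs

        tail_idx = nbrs[m_:]
        tail_pts = oc[m_:]
        self.d_pn = np.linalg.norm(tail_pts[:, None, :] - oc[tail_idx], axis=2)
        nb_pts = oc[tail_idx]
        self.d_nn = np.linalg.norm(nb_pts[:, :, None, :] - nb_pts[:, None, :, :],
                                   axis=3)
        self.d_pn_head = [np.linalg.norm(oc[:i] - oc[i], axis=1)
                          for i in range(1, m_)]
        self.d_nn_head = [squareform(pdist(oc[:i])) if i > 1 else np.zeros((1, 1))
                          for i in range(1, m_)]

    def factor(self, rho: float, l: float):
        """Unit-variance correlation factorization.

        For R = rho * exp(-d/l) + (1-rho) I returns ``(logdet, A, d)`` where
        rows of the sparse matrix ``A`` hold each spot's conditioning
        coefficients (in ordered index space) and ``d`` the conditional
        variances, so that ``e = (u - A u) / sqrt(d)`` is iid standard normal
        under the model.
        """
        n, m_ = self.n, self.m
        d = np.empty(n)
        d[0] = 1.0
        rows: list[np.ndarray] = []
        cols: list[np.ndarray] = []
        vals: list[np.ndarray] = []

        for i in range(1, m_):
            Knn = rho * np.exp(-self.d_nn_head[i - 1] / l)
            np.fill_diagonal(Knn, 1.0)
            kpn = rho * np.exp(-self.d_pn_head[i - 1] / l)
            b = np.linalg.solve(Knn, kpn)
            d[i] = 1.0 - float(b @ kpn)
            rows.append(np.full(i, i, dtype=np.intp))
            cols.append(np.arange(i, dtype=np.intp))
            vals.append(b)

        if n > m_:
            Knn = rho * np.exp(-self.d_nn / l)
            idx = np.arange(m_)
            Knn[:, idx, idx] = 1.0
            kpn = rho * np.exp(-self.d_pn / l)
            b = np.linalg.solve(Knn, kpn[..., None])[..., 0]
            d[m_:] = 1.0 - np.einsum("ij,ij->i", b, kpn)
            rows.append(np.repeat(np.arange(m_, n), m_))
            cols.append(self.nbrs[m_:].ravel())
            vals.append(b.ravel())

        np.maximum(d, 1e-12, out=d)
        if rows:
            A = sparse.csr_matrix(
                (np.concatenate(vals),
                 (np.concatenate(rows), np.concatenate(cols))),
                shape=(n, n),
            )
        else:  # n == 1 or m_ == 0, not reachable under n >= 2
            A = sparse.csr_matrix((n, n))
        logdet = float(np.sum(np.log(d)))
        return logdet, A, d


def gp_loglik_nn(
    y: np.ndarray,
    X: np.ndarray,
    coords: np.ndarray,
    params: KernelParams,
    m: int = DEFAULT_NEIGHBORS,
    structure: NNStructure | None = None,
) -> tuple[float, np.ndarray]:
    """Vecchia (nearest-neighbor) log-likelihood with GLS-profiled coefficient.

    For ``m >= n - 1`` the factorization conditions on all previous points
    and equals :func:`gp_loglik_exact` exactly.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = len(y)
    v = params.sigma2 + params.tau2
    if v <= 0:
        raise np.linalg.LinAlgError("singular covariance: sigma2 + tau2 must be positive")
    rho = params.sigma2 / v
    if structure is None:
        structure = NNStructure(coords, m)
    logdet_r, A, d = structure.factor(rho, params.lengthscale)
    ord_ = structure.order
    U = np.column_stack([y, X])[ord_]
    E = (U - A @ U) / np.sqrt(d)[:, None]
    ey, EX = E[:, 0], E[:, 1:]
    beta, _, rank, _ = np.linalg.lstsq(EX, ey, rcond=None)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    resid = ey - EX @ beta
    sse = float(resid @ resid)
    ll = -0.5 * (n * LOG2PI + n * math.log(v) + logdet_r + sse / v)
    return ll, beta


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _coord_scale(coords: np.ndarray) -> float:
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    span = float(np.max(coords.max(axis=0) - coords.min(axis=0)))
    if span <= 0:
        raise ValueError("coordinates are degenerate (zero extent)")
    return span


def fit_gene_gp(
    y: np.ndarray,
    X: np.ndarray | None,
    coords: np.ndarray,
    approx: str = "auto",
    m: int = DEFAULT_NEIGHBORS,
    exact_below: int = DEFAULT_EXACT_BELOW,
) -> GPFit:
    """Single-gene ML fit of (sigma2, tau2, lengthscale) with multi-start
    L-BFGS-B on the log-parameters.

    ``X=None`` means intercept only.  Coordinates are rescaled internally so
    the longer axis spans [0, 1]; the returned lengthscale is on the original
    scale (``lengthscale_scaled`` carries the [0, 1]-scale value).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if X is None:
        X = np.ones((n, 1))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    span = _coord_scale(coords)
    sc = coords / span

    use_exact = approx == "exact" or (approx == "auto" and n <= exact_below)
    structure = None if use_exact else NNStructure(sc, m)

    vy = max(float(np.var(y)), 1e-12)

    def negll(logp: np.ndarray) -> float:
        p = KernelParams(*np.exp(logp))
        try:
            if use_exact:
                ll, _ = gp_loglik_exact(y, X, sc, p, dense_limit=max(n, 2000))
            else:
                ll, _ = gp_loglik_nn(y, X, sc, p, m=m, structure=structure)
        except np.linalg.LinAlgError:
            return 1e12
        return -ll if np.isfinite(ll) else 1e12

    bounds = [
        (math.log(1e-6 * vy), math.log(1e3 * vy)),
        (math.log(1e-6 * vy), math.log(1e3 * vy)),
        (math.log(1e-3), math.log(2.0)),
    ]
    best = None
    for l0 in (0.05, 0.2, 0.75):  # small / medium / large lengthscale starts
        x0 = np.array([math.log(vy / 2), math.log(vy / 2), math.log(l0)])
        res = minimize(negll, x0, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 200})
        if best is None or res.fun < best.fun:
            best = res
    converged = bool(best.success)
    if not converged:
        logger.warning("fit_gene_gp: optimizer did not fully converge; "
                       "keeping best parameters found")

    sigma2, tau2, l_scaled = np.exp(best.x)
    p = KernelParams(sigma2, tau2, l_scaled)
    if use_exact:
        ll, beta = gp_loglik_exact(y, X, sc, p, dense_limit=max(n, 2000))
    else:
        ll, beta = gp_loglik_nn(y, X, sc, p, m=m, structure=structure)
    ll_null, _ = linear_loglik(y, X)
    lr = max(0.0, 2.0 * (ll - ll_null))
    return GPFit(
        params=KernelParams(sigma2, tau2, l_scaled * span),
        beta_hat=beta,
        loglik=ll,
        mu_hat=X @ beta,
        lr_stat=lr,
        pvalue=float(stats.chi2.sf(lr, df=2)),
        prop_sv=sigma2 / (sigma2 + tau2),
        converged=converged,
        n_neighbors_used=0 if use_exact else min(m, n - 1),
        lengthscale_scaled=l_scaled,
        loglik_null=ll_null,
    )


class _BatchEvaluator:
    """Profile log-likelihood of every gene at one (rho, lengthscale) point.

    The total variance and the (single-column) regression coefficient are
    profiled analytically, so one covariance factorization serves all genes.
    """

    def __init__(self, Y: np.ndarray, Xcols: np.ndarray | None,
                 coords: np.ndarray, use_exact: bool, m: int,
                 shared_col: np.ndarray | None = None) -> None:
        self.Y = Y
        self.n, self.G = Y.shape
        # a single shared design column (intercept or identical weight
        # columns) is transformed once for all genes
        self.shared_x = Xcols is None
        if Xcols is None:
            self.X = (np.ones((self.n, 1)) if shared_col is None
                      else shared_col.reshape(self.n, 1))
        else:
            self.X = Xcols
        self.use_exact = use_exact
        if use_exact:
            self.D = squareform(pdist(coords))
            self.structure = None
        else:
            self.structure = NNStructure(coords, m)
            ord_ = self.structure.order
            self._Yo = Y[ord_]
            self._Xo = self.X[ord_]

    def __call__(self, rho: float, l: float):
        n = self.n
        if self.use_exact:
            R = rho * np.exp(-self.D / l)
            np.fill_diagonal(R, 1.0)
            try:
                L = cholesky(R, lower=True)
            except np.linalg.LinAlgError:
                R[np.diag_indices(n)] += 1e-8
                L = cholesky(R, lower=True)
            logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
            TY = solve_triangular(L, self.Y, lower=True)
            TX = solve_triangular(L, self.X, lower=True)
        else:
            logdet, A, d = self.structure.factor(rho, l)
            isd = 1.0 / np.sqrt(d)[:, None]
            TY = (self._Yo - A @ self._Yo) * isd
            TX = (self._Xo - A @ self._Xo) * isd
        if self.shared_x:
            bnum = TX[:, 0] @ TY
            bden = np.full(self.G, float(TX[:, 0] @ TX[:, 0]))
        else:
            bnum = np.einsum("ig,ig->g", TX, TY)
            bden = np.einsum("ig,ig->g", TX, TX)
        beta = bnum / np.maximum(bden, _VAR_FLOOR)
        rss = np.einsum("ig,ig->g", TY, TY) - beta * bnum
        s = np.maximum(rss / n, _VAR_FLOOR)
        ll = -0.5 * (n * LOG2PI + logdet + n * np.log(s) + n)
        return ll, beta, s


def fit_genes(
    Y: np.ndarray,
    coords: np.ndarray,
    Xcols: np.ndarray | None = None,
    m: int = DEFAULT_NEIGHBORS,
    exact_below: int = DEFAULT_EXACT_BELOW,
    rho_grid: np.ndarray | None = None,
    l_grid: np.ndarray | None = None,
    refine_rounds: int = 3,
    max_candidates: int = 600,
    ridge_tol: float = DEFAULT_RIDGE_TOL,
) -> list[GPFit]:
    """Batched per-gene ML fits over a shared (rho, lengthscale) search.

    Parameters
    ----------
    Y
        n_spots x n_genes response matrix (one column per gene).
    Xcols
        n_spots x n_genes design column per gene, or ``None`` for a shared
        intercept.  (The batched path supports a single covariate column per
        gene; use :func:`fit_gene_gp` for richer designs.)
    ridge_tol
        The exponential-plus-nugget likelihood has a near-flat ridge for
        non-spatial genes: pushing the spatial proportion towards 1 with a
        lengthscale shorter than the spot spacing mimics white noise and can
        eke out a vanishing likelihood gain while degenerating towards
        interpolation.  A gene therefore keeps the iid (null) fit unless
        some spatial candidate beats it by more than ``ridge_tol``
        log-likelihood units (order-independent parsimony).

    The search evaluates a deterministic coarse grid of
    (spatial proportion rho, scaled lengthscale) points — each factorized
    once for all genes — then performs pattern-search refinement with
    halving steps.  The iid linear model (rho = 0) is always included, so
    the likelihood-ratio statistic is non-negative by construction.
    """
    Y = np.asarray(Y, dtype=float)
    n, G = Y.shape
    shared_x = Xcols is None
    shared_col = None
    if Xcols is not None:
        Xcols = np.asarray(Xcols, dtype=float)
        if Xcols.shape != Y.shape:
            raise ValueError("Xcols must match Y shape")
        if np.all(Xcols == Xcols[:, :1]):
            # identical design columns (e.g. unit weights): use the shared
            # fast path so results match the intercept-only route exactly
            shared_x = True
            shared_col = Xcols[:, 0].copy()
            Xcols = None
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    span = _coord_scale(coords)
    sc = coords / span
    use_exact = n <= exact_below

    ev = _BatchEvaluator(Y, Xcols, sc, use_exact, m, shared_col=shared_col)
    if shared_x:
        base = np.ones(n) if shared_col is None else shared_col
        Xfull = np.tile(base[:, None], (1, G))
    else:
        Xfull = Xcols

    if rho_grid is None:
        rho_grid = np.concatenate(([0.02, 0.05], np.linspace(0.1, 0.9, 9), [0.97]))
    if l_grid is None:
        l_grid = np.geomspace(5e-3, 1.5, 10)
    logl_grid = np.log(l_grid)

    # null model (rho = 0): closed form, shared by every lengthscale
    if shared_x:
        x0 = ev.X[:, 0]
        bnum0 = x0 @ Y
        bden0 = np.full(G, float(x0 @ x0))
    else:
        bnum0 = np.einsum("ig,ig->g", Xcols, Y)
        bden0 = np.einsum("ig,ig->g", Xcols, Xcols)
    beta0 = bnum0 / np.maximum(bden0, _VAR_FLOOR)
    rss0 = np.einsum("ig,ig->g", Y, Y) - beta0 * bnum0
    s0 = np.maximum(rss0 / n, _VAR_FLOOR)
    ll_null = -0.5 * (n * LOG2PI + n * np.log(s0) + n)

    logl0 = float(np.median(logl_grid))
    cand_rho = [0.0]
    cand_logl = [logl0]
    cand_ll = [ll_null.copy()]
    cand_beta = [beta0.copy()]
    cand_s = [s0.copy()]

    # pure-max tracking drives the refinement proposals
    best_ll = ll_null.copy()
    best_rho = np.zeros(G)
    best_logl = np.full(G, logl0)

    def consider(rho: float, logl: float) -> None:
        nonlocal best_ll
        ll, beta, s = ev(rho, math.exp(logl))
        ll = np.where(np.isfinite(ll), ll, -np.inf)
        cand_rho.append(rho)
        cand_logl.append(logl)
        cand_ll.append(ll)
        cand_beta.append(beta)
        cand_s.append(s)
        upd = ll > best_ll + 1e-12
        if np.any(upd):
            best_ll = np.where(upd, ll, best_ll)
            best_rho[upd] = rho
            best_logl[upd] = logl

    for logl in logl_grid:
        for rho in rho_grid:
            consider(float(rho), float(logl))

    drho = 0.5 * float(np.max(np.diff(np.concatenate(([0.0], rho_grid)))))
    dlogl = 0.5 * float(np.max(np.diff(logl_grid)))
    logl_lo, logl_hi = math.log(1e-3), math.log(2.0)
    for _ in range(refine_rounds):
        cand: dict[tuple[float, float], int] = {}
        for g in range(G):
            for dr in (-drho, 0.0, drho):
                for dl in (-dlogl, 0.0, dlogl):
                    if dr == 0.0 and dl == 0.0:
                        continue
                    r = min(max(best_rho[g] + dr, 0.0), _RHO_MAX)
                    ql = min(max(best_logl[g] + dl, logl_lo), logl_hi)
                    key = (round(r, 8), round(ql, 8))
                    cand[key] = cand.get(key, 0) + 1
        items = sorted(cand.items(), key=lambda kv: (-kv[1], kv[0]))[:max_candidates]
        for (r, ql), _count in items:
            if r == 0.0:
                continue  # null already included in closed form
            consider(r, ql)
        drho *= 0.5
        dlogl *= 0.5

    # parsimony vs the null: a spatial fit must beat the iid model by more
    # than ridge_tol to be kept (see docstring)
    LL = np.vstack(cand_ll)                      # candidates x genes
    rhos = np.asarray(cand_rho)
    logls = np.asarray(cand_logl)
    sel = LL.argmax(axis=0)
    sel[LL[0] >= LL.max(axis=0) - ridge_tol] = 0  # candidate 0 is the null

    sel_ll = LL[sel, np.arange(G)]
    sel_beta = np.vstack(cand_beta)[sel, np.arange(G)]
    sel_s = np.vstack(cand_s)[sel, np.arange(G)]
    lr = np.maximum(0.0, 2.0 * (sel_ll - ll_null))
    pvals = stats.chi2.sf(lr, df=2)
    fits: list[GPFit] = []
    for g in range(G):
        s = float(sel_s[g])
        rho = float(rhos[sel[g]])
        l_scaled = math.exp(float(logls[sel[g]]))
        sigma2 = rho * s
        tau2 = max((1.0 - rho) * s, _VAR_FLOOR)
        fits.append(GPFit(
            params=KernelParams(sigma2, tau2, l_scaled * span),
            beta_hat=np.array([sel_beta[g]]),
            loglik=float(sel_ll[g]),
            mu_hat=Xfull[:, g] * sel_beta[g],
            lr_stat=float(lr[g]),
            pvalue=float(pvals[g]),
            prop_sv=rho,
            converged=bool(np.isfinite(sel_ll[g])),
            n_neighbors_used=0 if use_exact else min(m, n - 1),
            lengthscale_scaled=l_scaled,
            loglik_null=float(ll_null[g]),
        ))
    logger.info("fit_genes: %d genes, n=%d, backend=%s", G, n,
                "exact" if use_exact else f"nn(m={min(m, n - 1)})")
    return fits


def fitted_values(
    Y: np.ndarray,
    coords: np.ndarray,
    fits: list[GPFit],
    m: int = DEFAULT_NEIGHBORS,
) -> np.ndarray:
    """Per-observation GP predictions (local kriging smoother).

    For each gene the signal at location i is predicted by conditioning on
    the ``m + 1`` nearest observations (self included; the covariance to the
    target carries the spatial part only, so the nugget damps the
    self-weight):

        pred_i = mu_i + c_i' (sigma2 K_nb + tau2 I)^-1 (y_nb - mu_nb)

    These are the fitted values whose residuals carry the non-spatial noise
    used by the mean-variance trend; for a null gene (sigma2 = 0) the
    prediction reduces to the fixed effect.  For a fit whose nugget has
    collapsed to ~0 the prediction approaches the observation itself and the
    residuals shrink accordingly — the parsimony guard in :func:`fit_genes`
    keeps genuinely non-spatial genes away from that regime.
    """
    Y = np.asarray(Y, dtype=float)
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    n, G = Y.shape
    if len(fits) != G:
        raise ValueError("one fit per gene required")
    k = min(m + 1, n)
    tree = cKDTree(coords)
    d_pn, idx = tree.query(coords, k=k)
    nb_pts = coords[idx]
    d_nn = np.linalg.norm(nb_pts[:, :, None, :] - nb_pts[:, None, :, :], axis=3)
    diag = np.arange(k)
    pred = np.empty((n, G))
    for g, f in enumerate(fits):
        mu = f.mu_hat
        s2, t2, l = f.params.sigma2, f.params.tau2, f.params.lengthscale
        if s2 <= 0:
            pred[:, g] = mu
            continue
        C = s2 * np.exp(-d_nn / l)
        C[:, diag, diag] += t2 + 1e-10 * s2
        c = s2 * np.exp(-d_pn / l)
        b = np.linalg.solve(C, c[..., None])[..., 0]
        resid_nb = Y[idx, g] - (mu[idx] if mu.ndim == 1 else mu)
        pred[:, g] = mu + np.einsum("ij,ij->i", b, resid_nb)
    return pred


def rank_genes(fits: list[GPFit], gene_ids: list[str]) -> RankTable:
    """Rank genes by decreasing likelihood-ratio statistic (ties: first wins)."""
    if len(fits) != len(gene_ids):
        raise ValueError("one fit per gene required")
    stat = np.array([f.lr_stat for f in fits])
    return RankTable(
        gene_ids=list(gene_ids),
        statistic=stat,
        rank=rank_from_statistic(stat),
        pvalue=np.array([f.pvalue for f in fits]),
        method_label="gp-lr",
    )


def morans_i(y: np.ndarray, coords: np.ndarray) -> float:
    """Moran's I with a row-normalized inverse-distance weight matrix."""
    y = np.asarray(y, dtype=float)
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    z = y - y.mean()
    denom = float(z @ z)
    if denom <= 0:
        raise ValueError("Moran's I is undefined for constant y")
    d = cdist(coords, coords)
    with np.errstate(divide="ignore"):
        W = 1.0 / d
    np.fill_diagonal(W, 0.0)
    if not np.all(np.isfinite(W)):
        raise ValueError("duplicate coordinates produce infinite weights")
    W /= W.sum(axis=1, keepdims=True)
    n = len(y)
    s0 = float(W.sum())  # == n after row normalization
    return (n / s0) * float(z @ (W @ z)) / denom


def detect(
    data: CountsDataset,
    method: str = "gp",
    m: int = DEFAULT_NEIGHBORS,
    exact_below: int = DEFAULT_EXACT_BELOW,
    ridge_tol: float = DEFAULT_RIDGE_TOL,
) -> tuple[RankTable, list[GPFit] | None]:
    """Unweighted spatially-variable-gene detection on logCPM values."""
    lc = logcpm(data)
    if method == "gp":
        fits = fit_genes(lc.values, data.coords, m=m, exact_below=exact_below,
                         ridge_tol=ridge_tol)
        return rank_genes(fits, data.gene_ids), fits
    if method == "moran":
        stat = np.array([morans_i(lc.values[:, g], data.coords)
                         for g in range(data.n_genes)])
        table = RankTable(
            gene_ids=list(data.gene_ids),
            statistic=stat,
            rank=rank_from_statistic(stat),
            pvalue=None,
            method_label="moran",
        )
        return table, None
    raise ValueError(f"unknown detection method {method!r}")
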