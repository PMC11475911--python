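"""Graph-Laplacian regularized Poisson log-linear deconvolution.

Per spot i and gene j the (platform-adjusted) count Y_ij is modeled as

    Y_ij | lambda_ij ~ Poisson(N_i * lambda_ij)
    log(lambda_ij) = alpha_i + log(sum_k theta_ik * mu_kj) + eps_ij

with N_i the spot's total UMI count, theta_i the cell-type proportions on
the probability simplex, mu the cell-type signature matrix, alpha_i a
spot-level fixed effect, and eps_ij a zero-mean random error with a
heavy-tailed (Cauchy-Gaussian-mixture approximation) density that is
marginalized over a fixed quadrature grid.

Estimation is two-staged: per-spot adaptive-LASSO ADMM selects which cell
types are present (cutoff 0.001 on the estimate), then a joint ADMM with a
graph-Laplacian penalty tr(theta' L theta) smooths proportions across
neighboring spots, restricted to the selected types. Both hyperparameters
are chosen by five-fold cross-validation over marker genes.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln, logsumexp, erf
from scipy.spatial.distance import pdist, squareform

from .io_prep import library_normalize

logger = logging.getLogger(__name__)

__all__ = [
    "SpatialGraph",
    "EpsilonGrid",
    "compute_signatures",
    "heavy_tail_density",
    "epsilon_grid",
    "base_negloglik",
    "fit_base_mle",
    "adaptive_lasso_penalty",
    "weights_from_mle",
    "build_spatial_graph",
    "laplacian_penalty",
    "project_simplex",
    "stage1_select",
    "stage2_smooth",
    "cross_validate",
]

TAIL_TRUNC = 8.0  # the heavy-tail density is supported on |eps| <= TAIL_TRUNC*sigma
PRESENCE_CUTOFF = 1e-3
WEIGHT_FLOOR = 1e-4
THETA_EPS = 1e-8  # lower bound keeping log(theta.mu) defined inside smooth solves


# --------------------------------------------------------------------------
# signatures
# --------------------------------------------------------------------------

def compute_signatures(
    ref: pd.DataFrame, annot: pd.Series, marker_genes: list[str]
) -> pd.DataFrame:
    """Cell-type signature matrix mu (K x genes).

    Row k is the average library-size-normalized expression over all cells
    of type k, restricted to the marker genes. ``ref`` is the (possibly
    platform-adjusted) genes x cells reference matrix.
    """
    annot = annot.loc[annot.index.intersection(ref.columns)]
    norm = library_normalize(ref, 1.0)
    rows = {}
    for ctype in sorted(annot.unique()):
        cells = annot.index[annot == ctype]
        cells = [c for c in cells if c in norm.columns]
        if len(cells) == 0:
            raise ValueError(f"cell type {ctype!r} has no cells")
        rows[ctype] = norm.loc[marker_genes, cells].mean(axis=1)
    return pd.DataFrame(rows).T


# --------------------------------------------------------------------------
# heavy-tailed error density and quadrature
# --------------------------------------------------------------------------

def _tail_constant(sigma: float, trunc: float = TAIL_TRUNC) -> float:
    """Normalizing constant C so the truncated density integrates to 1.

    Central mass (without C) is erf(3/sqrt(2)); the 1/|eps|-type tail
    integrates in closed form to a log.
    """
    central = float(erf(3.0 / math.sqrt(2.0)))
    # 2 * int_{3s}^{Ts} 2*sqrt(2) e^{-9/2} / (9 sqrt(pi) (e*s - 7/3 s^2)) de
    log_ratio = math.log((trunc - 7.0 / 3.0) / (3.0 - 7.0 / 3.0))
    tail = 4.0 * math.sqrt(2.0) * math.exp(-4.5) / (9.0 * math.sqrt(math.pi) * sigma) * log_ratio
    return 1.0 / (central + tail)


def heavy_tail_density(eps: np.ndarray | float, sigma: float) -> np.ndarray | float:
    """Heavy-tailed error density: Gaussian core for |eps| <= 3*sigma, a
    slowly decaying tail for 3*sigma < |eps| <= 8*sigma, zero beyond.

    The tail is proportional to 1/(|eps|*sigma - 7/3*sigma^2); because that
    decays only like 1/|eps| the support is truncated at 8*sigma and the
    constant C normalizes the truncated density (closed form).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    eps_arr = np.abs(np.asarray(eps, dtype=float))
    C = _tail_constant(sigma)
    core = C / (math.sqrt(2.0 * math.pi) * sigma) * np.exp(-(eps_arr**2) / (2.0 * sigma**2))
    with np.errstate(divide="ignore"):
        tail = (
            2.0 * math.sqrt(2.0) * C * math.exp(-4.5)
            / (9.0 * math.sqrt(math.pi) * (eps_arr * sigma - (7.0 / 3.0) * sigma**2))
        )
    out = np.where(eps_arr <= 3.0 * sigma, core, tail)
    out = np.where(eps_arr > TAIL_TRUNC * sigma, 0.0, out)
    return float(out) if np.isscalar(eps) else out


@dataclass(frozen=True)
class EpsilonGrid:
    """Fixed quadrature grid marginalizing the random error eps."""

    nodes: np.ndarray
    log_weights: np.ndarray  # normalized so sum(exp(log_weights)) == 1


_GRID_CACHE: dict[tuple[float, int], EpsilonGrid] = {}


def epsilon_grid(sigma: float, n_core: int = 25) -> EpsilonGrid:
    """Quadrature grid: ``n_core`` nodes spanning +-5*sigma plus tail nodes
    out to +-8*sigma; trapezoid weights from the heavy-tail density,
    normalized to sum to one. Cached per (sigma, n_core)."""
    key = (round(float(sigma), 12), n_core)
    if key in _GRID_CACHE:
        return _GRID_CACHE[key]
    if sigma <= 1e-8:
        grid = EpsilonGrid(np.array([0.0]), np.array([0.0]))
    else:
        core = np.linspace(-5.0 * sigma, 5.0 * sigma, n_core)
        # tail node spacing tracks the core resolution so dense settings
        # converge to the continuous integral
        step = max(min(0.5, 10.0 / (n_core - 1)), 1e-4)
        tail = np.arange(5.0 + step, TAIL_TRUNC + 1e-9, step) * sigma
        nodes = np.unique(np.concatenate([core, -tail, tail]))
        dens = heavy_tail_density(nodes, sigma)
        mids = np.empty(nodes.size + 1)
        mids[1:-1] = 0.5 * (nodes[1:] + nodes[:-1])
        mids[0], mids[-1] = nodes[0], nodes[-1]
        w = dens * np.diff(mids)
        w = w / w.sum()
        keep = w > 0
        grid = EpsilonGrid(nodes[keep], np.log(w[keep]))
    _GRID_CACHE[key] = grid
    return grid


# --------------------------------------------------------------------------
# base model likelihood
# --------------------------------------------------------------------------

def base_negloglik(
    theta: np.ndarray,
    alpha: float,
    Y: np.ndarray,
    N: float,
    mu: np.ndarray,
    sigma2: float,
    grid: EpsilonGrid | None = None,
    check_simplex: bool = True,
) -> float:
    """Negative log-likelihood of one spot under the base model.

    -sum_j log sum_m w_m Poisson(Y_j | N * exp(alpha + log(theta.mu_j) + eps_m))
    """
    theta = np.asarray(theta, dtype=float)
    if check_simplex and (theta.min() < -1e-9 or abs(theta.sum() - 1.0) > 1e-6):
        raise ValueError("theta must lie on the probability simplex")
    if grid is None:
        grid = epsilon_grid(math.sqrt(sigma2))
    s = theta @ mu  # per-gene mixture expression
    if np.any(s <= 0):
        if check_simplex:
            raise ValueError("all-zero predicted rate for some gene")
        s = np.maximum(s, 1e-12)  # restricted supports may zero a marker gene
    log_rate = np.log(N) + alpha + np.log(s)[:, None] + grid.nodes[None, :]
    ll_jm = Y[:, None] * log_rate - np.exp(log_rate) - gammaln(Y + 1.0)[:, None]
    return -float(logsumexp(ll_jm + grid.log_weights[None, :], axis=1).sum())


def _nll_and_grad(eta, alpha, Y, N, mu, grid, prox=None):
    """Negative log-likelihood and gradient wrt (eta, alpha) with
    theta = softmax(eta); optional proximal term (rho/2)||theta - v||^2."""
    eta = eta - eta.max()
    w = np.exp(eta)
    theta = w / w.sum()
    s = np.maximum(theta @ mu, 1e-12)
    # clip keeps exploratory optimizer steps with huge alpha finite
    log_rate = np.minimum(np.log(N) + alpha + np.log(s)[:, None] + grid.nodes[None, :], 300.0)
    rate = np.exp(log_rate)
    ll_jm = Y[:, None] * log_rate - rate - gammaln(Y + 1.0)[:, None]
    lw = ll_jm + grid.log_weights[None, :]
    tot = logsumexp(lw, axis=1)
    nll = -tot.sum()
    q = np.exp(lw - tot[:, None])  # posterior over nodes per gene
    resid = (q * (Y[:, None] - rate)).sum(axis=1)  # d loglik_j / d alpha
    dalpha = -resid.sum()
    ds = resid / s  # d loglik_j / d s_j
    dtheta = -(mu @ ds)
    if prox is not None:
        rho, v = prox
        nll += 0.5 * rho * np.sum((theta - v) ** 2)
        dtheta = dtheta + rho * (theta - v)
    deta = theta * (dtheta - float(theta @ dtheta))
    return nll, np.concatenate([deta, [dalpha]])


def fit_base_mle(
    Y: pd.DataFrame,
    N: np.ndarray,
    mu: pd.DataFrame,
    sigma_grid: tuple[float, ...] = (0.05, 0.1, 0.2, 0.4, 0.8),
    max_iter: int = 200,
) -> tuple[pd.DataFrame, np.ndarray, float]:
    """Per-spot maximum likelihood under the base model.

    theta_i is parameterized through a softmax (simplex by construction) and
    optimized jointly with alpha_i by L-BFGS; sigma^2 is profiled on a
    shared candidate grid (the value maximizing the summed likelihood is
    kept). Returns (theta_hat spots x K, alpha_hat, sigma2_hat).
    """
    genes = [g for g in Y.index if g in mu.columns]
    Yv = Y.loc[genes].to_numpy(dtype=float)
    muv = mu[genes].to_numpy(dtype=float)
    K, n_spots = muv.shape[0], Yv.shape[1]
    best = None
    for sigma in sigma_grid:
        grid = epsilon_grid(sigma)
        total = 0.0
        thetas = np.empty((n_spots, K))
        alphas = np.empty(n_spots)
        for i in range(n_spots):
            y = Yv[:, i]
            a0 = math.log(max(y.sum(), 1.0) / (N[i] * (np.full(K, 1.0 / K) @ muv).sum()))
            x0 = np.concatenate([np.zeros(K), [a0]])
            res = minimize(
                lambda x: _nll_and_grad(x[:K], x[K], y, N[i], muv, grid),
                x0, jac=True, method="L-BFGS-B",
                options={"maxiter": max_iter},
            )
            if not res.success and res.status != 1:
                logger.warning("MLE for spot %d did not converge: %s", i, res.message)
            eta = res.x[:K] - res.x[:K].max()
            w = np.exp(eta)
            thetas[i] = w / w.sum()
            alphas[i] = res.x[K]
            total -= res.fun
        if best is None or total > best[0]:
            best = (total, thetas, alphas, sigma)
    _, thetas, alphas, sigma = best
    theta_df = pd.DataFrame(thetas, index=Y.columns, columns=mu.index)
    return theta_df, alphas, sigma**2


# --------------------------------------------------------------------------
# penalties and the spatial graph
# --------------------------------------------------------------------------

def adaptive_lasso_penalty(theta: np.ndarray, q: np.ndarray) -> float:
    """r(theta_i) = sum_k q_ik * |theta_ik| with q the adaptive weights."""
    q = np.asarray(q, dtype=float)
    if (q < 0).any():
        raise ValueError("adaptive weights must be nonnegative")
    return float(np.sum(q * np.abs(theta)))


def weights_from_mle(theta_hat: pd.DataFrame, floor: float = WEIGHT_FLOOR) -> pd.DataFrame:
    """Adaptive weights q = 1 / max(theta_hat, floor) (reciprocal MLE,
    floored to avoid infinite weights at zero estimates)."""
    return 1.0 / theta_hat.clip(lower=floor)


@dataclass
class SpatialGraph:
    """Unweighted neighbor graph over spots: adjacency A, degrees, L = D - A."""

    adjacency: np.ndarray
    spot_ids: list[str]

    @property
    def degree(self) -> np.ndarray:
        return np.diag(self.adjacency.sum(axis=1))

    @property
    def laplacian(self) -> np.ndarray:
        return self.degree - self.adjacency


def build_spatial_graph(coords: pd.DataFrame, neighbor_factor: float = 1.2) -> SpatialGraph:
    """Spots are neighbors iff their center distance is at most
    ``neighbor_factor`` times the minimal nonzero inter-spot distance
    (factor 1.2 captures the 4-neighborhood of a square array and the
    6-neighborhood of a hexagonal one)."""
    xy = coords[["x", "y"]].to_numpy(dtype=float)
    n = xy.shape[0]
    if n == 1:
        return SpatialGraph(np.zeros((1, 1)), list(coords.index))
    d = squareform(pdist(xy))
    off = d[~np.eye(n, dtype=bool)]
    if (off == 0).any():
        logger.warning("duplicate spot coordinates detected")
    nonzero = off[off > 0]
    if nonzero.size == 0:
        return SpatialGraph(np.zeros((n, n)), list(coords.index))
    cutoff = neighbor_factor * nonzero.min()
    A = ((d <= cutoff) & (d > 0)).astype(float)
    return SpatialGraph(A, list(coords.index))


def laplacian_penalty(theta: np.ndarray, L: np.ndarray) -> float:
    """tr(theta' L theta) = 0.5 * sum_st A_st ||theta_s - theta_t||^2."""
    if not np.allclose(L, L.T):
        raise ValueError("Laplacian (hence adjacency) must be symmetric")
    return float(np.trace(theta.T @ L @ theta))


def project_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection of a vector onto the probability simplex."""
    u = np.sort(v)[::-1]
    css = np.cumsum(u) - 1.0
    ind = np.arange(1, v.size + 1)
    cond = u - css / ind > 0
    rho = ind[cond][-1]
    tau = css[cond][-1] / rho
    return np.maximum(v - tau, 0.0)


# --------------------------------------------------------------------------
# two-stage ADMM
# --------------------------------------------------------------------------

@dataclass
class ADMMTrace:
    objective: list[float] = field(default_factory=list)
    primal_residual: list[float] = field(default_factory=list)
    dual_residual: list[float] = field(default_factory=list)
    objective_per_spot: list[list[float]] = field(default_factory=list)


def _solve_theta_step(y, N, muv, grid, v, rho, x0, max_iter=30):
    """argmin_theta,alpha l(theta, alpha) + rho/2 ||theta - v||^2 via softmax L-BFGS."""
    K = muv.shape[0]
    res = minimize(
        lambda x: _nll_and_grad(x[:K], x[K], y, N, muv, grid, prox=(rho, v)),
        x0, jac=True, method="L-BFGS-B", options={"maxiter": max_iter},
    )
    eta = res.x[:K] - res.x[:K].max()
    w = np.exp(eta)
    return w / w.sum(), res.x[K], res.x


def stage1_select(
    Y: pd.DataFrame,
    N: np.ndarray,
    mu: pd.DataFrame,
    sigma2: float,
    alpha: np.ndarray,
    q: pd.DataFrame,
    lam_r: float,
    rho: float = 1.0,
    max_iter: int = 200,
    tol: float = 1e-5,
    theta_init: pd.DataFrame | None = None,
    cutoff: float = PRESENCE_CUTOFF,
    adapt_rho: bool = False,
    track_objective: bool = False,
) -> tuple[pd.DataFrame, list[np.ndarray], ADMMTrace]:
    """Per-spot adaptive-LASSO cell-type selection by ADMM.

    Minimizes l_i(theta_i, alpha_i) + lam_r * sum_k q_ik theta_ik over the
    simplex for each spot. The z-update is the simplex projection of
    theta + u - (lam_r/rho) q (the weighted-L1 prox restricted to the
    simplex, where |theta| = theta). Cell type k is present in spot i iff
    the final estimate theta_ik >= ``cutoff``.

    Returns (theta spots x K, selected index sets per spot, trace).
    """
    genes = [g for g in Y.index if g in mu.columns]
    Yv = Y.loc[genes].to_numpy(dtype=float)
    muv = mu[genes].to_numpy(dtype=float)
    grid = epsilon_grid(math.sqrt(sigma2))
    K, n_spots = muv.shape[0], Yv.shape[1]
    qv = q.to_numpy(dtype=float)
    theta0 = (theta_init.to_numpy(dtype=float) if theta_init is not None
              else np.full((n_spots, K), 1.0 / K))
    out = np.empty((n_spots, K))
    alphas = alpha.copy().astype(float)
    trace = ADMMTrace()
    total_obj = []
    n_unconverged = 0
    for i in range(n_spots):
        y = Yv[:, i]
        z = theta0[i].copy()
        u = np.zeros(K)
        rho_i = rho
        x0 = np.concatenate([np.log(np.maximum(z, 1e-6)), [alphas[i]]])
        converged = False
        spot_objs = []
        for it in range(max_iter):
            theta, a, x0 = _solve_theta_step(y, N[i], muv, grid, z - u, rho_i, x0)
            z_old = z
            z = project_simplex(theta + u - (lam_r / rho_i) * qv[i])
            u = u + theta - z
            r_primal = float(np.linalg.norm(theta - z))
            r_dual = float(rho_i * np.linalg.norm(z - z_old))
            if track_objective:
                spot_objs.append(
                    base_negloglik(z / z.sum(), a, y, N[i], muv, sigma2, grid,
                                   check_simplex=False)
                    + lam_r * adaptive_lasso_penalty(z, qv[i])
                )
            if r_primal < tol and r_dual < tol:
                converged = True
                break
            # optional residual balancing; off by default because with the
            # flat penalty parameter the iterates settle sparsity faster
            if adapt_rho:
                if r_primal > 10.0 * r_dual:
                    rho_i *= 2.0
                    u /= 2.0
                elif r_dual > 10.0 * r_primal:
                    rho_i /= 2.0
                    u *= 2.0
        if not converged:
            n_unconverged += 1
        if track_objective:
            trace.objective_per_spot.append(spot_objs)
        obj = (
            base_negloglik(np.maximum(z, 0) / max(z.sum(), 1e-12), a, y, N[i], muv,
                           sigma2, grid, check_simplex=False)
            + lam_r * adaptive_lasso_penalty(z, qv[i])
        )
        out[i] = z / z.sum()
        alphas[i] = a
        total_obj.append(obj)
        trace.primal_residual.append(r_primal)
        trace.dual_residual.append(r_dual)
    if n_unconverged:
        logger.warning(
            "stage-1 ADMM hit the iteration cap for %d/%d spots (best iterates kept)",
            n_unconverged, n_spots,
        )
    trace.objective = total_obj
    theta_df = pd.DataFrame(out, index=Y.columns, columns=mu.index)
    selected = [np.flatnonzero(out[i] >= cutoff) for i in range(n_spots)]
    for i, sel in enumerate(selected):
        if sel.size == 0:
            logger.warning("no cell type selected for spot %d; keeping all", i)
            selected[i] = np.arange(K)
    return theta_df, selected, trace


def _joint_nll_grad(flat, support_idx, Yv, N, muv, grid, lam_l, L, rho, V, n_spots, K):
    """Objective and gradient for the stage-2 theta step over all spots.

    ``flat`` packs, per spot, the softmax logits of the selected types and
    alpha_i. The Laplacian penalty and the proximal term couple spots.
    """
    theta = np.zeros((n_spots, K))
    alphas = np.empty(n_spots)
    pos = 0
    etas = []
    for i in range(n_spots):
        k = support_idx[i].size
        eta = flat[pos : pos + k]
        eta = eta - eta.max()
        w = np.exp(eta)
        theta[i, support_idx[i]] = w / w.sum()
        etas.append(eta)
        alphas[i] = flat[pos + k]
        pos += k + 1
    obj = 0.0
    dtheta_full = np.zeros((n_spots, K))
    dalpha = np.empty(n_spots)
    for i in range(n_spots):
        y = Yv[:, i]
        s = np.maximum(theta[i] @ muv, 1e-12)
        log_rate = np.minimum(
            np.log(N[i]) + alphas[i] + np.log(s)[:, None] + grid.nodes[None, :], 300.0
        )
        rate = np.exp(log_rate)
        ll_jm = y[:, None] * log_rate - rate - gammaln(y + 1.0)[:, None]
        lw = ll_jm + grid.log_weights[None, :]
        tot = logsumexp(lw, axis=1)
        obj -= tot.sum()
        qm = np.exp(lw - tot[:, None])
        resid = (qm * (y[:, None] - rate)).sum(axis=1)
        dalpha[i] = -resid.sum()
        dtheta_full[i] = -(muv @ (resid / s))
    if lam_l > 0:
        obj += lam_l * float(np.trace(theta.T @ L @ theta))
        dtheta_full += 2.0 * lam_l * (L @ theta)
    obj += 0.5 * rho * float(np.sum((theta - V) ** 2))
    dtheta_full += rho * (theta - V)
    gout = np.empty_like(flat)
    pos = 0
    for i in range(n_spots):
        idx = support_idx[i]
        k = idx.size
        th = theta[i, idx]
        dth = dtheta_full[i, idx]
        gout[pos : pos + k] = th * (dth - float(th @ dth))
        gout[pos + k] = dalpha[i]
        pos += k + 1
    return obj, gout


def stage2_smooth(
    Y: pd.DataFrame,
    N: np.ndarray,
    mu: pd.DataFrame,
    sigma2: float,
    alpha: np.ndarray,
    selected: list[np.ndarray],
    L: np.ndarray,
    lam_l: float,
    rho: float = 1.0,
    max_iter: int = 100,
    tol: float = 1e-5,
    theta_init: pd.DataFrame | None = None,
    inner_iter: int = 25,
) -> tuple[pd.DataFrame, ADMMTrace]:
    """Joint graph-Laplacian-smoothed fit over the selected supports.

    Minimizes sum_i l_i(theta_i, alpha_i) + lam_l * tr(theta' L theta) with
    theta_ik = 0 outside each spot's selected set and rows on the simplex
    (ADMM: smooth terms in the theta step, per-row support-restricted
    simplex projection in the z step). Returns the final proportions.
    """
    genes = [g for g in Y.index if g in mu.columns]
    Yv = Y.loc[genes].to_numpy(dtype=float)
    muv = mu[genes].to_numpy(dtype=float)
    grid = epsilon_grid(math.sqrt(sigma2))
    K, n_spots = muv.shape[0], Yv.shape[1]
    selected = [np.asarray(s) if np.asarray(s).size else np.arange(K) for s in selected]

    Z = np.zeros((n_spots, K))
    if theta_init is not None:
        ti = theta_init.to_numpy(dtype=float)
        for i, idx in enumerate(selected):
            sub = np.maximum(ti[i, idx], THETA_EPS)
            Z[i, idx] = sub / sub.sum()
    else:
        for i, idx in enumerate(selected):
            Z[i, idx] = 1.0 / idx.size
    U = np.zeros_like(Z)
    flat = np.concatenate(
        [np.concatenate([np.log(np.maximum(Z[i, selected[i]], 1e-6)), [alpha[i]]])
         for i in range(n_spots)]
    )
    trace = ADMMTrace()
    theta = Z.copy()
    for it in range(max_iter):
        V = Z - U
        res = minimize(
            _joint_nll_grad, flat,
            args=(selected, Yv, N, muv, grid, lam_l, L, rho, V, n_spots, K),
            jac=True, method="L-BFGS-B", options={"maxiter": inner_iter},
        )
        flat = res.x
        theta = np.zeros((n_spots, K))
        alphas = np.empty(n_spots)
        pos = 0
        for i in range(n_spots):
            idx = selected[i]
            k = idx.size
            eta = flat[pos : pos + k] - flat[pos : pos + k].max()
            w = np.exp(eta)
            theta[i, idx] = w / w.sum()
            alphas[i] = flat[pos + k]
            pos += k + 1
        Z_old = Z
        Z = np.zeros_like(theta)
        for i in range(n_spots):
            idx = selected[i]
            Z[i, idx] = project_simplex((theta + U)[i, idx])
        U = U + theta - Z
        r_primal = float(np.linalg.norm(theta - Z) / max(1, n_spots))
        r_dual = float(rho * np.linalg.norm(Z - Z_old) / max(1, n_spots))
        obj = lam_l * float(np.trace(Z.T @ L @ Z)) if lam_l > 0 else 0.0
        for i in range(n_spots):
            zi = np.maximum(Z[i], 0)
            zi = zi / zi.sum()
            obj += base_negloglik(zi, alphas[i], Yv[:, i], N[i], muv, sigma2,
                                  grid, check_simplex=False)
        trace.objective.append(obj)
        trace.primal_residual.append(r_primal)
        trace.dual_residual.append(r_dual)
        if r_primal < tol and r_dual < tol:
            break
    else:
        logger.warning("stage-2 ADMM reached max iterations")
    theta_df = pd.DataFrame(Z, index=Y.columns, columns=mu.index)
    return theta_df, trace


# --------------------------------------------------------------------------
# hyperparameter cross-validation
# --------------------------------------------------------------------------

def default_lambda_grid(n: int = 7) -> np.ndarray:
    """Logarithmic candidate grid on [0.1, 100] for both hyperparameters."""
    return np.round(np.logspace(-1, 2, n), 6)


def cross_validate(
    Y: pd.DataFrame,
    N: np.ndarray,
    mu: pd.DataFrame,
    L: np.ndarray,
    sigma2: float,
    alpha: np.ndarray,
    q: pd.DataFrame,
    theta_init: pd.DataFrame,
    lambda_r_grid: np.ndarray,
    lambda_l_grid: np.ndarray,
    n_folds: int = 5,
    seed: int = 0,
    admm_iter: int = 50,
) -> tuple[float, float, pd.DataFrame]:
    """Five-fold gene-wise cross-validation of (lambda_r, lambda_l).

    Marker genes are split into ``n_folds`` seeded groups of equal size.
    For each candidate pair, the two-stage fit runs on the training genes
    and the base-model log-likelihood of the held-out genes is computed at
    the fitted (theta, alpha); the pair with the largest mean validation
    log-likelihood wins, ties broken toward the lexicographically smallest
    pair (weakest regularization).

    Returns (lambda_r, lambda_l, score table).
    """
    lambda_r_grid = np.asarray(list(lambda_r_grid), dtype=float)
    lambda_l_grid = np.asarray(list(lambda_l_grid), dtype=float)
    if lambda_r_grid.size == 0 or lambda_l_grid.size == 0:
        raise ValueError("empty hyperparameter grid")
    genes = [g for g in Y.index if g in mu.columns]
    if len(genes) < n_folds:
        raise ValueError(f"need at least {n_folds} marker genes for CV")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(genes))
    folds = [sorted(order[f::n_folds]) for f in range(n_folds)]
    records = []
    for lam_r, lam_l in itertools.product(lambda_r_grid, lambda_l_grid):
        scores = []
        for fold in folds:
            val_genes = [genes[i] for i in fold]
            train_genes = [g for g in genes if g not in set(val_genes)]
            theta1, selected, _ = stage1_select(
                Y.loc[train_genes], N, mu[train_genes], sigma2, alpha, q, lam_r,
                max_iter=admm_iter, theta_init=theta_init,
            )
            theta2, _ = stage2_smooth(
                Y.loc[train_genes], N, mu[train_genes], sigma2, alpha, selected,
                L, lam_l, max_iter=admm_iter, theta_init=theta1,
            )
            grid = epsilon_grid(math.sqrt(sigma2))
            ll = 0.0
            Yval = Y.loc[val_genes].to_numpy(dtype=float)
            muval = mu[val_genes].to_numpy(dtype=float)
            th = theta2.to_numpy()
            for i in range(Yval.shape[1]):
                ti = np.maximum(th[i], THETA_EPS)
                ti = ti / ti.sum()
                ll -= base_negloglik(ti, alpha[i], Yval[:, i], N[i], muval,
                                     sigma2, grid, check_simplex=False)
            scores.append(ll / len(val_genes))
        records.append({"lambda_r": lam_r, "lambda_l": lam_l,
                        "mean_loglik": float(np.mean(scores))})
    table = pd.DataFrame.from_records(records)
    best_score = table["mean_loglik"].max()
    ties = table[np.isclose(table["mean_loglik"], best_score, rtol=0, atol=1e-9)]
    ties = ties.sort_values(["lambda_r", "lambda_l"], kind="stable")
    best = ties.iloc[0]
    return float(best["lambda_r"]), float(best["lambda_l"]), table
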