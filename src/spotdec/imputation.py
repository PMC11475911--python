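"""Random-walk imputation of cell-type composition and expression at
unmeasured locations on an enhanced-resolution grid.

The tissue outline and interior holes are recovered from a rasterized
occupancy mask; a finer square grid is laid over the bounding rectangle and
centers near the tissue are retained. Initial compositions come from the
nearest measured spot(s); one step of a Gaussian-kernel nearest-neighbor
random walk smooths them, and expression is imputed through the
Moore-Penrose pseudoinverse of the measured composition matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

__all__ = [
    "EdgeLabels",
    "HighResGrid",
    "ImputationKernel",
    "label_edge_spots",
    "build_highres_grid",
    "init_theta",
    "gaussian_kernel",
    "impute_theta",
    "impute_expression",
    "tune_imputation",
    "impute",
]


@dataclass
class EdgeLabels:
    """Per-spot edge/inner labels plus physical coordinates of hole pixels."""

    is_edge: pd.Series
    hole_centers: np.ndarray  # (n, 2) physical coords of in-hole raster cells


@dataclass
class HighResGrid:
    """Retained fine-grid centers (N* x 2) with spacings (D original, d new)."""

    centers: np.ndarray
    spacing_original: float
    spacing_new: float


@dataclass
class ImputationKernel:
    """Gaussian kernel W (cutoff phi, bandwidth tau) and the row-stochastic
    one-step walk matrix M = D^-1 W."""

    W: np.ndarray
    M: np.ndarray
    phi: float
    tau: float


def _spot_spacing(xy: np.ndarray) -> float:
    tree = cKDTree(xy)
    d, _ = tree.query(xy, k=min(2, len(xy)))
    if len(xy) < 2:
        return 1.0
    nn = d[:, 1]
    nn = nn[nn > 0]
    return float(np.median(nn)) if nn.size else 1.0


def label_edge_spots(coords: pd.DataFrame, spacing: float | None = None) -> EdgeLabels:
    """Classify spots as edge (bordering the tissue outline or an interior
    hole) or inner.

    Spot centers are snapped to a lattice with the array spacing D; filling
    the occupancy mask exposes interior holes, and a spot is an edge spot
    when its lattice cell is 4-adjacent to the tissue outside or to a hole
    cell. Degenerate layouts (all collinear) make every spot an edge spot.
    Assumes a roughly regular (square-array) spot layout.
    """
    xy = coords[["x", "y"]].to_numpy(dtype=float)
    n = len(xy)
    if n < 3 or np.linalg.matrix_rank(xy - xy.mean(axis=0)) < 2:
        return EdgeLabels(pd.Series(True, index=coords.index), np.empty((0, 2)))
    D = spacing if spacing is not None else _spot_spacing(xy)
    origin = xy.min(axis=0)
    ij = np.round((xy - origin) / D).astype(int)
    shape = ij.max(axis=0) + 3  # one-cell pad on every side
    occ = np.zeros((shape[1], shape[0]), dtype=bool)  # row = y, col = x
    occ[ij[:, 1] + 1, ij[:, 0] + 1] = True
    filled = ndimage.binary_fill_holes(occ)
    holes = filled & ~occ
    cross = ndimage.generate_binary_structure(2, 1)
    outside_or_hole = (~filled) | holes
    edge_cells = occ & ndimage.binary_dilation(outside_or_hole, structure=cross)
    is_edge = pd.Series(edge_cells[ij[:, 1] + 1, ij[:, 0] + 1], index=coords.index)
    hole_xy = (np.argwhere(holes)[:, ::-1] - 1) * D + origin
    return EdgeLabels(is_edge, hole_xy)


def build_highres_grid(coords: pd.DataFrame, D: float, d: float,
                       labels: EdgeLabels | None = None) -> HighResGrid:
    """Grid the spots' bounding rectangle into d-squares and retain centers
    within D of an inner spot or within (D - d)/2 of an edge spot."""
    if not (0 < d < D):
        raise ValueError("need 0 < d < D")
    if labels is None:
        labels = label_edge_spots(coords, spacing=D)
    xy = coords[["x", "y"]].to_numpy(dtype=float)
    lo, hi = xy.min(axis=0), xy.max(axis=0)
    nx = max(1, int(np.ceil((hi[0] - lo[0]) / d)))
    ny = max(1, int(np.ceil((hi[1] - lo[1]) / d)))
    gx, gy = np.meshgrid(lo[0] + (np.arange(nx) + 0.5) * d,
                         lo[1] + (np.arange(ny) + 0.5) * d)
    cand = np.column_stack([gx.ravel(), gy.ravel()])
    edge_mask = labels.is_edge.to_numpy()
    keep = np.zeros(len(cand), dtype=bool)
    inner = xy[~edge_mask]
    edge = xy[edge_mask]
    if inner.size:
        keep |= cKDTree(inner).query(cand)[0] <= D
    if edge.size:
        keep |= cKDTree(edge).query(cand)[0] <= (D - d) / 2.0
    return HighResGrid(cand[keep], D, d)


def init_theta(grid: HighResGrid, theta: pd.DataFrame, coords: pd.DataFrame,
               tie_tol: float = 1e-9) -> pd.DataFrame:
    """Initial composition at each new center: the mean of theta over the
    original spot(s) at minimal distance (ties within ``tie_tol`` averaged)."""
    xy = coords.loc[theta.index, ["x", "y"]].to_numpy(dtype=float)
    th = theta.to_numpy(dtype=float)
    out = np.empty((len(grid.centers), th.shape[1]))
    diffs = grid.centers[:, None, :] - xy[None, :, :]
    dists = np.linalg.norm(diffs, axis=2)
    for i, drow in enumerate(dists):
        nearest = drow <= drow.min() + tie_tol
        out[i] = th[nearest].mean(axis=0)
    ids = [f"new_{i}" for i in range(len(grid.centers))]
    return pd.DataFrame(out, index=ids, columns=theta.columns)


def gaussian_kernel(centers: np.ndarray, phi: float, tau: float) -> ImputationKernel:
    """W_ij = exp(-r_ij^2 / (2 tau^2)) for r_ij <= phi, else 0; M = D^-1 W.
    A center with an all-zero row (isolated) gets self-weight 1."""
    if phi <= 0 or tau <= 0:
        raise ValueError("phi and tau must be positive")
    diff = centers[:, None, :] - centers[None, :, :]
    r = np.linalg.norm(diff, axis=2)
    W = np.where(r <= phi, np.exp(-(r**2) / (2.0 * tau**2)), 0.0)
    rowsum = W.sum(axis=1)
    isolated = rowsum == 0
    if isolated.any():
        W[isolated, isolated] = 1.0
        rowsum = W.sum(axis=1)
    M = W / rowsum[:, None]
    return ImputationKernel(W, M, phi, tau)


def impute_theta(kernel: ImputationKernel, theta0: pd.DataFrame) -> pd.DataFrame:
    """One-step random walk: theta_imputed = M @ theta0 (rows stay on the simplex)."""
    return pd.DataFrame(kernel.M @ theta0.to_numpy(dtype=float),
                        index=theta0.index, columns=theta0.columns)


def impute_expression(theta_imputed: pd.DataFrame, theta: pd.DataFrame,
                      X: pd.DataFrame) -> pd.DataFrame:
    """X_imputed = theta_imputed theta^+ X with theta^+ = (theta'theta)^-1 theta'.

    ``X`` is the depth-normalized measured expression (spots x genes),
    aligned with ``theta`` (spots x K). A rank-deficient theta falls back to
    the SVD pseudoinverse with a warning.
    """
    th = theta.to_numpy(dtype=float)
    cols = list(theta.columns)
    gram = th.T @ th
    try:
        pinv = np.linalg.solve(gram, th.T)
    except np.linalg.LinAlgError:
        logger.warning("theta is rank deficient; using SVD pseudoinverse")
        pinv = np.linalg.pinv(th)
    out = theta_imputed[cols].to_numpy(dtype=float) @ pinv @ X.loc[theta.index].to_numpy(dtype=float)
    return pd.DataFrame(out, index=theta_imputed.index, columns=X.columns)


def impute(theta: pd.DataFrame, coords: pd.DataFrame, d: float, phi: float,
           tau: float, D: float | None = None,
           X: pd.DataFrame | None = None):
    """Full imputation at resolution ``d``: grid, init, one random-walk
    step, optional expression imputation. Returns (theta_imputed, centers)
    or (theta_imputed, centers, X_imputed)."""
    xy = coords.loc[theta.index, ["x", "y"]].to_numpy(dtype=float)
    if D is None:
        D = _spot_spacing(xy)
    labels = label_edge_spots(coords.loc[theta.index], spacing=D)
    grid = build_highres_grid(coords.loc[theta.index], D, d, labels)
    theta0 = init_theta(grid, theta, coords)
    kernel = gaussian_kernel(grid.centers, phi, tau)
    theta_imp = impute_theta(kernel, theta0)
    centers = pd.DataFrame(grid.centers, index=theta_imp.index, columns=["x", "y"])
    if X is None:
        return theta_imp, centers
    return theta_imp, centers, impute_expression(theta_imp, theta, X)


def tune_imputation(sc, phi_grid, tau_grid, sizes=tuple(range(100, 1000, 100)),
                    base_size: float = 1000.0):
    """Choose (phi, tau) minimizing the average composition RMSE when
    imputing from the coarsest map down to each finer one.

    ``sc`` is a single-cell-resolution tissue (``SingleCellSpatial``); it is
    coarse-grained at ``base_size`` and at each size in ``sizes``; for every
    candidate pair the base map's exact compositions are imputed onto each
    finer grid and compared to that grid's ground truth (each imputed
    center scored against its nearest truth spot). The search ranges for
    both parameters default to 1-200 in the caller's units.
    """
    from .simulation import coarse_grain  # local import to avoid a cycle

    phi_grid = list(phi_grid)
    tau_grid = list(tau_grid)
    if not phi_grid or not tau_grid:
        raise ValueError("empty hyperparameter grid")
    sizes = [s for s in sizes if s < base_size]
    if not sizes:
        raise ValueError("no target size finer than the base size")
    base = coarse_grain(sc, base_size)
    fine = {s: coarse_grain(sc, s) for s in sizes}
    labels = label_edge_spots(base.coords, spacing=base_size)
    best = None
    for phi in phi_grid:
        for tau in tau_grid:
            errs = []
            for s, target in fine.items():
                grid = build_highres_grid(base.coords, base_size, s, labels)
                if len(grid.centers) == 0:
                    continue
                theta0 = init_theta(grid, base.truth, base.coords)
                kern = gaussian_kernel(grid.centers, phi, tau)
                imp = impute_theta(kern, theta0).to_numpy()
                tree = cKDTree(target.coords[["x", "y"]].to_numpy())
                _, nearest = tree.query(grid.centers)
                truth = target.truth.to_numpy()[nearest]
                cols = [list(target.truth.columns).index(c) for c in base.truth.columns]
                errs.append(float(np.sqrt(np.mean((imp - truth[:, cols]) ** 2))))
            if not errs:
                raise ValueError(
                    "no retained grid centers at any target size; the base map "
                    "is too coarse for the requested resolutions"
                )
            score = float(np.mean(errs))
            if best is None or score < best[0]:
                best = (score, phi, tau)
    return best[1], best[2]
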