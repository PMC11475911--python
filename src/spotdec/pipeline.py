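"""End-to-end deconvolution: preprocessing, pseudo-spots, CVAE platform
adjustment, signature construction, MLE initialization, hyperparameter
cross-validation, and the two-stage regularized fit.

Every component can be disabled through ablation switches on
:class:`DeconvConfig` (no_cvae, no_pseudospots, no_lasso, no_laplacian),
reproducing the method's single-component test arms.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import cvae as cvae_mod
from . import glrm
from . import io_prep
from . import pseudospot as ps

logger = logging.getLogger(__name__)

__all__ = ["DeconvConfig", "DeconvResult", "deconvolve"]


@dataclass
class DeconvConfig:
    """Run configuration; defaults follow the method's standard settings."""

    n_hvg: int = 200
    marker_criteria: io_prep.MarkerCriteria = field(default_factory=io_prep.MarkerCriteria)
    pseudo_cells_min: int = 2
    pseudo_cells_max: int = 10
    n_pseudospots: int | None = None  # None -> min(100*N*K, 500000)
    cvae: cvae_mod.TrainConfig = field(default_factory=cvae_mod.TrainConfig)
    lambda_r: float | None = None  # None -> cross-validate
    lambda_l: float | None = None
    lambda_r_grid: tuple[float, ...] = tuple(glrm.default_lambda_grid())
    lambda_l_grid: tuple[float, ...] = tuple(glrm.default_lambda_grid())
    cv_folds: int = 5
    sigma_grid: tuple[float, ...] = (0.05, 0.1, 0.2, 0.4, 0.8)
    neighbor_factor: float = 1.2
    no_cvae: bool = False
    no_pseudospots: bool = False
    no_lasso: bool = False
    no_laplacian: bool = False
    stage1_iter: int = 100
    stage2_iter: int = 60
    seed: int = 0

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, default=str, indent=2)


@dataclass
class DeconvResult:
    theta: pd.DataFrame  # spots x K proportions
    theta_mle: pd.DataFrame
    alpha: np.ndarray
    sigma2: float
    lambda_r: float
    lambda_l: float
    marker_genes: list[str]
    gene_panel: list[str]
    config: DeconvConfig
    cv_table: pd.DataFrame | None = None

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.theta.to_csv(outdir / "proportions.csv")
        meta = {
            "lambda_r": self.lambda_r,
            "lambda_l": self.lambda_l,
            "sigma2": self.sigma2,
            "marker_genes": self.marker_genes,
            "gene_panel": self.gene_panel,
            "config": json.loads(self.config.to_json()),
        }
        (outdir / "run_metadata.json").write_text(json.dumps(meta, indent=2))


def _build_panel(ref: pd.DataFrame, annot: pd.Series, config: DeconvConfig):
    markers = io_prep.select_marker_genes(
        io_prep.library_normalize(ref, 1.0), annot, config.marker_criteria, raw=ref
    )
    n_hvg = min(config.n_hvg, ref.shape[0])
    hvgs = io_prep.select_hvgs(ref, n_hvg)
    panel = sorted(set(markers) | set(hvgs))
    return panel, markers


def deconvolve(
    st: pd.DataFrame,
    coords: pd.DataFrame,
    ref: pd.DataFrame,
    annot: pd.Series,
    config: DeconvConfig = DeconvConfig(),
) -> DeconvResult:
    """Estimate per-spot cell-type proportions.

    ``st``: genes x spots UMI counts; ``coords``: spot coordinates with
    columns x, y; ``ref``: genes x cells reference counts; ``annot``: cell
    -> type labels.
    """
    st = st.loc[:, st.sum(axis=0) > 0]
    coords = coords.loc[st.columns]
    shared = st.index.intersection(ref.index)
    if shared.empty:
        raise ValueError("ST and reference share no genes")
    st = st.loc[shared]
    ref = ref.loc[shared]
    annot = annot.loc[annot.index.intersection(ref.columns)]
    n_types = annot.nunique()
    n_spots = st.shape[1]
    depth = st.sum(axis=0).to_numpy(dtype=float)  # observed total UMI per spot

    panel, markers_raw = _build_panel(ref, annot, config)

    if config.no_cvae:
        adjusted_st = st
        adjusted_ref = ref
        markers = markers_raw
        N = depth
    else:
        st_p = io_prep.library_normalize(st.loc[panel], 1.0)
        ref_p = io_prep.library_normalize(ref.loc[panel], 1.0)
        if config.no_pseudospots:
            pseudo_tr = pseudo_val = None
            sc_cond = ref_p
        else:
            n_pseudo = (config.n_pseudospots if config.n_pseudospots is not None
                        else ps.plan_pseudospot_count(n_spots, n_types))
            pseudo = ps.generate_pseudospots(
                ref_p, annot, n_pseudo, config.pseudo_cells_min,
                config.pseudo_cells_max, seed=config.seed,
            )
            tr_idx, val_idx = ps.train_val_split(pseudo, config.cvae.val_fraction,
                                                 seed=config.seed)
            pseudo_expr = pseudo.expression.T  # genes x pseudo-spots
            pseudo_tr = pseudo_expr.iloc[:, tr_idx]
            pseudo_val = pseudo_expr.iloc[:, val_idx]
            sc_cond = pd.concat([ref_p, pseudo_expr], axis=1)
        st_scaled, factors_st = cvae_mod.minmax_scale(st_p)
        _, factors_sc = cvae_mod.minmax_scale(sc_cond)
        ref_scaled = cvae_mod.minmax_scale(ref_p, factors_sc)
        pseudo_tr_s = (cvae_mod.minmax_scale(pseudo_tr, factors_sc)
                       if pseudo_tr is not None else None)
        pseudo_val_s = (cvae_mod.minmax_scale(pseudo_val, factors_sc)
                        if pseudo_val is not None else None)
        trained = cvae_mod.train_cvae(
            st_scaled, ref_scaled, pseudo_tr_s, pseudo_val_s,
            factors_sc, factors_st, n_types, config.cvae,
        )
        adjusted_st = cvae_mod.transform_st(trained, st_scaled)
        adjusted_ref = cvae_mod.denoise_reference(trained, ref_scaled)
        markers = io_prep.select_marker_genes(
            io_prep.library_normalize(adjusted_ref, 1.0), annot, config.marker_criteria
        )
        if len(markers) < config.cv_folds:
            logger.warning(
                "only %d markers from the adjusted reference; falling back to "
                "the raw marker panel", len(markers),
            )
            markers = [g for g in markers_raw if g in adjusted_ref.index]
        N = adjusted_st.sum(axis=0).to_numpy(dtype=float)

    markers = [g for g in markers if g in adjusted_st.index]
    mu = glrm.compute_signatures(adjusted_ref, annot, markers)
    keep = mu.sum(axis=0) > 0
    mu = mu.loc[:, keep]
    markers = list(mu.columns)
    Y = adjusted_st.loc[markers]
    nz = Y.sum(axis=1) > 0
    Y = Y.loc[nz]
    mu = mu[list(Y.index)]
    markers = list(Y.index)

    graph = glrm.build_spatial_graph(coords, config.neighbor_factor)
    L = graph.laplacian

    theta_mle, alpha, sigma2 = glrm.fit_base_mle(Y, N, mu, sigma_grid=config.sigma_grid)
    q = glrm.weights_from_mle(theta_mle)

    lam_r, lam_l, cv_table = config.lambda_r, config.lambda_l, None
    if config.no_lasso:
        lam_r = 0.0
    if config.no_laplacian:
        lam_l = 0.0
    if lam_r is None or lam_l is None:
        cv_r = (lam_r,) if lam_r is not None else config.lambda_r_grid
        cv_l = (lam_l,) if lam_l is not None else config.lambda_l_grid
        lam_r, lam_l, cv_table = glrm.cross_validate(
            Y, N, mu, L, sigma2, alpha, q, theta_mle,
            np.asarray(cv_r), np.asarray(cv_l),
            n_folds=config.cv_folds, seed=config.seed,
        )

    theta1, selected, _ = glrm.stage1_select(
        Y, N, mu, sigma2, alpha, q, lam_r,
        max_iter=config.stage1_iter, theta_init=theta_mle,
    )
    theta2, _ = glrm.stage2_smooth(
        Y, N, mu, sigma2, alpha, selected, L, lam_l,
        max_iter=config.stage2_iter, theta_init=theta1,
    )
    return DeconvResult(
        theta=theta2, theta_mle=theta_mle, alpha=alpha, sigma2=sigma2,
        lambda_r=float(lam_r), lambda_l=float(lam_l),
        marker_genes=markers, gene_panel=panel, config=config, cv_table=cv_table,
    )
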