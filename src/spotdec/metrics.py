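"""Per-spot evaluation of estimated cell-type compositions against ground
truth (RMSE, Jensen-Shannon divergence, Pearson correlation, per-spot FDR)
and agreement of dominant-cell-type maps with region annotations (adjusted
Rand index and purity)."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

logger = logging.getLogger(__name__)

__all__ = ["rmse", "jsd", "pearson", "fdr", "evaluate", "aggregate", "ari_purity"]


def rmse(theta_hat: np.ndarray, theta: np.ndarray) -> float:
    """Root mean squared error over the K proportions of one spot."""
    theta_hat = np.asarray(theta_hat, float)
    theta = np.asarray(theta, float)
    if theta_hat.shape != theta.shape:
        raise ValueError("length mismatch")
    return float(np.sqrt(np.mean((theta_hat - theta) ** 2)))


def _kl(p: np.ndarray, q: np.ndarray) -> float:
    mask = p > 0
    return float(np.sum(p[mask] * np.log2(p[mask] / q[mask])))


def jsd(theta_hat: np.ndarray, theta: np.ndarray) -> float:
    """Jensen-Shannon divergence (base-2 logs, so bounded in [0, 1])."""
    p = np.asarray(theta_hat, float)
    q = np.asarray(theta, float)
    if (p < 0).any() or (q < 0).any():
        raise ValueError("negative entries")
    m = 0.5 * (p + q)
    return 0.5 * (_kl(p, m) + _kl(q, m))


def pearson(theta_hat: np.ndarray, theta: np.ndarray) -> float | None:
    """Sample correlation of the two K-vectors; None when either is constant."""
    p = np.asarray(theta_hat, float)
    q = np.asarray(theta, float)
    if p.size < 2:
        raise ValueError("need at least 2 cell types")
    if np.ptp(p) == 0 or np.ptp(q) == 0:
        return None
    return float(np.corrcoef(p, q)[0, 1])


def fdr(theta_hat: np.ndarray, theta: np.ndarray) -> float | None:
    """Fraction of predicted-present cell types (theta_hat > 0) that are
    truly absent; None when nothing is predicted present."""
    p = np.asarray(theta_hat, float)
    q = np.asarray(theta, float)
    called = p > 0
    if called.sum() == 0:
        return None
    return float(np.sum(called & (q == 0)) / called.sum())


def evaluate(theta_hat: pd.DataFrame, theta: pd.DataFrame) -> pd.DataFrame:
    """Per-spot metric table; rows aligned on shared spots, cell-type
    columns aligned by name."""
    spots = theta_hat.index.intersection(theta.index)
    if spots.empty:
        raise ValueError("no shared spots between estimate and truth")
    cols = [c for c in theta.columns if c in theta_hat.columns]
    rows = []
    for s in spots:
        p = theta_hat.loc[s, cols].to_numpy(float)
        q = theta.loc[s, cols].to_numpy(float)
        rows.append({
            "rmse": rmse(p, q),
            "jsd": jsd(p, q),
            "pearson": pearson(p, q),
            "fdr": fdr(p, q),
        })
    return pd.DataFrame(rows, index=spots)


def aggregate(per_spot: pd.DataFrame) -> dict:
    """Median and interquartile range per metric; spots with undefined
    values (e.g. constant-vector Pearson) are excluded and counted."""
    out = {}
    for col in per_spot.columns:
        vals = per_spot[col].dropna().astype(float)
        out[col] = {
            "median": float(vals.median()) if len(vals) else None,
            "iqr": float(vals.quantile(0.75) - vals.quantile(0.25)) if len(vals) else None,
            "n": int(len(vals)),
            "n_undefined": int(per_spot[col].isna().sum()),
        }
    return out


def ari_purity(dominant: pd.Series, regions: pd.Series) -> tuple[float, float]:
    """Adjusted Rand index and purity of the per-spot dominant-cell-type
    labeling against region annotations (purity maps each predicted class
    to its majority region)."""
    spots = dominant.index.intersection(regions.index)
    if spots.empty:
        raise ValueError("no shared spots between labelings")
    pred = dominant.loc[spots]
    true = regions.loc[spots]
    ari = float(adjusted_rand_score(true, pred))
    ct = pd.crosstab(pred, true)
    purity = float(ct.max(axis=1).sum() / ct.to_numpy().sum())
    return ari, purity


def dominant_type(theta: pd.DataFrame) -> pd.Series:
    """Argmax cell type per spot; ties resolve to the first column and are logged."""
    vals = theta.to_numpy()
    ties = (vals == vals.max(axis=1, keepdims=True)).sum(axis=1) > 1
    if ties.any():
        logger.info("%d spots had tied dominant types; first index kept", int(ties.sum()))
    return pd.Series(theta.columns[np.argmax(vals, axis=1)], index=theta.index)
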