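"""Reading, writing and preprocessing of count matrices, coordinates and annotations.

Count matrices are represented as pandas DataFrames with genes in rows
(index = gene ids) and samples (cells or spots) in columns. Spot
coordinates are DataFrames indexed by sample id with columns ``x``/``y``;
cell annotations are Series mapping cell id to cell-type label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
from scipy.stats import rankdata, mannwhitneyu
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerCriteria",
    "load_count_matrix",
    "write_count_matrix",
    "load_coordinates",
    "load_annotation",
    "library_normalize",
    "select_hvgs",
    "select_marker_genes",
]


@dataclass(frozen=True)
class MarkerCriteria:
    """Thresholds for pairwise cell-type marker selection.

    fdr_max: Benjamini-Hochberg FDR cutoff within each pairwise comparison.
    fc_min: minimum fold change (ratio of mean normalized expression,
        type a over type b).
    pct1_min: minimum fraction of type-a cells with raw count > 0.
    pct2_max: maximum fraction of type-b cells with raw count > 0.
    top_n: genes kept per ordered comparison after sorting by fold change.
    """

    fdr_max: float = 0.05
    fc_min: float = 1.2
    pct1_min: float = 0.3
    pct2_max: float = 0.1
    top_n: int = 20

    def __post_init__(self) -> None:
        if not (0 < self.fdr_max <= 1):
            raise ValueError("fdr_max must be in (0, 1]")
        if self.fc_min <= 0:
            raise ValueError("fc_min must be positive")
        if not (0 <= self.pct1_min <= 1 and 0 <= self.pct2_max <= 1):
            raise ValueError("pct thresholds must be fractions")
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")


def _validate_counts(df: pd.DataFrame) -> pd.DataFrame:
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene identifiers: {dupes[:5]}")
    if df.columns.has_duplicates:
        dupes = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample identifiers: {dupes[:5]}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError("count matrix contains non-numeric entries")
    if np.isnan(values).any():
        raise ValueError("count matrix contains missing values")
    if (values < 0).any():
        raise ValueError("count matrix contains negative entries")
    return df


def load_count_matrix(path: str | Path, orientation: str = "genes") -> pd.DataFrame:
    """Load a UMI count matrix, returned as genes x samples.

    ``path`` may be a CSV/TSV with header row and index column, or a
    MatrixMarket ``.mtx`` file with sidecar id files ``<stem>_genes.txt``
    and ``<stem>_samples.txt`` (one id per line, matching MTX rows/columns).
    ``orientation`` says what the file's rows are: ``"genes"`` or ``"samples"``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if orientation not in ("genes", "samples"):
        raise ValueError("orientation must be 'genes' or 'samples'")
    if path.suffix == ".mtx":
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        rows = path.with_name(path.stem + "_genes.txt").read_text().split()
        cols = path.with_name(path.stem + "_samples.txt").read_text().split()
        df = pd.DataFrame(np.asarray(mat), index=rows, columns=cols)
    else:
        sep = "\t" if path.suffix in (".tsv", ".txt") else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
    if orientation == "samples":
        df = df.T
    return _validate_counts(df)


def write_count_matrix(df: pd.DataFrame, path: str | Path) -> None:
    """Write a genes x samples matrix as CSV (round-trips with the loader)."""
    pd.DataFrame(df).to_csv(path)


def load_coordinates(path: str | Path) -> pd.DataFrame:
    """Load spot coordinates from a CSV with columns id,x,y."""
    df = pd.read_csv(path, index_col=0)
    missing = {"x", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"coordinate file lacks columns: {sorted(missing)}")
    coords = df[["x", "y"]].astype(float)
    if not np.isfinite(coords.to_numpy()).all():
        raise ValueError("non-finite coordinates")
    return coords


def load_annotation(path: str | Path) -> pd.Series:
    """Load a cell -> cell-type annotation from a CSV with columns id,cell_type."""
    df = pd.read_csv(path, index_col=0)
    if "cell_type" not in df.columns:
        raise ValueError("annotation file lacks a 'cell_type' column")
    return df["cell_type"].astype(str)


def library_normalize(counts: pd.DataFrame, scale: float = 1.0) -> pd.DataFrame:
    """Scale each sample (column) to a common total ``scale``.

    Entry (j, i) becomes ``scale * U_ij / sum_j U_ij``. Samples with zero
    total count are dropped with a logged warning.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    totals = counts.sum(axis=0)
    zero = totals[totals == 0].index.tolist()
    if zero:
        logger.warning("dropping %d zero-total samples: %s", len(zero), zero[:10])
        counts = counts.drop(columns=zero)
        totals = totals.drop(index=zero)
    return counts.div(totals, axis=1) * scale


def select_hvgs(ref: pd.DataFrame, n: int) -> list[str]:
    """Rank genes by normalized dispersion of log1p counts-per-10k; top ``n``.

    Dispersion = variance / mean of the log-normalized expression, z-scored
    within 20 mean-expression bins (the standard dispersion-based highly
    variable gene statistic). Deterministic given the input.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > ref.shape[0]:
        raise ValueError("n exceeds number of genes")
    logn = np.log1p(library_normalize(ref, 1e4))
    mean = logn.mean(axis=1)
    var = logn.var(axis=1, ddof=1) if logn.shape[1] > 1 else logn.var(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    disp = pd.Series(disp, index=ref.index)
    # z-score dispersion within mean bins so the statistic is not driven by
    # the global mean-dispersion trend
    nbins = min(20, max(1, ref.shape[0] // 2))
    bins = pd.cut(mean.rank(method="first"), bins=nbins, labels=False)
    normed = disp.copy()
    for b in range(nbins):
        mask = bins == b
        if mask.sum() == 0:
            continue
        mu, sd = disp[mask].mean(), disp[mask].std(ddof=0)
        normed[mask] = (disp[mask] - mu) / sd if sd > 0 else 0.0
    normed[var == 0] = -np.inf  # constant genes rank last
    order = normed.sort_values(ascending=False, kind="stable")
    return order.index[:n].tolist()


def select_marker_genes(
    ref_norm: pd.DataFrame,
    annot: pd.Series,
    crit: MarkerCriteria = MarkerCriteria(),
    raw: pd.DataFrame | None = None,
) -> list[str]:
    """Pairwise Wilcoxon rank-sum marker selection.

    For every ordered pair of cell types (a, b): a two-sided rank-sum test
    per gene on the normalized expression, BH correction across genes within
    the comparison, then threshold on FDR, fold change (mean_a/mean_b with a
    1e-9 pseudo-count), pct.1 (fraction of a-cells expressing) and pct.2.
    The top ``crit.top_n`` genes per comparison by fold change are unioned.

    ``raw``, if given, supplies the counts used for the "expressing"
    (count > 0) fractions; otherwise ``ref_norm > 0`` is used.
    """
    annot = annot.loc[annot.index.intersection(ref_norm.columns)]
    types = sorted(annot.unique())
    if len(types) < 2:
        raise ValueError("marker selection needs at least 2 cell types")
    expressed = (raw if raw is not None else ref_norm) > 0
    selected: set[str] = set()
    eps = 1e-9
    groups = {t: annot.index[annot == t] for t in types}
    usable = [t for t in types if len(groups[t]) >= 2]
    for t in types:
        if t not in usable:
            logger.warning("cell type %r has < 2 cells; skipping its comparisons", t)
    X = {t: ref_norm[groups[t]].to_numpy() for t in usable}
    pct = {t: expressed[groups[t]].mean(axis=1).to_numpy() for t in usable}
    means = {t: X[t].mean(axis=1) for t in usable}
    for a in usable:
        for b in usable:
            if a == b:
                continue
            stat_p = mannwhitneyu(
                X[a], X[b], axis=1, alternative="two-sided", method="asymptotic"
            )
            fdr = multipletests(stat_p.pvalue, method="fdr_bh")[1]
            fc = (means[a] + eps) / (means[b] + eps)
            keep = (
                (fdr < crit.fdr_max)
                & (fc >= crit.fc_min)
                & (pct[a] >= crit.pct1_min)
                & (pct[b] <= crit.pct2_max)
            )
            idx = np.flatnonzero(keep)
            top = idx[np.argsort(-fc[idx], kind="stable")][: crit.top_n]
            selected.update(ref_norm.index[top])
    return sorted(selected)
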