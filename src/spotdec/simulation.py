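"""Ground-truthed ST simulation by coarse-graining single-cell-resolution
spatial data, plus scenario generators (sequencing-based replacement,
density scaling, rare-type down-sampling, reference mismatch) and a fully
synthetic fixture generator.

Coarse-graining grids a tissue with known per-cell coordinates, counts and
type labels into square capture spots; the exact cell-count fractions per
spot are the deconvolution ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SingleCellSpatial",
    "SimulatedST",
    "coarse_grain",
    "sequencing_replace",
    "densify",
    "downsample_celltype",
    "mismatch_scenarios",
    "make_fixture",
]


@dataclass
class SingleCellSpatial:
    """Single-cell-resolution spatial data: counts (genes x cells),
    per-cell coordinates (x, y) and cell-type labels."""

    counts: pd.DataFrame
    coords: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        if not np.isfinite(self.coords[["x", "y"]].to_numpy()).all():
            raise ValueError("non-finite cell coordinates")


@dataclass
class SimulatedST:
    """Coarse-grained spot data with exact ground-truth composition."""

    counts: pd.DataFrame  # genes x spots, nUMI
    coords: pd.DataFrame  # spots x (x, y), square centers
    truth: pd.DataFrame  # spots x K cell-count fractions
    cells_per_spot: pd.Series


def coarse_grain(sc: SingleCellSpatial, grid_size: float, scale_n: int = 1000) -> SimulatedST:
    """Grid the tissue into ``grid_size`` squares and aggregate.

    Per nonempty square: ground truth = cell-count fractions per type, and
    nUMI_j = ceil(mean over cells of (U_ij / sum_j U_ij) * scale_n), i.e.
    the ceiling of the scaled average library-normalized expression.
    Squares are half-open and anchored at (min x, min y); only spots with
    at least one cell are retained.
    """
    if grid_size <= 0:
        raise ValueError("grid_size must be positive")
    if sc.counts.shape[1] == 0:
        raise ValueError("empty tissue")
    xy = sc.coords[["x", "y"]].to_numpy(dtype=float)
    origin = xy.min(axis=0)
    cell_bins = np.floor((xy - origin) / grid_size).astype(int)
    rel = sc.counts.div(sc.counts.sum(axis=0), axis=1)  # per-cell relative expression
    types = sorted(sc.labels.unique())
    type_codes = pd.Categorical(sc.labels.loc[sc.counts.columns], categories=types).codes
    spots, truth_rows, count_cols, centers, n_cells = [], [], [], [], []
    keys = pd.DataFrame(cell_bins, columns=["bx", "by"], index=sc.counts.columns)
    for (bx, by), cells in keys.groupby(["bx", "by"]).groups.items():
        cells = list(cells)
        spot_id = f"spot_{bx}_{by}"
        spots.append(spot_id)
        codes = type_codes[[sc.counts.columns.get_loc(c) for c in cells]]
        frac = np.bincount(codes, minlength=len(types)) / len(cells)
        truth_rows.append(frac)
        numi = np.ceil(rel[cells].mean(axis=1).to_numpy() * scale_n).astype(np.int64)
        count_cols.append(numi)
        centers.append(origin + (np.array([bx, by]) + 0.5) * grid_size)
        n_cells.append(len(cells))
    counts = pd.DataFrame(np.column_stack(count_cols), index=sc.counts.index, columns=spots)
    coords = pd.DataFrame(np.array(centers), index=spots, columns=["x", "y"])
    truth = pd.DataFrame(np.array(truth_rows), index=spots, columns=types)
    return SimulatedST(counts, coords, truth, pd.Series(n_cells, index=spots))


def _replacement_pools(annot: pd.Series, types, rng) -> dict:
    return {t: list(rng.permutation(annot.index[annot == t].to_numpy())) for t in types}


def sequencing_replace(
    sc: SingleCellSpatial, ref: pd.DataFrame, annot: pd.Series, seed: int = 0
) -> SingleCellSpatial:
    """Swap each cell's profile for a random same-type reference cell.

    Coordinates and labels are unchanged; reference cells are drawn without
    replacement while available, then with replacement. Produces a purely
    sequencing-based tissue on the original spatial layout.
    """
    rng = np.random.default_rng(seed)
    types = set(sc.labels.unique())
    missing = types - set(annot.unique())
    if missing:
        raise ValueError(f"reference lacks cell types: {sorted(missing)}")
    pools = _replacement_pools(annot, types, rng)
    new_cols = []
    for cell in sc.counts.columns:
        t = sc.labels.loc[cell]
        if pools[t]:
            donor = pools[t].pop()
        else:
            donor = rng.choice(annot.index[annot == t].to_numpy())
        new_cols.append(ref[donor].to_numpy())
    counts = pd.DataFrame(
        np.column_stack(new_cols), index=ref.index, columns=sc.counts.columns
    )
    return SingleCellSpatial(counts, sc.coords.copy(), sc.labels.copy())


def densify(
    sc: SingleCellSpatial, ref: pd.DataFrame, annot: pd.Series, factor: int, seed: int = 0
) -> SingleCellSpatial:
    """Multiply cell density by ``factor`` without changing composition.

    For every existing cell, (factor - 1) additional same-type cells are
    drawn from the reference (without replacement while available, then
    with replacement and a warning) and placed at the same location, so
    per-spot cell-type proportions are exactly preserved.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    rng = np.random.default_rng(seed)
    types = set(sc.labels.unique())
    pools = _replacement_pools(annot, types, rng)
    cols, ids, xs, ys, labs = [], [], [], [], []
    warned = False
    for cell in sc.counts.columns:
        t = sc.labels.loc[cell]
        x, y = sc.coords.loc[cell, ["x", "y"]]
        for r in range(factor - 1):
            if pools[t]:
                donor = pools[t].pop()
            else:
                if not warned:
                    logger.warning("reference exhausted for type %r; sampling with replacement", t)
                    warned = True
                donor = rng.choice(annot.index[annot == t].to_numpy())
            cols.append(ref[donor].to_numpy())
            ids.append(f"{cell}_dense{r}")
            xs.append(x)
            ys.append(y)
            labs.append(t)
    extra_counts = pd.DataFrame(np.column_stack(cols), index=ref.index, columns=ids) if ids else None
    base = sc.counts.reindex(index=ref.index, fill_value=0) if extra_counts is not None else sc.counts
    counts = pd.concat([base, extra_counts], axis=1) if extra_counts is not None else base
    coords = pd.concat([sc.coords, pd.DataFrame({"x": xs, "y": ys}, index=ids)])
    labels = pd.concat([sc.labels, pd.Series(labs, index=ids)])
    return SingleCellSpatial(counts, coords, labels)


def downsample_celltype(
    ref: pd.DataFrame, annot: pd.Series, celltype: str, n: int, seed: int = 0
) -> tuple[pd.DataFrame, pd.Series]:
    """Keep a seeded uniform sample of ``n`` cells of one type; all other
    types are untouched. Emulates a rare cell type in the reference."""
    cells = annot.index[annot == celltype]
    if n > len(cells):
        raise ValueError(f"requested {n} cells but only {len(cells)} of type {celltype!r}")
    rng = np.random.default_rng(seed)
    keep_type = rng.choice(cells.to_numpy(), size=n, replace=False)
    keep = annot.index[annot != celltype].tolist() + list(keep_type)
    keep = [c for c in ref.columns if c in set(keep)]
    return ref[keep], annot.loc[keep]


def mismatch_scenarios(
    ref: pd.DataFrame,
    annot: pd.Series,
    drop: list[str] | None = None,
    add_from: tuple[pd.DataFrame, pd.Series] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Build mismatched references: drop cell types (missing-type scenario)
    and/or append externally labeled cells (extra-type scenario)."""
    drop = drop or []
    missing = set(drop) - set(annot.unique())
    if missing:
        raise ValueError(f"cannot drop absent types: {sorted(missing)}")
    keep = annot.index[~annot.isin(drop)]
    if keep.empty or annot.loc[keep].nunique() < 2:
        raise ValueError("dropping would leave fewer than 2 cell types")
    out_ref, out_annot = ref[keep], annot.loc[keep]
    if add_from is not None:
        extra_counts, extra_labels = add_from
        extra_counts = extra_counts.reindex(index=out_ref.index, fill_value=0)
        out_ref = pd.concat([out_ref, extra_counts], axis=1)
        out_annot = pd.concat([out_annot, extra_labels.astype(str)])
    return out_ref, out_annot


def make_fixture(
    n_types: int = 5,
    n_cells: int = 2000,
    n_genes: int = 200,
    geometry: str = "layered",
    seed: int = 0,
    n_markers_per_type: int = 10,
    marker_fold: float = 8.0,
    layer_purity: float = 0.85,
    tissue_size: float = 1000.0,
    mean_depth: float = 300.0,
    n_ref_per_type: int = 100,
    platform_sd: float = 0.5,
    capture_exponent_sd: float = 0.25,
    bcv: float = 0.35,
) -> tuple[SingleCellSpatial, pd.DataFrame, pd.Series]:
    """Synthetic single-cell spatial tissue plus an external reference.

    Gene-by-type mean profiles come from a shared log-normal prior with a
    block of ``n_markers_per_type`` marker genes per type elevated by
    ``marker_fold``. Cells occupy a ``tissue_size``-square; the layered
    geometry assigns each of the K horizontal bands a dominant type
    (probability ``layer_purity``, remainder uniform), emulating cortical
    layers; "random" places types uniformly. Per-cell counts are
    gamma-Poisson (negative binomial, biological CV ``bcv``) around the
    type profile scaled by a log-normal sequencing depth.

    The external reference is generated from the same type profiles with an
    independent per-gene multiplicative log-normal(0, platform_sd^2)
    distortion emulating platform effects; ``platform_sd=0`` gives a
    distortion-free reference.
    """
    if n_types < 2:
        raise ValueError("need at least 2 cell types")
    if n_markers_per_type * n_types > n_genes:
        raise ValueError("marker blocks exceed the gene count")
    if geometry not in ("layered", "random"):
        raise ValueError("geometry must be 'layered' or 'random'")
    rng = np.random.default_rng(seed)
    genes = [f"g{j}" for j in range(n_genes)]
    types = [f"type{k}" for k in range(n_types)]

    base = rng.lognormal(mean=0.0, sigma=0.5, size=n_genes)
    profiles = np.tile(base, (n_types, 1))
    # marker blocks: near-silent off target (a few percent of baseline, so
    # only a small fraction of off-target cells show any count), elevated in
    # the target type -- the expression pattern of real marker genes
    for k in range(n_types):
        block = slice(k * n_markers_per_type, (k + 1) * n_markers_per_type)
        profiles[:, block] = base[block] * 0.02
        profiles[k, block] = base[block] * marker_fold
    profiles = profiles / profiles.sum(axis=1, keepdims=True)  # relative expression

    xy = rng.uniform(0.0, tissue_size, size=(n_cells, 2))
    if geometry == "layered":
        band = np.minimum((xy[:, 1] / tissue_size * n_types).astype(int), n_types - 1)
        coin = rng.random(n_cells)
        codes = np.where(coin < layer_purity, band, rng.integers(0, n_types, n_cells))
    else:
        codes = rng.integers(0, n_types, n_cells)
    depth = rng.lognormal(np.log(mean_depth), 0.3, size=n_cells)
    # gamma-Poisson (negative binomial) counts: within-type biological
    # variability with coefficient of variation ``bcv``
    shape = 1.0 / bcv**2
    biol = rng.gamma(shape, 1.0 / shape, size=(n_cells, n_genes))
    counts = rng.poisson(depth[:, None] * profiles[codes] * biol).T  # genes x cells
    cell_ids = [f"cell{i}" for i in range(n_cells)]
    sc = SingleCellSpatial(
        counts=pd.DataFrame(counts, index=genes, columns=cell_ids),
        coords=pd.DataFrame(xy, index=cell_ids, columns=["x", "y"]),
        labels=pd.Series([types[c] for c in codes], index=cell_ids),
    )

    if platform_sd > 0:
        # gene-specific capture: a log-normal efficiency factor plus a
        # capture exponent acting on the expression level, so the platform
        # effect is log-linear in abundance rather than a flat per-gene
        # offset (a flat offset is exactly the random effect the robust
        # Poisson error model absorbs, which real platform effects are not)
        distort = rng.lognormal(0.0, platform_sd, size=n_genes)
        exponent = np.clip(1.0 + rng.normal(0.0, capture_exponent_sd, size=n_genes), 0.4, 1.6)
    else:
        distort = np.ones(n_genes)
        exponent = np.ones(n_genes)
    ref_profiles = np.power(profiles, exponent) * distort
    ref_profiles = ref_profiles / ref_profiles.sum(axis=1, keepdims=True)
    ref_codes = np.repeat(np.arange(n_types), n_ref_per_type)
    ref_depth = rng.lognormal(np.log(mean_depth), 0.3, size=ref_codes.size)
    ref_biol = rng.gamma(shape, 1.0 / shape, size=(ref_codes.size, n_genes))
    ref_counts = rng.poisson(ref_depth[:, None] * ref_profiles[ref_codes] * ref_biol).T
    ref_ids = [f"ref{i}" for i in range(ref_codes.size)]
    ref = pd.DataFrame(ref_counts, index=genes, columns=ref_ids)
    ref_annot = pd.Series([types[c] for c in ref_codes], index=ref_ids)
    return sc, ref, ref_annot
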