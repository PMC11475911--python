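"""Pseudo-spot generation from reference scRNA-seq.

Pseudo-spots are artificial mixtures formed by averaging the normalized
profiles of randomly sampled reference cells. They give the scRNA-seq
condition of the CVAE a spectrum of cell-type compositions comparable to
real capture spots, which only ever measure mixtures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PseudoSpotSet", "plan_pseudospot_count", "generate_pseudospots", "train_val_split"]

PSEUDOSPOT_CAP = 500_000


@dataclass
class PseudoSpotSet:
    """Pseudo-spot expression (spots x genes), true composition and sizes."""

    expression: pd.DataFrame  # pseudo-spots x genes, averaged normalized expression
    composition: pd.DataFrame  # pseudo-spots x K cell-count fractions
    cells_per_spot: np.ndarray

    def __post_init__(self) -> None:
        rowsums = self.composition.to_numpy().sum(axis=1)
        if not np.allclose(rowsums, 1.0):
            raise ValueError("composition rows must sum to 1")


def plan_pseudospot_count(n_spots: int, n_types: int) -> int:
    """Default number of pseudo-spots: min(100 * N * K, 500,000)."""
    if n_spots < 1 or n_types < 1:
        raise ValueError("N and K must be >= 1")
    return min(100 * n_spots * n_types, PSEUDOSPOT_CAP)


def generate_pseudospots(
    ref_norm: pd.DataFrame,
    annot: pd.Series,
    n_spots: int,
    cells_min: int,
    cells_max: int,
    seed: int | np.random.Generator = 0,
) -> PseudoSpotSet:
    """Sample pseudo-spots by averaging random reference cells.

    Per pseudo-spot: draw the cell count uniformly in [cells_min, cells_max],
    sample that many cells uniformly without replacement (with replacement
    across pseudo-spots), average their normalized profiles (genes x cells
    input -> spot profile), and record the cell-count fractions per type.
    """
    n_cells = ref_norm.shape[1]
    if not (1 <= cells_min <= cells_max <= n_cells):
        raise ValueError("need 1 <= cells_min <= cells_max <= number of cells")
    rng = np.random.default_rng(seed)
    types = sorted(annot.unique())
    type_idx = pd.Categorical(annot.loc[ref_norm.columns], categories=types).codes
    X = ref_norm.to_numpy().T  # cells x genes
    sizes = rng.integers(cells_min, cells_max + 1, size=n_spots)
    expr = np.empty((n_spots, ref_norm.shape[0]))
    comp = np.zeros((n_spots, len(types)))
    for s, sz in enumerate(sizes):
        cells = rng.choice(n_cells, size=sz, replace=False)
        expr[s] = X[cells].mean(axis=0)
        counts = np.bincount(type_idx[cells], minlength=len(types))
        comp[s] = counts / sz
    ids = [f"pseudo_{s}" for s in range(n_spots)]
    return PseudoSpotSet(
        expression=pd.DataFrame(expr, index=ids, columns=ref_norm.index),
        composition=pd.DataFrame(comp, index=ids, columns=types),
        cells_per_spot=sizes,
    )


def train_val_split(
    pseudo: PseudoSpotSet, val_fraction: float = 0.2, seed: int | np.random.Generator = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded random 80/20 split; returns (train_idx, val_idx)."""
    if not (0 < val_fraction < 1):
        raise ValueError("val_fraction must be in (0, 1)")
    n = pseudo.expression.shape[0]
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_val = max(1, int(round(val_fraction * n)))
    return perm[n_val:], perm[:n_val]
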