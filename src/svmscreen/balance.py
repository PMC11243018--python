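"""SMOTE class balancing for two-class designs.

A one-vs-rest contrast of three equal concentration groups is inherently
imbalanced (9 vs 18 samples); class-size imbalance biases the decision
rule of two-class models.  SMOTE equalises the classes by synthesising
minority samples: each new sample is a convex combination of a random
minority sample and one of its k nearest minority neighbours,
x_new = x + u * (x_nb - x) with u ~ Uniform(0, 1).

Interpolation happens in the calibrated intensity space, before any
scaling, so synthetic rows cannot leak scaling statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = ["BalancedDesign", "smote_balance"]


@dataclass
class BalancedDesign:
    """A class-balanced design with per-row provenance."""

    x: np.ndarray  # samples x variables
    y: np.ndarray
    provenance: np.ndarray  # 'original' | 'synthetic' per row
    k_neighbors: int
    seed: int
    index: list | None = None  # row ids when the input carried them


def smote_balance(x, y, k: int = 5, seed: int = 0) -> BalancedDesign:
    """Oversample the minority class to parity with the majority.

    ``x`` may be an ndarray or a samples x variables DataFrame.  With
    already balanced classes the input is returned unchanged (all rows
    marked original).
    """
    index = list(x.index) if isinstance(x, pd.DataFrame) else None
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y)
    classes, counts = np.unique(ya, return_counts=True)
    if len(classes) != 2:
        raise ValueError("SMOTE balancing expects exactly two classes")

    n_min, n_maj = counts.min(), counts.max()
    provenance = np.array(["original"] * len(ya))
    if n_min == n_maj:
        return BalancedDesign(xa, ya, provenance, k, seed, index)

    minority = classes[np.argmin(counts)]
    min_idx = np.flatnonzero(ya == minority)
    if len(min_idx) < 2:
        raise ValueError("minority class needs at least 2 samples")
    if k >= len(min_idx):
        raise ValueError(
            f"k={k} must be smaller than the minority size {len(min_idx)}"
        )

    rng = np.random.default_rng(seed)
    x_min = xa[min_idx]
    # k nearest minority neighbours of each minority sample (self excluded)
    d = cdist(x_min, x_min)
    np.fill_diagonal(d, np.inf)
    neighbours = np.argsort(d, axis=1)[:, :k]

    new_rows = []
    for _ in range(n_maj - n_min):
        i = rng.integers(len(min_idx))
        j = neighbours[i, rng.integers(k)]
        u = rng.uniform()
        new_rows.append(x_min[i] + u * (x_min[j] - x_min[i]))

    x_out = np.vstack([xa, new_rows])
    y_out = np.concatenate([ya, [minority] * len(new_rows)])
    provenance = np.concatenate([provenance, ["synthetic"] * len(new_rows)])
    if index is not None:
        index = index + [f"smote-{i + 1}" for i in range(len(new_rows))]
    return BalancedDesign(x_out, y_out, provenance, k, seed, index)
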