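"""log2 transformation and missing-value-aware quantile normalization."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import LOG2, RAW, IntensityMatrix


def log2_transform(matrix: IntensityMatrix) -> IntensityMatrix:
    """Replace every observed intensity by its base-2 logarithm."""
    if matrix.scale != RAW:
        raise ValueError("matrix is already on the log2 scale")
    vals = matrix.values.to_numpy(dtype=float)
    bad = np.argwhere(~np.isnan(vals) & (vals <= 0))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"non-positive intensity at protein {matrix.protein_ids[i]!r}, "
            f"sample {matrix.sample_ids[j]!r}"
        )
    out = pd.DataFrame(
        np.log2(vals), index=matrix.values.index, columns=matrix.values.columns
    )
    return IntensityMatrix(out, scale=LOG2)


def quantile_normalize(matrix: IntensityMatrix, n_grid: int | None = None) -> IntensityMatrix:
    """Quantile normalization tolerant of missing values.

    Every sample's observed values are mapped, through their within-sample
    rank, onto a reference distribution: the across-sample mean of the
    per-sample empirical quantile functions evaluated on a common [0, 1]
    grid.  For complete data this reduces to classic quantile
    normalization (each sample's sorted values become the mean order
    statistics); with missing values each sample contributes its quantile
    curve only from its observed cells, and missing cells stay missing.
    Ties share their average rank, so within-sample order is preserved.
    """
    if matrix.scale != LOG2:
        raise ValueError("quantile normalization expects log2-scale data")
    vals = matrix.values.to_numpy(dtype=float)
    n, m = vals.shape
    if m < 2:
        raise ValueError("need at least two samples")
    n_obs = (~np.isnan(vals)).sum(axis=0)
    if (n_obs < 2).any():
        j = int(np.argmin(n_obs))
        raise ValueError(
            f"sample {matrix.sample_ids[j]!r} has fewer than 2 observed values"
        )

    if n_grid is None:
        n_grid = n
    grid = np.linspace(0.0, 1.0, max(n_grid, 2))
    curves = np.empty((len(grid), m))
    for j in range(m):
        obs = vals[~np.isnan(vals[:, j]), j]
        curves[:, j] = np.quantile(obs, grid)  # linear (type 7) interpolation
    reference = curves.mean(axis=1)

    out = np.full_like(vals, np.nan)
    for j in range(m):
        col = vals[:, j]
        mask = ~np.isnan(col)
        obs = col[mask]
        ranks = rankdata(obs, method="average")
        p = (ranks - 1.0) / (len(obs) - 1.0)
        out[mask, j] = np.interp(p, grid, reference)
    return IntensityMatrix(
        pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns),
        scale=LOG2,
    )
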