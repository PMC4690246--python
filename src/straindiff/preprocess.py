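"""Normalization applied before SFP/DE analysis and array clustering.

Quantile normalization forces every array column onto a common reference
distribution (the across-column mean of sorted values), the standard
preparation for comparing hybridization intensities across arrays. Z-scaling
standardizes each gene row before correlation-based clustering.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


def quantile_normalize(m: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns of a probe x array matrix.

    Column k's sorted values are replaced by the across-column means of the
    order statistics; ties within a column receive the mean of the tied
    ranks' reference values. A single-column matrix passes through
    unchanged. After normalization every column holds the identical multiset
    of values (up to tie handling).
    """
    values = m.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        r, c = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(
            f"missing/non-finite value at row {m.index[r]!r}, "
            f"column {m.columns[c]!r}"
        )
    n_rows, n_cols = values.shape
    if n_cols < 2:
        return m.copy()
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(n_cols):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        ranks = np.empty(n_rows, dtype=np.intp)
        ranks[order] = np.arange(n_rows)
        assigned = reference[ranks]
        # ties within the column get the mean reference value of their ranks
        uniq, inverse, counts = np.unique(col, return_inverse=True,
                                          return_counts=True)
        if (counts > 1).any():
            sums = np.bincount(inverse, weights=assigned)
            assigned = (sums / counts)[inverse]
        out[:, j] = assigned
    return pd.DataFrame(out, index=m.index, columns=m.columns)


def z_scale_genes(m: pd.DataFrame) -> pd.DataFrame:
    """Scale each gene row to mean 0, sample (n-1) sd 1.

    Constant rows map to all-zero with a logged warning.
    """
    if m.shape[1] < 2:
        raise ValueError("z_scale_genes needs >= 2 arrays")
    values = m.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    constant = (sd[:, 0] == 0)
    if constant.any():
        log.warning("z_scale_genes: %d constant rows set to zero (e.g. %r)",
                    int(constant.sum()), m.index[np.argmax(constant)])
    sd[sd == 0] = 1.0
    return pd.DataFrame((values - mean) / sd, index=m.index, columns=m.columns)
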