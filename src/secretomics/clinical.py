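"""Contingency statistics for marker-status vs clinicopathological variables.

Implements the Pearson chi-square (with optional Yates continuity correction
on 2x2 tables) and the two-sided Fisher exact test directly from their
definitions; crosstab output of standard statistical packages mixes the three
variants, so all are exposed and the caller picks per variable.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def _validate(table: np.ndarray) -> np.ndarray:
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (table < 0).any() or table.sum() < 1:
        raise ValueError("counts must be non-negative with a positive total")
    return table


def pearson_chi2(
    table, continuity_correction: bool = False
) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on a 2 x k (or r x k) table.

    Expected counts E_ij = row_i x col_j / N; the statistic is
    sum((|O - E| - c)^2 / E) with c = 0.5 when ``continuity_correction`` and
    the table is 2x2, else c = 0.  Returns (statistic, df, p-value).
    """
    table = _validate(table)
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("degenerate margin: a row or column sums to zero")
    expected = np.outer(rows, cols) / table.sum()
    c = 0.5 if continuity_correction and table.shape == (2, 2) else 0.0
    adj = np.abs(table - expected) - c
    if c:
        adj = np.maximum(adj, 0.0)  # correction never overshoots past E
    chi2 = float((adj**2 / expected).sum())
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table.

    Enumerates the hypergeometric support with the observed margins and sums
    the probabilities of all tables no more probable than the observed one
    (with a 1e-7 relative tolerance on the comparison).
    """
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2):
        raise ValueError("Fisher exact test requires a 2x2 table")
    if (table < 0).any() or table.sum() < 1:
        raise ValueError("counts must be non-negative with a positive total")
    a = table[0, 0]
    r1 = table[0].sum()
    c1 = table[:, 0].sum()
    n = table.sum()
    rv = stats.hypergeom(n, r1, c1)
    support = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    probs = rv.pmf(support)
    p_obs = rv.pmf(a)
    p = float(probs[probs <= p_obs * (1 + 1e-7)].sum())
    return min(p, 1.0)
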