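"""Target-decoy peptide FDR and the stepwise stringent quality-control filter.

The q-value of a PSM is the monotonized running decoy/target ratio: at each
ion-score threshold t, FDR(t) = #decoys(score >= t) / max(1, #targets(score >= t)),
and the q-value is the minimum FDR over all thresholds at or below the PSM's
score.  Decoys sort before targets at equal score, which makes the estimate
conservative.  The stepwise filter retains a target PSM if it clears at least
one (ion score, q) tier; the default tiers are (score > 30, q < 1%) and
(score > 40, q < 5%), with a 7-residue minimum peptide length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class QcTier:
    """One acceptance tier: ion score strictly above, q-value strictly below."""

    min_ion_score: float
    max_q: float

    def __post_init__(self) -> None:
        if not (0.0 < self.max_q <= 1.0):
            raise ValueError("max_q must be in (0, 1]")


DEFAULT_TIERS: tuple[QcTier, ...] = (QcTier(30.0, 0.01), QcTier(40.0, 0.05))
MIN_PEPTIDE_LENGTH = 7


def compute_peptide_fdr(psms: pd.DataFrame) -> pd.DataFrame:
    """Assign target-decoy q-values to every PSM.

    Returns a copy of ``psms`` with the ``q_value`` column set.  Decoy records
    receive q-values too (they are dropped later by the filter, not here).
    Empty input passes through unchanged.
    """
    if len(psms) == 0:
        out = psms.copy()
        out["q_value"] = pd.Series(dtype=float)
        return out
    # decoys first within a score tie -> counted before targets (conservative)
    order = np.lexsort((~psms["is_decoy"].to_numpy(), -psms["ion_score"].to_numpy()))
    scores = psms["ion_score"].to_numpy()[order]
    decoy = psms["is_decoy"].to_numpy()[order]
    # numerator counts every decoy at score >= s (full tie group), denominator
    # the running target count, so targets see tied decoys but not vice versa
    group_end = np.searchsorted(-scores, -scores, side="right") - 1
    n_decoys = np.cumsum(decoy)[group_end]
    n_targets = np.cumsum(~decoy)
    fdr = n_decoys / np.maximum(1, n_targets)
    # monotonize from the bottom: q(i) = min_{j >= i} fdr(j)
    q = np.minimum.accumulate(fdr[::-1])[::-1]
    out = psms.copy()
    q_col = np.empty(len(psms))
    q_col[order] = np.minimum(q, 1.0)
    out["q_value"] = q_col
    return out


def stepwise_qc_filter(
    psms: pd.DataFrame,
    tiers: Sequence[QcTier] = DEFAULT_TIERS,
    min_peptide_length: int = MIN_PEPTIDE_LENGTH,
) -> pd.DataFrame:
    """Retain target PSMs that satisfy at least one quality tier.

    A PSM passes a tier when ion_score > min_ion_score AND q_value < max_q.
    Decoys and peptides shorter than ``min_peptide_length`` are removed
    unconditionally.  Requires ``q_value`` to be set (see
    :func:`compute_peptide_fdr`).
    """
    if len(tiers) == 0:
        raise ValueError("at least one QC tier is required")
    if "q_value" not in psms.columns:
        raise ValueError("q_value column missing; run compute_peptide_fdr first")
    if len(psms) == 0:
        return psms.copy()
    score = psms["ion_score"].to_numpy(dtype=float)
    q = psms["q_value"].to_numpy(dtype=float)
    passes = np.zeros(len(psms), dtype=bool)
    for tier in tiers:
        passes |= (score > tier.min_ion_score) & (q < tier.max_q)
    passes &= ~psms["is_decoy"].to_numpy()
    passes &= psms["peptide"].str.len().to_numpy() >= min_peptide_length
    return psms.loc[passes].reset_index(drop=True)
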