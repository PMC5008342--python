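"""Spectral-count quantification: SAF1/NSAF5, replicate correlation, ANOVA screen.

For each gene product the per-run PSM count is normalised by its theoretical
number of full tryptic peptides (SAF1, displayed in units of 10), then by the
run total (NSAF5 = fraction of total SAF1, displayed in units of 1e5).  The
12 fractions of a (cell line, replicate) unit are pooled before quantification,
so NSAF5 does not depend on how PSMs were split across fractions.
"""

from __future__ import annotations

import itertools
import logging
import re

import numpy as np
import pandas as pd
from scipy import stats

from secretomics.design import StudyDesign
from secretomics.inference import ProteinGroup, assign_peptides

logger = logging.getLogger(__name__)

SAF1_SCALE = 10.0
NSAF5_SCALE = 1e5

_CLEAVE = re.compile(r"(?<=[KR])(?!P)")


def theoretical_tryptic_peptides(sequence: str, min_len: int = 7) -> int:
    """Count all possible full tryptic peptides of ``sequence``.

    Cleavage after every K or R not followed by P, zero missed cleavages;
    segments shorter than ``min_len`` residues do not count.  Positional
    segments are counted, so a repeated sequence counts once per position.
    """
    if not sequence:
        return 0
    return sum(1 for seg in _CLEAVE.split(sequence) if len(seg) >= min_len)


def tryptic_peptides(sequence: str, min_len: int = 7) -> list[str]:
    """The full tryptic peptides themselves (used by the simulator)."""
    return [seg for seg in _CLEAVE.split(sequence) if len(seg) >= min_len]


def compute_saf1(gp_psm_count: float, theo_count: int) -> float:
    """SAF1 = 10 x PSM count / theoretical tryptic peptide count."""
    if theo_count < 1:
        raise ValueError("theoretical peptide count must be >= 1")
    return SAF1_SCALE * gp_psm_count / theo_count


def compute_nsaf5(saf1_values: np.ndarray) -> np.ndarray:
    """NSAF5_i = 1e5 x SAF1_i / sum_j SAF1_j for one run."""
    saf1_values = np.asarray(saf1_values, dtype=float)
    total = saf1_values.sum()
    if total <= 0:
        raise ValueError("no quantifiable evidence in run")
    return NSAF5_SCALE * saf1_values / total


def psm_count_matrix(
    psms: pd.DataFrame, gp_groups: list[ProteinGroup], design: StudyDesign
) -> pd.DataFrame:
    """Raw PSM counts per GP per (cell line, replicate), fractions pooled.

    Each PSM is assigned to exactly one GP through its peptide (see
    :func:`secretomics.inference.assign_peptides`), so per-run totals are
    conserved.  PSMs whose peptide maps to no retained GP are dropped.
    """
    assignment = assign_peptides(gp_groups)
    df = psms.copy()
    df["gp_id"] = df["peptide"].map(assignment)
    df = df.dropna(subset=["gp_id"])
    counts = (
        df.groupby(["gp_id", "cell_line", "replicate"], observed=True)
        .size()
        .unstack(["cell_line", "replicate"], fill_value=0)
    )
    cols = pd.MultiIndex.from_tuples(design.runs(), names=["cell_line", "replicate"])
    counts = counts.reindex(columns=cols, fill_value=0)
    counts = counts.reindex(index=[g.gp_id for g in gp_groups], fill_value=0)
    counts.index.name = "gp_id"
    return counts


def abundance_matrix(
    counts: pd.DataFrame,
    gp_groups: list[ProteinGroup],
    sequences: dict[str, str],
    min_len: int = 7,
) -> pd.DataFrame:
    """NSAF5 matrix (GP x run) from a raw PSM-count matrix.

    The SAF1 denominator is the theoretical tryptic peptide count of the
    representative (longest-member) accession's sequence.  GPs whose
    representative yields zero theoretical peptides are excluded with a
    warning; absence from a run is zero evidence, not missing data.
    """
    theo = {}
    for gp in gp_groups:
        n = theoretical_tryptic_peptides(sequences[gp.representative], min_len)
        if n == 0:
            logger.warning(
                "GP %s has no theoretical tryptic peptides; excluded", gp.gp_id
            )
            continue
        theo[gp.gp_id] = n
    kept = counts.loc[counts.index.intersection(theo.keys(), sort=False)]
    denom = np.array([theo[g] for g in kept.index], dtype=float)
    saf1 = SAF1_SCALE * kept.to_numpy(dtype=float) / denom[:, None]
    nsaf5 = np.apply_along_axis(compute_nsaf5, 0, saf1)
    return pd.DataFrame(nsaf5, index=kept.index, columns=kept.columns)


def replicate_correlation(
    matrix: pd.DataFrame, min_shared: int = 3
) -> pd.DataFrame:
    """Pearson correlation over all run-column pairs.

    Each pair is computed on GPs quantified (nonzero) in both runs; pairs with
    fewer than ``min_shared`` shared GPs, or a constant column, are NaN.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least two run columns")
    cols = matrix.columns
    out = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i, j in itertools.combinations(range(len(cols)), 2):
        x = matrix.iloc[:, i].to_numpy(dtype=float)
        y = matrix.iloc[:, j].to_numpy(dtype=float)
        shared = (x > 0) & (y > 0)
        if shared.sum() < min_shared or x[shared].std() == 0 or y[shared].std() == 0:
            r = np.nan
        else:
            r = stats.pearsonr(x[shared], y[shared]).statistic
        out.iloc[i, j] = out.iloc[j, i] = r
    return out


def anova_screen(
    matrix: pd.DataFrame, design: StudyDesign, alpha: float = 0.05
) -> pd.DataFrame:
    """One-way ANOVA of NSAF5 across cell lines, per GP.

    Raw NSAF5 values (no transform), one group per cell line with its
    replicates, no multiple-testing correction; the significant set is
    {p < alpha}.  GPs with zero total variance are flagged degenerate and
    never significant.
    """
    if len(design.cell_lines) < 2 or design.n_replicates < 2:
        raise ValueError("ANOVA needs >= 2 groups and >= 2 replicates per group")
    records = []
    for gp_id, row in matrix.iterrows():
        groups = [
            row.loc[line].to_numpy(dtype=float) for line in design.cell_lines
        ]
        values = np.concatenate(groups)
        rec = {"gp_id": gp_id, "degenerate": False}
        for line, g in zip(design.cell_lines, groups):
            rec[f"mean_{line}"] = g.mean()
        if np.ptp(values) == 0:
            rec.update(F=0.0, p=1.0, degenerate=True)
        elif all(np.ptp(g) == 0 for g in groups):
            # zero within-group variance but unequal means
            rec.update(F=np.inf, p=0.0)
        else:
            res = stats.f_oneway(*groups)
            rec.update(F=float(res.statistic), p=float(res.pvalue))
        records.append(rec)
    out = pd.DataFrame(records).set_index("gp_id")
    out["significant"] = (out["p"] < alpha) & ~out["degenerate"]
    return out
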