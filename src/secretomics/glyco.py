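"""N-glycosite validation and precursor-area quantification.

PNGase F deglycosylation in heavy-oxygen water converts a glycosylated
asparagine to aspartate carrying an 18O atom, raising the peptide mass by
2.9848 Da per site.  A deamidated residue is accepted as an N-glycosite only
when (a) its protein-coordinate position falls on the canonical N-!P-[S/T]
sequon and (b) the reported mass delta equals n_sites x shift within
n_sites x tolerance.  Accepted sites are quantified by their summed precursor
areas normalised to the run's total identified-peptide area, with ratios
against the non-metastatic reference line.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from secretomics.design import StudyDesign
from secretomics.io import ProteinRecord
from secretomics.cluster import ClusterAssignment, kmeans_profiles

logger = logging.getLogger(__name__)

#: Peptide mass increase per deglycosylated site (Da), as printed in the
#: source search parameters.  The chemically exact 18O-deamidation value is
#: approximately 2.9883 Da; the default 0.01 Da tolerance accepts either.
O18_DEAMIDATION_SHIFT = 2.9848
MASS_TOL = 0.01

DEAMIDATION_LABEL = "deamid18O"


def find_sequons(sequence: str) -> list[tuple[int, str]]:
    """All N-glycosylation sequons of a sequence.

    Returns (1-based N position, 3-residue sequon) for every position i with
    residue N, residue i+1 != P and residue i+2 in {S, T}.  Overlapping
    sequons are all reported.
    """
    hits = []
    for i in range(len(sequence) - 2):
        if (
            sequence[i] == "N"
            and sequence[i + 1] != "P"
            and sequence[i + 2] in "ST"
        ):
            hits.append((i + 1, sequence[i : i + 3]))
    return hits


def validate_glyco_psm(
    row: pd.Series,
    proteome_by_acc: dict[str, ProteinRecord],
    shift: float = O18_DEAMIDATION_SHIFT,
    tol: float = MASS_TOL,
) -> tuple[list[dict], str | None]:
    """Validate one glyco-PSM; returns (accepted site records, rejection reason).

    Every flagged position must be an asparagine in the peptide (anything else
    is malformed input).  Shared peptides mapping to several proteins yield
    one record per protein, marked ambiguous.
    """
    peptide = row["peptide"]
    flags = [(pos, label) for pos, label in row["mod_flags"]
             if label == DEAMIDATION_LABEL]
    if not flags:
        return [], "no deamidation flag"
    for pos, _ in flags:
        if not (1 <= pos <= len(peptide)) or peptide[pos - 1] != "N":
            raise ValueError(
                f"flagged position {pos} in peptide {peptide} is not an N"
            )
    n_flagged = len(flags)
    delta = float(row["mass_delta"])
    if abs(delta - n_flagged * shift) > n_flagged * tol:
        return [], "mass mismatch"

    hits = [
        proteome_by_acc[acc]
        for acc in row["accessions"]
        if acc in proteome_by_acc and peptide in proteome_by_acc[acc].sequence
    ]
    if not hits:
        return [], "peptide maps to no protein"

    records = []
    for protein in hits:
        sequon_positions = dict(find_sequons(protein.sequence))
        start = protein.sequence.find(peptide)  # 0-based
        sites = []
        for pos, _ in flags:
            site = start + pos  # 1-based protein coordinate
            if site not in sequon_positions:
                sites = None  # this protein context fails the motif
                break
            sites.append((site, sequon_positions[site]))
        if sites is None:
            continue
        for site, sequon in sites:
            records.append(
                {
                    "accession": protein.accession,
                    "site_position": site,
                    "sequon": sequon,
                    "peptide": peptide,
                    "cell_line": row["cell_line"],
                    "replicate": row["replicate"],
                    "precursor_area": float(row["precursor_area"]),
                    "ambiguous": len(hits) > 1,
                }
            )
    if not records:
        return [], "non-motif deamidation"
    return records, None


def validate_glyco_table(
    psms: pd.DataFrame,
    proteome: list[ProteinRecord],
    shift: float = O18_DEAMIDATION_SHIFT,
    tol: float = MASS_TOL,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Validate a whole glyco-PSM table -> (accepted sites, rejections)."""
    by_acc = {p.accession: p for p in proteome}
    accepted, rejected = [], []
    for idx, row in psms.iterrows():
        records, reason = validate_glyco_psm(row, by_acc, shift=shift, tol=tol)
        if reason is None:
            accepted.extend(records)
        else:
            rejected.append(
                {"spectrum_id": row.get("spectrum_id", idx),
                 "peptide": row["peptide"], "reason": reason}
            )
    acc_df = pd.DataFrame(
        accepted,
        columns=["accession", "site_position", "sequon", "peptide", "cell_line",
                 "replicate", "precursor_area", "ambiguous"],
    )
    rej_df = pd.DataFrame(rejected, columns=["spectrum_id", "peptide", "reason"])
    return acc_df, rej_df


def normalize_glyco_areas(
    accepted: pd.DataFrame,
    all_peptides: pd.DataFrame,
    design: StudyDesign,
    reference_line: str | None = None,
    include_ambiguous: bool = False,
) -> pd.DataFrame:
    """Per-site normalized area matrix, rows (accession, site), runs as columns.

    A site's value in a run is the sum of its supporting-peptide areas divided
    by the run's total identified-peptide area (``all_peptides`` needs columns
    cell_line, replicate, precursor_area).  The returned frame carries a
    ``ratio_<line>`` attribute-free companion: ratios vs the mean of the
    reference line (default: the rank-0 line) are in ``.attrs['ratios']``,
    NaN where the reference signal is zero.
    """
    reference_line = reference_line or design.cell_lines[0]
    totals = all_peptides.groupby(["cell_line", "replicate"], observed=True)[
        "precursor_area"
    ].sum()
    if (totals <= 0).any():
        raise ValueError("run with zero total identified-peptide area")
    sites = accepted if include_ambiguous else accepted[~accepted["ambiguous"]]
    summed = (
        sites.groupby(["accession", "site_position", "cell_line", "replicate"],
                      observed=True)["precursor_area"]
        .sum()
        .unstack(["cell_line", "replicate"], fill_value=0.0)
    )
    cols = pd.MultiIndex.from_tuples(
        [rc for rc in totals.index], names=["cell_line", "replicate"]
    )
    summed = summed.reindex(columns=cols, fill_value=0.0)
    table = summed / totals.reindex(summed.columns).to_numpy()

    ref = table.loc[:, reference_line].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = table.div(ref.replace(0.0, np.nan), axis=0)
    table.attrs["ratios"] = ratios
    table.attrs["reference_line"] = reference_line
    return table


def glyco_trend(
    table: pd.DataFrame,
    design: StudyDesign,
    k: int = 2,
    seed: int = 0,
    n_restarts: int = 20,
) -> ClusterAssignment:
    """Two-cluster k-means over site profiles; increased cluster feeds candidates."""
    quantified = table.loc[(table > 0).sum(axis=1) >= 2]
    return kmeans_profiles(quantified, design, k=k, seed=seed, n_restarts=n_restarts)


def site_summary(accepted: pd.DataFrame) -> pd.DataFrame:
    """Unique (accession, site) tally with peptide support counts."""
    if accepted.empty:
        return pd.DataFrame(
            columns=["accession", "site_position", "sequon", "n_peptides"]
        )
    return (
        accepted.groupby(["accession", "site_position", "sequon"], observed=True)[
            "peptide"
        ]
        .nunique()
        .rename("n_peptides")
        .reset_index()
    )
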