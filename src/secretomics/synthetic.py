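"""Synthetic data with planted ground truth for the whole pipeline.

The generators emulate the inputs of a four cell-line label-free secretome
study: a proteome FASTA, PSM tables per (cell line, replicate, fraction) with
decoys, glyco-PSM tables with precursor areas and deamidation flags,
predictor-score tables consistent with planted secretion classes, and a
clinical cohort behind 2 x k contingency tables.  Abundance follows the
simplest monotone model — base x fold^rank for "increased" proteins,
base x fold^(-rank) for "decreased", base for "flat" — and every generator is
a pure function of its arguments including the seed.

Distributional stand-ins (nothing in the source data constrains them; all are
configurable): target ion scores ~ Normal(45, 8) and decoy scores
~ Normal(20, 8), truncated at 0; precursor areas log-normal with sigma = 0.25
on the natural-log scale; replicate noise mean-one log-normal; fractions
assigned by a uniform multinomial.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from secretomics.design import StudyDesign
from secretomics.glyco import DEAMIDATION_LABEL, O18_DEAMIDATION_SHIFT, find_sequons
from secretomics.io import ProteinRecord
from secretomics.quant import tryptic_peptides

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

TRENDS = ("increased", "decreased", "flat")

#: Default mix of planted secretion classes, matching the reported category
#: fractions (non-classical 52%, other 13%, membrane 14%, classical 21%).
SECRETION_CLASS_PROBS = {"Part1": 0.52, "Part2": 0.13, "Part3": 0.14, "Part4": 0.21}


def planted_abundance(trend: str, base: float, fold: float, rank: int) -> float:
    """Expected abundance of a protein in the cell line with the given rank."""
    if trend == "increased":
        return base * fold**rank
    if trend == "decreased":
        return base * fold**-rank
    return base


def generate_proteome(
    n_proteins: int,
    length_range: tuple[int, int] = (200, 400),
    sequon_rate: float = 1.0,
    seed: int = 0,
    frac_increased: float = 0.1,
    frac_decreased: float = 0.1,
    fold_step: float = 2.0,
    base_abundance_range: tuple[float, float] = (0.5, 2.0),
    secretion_probs: dict[str, float] = SECRETION_CLASS_PROBS,
) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Random proteome plus planted-truth table.

    ``sequon_rate`` is the expected number of N-glycosylation sequons per 100
    residues; sequons are planted by overwriting random positions with an
    N-X(!=P)-[S/T] triplet, and the truth records every sequon of the final
    sequence (planted and accidental alike) as a true glycosite.
    """
    lo, hi = length_range
    if lo > hi or lo < 7:
        raise ValueError("length_range must satisfy 7 <= min <= max")
    if fold_step < 1.0:
        raise ValueError("fold_step must be >= 1")
    rng = np.random.default_rng(seed)

    n_inc = round(frac_increased * n_proteins)
    n_dec = round(frac_decreased * n_proteins)
    trends = np.array(
        ["increased"] * n_inc
        + ["decreased"] * n_dec
        + ["flat"] * (n_proteins - n_inc - n_dec)
    )
    rng.shuffle(trends)
    classes = rng.choice(
        list(secretion_probs), size=n_proteins, p=list(secretion_probs.values())
    )
    log_lo, log_hi = np.log(base_abundance_range[0]), np.log(base_abundance_range[1])
    bases = np.exp(rng.uniform(log_lo, log_hi, size=n_proteins))

    proteome, truth_rows = [], []
    non_p = [a for a in AMINO_ACIDS if a != "P"]
    for i in range(n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = list(rng.choice(list(AMINO_ACIDS), size=length))
        n_plant = rng.poisson(sequon_rate * length / 100.0)
        for pos in rng.integers(0, length - 2, size=n_plant):
            seq[pos] = "N"
            seq[pos + 1] = rng.choice(non_p)
            seq[pos + 2] = rng.choice(["S", "T"])
        sequence = "".join(seq)
        sequons = find_sequons(sequence)
        acc, gene = f"PROT{i:05d}", f"GENE{i:05d}"
        proteome.append(ProteinRecord(acc, gene, sequence))
        truth_rows.append(
            {
                "accession": acc,
                "gene_id": gene,
                "length": length,
                "trend": trends[i],
                "base_abundance": float(bases[i]),
                "fold_step": fold_step if trends[i] != "flat" else 1.0,
                "secretion_class": str(classes[i]),
                "glycosites": [pos for pos, _ in sequons],
                "n_sequons": len(sequons),
            }
        )
    return proteome, pd.DataFrame(
        truth_rows,
        columns=["accession", "gene_id", "length", "trend", "base_abundance",
                 "fold_step", "secretion_class", "glycosites", "n_sequons"],
    )


def _truncated_normal(rng, mean, sd, size):
    x = rng.normal(mean, sd, size)
    return np.clip(x, 0.0, None)


def simulate_psm_tables(
    proteome: list[ProteinRecord],
    truth: pd.DataFrame,
    design: StudyDesign,
    depth: float = 2.0,
    decoy_fraction: float = 0.1,
    seed: int = 0,
    rep_sigma: float = 0.2,
    area_sigma: float = 0.25,
    min_peptide_length: int = 7,
    target_score: tuple[float, float] = (45.0, 8.0),
    decoy_score: tuple[float, float] = (20.0, 8.0),
) -> pd.DataFrame:
    """Simulate secretome PSM tables for every (cell line, replicate, fraction).

    Per protein and run, the PSM count is Poisson with mean
    abundance(line) x theoretical-peptide-count x depth (replicate noise is a
    mean-one log-normal, so the stated mean holds in expectation); peptides
    are drawn uniformly from the protein's full tryptic peptides of length
    >= ``min_peptide_length``.  Decoy PSMs (reversed peptides) are added so
    their expected share of the table is ``decoy_fraction``; q-values are left
    to the QC stage.  Fraction assignment is a uniform multinomial.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    if not (0.0 <= decoy_fraction < 1.0):
        raise ValueError("decoy_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    truth_by_acc = truth.set_index("accession")
    ranks = design.ranks

    peptides_by_acc = {
        p.accession: tryptic_peptides(p.sequence, min_peptide_length)
        for p in proteome
    }
    rows: list[dict] = []
    for line, rep in design.runs():
        rank = ranks[line]
        n_targets_run = 0
        for protein in proteome:
            peps = peptides_by_acc[protein.accession]
            if not peps:
                continue
            t = truth_by_acc.loc[protein.accession]
            abundance = planted_abundance(
                t["trend"], t["base_abundance"], t["fold_step"], rank
            )
            noise = (
                np.exp(rng.normal(-rep_sigma**2 / 2, rep_sigma))
                if rep_sigma > 0
                else 1.0
            )
            n = rng.poisson(abundance * len(peps) * depth * noise)
            if n == 0:
                continue
            n_targets_run += n
            chosen = rng.integers(0, len(peps), size=n)
            scores = _truncated_normal(rng, *target_score, n)
            areas = abundance * np.exp(rng.normal(0.0, area_sigma, n))
            fractions = rng.integers(1, design.n_fractions + 1, size=n)
            for j in range(n):
                rows.append(
                    {
                        "cell_line": line,
                        "replicate": rep,
                        "fraction": int(fractions[j]),
                        "peptide": peps[chosen[j]],
                        "accessions": [protein.accession],
                        "ion_score": float(scores[j]),
                        "is_decoy": False,
                        "precursor_area": float(areas[j]),
                        "mod_flags": [],
                    }
                )
        if decoy_fraction > 0 and n_targets_run > 0:
            n_decoys = rng.poisson(
                n_targets_run * decoy_fraction / (1 - decoy_fraction)
            )
            src = rng.integers(0, len(proteome), size=n_decoys)
            scores = _truncated_normal(rng, *decoy_score, n_decoys)
            fractions = rng.integers(1, design.n_fractions + 1, size=n_decoys)
            for j in range(n_decoys):
                peps = peptides_by_acc[proteome[src[j]].accession]
                if not peps:
                    continue
                pep = peps[rng.integers(0, len(peps))][::-1]
                rows.append(
                    {
                        "cell_line": line,
                        "replicate": rep,
                        "fraction": int(fractions[j]),
                        "peptide": pep,
                        "accessions": [f"DECOY_{proteome[src[j]].accession}"],
                        "ion_score": float(scores[j]),
                        "is_decoy": True,
                        "precursor_area": float(np.exp(rng.normal(0, area_sigma))),
                        "mod_flags": [],
                    }
                )
    df = pd.DataFrame(
        rows,
        columns=["cell_line", "replicate", "fraction", "peptide", "accessions",
                 "ion_score", "is_decoy", "precursor_area", "mod_flags"],
    )
    df["run_id"] = [
        design.run_id(line, rep, frac)
        for line, rep, frac in zip(df["cell_line"], df["replicate"], df["fraction"])
    ]
    df["spectrum_id"] = [f"{rid}_s{i}" for i, rid in enumerate(df["run_id"])]
    cols = ["run_id", "cell_line", "replicate", "fraction", "spectrum_id",
            "peptide", "accessions", "ion_score", "is_decoy", "precursor_area",
            "mod_flags"]
    return df[cols]


def simulate_glyco_psms(
    proteome: list[ProteinRecord],
    truth: pd.DataFrame,
    design: StudyDesign,
    seed: int = 0,
    depth: float = 3.0,
    shift: float = O18_DEAMIDATION_SHIFT,
    mass_noise: float = 0.002,
    contaminant_fraction: float = 0.0,
    rep_sigma: float = 0.2,
    area_sigma: float = 0.25,
) -> pd.DataFrame:
    """Simulate deglycosylated glyco-PSM tables with precursor areas.

    Each true glyco-PSM covers a planted glycosite: its peptide is the tryptic
    segment containing the site, its deamidation flag sits on that asparagine,
    and its mass delta is the 18O shift plus Gaussian noise well below the
    acceptance tolerance.  A site is detected in a run with probability
    1 - exp(-depth) (Poisson identification depth) and then contributes one
    record carrying the run's extracted precursor area, log-normal around the
    planted abundance.  A ``contaminant_fraction`` share of the table carries
    deamidation at non-sequon asparagines (correct mass, wrong motif) to
    exercise downstream rejection.
    """
    rng = np.random.default_rng(seed)
    truth_by_acc = truth.set_index("accession")
    ranks = design.ranks
    if truth["glycosites"].map(len).sum() == 0:
        import warnings

        warnings.warn("no planted glycosites in truth", stacklevel=2)

    # site -> (peptide, local flag position), resolvable by first-occurrence search
    site_peptides: list[tuple[str, str, int]] = []  # accession, peptide, local pos
    decoy_peptides: list[tuple[str, str, int]] = []  # non-sequon N carriers
    for protein in proteome:
        seq = protein.sequence
        sequon_pos = {pos for pos, _ in find_sequons(seq)}
        true_sites = set(truth_by_acc.loc[protein.accession, "glycosites"])
        start = 0
        for seg in tryptic_peptides(seq, min_len=1):
            seg_start = start
            start += len(seg)
            if len(seg) < 7 or seq.find(seg) != seg_start:
                continue  # ambiguous placement would corrupt coordinates
            for local, residue in enumerate(seg, start=1):
                if residue != "N":
                    continue
                site = seg_start + local
                if site in true_sites:
                    site_peptides.append((protein.accession, seg, local))
                elif site not in sequon_pos:
                    decoy_peptides.append((protein.accession, seg, local))

    rows: list[dict] = []
    counter = 0

    def emit(source: tuple[str, str, int], line: str, rep: int) -> None:
        nonlocal counter
        acc, pep, local = source
        t = truth_by_acc.loc[acc]
        abundance = planted_abundance(
            t["trend"], t["base_abundance"], t["fold_step"], ranks[line]
        )
        noise = (
            np.exp(rng.normal(-rep_sigma**2 / 2, rep_sigma)) if rep_sigma > 0 else 1.0
        )
        area = abundance * noise * (
            np.exp(rng.normal(0.0, area_sigma)) if area_sigma > 0 else 1.0
        )
        delta = shift + (rng.normal(0.0, mass_noise) if mass_noise > 0 else 0.0)
        rows.append(
            {
                "run_id": f"{line}_r{rep}_g",
                "cell_line": line,
                "replicate": rep,
                "fraction": 1,
                "spectrum_id": f"g{counter}",
                "peptide": pep,
                "accessions": [acc],
                "ion_score": float(_truncated_normal(rng, 45.0, 8.0, 1)[0]),
                "is_decoy": False,
                "precursor_area": float(area),
                "mod_flags": [(local, DEAMIDATION_LABEL)],
                "mass_delta": float(delta),
            }
        )
        counter += 1

    for line, rep in design.runs():
        for source in site_peptides:
            # Poisson depth governs detection only; a detected glyco peptide
            # contributes a single extracted precursor area per run
            if rng.poisson(depth) > 0:
                emit(source, line, rep)
        if contaminant_fraction > 0 and decoy_peptides:
            n_true = sum(1 for r in rows if r["cell_line"] == line and r["replicate"] == rep)
            n_cont = rng.poisson(
                n_true * contaminant_fraction / (1 - contaminant_fraction)
            )
            for idx in rng.integers(0, len(decoy_peptides), size=n_cont):
                emit(decoy_peptides[idx], line, rep)
    return pd.DataFrame(
        rows,
        columns=["run_id", "cell_line", "replicate", "fraction", "spectrum_id",
                 "peptide", "accessions", "ion_score", "is_decoy",
                 "precursor_area", "mod_flags", "mass_delta"],
    )


def simulate_predictor_scores(
    proteome: list[ProteinRecord], truth: pd.DataFrame, seed: int = 0
) -> pd.DataFrame:
    """Predictor-score table consistent with the planted secretion classes.

    Scores are drawn so the downstream classifier recovers every planted
    class: Part4 -> signal peptide, no TM helix; Part3 -> 1-3 TM helices;
    Part1 -> no signal, no TM, SecretomeP > 0.5; Part2 -> no signal, no TM,
    SecretomeP <= 0.5.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for _, t in truth.iterrows():
        cls = t["secretion_class"]
        if cls == "Part4":
            signal, tm = True, 0
            sp = rng.uniform(0.0, 1.0)
        elif cls == "Part3":
            signal, tm = bool(rng.integers(0, 2)) , int(rng.integers(1, 4))
            sp = rng.uniform(0.0, 1.0)
        elif cls == "Part1":
            signal, tm = False, 0
            sp = rng.uniform(0.501, 1.0)
        elif cls == "Part2":
            signal, tm = False, 0
            sp = rng.uniform(0.0, 0.5)
        else:
            raise ValueError(f"unknown secretion class {cls!r}")
        rows.append(
            {
                "accession": t["accession"],
                "signalp": signal,
                "secretomep": round(float(sp), 4),
                "tm_count": tm,
            }
        )
    return pd.DataFrame(rows)


def simulate_clinical_cohort(
    n_patients: int,
    positive_rate: float = 0.3,
    association: float | dict[str, float] = 1.0,
    seed: int = 0,
    covariates: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Patient table: binary marker status plus binary covariates.

    ``covariates`` maps variable name -> baseline probability of level 1 among
    marker-negative patients; for marker-positive patients the odds are
    multiplied by ``association`` (scalar, or per-variable dict; 1.0 = null).
    """
    if n_patients < 2:
        raise ValueError("need at least two patients")
    rng = np.random.default_rng(seed)
    covariates = covariates or {"covariate": 0.5}
    marker = rng.random(n_patients) < positive_rate
    data = {"marker": marker.astype(int)}
    for name, p0 in covariates.items():
        a = association[name] if isinstance(association, dict) else association
        odds = p0 / (1 - p0) * a
        p1 = odds / (1 + odds)
        p = np.where(marker, p1, p0)
        data[name] = (rng.random(n_patients) < p).astype(int)
    return pd.DataFrame(data)


def contingency_from_cohort(cohort: pd.DataFrame, variable: str) -> np.ndarray:
    """2 x k counts: rows marker positive/negative, columns covariate levels."""
    tab = pd.crosstab(cohort["marker"], cohort[variable])
    return tab.reindex(index=[1, 0], fill_value=0).to_numpy()
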