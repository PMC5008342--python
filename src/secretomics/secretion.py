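"""Secretion-pathway categorization from SignalP/SecretomeP/TMHMM outputs.

Each protein carries three predictor outputs: a classical signal-peptide flag
(SignalP), a non-classical secretion score in [0, 1] (SecretomeP, cutoff
strictly > 0.5) and a predicted transmembrane-helix count (TMHMM, zero or
nonzero).  The decision tree assigns exactly one of four categories:

* Part4 — classical secretome: signal peptide present, no TM helix;
* Part3 — extracellular membrane: >= 1 TM helix (overrides secretion scores);
* Part1 — non-classical secretome: no signal, no TM, SecretomeP > 0.5;
* Part2 — other: everything else.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

CATEGORIES = ("Part1", "Part2", "Part3", "Part4")


@dataclass(frozen=True)
class PredictorScores:
    accession: str
    signal_peptide: bool
    secretomep_score: float
    tm_count: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.secretomep_score <= 1.0):
            raise ValueError("SecretomeP score must be in [0, 1]")
        if self.tm_count < 0:
            raise ValueError("TM helix count must be >= 0")


def classify_secretion(scores: PredictorScores, secretomep_cutoff: float = 0.5) -> str:
    """Assign the secretion category for one protein's predictor scores."""
    if scores.signal_peptide and scores.tm_count == 0:
        return "Part4"
    if scores.tm_count != 0:
        return "Part3"
    if scores.secretomep_score > secretomep_cutoff:
        return "Part1"
    return "Part2"


def classify_table(
    predictors: pd.DataFrame, secretomep_cutoff: float = 0.5
) -> pd.Series:
    """Categorize a predictor table (columns accession, signalp, secretomep, tm_count)."""
    required = {"accession", "signalp", "secretomep", "tm_count"}
    missing = required - set(predictors.columns)
    if missing:
        raise ValueError(f"predictor table missing columns: {sorted(missing)}")
    out = predictors.apply(
        lambda r: classify_secretion(
            PredictorScores(
                r["accession"], bool(r["signalp"]),
                float(r["secretomep"]), int(r["tm_count"]),
            ),
            secretomep_cutoff,
        ),
        axis=1,
    )
    return pd.Series(out.to_numpy(), index=predictors["accession"], name="category")


def summarize_categories(assignments: pd.Series) -> pd.DataFrame:
    """Counts and fractions per category over a GP set; fractions sum to 1."""
    if len(assignments) == 0:
        raise ValueError("cannot summarize an empty category assignment")
    counts = assignments.value_counts().reindex(CATEGORIES, fill_value=0)
    return pd.DataFrame(
        {"count": counts, "fraction": counts / counts.sum()}
    ).rename_axis("category")
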