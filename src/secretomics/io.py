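"""Readers and writers for the pipeline's plain-text interchange formats.

Everything on disk is FASTA, TSV/CSV or JSON so each stage's output can be
inspected and each stage can be rerun independently.  In memory, PSM tables
are pandas DataFrames with list-valued ``accessions`` and ``mod_flags``
columns; on disk those are semicolon-joined strings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass(frozen=True)
class ProteinRecord:
    """One proteome entry: accession, gene identifier and sequence."""

    accession: str
    gene_id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


#: Column order of the PSM table dialect.
PSM_COLUMNS = [
    "run_id",
    "cell_line",
    "replicate",
    "fraction",
    "spectrum_id",
    "peptide",
    "accessions",
    "ion_score",
    "is_decoy",
    "precursor_area",
    "mod_flags",
]

#: Optional columns appended by downstream stages.
PSM_EXTRA_COLUMNS = ["q_value", "mass_delta"]


def write_fasta(proteome: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write a proteome as FASTA; the gene id travels in the description."""
    records = [
        SeqRecord(Seq(p.sequence), id=p.accession, description=f"gene:{p.gene_id}")
        for p in proteome
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a proteome FASTA.

    A ``gene:<id>`` token in the description is taken as the gene identifier;
    otherwise the accession doubles as its own gene id.
    """
    proteome = []
    for rec in SeqIO.parse(str(path), "fasta"):
        gene_id = rec.id
        for token in rec.description.split():
            if token.startswith("gene:"):
                gene_id = token[len("gene:"):]
        proteome.append(ProteinRecord(rec.id, gene_id, str(rec.seq)))
    return proteome


def _join_mods(mods: list[tuple[int, str]]) -> str:
    return ";".join(f"{pos}:{label}" for pos, label in mods)


def _split_mods(text: str) -> list[tuple[int, str]]:
    if not text or pd.isna(text):
        return []
    out = []
    for item in str(text).split(";"):
        pos, label = item.split(":", 1)
        out.append((int(pos), label))
    return out


def write_psm_table(psms: pd.DataFrame, path: str | Path) -> None:
    """Write a PSM table as TSV, serialising list-valued columns."""
    df = psms.copy()
    df["accessions"] = df["accessions"].map(";".join)
    df["mod_flags"] = df["mod_flags"].map(_join_mods)
    cols = PSM_COLUMNS + [c for c in PSM_EXTRA_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False)


def read_psm_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])
    df["accessions"] = df["accessions"].map(
        lambda s: [] if pd.isna(s) else str(s).split(";")
    )
    df["mod_flags"] = df["mod_flags"].map(_split_mods)
    df["is_decoy"] = df["is_decoy"].astype(bool)
    return df


def write_gene_map(gene_map: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"accession": list(gene_map), "gene_id": list(gene_map.values())}
    ).to_csv(path, sep="\t", index=False)


def read_gene_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["accession"], df["gene_id"]))


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    """Planted-truth table to JSON (one object per protein)."""
    payload = truth.to_dict(orient="records")
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.DataFrame(json.loads(Path(path).read_text()))


def read_contingency_csv(path: str | Path) -> pd.DataFrame:
    """Contingency table CSV: first column row labels, remaining columns counts."""
    df = pd.read_csv(path, index_col=0)
    return df.astype(int)
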