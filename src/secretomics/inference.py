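"""Parsimony protein inference and gene-product (GP) collapsing.

Peptides are mapped to proteins by exact substring search; proteins sharing an
identical peptide set are merged; proteins whose peptide set is a strict
subset of another's are subsumed; residual ambiguity is resolved by a greedy
set cover so the smallest explanatory set of groups is retained.  Groups are
then collapsed to the gene level through an accession->gene map, and only GPs
carrying at least one unique peptide are admitted to quantification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from secretomics.io import ProteinRecord

logger = logging.getLogger(__name__)


@dataclass
class ProteinGroup:
    """A parsimony group (or, after collapsing, a gene product).

    ``unique_peptides`` are the supporting peptides that map to no other
    retained group; uniqueness is evaluated after collapsing, so a peptide
    shared only between accessions of the same gene counts as unique.
    """

    gp_id: str
    representative: str
    members: tuple[str, ...]
    peptides: frozenset[str]
    unique_peptides: frozenset[str] = field(default_factory=frozenset)
    gene_id: str = ""
    n_psms: int = 0


def build_peptide_protein_map(
    peptides: pd.Series | list[str], proteome: list[ProteinRecord]
) -> dict[str, set[str]]:
    """Map each distinct peptide to the accessions whose sequence contains it.

    Matching is exact substring search (I and L are distinct residues).
    Peptides matching no protein are logged and dropped.
    """
    if not proteome:
        raise ValueError("proteome is empty")
    pmap: dict[str, set[str]] = {}
    unmatched = []
    for pep in sorted(set(peptides)):
        hits = {p.accession for p in proteome if pep in p.sequence}
        if hits:
            pmap[pep] = hits
        else:
            unmatched.append(pep)
    if unmatched:
        logger.warning("%d peptides match no protein and were dropped", len(unmatched))
    return pmap


def parsimony_group(
    pmap: dict[str, set[str]],
    psm_counts: dict[str, int] | None = None,
    sequences: dict[str, str] | None = None,
) -> list[ProteinGroup]:
    """Group proteins by the parsimony principle.

    Three passes: (1) proteins with identical peptide sets are merged;
    (2) groups whose peptide set is a strict subset of another's are subsumed;
    (3) greedy set cover retains the fewest groups explaining all peptides
    (ties broken by uncovered-peptide count, then total PSM count, then
    lexicographic accession, making the output order-independent).

    ``psm_counts`` maps peptide -> number of QC-passing PSMs (defaults to 1
    per peptide); ``sequences`` lets the representative be the longest member.
    """
    if not pmap:
        raise ValueError("peptide-protein map is empty")
    counts = psm_counts or {}

    by_protein: dict[str, set[str]] = {}
    for pep, accs in pmap.items():
        for acc in accs:
            by_protein.setdefault(acc, set()).add(pep)

    # (1) merge identical peptide sets
    by_pepset: dict[frozenset[str], list[str]] = {}
    for acc, peps in by_protein.items():
        by_pepset.setdefault(frozenset(peps), []).append(acc)
    candidates = [
        (pepset, tuple(sorted(accs))) for pepset, accs in by_pepset.items()
    ]

    # (2) subsume strict subsets
    survivors = []
    for pepset, accs in candidates:
        if not any(pepset < other for other, _ in candidates):
            survivors.append((pepset, accs))

    # (3) greedy set cover over the survivors
    def representative(accs: tuple[str, ...]) -> str:
        if sequences:
            return max(accs, key=lambda a: (len(sequences.get(a, "")), a))
        return accs[0]

    uncovered = set(pmap)
    retained: list[tuple[frozenset[str], tuple[str, ...]]] = []
    pool = list(survivors)
    while uncovered:
        def key(item):
            pepset, accs = item
            gain = len(pepset & uncovered)
            psms = sum(counts.get(p, 1) for p in pepset)
            return (-gain, -psms, accs[0])

        pool.sort(key=key)
        pepset, accs = pool.pop(0)
        if not pepset & uncovered:
            break
        retained.append((pepset, accs))
        uncovered -= pepset

    groups = []
    for pepset, accs in sorted(retained, key=lambda it: it[1][0]):
        rep = representative(accs)
        groups.append(
            ProteinGroup(
                gp_id=rep,
                representative=rep,
                members=accs,
                peptides=pepset,
                n_psms=sum(counts.get(p, 1) for p in pepset),
            )
        )
    return groups


def collapse_to_gp(
    groups: list[ProteinGroup],
    gene_map: dict[str, str],
    sequences: dict[str, str] | None = None,
) -> list[ProteinGroup]:
    """Merge parsimony groups sharing a gene id into gene products.

    The gene id is looked up for the representative accession; accessions
    absent from the map fall back to themselves (with a warning).  Peptide
    sets are unioned, PSM evidence summed, and unique-peptide sets are
    recomputed at GP level: a peptide is unique to a GP when no other
    retained GP's members contain it.
    """
    by_gene: dict[str, list[ProteinGroup]] = {}
    for g in groups:
        gene = gene_map.get(g.representative)
        if gene is None:
            logger.warning(
                "accession %s missing from gene map; used as its own GP",
                g.representative,
            )
            gene = g.representative
        by_gene.setdefault(gene, []).append(g)

    collapsed = []
    for gene, members in sorted(by_gene.items()):
        accs = tuple(sorted({a for g in members for a in g.members}))
        peps = frozenset().union(*(g.peptides for g in members))
        if sequences:
            rep = max(accs, key=lambda a: (len(sequences.get(a, "")), a))
        else:
            rep = members[0].representative
        collapsed.append(
            ProteinGroup(
                gp_id=gene,
                representative=rep,
                members=accs,
                peptides=peps,
                gene_id=gene,
                n_psms=sum(g.n_psms for g in members),
            )
        )

    # GP-level uniqueness
    owner: dict[str, list[str]] = {}
    for gp in collapsed:
        for pep in gp.peptides:
            owner.setdefault(pep, []).append(gp.gp_id)
    for gp in collapsed:
        gp.unique_peptides = frozenset(
            pep for pep in gp.peptides if len(owner[pep]) == 1
        )
    return collapsed


def select_quantifiable(gp_groups: list[ProteinGroup]) -> list[ProteinGroup]:
    """Keep GPs with >= 1 unique peptide; shared-only GPs are identification-only."""
    return [gp for gp in gp_groups if gp.unique_peptides]


def assign_peptides(gp_groups: list[ProteinGroup]) -> dict[str, str]:
    """Assign every supporting peptide to exactly one GP for spectral counting.

    Unique peptides go to their GP; shared peptides go to the GP with the
    largest supporting-peptide set (ties: larger PSM count, then lexicographic
    gp_id).  The assignment conserves total PSM counts per run.
    """
    claims: dict[str, list[ProteinGroup]] = {}
    for gp in gp_groups:
        for pep in gp.peptides:
            claims.setdefault(pep, []).append(gp)
    assignment = {}
    for pep, gps in claims.items():
        best = min(gps, key=lambda g: (-len(g.peptides), -g.n_psms, g.gp_id))
        assignment[pep] = best.gp_id
    return assignment


def groups_table(gp_groups: list[ProteinGroup]) -> pd.DataFrame:
    """Groups summary: gp_id, member accessions, peptide/unique/PSM tallies."""
    return pd.DataFrame(
        {
            "gp_id": [g.gp_id for g in gp_groups],
            "member_accessions": [";".join(g.members) for g in gp_groups],
            "n_peptides": [len(g.peptides) for g in gp_groups],
            "n_unique_peptides": [len(g.unique_peptides) for g in gp_groups],
            "n_psms": [g.n_psms for g in gp_groups],
        }
    )
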