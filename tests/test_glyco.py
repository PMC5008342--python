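"""Sequon finding, glyco-PSM validation and precursor-area quantification."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from secretomics.design import StudyDesign
from secretomics.glyco import (
    O18_DEAMIDATION_SHIFT,
    find_sequons,
    glyco_trend,
    normalize_glyco_areas,
    validate_glyco_psm,
    validate_glyco_table,
)
from secretomics.io import ProteinRecord

AA = list("ACDEFGHIKLMNPQRSTVWY")
SHIFT = O18_DEAMIDATION_SHIFT


def sliding_window_oracle(seq):
    return [
        (i + 1, seq[i : i + 3])
        for i in range(len(seq) - 2)
        if seq[i] == "N" and seq[i + 1] != "P" and seq[i + 2] in ("S", "T")
    ]


class TestFindSequons:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("NPS", []),                       # proline veto
            ("NGS", [(1, "NGS")]),             # canonical
            ("NNST", [(1, "NNS"), (2, "NST")]),  # overlapping sequons
            ("NGA", []),                       # third residue not S/T
            ("AN", []),                        # too short to host a sequon
        ],
    )
    def test_known_cases(self, seq, expected):
        assert find_sequons(seq) == expected

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_sliding_window_oracle(self, seed):
        rng = np.random.default_rng(seed)
        # N/S/T enriched alphabet to hit plenty of sequons
        seq = "".join(rng.choice(AA + list("NNSSTT"), size=150))
        assert find_sequons(seq) == sliding_window_oracle(seq)

    @given(st.text(alphabet="NPSTAG", min_size=0, max_size=60))
    @settings(deadline=None, derandomize=True, max_examples=100)
    def test_oracle_equivalence_property(self, seq):
        assert find_sequons(seq) == sliding_window_oracle(seq)


def glyco_row(peptide, flags, delta, accessions=("P1",), area=5.0):
    return pd.Series(
        {
            "run_id": "r", "cell_line": "Hep3B", "replicate": 1, "fraction": 1,
            "spectrum_id": "s0", "peptide": peptide,
            "accessions": list(accessions),
            "ion_score": 50.0, "is_decoy": False, "precursor_area": area,
            "mod_flags": flags, "mass_delta": delta,
        }
    )


class TestValidateGlycoPsm:
    # protein: sequon at N=9 (NGS), non-sequon N at 14
    protein = ProteinRecord("P1", "G1", "MAAAAAAKNGSCCCNAADDK")
    by_acc = {"P1": protein}

    def test_accepts_sequon_site_with_exact_shift(self):
        row = glyco_row("NGSCCCNAADDK", [(1, "deamid18O")], SHIFT)
        records, reason = validate_glyco_psm(row, self.by_acc)
        assert reason is None
        (rec,) = records
        assert rec["site_position"] == 9
        assert rec["sequon"] == "NGS"
        assert self.protein.sequence[rec["site_position"] - 1] == "N"

    def test_rejects_non_motif_deamidation(self):
        row = glyco_row("NGSCCCNAADDK", [(7, "deamid18O")], SHIFT)
        records, reason = validate_glyco_psm(row, self.by_acc)
        assert records == [] and reason == "non-motif deamidation"

    def test_rejects_mass_mismatch(self):
        row = glyco_row("NGSCCCNAADDK", [(1, "deamid18O")], SHIFT + 1.0)
        _, reason = validate_glyco_psm(row, self.by_acc)
        assert reason == "mass mismatch"

    def test_proline_vetoed_sequon_rejected(self):
        protein = ProteinRecord("P2", "G2", "AAAAKNPSCCCCK")
        row = glyco_row("NPSCCCCK", [(1, "deamid18O")], SHIFT, accessions=("P2",))
        _, reason = validate_glyco_psm(row, {"P2": protein})
        assert reason == "non-motif deamidation"

    def test_two_sites_additive_shift(self):
        protein = ProteinRecord("P3", "G3", "AAAKNGSNGTCCCK")
        row = glyco_row("NGSNGTCCCK", [(1, "deamid18O"), (4, "deamid18O")],
                        2 * SHIFT + 0.015, accessions=("P3",))
        records, reason = validate_glyco_psm(row, {"P3": protein})
        assert reason is None
        assert sorted(r["site_position"] for r in records) == [5, 8]

    def test_flag_on_non_asparagine_is_malformed(self):
        row = glyco_row("NGSCCCNAADDK", [(2, "deamid18O")], SHIFT)
        with pytest.raises(ValueError, match="not an N"):
            validate_glyco_psm(row, self.by_acc)

    def test_shared_peptide_yields_ambiguous_records(self):
        twin = ProteinRecord("P9", "G9", self.protein.sequence)
        row = glyco_row("NGSCCCNAADDK", [(1, "deamid18O")], SHIFT,
                        accessions=("P1", "P9"))
        records, reason = validate_glyco_psm(row, {"P1": self.protein, "P9": twin})
        assert reason is None and len(records) == 2
        assert all(r["ambiguous"] for r in records)


GLYCO_DESIGN = StudyDesign(n_replicates=2, n_fractions=1)


def area_table(site_values):
    """Accepted-site frame + matching total-area frame with constant totals."""
    rows, totals = [], []
    for (acc, site), per_run in site_values.items():
        for (line, rep), area in per_run.items():
            rows.append({"accession": acc, "site_position": site, "sequon": "NGS",
                         "peptide": "X", "cell_line": line, "replicate": rep,
                         "precursor_area": area, "ambiguous": False})
    for line, rep in GLYCO_DESIGN.runs():
        totals.append({"cell_line": line, "replicate": rep, "precursor_area": 10.0})
    return pd.DataFrame(rows), pd.DataFrame(totals)


class TestNormalizeGlycoAreas:
    def test_direct_ratio(self):
        accepted, totals = area_table(
            {("P1", 9): {(line, rep): 5.0 for line, rep in GLYCO_DESIGN.runs()}}
        )
        table = normalize_glyco_areas(accepted, totals, GLYCO_DESIGN)
        np.testing.assert_allclose(table.loc[("P1", 9)].to_numpy(), 0.5)

    def test_scale_invariance(self):
        accepted, totals = area_table(
            {("P1", 9): {(line, rep): 3.0 for line, rep in GLYCO_DESIGN.runs()}}
        )
        scaled = accepted.copy()
        scaled["precursor_area"] *= 10
        totals10 = totals.copy()
        totals10["precursor_area"] *= 10
        t1 = normalize_glyco_areas(accepted, totals, GLYCO_DESIGN)
        t2 = normalize_glyco_areas(scaled, totals10, GLYCO_DESIGN)
        pd.testing.assert_frame_equal(t1, t2)

    def test_planted_doubling_per_rank_recovered(self):
        values = {
            ("P1", 9): {
                (line, rep): 2.0**rank
                for rank, line in enumerate(GLYCO_DESIGN.cell_lines)
                for rep in (1, 2)
            }
        }
        accepted, totals = area_table(values)
        table = normalize_glyco_areas(accepted, totals, GLYCO_DESIGN)
        ratios = table.attrs["ratios"].loc[("P1", 9)]
        for rank, line in enumerate(GLYCO_DESIGN.cell_lines):
            assert ratios[line].mean() == pytest.approx(2.0**rank)

    def test_zero_total_area_is_error(self):
        accepted, totals = area_table(
            {("P1", 9): {(line, rep): 1.0 for line, rep in GLYCO_DESIGN.runs()}}
        )
        totals.loc[0, "precursor_area"] = 0.0
        with pytest.raises(ValueError, match="zero total"):
            normalize_glyco_areas(accepted, totals, GLYCO_DESIGN)


class TestGlycoTrend:
    def make_table(self, profiles):
        cols = pd.MultiIndex.from_tuples(GLYCO_DESIGN.runs(),
                                         names=["cell_line", "replicate"])
        rows = {key: np.repeat(p, 2) for key, p in profiles.items()}
        return pd.DataFrame.from_dict(rows, orient="index", columns=cols)

    def test_mirrored_sites_split_into_increased_and_decreased(self):
        profiles = {("P%d" % i, 1): [1, 2, 4, 8] for i in range(5)}
        profiles.update({("Q%d" % i, 1): [8, 4, 2, 1] for i in range(5)})
        table = self.make_table(profiles)
        out = glyco_trend(table, GLYCO_DESIGN, k=2, seed=0)
        assert sorted(out.trends) == ["decreased", "increased"]
        increased = out.gps_with_trend("increased")
        assert increased == {(f"P{i}", 1) for i in range(5)}


def test_validate_table_accepts_all_clean_sites(small_study, glyco_design):
    """With no contaminants, every emitted glyco-PSM passes validation and
    every accepted site re-verifies the sequon against the proteome."""
    from secretomics.synthetic import simulate_glyco_psms

    proteome, truth, _ = small_study
    psms = simulate_glyco_psms(proteome, truth, glyco_design, seed=3,
                               contaminant_fraction=0.0)
    accepted, rejected = validate_glyco_table(psms, proteome)
    assert len(rejected) == 0
    by_acc = {p.accession: p for p in proteome}
    for _, rec in accepted.iterrows():
        seq = by_acc[rec["accession"]].sequence
        pos = rec["site_position"]
        assert seq[pos - 1] == "N"
        assert (pos, rec["sequon"]) in find_sequons(seq)
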