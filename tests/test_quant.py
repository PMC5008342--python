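"""Tryptic counting, SAF1/NSAF5, replicate correlation and the ANOVA screen."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from secretomics.design import StudyDesign
from secretomics.inference import ProteinGroup
from secretomics.quant import (
    NSAF5_SCALE,
    abundance_matrix,
    anova_screen,
    compute_nsaf5,
    compute_saf1,
    psm_count_matrix,
    replicate_correlation,
    theoretical_tryptic_peptides,
    tryptic_peptides,
)

AA = list("ACDEFGHIKLMNPQRSTVWY")


def oracle_tryptic_count(seq: str, min_len: int = 7) -> int:
    """Character-walk oracle: cleave after K/R unless the next residue is P."""
    if not seq:
        return 0
    segments, start = [], 0
    for i, ch in enumerate(seq):
        if ch in "KR" and (i + 1 == len(seq) or seq[i + 1] != "P"):
            segments.append(seq[start : i + 1])
            start = i + 1
    if start < len(seq):
        segments.append(seq[start:])
    return sum(1 for s in segments if len(s) >= min_len)


class TestTheoreticalTrypticPeptides:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("AAAAAAA", 1),     # single 7-mer, no cleavage site
            ("AAAKAAA", 0),     # both segments below the length floor
            ("AAAKPAAAA", 1),   # K before P does not cleave
            ("", 0),
        ],
    )
    def test_known_cases(self, seq, expected):
        assert theoretical_tryptic_peptides(seq) == expected

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_character_walk_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(AA, size=200))
        assert theoretical_tryptic_peptides(seq) == oracle_tryptic_count(seq)

    def test_segments_reassemble_sequence(self):
        rng = np.random.default_rng(42)
        seq = "".join(rng.choice(AA, size=300))
        assert "".join(tryptic_peptides(seq, min_len=1)) == seq


class TestSafNsaf:
    def test_saf1_direct_formula(self):
        assert compute_saf1(10, 10) == 10.0
        assert compute_saf1(0, 5) == 0.0
        assert compute_saf1(6, 3) == 2 * compute_saf1(3, 3)

    def test_zero_theoretical_count_rejected(self):
        with pytest.raises(ValueError):
            compute_saf1(5, 0)

    def test_nsaf5_single_and_symmetric(self):
        assert compute_nsaf5([3.0])[0] == NSAF5_SCALE
        np.testing.assert_allclose(compute_nsaf5([2.0, 2.0]), [50000.0, 50000.0])

    @pytest.mark.parametrize("seed", range(5))
    def test_nsaf5_sums_to_scale(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.uniform(0, 100, size=rng.integers(1, 50))
        assert compute_nsaf5(values).sum() == pytest.approx(NSAF5_SCALE, rel=1e-9)

    def test_all_zero_run_is_an_error(self):
        with pytest.raises(ValueError, match="no quantifiable evidence"):
            compute_nsaf5([0.0, 0.0])

    @given(st.lists(st.floats(min_value=1e-3, max_value=1e6),
                    min_size=1, max_size=40))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_nsaf5_normalization_property(self, values):
        out = compute_nsaf5(values)
        assert out.sum() == pytest.approx(NSAF5_SCALE, rel=1e-9)
        assert (out >= 0).all()


def tiny_gp_setup():
    """Two GPs with known sequences and a hand-built QC-passed PSM table."""
    seqs = {"A": "AAAAAAAKCCCCCCCK", "B": "DDDDDDDK"}  # theo counts 2 and 1
    gps = [
        ProteinGroup("GA", "A", ("A",), frozenset({"AAAAAAAK", "CCCCCCCK"}),
                     frozenset({"AAAAAAAK"}), "GA", 0),
        ProteinGroup("GB", "B", ("B",), frozenset({"DDDDDDDK"}),
                     frozenset({"DDDDDDDK"}), "GB", 0),
    ]
    return seqs, gps


def psm_rows(counts: dict, design: StudyDesign, fractions=None) -> pd.DataFrame:
    rows = []
    for (pep, line, rep), n in counts.items():
        for i in range(n):
            frac = fractions[i % len(fractions)] if fractions else 1
            rows.append(
                {"run_id": f"{line}_r{rep}_f{frac}", "cell_line": line,
                 "replicate": rep, "fraction": frac, "spectrum_id": f"{pep}{i}",
                 "peptide": pep, "accessions": ["A"], "ion_score": 50.0,
                 "is_decoy": False, "precursor_area": 1.0, "mod_flags": []}
            )
    return pd.DataFrame(rows)


class TestAbundanceMatrix:
    design = StudyDesign(cell_lines=("L1", "L2"), n_replicates=1, n_fractions=12)

    def test_psm_counts_conserved_per_run(self):
        seqs, gps = tiny_gp_setup()
        psms = psm_rows(
            {("AAAAAAAK", "L1", 1): 4, ("DDDDDDDK", "L1", 1): 6,
             ("CCCCCCCK", "L2", 1): 5}, self.design)
        counts = psm_count_matrix(psms, gps, self.design)
        assert counts[("L1", 1)].sum() == 10
        assert counts[("L2", 1)].sum() == 5

    def test_nsaf5_values_match_hand_computation(self):
        seqs, gps = tiny_gp_setup()
        psms = psm_rows(
            {("AAAAAAAK", "L1", 1): 4, ("DDDDDDDK", "L1", 1): 6,
             ("CCCCCCCK", "L2", 1): 5}, self.design)
        counts = psm_count_matrix(psms, gps, self.design)
        matrix = abundance_matrix(counts, gps, seqs)
        # SAF1: GA = 10*4/2 = 20, GB = 10*6/1 = 60 -> NSAF5 25000 / 75000
        assert matrix.loc["GA", ("L1", 1)] == pytest.approx(25000.0)
        assert matrix.loc["GB", ("L1", 1)] == pytest.approx(75000.0)

    def test_scale_invariance_of_nsaf5(self):
        seqs, gps = tiny_gp_setup()
        base = {("AAAAAAAK", "L1", 1): 2, ("DDDDDDDK", "L1", 1): 3,
                ("DDDDDDDK", "L2", 1): 4}
        tripled = {k: 3 * v for k, v in base.items()}
        m1 = abundance_matrix(
            psm_count_matrix(psm_rows(base, self.design), gps, self.design),
            gps, seqs)
        m2 = abundance_matrix(
            psm_count_matrix(psm_rows(tripled, self.design), gps, self.design),
            gps, seqs)
        pd.testing.assert_frame_equal(m1, m2)

    def test_fraction_split_equals_pooled(self):
        seqs, gps = tiny_gp_setup()
        counts = {("AAAAAAAK", "L1", 1): 12, ("DDDDDDDK", "L1", 1): 6,
                  ("CCCCCCCK", "L2", 1): 12}
        pooled = psm_rows(counts, self.design)
        split = psm_rows(counts, self.design, fractions=list(range(1, 13)))
        m1 = abundance_matrix(
            psm_count_matrix(pooled, gps, self.design), gps, seqs)
        m2 = abundance_matrix(
            psm_count_matrix(split, gps, self.design), gps, seqs)
        pd.testing.assert_frame_equal(m1, m2)


class TestReplicateCorrelation:
    def test_self_and_anticorrelation(self):
        m = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [4.0, 3, 2, 1]})
        out = replicate_correlation(m)
        assert out.loc["a", "a"] == 1.0
        assert out.loc["a", "b"] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.uniform(1, 10, size=(30, 2)), columns=["a", "b"])
        out = replicate_correlation(m)
        x, y = m["a"].to_numpy(), m["b"].to_numpy()
        expected = np.cov(x, y, ddof=1)[0, 1] / (x.std(ddof=1) * y.std(ddof=1))
        assert out.loc["a", "b"] == pytest.approx(expected, rel=1e-12)

    def test_too_few_shared_gps_is_nan(self):
        m = pd.DataFrame({"a": [1.0, 0, 0, 2], "b": [1.0, 3, 0, 0]})
        assert np.isnan(replicate_correlation(m).loc["a", "b"])

    def test_single_column_rejected(self):
        with pytest.raises(ValueError):
            replicate_correlation(pd.DataFrame({"a": [1.0, 2]}))


class TestAnovaScreen:
    design = StudyDesign(n_replicates=3)

    def matrix(self, rows):
        cols = pd.MultiIndex.from_tuples(self.design.runs(),
                                         names=["cell_line", "replicate"])
        return pd.DataFrame(rows, columns=cols)

    def test_identical_group_patterns_give_f_zero(self):
        m = self.matrix([[1, 2, 3] * 4])
        out = anova_screen(m, self.design)
        assert out["F"].iloc[0] == pytest.approx(0.0)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_constant_gp_flagged_degenerate(self):
        m = self.matrix([[5.0] * 12])
        out = anova_screen(m, self.design)
        assert out["degenerate"].iloc[0]
        assert not out["significant"].iloc[0]

    def test_f_matches_between_within_mean_square_ratio(self):
        rng = np.random.default_rng(2)
        values = rng.uniform(0, 10, 12)
        m = self.matrix([values])
        out = anova_screen(m, self.design)
        groups = values.reshape(4, 3)
        grand = values.mean()
        ss_between = 3 * ((groups.mean(axis=1) - grand) ** 2).sum()
        ss_within = ((groups - groups.mean(axis=1, keepdims=True)) ** 2).sum()
        f_hand = (ss_between / 3) / (ss_within / 8)
        assert out["F"].iloc[0] == pytest.approx(f_hand, rel=1e-10)

    def test_strong_planted_effect_is_significant(self):
        profile = np.repeat([1.0, 2.0, 4.0, 8.0], 3)
        noisy = profile * (1 + 0.02 * np.sin(np.arange(12)))
        out = anova_screen(self.matrix([noisy]), self.design)
        assert out["significant"].iloc[0]
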