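"""Study design: the cell-line panel, its metastatic ordering, and run layout."""

from __future__ import annotations

from dataclasses import dataclass, field

#: Panel ordered by metastatic potential: none < low < high < highest.
DEFAULT_CELL_LINES: tuple[str, ...] = ("Hep3B", "MHCC97L", "MHCC97H", "HCCLM3")


@dataclass(frozen=True)
class StudyDesign:
    """Layout of a label-free secretome experiment.

    Parameters
    ----------
    cell_lines
        Panel labels in increasing order of metastatic potential; the position
        of a label is its metastatic rank (0 = non-metastatic control).
    n_replicates
        Biological replicates per cell line (3 for the secretome arm,
        2 for the glyco arm).
    n_fractions
        Peptide fractions per replicate (12 OFFGEL fractions).
    seed
        Base seed for any simulation tied to this design.
    """

    cell_lines: tuple[str, ...] = DEFAULT_CELL_LINES
    n_replicates: int = 3
    n_fractions: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.cell_lines) < 1:
            raise ValueError("need at least one cell line")
        if len(set(self.cell_lines)) != len(self.cell_lines):
            raise ValueError("cell line labels must be unique")
        if self.n_replicates < 1 or self.n_fractions < 1:
            raise ValueError("replicate and fraction counts must be >= 1")

    @property
    def ranks(self) -> dict[str, int]:
        """Metastatic rank per cell line (0..n_lines-1)."""
        return {line: i for i, line in enumerate(self.cell_lines)}

    def runs(self) -> list[tuple[str, int]]:
        """All (cell line, replicate) quantification units, replicates 1-based."""
        return [
            (line, rep)
            for line in self.cell_lines
            for rep in range(1, self.n_replicates + 1)
        ]

    def run_id(self, cell_line: str, replicate: int, fraction: int) -> str:
        return f"{cell_line}_r{replicate}_f{fraction}"
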