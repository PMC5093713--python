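"""Experiment design: cell lines, cell types, replicate structure.

The study design this package targets is a panel of human pluripotent and
somatic cell lines profiled in replicate LC-MS runs: induced pluripotent
stem cell (hiPSC) lines, embryonic stem cell (hESC) lines, and the somatic
cell (SC) lines the hiPSCs were reprogrammed from. The default design
mirrors that panel: nine lines (five hiPSC, two hESC, two parental SC),
three replicate runs per line.
"""

from __future__ import annotations

from dataclasses import dataclass, field

CELL_TYPES = ("hiPSC", "hESC", "SC")


@dataclass(frozen=True)
class CellLine:
    """One cell line: a name, its type, and (for hiPSCs) its parental SC."""

    name: str
    cell_type: str
    parent: str | None = None

    def __post_init__(self) -> None:
        if self.cell_type not in CELL_TYPES:
            raise ValueError(
                f"cell_type must be one of {CELL_TYPES}, got {self.cell_type!r}"
            )


@dataclass(frozen=True)
class ExperimentDesign:
    """Cell-line panel plus replicate count; validates internal consistency.

    Run identifiers are ``<line>_<replicate>`` with replicates numbered from 1.
    """

    cell_lines: tuple[CellLine, ...]
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if not self.cell_lines:
            raise ValueError("design must contain at least one cell line")
        names = [cl.name for cl in self.cell_lines]
        if len(set(names)) != len(names):
            raise ValueError("cell line names must be unique")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        sc_names = {cl.name for cl in self.cell_lines if cl.cell_type == "SC"}
        for cl in self.cell_lines:
            if cl.cell_type == "hiPSC" and cl.parent is not None:
                if cl.parent not in sc_names:
                    raise ValueError(
                        f"parent {cl.parent!r} of {cl.name!r} is not an SC line "
                        "in the design"
                    )

    # -- convenience accessors -------------------------------------------------

    @property
    def line_names(self) -> list[str]:
        return [cl.name for cl in self.cell_lines]

    def lines_of_type(self, cell_type: str) -> list[str]:
        return [cl.name for cl in self.cell_lines if cl.cell_type == cell_type]

    def cell_type_of(self, line: str) -> str:
        for cl in self.cell_lines:
            if cl.name == line:
                return cl.cell_type
        raise KeyError(f"unknown cell line {line!r}")

    def parent_of(self, line: str) -> str | None:
        for cl in self.cell_lines:
            if cl.name == line:
                return cl.parent
        raise KeyError(f"unknown cell line {line!r}")

    def run_ids(self, line: str | None = None) -> list[str]:
        lines = [line] if line is not None else self.line_names
        return [f"{ln}_{r}" for ln in lines for r in range(1, self.n_replicates + 1)]

    def run_line(self, run_id: str) -> str:
        line, _, rep = run_id.rpartition("_")
        if line not in set(self.line_names) or not rep.isdigit():
            raise KeyError(f"run id {run_id!r} does not match the design")
        return line


def default_design(n_replicates: int = 3) -> ExperimentDesign:
    """The nine-line panel: five hiPSC, two hESC, two parental SC lines."""
    return ExperimentDesign(
        cell_lines=(
            CellLine("Gra1", "hiPSC", parent="HGra"),
            CellLine("Gra2", "hiPSC", parent="HGra"),
            CellLine("Gra7", "hiPSC", parent="HGra"),
            CellLine("CBF46", "hiPSC", parent="HF"),
            CellLine("CBF50", "hiPSC", parent="HF"),
            CellLine("H9", "hESC"),
            CellLine("NTU1", "hESC"),
            CellLine("HGra", "SC"),
            CellLine("HF", "SC"),
        ),
        n_replicates=n_replicates,
    )


def default_comparison_plan(design: ExperimentDesign) -> list[tuple[str, str]]:
    """The 19-comparison plan: every hiPSC vs every hESC (10), each hiPSC vs
    its parental SC (5), and each hESC vs each SC (4)."""
    hipsc = design.lines_of_type("hiPSC")
    hesc = design.lines_of_type("hESC")
    sc = design.lines_of_type("SC")
    plan: list[tuple[str, str]] = [(a, b) for a in hipsc for b in hesc]
    for a in hipsc:
        parent = design.parent_of(a)
        if parent is not None:
            plan.append((a, parent))
    plan.extend((a, b) for a in hesc for b in sc)
    return plan
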