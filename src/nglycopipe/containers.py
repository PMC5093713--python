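"""In-memory containers shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import ExperimentDesign


@dataclass
class IntensityMatrix:
    """Features x runs intensity matrix with run metadata.

    ``values`` holds linear-scale intensities (NaN = not detected), one row
    per feature (glycosite or protein) and one column per run. ``runs`` is
    indexed by run id with columns ``cell_line``, ``cell_type`` and
    ``replicate``. ``features`` (optional) is indexed like ``values`` and may
    carry ``protein_id``, ``gene_symbol`` and ``varmod_flag``.
    """

    values: pd.DataFrame
    runs: pd.DataFrame
    features: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.runs.index)
        if missing:
            raise ValueError(f"runs metadata missing for columns: {sorted(missing)}")
        for col in ("cell_line", "cell_type", "replicate"):
            if col not in self.runs.columns:
                raise ValueError(f"runs metadata lacks required column {col!r}")
        if self.features is not None and not self.features.index.equals(
            self.values.index
        ):
            raise ValueError("features metadata index must match values index")

    @property
    def lines(self) -> list[str]:
        seen: list[str] = []
        for ln in self.runs.loc[self.values.columns, "cell_line"]:
            if ln not in seen:
                seen.append(ln)
        return seen

    def runs_of_line(self, line: str) -> list[str]:
        mask = self.runs["cell_line"] == line
        return [r for r in self.values.columns if r in set(self.runs.index[mask])]

    def line_values(self, line: str) -> pd.DataFrame:
        """Replicate columns of one cell line (features x replicates)."""
        return self.values[self.runs_of_line(line)]

    def log2(self) -> pd.DataFrame:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.log2(self.values)

    def line_mean_log2(self) -> pd.DataFrame:
        """Per-line mean of log2 intensities over non-missing replicates."""
        logv = self.log2()
        return pd.DataFrame(
            {line: logv[self.runs_of_line(line)].mean(axis=1) for line in self.lines}
        )

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(
            self.values.copy(),
            self.runs.copy(),
            None if self.features is None else self.features.copy(),
        )


def runs_metadata(design: ExperimentDesign) -> pd.DataFrame:
    """Run metadata table (run id -> cell_line/cell_type/replicate) for a design."""
    rows = []
    for cl in design.cell_lines:
        for rep in range(1, design.n_replicates + 1):
            rows.append(
                {
                    "run": f"{cl.name}_{rep}",
                    "cell_line": cl.name,
                    "cell_type": cl.cell_type,
                    "replicate": rep,
                }
            )
    return pd.DataFrame(rows).set_index("run")


@dataclass
class ExpressionMatrix:
    """Probes x samples expression matrix with sample metadata and probe map.

    ``values`` holds non-negative linear-scale expression; ``samples`` is
    indexed by sample id with columns ``cell_line``, ``cell_type``,
    ``replicate``; ``probe_map`` maps probe id -> gene symbol (probes absent
    from the map are unannotated).
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    probe_map: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"sample metadata missing for: {sorted(missing)}")
        counts = self.samples.loc[list(self.values.columns)].groupby("cell_line").size()
        if (counts < 2).any():
            low = sorted(counts.index[counts < 2])
            raise ValueError(f"every cell line needs >=2 replicate samples: {low}")

    def samples_of_type(self, cell_type: str) -> list[str]:
        mask = self.samples["cell_type"] == cell_type
        return [s for s in self.values.columns if s in set(self.samples.index[mask])]

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(), self.samples.copy(), self.probe_map.copy()
        )
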