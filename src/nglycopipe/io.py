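"""Readers and writers for the pipeline's plain-text interchange formats."""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .containers import ExpressionMatrix, IntensityMatrix, runs_metadata
from .design import ExperimentDesign


def write_fasta(records, path: str | Path) -> None:
    SeqIO.write(records, str(path), "fasta")


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def matrix_to_table(matrix: IntensityMatrix, id_name: str = "protein_id") -> pd.DataFrame:
    """Flatten an IntensityMatrix to {id, intensity_<run>...} for TSV export."""
    table = matrix.values.copy()
    table.columns = [f"intensity_{run}" for run in table.columns]
    table.index.name = id_name
    return table


def read_proteome_table(path: str | Path, design: ExperimentDesign) -> IntensityMatrix:
    """Read a tab-delimited {protein_id, intensity_<run>...} table."""
    table = pd.read_csv(path, sep="\t", index_col=0)
    runs = [c[len("intensity_") :] for c in table.columns if c.startswith("intensity_")]
    values = table[[f"intensity_{r}" for r in runs]]
    values.columns = runs
    return IntensityMatrix(values=values, runs=runs_metadata(design).loc[runs])


def write_expression(matrix: ExpressionMatrix, prefix: str | Path) -> dict[str, Path]:
    """Write an expression matrix as three TSVs: values, probe map, sample sheet."""
    prefix = Path(prefix)
    paths = {
        "values": prefix.with_suffix(".values.tsv"),
        "probe_map": prefix.with_suffix(".probe_map.tsv"),
        "samples": prefix.with_suffix(".samples.tsv"),
    }
    write_tsv(matrix.values, paths["values"])
    pm = matrix.probe_map.rename("gene_symbol").to_frame()
    pm.index.name = "probe_id"
    write_tsv(pm, paths["probe_map"])
    write_tsv(matrix.samples, paths["samples"])
    return paths


def read_expression(
    values_path: str | Path, probe_map_path: str | Path, samples_path: str | Path
) -> ExpressionMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    probe_map = pd.read_csv(probe_map_path, sep="\t", index_col=0)["gene_symbol"]
    samples = pd.read_csv(samples_path, sep="\t", index_col=0)
    return ExpressionMatrix(values=values, samples=samples, probe_map=probe_map)


def sha256_file(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
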