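"""Glycosite identification: table parsing, quality filters, sequon validation.

N-linked glycans attach to asparagine within the consensus tripeptide
(sequon) N-X-[S/T/C] where X is any residue except proline. Search-engine
output (MaxQuant-style site tables) is filtered here the way a label-free
glycoproteomics analysis requires before quantitation:

* contaminant (``CON__``) and reverse-decoy (``REV__``) identifications are
  dropped;
* the site-localization score must be >= 50 and the localization
  probability >= 0.8 in at least two replicate runs of at least one cell
  line (both thresholds inclusive);
* the reported site must fall on a genuine sequon of its protein sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .design import ExperimentDesign

logger = logging.getLogger(__name__)

SEQON_THIRD_RESIDUES = frozenset("STC")
_X_RESIDUES = frozenset("ACDEFGHIKLMNQRSTVWY")  # the 20 amino acids minus P

REQUIRED_COLUMNS = (
    "protein_id",
    "gene_symbol",
    "position",
    "sequence_window",
    "peptide",
    "localization_score",
    "contaminant_flag",
    "reverse_flag",
    "varmod_flag",
)


class FormatError(ValueError):
    """Raised when an input table does not match the expected dialect."""


@dataclass(frozen=True)
class SequonHit:
    """One N-X(!=P)-[S/T/C] match; ``position`` is the 1-based index of N."""

    position: int
    x_residue: str
    third_residue: str


@dataclass
class GlycoSiteRecord:
    """One glycosylation site with its evidence and per-run intensities."""

    protein_id: str
    gene_symbol: str
    position: int
    peptide: str
    sequence_window: str
    localization_score: float
    localization_probs: dict[str, float]
    contaminant_flag: bool = False
    reverse_flag: bool = False
    varmod_flag: bool = False
    intensities: dict[str, float] = field(default_factory=dict)

    @property
    def site_id(self) -> str:
        return f"{self.protein_id}@{self.position}"

    def detected_lines(self, design: ExperimentDesign) -> set[str]:
        """Cell lines with at least one non-missing intensity for this site."""
        lines = set()
        for run, value in self.intensities.items():
            if value == value:  # not NaN
                lines.add(design.run_line(run))
        return lines


def _to_bool(value) -> bool:
    if isinstance(value, str):
        return value.strip().lower() in {"1", "true", "yes", "+"}
    return bool(value)


def parse_site_table(path: str | Path) -> list[GlycoSiteRecord]:
    """Read a tab-delimited glycosite table into records.

    Intensity columns are named ``intensity_<cellline>_<rep>``; empty cells
    are preserved as missing (NaN), never coerced to zero. Localization
    probabilities may be per-run (``localization_prob_<cellline>_<rep>``) or
    a single ``localization_prob`` column applied to every run.
    """
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise FormatError(f"{path.name}: missing required column {col!r}")
    intensity_cols = [c for c in table.columns if c.startswith("intensity_")]
    if not intensity_cols:
        raise FormatError(f"{path.name}: no intensity_<run> columns found")
    prob_run_cols = [c for c in table.columns if c.startswith("localization_prob_")]
    if not prob_run_cols and "localization_prob" not in table.columns:
        raise FormatError(
            f"{path.name}: missing required column 'localization_prob' "
            "(or per-run 'localization_prob_<run>' columns)"
        )

    def numeric(col: str, allow_missing: bool) -> pd.Series:
        raw = table[col].str.strip()
        vals = pd.to_numeric(raw.replace("", None), errors="coerce")
        bad = vals.isna() & (raw != "")
        if bad.any():
            row = int(bad.idxmax()) + 2  # 1-based, counting the header line
            raise FormatError(f"{path.name}: non-numeric value in {col!r} at line {row}")
        if not allow_missing and vals.isna().any():
            row = int(vals.isna().idxmax()) + 2
            raise FormatError(f"{path.name}: empty value in {col!r} at line {row}")
        return vals

    intens = {c: numeric(c, allow_missing=True) for c in intensity_cols}
    score = numeric("localization_score", allow_missing=False)
    position = numeric("position", allow_missing=False)
    probs = {c: numeric(c, allow_missing=True) for c in prob_run_cols}
    single_prob = (
        numeric("localization_prob", allow_missing=True)
        if "localization_prob" in table.columns
        else None
    )

    run_ids = [c[len("intensity_") :] for c in intensity_cols]
    records: list[GlycoSiteRecord] = []
    for i in range(len(table)):
        loc_probs: dict[str, float] = {}
        for c in prob_run_cols:
            v = probs[c].iloc[i]
            if v == v:
                loc_probs[c[len("localization_prob_") :]] = float(v)
        if not loc_probs and single_prob is not None:
            v = single_prob.iloc[i]
            if v == v:
                loc_probs = {run: float(v) for run in run_ids}
        records.append(
            GlycoSiteRecord(
                protein_id=table["protein_id"].iloc[i],
                gene_symbol=table["gene_symbol"].iloc[i],
                position=int(position.iloc[i]),
                peptide=table["peptide"].iloc[i],
                sequence_window=table["sequence_window"].iloc[i],
                localization_score=float(score.iloc[i]),
                localization_probs=loc_probs,
                contaminant_flag=_to_bool(table["contaminant_flag"].iloc[i]),
                reverse_flag=_to_bool(table["reverse_flag"].iloc[i]),
                varmod_flag=_to_bool(table["varmod_flag"].iloc[i]),
                intensities={
                    run: float(intens[c].iloc[i])
                    for run, c in zip(run_ids, intensity_cols)
                },
            )
        )
    return records


def filter_records(
    records: Sequence[GlycoSiteRecord],
    design: ExperimentDesign | None = None,
    min_score: float = 50.0,
    min_prob: float = 0.8,
    min_prob_replicates: int = 2,
    per_line: bool = True,
) -> list[GlycoSiteRecord]:
    """Apply decoy/contaminant exclusion and the localization quality gates.

    A record is retained iff it is neither a contaminant nor a reverse hit,
    its localization score is >= ``min_score``, and its localization
    probability is >= ``min_prob`` in at least ``min_prob_replicates`` runs —
    by default within at least one cell line (``per_line=True``); with
    ``per_line=False`` the replicate count is taken across all runs.
    """

    def line_of(run: str) -> str:
        if design is not None:
            return design.run_line(run)
        return run.rpartition("_")[0]

    kept: list[GlycoSiteRecord] = []
    for rec in records:
        if rec.contaminant_flag or rec.reverse_flag:
            continue
        if rec.localization_score < min_score:
            continue
        passing = [run for run, p in rec.localization_probs.items() if p >= min_prob]
        if per_line:
            per = pd.Series([line_of(r) for r in passing]).value_counts()
            ok = bool((per >= min_prob_replicates).any()) if len(per) else False
        else:
            ok = len(passing) >= min_prob_replicates
        if ok:
            kept.append(rec)
    return kept


def find_sequons(sequence: str) -> list[SequonHit]:
    """Scan a protein sequence for N-X(!=P)-[S/T/C] sequons (1-based positions).

    Overlapping sequons are all reported; positions within two residues of
    the C-terminus cannot complete a sequon (no wraparound). Unknown letters
    never match.
    """
    seq = sequence.upper()
    hits: list[SequonHit] = []
    for i in range(len(seq) - 2):
        if (
            seq[i] == "N"
            and seq[i + 1] in _X_RESIDUES
            and seq[i + 2] in SEQON_THIRD_RESIDUES
        ):
            hits.append(SequonHit(i + 1, seq[i + 1], seq[i + 2]))
    return hits


def validate_sites(
    records: Sequence[GlycoSiteRecord],
    db: Mapping[str, str] | Iterable,
) -> tuple[list[GlycoSiteRecord], dict[str, int], list[tuple[str, str]]]:
    """Keep records whose position is a true sequon of their protein.

    ``db`` maps protein id -> sequence (or is an iterable of Biopython
    SeqRecords). Returns (valid records, tally of the N+2 residue over valid
    sites, exclusion list of (site_id, reason)).
    """
    if not isinstance(db, Mapping):
        db = {rec.id: str(rec.seq) for rec in db}
    sequons: dict[str, dict[int, SequonHit]] = {}
    valid: list[GlycoSiteRecord] = []
    tally = {"T": 0, "S": 0, "C": 0}
    excluded: list[tuple[str, str]] = []
    for rec in records:
        seq = db.get(rec.protein_id)
        if seq is None:
            logger.warning("protein %s absent from FASTA; site excluded", rec.protein_id)
            excluded.append((rec.site_id, "protein_not_in_database"))
            continue
        if rec.protein_id not in sequons:
            sequons[rec.protein_id] = {h.position: h for h in find_sequons(seq)}
        hit = sequons[rec.protein_id].get(rec.position)
        if hit is None:
            excluded.append((rec.site_id, "not_a_sequon"))
            continue
        tally[hit.third_residue] += 1
        valid.append(rec)
    return valid, tally, excluded


@dataclass
class IdentificationSummary:
    """Per-line and cross-line identification counts."""

    per_line: pd.DataFrame  # index cell line; n_proteins, n_peptides, n_sites
    overlap_hipsc_hesc: int  # proteins seen in both PSC groups
    overlap_all_types: int  # proteins seen in all three cell-type groups
    sites_in_one_line: int
    sites_in_two_plus: int
    sites_in_seven_plus: int
    residue_tally: dict[str, int] = field(default_factory=dict)


def summarize_identifications(
    records: Sequence[GlycoSiteRecord],
    design: ExperimentDesign,
    residue_tally: dict[str, int] | None = None,
) -> IdentificationSummary:
    """Count identifications per line and their overlap across cell types.

    A site counts as identified in a line if it has at least one non-missing
    intensity among that line's runs.
    """
    lines = design.line_names
    proteins: dict[str, set[str]] = {ln: set() for ln in lines}
    peptides: dict[str, set[str]] = {ln: set() for ln in lines}
    sites: dict[str, set[str]] = {ln: set() for ln in lines}
    site_lines: dict[str, set[str]] = {}
    for rec in records:
        detected = rec.detected_lines(design)
        site_lines.setdefault(rec.site_id, set()).update(detected)
        for ln in detected:
            proteins[ln].add(rec.protein_id)
            peptides[ln].add(rec.peptide)
            sites[ln].add(rec.site_id)
    per_line = pd.DataFrame(
        {
            "n_proteins": [len(proteins[ln]) for ln in lines],
            "n_peptides": [len(peptides[ln]) for ln in lines],
            "n_sites": [len(sites[ln]) for ln in lines],
        },
        index=pd.Index(lines, name="cell_line"),
    )

    def group_union(cell_type: str) -> set[str]:
        out: set[str] = set()
        for ln in design.lines_of_type(cell_type):
            out |= proteins[ln]
        return out

    hipsc, hesc, sc = (group_union(t) for t in ("hiPSC", "hESC", "SC"))
    n_lines = pd.Series({s: len(v) for s, v in site_lines.items()})
    return IdentificationSummary(
        per_line=per_line,
        overlap_hipsc_hesc=len(hipsc & hesc),
        overlap_all_types=len(hipsc & hesc & sc),
        sites_in_one_line=int((n_lines == 1).sum()),
        sites_in_two_plus=int((n_lines >= 2).sum()),
        sites_in_seven_plus=int((n_lines >= 7).sum()),
        residue_tally=dict(residue_tally or {}),
    )


def load_fasta(path: str | Path) -> dict[str, str]:
    """Read a protein FASTA into an id -> sequence mapping."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def records_to_matrix(records: Sequence[GlycoSiteRecord], design: ExperimentDesign):
    """Assemble an IntensityMatrix (features x runs) from site records."""
    from .containers import IntensityMatrix, runs_metadata

    runs = design.run_ids()
    index = pd.Index([r.site_id for r in records], name="site")
    if index.has_duplicates:
        raise ValueError("duplicate site ids among records")
    values = pd.DataFrame(
        [[rec.intensities.get(run, float("nan")) for run in runs] for rec in records],
        index=index,
        columns=runs,
    )
    features = pd.DataFrame(
        {
            "protein_id": [r.protein_id for r in records],
            "gene_symbol": [r.gene_symbol for r in records],
            "varmod_flag": [r.varmod_flag for r in records],
        },
        index=index,
    )
    return IntensityMatrix(values=values, runs=runs_metadata(design), features=features)
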