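"""Protein-level calibration of glycosite fold changes.

A change in a glycopeptide's intensity can reflect either a change in
site occupancy/glycosylation or simply a change in the parent protein's
abundance. Dividing the glyco fold change by the protein fold change
(subtraction in log2 space) isolates the glycosylation-specific component.
A calibrated site is *retained* when its calibrated fold change is still
>=2-fold in either direction; calibrated changes in [1.75, 2) are retained
with a ``near_threshold`` flag; anything weaker is *explained by protein*;
proteins absent from the proteome table are *unmatched* and keep their
uncalibrated fold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .containers import IntensityMatrix

RETAINED = "retained"
EXPLAINED = "explained_by_protein"
UNMATCHED = "unmatched"


@dataclass
class CalibrationRecord:
    """One glycosite's fold change before/after protein-level calibration."""

    protein_id: str
    site: str
    glyco_fold: float
    protein_fold: float | None = None
    calibrated_fold: float | None = None
    status: str = UNMATCHED
    near_threshold: bool = False
    error: str | None = None


def protein_fold_changes(
    proteome: IntensityMatrix, line_a: str, line_b: str
) -> dict[str, float]:
    """Per-protein linear fold change (mean_a / mean_b) from a proteome matrix.

    Requires >=2 non-missing replicates in each line; proteins failing that
    are omitted (treated downstream as unmatched).
    """
    folds: dict[str, float] = {}
    va = proteome.line_values(line_a)
    vb = proteome.line_values(line_b)
    ok = (va.notna().sum(axis=1) >= 2) & (vb.notna().sum(axis=1) >= 2)
    ratio = va.mean(axis=1) / vb.mean(axis=1)
    for protein in proteome.values.index[ok]:
        folds[str(protein)] = float(ratio.loc[protein])
    return folds


def calibrate(
    glyco: pd.DataFrame,
    protein_folds: Mapping[str, float],
    retain_threshold: float = 2.0,
    note_threshold: float = 1.75,
) -> list[CalibrationRecord]:
    """Calibrate altered glycosites by their protein fold changes.

    ``glyco`` holds one row per altered site with columns ``protein_id`` and
    ``fold_change`` (linear ratio, index = site id). Calibration divides in
    linear space; classification uses the magnitude of the calibrated log2
    fold change.
    """
    if not 1 < note_threshold <= retain_threshold:
        raise ValueError("need 1 < note_threshold <= retain_threshold")
    log_retain = math.log2(retain_threshold)
    log_note = math.log2(note_threshold)
    records: list[CalibrationRecord] = []
    for site, row in glyco.iterrows():
        protein = str(row["protein_id"])
        gfold = float(row["fold_change"])
        rec = CalibrationRecord(protein_id=protein, site=str(site), glyco_fold=gfold)
        pfold = protein_folds.get(protein)
        if pfold is None:
            rec.status = UNMATCHED
        elif pfold <= 0:
            rec.protein_fold = float(pfold)
            rec.error = "nonpositive_protein_fold"
        else:
            rec.protein_fold = float(pfold)
            rec.calibrated_fold = gfold / pfold
            mag = abs(math.log2(rec.calibrated_fold))
            if mag >= log_retain:
                rec.status = RETAINED
            elif mag >= log_note:
                rec.status = RETAINED
                rec.near_threshold = True
            else:
                rec.status = EXPLAINED
        records.append(rec)
    return records


def calibration_summary(records: Sequence[CalibrationRecord]) -> dict:
    """Protein-level accounting of a calibration run.

    A protein is matched if any of its sites was calibrated; retained if
    any site was retained; otherwise explained. ``retained_percent`` is
    100 * retained / matched (None, flagged, when nothing matched).
    """
    by_protein: dict[str, list[CalibrationRecord]] = {}
    for rec in records:
        if rec.error is not None:
            continue
        by_protein.setdefault(rec.protein_id, []).append(rec)
    n_matched = n_retained = n_explained = n_unmatched = n_near = 0
    for recs in by_protein.values():
        statuses = {r.status for r in recs}
        if statuses <= {UNMATCHED}:
            n_unmatched += 1
            continue
        n_matched += 1
        if RETAINED in statuses:
            n_retained += 1
            if any(r.near_threshold for r in recs if r.status == RETAINED):
                n_near += 1
        else:
            n_explained += 1
    summary = {
        "n_altered": len(by_protein),
        "n_matched": n_matched,
        "n_unmatched": n_unmatched,
        "n_retained": n_retained,
        "n_explained": n_explained,
        "n_near_threshold": n_near,
        "retained_percent": (
            100.0 * n_retained / n_matched if n_matched else None
        ),
    }
    return summary


def records_to_frame(records: Sequence[CalibrationRecord]) -> pd.DataFrame:
    """Tabular view of calibration records (one row per site)."""
    return pd.DataFrame(
        [
            {
                "protein_id": r.protein_id,
                "site": r.site,
                "glyco_fold": r.glyco_fold,
                "protein_fold": r.protein_fold,
                "calibrated_fold": r.calibrated_fold,
                "status": r.status,
                "near_threshold": r.near_threshold,
                "error": r.error,
            }
            for r in records
        ]
    )
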