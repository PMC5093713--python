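"""Multiplexed label-free quantitation.

Each pairwise comparison of two cell lines considers a site *comparable*
when it has >=2 non-missing replicates with replicate CV <= 20% in *both*
lines and carries no variable-modification (oxidation/acetylation) flag.
Fold change is the ratio of mean-normalized replicate means; calls use an
inclusive >=2-fold gate in either direction. Per-protein categories roll
site calls up (up / down / both / unchanged), and the voting rule marks a
site a *general* alteration when it is called in one consistent direction
in at least k of the comparisons and never in the opposite direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import IntensityMatrix


@dataclass(frozen=True)
class ComparisonSpec:
    """One pairwise comparison: numerator line, denominator line, gates."""

    line_a: str
    line_b: str
    fold_threshold: float = 2.0
    cv_threshold: float = 0.20

    def __post_init__(self) -> None:
        if self.line_a == self.line_b:
            raise ValueError("line_a and line_b must differ")
        if self.fold_threshold < 1:
            raise ValueError("fold_threshold must be >= 1")
        if not 0 < self.cv_threshold <= 1:
            raise ValueError("cv_threshold must be in (0, 1]")


@dataclass
class ComparisonResult:
    """Per-site fold changes and calls, per-protein categories, and counts."""

    spec: ComparisonSpec
    sites: pd.DataFrame  # index site; protein_id, means, cvs, fold_change, call, comparable
    protein_categories: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))
    counts: dict = field(default_factory=dict)


def mean_normalize(matrix: IntensityMatrix) -> IntensityMatrix:
    """Scale each run by one factor so all run means (over non-missing
    features) equal the grand mean of run means; missing stays missing."""
    out = matrix.copy()
    run_means = out.values.mean(axis=0, skipna=True)
    if run_means.isna().any() or (run_means <= 0).any():
        bad = run_means.index[run_means.isna() | (run_means <= 0)].tolist()
        raise ValueError(f"run(s) with no usable intensities: {bad}")
    grand = run_means.mean()
    out.values = out.values * (grand / run_means)
    return out


def compare(matrix: IntensityMatrix, spec: ComparisonSpec) -> ComparisonResult:
    """Run one pairwise comparison on an (already normalized) matrix."""
    for line in (spec.line_a, spec.line_b):
        if line not in matrix.lines:
            raise ValueError(f"cell line {line!r} not present in the matrix")
        if len(matrix.runs_of_line(line)) < 2:
            raise ValueError(f"cell line {line!r} has fewer than 2 replicates")

    def line_stats(line: str) -> tuple[pd.Series, pd.Series, pd.Series]:
        vals = matrix.line_values(line)
        n = vals.notna().sum(axis=1)
        mean = vals.mean(axis=1)
        cv = vals.std(axis=1, ddof=1) / mean
        return n, mean, cv

    n_a, mean_a, cv_a = line_stats(spec.line_a)
    n_b, mean_b, cv_b = line_stats(spec.line_b)
    if matrix.features is not None and "varmod_flag" in matrix.features:
        varmod = matrix.features["varmod_flag"].astype(bool)
    else:
        varmod = pd.Series(False, index=matrix.values.index)
    comparable = (
        (n_a >= 2)
        & (n_b >= 2)
        & (cv_a <= spec.cv_threshold)
        & (cv_b <= spec.cv_threshold)
        & ~varmod
    )
    fold = mean_a / mean_b
    call = pd.Series("unchanged", index=matrix.values.index, dtype=object)
    call[comparable & (fold >= spec.fold_threshold)] = "up"
    call[comparable & (fold <= 1.0 / spec.fold_threshold)] = "down"
    call[~comparable] = pd.NA
    sites = pd.DataFrame(
        {
            "protein_id": (
                matrix.features["protein_id"]
                if matrix.features is not None and "protein_id" in matrix.features
                else pd.Series(matrix.values.index, index=matrix.values.index)
            ),
            "mean_a": mean_a,
            "mean_b": mean_b,
            "cv_a": cv_a,
            "cv_b": cv_b,
            "fold_change": fold.where(comparable),
            "call": call,
            "comparable": comparable,
        }
    )
    result = ComparisonResult(spec=spec, sites=sites)
    result.protein_categories = protein_rollup(sites)
    result.counts = _count(sites, result.protein_categories)
    return result


def protein_rollup(sites: pd.DataFrame) -> pd.Series:
    """Collapse site calls to protein categories.

    up: >=1 up site, no down sites; down symmetrically; both: >=1 of each;
    unchanged: comparable sites but no calls. Only comparable sites count.
    """
    comp = sites[sites["comparable"]]
    categories = {}
    for protein, grp in comp.groupby("protein_id"):
        calls = set(grp["call"])
        has_up, has_down = "up" in calls, "down" in calls
        if has_up and has_down:
            categories[protein] = "both"
        elif has_up:
            categories[protein] = "up"
        elif has_down:
            categories[protein] = "down"
        else:
            categories[protein] = "unchanged"
    return pd.Series(categories, dtype=object).sort_index()


def _count(sites: pd.DataFrame, categories: pd.Series) -> dict:
    comp = sites[sites["comparable"]]
    cat_counts = categories.value_counts().to_dict()
    n_proteins = len(categories)
    n_altered = sum(cat_counts.get(c, 0) for c in ("up", "down", "both"))
    return {
        "n_comparable_sites": int(len(comp)),
        "n_sites_up": int((comp["call"] == "up").sum()),
        "n_sites_down": int((comp["call"] == "down").sum()),
        "n_sites_unchanged": int((comp["call"] == "unchanged").sum()),
        "n_comparable_proteins": n_proteins,
        "n_proteins_up": int(cat_counts.get("up", 0)),
        "n_proteins_down": int(cat_counts.get("down", 0)),
        "n_proteins_both": int(cat_counts.get("both", 0)),
        "n_proteins_altered": int(n_altered),
        "pct_proteins_altered": (
            100.0 * n_altered / n_proteins if n_proteins else float("nan")
        ),
    }


@dataclass
class VotingResult:
    """Per-site vote tallies across comparisons and the qualifying set."""

    table: pd.DataFrame  # index site; n_up, n_down, n_called, qualifies, direction
    k: int
    require_consistency: bool

    @property
    def qualifying(self) -> pd.DataFrame:
        return self.table[self.table["qualifies"]]


def general_alterations(
    results: Sequence[ComparisonResult],
    k: int = 5,
    require_consistency: bool = True,
) -> VotingResult:
    """Vote a site a general alteration when called >=k times in one direction.

    With ``require_consistency`` (default) any opposite-direction call
    disqualifies the site; switched off, a site qualifies whenever either
    direction reaches k (the majority direction is reported).
    """
    if results and k > len(results):
        raise ValueError("k cannot exceed the number of comparisons")
    calls = pd.DataFrame({i: r.sites["call"] for i, r in enumerate(results)})
    n_up = (calls == "up").sum(axis=1)
    n_down = (calls == "down").sum(axis=1)
    if require_consistency:
        qualifies = ((n_up >= k) & (n_down == 0)) | ((n_down >= k) & (n_up == 0))
    else:
        qualifies = (n_up >= k) | (n_down >= k)
    direction = pd.Series(pd.NA, index=calls.index, dtype=object)
    direction[qualifies & (n_up >= n_down)] = "up"
    direction[qualifies & (n_down > n_up)] = "down"
    table = pd.DataFrame(
        {
            "n_up": n_up,
            "n_down": n_down,
            "n_called": n_up + n_down,
            "qualifies": qualifies,
            "direction": direction,
        }
    )
    return VotingResult(table=table, k=k, require_consistency=require_consistency)


def altered_sites(result: ComparisonResult) -> pd.DataFrame:
    """Sites called up or down in one comparison, with their fold changes."""
    mask = result.sites["call"].isin(["up", "down"])
    out = result.sites.loc[mask, ["protein_id", "fold_change", "call"]].copy()
    out.index.name = "site"
    return out


def log2_fold(fold: float) -> float:
    return math.log2(fold)
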