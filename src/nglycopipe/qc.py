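"""Dataset quality control: replicate correlations, detection breakdown,
coefficient-of-variation profile, and cell-line clustering.

Correlations are computed on log2 intensities over features co-observed in
both runs (scale-invariant); CVs are computed on the linear scale as
sample standard deviation over mean, the convention under which a "CV <=
20%" reproducibility gate is stated.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

from .containers import IntensityMatrix


def _pearson(x: pd.Series, y: pd.Series, min_shared: int = 3) -> tuple[float, int]:
    mask = x.notna() & y.notna()
    n = int(mask.sum())
    if n < min_shared:
        return float("nan"), n
    xv, yv = x[mask].to_numpy(float), y[mask].to_numpy(float)
    sx, sy = xv.std(ddof=1), yv.std(ddof=1)
    if sx == 0 or sy == 0:
        return float("nan"), n
    return float(np.corrcoef(xv, yv)[0, 1]), n


def run_correlations(matrix: IntensityMatrix, min_shared: int = 3) -> pd.DataFrame:
    """Pearson r on log2 intensities for every unordered run pair.

    Pairs sharing fewer than ``min_shared`` co-observed features get r = NaN
    (flagged, never fabricated). Returns a table with run_a, run_b, the
    lines they belong to, r and the co-observation count.
    """
    logv = matrix.log2()
    rows = []
    for a, b in combinations(logv.columns, 2):
        r, n = _pearson(logv[a], logv[b], min_shared)
        rows.append(
            {
                "run_a": a,
                "run_b": b,
                "line_a": matrix.runs.loc[a, "cell_line"],
                "line_b": matrix.runs.loc[b, "cell_line"],
                "r": r,
                "n_shared": n,
            }
        )
    return pd.DataFrame(rows)


def replicate_correlations(matrix: IntensityMatrix) -> dict[str, list[float]]:
    """Within-line (replicate) pairwise correlations, per cell line."""
    corr = run_correlations(matrix)
    same = corr[corr["line_a"] == corr["line_b"]]
    return {
        line: sorted(grp["r"].dropna().tolist())
        for line, grp in same.groupby("line_a")
    }


def cross_line_correlations(matrix: IntensityMatrix) -> dict[tuple[str, str], float]:
    """Pearson r between line-mean log2 profiles for every line pair."""
    means = matrix.line_mean_log2()
    out: dict[tuple[str, str], float] = {}
    for a, b in combinations(means.columns, 2):
        out[(a, b)] = _pearson(means[a], means[b])[0]
    return out


def detection_breakdown(matrix: IntensityMatrix) -> pd.DataFrame:
    """Per line, the fraction of detected features seen in 3 / 2 / 1 replicates.

    A feature enters a line's denominator if detected in >=1 of its
    replicates; each feature falls in exactly one bin, so the fractions sum
    to 1. With more than three replicates the "3" bin covers >=3.
    """
    rows = []
    for line in matrix.lines:
        counts = matrix.line_values(line).notna().sum(axis=1)
        counts = counts[counts >= 1]
        denom = len(counts)
        rows.append(
            {
                "cell_line": line,
                "n_detected": denom,
                "frac_3": float((counts >= 3).sum() / denom) if denom else float("nan"),
                "frac_2": float((counts == 2).sum() / denom) if denom else float("nan"),
                "frac_1": float((counts == 1).sum() / denom) if denom else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("cell_line")


def cv_profile(
    matrix: IntensityMatrix, threshold: float = 0.20
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-feature replicate CV per line, plus the fraction <= ``threshold``.

    CV = sample (n-1) standard deviation / mean of linear-scale replicate
    intensities, defined only where >=2 replicates are non-missing and the
    mean is positive; the pass fraction is taken over defined CVs.
    """
    cvs = {}
    fractions = {}
    for line in matrix.lines:
        vals = matrix.line_values(line)
        n = vals.notna().sum(axis=1)
        mean = vals.mean(axis=1)
        sd = vals.std(axis=1, ddof=1)
        cv = sd / mean
        cv[(n < 2) | (mean <= 0)] = np.nan
        cvs[line] = cv
        defined = cv.dropna()
        fractions[line] = (
            float((defined <= threshold).sum() / len(defined))
            if len(defined)
            else float("nan")
        )
    return pd.DataFrame(cvs), fractions


def cluster_cell_lines(
    matrix: IntensityMatrix,
) -> tuple[np.ndarray, list[str]]:
    """Average-linkage hierarchical clustering of cell lines.

    Distance is 1 - Pearson r between line-mean log2 profiles (co-observed
    features only). Lines are ordered lexicographically before linkage so
    the result is independent of input column order; ties break
    deterministically. Returns (scipy linkage matrix, line labels).
    """
    labels = sorted(matrix.lines)
    if len(labels) < 3:
        raise ValueError("clustering requires >=3 cell lines")
    means = matrix.line_mean_log2()[labels]
    dist = np.zeros((len(labels), len(labels)))
    for i, j in combinations(range(len(labels)), 2):
        r, _ = _pearson(means[labels[i]], means[labels[j]])
        d = 1.0 - r if r == r else 2.0
        dist[i, j] = dist[j, i] = max(d, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    return z, labels


def linkage_to_newick(z: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage tree as a Newick string with branch lengths."""
    tree = to_tree(z)

    def render(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return render(tree, tree.dist) + ";"


@dataclass
class QCReport:
    """Bundle of the quality-control outputs for one intensity matrix."""

    replicate_correlations: dict[str, list[float]]
    cross_line_correlations: dict[tuple[str, str], float]
    detection: pd.DataFrame
    cv_fractions: dict[str, float]
    cv_threshold: float
    linkage: np.ndarray
    linkage_labels: list[str]

    def summary(self) -> dict[str, float]:
        rep = [r for rs in self.replicate_correlations.values() for r in rs]
        return {
            "replicate_r_min": min(rep) if rep else float("nan"),
            "replicate_r_max": max(rep) if rep else float("nan"),
            "median_frac_3_replicates": float(self.detection["frac_3"].median()),
            "cv_pass_fraction_min": min(self.cv_fractions.values()),
            "cv_pass_fraction_max": max(self.cv_fractions.values()),
        }


def qc_report(matrix: IntensityMatrix, cv_threshold: float = 0.20) -> QCReport:
    """Compute the full QC report for an intensity matrix."""
    z, labels = cluster_cell_lines(matrix)
    _, cv_fracs = cv_profile(matrix, cv_threshold)
    return QCReport(
        replicate_correlations=replicate_correlations(matrix),
        cross_line_correlations=cross_line_correlations(matrix),
        detection=detection_breakdown(matrix),
        cv_fractions=cv_fracs,
        cv_threshold=cv_threshold,
        linkage=z,
        linkage_labels=labels,
    )
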