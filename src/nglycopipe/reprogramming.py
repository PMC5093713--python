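"""Imperfect-reprogramming state classification from expression data.

Reprogramming a somatic cell (SC) to an induced pluripotent stem cell
(hiPSC) should move each gene's expression to the embryonic stem cell
(hESC) level. Comparing the three group means classifies each gene whose
hiPSC-vs-hESC difference is significant into one of four imperfect-
reprogramming states:

* incomplete silencing (somatic memory):  hiPSC > hESC and SC > hESC
* over-silencing:                         hiPSC < hESC and SC > hESC
* incomplete reactivation:                hiPSC < hESC and SC < hESC
* over-reactivation:                      hiPSC > hESC and SC < hESC

Equality in either governing comparison, or a non-significant test, yields
``unchanged``. Upstream, probes in the bottom intensity quantile of every
sample are discarded and redundant probes per gene are collapsed to the
one with the highest total intensity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix

logger = logging.getLogger(__name__)

STATES = (
    "incomplete_silencing",
    "over_silencing",
    "incomplete_reactivation",
    "over_reactivation",
    "unchanged",
)


def filter_probes(matrix: ExpressionMatrix, quantile: float = 0.20) -> ExpressionMatrix:
    """Drop probes lying in the bottom ``quantile`` of every sample.

    The cut is each sample's own ``quantile`` intensity; a probe is removed
    only if it falls strictly below that cut in all samples, so quantile 0
    removes nothing.
    """
    if not 0 <= quantile < 1:
        raise ValueError("quantile must be in [0, 1)")
    cuts = matrix.values.quantile(quantile, axis=0)
    removed = (matrix.values < cuts).all(axis=1)
    out = matrix.copy()
    out.values = out.values.loc[~removed]
    return out


def collapse_probes(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Collapse redundant probes: keep, per gene, the probe with the highest
    total intensity across samples (ties: lexicographically smaller probe id).

    Probes without a gene mapping are dropped (count logged). The returned
    matrix is indexed by gene symbol.
    """
    mapped = matrix.values.index.intersection(matrix.probe_map.index)
    n_dropped = len(matrix.values.index) - len(mapped)
    if n_dropped:
        logger.info("dropped %d probes without gene mapping", n_dropped)
    values = matrix.values.loc[mapped]
    totals = values.sum(axis=1)
    choice = (
        pd.DataFrame(
            {
                "gene": matrix.probe_map.loc[mapped].to_numpy(),
                "total": totals.to_numpy(),
                "probe": mapped,
            }
        )
        .sort_values(["gene", "total", "probe"], ascending=[True, False, True])
        .drop_duplicates("gene", keep="first")
    )
    collapsed = values.loc[choice["probe"]]
    collapsed.index = pd.Index(choice["gene"].to_numpy(), name="gene")
    out = matrix.copy()
    out.values = collapsed
    out.probe_map = pd.Series(choice["probe"].to_numpy(), index=collapsed.index)
    return out


def differential_test(
    matrix: ExpressionMatrix,
    group_a: list[str] | None = None,
    group_b: list[str] | None = None,
) -> pd.DataFrame:
    """Two-sided Welch t-test on log2 expression, per gene.

    Defaults pool all hiPSC samples against all hESC samples. Genes with
    zero variance in both groups get t = 0, p = 1 when the means are equal
    (and the smallest positive p when they differ, rather than an exact 0).
    """
    if group_a is None:
        group_a = matrix.samples_of_type("hiPSC")
    if group_b is None:
        group_b = matrix.samples_of_type("hESC")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >=2 samples")
    log = np.log2(matrix.values)
    a = log[group_a].to_numpy(float)
    b = log[group_b].to_numpy(float)
    import warnings

    with warnings.catch_warnings():
        # constant genes trigger a harmless precision warning; handled below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    degenerate = ~np.isfinite(t)
    equal_means = np.isclose(a.mean(axis=1), b.mean(axis=1))
    t = np.where(degenerate, np.where(equal_means, 0.0, np.inf), t)
    p = np.where(
        degenerate, np.where(equal_means, 1.0, np.nextafter(0.0, 1.0)), p
    )
    p = np.clip(p, np.nextafter(0.0, 1.0), 1.0)
    return pd.DataFrame({"t": t, "p": p}, index=matrix.values.index)


def classify_state(
    mean_ipsc: float, mean_esc: float, mean_sc: float, significant: bool
) -> str:
    """Assign the imperfect-reprogramming state from the three group means.

    Non-significant genes, or genes where either governing comparison is an
    exact tie, are ``unchanged``; the four states partition the strict
    inequality sign combinations.
    """
    if not significant:
        return "unchanged"
    if mean_ipsc > mean_esc and mean_sc > mean_esc:
        return "incomplete_silencing"
    if mean_ipsc < mean_esc and mean_sc > mean_esc:
        return "over_silencing"
    if mean_ipsc < mean_esc and mean_sc < mean_esc:
        return "incomplete_reactivation"
    if mean_ipsc > mean_esc and mean_sc < mean_esc:
        return "over_reactivation"
    return "unchanged"


@dataclass
class ReprogrammingCall:
    """Per-gene group means, test result, and assigned state."""

    gene: str
    mean_ipsc: float
    mean_esc: float
    mean_sc: float
    t_statistic: float
    p_value: float
    state: str


def classify_genes(
    matrix: ExpressionMatrix,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Classify every gene of a (filtered, collapsed) expression matrix.

    Group means are means of log2 expression over all samples of each cell
    type; significance is the pooled hiPSC-vs-hESC Welch test at ``alpha``.
    Returns a table {gene, mean_ipsc, mean_esc, mean_sc, t, p, state}.
    """
    log = np.log2(matrix.values)
    means = {
        ct: log[matrix.samples_of_type(ct)].mean(axis=1)
        for ct in ("hiPSC", "hESC", "SC")
    }
    tests = differential_test(matrix)
    states = [
        classify_state(
            means["hiPSC"].iloc[i],
            means["hESC"].iloc[i],
            means["SC"].iloc[i],
            bool(tests["p"].iloc[i] < alpha),
        )
        for i in range(len(matrix.values))
    ]
    return pd.DataFrame(
        {
            "mean_ipsc": means["hiPSC"],
            "mean_esc": means["hESC"],
            "mean_sc": means["SC"],
            "t": tests["t"],
            "p": tests["p"],
            "state": states,
        },
        index=matrix.values.index,
    )
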