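"""Recovery benchmarks of the pipeline against planted synthetic truth.

These routines quantify how well each stage recovers what the generator
planted: sensitivity and false-call rate of the >=2-fold + CV-gate +
voting quantitation chain, and the recovery rate of planted imperfect-
reprogramming states. They are Monte-Carlo evaluations over multiple
generator seeds, not fits.
"""

from __future__ import annotations

from dataclasses import replace

from .design import ExperimentDesign, default_design
from .quant import ComparisonSpec, compare, general_alterations, mean_normalize
from .reprogramming import STATES, classify_genes, collapse_probes, filter_probes
from .synthetic import TruthConfig, simulate_expression, simulate_glyco_experiment


def quantitation_recovery(
    design: ExperimentDesign | None = None,
    cfg: TruthConfig | None = None,
    n_seeds: int = 20,
    base_seed: int = 0,
    vote_k: int = 5,
    fold_threshold: float = 2.0,
    cv_threshold: float = 0.20,
) -> dict:
    """Sensitivity / false-call rate of the voting quantitation chain.

    For each seed a fresh experiment is simulated; the hiPSC-vs-hESC
    comparisons are run on the normalized matrix and voted with ``k``.
    Sensitivity counts planted altered sites recovered with the planted
    direction; the false-call rate counts clean unplanted sites that
    qualify anyway.
    """
    design = design or default_design()
    cfg = cfg or TruthConfig(n_proteins=100)
    n_true = n_recovered = n_null = n_false = 0
    for i in range(n_seeds):
        run_cfg = replace(cfg, seed=base_seed + 10_000 + i)
        _, matrix, truth = simulate_glyco_experiment(design, run_cfg)
        normalized = mean_normalize(matrix)
        results = [
            compare(
                normalized,
                ComparisonSpec(a, b, fold_threshold, cv_threshold),
            )
            for a, b in truth.target_pairs
        ]
        voting = general_alterations(results, k=vote_k)
        qualifying = voting.qualifying
        for site, direction in truth.altered_sites.items():
            n_true += 1
            if site in qualifying.index and qualifying.loc[site, "direction"] == direction:
                n_recovered += 1
        null_sites = set(truth.clean_sites) - set(truth.altered_sites)
        n_null += len(null_sites)
        n_false += sum(site in qualifying.index for site in null_sites)
    return {
        "sensitivity": n_recovered / n_true if n_true else float("nan"),
        "false_call_rate": n_false / n_null if n_null else float("nan"),
        "n_planted": n_true,
        "n_null": n_null,
        "n_seeds": n_seeds,
    }


def state_recovery(
    design: ExperimentDesign | None = None,
    genes_per_state: int = 15,
    n_genes: int = 200,
    seed: int = 0,
    margin: float = 1.0,
    noise_sd: float = 0.2,
    probe_quantile: float = 0.20,
    alpha: float = 0.05,
) -> dict:
    """Fraction of planted reprogramming states recovered end to end."""
    design = design or default_design()
    real_states = [s for s in STATES if s != "unchanged"]
    planted = {
        f"{s.upper()}_{i:02d}": s for s in real_states for i in range(genes_per_state)
    }
    matrix = simulate_expression(
        design, planted, n_genes=n_genes, seed=seed, margin=margin, noise_sd=noise_sd
    )
    collapsed = collapse_probes(filter_probes(matrix, probe_quantile))
    calls = classify_genes(collapsed, alpha=alpha)
    genes = [g for g in planted if g in calls.index]
    recovered = sum(calls.loc[g, "state"] == planted[g] for g in genes)
    # planted genes lost to probe filtering count as misses
    return {
        "recovery": recovered / len(planted) if planted else float("nan"),
        "n_planted": len(planted),
        "n_classified": len(genes),
    }
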