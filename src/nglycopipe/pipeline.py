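"""End-to-end orchestration: simulate -> identify -> qc -> quantify ->
calibrate -> network -> reprogram, under a single master seed.

A master seed deterministically derives one sub-seed per stage, so a stage
re-run in isolation reproduces its part of a full run, and two full runs
with the same configuration produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calibration as cal
from . import identification as ident
from . import network as net
from . import qc as qcmod
from . import quant
from . import reprogramming as reprog
from . import synthetic
from .design import CellLine, ExperimentDesign, default_comparison_plan, default_design
from .io import (
    matrix_to_table,
    sha256_file,
    write_expression,
    write_fasta,
    write_tsv,
)

logger = logging.getLogger(__name__)

STAGES = (
    "db",
    "glyco",
    "proteome",
    "expression",
    "network",
    "randomization",
    "genesets",
)


def derive_stage_seeds(master_seed: int) -> dict[str, int]:
    """One reproducible sub-seed (< 2^31) per pipeline stage."""
    state = np.random.SeedSequence(master_seed).generate_state(len(STAGES))
    return {stage: int(s % (2**31)) for stage, s in zip(STAGES, state)}


@dataclass
class RunConfig:
    """All inputs and thresholds of one pipeline run."""

    design: ExperimentDesign = field(default_factory=default_design)
    comparisons: list[tuple[str, str]] | None = None  # None -> default 19-pair plan
    truth: synthetic.TruthConfig = field(default_factory=synthetic.TruthConfig)
    min_score: float = 50.0
    min_prob: float = 0.8
    min_prob_replicates: int = 2
    cv_threshold: float = 0.20
    fold_threshold: float = 2.0
    note_threshold: float = 1.75
    vote_k: int = 5
    confidence_threshold: float = 0.7
    n_random: int = 1000
    probe_quantile: float = 0.20
    alpha: float = 0.05
    calibration_pair: tuple[str, str] | None = None  # None -> first hiPSC/hESC pair
    expression_genes_per_state: int = 10
    expression_n_genes: int = 300
    network_n_nodes: int = 200
    plurinet_size: int = 45
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.comparisons is None:
            self.comparisons = default_comparison_plan(self.design)
        if self.calibration_pair is None:
            self.calibration_pair = (
                self.design.lines_of_type("hiPSC")[0],
                self.design.lines_of_type("hESC")[0],
            )
        self.validate()

    def validate(self) -> None:
        lines = set(self.design.line_names)
        for a, b in list(self.comparisons) + [self.calibration_pair]:
            if a not in lines or b not in lines:
                raise ValueError(f"comparison ({a}, {b}) references undefined cell line")
        checks = {
            "min_prob": 0 <= self.min_prob <= 1,
            "cv_threshold": 0 < self.cv_threshold <= 1,
            "fold_threshold": self.fold_threshold >= 1,
            "note_threshold": 1 < self.note_threshold <= self.fold_threshold,
            "vote_k": 1 <= self.vote_k <= len(self.hipsc_hesc_comparisons()),
            "confidence_threshold": 0 <= self.confidence_threshold <= 1,
            "n_random": self.n_random >= 1,
            "probe_quantile": 0 <= self.probe_quantile < 1,
            "alpha": 0 < self.alpha < 1,
            "min_score": np.isfinite(self.min_score),
        }
        bad = [k for k, ok in checks.items() if not ok]
        if bad:
            raise ValueError(f"config values out of domain: {bad}")

    def hipsc_hesc_comparisons(self) -> list[tuple[str, str]]:
        return [
            (a, b)
            for a, b in self.comparisons
            if self.design.cell_type_of(a) == "hiPSC"
            and self.design.cell_type_of(b) == "hESC"
        ]

    # -- (de)serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["design"] = {
            "n_replicates": self.design.n_replicates,
            "cell_lines": [
                {"name": cl.name, "cell_type": cl.cell_type, "parent": cl.parent}
                for cl in self.design.cell_lines
            ],
        }
        d["comparisons"] = [list(c) for c in self.comparisons]
        d["calibration_pair"] = list(self.calibration_pair)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "design" in d:
            dd = d["design"]
            d["design"] = ExperimentDesign(
                cell_lines=tuple(
                    CellLine(c["name"], c["cell_type"], c.get("parent"))
                    for c in dd["cell_lines"]
                ),
                n_replicates=dd.get("n_replicates", 3),
            )
        if d.get("comparisons") is not None:
            d["comparisons"] = [tuple(c) for c in d["comparisons"]]
        if d.get("calibration_pair") is not None:
            d["calibration_pair"] = tuple(d["calibration_pair"])
        if "truth" in d and isinstance(d["truth"], dict):
            d["truth"] = synthetic.TruthConfig(**d["truth"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _planted_expression_states(config: RunConfig) -> dict[str, str]:
    states = {}
    real_states = [s for s in reprog.STATES if s != "unchanged"]
    for state in real_states:
        for i in range(config.expression_genes_per_state):
            states[f"{state.upper()}_{i + 1:02d}"] = state
    return states


def run_all(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the full pipeline into ``outdir``; returns the run report.

    The report holds per-stage summaries plus a SHA-256 checksum of every
    file written, and is itself written as ``report.json``.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = derive_stage_seeds(config.master_seed)
    report: dict = {"master_seed": config.master_seed, "stages": {}}
    written: list[Path] = []

    def emit(name: str, df: pd.DataFrame, index: bool = True) -> Path:
        path = outdir / name
        write_tsv(df, path, index=index)
        written.append(path)
        return path

    # --- simulate -------------------------------------------------------------
    logger.info("stage: simulate")
    db, sequon_truth = synthetic.generate_protein_db(
        config.truth.n_proteins, config.truth.mean_protein_length, seeds["db"]
    )
    fasta_path = outdir / "proteins.fasta"
    write_fasta(db, fasta_path)
    written.append(fasta_path)
    emit("sequon_truth.tsv", sequon_truth, index=False)
    truth_cfg = replace(config.truth, seed=seeds["glyco"])
    table, _, truth = synthetic.simulate_glyco_experiment(config.design, truth_cfg, db=db)
    table_path = emit("glycosites.tsv", table, index=False)
    report["stages"]["simulate"] = {
        "n_rows": int(len(table)),
        "n_planted_altered_sites": len(truth.altered_sites),
    }

    # --- identify -------------------------------------------------------------
    logger.info("stage: identify")
    records = ident.parse_site_table(table_path)
    filtered = ident.filter_records(
        records,
        design=config.design,
        min_score=config.min_score,
        min_prob=config.min_prob,
        min_prob_replicates=config.min_prob_replicates,
    )
    db_map = {rec.id: str(rec.seq) for rec in db}
    valid, tally, excluded = ident.validate_sites(filtered, db_map)
    emit(
        "excluded_sites.tsv",
        pd.DataFrame(excluded, columns=["site", "reason"]),
        index=False,
    )
    summary = ident.summarize_identifications(valid, config.design, tally)
    emit("identification_per_line.tsv", summary.per_line)
    report["stages"]["identify"] = {
        "n_parsed": len(records),
        "n_after_filters": len(filtered),
        "n_sequon_valid": len(valid),
        "residue_tally": summary.residue_tally,
        "overlap_hipsc_hesc": summary.overlap_hipsc_hesc,
        "overlap_all_types": summary.overlap_all_types,
    }

    # --- qc -------------------------------------------------------------------
    logger.info("stage: qc")
    matrix = ident.records_to_matrix(valid, config.design)
    qc = qcmod.qc_report(matrix, cv_threshold=config.cv_threshold)
    emit("qc_detection.tsv", qc.detection)
    emit(
        "qc_cv_fractions.tsv",
        pd.DataFrame(
            sorted(qc.cv_fractions.items()), columns=["cell_line", "frac_cv_pass"]
        ),
        index=False,
    )
    newick_path = outdir / "qc_dendrogram.nwk"
    newick_path.write_text(qcmod.linkage_to_newick(qc.linkage, qc.linkage_labels) + "\n")
    written.append(newick_path)
    report["stages"]["qc"] = {k: v for k, v in qc.summary().items()}

    # --- quantify -------------------------------------------------------------
    logger.info("stage: quantify")
    normalized = quant.mean_normalize(matrix)
    results: dict[tuple[str, str], quant.ComparisonResult] = {}
    counts_rows = []
    all_sites = []
    for a, b in config.comparisons:
        spec = quant.ComparisonSpec(
            a, b, fold_threshold=config.fold_threshold, cv_threshold=config.cv_threshold
        )
        res = quant.compare(normalized, spec)
        results[(a, b)] = res
        counts_rows.append({"line_a": a, "line_b": b, **res.counts})
        sites = res.sites[res.sites["comparable"]].copy()
        sites.insert(0, "line_b", b)
        sites.insert(0, "line_a", a)
        all_sites.append(sites)
    emit("comparison_counts.tsv", pd.DataFrame(counts_rows), index=False)
    emit("comparison_sites.tsv", pd.concat(all_sites), index=True)
    vote_results = [results[p] for p in config.hipsc_hesc_comparisons()]
    voting = quant.general_alterations(vote_results, k=config.vote_k)
    emit("general_alterations.tsv", voting.qualifying)
    report["stages"]["quantify"] = {
        "n_comparisons": len(results),
        "n_general_alteration_sites": int(len(voting.qualifying)),
        "mean_pct_altered_hipsc_hesc": float(
            np.mean(
                [results[p].counts["pct_proteins_altered"]
                 for p in config.hipsc_hesc_comparisons()]
            )
        ),
    }

    # --- calibrate ------------------------------------------------------------
    logger.info("stage: calibrate")
    pair = config.calibration_pair
    proteome = synthetic.simulate_proteome(
        truth, config.design, seed=seeds["proteome"],
        replicate_cv=config.truth.replicate_cv,
    )
    emit("proteome.tsv", matrix_to_table(proteome))
    glyco_altered = quant.altered_sites(results[pair])
    protein_folds = cal.protein_fold_changes(proteome, *pair)
    cal_records = cal.calibrate(
        glyco_altered,
        protein_folds,
        retain_threshold=config.fold_threshold,
        note_threshold=config.note_threshold,
    )
    emit("calibration.tsv", cal.records_to_frame(cal_records), index=False)
    cal_summary = cal.calibration_summary(cal_records)
    report["stages"]["calibrate"] = cal_summary
    retained_proteins = sorted(
        {
            r.protein_id
            for r in cal_records
            if r.status == cal.RETAINED and r.error is None
        }
    )

    # --- network --------------------------------------------------------------
    logger.info("stage: network")
    gene_of = (
        matrix.features["gene_symbol"].groupby(matrix.features["protein_id"]).first()
    )
    candidates = sorted({str(gene_of.get(p, p)) for p in retained_proteins})
    edges, planted = synthetic.simulate_network(
        n_nodes=config.network_n_nodes,
        plurinet_size=config.plurinet_size,
        candidates=candidates,
        planted_links=len(candidates),
        seed=seeds["network"],
        confidence_threshold=config.confidence_threshold,
    )
    truth.candidate_plurinet_links = planted
    emit("network_edges.tsv", edges, index=False)
    plurinet = [f"PLURI{i + 1:03d}" for i in range(config.plurinet_size)]
    subnet = net.build_subnetwork(
        candidates, plurinet, edges, threshold=config.confidence_threshold
    )
    metrics = net.randomization_test(
        subnet, n_random=config.n_random, seed=seeds["randomization"]
    )
    universe = sorted(set(edges["node_a"]) | set(edges["node_b"]))
    fisher_p, fisher_table = net.fisher_overlap(
        candidates, plurinet, universe, edges, threshold=config.confidence_threshold
    )
    gene_sets = synthetic.simulate_gene_sets(
        universe,
        seed=seeds["genesets"],
        planted={"PLURIPOTENCY_MODULE": set(plurinet) | set(candidates)},
    )
    subnet_genes = list(subnet.graph.nodes)
    enrichment = net.enrich_pathways(subnet_genes, gene_sets, universe)
    emit("network_enrichment.tsv", enrichment, index=False)
    report["stages"]["network"] = {
        "n_candidates_in_subnetwork": len(subnet.candidates),
        "n_plurinet_in_subnetwork": len(subnet.plurinet_nodes),
        "clustering_coefficient": metrics.clustering_coefficient,
        "mean_shortest_path": metrics.mean_shortest_path,
        "empirical_p_clustering": metrics.empirical_p_clustering,
        "empirical_p_path": metrics.empirical_p_path,
        "fisher_p": fisher_p,
        "fisher_table": fisher_table.tolist(),
    }

    # --- reprogram ------------------------------------------------------------
    logger.info("stage: reprogram")
    planted_states = _planted_expression_states(config)
    truth.reprogramming_states = planted_states
    expression = synthetic.simulate_expression(
        config.design,
        planted_states,
        n_genes=config.expression_n_genes,
        seed=seeds["expression"],
    )
    for p in write_expression(expression, outdir / "expression").values():
        written.append(p)
    filtered_expr = reprog.filter_probes(expression, quantile=config.probe_quantile)
    collapsed = reprog.collapse_probes(filtered_expr)
    calls = reprog.classify_genes(collapsed, alpha=config.alpha)
    emit("reprogramming_calls.tsv", calls)
    planted_genes = [g for g in planted_states if g in calls.index]
    n_recovered = sum(
        calls.loc[g, "state"] == planted_states[g] for g in planted_genes
    )
    report["stages"]["reprogram"] = {
        "n_genes_classified": int(len(calls)),
        "n_planted": len(planted_genes),
        "state_recovery": (
            n_recovered / len(planted_genes) if planted_genes else float("nan")
        ),
        "state_counts": calls["state"].value_counts().to_dict(),
    }

    # --- report ---------------------------------------------------------------
    report["checksums"] = {p.name: sha256_file(p) for p in sorted(written)}
    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    logger.info("run complete: %s", report_path)
    return report
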