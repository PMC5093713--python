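"""Synthetic-data generators with planted ground truth.

Every pipeline input can be generated here with a known truth: protein
sequences with enumerable sequons, a MaxQuant-style glycosite table with
planted fold changes between cell-type groups, a matched proteome table
with planted protein-level (explained-by-protein) changes, an expression
matrix with planted imperfect-reprogramming states, and a confidence-
scored interaction network with planted candidate–PluriNet links.

Intensities are generated in log2 space with normal replicate noise of
standard deviation cv / ln 2 (so the linear-scale coefficient of variation
approximates the configured ``replicate_cv`` for small CV) and exported on
the linear scale. Missingness is missing-at-random at the run level.
Decoy rows use MaxQuant-style ``REV__``/``CON__`` identifier prefixes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, IntensityMatrix, runs_metadata
from .design import ExperimentDesign
from .identification import find_sequons
from .reprogramming import STATES

# residue alphabet with frequencies boosted for N/S/T so sequons occur at a
# realistic density (roughly one per 60 residues)
_ALPHABET = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_WEIGHTS = np.array(
    [7, 1, 5, 6, 4, 7, 2, 5, 5, 9, 2, 6, 5, 4, 5, 6, 10, 6, 1, 3], dtype=float
)
_WEIGHTS /= _WEIGHTS.sum()

LOG2E_SD_PER_CV = 1.0 / math.log(2.0)  # log2-space sd per unit CV


@dataclass(frozen=True)
class TruthConfig:
    """Parameters of the planted statistical structure of a glyco experiment.

    ``planted_log2fc`` is the hiPSC-vs-hESC effect planted on altered sites
    (default log2(2.5): comfortably past the 2-fold call threshold);
    ``frac_altered`` defaults to the typical fraction of glycoproteins
    altered between hiPSC and hESC lines; ``frac_sc_altered`` plants the
    much larger PSC-vs-SC divergence that drives the two-cluster structure
    of the panel; ``replicate_cv`` targets the mostly-<=20% replicate CV
    regime of a well-behaved label-free run.
    """

    n_proteins: int = 150
    mean_protein_length: int = 300
    mean_sites_per_protein: float = 1.8
    frac_altered: float = 0.17
    planted_log2fc: float = math.log2(2.5)
    frac_sc_altered: float = 0.43
    replicate_cv: float = 0.10
    missing_rate: float = 0.05
    decoy_rate: float = 0.05
    varmod_rate: float = 0.05
    loc_fail_rate: float = 0.10
    baseline_log2: float = 23.0
    baseline_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if self.mean_protein_length < 20:
            raise ValueError("mean_protein_length must be >= 20")
        for name in (
            "frac_altered",
            "frac_sc_altered",
            "missing_rate",
            "decoy_rate",
            "varmod_rate",
            "loc_fail_rate",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.replicate_cv < 0:
            raise ValueError("replicate_cv must be >= 0")


@dataclass
class SyntheticTruth:
    """Everything planted into one synthetic experiment."""

    planted_log2fc: float
    target_pairs: list[tuple[str, str]]  # (hiPSC line, hESC line) pairs
    altered_sites: dict[str, str] = field(default_factory=dict)  # site -> up|down
    sc_altered_sites: dict[str, str] = field(default_factory=dict)
    site_protein: dict[str, str] = field(default_factory=dict)
    clean_sites: list[str] = field(default_factory=list)
    protein_level_changes: dict[str, float] = field(default_factory=dict)
    explained_proteins: set[str] = field(default_factory=set)
    matched_proteins: set[str] = field(default_factory=set)
    reprogramming_states: dict[str, str] = field(default_factory=dict)
    candidate_plurinet_links: list[tuple[str, str]] = field(default_factory=list)

    @property
    def altered_proteins(self) -> dict[str, str]:
        """Protein -> direction; proteins with conflicting site directions
        are labelled 'both'."""
        out: dict[str, str] = {}
        for site, direction in self.altered_sites.items():
            protein = self.site_protein[site]
            prev = out.get(protein)
            if prev is None:
                out[protein] = direction
            elif prev != direction:
                out[protein] = "both"
        return out


def generate_protein_db(
    n_proteins: int, mean_length: int = 300, seed: int = 0
) -> tuple[list, pd.DataFrame]:
    """Random protein database plus its exhaustive sequon truth table.

    Returns (Biopython SeqRecords with ids SYNP0001..., DataFrame with one
    row per sequon: protein_id, position, x_residue, third_residue). The
    same arguments always yield byte-identical records.
    """
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    if mean_length < 20:
        raise ValueError("mean_length must be >= 20")
    rng = np.random.default_rng(seed)
    records = []
    truth_rows = []
    for i in range(n_proteins):
        pid = f"SYNP{i + 1:04d}"
        length = max(20, int(rng.poisson(mean_length)))
        seq = "".join(rng.choice(_ALPHABET, size=length, p=_WEIGHTS))
        records.append(SeqRecord(Seq(seq), id=pid, description=""))
        for hit in find_sequons(seq):
            truth_rows.append(
                {
                    "protein_id": pid,
                    "position": hit.position,
                    "x_residue": hit.x_residue,
                    "third_residue": hit.third_residue,
                }
            )
    truth = pd.DataFrame(
        truth_rows, columns=["protein_id", "position", "x_residue", "third_residue"]
    )
    return records, truth


def _window(seq: str, pos: int, flank: int = 6) -> str:
    left = seq[max(0, pos - 1 - flank) : pos - 1].rjust(flank, "_")
    right = seq[pos : pos + flank].ljust(flank, "_")
    return left + seq[pos - 1] + right


def simulate_glyco_experiment(
    design: ExperimentDesign, cfg: TruthConfig, db: list | None = None
) -> tuple[pd.DataFrame, IntensityMatrix, SyntheticTruth]:
    """Simulate a full glycosite table for a cell-line panel.

    Planted hiPSC-vs-hESC alterations of ``cfg.planted_log2fc`` log2 units
    are applied to a ``cfg.frac_altered`` fraction of the clean, plantable
    sites (non-decoy, no variable-modification flag, passing localization
    gates); an independent ``cfg.frac_sc_altered`` fraction receives an
    SC-group shift. Returns (tab-delimited-ready table, intensity matrix
    over all rows, truth object).
    """
    if not design.cell_lines:
        raise ValueError("empty design")
    ss = np.random.SeedSequence(cfg.seed)
    db_seed = int(ss.generate_state(1)[0] % (2**31))
    rng = np.random.default_rng(ss.spawn(1)[0])
    if db is None:
        db, _ = generate_protein_db(cfg.n_proteins, cfg.mean_protein_length, db_seed)
    sequences = {rec.id: str(rec.seq) for rec in db}

    runs = design.run_ids()
    hipsc = design.lines_of_type("hiPSC")
    hesc = design.lines_of_type("hESC")
    sc = design.lines_of_type("SC")
    target_pairs = [(a, b) for a in hipsc for b in hesc]
    truth = SyntheticTruth(planted_log2fc=cfg.planted_log2fc, target_pairs=target_pairs)

    # choose sites on true sequons
    rows: list[dict] = []
    for pid, seq in sequences.items():
        hits = find_sequons(seq)
        if not hits:
            continue
        k = min(len(hits), 1 + rng.poisson(max(cfg.mean_sites_per_protein - 1, 0.0)))
        chosen = rng.choice(len(hits), size=k, replace=False)
        for idx in sorted(chosen):
            hit = hits[idx]
            pos = hit.position
            rows.append(
                {
                    "protein_id": pid,
                    "gene_symbol": pid.replace("SYNP", "GENE"),
                    "position": pos,
                    "sequence_window": _window(seq, pos),
                    "peptide": seq[max(0, pos - 6) : pos + 7],
                }
            )
    n_rows = len(rows)

    decoy = rng.random(n_rows) < cfg.decoy_rate
    varmod = rng.random(n_rows) < cfg.varmod_rate
    loc_fail = rng.random(n_rows) < cfg.loc_fail_rate
    fail_by_score = rng.random(n_rows) < 0.5

    site_ids: list[str] = []
    for i, row in enumerate(rows):
        if decoy[i]:
            prefix = "REV__" if rng.random() < 0.5 else "CON__"
            row["protein_id"] = prefix + row["protein_id"]
            row["gene_symbol"] = ""
            row["reverse_flag"] = int(prefix == "REV__")
            row["contaminant_flag"] = int(prefix == "CON__")
        else:
            row["reverse_flag"] = 0
            row["contaminant_flag"] = 0
        row["varmod_flag"] = int(varmod[i])
        if loc_fail[i] and fail_by_score[i]:
            row["localization_score"] = round(float(rng.uniform(5, 45)), 2)
        else:
            row["localization_score"] = round(float(rng.uniform(60, 180)), 2)
        if loc_fail[i] and not fail_by_score[i]:
            probs = rng.uniform(0.05, 0.75, size=len(runs))
        else:
            probs = rng.uniform(0.85, 1.0, size=len(runs))
        for run, p in zip(runs, probs):
            row[f"localization_prob_{run}"] = round(float(p), 3)
        site_ids.append(f"{row['protein_id']}@{row['position']}")
        truth.site_protein[site_ids[-1]] = row["protein_id"]

    plantable = [
        i for i in range(n_rows) if not (decoy[i] or varmod[i] or loc_fail[i])
    ]
    truth.clean_sites = [site_ids[i] for i in plantable]
    n_altered = round(cfg.frac_altered * len(plantable))
    altered_idx = (
        rng.choice(plantable, size=n_altered, replace=False) if n_altered else []
    )
    directions = rng.random(n_altered) < 0.5
    line_shift: dict[int, dict[str, float]] = {}
    for j, i in enumerate(altered_idx):
        sign = 1.0 if directions[j] else -1.0
        truth.altered_sites[site_ids[i]] = "up" if sign > 0 else "down"
        line_shift[i] = {ln: sign * cfg.planted_log2fc for ln in hipsc}
    n_sc = round(cfg.frac_sc_altered * len(plantable))
    sc_idx = rng.choice(plantable, size=n_sc, replace=False) if n_sc else []
    sc_dirs = rng.random(n_sc) < 0.5
    for j, i in enumerate(sc_idx):
        sign = 1.0 if sc_dirs[j] else -1.0
        truth.sc_altered_sites[site_ids[i]] = "up" if sign > 0 else "down"
        shifts = line_shift.setdefault(i, {})
        for ln in sc:
            shifts[ln] = shifts.get(ln, 0.0) + sign * cfg.planted_log2fc

    baselines = rng.normal(cfg.baseline_log2, cfg.baseline_sd, size=n_rows)
    sigma = cfg.replicate_cv * LOG2E_SD_PER_CV
    noise = rng.normal(0.0, sigma, size=(n_rows, len(runs)))
    missing = rng.random((n_rows, len(runs))) < cfg.missing_rate
    values = np.empty((n_rows, len(runs)))
    for j, run in enumerate(runs):
        line = design.run_line(run)
        for i in range(n_rows):
            mu = baselines[i] + line_shift.get(i, {}).get(line, 0.0)
            values[i, j] = 2.0 ** (mu + noise[i, j])
    values[missing] = np.nan

    for i, row in enumerate(rows):
        for j, run in enumerate(runs):
            v = values[i, j]
            row[f"intensity_{run}"] = "" if np.isnan(v) else f"{v:.6g}"
    prob_cols = [f"localization_prob_{r}" for r in runs]
    intensity_cols = [f"intensity_{r}" for r in runs]
    columns = (
        [
            "protein_id",
            "gene_symbol",
            "position",
            "sequence_window",
            "peptide",
            "localization_score",
        ]
        + prob_cols
        + ["contaminant_flag", "reverse_flag", "varmod_flag"]
        + intensity_cols
    )
    table = pd.DataFrame(rows, columns=columns)

    matrix = IntensityMatrix(
        values=pd.DataFrame(values, index=pd.Index(site_ids, name="site"), columns=runs),
        runs=runs_metadata(design),
        features=pd.DataFrame(
            {
                "protein_id": [r["protein_id"] for r in rows],
                "gene_symbol": [r["gene_symbol"] for r in rows],
                "varmod_flag": [bool(r["varmod_flag"]) for r in rows],
            },
            index=pd.Index(site_ids, name="site"),
        ),
    )
    return table, matrix, truth


def simulate_proteome(
    truth: SyntheticTruth,
    design: ExperimentDesign,
    match_fraction: float = 0.742,
    explained_fraction: float = 0.087,
    seed: int = 0,
    replicate_cv: float = 0.10,
    n_background: int = 60,
    baseline_log2: float = 24.0,
) -> IntensityMatrix:
    """Simulate the matched whole-proteome quantitation table.

    ``match_fraction`` of the glyco-altered proteins appear in the table;
    of those, ``explained_fraction`` get a protein-level change equal to
    their glyco change (planted explained-by-protein cases, recorded in
    ``truth``); the rest of the matched and all background proteins stay
    flat. Defaults reflect a typical matched-proteome coverage (~74%
    matched, ~9% of matched explained).
    """
    if not 0 <= match_fraction <= 1:
        raise ValueError("match_fraction must be in [0, 1]")
    if not 0 <= explained_fraction <= 1:
        raise ValueError("explained_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    altered = truth.altered_proteins
    proteins = sorted(altered)
    n_match = round(match_fraction * len(proteins))
    matched = sorted(rng.choice(proteins, size=n_match, replace=False)) if n_match else []
    consistent = [p for p in matched if altered[p] != "both"]
    n_explained = min(round(explained_fraction * n_match), len(consistent))
    explained = (
        sorted(rng.choice(consistent, size=n_explained, replace=False))
        if n_explained
        else []
    )
    truth.matched_proteins = set(matched)
    truth.explained_proteins = set(explained)

    hipsc = set(design.lines_of_type("hiPSC"))
    all_proteins = list(matched) + [f"BGPR{i + 1:04d}" for i in range(n_background)]
    runs = design.run_ids()
    sigma = replicate_cv * LOG2E_SD_PER_CV
    values = np.empty((len(all_proteins), len(runs)))
    for i, protein in enumerate(all_proteins):
        base = rng.normal(baseline_log2, 1.5)
        if protein in truth.explained_proteins:
            sign = 1.0 if altered[protein] == "up" else -1.0
            lfc = sign * truth.planted_log2fc
        else:
            lfc = 0.0
        truth.protein_level_changes[protein] = lfc
        for j, run in enumerate(runs):
            mu = base + (lfc if design.run_line(run) in hipsc else 0.0)
            values[i, j] = 2.0 ** (mu + rng.normal(0.0, sigma))
    return IntensityMatrix(
        values=pd.DataFrame(
            values, index=pd.Index(all_proteins, name="protein_id"), columns=runs
        ),
        runs=runs_metadata(design),
    )


_STATE_PATTERN = {
    # (hiPSC offset, hESC offset, SC offset) in units of the margin
    "incomplete_silencing": (1.0, 0.0, 1.0),
    "over_silencing": (-1.0, 0.0, 1.0),
    "incomplete_reactivation": (-1.0, 0.0, -1.0),
    "over_reactivation": (1.0, 0.0, -1.0),
    "unchanged": (0.0, 0.0, 0.0),
}


def simulate_expression(
    design: ExperimentDesign,
    planted_states: Mapping[str, str],
    n_genes: int = 500,
    seed: int = 0,
    margin: float = 1.0,
    noise_sd: float = 0.2,
    n_replicates: int = 2,
    duplicate_frac: float = 0.10,
    low_probe_frac: float = 0.10,
    base_log2: float = 8.0,
) -> ExpressionMatrix:
    """Simulate a probes x samples expression matrix with planted states.

    Each planted gene's (hiPSC, hESC, SC) group means satisfy its state's
    inequality pattern with the given log2 ``margin``; filler genes are
    flat. ``duplicate_frac`` of genes get a redundant lower-intensity
    probe, and ``low_probe_frac`` extra probes sit at the bottom of every
    sample's intensity range to exercise probe filtering.
    """
    for gene, state in planted_states.items():
        if state not in STATES:
            raise ValueError(f"unknown state {state!r} for gene {gene!r}")
    if len(planted_states) > n_genes:
        raise ValueError("n_genes must cover the planted genes")
    rng = np.random.default_rng(seed)
    genes = list(planted_states) + [
        f"FILLER{i + 1:04d}" for i in range(n_genes - len(planted_states))
    ]
    samples = [
        f"{ln}_{r}" for ln in design.line_names for r in range(1, n_replicates + 1)
    ]
    sample_type = {
        s: design.cell_type_of(s.rpartition("_")[0]) for s in samples
    }

    probe_rows = []
    probe_ids = []
    probe_genes = []
    for i, gene in enumerate(genes):
        state = planted_states.get(gene, "unchanged")
        off = _STATE_PATTERN[state]
        base = rng.normal(base_log2, 1.0)
        means = {
            "hiPSC": base + off[0] * margin,
            "hESC": base + off[1] * margin,
            "SC": base + off[2] * margin,
        }
        row = [
            means[sample_type[s]] + rng.normal(0.0, noise_sd) for s in samples
        ]
        probe_rows.append(row)
        probe_ids.append(f"PR{i + 1:05d}A")
        probe_genes.append(gene)
        if rng.random() < duplicate_frac:
            probe_rows.append([v - 0.5 + rng.normal(0.0, noise_sd) for v in row])
            probe_ids.append(f"PR{i + 1:05d}B")
            probe_genes.append(gene)
    n_low = round(low_probe_frac * n_genes)
    for i in range(n_low):
        probe_rows.append(list(rng.normal(2.0, 0.1, size=len(samples))))
        probe_ids.append(f"PRLOW{i + 1:04d}")
        probe_genes.append(f"LOWGENE{i + 1:04d}")

    values = pd.DataFrame(
        2.0 ** np.array(probe_rows),
        index=pd.Index(probe_ids, name="probe_id"),
        columns=samples,
    )
    meta = pd.DataFrame(
        {
            "cell_line": [s.rpartition("_")[0] for s in samples],
            "cell_type": [sample_type[s] for s in samples],
            "replicate": [int(s.rpartition("_")[2]) for s in samples],
        },
        index=pd.Index(samples, name="sample"),
    )
    probe_map = pd.Series(probe_genes, index=values.index, name="gene_symbol")
    return ExpressionMatrix(values=values, samples=meta, probe_map=probe_map)


def simulate_network(
    n_nodes: int = 200,
    plurinet_size: int = 45,
    candidates: Sequence[str] = (),
    planted_links: int = 16,
    seed: int = 0,
    confidence_threshold: float = 0.7,
    background_degree: float = 4.0,
    module_density: float = 0.05,
    clique_size: int = 5,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Simulate a confidence-scored edge list with planted candidate–PluriNet links.

    Exactly ``planted_links`` candidate–PluriNet edges carry confidence
    above the threshold (assigned round-robin over candidates, so k links
    over >=k candidates touch k distinct candidates); no background edge
    joins a candidate to a PluriNet node. The PluriNet seed set gets a
    triangle-rich module: a tiling of ``clique_size``-cliques (protein
    complexes) plus sparse ``module_density`` cross-links, so its observed
    clustering exceeds degree-preserving-null expectation.
    Returns (edge list, planted link list).
    """
    cand = [str(c).upper() for c in candidates]
    if plurinet_size + len(cand) > n_nodes:
        raise ValueError("plurinet_size + candidates exceeds n_nodes")
    if planted_links > len(cand) * plurinet_size:
        raise ValueError("more planted links than candidate-PluriNet pairs")
    if planted_links > 0 and not cand:
        raise ValueError("planted links require candidates")
    rng = np.random.default_rng(seed)
    pluri = [f"PLURI{i + 1:03d}" for i in range(plurinet_size)]
    n_other = n_nodes - plurinet_size - len(cand)
    other = [f"OTHER{i + 1:04d}" for i in range(n_other)]

    edges: dict[tuple[str, str], float] = {}

    def add(a: str, b: str, conf: float) -> None:
        key = (a, b) if a < b else (b, a)
        edges[key] = conf

    # candidate links target the first few complexes so the induced
    # subnetwork retains co-complex (triangle-forming) PluriNet nodes
    target_pool = pluri[: min(plurinet_size, 2 * clique_size)]
    planted: list[tuple[str, str]] = []
    used: dict[str, set[str]] = {c: set() for c in cand}
    for j in range(planted_links):
        c = cand[j % len(cand)]
        free = [p for p in target_pool if p not in used[c]] or [
            p for p in pluri if p not in used[c]
        ]
        p = free[int(rng.integers(len(free)))]
        used[c].add(p)
        add(c, p, round(float(rng.uniform(0.75, 0.99)), 3))
        planted.append((c, p))

    for start in range(0, plurinet_size, max(clique_size - 1, 1)):
        clique = pluri[start : start + clique_size]
        for i in range(len(clique)):
            for j in range(i + 1, len(clique)):
                add(clique[i], clique[j], round(float(rng.uniform(0.7, 0.99)), 3))
    for i in range(plurinet_size):
        for j in range(i + 1, plurinet_size):
            if rng.random() < module_density:
                add(pluri[i], pluri[j], round(float(rng.uniform(0.7, 0.99)), 3))

    nodes = cand + pluri + other
    cand_set, pluri_set = set(cand), set(pluri)
    n_background = round(background_degree * n_nodes / 2)
    attempts = 0
    while n_background > 0 and attempts < 50 * n_background:
        attempts += 1
        i, j = rng.integers(len(nodes)), rng.integers(len(nodes))
        a, b = nodes[int(i)], nodes[int(j)]
        if a == b:
            continue
        if (a in cand_set and b in pluri_set) or (b in cand_set and a in pluri_set):
            continue  # keep the planted candidate-PluriNet link count exact
        key = (a, b) if a < b else (b, a)
        if key in edges:
            continue
        edges[key] = round(float(rng.uniform(0.4, 0.95)), 3)
        n_background -= 1

    table = pd.DataFrame(
        [(a, b, c) for (a, b), c in sorted(edges.items())],
        columns=["node_a", "node_b", "confidence"],
    )
    return table, planted


def simulate_gene_sets(
    universe: Iterable[str],
    n_sets: int = 10,
    set_size: int = 30,
    seed: int = 0,
    planted: Mapping[str, Iterable[str]] | None = None,
) -> dict[str, set[str]]:
    """Random gene sets over a universe, plus optional planted sets."""
    rng = np.random.default_rng(seed)
    uni = sorted({str(u).upper() for u in universe})
    sets: dict[str, set[str]] = {}
    for i in range(n_sets):
        k = min(set_size, len(uni))
        members = rng.choice(uni, size=k, replace=False)
        sets[f"RANDOM_SET_{i + 1:02d}"] = set(map(str, members))
    for name, members in (planted or {}).items():
        sets[str(name)] = {str(m).upper() for m in members}
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path) -> None:
    """Write gene sets in GMT format (name, description, members)."""
    lines = [
        "\t".join([name, "synthetic"] + sorted(map(str, members)))
        for name, members in sets.items()
    ]
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")
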