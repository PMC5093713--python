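"""Sequon scanning, table parsing, and identification filters."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nglycopipe.design import CellLine, ExperimentDesign
from nglycopipe.identification import (
    FormatError,
    GlycoSiteRecord,
    filter_records,
    find_sequons,
    parse_site_table,
    summarize_identifications,
    validate_sites,
)

TWO_LINE_DESIGN = ExperimentDesign(
    cell_lines=(CellLine("A", "hiPSC"), CellLine("B", "hESC")),
    n_replicates=3,
)
RUNS = TWO_LINE_DESIGN.run_ids()


def brute_force_sequons(seq: str) -> list[int]:
    """Independent oracle: literal triple scan."""
    seq = seq.upper()
    out = []
    for i in range(len(seq)):
        if (
            i + 2 < len(seq)
            and seq[i] == "N"
            and seq[i + 1] in "ACDEFGHIKLMNQRSTVWY"
            and seq[i + 2] in "STC"
        ):
            out.append(i + 1)
    return out


class TestFindSequons:
    @pytest.mark.parametrize(
        "seq, positions",
        [
            ("ANGTA", [2]),
            ("ANPSA", []),  # X = P never glycosylated
            ("NNSS", [1, 2]),  # overlapping sequons both count
            ("NGT", [1]),
            ("NGTNA", [1]),  # truncated second motif at the terminus
            ("NXT", []),  # unknown letter never matches
            ("NN", []),  # too short to complete a sequon
            ("NGC", [1]),  # rare N-X-C sequon counts
        ],
    )
    def test_examples(self, seq, positions):
        assert [h.position for h in find_sequons(seq)] == positions

    def test_hit_fields_obey_the_motif(self):
        for hit in find_sequons("ANGTANCSANQCA"):
            assert hit.x_residue != "P"
            assert hit.third_residue in "STC"

    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWYX", max_size=60))
    @settings(max_examples=300, derandomize=True)
    def test_agrees_with_brute_force_scan(self, seq):
        assert [h.position for h in find_sequons(seq)] == brute_force_sequons(seq)


def _record(**kw) -> GlycoSiteRecord:
    base = dict(
        protein_id="P1",
        gene_symbol="G1",
        position=2,
        peptide="ANGTA",
        sequence_window="ANGTA",
        localization_score=100.0,
        localization_probs={r: 0.95 for r in RUNS},
        intensities={r: 10.0 for r in RUNS},
    )
    base.update(kw)
    return GlycoSiteRecord(**base)


class TestFilterRecords:
    def test_reverse_and_contaminant_removed(self):
        records = [_record(), _record(reverse_flag=True), _record(contaminant_flag=True)]
        assert filter_records(records, TWO_LINE_DESIGN) == [records[0]]

    def test_score_threshold_inclusive(self):
        below = _record(localization_score=49.9)
        at = _record(localization_score=50.0)
        assert filter_records([below, at], TWO_LINE_DESIGN) == [at]

    def test_probability_gate_needs_two_replicates_in_one_line(self):
        probs_2of3 = {"A_1": 0.85, "A_2": 0.85, "A_3": 0.5, "B_1": 0.5, "B_2": 0.5, "B_3": 0.5}
        probs_1per_line = {"A_1": 0.85, "A_2": 0.5, "A_3": 0.5, "B_1": 0.85, "B_2": 0.5, "B_3": 0.5}
        kept = _record(localization_probs=probs_2of3)
        dropped = _record(localization_probs=probs_1per_line)
        assert filter_records([kept, dropped], TWO_LINE_DESIGN) == [kept]
        # across-runs mode counts the two scattered passes together
        assert filter_records([dropped], TWO_LINE_DESIGN, per_line=False) == [dropped]

    def test_probability_threshold_inclusive(self):
        rec = _record(localization_probs={r: 0.8 for r in RUNS})
        assert filter_records([rec], TWO_LINE_DESIGN) == [rec]

    def test_idempotent(self, sim, design):
        import nglycopipe.identification as ident

        records = [
            ident.GlycoSiteRecord(
                protein_id=row["protein_id"],
                gene_symbol=row["gene_symbol"],
                position=int(row["position"]),
                peptide=row["peptide"],
                sequence_window=row["sequence_window"],
                localization_score=float(row["localization_score"]),
                localization_probs={
                    r: float(row[f"localization_prob_{r}"]) for r in design.run_ids()
                },
                contaminant_flag=bool(row["contaminant_flag"]),
                reverse_flag=bool(row["reverse_flag"]),
                varmod_flag=bool(row["varmod_flag"]),
            )
            for _, row in sim["table"].iterrows()
        ]
        once = filter_records(records, design)
        twice = filter_records(once, design)
        assert twice == once
        assert len(once) < len(records)  # decoys and low-quality rows removed


class TestParseSiteTable(object):
    HEADER = (
        "protein_id\tgene_symbol\tposition\tsequence_window\tpeptide\t"
        "localization_score\tlocalization_prob\tcontaminant_flag\t"
        "reverse_flag\tvarmod_flag\tintensity_A_1\tintensity_A_2"
    )

    def _write(self, tmp_path, rows, header=None):
        path = tmp_path / "sites.tsv"
        path.write_text("\n".join([header or self.HEADER] + rows) + "\n")
        return path

    def test_parses_rows_and_missing_intensities(self, tmp_path):
        rows = [
            "P1\tG1\t2\tANGTA\tANGTA\t100\t0.9\t0\t0\t0\t10\t12",
            "P2\tG2\t5\tNNSSA\tNNSSA\t80\t0.85\t0\t0\t0\t\t8",
            "P3\tG3\t7\tQNGSV\tQNGSV\t60\t0.95\t0\t1\t0\t5\t5",
        ]
        records = parse_site_table(self._write(tmp_path, rows))
        assert len(records) == 3
        assert records[1].intensities["A_1"] != records[1].intensities["A_1"]  # NaN
        assert records[1].intensities["A_2"] == 8.0
        assert records[2].reverse_flag
        # single-column probability is broadcast to every run
        assert records[0].localization_probs == {"A_1": 0.9, "A_2": 0.9}

    def test_missing_required_column_is_named(self, tmp_path):
        header = self.HEADER.replace("localization_score\t", "")
        row = "P1\tG1\t2\tANGTA\tANGTA\t0.9\t0\t0\t0\t10\t12"
        with pytest.raises(FormatError, match="localization_score"):
            parse_site_table(self._write(tmp_path, [row], header=header))

    def test_non_numeric_intensity_reports_line(self, tmp_path):
        rows = [
            "P1\tG1\t2\tANGTA\tANGTA\t100\t0.9\t0\t0\t0\t10\t12",
            "P2\tG2\t5\tNNSSA\tNNSSA\t80\t0.85\t0\t0\t0\toops\t8",
        ]
        with pytest.raises(FormatError, match="line 3"):
            parse_site_table(self._write(tmp_path, rows))


class TestValidateSites:
    DB = {"P1": "ANGTA", "P2": "ANPSA"}

    def test_true_sequon_valid_and_tallied(self):
        rec = _record(protein_id="P1", position=2)
        valid, tally, excluded = validate_sites([rec], self.DB)
        assert valid == [rec]
        assert tally == {"T": 1, "S": 0, "C": 0}
        assert excluded == []

    def test_n_p_s_site_rejected(self):
        rec = _record(protein_id="P2", position=2)
        valid, tally, excluded = validate_sites([rec], self.DB)
        assert valid == []
        assert excluded == [("P2@2", "not_a_sequon")]

    def test_unknown_protein_listed_not_fatal(self):
        rec = _record(protein_id="PX", position=2)
        valid, _, excluded = validate_sites([rec], self.DB)
        assert valid == []
        assert excluded == [("PX@2", "protein_not_in_database")]

    def test_tally_sums_to_valid_count_on_synthetic(self, sim):
        import numpy as np

        from nglycopipe.synthetic import generate_protein_db

        cfg = sim["cfg"]
        db_seed = int(np.random.SeedSequence(cfg.seed).generate_state(1)[0] % (2**31))
        db, _ = generate_protein_db(cfg.n_proteins, cfg.mean_protein_length, db_seed)
        db_map = {r.id: str(r.seq) for r in db}
        records = [
            _record(protein_id=row["protein_id"], position=int(row["position"]))
            for _, row in sim["table"].iterrows()
        ]
        valid, tally, excluded = validate_sites(records, db_map)
        assert sum(tally.values()) == len(valid)
        assert len(valid) + len(excluded) == len(records)


class TestSummarize:
    def _recs(self, line_values):
        # one protein per record; detected where intensity present
        recs = []
        for pid, lines in line_values.items():
            intens = {}
            for ln in lines:
                for rep in (1, 2, 3):
                    intens[f"{ln}_{rep}"] = 5.0
            recs.append(_record(protein_id=pid, intensities=intens))
        return recs

    def test_identical_sets_overlap_fully(self):
        recs = self._recs({"P1": ["A", "B"], "P2": ["A", "B"]})
        s = summarize_identifications(recs, TWO_LINE_DESIGN)
        assert s.overlap_hipsc_hesc == 2

    def test_disjoint_sets_overlap_zero(self):
        recs = self._recs({"P1": ["A"], "P2": ["B"]})
        s = summarize_identifications(recs, TWO_LINE_DESIGN)
        assert s.overlap_hipsc_hesc == 0
        assert s.sites_in_one_line == 2

    def test_nine_line_overlaps_match_set_algebra(self, sim, design):
        from nglycopipe.identification import records_to_matrix

        matrix = sim["matrix"]
        # oracle by exhaustive set operations over the detection pattern
        detected = matrix.values.notna()
        per_line_prot: dict[str, set] = {}
        for line in design.line_names:
            cols = [f"{line}_{r}" for r in range(1, 4)]
            mask = detected[cols].any(axis=1)
            per_line_prot[line] = set(
                matrix.features.loc[mask[mask].index, "protein_id"]
            )
        union = lambda t: set().union(
            *(per_line_prot[ln] for ln in design.lines_of_type(t))
        )
        expected_overlap = len(union("hiPSC") & union("hESC"))
        recs = []
        for site, row in matrix.features.iterrows():
            pid, pos = site.rsplit("@", 1)
            recs.append(
                _record(
                    protein_id=row["protein_id"],
                    position=int(pos),
                    intensities={
                        run: (
                            float(matrix.values.loc[site, run])
                            if detected.loc[site, run]
                            else math.nan
                        )
                        for run in matrix.values.columns
                    },
                )
            )
        s = summarize_identifications(recs, design)
        assert s.overlap_hipsc_hesc == expected_overlap
        assert (s.per_line["n_proteins"] >= 0).all()
        assert s.sites_in_two_plus >= s.sites_in_seven_plus
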